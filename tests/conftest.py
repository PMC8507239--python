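import numpy as np
import pytest

from sagbin import simulate
from sagbin.seqio import AssemblyKind, Contig, GenomeAssembly
from sagbin.simulate import CommunitySpec, _random_seq


def make_assembly(seqs: dict[str, str], kind=AssemblyKind.REFERENCE,
                  aid: str = "asm") -> GenomeAssembly:
    return GenomeAssembly(aid, [Contig(k, v) for k, v in seqs.items()], kind)


def random_seq(seed: int, length: int, gc: float = 0.5) -> str:
    return _random_seq(np.random.default_rng(seed), length, gc)


def mutate(seq: str, rate: float, seed: int) -> str:
    out, _ = simulate._mutate(np.random.default_rng(seed), seq, rate)
    return out


@pytest.fixture(scope="session")
def small_community() -> simulate.SyntheticCommunity:
    """3 species of 60 kb, one strain pair at 1.5% divergence with plasmids."""
    spec = CommunitySpec(n_species=3, genome_len=60_000,
                         strain_pairs=[(0, 0.015, (12_000, 10_000))], seed=1234)
    return simulate.generate_references(spec)
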