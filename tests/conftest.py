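import numpy as np
import pytest

from mthet import datasets, peak_calls
from mthet.haplotyping import Alignment
from mthet.trace_sim import HaplotypeSeq, MixtureState

POSITIONS_16S = (365, 580)
POSITIONS_COI = (240, 264, 303, 375)


@pytest.fixture(scope="session")
def table_16s() -> peak_calls.CallTable:
    return datasets.load_fixture("table2_16s")


@pytest.fixture(scope="session")
def table_coi_adults() -> peak_calls.CallTable:
    return datasets.load_fixture("table4_coi_adults")


@pytest.fixture(scope="session")
def table_coi_families() -> peak_calls.CallTable:
    return datasets.load_fixture("table5_coi_families_tissues")


@pytest.fixture(scope="session")
def all_tables() -> dict[str, peak_calls.CallTable]:
    return datasets.load_all_fixtures()


@pytest.fixture(scope="session")
def two_haplotypes() -> tuple[HaplotypeSeq, HaplotypeSeq]:
    """Two 12-bp haplotypes differing only at position 5 (T vs C)."""
    base = "ACGTATTGCAGT"
    h1 = HaplotypeSeq("H1", base[:4] + "T" + base[5:])
    h2 = HaplotypeSeq("H2", base[:4] + "C" + base[5:])
    return h1, h2


def make_mixture(f1: float) -> MixtureState:
    return MixtureState({"H1": f1, "H2": 1.0 - f1})


@pytest.fixture(scope="session")
def aln_16s() -> Alignment:
    """Surrogate 16S alignment: three haplotypes with the published site states
    at 365/442/580 (hap1 C-A-T, hap2 C-G-T, hap3 T-A-A) on a fixed random
    background, replicated 8/1/2 as in the published haplotype counts."""
    rng = np.random.default_rng(16)
    background = "".join(rng.choice(list("ACGT"), size=600))

    def variant(b365: str, b442: str, b580: str) -> str:
        s = list(background)
        s[364], s[441], s[579] = b365, b442, b580
        return "".join(s)

    haps = [
        ("hap16S-1", variant("C", "A", "T")),
        ("hap16S-2", variant("C", "G", "T")),
        ("hap16S-3", variant("T", "A", "A")),
    ]
    return Alignment.from_haplotype_counts(haps, [8, 1, 2], locus="16S")


def random_alignment(rng: np.random.Generator, n_seqs: int, length: int, n_states: int = 4) -> Alignment:
    bases = np.array(list("ACGT")[:n_states])
    seqs = ["".join(rng.choice(bases, size=length)) for _ in range(n_seqs)]
    return Alignment(ids=[f"s{i}" for i in range(n_seqs)], seqs=seqs)
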