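import numpy as np
import pytest

from lucdesign import SequenceRecord
from lucdesign.constructs import CodonTable
from lucdesign.design import EditOperation, PeptideBlock

AA = "ACDEFGHIKLMNPQRSTVWY"

#: Donor peptides and their nested cut points used in the worked design
#: example (group 1/3 donor, group 2 donor, and the 47-50 substitution).
DONOR1 = "GRCHSYEGDKDTGQGGIGEPI"
DONOR1_CUTS = (8, 15)
DONOR2 = "DRCASFADKIQKEVDYIKGLAG"
DONOR2_CUTS = (7, 14)
SERIES_NAMES = (
    "ALuc55", "ALuc56", "ALuc57",
    "ALuc60", "ALuc61", "ALuc62",
    "ALuc65", "ALuc66", "ALuc67", "ALuc68",
)


def random_peptide(rng: np.random.Generator, n: int) -> str:
    return "".join(AA[i] for i in rng.integers(0, len(AA), size=n))


@pytest.fixture(scope="session")
def codon_table() -> CodonTable:
    return CodonTable.from_tsv()


@pytest.fixture(scope="session")
def template_194() -> SequenceRecord:
    """A 194-residue protein standing in for the design template."""
    rng = np.random.default_rng(20230713)
    return SequenceRecord("template", random_peptide(rng, 194))


@pytest.fixture(scope="session")
def group1_blocks() -> list:
    frags, acc = [], ""
    prev = 0
    for cut in (*DONOR1_CUTS, len(DONOR1)):
        acc += DONOR1[prev:cut]
        frags.append(PeptideBlock(acc, 51, "donor_row_1"))
        prev = cut
    return frags


@pytest.fixture(scope="session")
def group2_blocks() -> list:
    frags, acc = [], ""
    prev = 0
    for cut in (*DONOR2_CUTS, len(DONOR2)):
        acc += DONOR2[prev:cut]
        frags.append(PeptideBlock(acc, 51, "donor_row_2"))
        prev = cut
    return frags


@pytest.fixture(scope="session")
def substitution_47_50() -> EditOperation:
    return EditOperation("substitution", 47, 50, "KWLP")
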