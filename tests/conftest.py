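import numpy as np
import pytest

from edd_screen import data_path
from edd_screen.seqio import AlignedRow, AlignmentBlock, read_fasta

AA = "ACDEFGHIKLMNPQRSTVWY"

# residues cycled so that no column of a stacked block ever reaches 60%
# coverage for any residue or similarity group
UNCONSERVED_CYCLE = ["A", "D", "K", "F", "N", "P", "C", "W", "I", "S"]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ecoli_edd():
    """The packaged E. coli EDD protein (P0ADF6)."""
    return read_fasta(data_path("P0ADF6.fasta"))[0]


@pytest.fixture(scope="session")
def reference_set():
    """Packaged EDD/DHAD reference proteins (class in group_label)."""
    return read_fasta(data_path("dehydratase_refs.fasta"))


def make_block(rows_residues, prefix="s"):
    return AlignmentBlock(
        [
            AlignedRow(id=f"{prefix}{i}", residues=res)
            for i, res in enumerate(rows_residues)
        ]
    )


@pytest.fixture()
def motif_toy_block():
    """16-column block: cols 1-7 invariant LAHGFAA, 8-11 unconserved,
    12 all D or E, 13 all K, 14-16 unconserved."""
    rows = []
    for i in range(10):
        v1 = "".join(UNCONSERVED_CYCLE[(i + j) % 10] for j in range(4))
        v2 = "".join(UNCONSERVED_CYCLE[(i + j) % 10] for j in range(3))
        de = "D" if i % 2 == 0 else "E"
        rows.append("LAHGFAA" + v1 + de + "K" + v2)
    return make_block(rows)
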