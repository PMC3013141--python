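import numpy as np
import pytest

from hydroxysite.dataset import NEGATIVE, POSITIVE, PeptideWindow, ProteinRecord
from hydroxysite.io_formats import AAIndexTable, DisorderTrack, PSSMProfile

# A 3-record miniature AAindex1 flat file, plus one record containing NA.
AAINDEX_FIXTURE = """\
H TEST0001
D alpha helix propensity (synthetic miniature)
R PMID:0000000
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.100   0.200   0.300   0.400   0.500   0.600   0.700   0.800   0.900   1.000
   1.100   1.200   1.300   1.400   1.500   1.600   1.700   1.800   1.900   2.000
//
H TEST0002
D hydrophobicity scale (synthetic miniature)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  -1.000  -0.500   0.000   0.500   1.000   1.500   2.000   2.500   3.000   3.500
   4.000   4.500   5.000   5.500   6.000   6.500   7.000   7.500   8.000   8.500
//
H TEST0003
D side-chain volume (synthetic miniature)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
  88.600 173.400 114.100 111.100 108.500 143.800 138.400  60.100 153.200 166.700
 166.700 168.600 162.900 189.900 112.700  89.000 116.100 227.800 193.600 140.000
//
H TESTNA01
D record with missing values
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   0.100   0.200      NA   0.400   0.500   0.600   0.700   0.800   0.900   1.000
   1.100   1.200   1.300   1.400   1.500   1.600   1.700   1.800   1.900   2.000
//
"""


@pytest.fixture
def aaindex_file(tmp_path):
    path = tmp_path / "aaindex.txt"
    path.write_text(AAINDEX_FIXTURE)
    return path


@pytest.fixture
def mini_table():
    """Three synthetic amino-acid indices with cluster labels."""
    rng = np.random.default_rng(7)
    table = AAIndexTable()
    for i, cluster in enumerate(
        ["hydrophobicity", "beta-propensity", "composition"], start=1
    ):
        acc = f"FIXT{i:04d}"
        table.entries[acc] = np.round(rng.normal(0, 1, 20), 3)
        table.clusters[acc] = cluster
    return table


def make_window(
    residues="ACDEFGPLMNQRS",
    label=NEGATIVE,
    protein_id="prot1",
    center=6,
    pssm_rows=None,
    disorder=None,
    seed=0,
):
    """A peptide window with deterministic random profile tracks."""
    rng = np.random.default_rng(seed)
    w = len(residues)
    if pssm_rows is None:
        pssm_rows = np.round(rng.normal(-1, 2, size=(w, 20)))
    if disorder is None:
        disorder = np.round(rng.uniform(0, 1, size=w), 4)
    return PeptideWindow(
        protein_id=protein_id,
        center=center,
        residues=residues,
        label=label,
        pssm_rows=pssm_rows,
        disorder=disorder,
    )


@pytest.fixture
def toy_record():
    """A 40-residue protein with two prolines, one annotated."""
    seq = "ACDEFGPIKLMNQRSTVWYACDEFGPIKLMNQRSTVWYAC"
    rng = np.random.default_rng(11)
    return ProteinRecord(
        id="toy1",
        sequence=seq,
        pssm=PSSMProfile(sequence=seq, scores=np.round(rng.normal(-1, 2, (40, 20)))),
        disorder=DisorderTrack(np.round(rng.uniform(0, 1, 40), 4)),
        positive_sites={6},
    )
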