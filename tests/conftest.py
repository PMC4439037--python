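import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from ephcompare.structure_io import Atom, Chain, Residue, Structure
from ephcompare import synthetic_data
from ephcompare.itc_model import ThermoParams, TitrationSchedule


@pytest.fixture(scope="session")
def reference_complex():
    """Untilted synthetic two-chain complex (the 0-degree reference)."""
    st = synthetic_data.make_tilted_complex(0.0, seed=7)
    return st.chain("R"), st.chain("L")


@pytest.fixture
def tilted_factory():
    def _make(theta: float, seed: int = 7):
        st = synthetic_data.make_tilted_complex(theta, seed=seed)
        return st.chain("R"), st.chain("L")

    return _make


@pytest.fixture
def vp_itc_schedule():
    return TitrationSchedule.vp_itc_default()


@pytest.fixture
def tight_binder_params():
    """Tight-binding exothermic one-site parameters (n=1, K_d=9 nM)."""
    return ThermoParams(n=1.0, K_a=1.0 / 9e-9, dH=-2145.0)


def make_single_atom_residue(
    chain_id: str,
    seq_num: int,
    res_name: str,
    atom_name: str,
    element: str,
    pos,
) -> Residue:
    return Residue(
        chain_id=chain_id,
        seq_num=seq_num,
        res_name=res_name,
        atoms=[Atom(atom_name, element, np.asarray(pos, float))],
    )


MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00 11.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.000  1.00 11.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.000  1.00 11.00           C
ATOM      8  O   GLY A   2       6.030   1.580   0.000  1.00 11.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA ASER A   1       1.458   0.000   0.000  0.60 10.00           C
ATOM      3  CA BSER A   1       1.500   0.100   0.000  0.40 10.00           C
ATOM      4  C   SER A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      5  O   SER A   1       1.251   2.390   0.000  1.00 10.00           O
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p
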