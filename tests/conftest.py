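import numpy as np
import pytest
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")


@pytest.fixture
def benzene():
    return Chem.MolFromSmiles("c1ccccc1")


@pytest.fixture
def toluene():
    return Chem.MolFromSmiles("Cc1ccccc1")


@pytest.fixture
def hexagon_coords():
    """Planar benzene-like hexagon, 1.4 Å bond length, atom k at angle 60k°."""
    angles = np.deg2rad(60.0 * np.arange(6))
    r = 1.4
    return np.column_stack([r * np.cos(angles), r * np.sin(angles), np.zeros(6)])


@pytest.fixture
def smi_file(tmp_path):
    p = tmp_path / "ligands.smi"
    p.write_text("ligA CCO\nligB CC(=O)[O-]\nligC c1ccccc1\n")
    return p


@pytest.fixture
def affinity_csv(tmp_path):
    p = tmp_path / "exp.csv"
    p.write_text(
        "id,dg_exp_kcal,sigma_exp_kcal\n"
        "ligA,-9.1,0.2\nligB,-10.4,0.0\nligC,-8.3,0.5\n"
    )
    return p
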