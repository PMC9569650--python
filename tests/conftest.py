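import numpy as np
import pandas as pd
import pytest

from pepshift.ensemble import ToyShiftPredictor
from pepshift.shifts import RandomCoilModel, ShiftTable


def make_shift_table(peptide_id, rows):
    """rows: iterable of (residue_index, residue_name, atom_name, shift_ppm)."""
    return ShiftTable(
        peptide_id=peptide_id,
        data=pd.DataFrame(
            rows, columns=["residue_index", "residue_name", "atom_name", "shift_ppm"]
        ),
    )


@pytest.fixture(scope="session")
def rc():
    return RandomCoilModel.from_packaged()


@pytest.fixture(scope="session")
def toy_predictor(rc):
    return ToyShiftPredictor(rc)


@pytest.fixture(scope="session")
def coil_conformer():
    """Single-model 5-residue conformer with every (phi, psi) at the coil basin center."""
    from pepshift.ensemble import ConformerEnsemble, load_basins
    from pepshift.synthetic import build_backbone

    center = load_basins()["coil"]["center"]
    n = 5
    phi = np.full(n, center[0])
    psi = np.full(n, center[1])
    coords = build_backbone(phi, psi)
    return ConformerEnsemble.from_coords(
        "coil5", np.arange(1, n + 1), ["ALA", "LYS", "MET", "ASP", "GLY"], coords[None]
    )
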