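"""File formats and run configuration.

Multi-model PDB ensembles (via biotite), tidy CSV dialects for shift
tables, temperature series, ³J couplings and R₂ rates, and the YAML run
configuration.  Residue numbering is 1-based everywhere (PDB convention);
readers enforce it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .coupling import TempSeries
from .ensemble import BACKBONE_ATOMS, ConformerEnsemble

__all__ = [
    "read_pdb_ensemble",
    "write_pdb_ensemble",
    "read_shift_csv",
    "write_shift_csv",
    "read_temp_series_csv",
    "read_jcoupling_csv",
    "read_r2_csv",
    "RunConfig",
]

from .shifts import ShiftTable


# PDB residue-name fields are 3 characters; the package's 4-letter codes
# for non-standard residues are mapped both ways without alias loss.
_TO_PDB_NAME = {"DGLU": "DGL", "HCIT": "HCI"}
_FROM_PDB_NAME = {"DGL": "DGLU", "HCI": "HCIT"}


def write_pdb_ensemble(ens: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB (MODEL/ENDMDL records)."""
    n_atoms = ens.n_residues * 4
    template = struc.AtomArray(n_atoms)
    coords = np.zeros((ens.n_models, n_atoms, 3))
    idx = 0
    for i, (res_idx, res_name) in enumerate(zip(ens.residue_indices, ens.residue_names)):
        for a, atom_name in enumerate(BACKBONE_ATOMS):
            template.chain_id[idx] = "A"
            template.res_id[idx] = int(res_idx)
            template.res_name[idx] = _TO_PDB_NAME.get(res_name, res_name)
            template.atom_name[idx] = atom_name
            template.element[idx] = atom_name[0]
            template.hetero[idx] = False
            coords[:, idx, :] = ens.coords[:, i, a, :]
            idx += 1
    stack = struc.AtomArrayStack(ens.n_models, n_atoms)
    for cat in template.get_annotation_categories():
        stack.set_annotation(cat, template.get_annotation(cat))
    stack.coord = coords
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_pdb_ensemble(
    path: str | Path, peptide_id: str | None = None, cyclic_head: bool = False
) -> ConformerEnsemble:
    """Read a multi-model PDB into a backbone ensemble.

    Requires N, CA, C and O in every residue of every model and identical
    residue composition across models; φ/ψ are derived from coordinates.
    Non-standard residue names (DGLU, HCIT, ...) pass through unchanged.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if stack.stack_depth() == 0:
        raise ValueError(f"{path}: no models found")
    first = stack[0]
    res_ids = []
    res_names = []
    atom_rows = []  # indices into the atom array, (n_res, 4)
    for res_id in np.unique(first.res_id):
        mask = first.res_id == res_id
        names_here = first.res_name[mask]
        raw_name = str(names_here[0])
        res_names.append(_FROM_PDB_NAME.get(raw_name, raw_name))
        res_ids.append(int(res_id))
        row = []
        for atom_name in BACKBONE_ATOMS:
            hits = np.flatnonzero(mask & (first.atom_name == atom_name))
            if len(hits) != 1:
                raise ValueError(
                    f"{path}: residue {res_id} needs exactly one {atom_name} atom, "
                    f"found {len(hits)}"
                )
            row.append(int(hits[0]))
        atom_rows.append(row)
    if any(r <= 0 for r in res_ids):
        raise ValueError(f"{path}: residue numbering must be 1-based and positive")
    rows = np.asarray(atom_rows)
    coords = stack.coord[:, rows.ravel(), :].reshape(stack.stack_depth(), len(res_ids), 4, 3)
    return ConformerEnsemble.from_coords(
        peptide_id=peptide_id or Path(path).stem,
        residue_indices=res_ids,
        residue_names=res_names,
        coords=coords,
        cyclic_head=cyclic_head,
    )


def write_shift_csv(table: ShiftTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_shift_csv(path: str | Path, peptide_id: str | None = None) -> ShiftTable:
    """Read a shift CSV (peptide_id,residue_index,residue_name,atom_name,shift_ppm).

    Duplicated (residue_index, atom_name) cells are rejected with the CSV
    line numbers of all offending rows.
    """
    df = pd.read_csv(path)
    required = {"residue_index", "residue_name", "atom_name", "shift_ppm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if peptide_id is None:
        peptide_id = (
            str(df["peptide_id"].iloc[0]) if "peptide_id" in df.columns and len(df) else Path(path).stem
        )
    dup = df.duplicated(subset=["residue_index", "atom_name"], keep=False)
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup]]  # +2: header + 1-based
        raise ValueError(f"{path}: duplicated (residue_index, atom_name) rows at lines {lines}")
    return ShiftTable(
        peptide_id=peptide_id,
        data=df[["residue_index", "residue_name", "atom_name", "shift_ppm"]],
    )


def read_temp_series_csv(path: str | Path) -> list[TempSeries]:
    """Read `residue_index,temperature_K,shift_ppm` into per-residue series."""
    df = pd.read_csv(path)
    out = []
    for res_idx, grp in df.groupby("residue_index"):
        out.append(
            TempSeries(
                residue_index=int(res_idx),
                temperatures_K=grp["temperature_K"].to_numpy(float),
                shifts_ppm=grp["shift_ppm"].to_numpy(float),
            )
        )
    return out


def read_jcoupling_csv(path: str | Path) -> pd.DataFrame:
    """Read `residue_index,j_obs_hz,j_err_hz`; warn-range couplings pass through."""
    df = pd.read_csv(path)
    if not {"residue_index", "j_obs_hz"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns residue_index, j_obs_hz[, j_err_hz]")
    return df


def read_r2_csv(path: str | Path) -> dict[int, float]:
    df = pd.read_csv(path)
    if not {"residue_index", "r2_hz"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns residue_index, r2_hz")
    if (df["r2_hz"] < 0).any():
        raise ValueError(f"{path}: negative R2 rates")
    return {int(r.residue_index): float(r.r2_hz) for r in df.itertuples()}


@dataclass
class RunConfig:
    """Effective configuration of a pipeline run.

    Every analysis decision surfaced here is echoed into the output
    manifest.  CLI flags override YAML values; the merged config is always
    written to the run directory.
    """

    input_dir: str = "."
    output_dir: str = "pepshift_run"
    peptide_id: str = "synthetic"
    random_coil_table: str = "random_coil"
    karplus_preset: str | None = None  # None -> packaged default
    s2_preset: str = "pepshift-rci:v1"
    structure_threshold_ppm: float = 2.0
    structure_window: int = 3
    tempco_threshold_ppb_per_K: float = -4.6
    proline_trans_max_ppm: float = 6.0
    proline_cis_min_ppm: float = 8.0
    select_n: int = 50
    select_mode: str = "lowest"
    seed: int = 0
    filter_durations_s: tuple[float, ...] = (0.125, 0.250)
    noise_floor: float = 0.1
    cluster_before_select: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "filter_durations_s" in raw:
            raw["filter_durations_s"] = tuple(raw["filter_durations_s"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter_durations_s"] = list(d["filter_durations_s"])
        return d

    def write_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
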