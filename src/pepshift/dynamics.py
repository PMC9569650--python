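"""Per-residue flexibility metrics.

Cα root-mean-square fluctuations from conformer ensembles, random-coil-index
style order parameters (S²) predicted from secondary chemical shifts, and
T₂-filter intensity-ratio modelling for CPMG-filtered HSQC experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import ConformerEnsemble
from .shifts import SecondaryShiftTable

__all__ = [
    "S2Coefficients",
    "RelaxationFilterModel",
    "rmsf",
    "region_average",
    "predict_s2",
    "t2_filter",
]


def _ca_block(ens: ConformerEnsemble, align_range) -> tuple[np.ndarray, np.ndarray]:
    ca = ens.coords[:, :, 1, :]  # (M, n_res, 3)
    if align_range is None:
        mask = np.ones(ens.n_residues, dtype=bool)
    else:
        lo, hi = align_range
        mask = (ens.residue_indices >= lo) & (ens.residue_indices <= hi)
        if not mask.any():
            raise ValueError(f"align_range {align_range} selects no residues")
    return ca, mask


def rmsf(
    ens: ConformerEnsemble, align_range: tuple[int, int] | None = None
) -> pd.DataFrame:
    """Per-residue Cα RMSF (Å) about the ensemble mean structure.

    Models are superposed (Kabsch, on Cα of ``align_range`` or the whole
    chain) onto the mean structure, which is refined by a second
    superposition pass; RMSF_i is the root mean over models of the squared
    displacement of Cα_i from its mean position.
    """
    if ens.n_models < 2:
        raise ValueError("RMSF needs at least 2 models")
    ca, mask = _ca_block(ens, align_range)
    work = ca.copy()
    # pass 1: superpose on the first model, form a provisional mean;
    # pass 2: superpose on that mean and recompute it.
    reference = work[0, mask]
    for _ in range(2):
        for k in range(ens.n_models):
            sel = work[k, mask]
            selc = sel.mean(axis=0)
            refc = reference.mean(axis=0)
            a = sel - selc
            b = reference - refc
            h = a.T @ b
            u, s, vt = np.linalg.svd(h)
            d = np.sign(np.linalg.det(vt.T @ u.T))
            rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
            work[k] = (work[k] - selc) @ rot.T + refc
        reference = work[:, mask].mean(axis=0)
    mean_all = work.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((work - mean_all) ** 2, axis=2), axis=0))
    return pd.DataFrame({"residue_index": ens.residue_indices, "rmsf_A": fluct})


def region_average(
    values: pd.DataFrame | pd.Series,
    residue_range: tuple[int, int],
    column: str = "rmsf_A",
) -> tuple[float, float]:
    """Mean and sample SD of a per-residue metric over an inclusive range."""
    if isinstance(values, pd.DataFrame):
        series = values.set_index("residue_index")[column]
    else:
        series = values
    lo, hi = residue_range
    sel = series[(series.index >= lo) & (series.index <= hi)].dropna()
    if sel.empty:
        raise ValueError(f"residue range {residue_range} selects no values")
    sd = float(sel.std(ddof=1)) if len(sel) > 1 else 0.0
    return float(sel.mean()), sd


@dataclass(frozen=True)
class S2Coefficients:
    """Coefficients of the shift-based S² map (random-coil-index style).

    Per-residue, the weighted mean m of absolute secondary shifts (weights
    per nucleus, ppm) is floored at ``m_min`` and mapped monotonically to
    S² = floor + (1 − floor)·(1 − exp(−(m − m_min)/scale)) ∈ [floor, 1):
    shifts at the coil baseline predict maximal flexibility, large
    secondary shifts predict rigidity.
    """

    weights: Mapping[str, float] = field(
        default_factory=lambda: {"CA": 1.0, "CB": 1.0, "N": 0.4, "H": 8.0, "HA": 8.0}
    )
    m_min: float = 0.05  # ppm
    scale: float = 1.0  # ppm
    floor: float = 0.3
    preset_id: str = "pepshift-rci:v1"


def predict_s2(
    sec: SecondaryShiftTable, coeffs: S2Coefficients | None = None
) -> pd.DataFrame:
    """Shift-predicted backbone order parameters S² in [floor, 1].

    Residues with fewer than two usable backbone nuclei are reported
    missing (NaN).  Output carries the preset id of the coefficient block.
    """
    c = coeffs or S2Coefficients()
    rows = []
    for res_idx, grp in sec.data.groupby("residue_index"):
        usable = grp[grp["atom_name"].isin(c.weights)]
        if len(usable) < 2:
            rows.append({"residue_index": int(res_idx), "s2": np.nan})
            continue
        w = np.array([c.weights[a] for a in usable["atom_name"]])
        m = float(np.sum(w * usable["delta_ppm"].abs()) / np.sum(w))
        m = max(m, c.m_min)
        s2 = c.floor + (1.0 - c.floor) * (1.0 - np.exp(-(m - c.m_min) / c.scale))
        rows.append({"residue_index": int(res_idx), "s2": s2})
    out = pd.DataFrame(rows)
    out.attrs["preset_id"] = c.preset_id
    return out


@dataclass
class RelaxationFilterModel:
    """A CPMG T₂ filter of duration T with per-residue ¹⁵N R₂ rates.

    ``filter_s`` is the filter duration (s); its nominal rate is 1/T (Hz).
    ``r2_hz`` maps residue index to the transverse auto-relaxation rate.
    Peaks whose predicted intensity ratio falls at or below ``noise_floor``
    (fraction of the unfiltered reference) are flagged undetectable.
    """

    filter_s: float
    r2_hz: Mapping[int, float]
    noise_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.filter_s <= 0:
            raise ValueError("filter duration must be positive")
        if any(r < 0 for r in self.r2_hz.values()):
            raise ValueError("R2 rates must be non-negative")

    @property
    def nominal_rate_hz(self) -> float:
        return 1.0 / self.filter_s


def t2_filter(model: RelaxationFilterModel) -> pd.DataFrame:
    """Predicted T₂-filter intensity ratios I_CPMG/I₀ = exp(−R₂·T).

    A residue is detectable in the filtered spectrum iff its ratio exceeds
    the noise floor — i.e. its T₂ outlives the applied filter.
    """
    rows = []
    for res_idx in sorted(model.r2_hz):
        ratio = float(np.exp(-model.r2_hz[res_idx] * model.filter_s))
        rows.append(
            {
                "residue_index": int(res_idx),
                "intensity_ratio": ratio,
                "detectable": bool(ratio > model.noise_floor),
            }
        )
    return pd.DataFrame(rows)
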