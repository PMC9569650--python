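"""Scalar-coupling and amide temperature-coefficient analysis.

³J(HN–Hα) back-calculation from backbone φ dihedrals through the Karplus
relation, validation of predicted against measured couplings, and
ordinary-least-squares amide-proton temperature coefficients (ppb/K) with
hydrogen-bond classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "KarplusParams",
    "JCouplingRecord",
    "TempSeries",
    "TempCoefficient",
    "karplus_j",
    "ensemble_j",
    "validate_j",
    "fit_temp_coefficient",
    "HBOND_THRESHOLD_PPB_PER_K",
]

#: Amide temperature-coefficient boundary (ppb/K).  Slopes more negative than
#: this indicate solvent-exposed amide protons; less negative (but still
#: non-positive) slopes indicate intramolecular hydrogen bonding.  The
#: boundary itself classifies as solvent_exposed (<= convention).
HBOND_THRESHOLD_PPB_PER_K = -4.6


@dataclass(frozen=True)
class KarplusParams:
    """Coefficients of J(φ) = A·cos²(φ−θ₀) + B·cos(φ−θ₀) + C (Hz, degrees).

    θ₀ = +60° is the phase relating the backbone φ dihedral to the
    H–N–Cα–Hα dihedral for ³J(HN–Hα).
    """

    A: float
    B: float
    C: float
    theta0: float = 60.0
    preset_id: str = "custom"

    @classmethod
    def preset(cls, name: str | None = None) -> "KarplusParams":
        """Load a named coefficient preset shipped with the package."""
        ref = resources.files("pepshift.data").joinpath("karplus_presets.yaml")
        cfg = yaml.safe_load(ref.read_text())
        if name is None:
            name = cfg["default"]
        try:
            p = cfg["presets"][name]
        except KeyError:
            raise KeyError(f"unknown Karplus preset {name!r}; available: {list(cfg['presets'])}")
        return cls(A=p["A"], B=p["B"], C=p["C"], theta0=p["theta0"], preset_id=name)


@dataclass
class JCouplingRecord:
    residue_index: int
    j_obs_hz: float | None = None
    j_err_hz: float | None = None
    j_pred_hz: float | None = None

    def __post_init__(self) -> None:
        # physical-range sanity check: warn, never reject
        for label, j in (("observed", self.j_obs_hz), ("predicted", self.j_pred_hz)):
            if j is not None and not (0.0 < j < 15.0):
                warnings.warn(
                    f"residue {self.residue_index}: {label} 3J(HN-HA) = {j:.2f} Hz "
                    "outside the physical range (0, 15) Hz",
                    stacklevel=2,
                )


@dataclass
class TempSeries:
    """Amide-proton chemical shift observed over a series of temperatures."""

    residue_index: int
    temperatures_K: np.ndarray
    shifts_ppm: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures_K, dtype=float)
        s = np.asarray(self.shifts_ppm, dtype=float)
        if t.shape != s.shape:
            raise ValueError("temperature and shift arrays must have equal length")
        order = np.argsort(t)
        self.temperatures_K = t[order]
        self.shifts_ppm = s[order]


@dataclass
class TempCoefficient:
    residue_index: int
    slope_ppb_per_K: float
    stderr_ppb_per_K: float
    classification: str  # solvent_exposed | hbond_protected | exchange_or_aromatic


def karplus_j(phi_deg: float | np.ndarray, params: KarplusParams) -> float | np.ndarray:
    """³J(HN–Hα) in Hz from the backbone φ dihedral (degrees)."""
    theta = np.deg2rad(np.asarray(phi_deg, dtype=float) - params.theta0)
    c = np.cos(theta)
    j = params.A * c**2 + params.B * c + params.C
    return float(j) if np.isscalar(phi_deg) else j


def circular_mean_deg(angles_deg: np.ndarray) -> float:
    """Mean direction of angles in degrees via the unit-vector average."""
    a = np.deg2rad(np.asarray(angles_deg, dtype=float))
    return float(np.rad2deg(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))))


def ensemble_j(ensemble, params: KarplusParams) -> pd.DataFrame:
    """Predicted ³J(HN–Hα) per residue from an ensemble's φ dihedrals.

    The φ angle is averaged over models on the circle (unit-vector mean),
    then fed once through the Karplus curve.  Residues without a defined φ
    in every model (chain start) and prolines (no amide proton) are
    reported missing.
    """
    rows = []
    for i, (res_idx, res_name) in enumerate(
        zip(ensemble.residue_indices, ensemble.residue_names)
    ):
        phis = ensemble.phi[:, i]
        if res_name.upper() == "PRO" or np.isnan(phis).any():
            rows.append({"residue_index": int(res_idx), "phi_mean_deg": np.nan, "j_pred_hz": np.nan})
            continue
        phi_mean = circular_mean_deg(phis)
        rows.append(
            {
                "residue_index": int(res_idx),
                "phi_mean_deg": phi_mean,
                "j_pred_hz": karplus_j(phi_mean, params),
            }
        )
    return pd.DataFrame(rows)


def validate_j(records: list[JCouplingRecord]) -> dict:
    """Pearson correlation and RMS deviation of observed vs predicted ³J.

    Returns ``{"r": float | None, "rmsd_hz": float, "n": int}``; ``r`` is
    ``None`` when either vector has zero variance (correlation undefined).
    """
    pairs = [
        (r.j_obs_hz, r.j_pred_hz)
        for r in records
        if r.j_obs_hz is not None and r.j_pred_hz is not None
        and np.isfinite(r.j_obs_hz) and np.isfinite(r.j_pred_hz)
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 paired observed/predicted couplings")
    obs = np.array([p[0] for p in pairs])
    pred = np.array([p[1] for p in pairs])
    rmsd = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.std(obs) == 0 or np.std(pred) == 0:
        return {"r": None, "rmsd_hz": rmsd, "n": len(pairs)}
    r = float(stats.pearsonr(obs, pred).statistic)
    return {"r": r, "rmsd_hz": rmsd, "n": len(pairs)}


def fit_temp_coefficient(series: TempSeries) -> TempCoefficient:
    """Amide temperature coefficient from the slope of δ(HN) vs T.

    Ordinary least squares on shift (ppm) against temperature (K); the
    slope and its standard error are reported in ppb/K.  Classification:
    ``solvent_exposed`` for slope ≤ −4.6 ppb/K, ``hbond_protected`` for
    slope in (−4.6, 0], ``exchange_or_aromatic`` for positive slope.
    """
    t = series.temperatures_K
    s = series.shifts_ppm
    if len(t) < 3:
        raise ValueError("temperature series needs at least 3 points")
    if len(np.unique(t)) < 2:
        raise ValueError("temperature series is degenerate (single temperature)")
    fit = stats.linregress(t, s)
    slope = float(fit.slope) * 1000.0  # ppm/K -> ppb/K
    stderr = float(fit.stderr) * 1000.0
    # boundary slope classifies as solvent_exposed (<= convention), robust to
    # last-digit rounding of the regression
    if slope <= HBOND_THRESHOLD_PPB_PER_K or np.isclose(slope, HBOND_THRESHOLD_PPB_PER_K):
        cls = "solvent_exposed"
    elif slope <= 0.0:
        cls = "hbond_protected"
    else:
        cls = "exchange_or_aromatic"
    return TempCoefficient(
        residue_index=series.residue_index,
        slope_ppb_per_K=slope,
        stderr_ppb_per_K=stderr,
        classification=cls,
    )
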