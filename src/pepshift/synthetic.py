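"""Synthetic input generation for the whole pipeline.

Emulates the statistical structure of the real inputs — random-coil shifts
plus basin-dependent secondary offsets with Gaussian measurement noise,
minor cis-proline populations, linear amide-shift temperature dependence,
and an "observed" shift table formed as the population average over a
hidden true sub-ensemble of conformers — so every analysis stage is
testable without spectrometer or MD-engine output.  Ground truth is stored
alongside for recovery scoring.  All generators are pure functions of
(spec, seed).

Conformer geometry is idealized: backbones are built from sampled (φ, ψ)
with fixed bond lengths and angles (NeRF chain extension), ω fixed at 180°.
The macrocyclic head is enforced as a closure distance check with rejection
sampling, a proxy for the side-chain bridge of the c[K-R-G-D-e] cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coupling import TempSeries
from .ensemble import (
    ConformerEnsemble,
    ToyShiftPredictor,
    _mean_shift_table,
    load_basins,
    predict_shifts,
)
from .shifts import ShiftTable

__all__ = [
    "RGDECHI_1_14",
    "PSI_RGDECHI",
    "SyntheticSpec",
    "GroundTruth",
    "parse_sequence",
    "build_backbone",
    "generate_ensemble",
    "simulate_observed_shifts",
    "simulate_temp_series",
    "simulate_proline",
    "make_recovery_instance",
    "write_bundle",
]

#: The truncated RGDechi peptide: cyclic RGD penta-peptide head (with a
#: D-glutamate) followed by the echistatin-derived tail.
RGDECHI_1_14 = "c[K-R-G-D-e]-M-D-D-P-G-R-N-P-H"
#: The pseudopeptide variant with the homocitrulline-containing C-terminal
#: extension (reduced Pro–Gly amide bond not represented in shift tables).
PSI_RGDECHI = "c[K-R-G-D-e]-M-D-D-P-G-R-N-P-H-hCit-G-P-A-T"

_ONE_LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def parse_sequence(sequence: str) -> tuple[list[str], int]:
    """Parse a dash-separated peptide string into 3-letter codes.

    ``c[...]`` marks a cyclic head; lowercase one-letter codes denote
    D-amino acids (``e`` → DGLU); the token ``hCit`` (homocitrulline) maps
    to HCIT.  Returns (residue names, cyclic head length — 0 if acyclic).
    """
    seq = sequence.strip()
    head_len = 0
    tokens: list[str] = []
    if seq.startswith("c["):
        close = seq.index("]")
        head = seq[2:close]
        tokens.extend(head.split("-"))
        head_len = len(tokens)
        rest = seq[close + 1 :].lstrip("-")
    else:
        rest = seq
    if rest:
        tokens.extend(rest.split("-"))
    names = []
    for tok in tokens:
        if tok.upper() in ("HCIT", "HCYT"):
            names.append("HCIT")
        elif len(tok) == 1 and tok.isupper():
            names.append(_ONE_LETTER[tok])
        elif len(tok) == 1 and tok.islower():
            names.append("D" + _ONE_LETTER[tok.upper()])
        elif len(tok) == 3:
            names.append(tok.upper())
        else:
            raise ValueError(f"unrecognised sequence token {tok!r}")
    return names, head_len


# ---------------------------------------------------------------------------
# Idealized backbone geometry (NeRF chain extension)
# ---------------------------------------------------------------------------

# Standard backbone geometry: bond lengths (Å) and angles (degrees).
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_OMEGA = 180.0


def _place_atom(a, b, c, r: float, theta_deg: float, chi_deg: float) -> np.ndarray:
    """Place atom d with |cd|=r, angle(b,c,d)=theta, dihedral(a,b,c,d)=chi."""
    theta = np.deg2rad(theta_deg)
    chi = np.deg2rad(chi_deg)
    bc = c - b
    bc_u = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_u)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc_u)
    d_local = np.array(
        [-r * np.cos(theta), r * np.sin(theta) * np.cos(chi), r * np.sin(theta) * np.sin(chi)]
    )
    return c + d_local[0] * bc_u + d_local[1] * m + d_local[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Backbone (n_res, 4, 3) coordinates from dihedrals with ideal geometry.

    ``phi[0]`` is ignored (undefined at the chain start); ``psi[-1]`` is
    used only to place the final carbonyl oxygen.
    """
    n = len(phi)
    coords = np.zeros((n, 4, 3))
    coords[0, 0] = np.array([0.0, 0.0, 0.0])  # N
    coords[0, 1] = np.array([_B_N_CA, 0.0, 0.0])  # CA
    alpha = np.deg2rad(180.0 - _A_N_CA_C)
    coords[0, 2] = coords[0, 1] + _B_CA_C * np.array([np.cos(alpha), np.sin(alpha), 0.0])  # C
    for i in range(n - 1):
        n_next = _place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2], _B_C_N, _A_CA_C_N, psi[i]
        )
        ca_next = _place_atom(coords[i, 1], coords[i, 2], n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_next = _place_atom(coords[i, 2], n_next, ca_next, _B_CA_C, _A_N_CA_C, phi[i + 1])
        coords[i + 1, 0] = n_next
        coords[i + 1, 1] = ca_next
        coords[i + 1, 2] = c_next
    for i in range(n):
        coords[i, 3] = _place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2], _B_C_O, _A_CA_C_O, psi[i] + 180.0
        )
    return coords


# ---------------------------------------------------------------------------
# Spec and ground truth
# ---------------------------------------------------------------------------

#: Temperatures of the amide-shift series (K), matching a 1D series
#: acquired in 2 K steps from 298 K.
DEFAULT_TEMPERATURES_K = (298.0, 300.0, 302.0, 304.0, 306.0, 308.0, 310.0)


def _default_r2() -> dict[int, float]:
    # Five fast-relaxing residues (cycle entry, mid-chain and C-terminal
    # positions) against a slowly relaxing background, emulating the
    # pattern of peaks lost through a 250 ms CPMG filter.
    fast = {1, 7, 11, 12, 14}
    return {i: (12.0 if i in fast else 1.5) for i in range(1, 15)}


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic generators.

    Defaults describe the flexible-peptide regime the pipeline targets:
    predominantly coil basin populations, sub-0.1 ppm shift noise, minor
    (<10%) cis-proline populations, amide temperature coefficients around
    −6 ppb/K, and a candidate ensemble of a few hundred conformers hiding a
    50-member true sub-ensemble.
    """

    sequence: str = RGDECHI_1_14
    populations: Mapping[str, float] = field(
        default_factory=lambda: {"helix": 0.2, "strand": 0.2, "coil": 0.6}
    )
    n_conformers: int = 400
    n_true: int = 50
    shift_noise_ppm: float = 0.05
    temperatures_K: Sequence[float] = DEFAULT_TEMPERATURES_K
    slopes_ppb_per_K: Mapping[int, float] = field(
        default_factory=lambda: {i: -6.0 for i in range(1, 15)}
    )
    temp_noise_ppb: float = 2.0
    cis_fractions: Mapping[int, float] = field(default_factory=lambda: {9: 0.08, 13: 0.05})
    r2_hz: Mapping[int, float] = field(default_factory=_default_r2)
    closure_max_A: float = 10.0
    max_closure_retries: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.populations.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"basin populations must sum to 1, got {total}")
        if self.shift_noise_ppm < 0:
            raise ValueError("shift noise must be >= 0")
        if any(not 0 <= f <= 1 for f in self.cis_fractions.values()):
            raise ValueError("cis fractions must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything needed to score recovery tests without re-generation."""

    true_ids: list[int]
    basins: np.ndarray  # (M, n_res) basin label indices into basin_names
    basin_names: list[str]
    slopes_ppb_per_K: dict[int, float]
    cis_fractions: dict[int, float]
    r2_hz: dict[int, float]

    def to_json(self) -> dict:
        return {
            "true_ids": [int(i) for i in self.true_ids],
            "basin_names": self.basin_names,
            "basins": self.basins.tolist(),
            "slopes_ppb_per_K": {str(k): v for k, v in self.slopes_ppb_per_K.items()},
            "cis_fractions": {str(k): v for k, v in self.cis_fractions.items()},
            "r2_hz": {str(k): v for k, v in self.r2_hz.items()},
        }


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def _wrapped_normal(rng: np.random.Generator, center: float, width: float) -> float:
    return float((rng.normal(center, width) + 180.0) % 360.0 - 180.0)


def _sample_model(
    rng: np.random.Generator,
    n_res: int,
    basin_names: list[str],
    basin_probs: np.ndarray,
    basins: dict,
    head_len: int,
    closure_max: float,
    max_retries: int,
):
    """One conformer: basin draw, dihedral draw, backbone build, closure check."""
    for attempt in range(max_retries):
        which = rng.choice(len(basin_names), size=n_res, p=basin_probs)
        phi = np.empty(n_res)
        psi = np.empty(n_res)
        for i, b_idx in enumerate(which):
            b = basins[basin_names[b_idx]]
            phi[i] = _wrapped_normal(rng, b["center"][0], b["width"][0])
            psi[i] = _wrapped_normal(rng, b["center"][1], b["width"][1])
        coords = build_backbone(phi, psi)
        if head_len >= 3:
            gap = np.linalg.norm(coords[0, 1] - coords[head_len - 1, 1])  # CA..CA
            if gap > closure_max:
                continue
        return coords, which
    raise RuntimeError(
        f"macrocycle closure failed after {max_retries} attempts "
        f"(threshold {closure_max} Å); widen the threshold or reseed"
    )


def generate_ensemble(
    spec: SyntheticSpec,
    populations_per_model: Sequence[Mapping[str, float]] | None = None,
    peptide_id: str = "synthetic",
) -> tuple[ConformerEnsemble, GroundTruth]:
    """Generate an idealized conformer ensemble with stored ground truth.

    Per conformer and residue a Ramachandran basin is drawn from the
    population vector, (φ, ψ) are drawn from that basin's wrapped normal,
    and the backbone is built with ideal geometry.  For cyclic-head
    sequences a CA(first)–CA(last head residue) closure distance is
    enforced by rejection sampling.  ``populations_per_model`` overrides
    the spec populations conformer-by-conformer (used by the recovery
    instance).  Deterministic for a fixed spec/seed.
    """
    rng = np.random.default_rng(spec.seed)
    names, head_len = parse_sequence(spec.sequence)
    n_res = len(names)
    basins = load_basins()
    basin_names = sorted(basins)
    coords = np.empty((spec.n_conformers, n_res, 4, 3))
    which_all = np.empty((spec.n_conformers, n_res), dtype=int)
    for k in range(spec.n_conformers):
        pops = (
            populations_per_model[k] if populations_per_model is not None else spec.populations
        )
        probs = np.array([pops.get(b, 0.0) for b in basin_names], dtype=float)
        probs = probs / probs.sum()
        coords[k], which_all[k] = _sample_model(
            rng, n_res, basin_names, probs, basins, head_len,
            spec.closure_max_A, spec.max_closure_retries,
        )
    ens = ConformerEnsemble.from_coords(
        peptide_id=peptide_id,
        residue_indices=np.arange(1, n_res + 1),
        residue_names=names,
        coords=coords,
        cyclic_head=head_len >= 3,
    )
    n_true = min(spec.n_true, spec.n_conformers)
    true_ids = sorted(int(i) for i in rng.choice(spec.n_conformers, size=n_true, replace=False))
    truth = GroundTruth(
        true_ids=true_ids,
        basins=which_all,
        basin_names=basin_names,
        slopes_ppb_per_K=dict(spec.slopes_ppb_per_K),
        cis_fractions=dict(spec.cis_fractions),
        r2_hz=dict(spec.r2_hz),
    )
    return ens, truth


def simulate_observed_shifts(
    ens: ConformerEnsemble,
    true_ids: Sequence[int],
    sigma_ppm: float,
    seed: int,
    predictor: ToyShiftPredictor | None = None,
) -> ShiftTable:
    """Observed shift table: population average over the true sub-ensemble.

    obs = cell-wise mean of the toy-predicted tables of ``true_ids`` plus
    i.i.d. Gaussian noise of ``sigma_ppm`` per cell (fast-exchange
    ensemble averaging with measurement noise).
    """
    if len(true_ids) == 0:
        raise ValueError("true_ids must be non-empty")
    pred = predictor or ToyShiftPredictor()
    tables = [predict_shifts(ens, int(i), pred) for i in true_ids]
    mean = _mean_shift_table(tables)
    rng = np.random.default_rng(seed)
    data = mean.data.copy()
    if sigma_ppm > 0:
        data["shift_ppm"] = data["shift_ppm"] + rng.normal(0.0, sigma_ppm, size=len(data))
    return ShiftTable(peptide_id=ens.peptide_id, data=data)


def simulate_temp_series(
    slopes_ppb_per_K: Mapping[int, float],
    temperatures_K: Sequence[float] = DEFAULT_TEMPERATURES_K,
    sigma_ppb: float = 0.0,
    seed: int = 0,
    intercept_ppm: float = 8.30,
    t_ref_K: float = 298.0,
) -> list[TempSeries]:
    """Linear amide-shift temperature series with Gaussian noise (per residue)."""
    if len(temperatures_K) < 3:
        raise ValueError("need at least 3 temperatures")
    rng = np.random.default_rng(seed)
    t = np.asarray(temperatures_K, dtype=float)
    out = []
    for res_idx in sorted(slopes_ppb_per_K):
        slope_ppm = slopes_ppb_per_K[res_idx] / 1000.0
        shifts = intercept_ppm + slope_ppm * (t - t_ref_K)
        if sigma_ppb > 0:
            shifts = shifts + rng.normal(0.0, sigma_ppb / 1000.0, size=len(t))
        out.append(TempSeries(residue_index=res_idx, temperatures_K=t, shifts_ppm=shifts))
    return out


# Reference Cβ/Cγ pairs for the two proline rotamer/isomer states (ppm):
# trans Xaa-Pro near (32, 27), Δβγ ≈ 5; cis near (35, 25), Δβγ ≈ 10.
_TRANS_CB_CG = (32.1, 27.2)
_CIS_CB_CG = (34.8, 25.1)


def simulate_proline(
    cis_fraction: float,
    seed: int = 0,
    noise_ppm: float = 0.0,
    reference_intensity: float = 1.0,
) -> dict:
    """Cis/trans proline peak pairs with population-proportional intensities.

    Emits a trans-like (Δβγ≈5 ppm) and, when the cis population is
    non-zero, a cis-like (Δβγ≈10 ppm) Cβ/Cγ pair; intensities are
    proportional to the respective populations.
    """
    if not 0.0 <= cis_fraction <= 1.0:
        raise ValueError("cis_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def jitter(pair):
        return tuple(float(v + rng.normal(0.0, noise_ppm)) if noise_ppm > 0 else float(v) for v in pair)

    peaks = {}
    if cis_fraction < 1.0:
        cb, cg = jitter(_TRANS_CB_CG)
        peaks["trans"] = {"cb_ppm": cb, "cg_ppm": cg, "intensity": reference_intensity * (1.0 - cis_fraction)}
    if cis_fraction > 0.0:
        cb, cg = jitter(_CIS_CB_CG)
        peaks["cis"] = {"cb_ppm": cb, "cg_ppm": cg, "intensity": reference_intensity * cis_fraction}
    return peaks


def make_recovery_instance(
    n_total: int = 400,
    n_true: int = 50,
    sigma_ppm: float = 0.05,
    seed: int = 0,
    sequence: str = RGDECHI_1_14,
    true_populations: Mapping[str, float] | None = None,
    decoy_populations: Mapping[str, float] | None = None,
) -> tuple[ConformerEnsemble, GroundTruth, ShiftTable]:
    """Hidden-sub-ensemble recovery instance for the selection protocol.

    A coherent conformational state (helix-biased basin populations) is
    planted in ``n_true`` conformers of an ``n_total``-member candidate
    ensemble whose remaining decoys sample basins uniformly; the observed
    table is the noisy population average over the true members.  Returns
    (ensemble, ground truth, observed shifts).
    """
    rng = np.random.default_rng(seed)
    true_pop = dict(true_populations or {"helix": 0.85, "coil": 0.15})
    decoy_pop = dict(decoy_populations or {"helix": 1 / 3, "strand": 1 / 3, "coil": 1 / 3})
    true_ids = sorted(int(i) for i in rng.choice(n_total, size=n_true, replace=False))
    true_set = set(true_ids)
    per_model = [true_pop if k in true_set else decoy_pop for k in range(n_total)]
    spec = SyntheticSpec(
        sequence=sequence,
        n_conformers=n_total,
        n_true=n_true,
        shift_noise_ppm=sigma_ppm,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    ens, truth = generate_ensemble(spec, populations_per_model=per_model)
    truth.true_ids = true_ids
    obs = simulate_observed_shifts(
        ens, true_ids, sigma_ppm, seed=int(rng.integers(0, 2**31 - 1))
    )
    return ens, truth, obs


def write_bundle(spec: SyntheticSpec, outdir: str | Path) -> dict[str, Path]:
    """Write a complete synthetic input bundle (PDB + CSVs + ground truth).

    Produces the candidate-ensemble PDB, observed-shift CSV, amide
    temperature-series CSV, observed ³J CSV (back-calculated from the true
    sub-ensemble with 0.3 Hz noise), per-residue R₂ CSV, proline peak
    table and a ground-truth JSON.
    """
    from .coupling import KarplusParams, ensemble_j
    from .io import write_pdb_ensemble, write_shift_csv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed + 1)
    ens, truth = generate_ensemble(spec)
    obs = simulate_observed_shifts(
        ens, truth.true_ids, spec.shift_noise_ppm, seed=int(rng.integers(0, 2**31 - 1))
    )
    paths: dict[str, Path] = {}

    paths["ensemble_pdb"] = outdir / "ensemble.pdb"
    write_pdb_ensemble(ens, paths["ensemble_pdb"])
    paths["shifts_csv"] = outdir / "observed_shifts.csv"
    write_shift_csv(obs, paths["shifts_csv"])

    series = simulate_temp_series(
        spec.slopes_ppb_per_K, spec.temperatures_K, spec.temp_noise_ppb,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    rows = [
        {"residue_index": s.residue_index, "temperature_K": t, "shift_ppm": v}
        for s in series
        for t, v in zip(s.temperatures_K, s.shifts_ppm)
    ]
    paths["tempseries_csv"] = outdir / "temp_series.csv"
    pd.DataFrame(rows).to_csv(paths["tempseries_csv"], index=False)

    true_sub = ens.subset(truth.true_ids)
    jpred = ensemble_j(true_sub, KarplusParams.preset())
    jrows = []
    for _, row in jpred.dropna().iterrows():
        jrows.append(
            {
                "residue_index": int(row["residue_index"]),
                "j_obs_hz": float(row["j_pred_hz"] + rng.normal(0.0, 0.3)),
                "j_err_hz": 0.3,
            }
        )
    paths["jcoupling_csv"] = outdir / "jcoupling.csv"
    pd.DataFrame(jrows).to_csv(paths["jcoupling_csv"], index=False)

    paths["r2_csv"] = outdir / "r2.csv"
    pd.DataFrame(
        [{"residue_index": k, "r2_hz": v} for k, v in sorted(spec.r2_hz.items())]
    ).to_csv(paths["r2_csv"], index=False)

    prows = []
    for res_idx, f in sorted(spec.cis_fractions.items()):
        peaks = simulate_proline(f, seed=int(rng.integers(0, 2**31 - 1)))
        for form, peak in peaks.items():
            prows.append({"residue_index": res_idx, "form": form, **peak})
    paths["proline_csv"] = outdir / "proline_peaks.csv"
    pd.DataFrame(prows).to_csv(paths["proline_csv"], index=False)

    paths["ground_truth_json"] = outdir / "ground_truth.json"
    paths["ground_truth_json"].write_text(json.dumps(truth.to_json(), indent=1))
    return paths
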