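"""Conformer ensembles and chemical-shift-driven conformer selection.

A :class:`ConformerEnsemble` holds M backbone models of one peptide.  The
selection workflow mirrors the chemical-shift (CS) protocol for flexible
peptides: cluster the candidate ensemble on pairwise backbone RMSD with the
Kelley penalty choosing the cut level, back-calculate shifts per
representative through a pluggable predictor, score each conformer against
the observed shifts with a global CS-RMSD (sum of per-nucleus-class RMSDs),
and build lowest-N / highest-N / random-N sub-ensembles, validated by the
Q factor and the ³J correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .shifts import RandomCoilModel, SecondaryShiftTable, ShiftTable, _hn_class

__all__ = [
    "ConformerEnsemble",
    "ClusterResult",
    "SelectionResult",
    "ValidationReport",
    "dihedral",
    "kabsch_superpose",
    "pairwise_rmsd",
    "kelley_cluster",
    "ShiftPredictor",
    "ToyShiftPredictor",
    "predict_shifts",
    "global_cs_rmsd",
    "select_ensemble",
    "q_factor",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal superposition of ``mobile`` onto ``target`` (both (n, 3)).

    Returns the transformed mobile coordinates and the post-fit RMSD (Å).
    Kabsch via SVD with the proper-rotation (det +1) correction.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    a = mobile - mc
    b = target - tc
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    moved = a @ rot.T + tc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - (b + tc)) ** 2, axis=1))))
    return moved, rmsd


@dataclass
class ConformerEnsemble:
    """M backbone models of one peptide.

    ``coords`` has shape (M, n_res, 4, 3) over atoms (N, CA, C, O) in Å;
    ``phi``/``psi`` have shape (M, n_res) in degrees with NaN where the
    dihedral is undefined (chain termini).  ``cyclic_head`` marks peptides
    whose first five residues form the c[K-R-G-D-e] macrocycle.
    """

    peptide_id: str
    residue_indices: np.ndarray
    residue_names: list[str]
    coords: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    cyclic_head: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 4 or self.coords.shape[2:] != (4, 3):
            raise ValueError("coords must have shape (M, n_res, 4, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        if self.coords.shape[1] != len(self.residue_names):
            raise ValueError("coords and residue_names disagree on residue count")

    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    @classmethod
    def from_coords(
        cls,
        peptide_id: str,
        residue_indices: Sequence[int],
        residue_names: Sequence[str],
        coords: np.ndarray,
        cyclic_head: bool = False,
    ) -> "ConformerEnsemble":
        """Build an ensemble from backbone coordinates, deriving φ/ψ."""
        coords = np.asarray(coords, dtype=float)
        m, n = coords.shape[0], coords.shape[1]
        phi = np.full((m, n), np.nan)
        psi = np.full((m, n), np.nan)
        ni, ca, c = 0, 1, 2
        for k in range(m):
            for i in range(n):
                if i > 0:
                    phi[k, i] = dihedral(
                        coords[k, i - 1, c], coords[k, i, ni], coords[k, i, ca], coords[k, i, c]
                    )
                if i < n - 1:
                    psi[k, i] = dihedral(
                        coords[k, i, ni], coords[k, i, ca], coords[k, i, c], coords[k, i + 1, ni]
                    )
        return cls(
            peptide_id=peptide_id,
            residue_indices=np.asarray(residue_indices, dtype=int),
            residue_names=list(residue_names),
            coords=coords,
            phi=phi,
            psi=psi,
            cyclic_head=cyclic_head,
        )

    def subset(self, model_ids: Sequence[int]) -> "ConformerEnsemble":
        ids = list(model_ids)
        return ConformerEnsemble(
            peptide_id=self.peptide_id,
            residue_indices=self.residue_indices,
            residue_names=self.residue_names,
            coords=self.coords[ids],
            phi=self.phi[ids],
            psi=self.psi[ids],
            cyclic_head=self.cyclic_head,
        )


# ---------------------------------------------------------------------------
# Pairwise RMSD and Kelley clustering
# ---------------------------------------------------------------------------

def _atom_block(ens: ConformerEnsemble, atom_selection: Sequence[str], align_range) -> np.ndarray:
    atom_idx = [BACKBONE_ATOMS.index(a) for a in atom_selection]
    if not atom_idx:
        raise ValueError("empty atom selection")
    if align_range is None:
        res_mask = np.ones(ens.n_residues, dtype=bool)
    else:
        lo, hi = align_range
        res_mask = (ens.residue_indices >= lo) & (ens.residue_indices <= hi)
        if not res_mask.any():
            raise ValueError(f"align_range {align_range} selects no residues")
    block = ens.coords[:, res_mask][:, :, atom_idx, :]
    return block.reshape(ens.n_models, -1, 3)


def pairwise_rmsd(
    ens: ConformerEnsemble,
    atom_selection: Sequence[str] = ("CA",),
    align_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Symmetric matrix of optimal-superposition RMSDs (Å) between models."""
    pts = _atom_block(ens, atom_selection, align_range)
    m = ens.n_models
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            _, rmsd = kabsch_superpose(pts[i], pts[j])
            d[i, j] = d[j, i] = rmsd
    return d


@dataclass
class ClusterResult:
    labels: np.ndarray  # cluster id per model, 1-based
    representatives: dict[int, int]  # cluster id -> medoid model index
    penalties: pd.DataFrame  # columns: n_clusters, avg_spread, norm_spread, penalty
    n_clusters: int


def _level_spread(d: np.ndarray, labels: np.ndarray) -> float | None:
    """Kelley level spread: mean pairwise distance over multi-member clusters."""
    spreads = []
    for cid in np.unique(labels):
        members = np.flatnonzero(labels == cid)
        if len(members) < 2:
            continue
        sub = d[np.ix_(members, members)]
        spreads.append(sub[np.triu_indices(len(members), k=1)].mean())
    if not spreads:
        return None
    return float(np.mean(spreads))


def kelley_cluster(d: np.ndarray) -> ClusterResult:
    """Average-linkage hierarchical clustering with the Kelley penalty cut.

    For each cut level with k clusters the average within-cluster spread is
    computed over clusters of two or more members, normalised across levels
    onto [1, M−1], and penalised by adding k; the level minimising the
    penalty is chosen.  Each cluster is represented by its medoid (smallest
    summed distance to cluster mates, lowest model index on ties).  Fewer
    than 3 models yields a single trivial cluster.
    """
    d = np.asarray(d, dtype=float)
    m = d.shape[0]
    if d.shape != (m, m):
        raise ValueError("distance matrix must be square")
    if m < 3:
        labels = np.ones(m, dtype=int)
        reps = {1: int(np.argmin(d.sum(axis=0)))}
        pen = pd.DataFrame(
            {"n_clusters": [1], "avg_spread": [np.nan], "norm_spread": [np.nan], "penalty": [np.nan]}
        )
        return ClusterResult(labels=labels, representatives=reps, penalties=pen, n_clusters=1)

    z = linkage(squareform(d, checks=False), method="average")
    levels = []
    for k in range(1, m):
        labels_k = fcluster(z, t=k, criterion="maxclust")
        spread = _level_spread(d, labels_k)
        levels.append({"n_clusters": k, "labels": labels_k, "avg_spread": spread})
    usable = [lv for lv in levels if lv["avg_spread"] is not None]
    spreads = np.array([lv["avg_spread"] for lv in usable])
    smin, smax = spreads.min(), spreads.max()
    if smax > smin:
        norm = (spreads - smin) / (smax - smin) * (m - 2) + 1.0
    else:  # all spreads equal (e.g. identical models): no spread signal
        norm = np.ones_like(spreads)
    for lv, ns in zip(usable, norm):
        lv["norm_spread"] = float(ns)
        lv["penalty"] = float(ns) + lv["n_clusters"]
    best = min(usable, key=lambda lv: (lv["penalty"], lv["n_clusters"]))
    labels = best["labels"]
    reps: dict[int, int] = {}
    for cid in np.unique(labels):
        members = np.flatnonzero(labels == cid)
        sums = d[np.ix_(members, members)].sum(axis=1)
        reps[int(cid)] = int(members[np.argmin(sums)])
    pen = pd.DataFrame(
        [
            {
                "n_clusters": lv["n_clusters"],
                "avg_spread": lv["avg_spread"],
                "norm_spread": lv.get("norm_spread", np.nan),
                "penalty": lv.get("penalty", np.nan),
            }
            for lv in levels
        ]
    )
    return ClusterResult(
        labels=labels, representatives=reps, penalties=pen, n_clusters=int(best["n_clusters"])
    )


# ---------------------------------------------------------------------------
# Shift back-calculation (pluggable predictor contract + built-in toy)
# ---------------------------------------------------------------------------

class ShiftPredictor(Protocol):
    """Contract for shift back-calculators: geometry in, ShiftTable out."""

    nuclei: tuple[str, ...]
    predictor_id: str

    def predict(
        self,
        peptide_id: str,
        residue_indices: np.ndarray,
        residue_names: Sequence[str],
        phi: np.ndarray,
        psi: np.ndarray,
    ) -> ShiftTable: ...


def load_basins() -> dict:
    ref = resources.files("pepshift.data").joinpath("basins.yaml")
    return yaml.safe_load(ref.read_text())["basins"]


def _wrap_deg(a: np.ndarray | float) -> np.ndarray | float:
    return (a + 180.0) % 360.0 - 180.0


def classify_basin(phi: float, psi: float, basins: Mapping[str, dict]) -> str:
    """Nearest Ramachandran basin in width-normalised wrapped distance."""
    best, best_d = None, np.inf
    for name, b in basins.items():
        dphi = _wrap_deg(phi - b["center"][0]) / b["width"][0]
        dpsi = _wrap_deg(psi - b["center"][1]) / b["width"][1]
        dist = dphi**2 + dpsi**2
        if dist < best_d:
            best, best_d = name, dist
    return best


class ToyShiftPredictor:
    """Built-in dihedral-basin shift predictor.

    Predicted shift = random-coil value + a fixed per-basin offset from the
    versioned basin table: the helix basin lowers ΔδHA and raises ΔδCα, the
    strand basin does the reverse, the coil basin is offset-free.  Residues
    with an undefined φ or ψ (termini) are treated as coil.  Deterministic
    for a fixed conformer and table version.
    """

    predictor_id = "pepshift-toy:v1"
    nuclei = ("H", "HA", "N", "CA", "CB")

    def __init__(self, rc: RandomCoilModel | None = None):
        self.rc = rc if rc is not None else RandomCoilModel.from_packaged()
        self.basins = load_basins()

    def predict(
        self,
        peptide_id: str,
        residue_indices: np.ndarray,
        residue_names: Sequence[str],
        phi: np.ndarray,
        psi: np.ndarray,
    ) -> ShiftTable:
        rows = []
        for res_idx, res_name, f, y in zip(residue_indices, residue_names, phi, psi):
            if np.isnan(f) or np.isnan(y):
                basin = "coil"
            else:
                basin = classify_basin(float(f), float(y), self.basins)
            offsets = self.basins[basin]["offsets"]
            for atom in self.nuclei:
                ref = self.rc.lookup(res_name, atom)
                if ref is None:
                    continue
                rows.append(
                    {
                        "residue_index": int(res_idx),
                        "residue_name": res_name,
                        "atom_name": atom,
                        "shift_ppm": ref + float(offsets.get(atom, 0.0)),
                    }
                )
        return ShiftTable(peptide_id=peptide_id, data=pd.DataFrame(rows))


def predict_shifts(
    ens: ConformerEnsemble, model_id: int, predictor: ShiftPredictor
) -> ShiftTable:
    """Back-calculate a shift table for one conformer of an ensemble."""
    return predictor.predict(
        ens.peptide_id,
        ens.residue_indices,
        ens.residue_names,
        ens.phi[model_id],
        ens.psi[model_id],
    )


# ---------------------------------------------------------------------------
# Global CS-RMSD scoring, selection, Q factor
# ---------------------------------------------------------------------------

#: Nucleus classes entering the global CS-RMSD sum.
CS_RMSD_CLASSES = ("CA", "CB", "HN", "HA", "N", "Hside")


def global_cs_rmsd(
    obs: ShiftTable,
    pred: ShiftTable,
    class_weights: Mapping[str, float] | None = None,
) -> dict:
    """Global chemical-shift RMSD between observed and predicted tables.

    The RMSD is computed per nucleus class (Cα, Cβ, HN, Hα, N, side-chain H)
    over the (residue, atom) cells present in both tables; the global value
    is the sum of class RMSDs (unweighted by default).  Classes with no
    shared cells are skipped and listed under ``skipped_classes``.
    """
    a = obs.cells()
    b = pred.cells()
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared (residue, atom) cells between observed and predicted tables")
    diffs = (a.loc[shared] - b.loc[shared]).reset_index()
    diffs["cls"] = [_hn_class(atom) for atom in diffs["atom_name"]]
    per_class: dict[str, float] = {}
    for cls_name, grp in diffs.groupby("cls"):
        if cls_name not in CS_RMSD_CLASSES:
            continue
        per_class[cls_name] = float(np.sqrt(np.mean(grp["shift_ppm"] ** 2)))
    skipped = [c for c in CS_RMSD_CLASSES if c not in per_class]
    w = class_weights or {}
    global_ppm = float(sum(per_class[c] * float(w.get(c, 1.0)) for c in per_class))
    return {"per_class": per_class, "global_ppm": global_ppm, "skipped_classes": skipped}


def _mean_shift_table(tables: Sequence[ShiftTable]) -> ShiftTable:
    """Cell-wise mean of shift tables (fast-exchange population average)."""
    frames = [t.data for t in tables]
    cat = pd.concat(frames, ignore_index=True)
    grouped = (
        cat.groupby(["residue_index", "residue_name", "atom_name"], as_index=False)["shift_ppm"]
        .mean()
    )
    return ShiftTable(peptide_id=tables[0].peptide_id, data=grouped)


@dataclass
class SelectionResult:
    ranking: pd.DataFrame  # conformer_id, per-class columns, global_cs_rmsd
    selected_ids: list[int]
    mode: str
    seed: int | None
    ensemble_cs_rmsd: float  # score of the population-averaged predicted table
    ensemble_cs_rmsd_per_class: dict[str, float]
    mean_of_scores: float  # mean of per-conformer global scores, for transparency
    warning: str | None = None


def select_ensemble(
    obs: ShiftTable,
    predicted: Mapping[int, ShiftTable],
    n: int = 50,
    mode: str = "lowest",
    seed: int | None = None,
) -> SelectionResult:
    """Rank conformers by global CS-RMSD and select an N-member ensemble.

    ``predicted`` maps conformer id to its back-calculated shift table.
    Modes: ``lowest`` (the N best-scoring conformers, the CS selection
    protocol), ``highest`` and ``random`` (seeded, without replacement) as
    negative controls.  The ensemble-level score is the global CS-RMSD of
    the observed table against the cell-wise mean of the selected
    conformers' predicted tables; ties in ranking break on ascending
    conformer id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("lowest", "highest", "random"):
        raise ValueError(f"unknown selection mode {mode!r}")
    rows = []
    for cid in sorted(predicted):
        score = global_cs_rmsd(obs, predicted[cid])
        row = {"conformer_id": cid, "global_cs_rmsd": score["global_ppm"]}
        for cls_name, val in score["per_class"].items():
            row[f"rmsd_{cls_name}"] = val
        rows.append(row)
    ranking = pd.DataFrame(rows).sort_values(
        ["global_cs_rmsd", "conformer_id"], ascending=[True, True], kind="mergesort"
    ).reset_index(drop=True)

    warning = None
    n_avail = len(ranking)
    if n > n_avail:
        warning = f"requested {n} conformers but only {n_avail} available; selecting all"
        n = n_avail
    if mode == "lowest":
        selected = ranking["conformer_id"].head(n).tolist()
    elif mode == "highest":
        selected = (
            ranking.sort_values(
                ["global_cs_rmsd", "conformer_id"], ascending=[False, True], kind="mergesort"
            )["conformer_id"].head(n).tolist()
        )
    else:
        rng = np.random.default_rng(seed)
        selected = [int(c) for c in rng.choice(ranking["conformer_id"].to_numpy(), size=n, replace=False)]

    mean_table = _mean_shift_table([predicted[cid] for cid in selected])
    ens_score = global_cs_rmsd(obs, mean_table)
    sel_scores = ranking.set_index("conformer_id").loc[selected, "global_cs_rmsd"]
    return SelectionResult(
        ranking=ranking,
        selected_ids=[int(c) for c in selected],
        mode=mode,
        seed=seed,
        ensemble_cs_rmsd=ens_score["global_ppm"],
        ensemble_cs_rmsd_per_class=ens_score["per_class"],
        mean_of_scores=float(sel_scores.mean()),
        warning=warning,
    )


@dataclass
class ValidationReport:
    q_pooled: float
    q_per_class: dict[str, float]
    per_residue_cumulative: pd.DataFrame
    j_correlation: float | None = None


def q_factor(sec_obs: SecondaryShiftTable, sec_pred: SecondaryShiftTable) -> ValidationReport:
    """Q = rms(Δδobs − Δδpred) / rms(Δδobs) over shared secondary-shift cells.

    Operates on secondary shifts, not raw shifts.  Reported pooled over all
    shared cells and per nucleus class; undefined (ValueError) when
    rms(Δδobs) is zero.  Also returns the per-residue cumulative absolute
    shift difference.
    """
    a = sec_obs.data.set_index(["residue_index", "atom_name"])["delta_ppm"]
    b = sec_pred.data.set_index(["residue_index", "atom_name"])["delta_ppm"]
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no shared secondary-shift cells")
    obs = a.loc[shared]
    pred = b.loc[shared]
    rms_obs = float(np.sqrt(np.mean(obs**2)))
    if rms_obs == 0:
        raise ValueError("rms(Δδobs) is zero; Q factor undefined")
    q_pooled = float(np.sqrt(np.mean((obs - pred) ** 2)) / rms_obs)
    per_class: dict[str, float] = {}
    frame = (obs - pred).reset_index()
    frame["cls"] = [_hn_class(atom) for atom in frame["atom_name"]]
    obs_frame = obs.reset_index()
    obs_frame["cls"] = frame["cls"]
    for cls_name in frame["cls"].unique():
        do = obs_frame.loc[obs_frame["cls"] == cls_name, "delta_ppm"]
        dd = frame.loc[frame["cls"] == cls_name, "delta_ppm"]
        denom = float(np.sqrt(np.mean(do**2)))
        if denom > 0:
            per_class[cls_name] = float(np.sqrt(np.mean(dd**2)) / denom)
    cumulative = (
        (obs - pred).abs().groupby(level="residue_index").sum().rename("cumulative_abs_ppm")
    ).reset_index()
    return ValidationReport(q_pooled=q_pooled, q_per_class=per_class, per_residue_cumulative=cumulative)
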