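"""Chemical-shift analysis for flexible peptides.

Secondary chemical shifts (observed minus random-coil reference), secondary
structure calling from the ``ΔδCα − ΔδCβ`` difference, proline cis/trans
configuration from the ``Δβγ = δCβ − δCγ`` difference, cis populations from
peak intensities, and combined chemical-shift perturbations between peptide
variants.

All shift containers are thin wrappers around tidy :class:`pandas.DataFrame`
objects keyed by 1-based residue index and IUPAC-style atom label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ATOM_VOCABULARY",
    "DEFAULT_RESIDUE_ALIASES",
    "ShiftTable",
    "RandomCoilModel",
    "SecondaryShiftTable",
    "ProlineRecord",
    "CSPProfile",
    "secondary_shifts",
    "call_secondary_structure",
    "classify_proline",
    "cis_population",
    "combined_csp",
]

#: Controlled vocabulary of atom labels accepted in shift tables.  Backbone
#: nuclei plus the side-chain protons/carbons this pipeline consumes.
ATOM_VOCABULARY = frozenset(
    {
        "H", "HA", "HA2", "HA3", "N", "CA", "CB", "CG",
        "HB", "HB2", "HB3", "HG", "HG2", "HG3",
        "HD", "HD2", "HD3", "HE", "HE2", "HE3", "HZ", "HH",
    }
)

#: Non-standard residue types mapped onto the standard residue whose
#: random-coil values they borrow.  D-glutamate keeps L-Glu shifts;
#: homocitrulline differs from lysine only at the side-chain terminus and is
#: treated as lysine.
DEFAULT_RESIDUE_ALIASES: Mapping[str, str] = {"DGLU": "GLU", "HCIT": "LYS"}

_SHIFT_COLUMNS = ["peptide_id", "residue_index", "residue_name", "atom_name", "shift_ppm"]


def _hn_class(atom: str) -> str:
    """Nucleus class used for CS-RMSD bookkeeping: CA, CB, HN, HA, N or Hside."""
    if atom == "CA":
        return "CA"
    if atom == "CB":
        return "CB"
    if atom == "H":
        return "HN"
    if atom in ("HA", "HA2", "HA3"):
        return "HA"
    if atom == "N":
        return "N"
    if atom.startswith("H"):
        return "Hside"
    return "Cside"


@dataclass
class ShiftTable:
    """Per-residue, per-atom chemical shifts (ppm) for one peptide.

    Parameters
    ----------
    peptide_id:
        Identifier of the peptide the shifts belong to.
    data:
        Tidy frame with columns ``residue_index`` (1-based int),
        ``residue_name`` (3-letter code, non-standard codes allowed),
        ``atom_name`` (controlled vocabulary) and ``shift_ppm``.
        Missing values are absent rows, never sentinels.
    """

    peptide_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data, columns=[c for c in _SHIFT_COLUMNS if c != "peptide_id"])
        df = df.reset_index(drop=True)
        df["residue_index"] = df["residue_index"].astype(int)
        df["shift_ppm"] = df["shift_ppm"].astype(float)
        if (df["residue_index"] <= 0).any():
            raise ValueError("residue_index must be 1-based and strictly positive")
        if not np.isfinite(df["shift_ppm"]).all():
            raise ValueError("shift_ppm values must be finite")
        bad = set(df["atom_name"]) - ATOM_VOCABULARY
        if bad:
            raise ValueError(f"atom labels outside the controlled vocabulary: {sorted(bad)}")
        dup = df.duplicated(subset=["residue_index", "atom_name"], keep=False)
        if dup.any():
            rows = df.index[dup].tolist()
            raise ValueError(f"duplicated (residue_index, atom_name) cells at rows {rows}")
        self.data = df

    # -- convenience accessors -------------------------------------------------
    def get(self, residue_index: int, atom_name: str) -> float | None:
        sel = self.data[
            (self.data["residue_index"] == residue_index) & (self.data["atom_name"] == atom_name)
        ]
        if sel.empty:
            return None
        return float(sel["shift_ppm"].iloc[0])

    def residues(self) -> pd.DataFrame:
        """Unique (residue_index, residue_name) pairs, sorted by index."""
        return (
            self.data[["residue_index", "residue_name"]]
            .drop_duplicates()
            .sort_values("residue_index")
            .reset_index(drop=True)
        )

    def cells(self) -> pd.DataFrame:
        """Indexed view keyed by (residue_index, atom_name)."""
        return self.data.set_index(["residue_index", "atom_name"])["shift_ppm"]

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out.insert(0, "peptide_id", self.peptide_id)
        return out


@dataclass
class RandomCoilModel:
    """Residue-type random-coil reference shifts with optional corrections.

    ``table`` maps (residue_name, atom_name) -> shift (ppm).  ``corrections``
    holds optional additive neighbor/temperature/pH terms keyed the same way
    and defaults to zero everywhere.  ``aliases`` maps non-standard residue
    codes to the standard residue whose values they borrow.
    """

    table: pd.DataFrame
    corrections: Mapping[tuple[str, str], float] = field(default_factory=dict)
    aliases: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_RESIDUE_ALIASES))
    source_id: str = "custom"
    temperature_K: float = 298.0
    pH: float = 7.0

    @classmethod
    def from_packaged(cls, name: str = "random_coil") -> "RandomCoilModel":
        """Load the versioned random-coil table shipped with the package."""
        ref = resources.files("pepshift.data").joinpath(f"{name}.csv")
        with resources.as_file(ref) as path:
            table = pd.read_csv(path, comment="#")
        return cls(table=table, source_id=f"pepshift:{name}:v1")

    def lookup(self, residue_name: str, atom_name: str) -> float | None:
        """Reference shift for a residue type/atom, applying aliases.

        Raises ``KeyError`` for a residue type with no entry and no alias;
        returns ``None`` when the residue type is known but the atom is not
        tabulated for it (e.g. CB of glycine).
        """
        if not hasattr(self, "_cache"):
            cache: dict[tuple[str, str], float] = {}
            for row in self.table.itertuples():
                cache[(row.residue_name, row.atom_name)] = float(row.shift_ppm)
            object.__setattr__(self, "_cache", cache)
            object.__setattr__(self, "_known", set(self.table["residue_name"]))
        name = residue_name.upper()
        name = self.aliases.get(name, name)
        if name not in self._known:
            raise KeyError(
                f"no random-coil reference for residue type {residue_name!r} "
                f"(no alias configured; known aliases: {dict(self.aliases)})"
            )
        value = self._cache.get((name, atom_name))
        if value is None:
            return None
        return value + float(self.corrections.get((name, atom_name), 0.0))


@dataclass
class SecondaryShiftTable:
    """Per-residue secondary shifts Δδ = δobs − δrandom-coil (ppm).

    ``data`` is tidy with columns residue_index, residue_name, atom_name,
    delta_ppm.  ``ca_minus_cb`` holds the per-residue ΔδCα − ΔδCβ difference
    where both nuclei are populated; ``calls`` holds the per-residue
    secondary-structure call once assigned.
    """

    peptide_id: str
    data: pd.DataFrame
    ca_minus_cb: pd.Series
    calls: pd.Series | None = None

    def delta(self, residue_index: int, atom_name: str) -> float | None:
        sel = self.data[
            (self.data["residue_index"] == residue_index) & (self.data["atom_name"] == atom_name)
        ]
        if sel.empty:
            return None
        return float(sel["delta_ppm"].iloc[0])


@dataclass
class ProlineRecord:
    residue_index: int
    delta_cb: float
    delta_cg: float
    delta_bg: float
    configuration: str  # trans | cis | ambiguous
    cis_fraction: float | None = None

    @property
    def trans_fraction(self) -> float | None:
        return None if self.cis_fraction is None else 1.0 - self.cis_fraction


@dataclass
class CSPProfile:
    """Combined ¹H/¹⁵N/¹³C chemical-shift perturbation per residue."""

    data: pd.DataFrame  # residue_index, csp_ppm, flag
    mean: float
    sd: float


# ---------------------------------------------------------------------------
# Secondary shifts and structure calling
# ---------------------------------------------------------------------------

_SECONDARY_NUCLEI = ("H", "HA", "N", "CA", "CB")


def secondary_shifts(obs: ShiftTable, rc: RandomCoilModel) -> SecondaryShiftTable:
    """Compute secondary shifts Δδ = δobs − δrandom-coil for every observed cell.

    Only backbone nuclei (H, HA, N, CA, CB) are referenced; missing cells
    propagate as missing, never as zero.  An observed residue type with no
    random-coil entry and no configured alias raises ``KeyError`` naming the
    residue.
    """
    rows = []
    for _, row in obs.data.iterrows():
        atom = row["atom_name"]
        if atom not in _SECONDARY_NUCLEI:
            continue
        ref = rc.lookup(row["residue_name"], atom)
        if ref is None:
            continue
        rows.append(
            {
                "residue_index": int(row["residue_index"]),
                "residue_name": row["residue_name"],
                "atom_name": atom,
                "delta_ppm": float(row["shift_ppm"]) - ref,
            }
        )
    data = pd.DataFrame(rows, columns=["residue_index", "residue_name", "atom_name", "delta_ppm"])
    ca = data[data["atom_name"] == "CA"].set_index("residue_index")["delta_ppm"]
    cb = data[data["atom_name"] == "CB"].set_index("residue_index")["delta_ppm"]
    ca_minus_cb = (ca - cb).dropna().sort_index()
    return SecondaryShiftTable(peptide_id=obs.peptide_id, data=data, ca_minus_cb=ca_minus_cb)


def call_secondary_structure(
    sec: SecondaryShiftTable, window: int = 3, threshold_ppm: float = 2.0
) -> pd.Series:
    """Per-residue {helix, strand, coil} calls from ΔδCα − ΔδCβ runs.

    A residue is called helix (strand) when it belongs to a run of at least
    ``window`` consecutive residues whose ΔδCα − ΔδCβ values all exceed
    ``+threshold_ppm`` (fall below ``−threshold_ppm``).  Everything else,
    including residues without both Cα and Cβ shifts, is coil.
    """
    if window < 2:
        raise ValueError("window must be >= 2: a single-residue run is not 'consecutive'")
    series = sec.ca_minus_cb.sort_index()
    idx = series.index.to_numpy()
    vals = series.to_numpy()
    calls = pd.Series("coil", index=idx, dtype=object)
    n = len(idx)
    for sign, label in ((1, "helix"), (-1, "strand")):
        above = sign * vals > threshold_ppm
        i = 0
        while i < n:
            if not above[i]:
                i += 1
                continue
            j = i  # extend the run over consecutive residue indices
            while j + 1 < n and above[j + 1] and idx[j + 1] == idx[j] + 1:
                j += 1
            if j - i + 1 >= window:
                calls.iloc[i : j + 1] = label
            i = j + 1
    sec.calls = calls
    return calls


# ---------------------------------------------------------------------------
# Proline cis/trans analysis
# ---------------------------------------------------------------------------

def classify_proline(
    delta_cb: float,
    delta_cg: float,
    residue_index: int = 0,
    residue_name: str = "PRO",
    trans_max: float = 6.0,
    cis_min: float = 8.0,
) -> ProlineRecord:
    """Classify an Xaa-Pro peptide bond from the proline Cβ/Cγ shifts.

    Δβγ = δCβ − δCγ is ~5 ppm for a trans and ~10 ppm for a cis peptide
    bond; values between ``trans_max`` and ``cis_min`` are called ambiguous
    rather than forced onto either side.
    """
    if residue_name.upper() != "PRO":
        raise ValueError(f"Δβγ classification applies to prolines only, got {residue_name!r}")
    if trans_max >= cis_min:
        raise ValueError("trans_max must be below cis_min")
    dbg = float(delta_cb) - float(delta_cg)
    if dbg <= trans_max:
        config = "trans"
    elif dbg >= cis_min:
        config = "cis"
    else:
        config = "ambiguous"
    return ProlineRecord(
        residue_index=residue_index,
        delta_cb=float(delta_cb),
        delta_cg=float(delta_cg),
        delta_bg=dbg,
        configuration=config,
    )


def cis_population(i_cis: float, i_trans: float) -> float | None:
    """Cis fraction from cis/trans peak intensities: I_cis / (I_cis + I_trans).

    Returns ``None`` (missing) when both intensities are zero.
    """
    if i_cis < 0 or i_trans < 0:
        raise ValueError("peak intensities must be non-negative")
    total = i_cis + i_trans
    if total == 0:
        return None
    return i_cis / total


# ---------------------------------------------------------------------------
# Chemical-shift perturbation between peptide variants
# ---------------------------------------------------------------------------

#: Default per-nucleus CSP scale factors (root-mean-square combination):
#: protons 1.0, nitrogen 0.154, carbons 0.25 — standard practice for
#: combined ¹H/¹⁵N/¹³C perturbations.
DEFAULT_CSP_WEIGHTS: Mapping[str, float] = {"H": 1.0, "N": 0.154, "C": 0.25}


def _element_weight(atom: str, weights: Mapping[str, float]) -> float:
    return float(weights[atom[0]])


def combined_csp(
    a: ShiftTable,
    b: ShiftTable,
    weights: Mapping[str, float] | None = None,
    backbone_only: bool = False,
) -> CSPProfile:
    """Combined per-residue chemical-shift perturbation between two peptides.

    For each residue, CSP = sqrt(mean over shared nuclei of (w·Δδ)²) with
    element-wise weights ``w``.  Residues are flagged ``below_avg``,
    ``above_avg`` or ``above_avg_plus_sd`` against the profile mean and SD
    computed over non-missing residues.
    """
    w = dict(DEFAULT_CSP_WEIGHTS if weights is None else weights)
    if any(v <= 0 for v in w.values()):
        raise ValueError("CSP weights must be positive")
    cells_a = a.cells()
    cells_b = b.cells()
    shared = cells_a.index.intersection(cells_b.index)
    if backbone_only:
        shared = pd.MultiIndex.from_tuples(
            [t for t in shared if t[1] in ("H", "HA", "N", "CA", "CB")],
            names=shared.names,
        ) if len(shared) else shared
    if len(shared) == 0:
        raise ValueError("no common (residue, atom) cells between the two shift tables")
    diffs = (cells_a.loc[shared] - cells_b.loc[shared]).reset_index()
    diffs["w"] = [_element_weight(atom, w) for atom in diffs["atom_name"]]
    diffs["sq"] = (diffs["w"] * diffs["shift_ppm"]) ** 2
    per_res = diffs.groupby("residue_index")["sq"].mean().pow(0.5)
    mean = float(per_res.mean())
    sd = float(per_res.std(ddof=1)) if len(per_res) > 1 else 0.0
    flags = pd.Series("below_avg", index=per_res.index, dtype=object)
    flags[per_res >= mean] = "above_avg"
    flags[per_res >= mean + sd] = "above_avg_plus_sd"
    data = pd.DataFrame(
        {"residue_index": per_res.index, "csp_ppm": per_res.values, "flag": flags.values}
    )
    return CSPProfile(data=data, mean=mean, sd=sd)
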