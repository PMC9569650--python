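# Methods

`pepshift` implements the chemical-shift side of an integrated NMR/MD
workflow for flexible peptides: it reads per-residue chemical shifts and
candidate conformer ensembles, characterises local structure and dynamics
from the shifts, and selects the sub-ensemble of conformers that best
reproduces the observations. This note records the models, the tunable
parameters, the synthetic-data design and the numerical choices, in the
order the pipeline runs.

## Secondary shifts and structure calling

Secondary shifts are Δδ = δ_obs − δ_rc, where δ_rc is a residue-type
random-coil reference. The packaged reference (`data/random_coil.csv`,
version 1) holds standard literature statistical-coil values (ppm, neutral
pH, ~298 K) for H, HA, N, CA, CB; it is swappable via config, and
neighbor/temperature/pH corrections are additive terms that default to
zero. Non-standard residues go through an explicit alias map
(DGLU→GLU, HCIT→LYS — homocitrulline differs from lysine only at the
side-chain terminus); an unmapped residue type fails loudly rather than
silently borrowing glycine values.

Structure calls use the ΔδCα − ΔδCβ difference: a run of at least
`window` (default 3) consecutive residues above +2 ppm is helix, below
−2 ppm strand, everything else coil. "Consecutive" requires contiguous
residue numbering; a window below 2 is rejected because a single-residue
"run" is meaningless. The 3-residue default is the shortest window that
still demands corroboration from neighbours.

## Proline cis/trans and populations

The Xaa-Pro bond configuration follows Δβγ = δCβ − δCγ: ~5 ppm for trans,
~10 ppm for cis. Defaults call trans at Δβγ ≤ 6.0 ppm and cis at
≥ 8.0 ppm, with an explicit ambiguous band between, so near-boundary
shifts are never forced onto either side. Cis populations are
I_cis/(I_cis + I_trans) from peak intensities; both intensities zero is
reported missing, negative intensities are rejected.

## Combined chemical-shift perturbation

Between two peptide variants, per-residue
CSP = sqrt(mean over shared nuclei of (w·Δδ)²) with element weights
w_H = 1.0, w_N = 0.154, w_C = 0.25 (standard scaling of nitrogen and
carbon dispersions onto the proton scale; configurable). Both
backbone+side-chain (default) and backbone-only variants are supported.
Residues are flagged against the profile mean and mean+SD.

## ³J couplings and temperature coefficients

³J(HN–Hα) follows the Karplus relation
J(φ) = A·cos²(φ−θ₀) + B·cos(φ−θ₀) + C with θ₀ = +60°, the standard phase
between the backbone φ and the H–N–Cα–Hα dihedral. Two named coefficient
presets ship (`vuister_bax_1993`: 6.51/−1.76/1.60; `hu_bax_1997`:
7.09/−1.42/1.55 Hz); the default is `hu_bax_1997` and the active preset
id is stamped into every output, so swapping parameterisations is a
config change, not a code change. Ensemble couplings average φ over
models on the circle (unit-vector mean) before a single pass through the
curve — naive arithmetic averaging of angles breaks near ±180°. Observed
vs predicted couplings are compared by Pearson r and RMS deviation;
couplings outside (0, 15) Hz draw a warning, not an error.

Amide temperature coefficients are the OLS gradient of δ(HN) vs T in
ppb/K with its standard error. Classification: slope ≤ −4.6 ppb/K
solvent-exposed, in (−4.6, 0] consistent with intramolecular hydrogen
bonding, positive slopes conformational exchange or ring-current effects.
The boundary itself classifies as solvent-exposed (≤ convention, applied
with a last-digit floating-point tolerance).

## Ensemble clustering and CS-driven selection

Candidate ensembles are clustered on pairwise Cα RMSD after optimal
(Kabsch) superposition, with an average-linkage hierarchical tree. The
cut level is chosen by the Kelley penalty: at each level, the mean
within-cluster spread (mean pairwise distance over clusters of ≥2
members) is normalised across levels onto [1, M−1] and the cluster count
is added; the minimum wins, ties break toward fewer clusters. Identical
points therefore collapse to one cluster. Each cluster is represented by
its medoid (lowest model index on ties).

Shift back-calculation is a pluggable contract (geometry in, shift table
out). The built-in toy predictor adds fixed per-basin offsets
(`data/basins.yaml`, version 1) to the random-coil value after assigning
each residue's (φ, ψ) to the nearest Ramachandran basin in
width-normalised wrapped distance: the helix basin raises ΔδCα and lowers
ΔδHA, the strand basin does the reverse, coil is offset-free, termini
(undefined dihedrals) count as coil. The same basin table drives the
synthetic generator, so generation and prediction are mutually consistent
by construction. Real predictors (e.g. empirical shift surfaces) plug in
behind the same contract and are outside the test path.

Conformers are scored by a global CS-RMSD: the RMSD per nucleus class
(Cα, Cβ, HN, Hα, N, side-chain H) over cells shared between observed and
predicted tables, summed unweighted across classes (per-class weighting
exists but is off by default); classes absent from the observations are
skipped and logged. Selection keeps the N lowest-scoring conformers
(N = 50 by default), with highest-N and seeded random-N as negative
controls. The ensemble-level score treats the selection as a fast-exchange
population: the observed table is compared with the cell-wise mean of the
selected conformers' predicted tables. The mean of per-conformer scores
is also emitted for transparency, since a single reported ensemble value
could reasonably mean either. Ranking is a total order with ties broken
on ascending conformer id.

Validation uses Q = rms(Δδ_obs − Δδ_pred)/rms(Δδ_obs) on secondary
shifts (pooled and per class; undefined when rms(Δδ_obs)=0) and the ³J
correlation above.

## Dynamics metrics

Cα RMSF superposes all models onto a reference refined in two passes
(first model, then the provisional mean), then takes the root mean square
displacement from the mean position. Because superposition absorbs six
rigid-body degrees of freedom, an isotropic jitter of σ per coordinate
yields an expected RMSF slightly below σ√3 — about sqrt(1 − 6/(3n))·σ√3
for n Cα atoms — which the tests account for.

S² order parameters are predicted from shifts in the random-coil-index
spirit: the per-residue weighted mean m of |Δδ| (weights CA 1.0, CB 1.0,
N 0.4, H 8.0, HA 8.0 — protons up-weighted for their smaller dispersion)
is floored at m_min = 0.05 ppm and mapped monotonically to
S² = floor + (1−floor)(1 − exp(−(m − m_min)/scale)) with floor 0.3 and
scale 1.0 ppm. The preset id (`pepshift-rci:v1`) is stamped into outputs;
only ordering and bounds are asserted anywhere, never preset-specific
values, since the mapping is a calibration choice.

The T₂-filter model is I_CPMG/I₀ = exp(−R₂·T) for a CPMG filter of
duration T (nominal rate 1/T; the shipped defaults are 125 ms = 8 Hz and
250 ms = 4 Hz). A peak is detectable iff its ratio exceeds the noise
floor (default 0.1 of the unfiltered intensity) — i.e. its T₂ outlives
the filter. The floor turns the qualitative presence/absence reading of
filtered spectra into a quantitative, configurable criterion.

## Synthetic data: what it emulates and what it does not

The generator replaces spectrometer and MD-engine inputs. Conformers are
built per residue by drawing a Ramachandran basin from a population
vector, drawing (φ, ψ) from that basin's wrapped normal (helix
(−63, −42)±10°, strand (−120, 130)±15°, coil (−75, 150)±25°), and
extending an idealized backbone (fixed bond lengths/angles, ω = 180°,
NeRF construction). The cyclic penta-peptide head is enforced as a
CA(1)–CA(5) closure distance ≤ 10 Å with rejection sampling (a proxy for
the side-chain bridge of the c[K-R-G-D-e] macrocycle); persistent failure
reports the seed. Observed shift tables are the cell-wise mean of the toy
predictions over a hidden true sub-ensemble plus i.i.d. Gaussian noise
(default σ = 0.05 ppm). Temperature series are linear with −6 ppb/K
default slopes and 2 ppb noise over 298–310 K in 2 K steps; prolines emit
trans-like (Δβγ≈5) and cis-like (Δβγ≈10) peak pairs with intensities
proportional to populations (defaults 8% and 5% cis); default R₂ profiles
place five fast-relaxing residues (1, 7, 11, 12, 14) on a slow
background so a 250 ms filter removes exactly those peaks.

The recovery instance plants a coherent conformational state: 50 of 400
conformers draw basins from a helix-biased profile (85/0/15) while the
decoys sample uniformly (1/3 each). This coherence is what makes
recovery well-posed — if the true members were i.i.d. draws from the same
distribution as the decoys, proximity to their population average would
carry no membership information and any selector would sit at chance.
Passing recovery therefore demonstrates that the scoring and selection
machinery inverts the generative model it is given; it does not
demonstrate that a 50-member selection from real MD snapshots scored by a
real predictor identifies "the" solution ensemble, which is
underdetermined for disordered peptides. The generator likewise omits
side-chain geometry, force-field energetics, spectral overlap and peak
picking.

## Problem sizes and numerical choices

Default study sizes: candidate ensembles of ~400 conformers (391/400 in
the acceptance workloads), true sub-ensembles of 50, 14–19 residue
peptides, 7-point temperature series, 200-model jitter ensembles for the
RMSF closed-form check. The Kelley two-group check uses two tight
families (0.1 Å jitter about helical and extended references, 8 models
each) so the within-group spread is far below the between-group
distance, and re-derives the penalty minimum exhaustively at every cut
level. All stochastic paths take explicit seeds and are bit-reproducible;
CSV/PDB round trips preserve shifts exactly and coordinates to the 3
decimals PDB carries. Degenerate inputs are defined, not accidental:
identical models give zero RMSD/RMSF matrices, all-identical distances
give one cluster, zero-variance couplings report correlation as
undefined, and rms(Δδ_obs)=0 makes Q undefined rather than infinite.

## Known limitations

The toy predictor's offsets are deliberately coarse (three basins, fixed
offsets) and are not a substitute for empirical shift prediction on real
structures. The closure check constrains only the CA(1)–CA(5) distance,
not true macrocycle geometry or D-amino-acid chirality. The S² map and
the CSP weights are conventions with preset ids, not fitted calibrations.
Only multi-model PDB is read; trajectory formats are upstream
conversions.
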