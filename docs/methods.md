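# Methods

This note describes the statistical models behind `bundlemap`, the
conventions and tunable parameters that matter, what the synthetic
generators do and do not emulate, and the numerical choices made where the
design was genuinely open.

## Units and conventions

Coordinates and distances are micrometres; window areas are µm².  The
intensity of a pattern is always the empirical `λ = n / window area`
(points/µm² internally; the user-facing unit is bundles/mm², a factor of
10⁶).  No fitted or adaptive intensity ever enters the regularity
statistics: the homogeneous convention keeps λK and the Clark–Evans
benchmark interpretable across sections of very different packing density.
Analysis windows are axis-aligned rectangles; polygonal windows are out of
scope.

## Second-order statistics

**Ripley's K.**  K̂(r) = (A/n²) Σᵢ Σ_{j≠i} w_ij 1[d_ij ≤ r].  Corrections:
`none` (w = 1), `translation` (w_ij = A / |W ∩ W+(x_j−x_i)|, unbiased under
homogeneity, the default), and `border` (reduced-sample: only points at
least r from the boundary serve as reference points).  Radii beyond half
the shorter window side are truncated with a warning because every
correction breaks down there; the default grid is 100 radii from 0 to
min(side)/4.  The scaled presentation reports λK̂ against r√λ, computed
post hoc from the same estimate, never by re-estimating on a scaled grid.
Under complete spatial randomness λK = π at scaled radius 1 and ≈79 at
scaled radius 5; a *deficit* relative to π at scaled radius 1 is the
regularity signature used throughout.

`none` and `translation` estimates are non-decreasing in r by
construction.  The `border` estimator is not guaranteed monotone — its
risk set shrinks with r — which is a property of all reduced-sample
estimators, not a defect; monotonicity is asserted only for the other two.

**G function.**  The empirical CDF of per-point nearest-neighbour
distances, with `border` (reduced-sample) correction by default, reported
alongside the Poisson benchmark 1 − exp(−λπr²) and their difference.
Negative differences at small r mean nearest neighbours sit farther away
than chance — regularity.

**Clark–Evans ratio.**  R = d̄_NN · 2√λ, with z = (d̄_NN − 1/(2√λ)) /
(0.26136/√(n_used·λ)) and a two-sided normal p-value by default (one-sided
regularity tests by flag).  Homogeneity is assumed.  The default
`guard_margin` correction averages nearest-neighbour distances only over
points at least 1.5× the Poisson-expected NN distance (1.5/(2√λ)) from the
boundary, while neighbours may lie anywhere in the window.  The margin is
deliberately a *fixed* multiple of the expected NN distance rather than a
data-dependent quantity such as the largest observed NN distance: because
λ is estimated from the same pattern, the test's calibration relies on the
negative correlation between d̄_NN and the benchmark 1/(2√λ̂); a
data-dependent margin decouples the retained subset from that estimate and
measurably inflates the type-I error (to ≈9% at nominal 5% in CSR
simulations), whereas the fixed margin keeps the rejection rate inside
[0.03, 0.07] at the bundle densities of interest (≈650–1,300/mm²).  No
Donnelly small-sample correction is applied (known limitation: at n below
a few hundred the test drifts slightly anticonservative).

## Kernel intensity maps and bandwidth selection

λ̂(u) = Σᵢ φ_σ(u − xᵢ) / e(u), with φ_σ an isotropic Gaussian and e(u)
the mass of the kernel centred at the *evaluation point* that falls inside
the window (uniform edge correction).  This estimator is pointwise
unbiased under homogeneity — a flat pattern yields a flat map — and its
integral over the window is ≈n (within 5% for σ up to a quarter of the
window side; exact mass conservation would require a per-point correction
that is pointwise biased near edges, the wrong trade-off for maps that are
read off visually).  Values are reported in bundles/mm²; `scaled_values`
divides by the map mean so histograms of relative density are comparable
across sections.  Grid spacing defaults to σ/4 and warns above σ.

Near a window edge the kernel is one-sidedly truncated, so reading a
*gradient* off the map at the very boundary is biased toward the interior
value by roughly 0.8σ × slope even with edge correction.  Density
gradients should therefore be quantified between interior endpoints
(≥2σ from the boundary), which is how the gradient-recovery checks are set
up: a 204→424 bundles/mm² ramp over 2.5 mm, read at endpoints 600 µm
inside a wider window, is recovered within 10% at σ = 300 µm.

**Cross-validated bandwidth.**  `cv_bandwidth` maximises the leave-one-out
point-process log-likelihood Σᵢ log λ̂₋ᵢ(xᵢ) − ∫_W λ̂(u) du over a σ grid
(default: 24 log-spaced values from min(side)/50 to min(side)/4), with the
integral evaluated by midpoint quadrature on a σ/4 grid.  The criterion is
scale-equivariant: scaling the pattern and the grid by c scales the
optimum by c, exactly.  For *exactly* homogeneous patterns the criterion
is typically monotone increasing — the flattest map on offer is optimal —
so the argmax sits near the grid ceiling and a boundary warning is
emitted; on a ~2,000-point CSR pattern in a 2×2 mm window the selected σ
lands in the several-hundred-µm range (≈360 µm with the default grid).
Patterns with genuine structure (clusters, gradients) produce interior
optima, verified against an independent brute-force evaluation.

## Synthetic study conditions

The generators stand in for traced tangential sections and measured
distance sequences; their defaults are the study conditions used by the
tests and the acceptance script.

* `gen_poisson` — homogeneous Poisson, the null everywhere.
* `gen_hex_lattice` — triangular lattice; with zero jitter every interior
  point has six neighbours at exactly the spacing, the density is
  2/(√3·d²), and on a window commensurate with the lattice pitch the
  realized λ is exact, so the Clark–Evans closed form 2√2·3^(−1/4) = 2.1491
  is reproduced to < 0.01.
* `gen_hardcore` — Matérn type-II thinning: Poisson parent with uniform
  marks, a point dies if a neighbour within the hard-core distance carries
  an earlier mark.  The parent is drawn on a window buffered by the
  hard-core distance and clipped after thinning so the closed-form
  retained intensity (1 − exp(−λ_p πh²))/(πh²) holds without edge bias.
  Parameters violating the disk-jamming packing fraction (0.5472) are
  rejected.
* `gen_banded` — the morphology actually observed: quasi-parallel strings
  of bundles, spaced `band_spacing` apart, each perturbed sinusoidally
  (amplitude `wobble`, wavelength 400 µm, independent random phases) with
  points every `along_spacing` along the string.  With band 60 µm /
  along 25 µm / wobble 16 µm the maps show nearest neighbours
  concentrated in 20–45 µm, Clark–Evans R ≈ 1.30 (inside the 1.2–1.45
  band typical of real sections) and a λK deficit at scaled radius 1 of
  ≈0.8 (observed order ≈0.7).  The wobble amplitude and wavelength have no
  measured counterparts; they were calibrated once against this K/G
  signature and frozen.  String bifurcation is available
  (`branch_prob_per_um`) but defaults off, as no branching statistics
  exist to match.
* `gen_gradient_poisson` — linear intensity ramp along one axis, realised
  by thinning a homogeneous parent at the peak rate.
* `gen_distance_sequence` — shifted gamma matched to target mean/SD/skew
  by moments (shape 4/γ², scale s·γ/2, shift m − 2s/γ), Gaussian at γ = 0,
  with optional AR(1) rank reordering to emulate smooth spacing gradients.
  The family cannot represent weakly skewed, strongly dispersed targets
  whose implied shift is negative (γ < 2s/m, e.g. the hedgehog block's
  printed moments); such requests are rejected with a suggestion rather
  than silently truncated.

All generators draw from a single seeded stream per call and are
bit-reproducible; none of them emulates staining artefacts, blood-vessel
exclusions, curvature of the cortical sheet, or measurement error in
bundle-centre placement — so passing tests certify the estimators under
the stated geometric models, not robustness to histological noise.

## Distance-sequence statistics

Summaries report the n−1 SD, bias-adjusted skewness and excess kurtosis,
and a KS normality screen using the sample's own mean/SD.  No Lilliefors
correction is applied — the printed tables this mirrors use the naive
test, whose p-values are inflated by parameter estimation; this is a
faithful-reproduction choice, and the screen is used only as a gate for
choosing between t and Mann–Whitney comparisons.  Histograms are anchored
at zero with left-closed bins.  Mann–Whitney uses exact enumeration for
tie-free samples up to n = 20 per group, otherwise the tie-corrected
normal approximation; Kruskal–Wallis delegates to Mann–Whitney for two
groups.  The sequential scan partitions the traverse into consecutive
groups (default 100), drops a trailing remainder, and reports raw adjacent
p-values (a Holm adjustment is available but off by default, matching how
such scans are conventionally displayed).

## Species-level estimators

Total minicolumns in left V-1 = bundle density × V-1 area, rounded to the
nearest integer (banker's rounding).  Species with both tangential and
orthogonal density estimates carry a (low, high) range; regressions
resolve ranges by a `midpoint` / `low` / `high` policy, except that a
species whose table row prints a single total (the guinea pig) uses the
orthogonal-density product, the tabulated convention.  Neurons per
minicolumn = areal neuron density (V-1 neurons / area) × π(d/2)² with d
the median inter-bundle spacing converted to mm.  Known anomalies are
preserved, not repaired: the hedgehog's printed total (8,665) differs from
its own density × area (8,865), and the primate neurons-per-column entries
are ~10× below what the cylinder formula yields from the printed V-1
totals; both recomputed and printed values are exposed side by side, and
the primate rows are excluded from exact checks.

Power-law fits are OLS of log₁₀y on log₁₀x; R² equals the squared Pearson
correlation of the logs and is invariant to unit rescaling.  Across the
packaged table the acuity ~ total-minicolumn fit gives R² = 0.916 at the
midpoint policy (0.900/0.920 at the low/high endpoints) — a strong
relationship, though lower than the 0.97 sometimes quoted for this
comparison, which is not reachable from the packaged values under any
endpoint convention (verified exhaustively); acuity ~ median spacing gives
R² ≈ 0.01, confirming that the *count*, not the spacing, carries the
signal.  CP-ratio fits are exposed only for user-supplied data, since no
CP values are packaged.

## Problem sizes

The test suite and acceptance script use: 200-pattern CSR ensembles of
n ≈ 500 for the K benchmarks; 1,000 CSR simulations at 643 bundles/mm² in
1 mm² for Clark–Evans calibration; 10-seed banded ensembles in 1.5×1.5 mm
windows for the regularity signature; a ~2,250-point gradient pattern and
a ~2,000-point CSR pattern for density mapping and bandwidth selection.
These sizes put Monte-Carlo error well below the tolerances they are
checked against while keeping a full run under a minute.

## Known limitations

* Clark–Evans uses the classical normal approximation only (no Donnelly
  correction); refuse below n = 10, mildly anticonservative below a few
  hundred points.
* Inhomogeneous K, the pair-correlation function, anisotropy analysis and
  simulation envelopes beyond the Poisson closed forms are out of scope.
* The banded generator's curvature/branching parameters are qualitative
  stand-ins; only the K/G/R signatures, not the visual morphology, are
  matched quantitatively.
* Density maps assume a rectangular window; sections with irregular
  outlines must be cropped to a rectangle before analysis.
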