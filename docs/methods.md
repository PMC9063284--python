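# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
test worlds do and do not establish about real data.

## Index construction

**Components.** Seven built-environment quantities per spatial unit:
population density (inhabitants/ha), retail & service density (area
fraction), land-use mix (entropy), street connectivity (true
intersections/km²), green space (area fraction), sidewalk density (area
fraction), public transport density (stops/km²). Raw layers are rasterized
to square cells (25 m default): polygon layers as exact per-cell area
fractions, point layers as per-cell counts with half-open cell ownership
(`[x0, x0+cell) × [y0, y0+cell)`, origin at the lower-left), so boundary
points are never double-counted.

**True intersections.** Nodes of the street network where ≥ 3
pedestrian-accessible legs meet. Degree is counted on segment endpoints
after removing inaccessible road classes (configurable; default
`{highway, motorway}`), so reclassifying one arm can demote a crossing to a
through-node. The network must be noded: endpoints that are nearly but not
exactly coincident raise an error listing the offending coordinates rather
than being silently snapped (silent repair hides data errors); an explicit
`snap_network(tolerance)` preprocessor is available.

**Buffer aggregation.** Focal statistics with a circular kernel: a cell
belongs to the kernel if its *centre* lies within the radius of the focal
cell's centre. At raster edges the denominator shrinks to the in-bounds
kernel cells, keeping edge means unbiased. Count layers are converted to
densities by dividing the kernel mean (events per cell) by the cell area;
point densities are reported per km² and population per hectare (the unit
choice cancels after z-standardization; these are chosen for
interpretability). Radii below the cell size degenerate to the identity
(warned). The implementation accumulates shifted array copies in a fixed
offset order, which makes it bit-identical to a per-cell loop evaluating
offsets in the same order — the property the oracle tests exploit.
Sub-cell (area-weighted) kernel membership is out of scope.

**Land-use mix.** Normalized Shannon entropy over k = 5 walking-relevant
classes, `H = -Σ pᵢ ln pᵢ / ln k`, with `0·ln 0 = 0`; the stated [0, 1]
range with 1 = perfect mix forces the `ln k` normalization. Shares are
aggregated over the buffer (or zone) *first* and the entropy taken second:
the quantity describes how evenly land uses are distributed over the area,
which the mean of cellwise entropies does not. A unit with no relevant
area scores 0 and is logged. Density denominators use the full buffer
area (no land/water distinction).

**Neighbourhood scale.** Zonal means of the identical raw rasters over
non-overlapping polygons (cell-centre-in-polygon membership); zones without
cell centres are missing and logged. Each unit inherits the values of its
containing neighbourhood, so all four scales share one table schema.

**Composite.** Per scale: z-standardize each component with the sample
(n−1) SD — the choice is immaterial after min-max scaling but fixed for
reproducibility; a constant component is an error naming the component.
The raw index is the unweighted mean of the seven z-scores (weighted or
data-driven composites are out of scope), then min-max scaled to 0–100.
Standardization and scaling are relative to *whatever unit universe is
supplied*: indices built on different universes, or different scales, are
not comparable, and each buffer size is scaled on its own distribution.
Leave-one-out partial indices are the means of the remaining six z-scores,
each re-scaled to 0–100 independently so "per 10 points" is comparable
across partials; the mean of the seven *raw* partials reproduces the full
raw index exactly (a consistency identity the tests check). Quintiles use
average ranks with the ceiling rule `⌈5r/n⌉`, which is deterministic and
total under ties.

## Walking outcomes

Trip diaries yield per-respondent daily totals of walking minutes and
metres, split by purpose class: work and study are non-discretionary
(fixed destinations); grocery shopping, shopping, leisure walks,
sports/hobby, recreational visits, home visits and residual "other" trips
are discretionary (destination choice). The vocabulary is an explicit
mapping; unknown labels raise rather than default. A respondent with a
completed diary and no walking legs is a true observed zero — the
left-censored observation the Tobit model depends on — never a missing
value. Only walking legs of multi-modal trips contribute (whole-trip
attribution is configurable for sources without stage detail), and
access/egress walking to public transport counts as walking. Inclusion
rules: age 18–65 inclusive, no personal-circumstance immobility, no travel
abroad, then complete-case deletion on the model variables with a
per-variable missingness log. The rules are intersections of row masks,
hence order-invariant.

## Censored regression

With more than half of respondents at zero, OLS on observed minutes is
biased toward zero. The Tobit model assumes a latent `y* = xβ + ε`,
`ε ~ N(0, σ²)`, observed as `y = max(0, y*)`, with log-likelihood

```
ℓ(β, σ) = Σ_{y=0} log Φ(−xβ/σ) + Σ_{y>0} [ log φ((y−xβ)/σ) − log σ ].
```

Maximization is BFGS over `(β, log σ)` (the log enforces σ > 0) with
analytic gradients, `log Φ` evaluated stably via `log_ndtr`, the inverse
Mills ratio in log space, OLS-on-positives initialization and three
jittered restarts. Convergence is judged by the relative gradient norm at
the solution (BFGS's own line-search can report "precision loss" at a
genuine optimum). The coefficient covariance is the inverse observed
information, obtained by central differences of the analytic gradient;
σ's standard error comes off the `log σ` diagonal by the delta method.
Degenerate inputs (all-censored outcome, rank-deficient design, n ≤ p)
raise; non-convergence is reported, never hidden. Observations are treated
as independent — no clustering or multilevel structure — and
marginal-effect decompositions are not computed; coefficients are on the
latent scale.

Effects are reported per 10 points of the 0–100 index — "a 10% increase"
of a scale spanning exactly 0–100 — with 95% Wald intervals (`10·(β ±
1.96·SE)`); Wald matches standard censored-regression reporting.
Model 1 is unadjusted; Model 2 adds the full confounder set (age group,
sex, ethnic background, education, work status, household income, car
ownership, household composition, same-day cycling, season, weekday,
response type as full dummy blocks against the first level, and the
continuous neighbourhood SES score). The attenuation analysis refits
Model 2 with each partial index and flags the smallest estimate; stratified
fits drop the stratifier from the confounder set within its strata and
report too-small strata as not estimable; interaction tests are joint Wald
chi-squared tests of index × modifier dummy products in the pooled model.
Distance outcomes run through the identical machinery.

## Synthetic worlds

The generator emulates the *structure* of national data, not its
geography. One scenario seed is expanded into fixed per-stage substreams
(landscape, survey), so stages regenerate independently and
bit-identically. Coordinates are arbitrary planar metres — all component
math needs only a metric frame, so no georeferencing is attached.

Defaults (one place to read them: `SyntheticScenario`): 5 km × 5 km extent,
25 m cells, 3 urban centres, 400 postal-code units, 2000 respondents.
Population is a sum of Gaussian kernels (peak ≈ 5 inhabitants/cell ≈ 80/ha,
kernel SD ≈ extent/8) plus truncated noise. Urbanicity (population scaled
to [0, 1]) drives everything else: land-use class probabilities (at
urbanicity 0 only residential fill and non-relevant area remain), transit
intensity (inhomogeneous Poisson, ~0.001–0.05 stops/cell), and sidewalk
share (0.05 + 0.5·urbanicity). Sidewalk noise has a spatially coherent
blockwise component in addition to white noise — buffer averaging
annihilates white noise, which would otherwise leave sidewalk density
collinear with population density, unlike real data where the components
are strongly but imperfectly correlated. Roads form a jittered axis-aligned
grid (250 m spacing), noded at every crossing, with a small fraction of
lines classed as highways; neighbourhoods are a 5 × 5 rectangular
partition; unit centroids are population-weighted distinct cells.

The survey draws covariates independently from configurable categorical
margins loosely matching a national travel survey's composition (≈52%
female, ≈83% native background, three age bands, etc. — only the schema,
not the exact margins, matters for testing); neighbourhood SES is mildly
*decreasing* in walkability, mimicking the observed gradient. The latent
outcome is `intercept + 0.85·walkability + γ'covariates + ε` with σ = 35
min; the slope matches the scale of published effect estimates (≈8.5 min
per 10 points) and σ the observed outcome dispersion (SD ≈ 25 min on a
zero-heavy outcome). The intercept is calibrated by bisection on the
expected censored share so that a configured fraction (default 55%) of
respondents reports zero — the "more than half" regime. Observed minutes
are the rounded positive part of the latent outcome: diaries report whole
minutes, and integer totals make the per-trip re-sum invariant exact in
floating point. Trips allocate the daily minutes multinomially over 1–3
purpose-labelled trips; metres are minutes × a per-respondent walking
speed ≈ N(80, 4) m/min clipped to [60, 100] — any fixed plausible speed
preserves the minutes/metres proportionality. Small rates of out-of-range
ages (2%), immobility (1.5%) and abroad travel (1%) give the exclusion
rules work to do. Component-driven worlds (`true_component_betas`, in
latent minutes per component z-SD) support the attenuation validation; the
driver effect there is set large enough (25 min/SD at n = 2000) that the
leave-one-out signature is separable from the strong inter-component
correlation the urban gradient induces.

**What passing tests do not show.** Covariates are drawn independently, so
real-world confounding structure (beyond the built-in SES–walkability
gradient) is absent; the road grid and rectangular neighbourhoods carry no
realistic topology; there is no survey nonresponse, weighting, trip
chaining or residential self-selection. Calibration results (CI coverage,
attenuation detection) demonstrate correctness of the estimators under the
assumed data-generating process, not the substantive validity of any
real-world index.

## Numerical choices and problem sizes

Entropy clips floating-point residue into [0, 1]; share vectors must sum
to 1 within 1e−9. Constant-column detection uses exact range (max = min),
not a computed SD, which carries rounding residue. The focal oracle
comparison is bit-exact by construction (same fold order). Likelihood
agreement with an independent erfc-based implementation is asserted to
1e−10; the uncensored Tobit/OLS limit to 1e−6 relative. Test problem
sizes — 200 replicates of n = 2000 for coverage, 20 seeds of a 200 × 200
cell landscape for attenuation, 40 × 40 grids for the focal oracle — keep
the full suite under two minutes while leaving the Monte Carlo bands
(93–97% coverage, ≥ 18/20 attenuation hits) statistically meaningful.

Pipeline artifacts are plain text (ASCII grids, GeoJSON, CSV, JSON
manifest) with fixed float formatting and sorted keys, so a re-run with
the same config is byte-identical; the manifest records per-stage SHA-256
checksums and no timestamps.
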