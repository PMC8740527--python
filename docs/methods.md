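# Methods

## The measurement model

An incubation starts at T0 with dissolved organic carbon DOC₀ and a small
bacterioplankton inoculum. Cells grow on the dissolved pool until a
limiting resource is exhausted (stationary phase, typically day 6–10),
and a fraction BGE of every consumed carbon atom is retained as biomass:

    BB(t) − BB(0) = BGE · [DOC*(0) − DOC*(t)],   DOC* = OC − BB.

Because samples are not re-filtered at every time point, the measured
organic carbon OC contains the cells; subtracting biomass carbon BB gives
the dissolved pool DOC* actually being drawn down. Differentiating the
identity above gives the estimator used throughout: BGE is the quotient
of the two fitted slopes (BP over the DOC* removal rate), which is exact
for any growth shape because OLS is linear in the response — the
curvature of BB(t) cancels in the ratio.

Model-I (ordinary least squares) regression is used for both slopes, as
is conventional when time is the error-free regressor. Model-II
(standardized major axis) and exponential fits are provided separately
(`omrex.stats`) for relationships where both variables carry error, e.g.
drawdown rates against the initial degradation index.

### Resolvability gates

A growth efficiency is reported only when (1) the T0→stationary DOC*
drawdown exceeds 1.4 µmol C L⁻¹ — twice the 0.7 µmol C L⁻¹
high-temperature-combustion precision, so the signal is analytically
resolvable — and (2) both slope regressions are significant (two-tailed
p < 0.05). The gates are a pure conjunction; raising any threshold can
only remove reported values.

### Error propagation

The BGE uncertainty is standard first-order propagation for a quotient,
σ_BGE = BGE·√[(σ_r/r)² + (σ_BP/BP)²]. A `mode="literal"` variant of
`bge_error` evaluates the same expression with the ratios inverted
(value/error in place of error/value). It exists because that inverted
form circulates in the literature; on representative inputs (rate 0.18 ± 0.03, BP
0.07 ± 0.01, BGE 0.389) it yields 3.59 where the propagated value is
0.085, i.e. it cannot produce tabled uncertainties of a few hundredths,
and the test suite documents this inconsistency explicitly. The standard
mode is the default.

## Stationary-phase detection

"No cell growth with time" is operationalized as a changepoint: ln
abundance is modelled as a rising line up to a breakpoint and flat (or
declining — the grazing-driven death phase of undiluted treatments)
afterwards. The breakpoint among observed times minimizing a BIC over
both segments is selected; the growth segment must then be significantly
positive (one-sided p < 0.05), otherwise the series has no growth, and a
series whose best model is a single growth line has no stationary phase
yet. An earlier design — testing each trailing 3-point window for
significant growth — was abandoned: with one residual degree of freedom
the window test is so weak that ordinary measurement noise (3% CV)
produces false stalls days before, and spurious "growth", days after, the
true plateau. The changepoint form recovers planted stationary days
within ±1 day across the synthetic suite while honouring the same verbal
definition of stationary phase. Detected onsets can always be overridden per experiment via
the `days_to_stationary` column.

## Biomass conversion choices

* Sphere diameter for low-aspect cells is (max + min)/2 — symmetric, and
  exact when the two dimensions agree. Rod radius is min/2 (a cell's
  width), the standard bacilli geometry that makes h = max − min the
  cylinder length. Aspect ratio exactly 1.5 takes the rod branch (the
  sphere rule is strictly "< 1.5").
* Per-image mean biovolume is the arithmetic mean of per-cell
  biovolumes, and per-experiment cell carbon applies the power law to
  the mean biovolume (not the mean of per-cell carbons); a
  per-cell aggregation path is exposed for sensitivity checks
  (`aggregation="cell"`). Because a·V^b is concave for b < 1 the two
  orders differ by a few percent at realistic size spreads.
* All carbon mass uses 12.011 g mol⁻¹. Three biovolume→carbon
  calibrations ship as configuration: (91.71, 0.686), (108.8, 0.898) and
  (103.02, 0.59); swapping them rescales BP and BGE roughly
  proportionally.
* Filter-based particulate carbon is corrected as
  (measured − 5.3 µg C L⁻¹)/0.783, a DOM-sorption blank and a cell
  retention fraction, floored at zero.

## Amino-acid indicators

mol% composition, THAA carbon (weighting each analyte by its carbon
atoms) and two degradation indicators: the DI — a weighted sum of
standardized mol% values, invariant to overall concentration — and the
combined mol% of GABA + beta-alanine, non-protein products of amino-acid
decomposition that accumulate as material degrades. The 18-analyte set
and the DI coefficient table are configuration with a provenance label.
**The shipped DI defaults are synthetic illustrative values**: the signs
follow the qualitative pattern of protein-amino-acid degradation indices
(aromatic and branched-chain amino acids load positive/fresh; Gly, Ser,
Thr negative/degraded), but the numbers are not a published calibration
and results on real data should substitute one. Non-protein amino acids
are normalized into mol% but excluded from the DI unless the coefficient
table lists them; acid-hydrolysis losses (e.g. Trp destruction) are not
corrected. Phase shifts are tested per indicator with a two-sample
t-test on replicates; "more degraded" means DI fell or GABA+B-Ala rose
significantly.

## MS feature z-scores

Features are kept when the maximum sample area exceeds 3× the process
blank (zero blank keeps any detected feature). "Relative abundance" for
z-scoring is the peak area itself: the z-score is invariant to any
per-feature affine rescaling, so total-area normalization only matters
through sample-level weighting and is left to the caller. The sample
standard deviation (n − 1) is used; with the small sample counts typical
of these experiments this is materially different from the population
form and is the documented convention. Constant features have no defined
z-score and are excluded with a warning. Class summaries use a
one-sample t-test of Δz against zero (classes with zero spread are
treated exactly: p = 0 for a nonzero mean); the correlation screen
reports raw Pearson p-values, matching the published analysis style, with
Benjamini–Hochberg left to the caller as an option.

## Community statistics

Alpha diversity is computed on non-rarefied counts — at these read
depths H is insensitive to sampling effort, and rarefaction discards
data; a rarefying option remains for sensitivity checks. Natural log is
the default base. The Shannon variance is the classical large-sample form
var(H) = [Σ p ln²p − H²]/N + (S − 1)/(2N²), and Hutcheson's t-test uses
t = (H₁−H₂)/√(V₁+V₂) with Welch-style degrees of freedom. With read
depths above 10⁴ the variances are tiny, so even small H differences are
formally significant — the test answers "are these two sequenced samples
drawn from the same composition", not "is the ecological difference
large".

Responder calls add a detection-limit pseudocount of 1/read-depth to both
phases' relative abundances before the log2 ratio, so taxa absent at one
phase get finite fold changes; the threshold log2(3) ≈ 1.58 encodes "at
least threefold". The indicator statistic is the point-biserial
correlation between an ASV's abundances and group membership, computed
with group-equalizing weights (each group contributes equal total weight,
so unequal group sizes do not bias the statistic; with equal sizes it is
the plain correlation). Permutation significance compares |r.g| against
label shuffles — two-sided, since a perfect anti-indicator is as extreme
as a perfect indicator — with p = (1 + #{|perm| ≥ |obs|})/(1 + n_perm)
for random permutations and the exact enumeration fraction when all
distinct label arrangements are feasible (≤ ~5,000 arrangements). Only
the single-group point-biserial form is implemented; the full multi-level
site-combination search of dedicated indicator-species software is out of
scope.

## The synthetic generator

The generator mirrors the marginal statistical structure of the field
experiments; it is phenomenological, not mechanistic (no grazer dynamics,
iron limitation or priming), so passing tests demonstrate that the
estimators recover the quantities these experiments are designed to
measure, not that any particular ocean behaves this way.

* **Growth**: lag (1–2 d) → exponential → stationary, with an
  exponential death phase after stationary in undiluted treatments. The
  piecewise form makes the planted stationary day identifiable — a
  smooth logistic visibly plateaus days before its nominal saturation
  point, which no detector can undo. Cell dimensions are drawn by
  inverting the sphere/rod formulas at biovolumes uniform in
  0.03–0.09 µm³ and aspect ratios in 1.0–1.9.
* **Carbon**: OC(t) = DOC₀ + BB(t) − ΔBB(t)/BGE_true plus N(0, 0.7²)
  per replicate vial (triplicates), DOC₀ uniform in 54–61 µmol C L⁻¹,
  seven sampling times T0→stationary (the 2–3-day schedule) and sparse
  ~20-day sampling to day 90 with a slow residual removal
  (0.02 µmol C L⁻¹ d⁻¹). At BGE_true = 1, OC is exactly flat — consumed
  carbon reappears as biomass — while DOC* declines at BP; that identity
  is what the estimator inverts.
* **Amino acids**: phase compositions are convex mixtures from a fresh
  toward a degraded endmember (GABA+B-Ala 1.0 → 6.6 mol% across the full
  trajectory), with total THAA carbon declining by 33% of the concurrent
  DOC* decline and 4% replicate CV.
* **MS**: lognormal areas; a planted labile subset (40% of amino
  acid-like and terpenoid-like features) decays ×0.55 by stationary
  phase; a contaminant subset carries blanks above one third of its
  maximum area so the 3× filter removes it.
* **ASVs**: a deterministic base composition — 13 dominant stable taxa
  holding 55% (the SAR11/SAR86-like fraction), ranks 14–100 holding 41%
  (so the top 100 carry ≈96%), a 392-ASV rare tail — jittered once per
  experiment by a Dirichlet draw (concentration parameter scales the
  per-ASV Dirichlet totals; the default gives mild between-experiment
  overdispersion while keeping the two phases of one experiment coupled,
  as they are in a real incubation). Twelve planted responders among the
  mid ranks multiply sixfold at stationary before renormalization —
  comfortably in the "at least threefold" class; a fold exactly at 3
  lands *below* the log2(3) threshold after renormalization and is not a
  recoverable design. Read depths are uniform in 10,951–44,686 and
  counts multinomial, two replicate samples per phase.

All generators are pure functions of (params, seed).

## Problem sizes and numerical conventions

The shipped test and acceptance runs use 4-experiment bundles,
200 Monte-Carlo replicates per BGE truth value, six seeds × four
experiments for responder precision/recall, and 199–9,999 permutations
for indicator tests — sizes chosen so the whole suite completes in
seconds while leaving Monte-Carlo standard errors an order of magnitude
below the tolerances being checked. Ties in top-N selection break by ASV
id; empty strata are omitted from summaries and singleton strata report
an undefined (NaN) SD; summary statistics use the sample SD (ddof = 1).
Rates are reported at full precision internally and rounded to two
decimals only in table-emulation output.

## Known limitations

* The DI coefficients are placeholders (see above); absolute DI values
  are therefore not comparable to published scores until a real
  calibration is configured.
* `analyze_experiment` treats replicate DOC* observations as independent
  regression points, matching the triplicate-vial design; serially
  correlated instrument drift would narrow the reported errors.
* The undiluted design confounds growth with grazing and viral loss; the
  package only annotates treatment, it does not model mortality.
* Hutcheson's test inherits the multinomial-sampling view of diversity;
  it ignores compositional overdispersion between biological replicates.
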