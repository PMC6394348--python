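# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `surveysub`, in the spirit of a package methods
appendix. Everything here is implemented and exercised by the test suite;
no number is quoted that the code does not compute.

## 1. Virtual population

**Resampling.** A virtual population is built from the three survey tables
by resampling: each site receives as many fish as were measured there on
average over the five survey years matching a scenario, and each fish's
1-cm length bin and (when known) sex are drawn with replacement from the
site's pooled scenario-year length records. Lengths are jittered uniformly
to mm within the bin. A site never measured during the scenario years
borrows its depth-stratum pool. This preserves the site-level abundance and
length structure of the input data without assuming a parametric length
distribution.

**Scenarios.** Six scenarios condition the resampling on the five most
extreme years by: mean middle-shelf bottom temperature (warm/cold), Simpson
diversity 1 − Σp² of the otolith age composition (high/low diversity), and
total catch (high/low abundance). Two pairing constraints prevent
confounding: the diversity pair shares identical per-site fish counts
(targets computed over all years for both members), and the abundance pair
must agree in age composition to within 3 percentage points at every age
group. The undocumented detail here is the enforcement mechanism; we
re-draw the low-abundance resampling (same years, fresh randomness) up to
200 times and fail loudly with the worst per-age discrepancy if the bound
cannot be met. The 3% bound is interpreted on composition *proportions*
(percentage points), since the pair's totals differ by construction.

**Sex assignment.** Undetermined sexes are resolved by drawing from the most
specific sex ratio supported by ≥ 10 known-sex fish, escalating
cm × site → cm × stratum → cm → overall. The threshold of 10 is the
conventional minimum cell size for a stable binomial ratio.

**Size-at-age.** True continuous age is
α + β₁(sex)·size_mm² + β₂·rλ + e. The β₁ (1.05e-5 male, 1.0e-5 female,
per mm²) and β₂ (−0.031 yr per rotated-latitude degree) defaults are the
relation's published magnitudes; they are plausible only with size in mm
(a 80 cm fish maps to ~6.4–6.7 years), so mm is the internal unit and cm
coefficients are accepted via `size_unit`. α is not published; the default
0.5 yr, with rλ centered on the domain mean, places the young length modes
(20–40 cm) at ages 1–3. Continuous age is rounded **half up** and clipped
to [0, 12]; rounding direction is an undocumented detail of the source
analysis, and half-up keeps the mode-to-age mapping symmetric.

**Spatial error.** e is a zero-mean Gaussian random field over sites,
specified by a covariogram (family, nugget, sill, range) and simulated
exactly by Cholesky factorization of the site covariance — cheap at a few
hundred sites and free of spectral-approximation error. Defaults
(exponential, nugget 0.05 yr², sill 0.25 yr², range = 15% of the site-cloud
diagonal) are not published; they give site-level age shifts of ±0.5 yr
(1 sd) with visible but not overwhelming patchiness, and every parameter is
configurable. With sill = nugget the field degenerates to independent site
noise; with sill = 0 it vanishes — these are the sensitivity-grid arms.
An optional per-fish independent noise term (default 0) is available.

**Geometry.** Coordinates are treated as planar at survey scale (no
projection); rotation preserves pairwise distances exactly. The rotation
angle defaults to −45°, aligning a NW–SE shelf axis with N–S; rλ is the
centered rotated latitude. The cruise route is the rank order of rλ
ascending (SE first), and the NW/SE area split is at the median rλ unless a
boundary is configured. With β₂ < 0 the deterministic age gradient then
runs opposite in sign to the field system that motivated it; no result
depends on the sign, only on the existence of a monotone gradient.

## 2. Synthetic survey generator

The generator emulates the statistical structure the framework assumes so
the pipeline is testable with no external data: 375 grid sites revisited
for 10 years (a scaled-down span of a multi-decadal series; 5 of 10 years
are selected per scenario), ~30 measured fish per site-year, a smooth
cross-shelf depth profile cut into inner (<50 m), middle (50–100 m) and
outer (100–200 m) strata, and a temperature surface with inter-annual
noise plus a warm/cold regime shift (−2.5 °C) that puts most cold-regime
middle-shelf stations below 2 °C. Lengths come from a six-mode normal
mixture whose means (22, 39, 50, 59, 67, 74 cm) are exactly the lengths at
which the default size-at-age relation crosses ages 1–6, so the length
modes correspond to young age groups by construction. Mode weights are
tilted log-linearly along the shelf (default 0.9 log-odds per normalized
shelf length) to create the spatially structured mean size and age the
framework studies. The historical otolith table is collected
length-stratified (3 per cm × sex × area per year) and aged with the same
relation plus N(0, 0.3) noise — it only drives scenario selection by age
diversity, so an approximate ageing suffices.

What the generator does **not** emulate: fish movement and ontogenetic
migration, gear selectivity and catchability, zero-catch stations
(stations are re-fished to at least one fish), temperature-dependent
distribution shifts beyond the regime mean, and inter-annual cohort
dynamics. Passing tests therefore demonstrate correctness of the
*framework* under controlled conditions, not fidelity of any one scenario
to a particular real survey year.

## 3. Age reading

Reading bias and error are a row-stochastic misclassification matrix over
ages 0–12. The published calibration is aggregate: the probability of
reading the true age is ≈ 61%. The age-specific values of the underlying
reference study are not published, so the default matrix is a parametric
stand-in: every diagonal equals the target accuracy and the off-diagonal
mass decays geometrically with age distance (default decay 0.35, i.e.
misreads predominantly ±1 year, as in reference ageing studies), optionally
skewed by an asymmetry factor to encode systematic over-/under-ageing.
Because the diagonal is set to the target exactly, the weight-averaged
accuracy equals the target for *any* age composition — the calibration
contract holds identically rather than approximately. Edge rows fold lost
off-diagonal mass inward without touching the diagonal. A full
user-supplied matrix is accepted for fidelity to an external ageing study.
Reads are independent across fish; reader-level correlation is not modelled.

The second-reader check re-reads a uniform 20% of the sub-sample with
independent randomness and reports the standard ageing-precision metric:
per-fish CV = sd(two reads, ddof 1)/mean(two reads) (zero when both reads
are 0), averaged within first-read age.

## 4. Evaluation model

`AgeGAM` fits age ~ intercept + sex + per-sex P-spline of length +
tensor-product P-spline of (lon, lat) by penalized weighted least squares.
Bases are cubic B-splines on equally spaced knots; penalties are
second-order difference matrices (Eilers–Marx), with one smoothing
parameter shared by the two sex-specific length smooths and one for the
spatial tensor (kron(P₁,I) + kron(I,P₂)). Smoothing parameters minimize
GCV, n·RSS_w/(n − edf)², over a log₁₀ grid from 10⁻³ to 10³; a 10⁻⁷ ridge
keeps the normal equations positive definite across the penalties'
polynomial null spaces. Observation weights are the size-specific
within-site stage-2 abundance (the count of measured fish in the record's
site × cm-bin cell), rescaled to mean 1 — the rescaling changes no relative
weighting but stabilizes the reported variance quantities across designs.

**Basis dimensions.** Defaults are 40 basis functions for length and 6×6
for space. The length basis is deliberately generous: the response is an
*integer* age group, so the conditional mean is a staircase in length, and
the mgcv-style k-check (selected edf saturating at the basis size with the
smoothing parameter at the grid floor) shows smaller bases underfit it; at
40 the selected edf sits well inside the basis on large samples and shrinks
to ~35 on 750-record sub-samples. Explained variance is the weighted R²
(equal to Gaussian deviance explained), with adjusted R² computed from the
effective degrees of freedom.

**Known limit.** Because round(a(length) + b(space)) is not additive in
(length, space), an additive model cannot fit the discretized response
exactly even with no noise anywhere: the recovery check on a noiseless
census measures ~98.5% explained variance (our fit and an `mgcv` reference
fit agree to 0.1 pp on identical data), with the remaining ~1.5% being
irreducible discretization-by-gradient interaction. This is a property of
fitting integer age groups with an additive smooth model, not an
implementation artifact.

**Prediction error.** Repeated holdout (default 300 iterations deleting a
uniform 30%) refits on the remainder using the full-sample smoothing
parameters (one GCV selection, reused — cheap and removes selection noise
from the comparison) and predicts the deleted fish. The headline "mean
error" is the mean absolute difference between the *discretized* prediction
(same rounding rule as the population) and the true age group: predictions
in this framework are age-group assignments, and the continuous-scale MAE
would otherwise be floored near 0.25 yr by rounding alone. The
continuous-scale MAE and the signed mean are reported alongside. With a
single iteration the sd is reported as 0 with a `degenerate_sd` flag.
Covariates outside the training hull are clamped and counted
(`last_extrapolated`), never silently dropped.

**Derived estimates.** The age-frequency distribution is reconstructed by
predicting every stage-2 fish (all sites by default) and tabulating
discretized predictions; the *mis-aged fraction* between two equal-total
compositions is their total-variation distance ½Σ|N̂ₐ−Nₐ|/N — the published
analyses report "% of fish mis-aged" without a formula, and TV distance is
the natural count-displacement reading. Size-at-age reports mean, SE and
modal 1-cm bin (ties broken toward the smaller bin) for ages 1–3. Spatial
patterns are cell means on a regular grid (population maps 10–20 cells per
axis with a ≥5-fish mask; sub-sample maps use a ≥3-fish mask since ~750
fish spread thin), compared by correlation, RMSE and max absolute
difference over shared unmasked cells; constant maps flag the correlation
as degenerate. Residual diagnostics include D'Agostino normality, a
variance-trend test, and Moran's I of site-mean residuals (inverse-distance
weights, permutation p-value) — with the spatial term included, site-mean
residuals show no significant positive autocorrelation.

## 5. Sensitivity grid

The 2×2×2 factorial crosses population autocorrelation (off = sill reduced
to the nugget by default, preserving site-error variance and isolating the
*correlation*; an alternative mode removes site error entirely, since the
source analysis is ambiguous), reading error (off = identity matrix), and
the spatial model term, for each design and replicate (default 20
replicates; the source replication count is unstated). Populations are
rebuilt per replicate with replicate seeds; all cells of a replicate share
one site preselection. Attribution is the marginal on-minus-off contrast
per factor computed within replicate and averaged, with replicate sd; the
interaction remainder (all-on minus all-off minus summed contrasts) is
reported rather than a full ANOVA decomposition. Pipeline failures are
reported with their cell identity; the grid is never silently incomplete.

## 6. Reproducibility and problem sizes

Every stochastic step takes a NumPy `Generator` or integer seed; identical
seeds give identical tables, populations, sub-samples, reads and reports.
Default problem sizes (375 sites × 10 years, ~30 fish/site-year,
~11,000-fish populations, 30–50 holdout iterations in the bundled checks,
scaled from the 300 of the full protocol) were chosen so the entire
pipeline — generation to sensitivity grid — runs on a laptop-class single
core in seconds to a few minutes per analysis.
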