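# surveysub

Simulation framework for evaluating **trait sub-sampling strategies in
multi-stage biological surveys** of populations with spatially structured
traits.

## The problem

Many monitoring programs use a multi-stage design: sites are the primary
sampling units (stage 1), individuals are measured within each site
(stage 2), and — because trait determination such as otolith ageing is
costly — only a sub-sample of measured individuals is retained for the trait
(stage 3). When the trait is structured over space, the *stage-3 design*
itself can bias the population estimates built from it. `surveysub` lets you
quantify that bias: it builds virtual fish populations in which every
fish's true age is known, simulates contrasting stage-3 designs, pushes the
aged fish through a realistic otolith-reading error model, and measures how
well each design recovers the population's age structure, size-at-age and
spatial patterns.

The case emulated by the built-in synthetic survey is an eastern Bering Sea
style groundfish trawl survey: a square grid of 375 stations fished every
year along a SE→NW cruise route, inner/middle/outer depth strata, warm/cold
bottom-temperature regimes (cold years put much of the middle shelf below
the 2 °C "cold pool" threshold), and a multimodal length distribution whose
modes correspond to young age groups.

## The model

Each fish *i* in the virtual population receives a true age from a
quadratic size-at-age relation with a geographic gradient,

```
age_i = α + β₁(sex_i) · size_i² + β₂ · rλ_i + e_i
```

where size is in mm (β₁ = 1.05·10⁻⁵ for males, 1.0·10⁻⁵ for females),
rλ is the *rotated latitude* — latitude after rotating coordinates so the
shelf's NW–SE axis runs N–S (β₂ = −0.031 yr/degree) — and *e* is a
site-level, spatially autocorrelated Gaussian error drawn from a
covariogram (exponential by default; nugget 0.05, sill 0.25 yr²).
Continuous ages are rounded half-up to integer age groups.

Stage-3 designs compared:

* **RS** (random): 4 fish per preselected site, uniformly;
* **LSS** (length-stratified): 3 fish per (1-cm bin × sex × NW/SE area)
  cell, filled in cruise order — late-route sites contribute nothing once
  quotas fill;
* **census** (every fish at preselected sites) and **size-matched RS**.

Recorded "otolith ages" pass through a row-stochastic misclassification
matrix calibrated so the aggregate probability of reading the true age is
61%; a second-reader protocol re-reads 20% of specimens for the
age-specific inter-reader CV.

Evaluation fits each aged sub-sample with a weighted additive model
(P-spline penalized WLS, the in-package `AgeGAM`/`AgeGAMResults` pair),

```
age_i = α + s₁(size_i) × sex_i + s₂(φ_i, λ_i) + ε_i
```

with observation weights equal to the size-specific abundance within each
site, then reports repeated-holdout prediction error (300 × 30% by
default), the reconstructed age-frequency distribution and its *mis-aged
fraction* (total-variation distance from truth), mean/modal size-at-age for
ages 1–3, and gridded spatial-pattern recovery. A 2×2×2 factorial
sensitivity grid (population autocorrelation × reading error × spatial
model term) attributes the error sources.

## Worked example

```python
import numpy as np
from surveysub import *
from surveysub.synthetic import SyntheticSurveyConfig, generate_synthetic_survey

hauls, lengths, otoliths = generate_synthetic_survey(SyntheticSurveyConfig(seed=7))
pop = build_population(hauls, lengths, ScenarioSpec("warm"), seed=7, otoliths=otoliths)

rng = np.random.default_rng(7)
preselected = select_age_sites(pop.sites, 0.5, rng)
rs = random_subsample(pop, preselected, DesignConfig(kind="random"), rng)
rs.records = apply_reading(rs.records, ReadingModel(), rng)   # 61% accuracy
report = evaluate_design(pop, rs, GamSpec(), rng, n_iterations=50)
print(report.to_text())
```

prints (abridged):

```
design: random
Weighted additive age-at-length model
================================================
n obs                        748
effective df               35.55
% variance explained       66.63
================================================
holdout MAE 0.356 (sd 0.039, continuous 0.425, signed +0.079)
mis-aged fraction 0.0209
size at age (sample):
 age   n  mean_length  se_length  modal_bin
   1  95    29.221280   1.129122         21
   2 152    36.060185   0.809256         42
   3 166    45.157494   0.805986         46
spatial recovery: {'age': {'correlation': 0.53, 'rmse': 0.71, ...}}
```

Read: the RS design collected 748 otoliths (4 × 187 preselected sites); the
weighted GAM explains 66.6% of the age variance in this scaled-down survey;
repeated holdout misassigns the average fish's age group by 0.36 years; the
reconstructed age composition misplaces 2.1% of fish; and the RS age map
tracks the population map with RMSE 0.71 years. Running the same evaluation
on the length-stratified sub-sample shows the signature failure mode: far
fewer sites contribute fish (the quota fills early along the route) and the
spatial age map degrades several-fold in RMSE while whole-population
summaries stay comparable.

A `surveysub` command-line interface wraps the same steps
(`surveysub generate-data / sample / process / evaluate / sensitivity`).

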