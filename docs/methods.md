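# Methods

`oysterhsm` implements a two-part ("hurdle") habitat-suitability analysis of
a bivalve invasion front, together with a synthetic survey generator that
serves as its test bed. This note records the models, their assumptions, the
parameters that matter, and the numerical choices made where the design was
genuinely open.

## The scientific problem

At the leading edge of a marine invasion the species does not yet occupy all
suitable habitat, so classical habitat-suitability models calibrated on
established populations mispredict risk. The approach taken here is to model
*occurrence* (can the species establish at a site?) and *conditional
abundance* (how dense can an established population become?) separately,
because different environmental factors drive each: the availability of
stable hard substrate governs colonization, while shelter from waves governs
population build-up, with a collapse in density below a minimum-salinity
threshold near 8 psu. Projections of the two models over habitat strata are
then combined into a *possible* population size — the population a habitat
could sustain if all predicted-suitable area were occupied at predicted
density — which is a risk quantity, not a census.

## Synthetic survey generator

`GeneratorConfig` encodes the study conditions: 15 sites in each of three
habitat types (marina, pier, natural rocky), five 0.25 m² quadrats per site,
a north–south gradient of regional surface salinity from 25 to 10 psu
(`salinity_endpoints`), and per-habitat wave-exposure and substrate
distributions (marinas: 100 % substrate, strongly sheltered; piers:
intermediate; natural rock: variable substrate declining southwards).

Design choices worth knowing:

* **Minimum salinity vs. the gradient.** The model covariate is the
  *minimum* salinity a site experiences, which dips below the regional
  surface gradient. The generator draws
  `min_salinity = gradient(lat) − Gamma(4, 1)` (mean 4 psu drawdown,
  SD 2). This puts a realistic fraction of southern survey sites below the
  8-psu breakpoint, without which the breakpoint would be invisible to any
  fitted model at survey scale.
* **Truth structure.** Occupancy is Bernoulli on a logit-linear predictor
  dominated by substrate fraction (+5.2), with a small *positive* exposure
  slope (+0.10) and a negligible salinity slope (+0.03) — occurrence rises
  slightly with exposure even though abundance falls with it. Conditional
  log density is linear in ln(exposure) (−0.62) and substrate (+0.15), with
  a sharp piecewise-linear penalty of 1.0 log-units per psu below the 8-psu
  breakpoint.
* **Targeted first quadrat.** Field crews place the first quadrat on the
  densest patch. The generator draws counts for `n_candidate_patches = 20`
  candidate patches (negative binomial around density × 0.25 m², dispersion
  5 — field counts are clumped, so Poisson would understate quadrat
  variance); the first quadrat takes the maximum-count patch, the other
  four are sampled without replacement from the rest. This induces a known
  upward bias of observed site abundance relative to the latent density,
  which is deliberate: the survey design being emulated accepts that bias
  in exchange for a low false-absence rate, and downstream estimates are
  interpreted as *possible* rather than average abundance.
* **Calibration.** The default truth coefficients were frozen with
  `scripts/calibrate_generator.py` so that observed habitat mean abundances
  over presence sites land near 10.4 / 3.3 / 2.8 ind m⁻² (marina / pier /
  natural). These are calibration anchors for realism, not claims.
* **What the generator does not emulate.** No spatial autocorrelation
  between sites (the emulated design enforces site separation), no
  temperature effects, no observation error in covariates, and latitude is
  an abstract [0, 1] proxy with no geodesy. Passing recovery tests
  therefore show the estimators work under clumped counts, targeted
  sampling and a realistic gradient — not that they are robust to spatial
  structure or covariate error.

Shell lengths are log-normal per habitat, parameterized by (mode, log-SD):
marina mode 107.5 mm, natural 62.5 mm — large oysters dominate marinas.

## Covariate preparation

Wave exposure is depth-attenuated as `E(d) = E₀·exp(−k·d)` with `k = 1` per
metre by default; the attenuation formula used by the exposure model this
emulates is external to the package, so the functional form is exponential
decay with `k` exposed in `CovariateConfig`. Marina exposures above 10 000
(the "very sheltered" class boundary on the dimensionless fetch index) are
treated as breakwater artefacts and replaced by the mean of marinas at or
below the threshold — an idempotent operation that errors when no sheltered
reference marina exists. The exposure layer's units are treated as a
positive dimensionless index throughout.

The collinearity screen reports pairwise Pearson r and VIFs (flagging
|r| ≥ 0.70 or VIF ≥ 5) but never drops variables itself; `recommended_drop`
is a greedy highest-VIF-first suggestion. A constant column gets an
infinite-VIF sentinel rather than a crash.

## Occurrence ensemble

Candidate members are four families — linear logistic, spline logistic
(`SplineTransformer` + penalized logistic; the package's GAM-flavoured
member), gradient-boosted trees, random forest — each fitted on 100 random
80/20 split-samples of the first-quadrat presence table. The first-quadrat
substrate is used (not the site mean) because the targeted quadrat records
the substrate the animals actually attach to. Members pass into the
ensemble only with holdout AUC ≥ 0.70 *and* TSS ≥ 0.50; the ensemble is the
unweighted mean probability of included members (no better-than-uniform
weighting is assumed), evaluated by its AUC on the full calibration table,
and classifies presence where probability strictly exceeds the
sensitivity+specificity-maximizing cutoff (a tie at the cutoff is absence).

TSS is maximized over midpoints of consecutive sorted unique scores plus
the two trivial boundary classifiers, so the optimum is never negative;
ties go to the threshold nearest 0.5, then to the larger threshold.
Degenerate splits (a single class in train or holdout) are skipped with a
logged warning. Hyperparameters per family are documented defaults in
`CommitteeConfig`; the contract is the gate-and-ensemble logic, not tuning.

## Abundance model

A random forest regresses log observed abundance on site-mean covariates
across presence sites. Natural log is used; no +1 offset is needed because
the design granularity makes the smallest presence abundance 0.8 ind m⁻².
Trees are fixed at 500 (the error curve stabilizes well before that) and
the grid runs over variables-per-split; the point with the smallest mean
validation RMSE over 6-fold × 10-repeat CV wins (tie → smaller value).

Two retransformation corrections follow, both estimated on *out-of-bag*
predictions of the final forest so they are not fitted to memorized
training predictions:

1. **Bias line** — least squares of observed on estimated log values,
   `obs = a + b·pred`; forests compress extremes, so typically `b ≥ 1`
   stretches predictions back. Constant predictions fall back to the
   identity line with a warning.
2. **Duan smearing** — `S = mean(exp(residual))` with residuals taken on
   the *corrected* log scale, because that is the scale actually
   back-transformed. Predictions are `exp(a + b·forest(x))·S`, strictly
   positive.

The forest's residual range compression (predicted range slightly narrower
than observed) is accepted behavior and not corrected further.

## Predictor influence

Importance is the mean over 3 runs of `1 − r(pred, pred with one column
permuted)` — raw values in [0, 2], deliberately not normalized to sum to 1.
Permutations are seeded, independent per variable and per run (runs
outermost, variables in column order). Response curves use the evaluation
strip: 100 grid points across the variable's observed interval (an explicit
range may be supplied, e.g. to probe the salinity breakpoint region), other
variables pinned at their medians; occurrence curves are on the probability
scale and abundance curves on the log scale. Two-variable partial
dependence instead clamps the pair to a lattice and averages predictions
over the data, preserving the joint distribution of the remaining
covariates — both conventions are implemented because they answer different
questions, and they are named distinctly.

## Projection and population estimation

Projection sites carry habitat type, covariates, depth and the habitat area
they represent; marina exposures are substituted then depth-attenuated
before prediction. Abundance is predicted only where occurrence is
predicted (the hurdle). Per stratum h,

    Nh = x̄h · Ph · Ah

with x̄h the *simple* mean of predicted abundance over predicted-present
sites (an area-weighted mean is a documented alternative; simple means are
reported throughout), Ph the predicted prevalence, and Ah the stratum's
areal extent. Rocky-habitat area is the natural-habitat area times the
fraction of natural projection sites with any hard substrate. Biomass is
`Nh · Σ f_c · W(mid_c)` over 5-mm shell-length classes with the allometric
law `W(L) = a·L^b`; the default law is calibrated exactly through the two
size-class anchors (62.5 mm, 40 g) and (107.5 mm, 140 g), giving b ≈ 2.31 —
the underlying >1000-individual regression is unpublished, so this
two-point approximation is prominently overridable. Per-unit-area risk
standardizes by total habitat: abundance `x̄h·Ph`, biomass `Bh/Ah`.

Uncertainty is a seeded percentile bootstrap: projection sites are
resampled with replacement within stratum, x̄h, Ph, Nh, Bh recomputed per
resample (Ah and the length frequencies held fixed), and 2.5/97.5
percentiles reported. The point estimate is always the plug-in statistic.
Known limitation: percentile intervals for a lognormal-like mean at n ≈ 30
undercover as skew grows (measured ≈ 91 % at log-SD 0.9 vs ≈ 93–94 % at
log-SD ≤ 0.6); with the log-scale spreads this package models (≤ ~0.6)
coverage stays near nominal.

## Problem sizes and determinism

Every stage takes a single seed; all internal streams derive from it via
`SeedSequence`, and identical config + seed reproduces byte-identical
output tables. Default fitting sizes follow the emulated analysis (100
committee splits, 6×10 CV, 1000 bootstrap resamples). Replicated studies —
parameter-recovery (20 surveys) and bootstrap-coverage (500 simulated
datasets) checks — use reduced per-replicate fitting sizes (20 splits, 2 CV
repeats) as the package's own choice of experiment scale; the generator's
study conditions (45 sites, default truth) are never reduced.

## Known limitations

* Nh is a *possible* population size under non-equilibrium assumptions;
  nothing here estimates the current standing population.
* The marina habitat area is an input; no GIS digitization is performed.
* Piers are surveyed but not projected (their depth and substrate cannot be
  assumed representatively), mirroring the emulated workflow.
* The two-point length-weight law extrapolates poorly outside ~40–150 mm.
* The screen is advisory; models are always fitted with the supplied
  predictor set.
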