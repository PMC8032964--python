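# Methods

## Normative model

Each regional volume (or its logarithm, see *Skewed regions*) is modelled as
a Gaussian process over three covariates: postmenstrual age at scan (weeks),
postnatal days, and sex (coded 0 = female, 1 = male).  Covariates are mapped
to comparable scales by fixed constants — (PMA − 40)/4, days/7, sex − 0.5 —
and targets are standardized to zero mean, unit SD before fitting (restored
on output).  The kernel is

    k(x, x') = σ_f² exp(−½ Σ_d (x_d − x'_d)²/ℓ_d²)  +  σ_l² xᵀx'  +  σ_n² δ

an anisotropic squared-exponential for smooth non-linearity, a linear kernel
so near-linear growth does not force the length-scales to degenerate and so
predictive variance keeps growing outside the training ages, and white
observation noise.  Six hyperparameters (log σ_f², log ℓ_pma, log ℓ_days,
log ℓ_sex, log σ_l², log σ_n²) are optimized by L-BFGS on the log marginal
likelihood with analytic gradients, from 5 seeded restarts (a fixed default
start plus log-normal perturbations, SD 0.7), bounds e^±… on [−15, 8],
gradient tolerance 1e-6, and a noise floor of 1e-6 on the standardized scale
(disable with `noise_floor=None` for interpolation checks).  A jitter of
1e-8 is added to the training covariance diagonal.  Fits that exhaust all
restarts without converging keep the best point and carry a warning flag.

The atypicality index is AI = (observed − predicted)/predictive SD, with the
predictive SD including σ_n² — the total uncertainty for a *new*
observation.  That choice is what makes the tail calibration meaningful: a
held-out typical subject scores AI ~ N(0, 1), so the strict threshold
|AI| > 2.6 (the 0.5% per-tail normal quantile 2.5758…, rounded to one
decimal for reporting) selects roughly the top and bottom 0.5% of the
typical population.  Missing volumes (e.g. stroke-masked cortical volumes)
yield absent entries, never zeros.  Queries outside the modelled 37–45-week
window attach an extrapolation warning.

### Skewed regions

Ventricular and extracerebral CSF volumes are right-skewed in neonates.
`fit_region_model` fits untransformed by default and exposes a
`log_transform` flag; `fit_normative_models` and the pipeline turn the flag
on for these two regions.  Rationale: with multiplicative (log-normal)
residuals an untransformed Gaussian model has a heavy upper tail (at
σ_log = 0.3 the nominal 0.5% upper tail becomes ≈1.7%), which would quietly
break the extreme-deviation calibration for those regions; on the log scale
the AI is again a well-calibrated z-score and the threshold keeps its
meaning.  Monotonicity means extreme-deviation *flags* are unaffected in
direction, only properly calibrated.

## Synthetic cohorts

The generator emulates the statistical shape of the study data, not images:

- **Normative sample** (default n=219): birth age ~ truncated normal
  (40.1, 1.4; [37, 43] wk), postnatal days ~ 1 + Poisson(3.2) capped so scan
  PMA ≤ 45, ~50% male.  Regional volumes follow a linear growth law
  a_r + b_r(PMA−40) + c_r·male + d_r·days with additive Gaussian residuals;
  residuals share a global brain-size factor (loading 0.5 for tissue,
  negative for CSF spaces) so each region's AI is marginally standard
  normal but regions are realistically correlated.  CSF spaces use
  multiplicative log-normal residuals (σ_log 0.25/0.30).  Absolute
  calibration of a_r, b_r, s_r is from field-typical neonatal volumetrics;
  no published cohort means exist to anchor them, so they are documented
  constants, not estimates.
- **CHD sample** (default n=66): birth age ~ truncated normal (38.5, 0.6)
  with a 4/66 preterm fraction (34.5–36.9 wk, scanned once ≥37 wk PMA);
  subgroup labels (abnormal streaming / left-sided / right-sided) at
  32:18:16; injury labels at the published class frequencies, with stroke
  masking cortical grey matter, white matter and TTV at generation time.
  Saturation, haemoglobin and vessel flows are drawn so their product lands
  on CDO₂ ≈ 1795 (495) mL O₂/min (moment-matched, truncation-aware); flows
  split 40/40/20 across vessels via a Dirichlet draw.  Each region's AI is
  shifted by a configured deficit δ_r (the Table-style targets, e.g.
  cortical grey matter −0.58) plus a CDO₂ coupling: γ (default 0.45) per
  CDO₂ SD for deep grey, γ_tissue (0.30) for other tissue, none for CSF
  spaces.  Cognition = 93 + κ·(deep-grey AI − δ̄) + ι·z(log IMD) + noise
  (κ = 5 points per AI unit, ι = −2.5, noise SD 8 → composite ≈ 93 (10));
  motor is null-coupled at 94 (10).  Missingness mirrors the study: flows
  absent in 13/66, follow-up attended by 46/66, one attendee missing IMD.
- The generator stores the latent deep-grey AI and standardized CDO₂ as
  `latent_*` columns — the mediation ground truth (true ACME per CDO₂ SD is
  exactly γ·κ) used by the recovery tests.

What the generator does **not** emulate: scanner/site effects, non-linear
growth curvature, age-dependent heteroscedasticity, informative missingness,
genuine diagnosis-specific physiology (subgroups differ only by label), or
any image-level process.  Passing tests therefore demonstrate correctness of
the estimators under the assumed generative family, not robustness to those
real-world violations.

## Statistics

- **Partial Spearman** (the `ppcor` convention): rank-transform all three
  variables (average ranks for ties), residualize the two variables of
  interest on the ranked covariate by least squares, Pearson-correlate the
  residuals; p from the t approximation on n − 3 df; pairwise-complete rows.
- **Fisher exact** on 2×2 tables: the reported OR is the conditional MLE
  under the noncentral hypergeometric model with the exact conditional CI
  (the convention of R's `fisher.test`, which reproduces published ORs that
  the sample cross-product does not); two-sided p by the minimum-likelihood
  rule.  A zero margin makes the OR undefined (reported as NaN, p = 1).
- **BH-FDR**: step-up with cumulative-minimum enforcement, applied within
  each outcome's 13-region family in the association screen and across the
  gated family of mediation p-values.
- **Standardized OLS**: z-scored outcome and predictors; R², adjusted R²,
  F; optional seeded bootstrap percentile CI for R² (1000 draws) — offered
  without claiming equivalence to any particular published CI method.
- **Quintile ranks**: position-based on a stable sort (ties broken by input
  order), group sizes within one of equal, rank 1 = lowest.
- **CDO₂** applies the printed formula literally with haemoglobin in g/dL;
  the g/dL→per-mL conversion factor is *not* inserted, because the
  conventional reported scale (cohort mean ≈ 1795 under the label
  mL O₂/min) is only obtained without it.  Percent-scale saturation is
  rejected rather than silently rescaled.

## Mediation

Models: (a) outcome ~ treatment + mediator + covariates; (b) outcome ~
mediator + covariates (reported only); (c) mediator ~ treatment.  With no
interaction, ACME = coefficient(c, treatment) × coefficient(a, mediator).
By default treatment, mediator and outcome are z-scored so paths match the
standardized path-diagram convention.  Uncertainty: 1000 quasi-Bayesian
draws of each model's coefficients from their asymptotic normal sampling
distributions; percentile CI; two-sided p = twice the smaller tail fraction
of draws crossing zero; fully seeded.

Sensitivity: for an assumed error correlation ρ between the mediator and
outcome equations, the linear-case closed form gives

    ACME(ρ) = ACME(0) − α (s₁/s₂) ρ √((1 − r̃²)/(1 − ρ²))

with α the treatment→mediator path, s₁, s₂ the residual SDs of the reduced
outcome model (outcome ~ treatment + covariates) and the mediator model, and
r̃ their residual correlation.  The curve is anchored at the unadjusted
point estimate, so ACME(0) equals the product of coefficients exactly even
though model (c) omits the outcome covariates; the two formulations agree
asymptotically, and on no-confounding simulations the critical ρ (root of
the curve, grid −0.9…0.9 step 0.05 then bisection to 1e-4) matches r̃ to
<0.02 at n = 2000.  When the curve does not change sign on the grid the
critical ρ is reported as outside-grid (None).

## Pipeline and reproducibility

Normative models are fitted once on the normative cohort and frozen before
any CHD subject is scored; whole-sample and ≥37-week analyses share them.
All randomness flows from one master seed through `numpy` `SeedSequence`
spawning (per-cohort, per-region-fit and per-mediator streams); identical
seeds give byte-identical report CSVs.  The manifest records seed, config
hash and library versions.  CSV round-trips preserve values to 6
significant digits; missing values are empty cells.

## Problem sizes in the checks

The test suite fits at the study scale (219 normative subjects) for
cross-validated calibration, uses 500-subject CHD cohorts for deficit
recovery, 200 cohorts of n = 500 for ACME bias/coverage, and n = 2000 for
the critical-ρ oracle.  The tail-calibration check and the acceptance
script fit on 1000 normative subjects and score 20,000 held-out typical
subjects; the script runs the optimizer with 2 restarts and 120 iterations
per region (the library default is 5 restarts), which the marginal
likelihood surface of these near-linear growth data tolerates well.

## Known limitations

- GP predictive SDs are honestly conservative near the edges of the
  training covariate range, so the two-sided extreme rate on held-out
  typical subjects sits slightly below 2 × 0.5% at modest training sizes
  (≈0.9% at n = 500–1000); it approaches the nominal rate as the normative
  sample grows.
- The mediation machinery is the linear, no-interaction, single-mediator
  case only; treatment–mediator interactions, non-continuous outcomes and
  joint multiple mediators are out of scope.
- The exact-CI convention for the conditional OR is not uniquely determined
  by published values in degenerate, heavily-tied tables; ORs are the
  validated quantity.
- No site/scanner harmonization, warped GPs or non-Gaussian likelihoods.
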