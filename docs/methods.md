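# Methods

## The model

Each scored blood sample contributes a count `k` of chromosome aberrations
(total exchanges by default, stable translocations as an alternate endpoint)
in `n` lymphocytes.  With aberrations rare and cells numerous, `k` is
treated as Poisson with mean `n·λ`, and `log λ` is linear in the
explanatory variables.  The package fits three members of one model family,
all maximum-likelihood mixed-effects Poisson regressions:

**Pre-flight (ex-vivo) dose response.**  For subject `i` (a crew-mission)
and gamma dose `x_ij` (Gy),

    log λ_ij = β0 + W0i + (β1 + W1i)·x_ij + β2·(age_i − 50) + β3·F_i ,

with `(W0i, W1i)` bivariate normal, unstructured covariance
`(σ_W0, σ_W1, ρ)`.  The random intercept is the subject's background level;
the random slope is the subject's radiosensitivity to gamma rays.  Doses
above a cap (default 0.5 Gy) are excluded: the object of inference is the
low-dose response relevant to mission exposures of a few cGy.
A subject's *average slope* `B_i` (CAR per Gy) is the chord of the fitted
curve from dose 0 to the subject's own top dose,
`B_i = (λ̂(x_max) − λ̂(0)) / x_max`, evaluated with the subject's empirical-
Bayes effects and, by default, the subject's own age/gender terms (a
documented switch restricts it to the dose terms only).

**Post-flight prediction (two stage).**  Stage 1 refits the pre-flight model
*without* the unirradiated baseline rows and extracts empirical-Bayes
posterior means `(w0i, w1i)` of the random effects.  Stage 2 pools each
subject's post-flight samples (exposure = the mission blood-forming-organ
dose, `BFO_i`, 0.01–0.04 Gy) with the held-out baseline rows (exposure 0)
and fits

    log λ_ij = β0 + U0i + β1·x_ij + β2·(age−50) + β3·F + β4·w0i + β5·w1i·x_ij ,

random intercept only.  The plug-ins are treated as known covariates; `β5`
measures how much pre-flight radiosensitivity modifies the in-vivo dose
slope over and above dose, age and gender.  Holding the baseline rows out of
stage 1 keeps the two stages from using any observation twice.
Early (~2–4 weeks) and late (>6 months) post-flight samples enter with the
same BFO dose and no time covariate, matching the finding of no recovery
between the two collections; the recovery question itself is answered
separately by a paired t-test on observed per-subject rates.
A dose-rate variant replaces the exposure column by
`100·BFO/duration` (cGy/day) and reports AIC/log-likelihood against the
dose model on identical rows.  cGy/day is used in the design as well as in
reports: it keeps the exposure column near 0.01–0.02, where the
finite-difference machinery is well conditioned, whereas Gy/day (~1e-4)
degrades the numerical gradient.

**Joint model and RBE.**  All rows enter one fit with separate slopes for
the ex-vivo gamma dose (`β1,pre`, random slope `U1i`) and the in-vivo BFO
dose (`β1,post`, no subject perturbation — the BFO dose range is too narrow
to identify one):

    log λ_ij = β0 + U0i + (β1,pre + U1i)·x_pre,ij + β1,post·x_post,ij
               + β2·(age−50) + β3·F .

The relative biological effectiveness is the gamma dose equivalent of one
unit of space-radiation dose: `RBE = β1,post/β1,pre` on average and
`RBE_i = β1,post/(β1,pre + û1i)` per subject.  Because `U2i` on the in-vivo
slope is not modeled, the per-subject spread is flagged as conservative.
The SE of the average RBE is by the delta method using the full joint
covariance of the two slopes (an independent-SE variant is available for
comparison); subjects with a nonpositive EB-adjusted gamma slope are
flagged, not dropped silently.

## Estimation

The marginal likelihood integrates the Poisson likelihood over the 1- or
2-dimensional random effect per subject.  The integral uses **adaptive
Gauss–Hermite quadrature**: a vectorized Newton iteration finds every
subject's posterior mode and curvature, and the Hermite grid (default 7
nodes per dimension) is centered and scaled there.  Adaptivity matters
because counts of 20–40 aberrations make the integrand far narrower than
the prior; at order 7 the result agrees with a 1e5-point dense-grid
integral to ~1e-9 relative error on test instances, and orders 7 vs 25
differ by <1e-4 on a full cohort.  Plain prior-centered quadrature is
available as a fallback.  When both random-effect SDs are zero the code
switches to the exact sum of Poisson log-pmfs.

The covariance is parameterized as `(log σ0, log σ1, atanh ρ)` so the
optimizer (L-BFGS-B) works on an unconstrained scale; `log σ` is bounded in
`[−8, 4]`, and a fitted `log σ < −5` is reported as a boundary fit with its
SE suppressed.  Starting values come from a small in-package IRLS Poisson
GLM with SDs of 0.3.  Standard errors are from the inverse of a
central-difference observed information matrix (step `1e-4·(1+|θ|)`), with
delta-method transforms back to the `σ/ρ` scale; Wald Z and two-sided
normal p-values follow.  Subjects with a single row (or none) are handled
through the prior; constant covariate columns (e.g. an all-male cohort) are
dropped from the design with a log message rather than producing a singular
information matrix.  Fits that fail to converge are returned flagged, never
silently.

Empirical-Bayes posterior means and SDs reuse the same quadrature machinery
(prior × likelihood, normalized per subject); they shrink to 0 as a
subject's data or the prior variance vanishes.

## Synthetic cohorts

The generator reproduces the study design the models assume: 43
crew-missions from 38 astronauts (5 repeat fliers share person-level
effects across two missions), ages 37–57, 10 female; a pre-flight series at
{0, 0.1, 0.2, 0.3, 0.4} Gy with ~8000 cells for the unirradiated baseline
and 1500 per irradiated sample; BFO doses uniform on 0.01–0.04 Gy with
dose rates 0.012–0.024 cGy/day and durations 67–215 days made mutually
consistent; post-flight samples of 8000 cells for 39/43 subjects early and
31/43 at both time points, equal true rates at the two time points by
default.  Fixed effects default to the published estimates
(β0 = −5.717, β1,pre = 4.151, β2 = 0.029, β3 = 0.168, β1,post = 12.475)
and random-effect SDs to (0.46, 0.88).  Values the source analysis does not
print were set once to field-plausible defaults and documented here:

* `ρ_W = +0.4` — background and radiosensitivity are reported as positively
  correlated with no printed value;
* `post_coupling = 0.5` — there is no published generative analog of `β5`,
  so the in-vivo slope of subject `i` is `β1,post·exp(0.5·W1i)`; to first
  order this induces a linear radiosensitivity-by-dose term of magnitude
  `0.5·β1,post ≈ 6.2`, the order of the published second-stage estimate.
  Setting it to 0 decouples the stages (the null used for calibration);
* repeat fliers carry a ×1.5 baseline and ×1.23 slope multiplier on their
  second mission, the published point estimates.

Counts are Poisson draws `k ~ Poisson(n·λ)`; any realized `λ ≥ 1` aborts
with an instructive error (the Poisson approximation presumes rare events).
Generation is bit-reproducible given the seed, and the realized random
effects and per-sample rates are retained for recovery testing.

What the generator does *not* emulate: non-Poisson overdispersion or
within-cell multiplicity, clonal aberrations, scoring-protocol differences
(probe combinations, whole-genome extrapolation), dosimetry error in the
BFO dose, and any non-log-linear dose response.  Passing recovery tests
therefore demonstrate that the estimation machinery is correct and
calibrated *under the model's own assumptions*, not that the model is
adequate for any particular real cohort.

## Verification scales

Parameter-recovery runs use cohorts of 100–150 subjects and 50 replicates —
large enough that 2-SE coverage and power criteria are sharp, small enough
to keep a full verification run in minutes on one CPU.  Recovery replicates
omit repeat fliers (their mission-2 multipliers are deliberate
contamination of the clean generating truth and would bias slope recovery by
~0.03); the repeat-flier machinery is exercised by its own tests.
Calibration of the paired recovery t-test uses 200 default-size cohorts
(31 pairs each).

## Known limitations

* Random-effect structures beyond intercept + one slope are out of scope,
  as are MCMC posteriors, overdispersed (negative-binomial) counts, and
  leave-one-out validation machinery.
* The two-stage CIs treat the stage-1 plug-ins as constants (the
  conventional plug-in treatment); stage-1 estimation error therefore
  attenuates `β5` and narrows its CI somewhat.  An optional delta-method
  widening using the stage-1 posterior variance exists but is off by
  default.
* Boundary variance fits (σ → 0) report no SE for that component; profile
  or likelihood-ratio intervals are not implemented.
* The per-subject RBE range understates the true between-subject spread by
  construction (no `U2i`), and the average-RBE SE inherits whatever
  misspecification the joint model has.
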