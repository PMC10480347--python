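# Methods

`trajprs` implements a complete analysis chain for studying how standardized
polygenic risk scores (PRS) relate to latent trajectories of posttraumatic
stress symptoms measured repeatedly after a potentially traumatic exposure
period (a combat deployment). Because the cohorts this design comes from are
restricted, every stage is exercised on synthetic cohorts whose generating
parameters are known; the package therefore contains both the analysis
methods and a first-class generator that encodes the study conditions.

## Symptom scale harmonization

Waves use abbreviated versions of a symptom checklist: 6 items before
deployment, 5 at the post-deployment assessment and the full 17 items at the
two follow-ups, each item rated 0–4. Totals are mapped to a common scale as
the percentage of the maximum attainable score, `100·total/(4·n_items)`. The
transform is linear, so means, medians and IQRs of totals can be harmonized
directly; full precision is kept internally and rounding to two decimals
happens only at presentation. Non-integer totals are accepted (summary values
are legitimate inputs). Proration of partially answered instruments is not
attempted: an observed wave is assumed to carry a complete total.

## Synthetic cohort generator

One subject row carries age (normal, mean 25.9, SD 5.9 years, floored at 18),
sex (94.5% male), ten standard-normal ancestry principal components, eight
binary exposure flags with marginal prevalences 80.6/47.3/80.5/73.0/9.5/70.9/
67.0/83.7%, and six PRS drawn standard normal and re-standardized within the
sample. A binary "new exposure during follow-up" flag is drawn with
class-conditional rates (34.8/63.6/50.6/63.8% for the low/increasing/
decreasing/high classes) to support the trajectory-interpretation contrasts.

**Class membership.** True classes follow a reference-coded multinomial logit
in the PRS (and optionally covariates). Per-SD log odds default to the
significant reported associations: PTSD-PRS 1.12 (increasing vs low) and 1.23
(high vs low); MDD-PRS 1.16/1.16/1.18 for increasing/decreasing/high vs low;
the other four scores are null. Covariate effects on membership default to
zero (no values are reported for them) but are configurable. The class
intercepts are calibrated by root-solving so the cohort-average membership
probabilities match the target prevalences (77.2/10.5/8.0/4.3%) exactly;
configured conditional odds ratios are untouched by the calibration.

**Trajectories.** Harmonized scores follow subject-level lines: class
intercept and slope (defaults 12/18/45/55 percent and −0.3/+2.5/−2.8/0.0
percent/month — values that encode the described ordering and shapes; the
fitted growth parameters themselves are not published in machine-readable
form) plus a random intercept/slope deviation with covariance shared across
classes (default SDs 2.2 percent and 0.12 percent/month, uncorrelated) and
residual noise (SD 2.2 percent), clipped to [0, 100]. The variance defaults
were chosen so that fewer than 1% of post-deployment scores hit the bounds,
keeping the within-class structure effectively linear; the clipping
diagnostic (`clipped_fraction`) is computed over the post-deployment waves
that enter the trajectory model, since extrapolating the configured class
lines to the pre-deployment pseudo-time necessarily floors the increasing
class. Follow-up times are normal with the observed means/SDs (2.38 (0.62)
and 11.76 (1.74) months after the post-deployment assessment, which is coded
as time 0), with a small enforced gap keeping them strictly increasing; the
jitter distribution is assumed normal, as only its mean and SD are reported.
The pre-deployment score evaluates the same subject line at a pseudo-time of
−9 months, so the missingness mechanism below has a real severity predictor.
Raw totals are back-computed on each wave's instrument scale.

**Missingness.** A configurable fraction (11.14%) of subjects are unit
nonresponders with no post-deployment data (optionally severity-dependent via
`unit_mar_coef`; independent by default). Among the rest, each
post-deployment wave is missing with probability
`logit⁻¹(a_w + 0.03·(pre − mean) + u)`, where `u` is a shared normal frailty.
The frailty is essential: with independent wave dropout no intercepts can
jointly reproduce the observed pattern shares (59.4% with all three waves,
29.5% missing one, and 3.5% observed at post-deployment only), because real
attrition is positively correlated within subject. The two follow-up waves
share an intercept; the three free parameters (post intercept, follow-up
intercept, frailty SD) are calibrated by root-solving the exact expected
pattern shares (frailty integrated by Gauss–Hermite quadrature, patterns
conditioned on at least one observed wave). Everything flows from one integer
seed; identical configurations give byte-identical tables.

## Growth mixture model

For subject *i* with harmonized post-deployment scores `y_i` at times `t_i`,
class *k* implies `y_i ~ N(X_i β_k, Z_i Ψ Z_iᵀ + σ² I)` with `X_i = [1, t_i]`;
`Z_i` is empty (latent class growth analysis), an intercept, or intercept and
slope (default), with `Ψ` shared across classes (class-specific covariances
are out of scope, matching the equality constraint used for convergence in
this literature). Membership probabilities follow a multinomial logit on
subject covariates — by default the pre-deployment severity score, placed in
the membership model (not the trajectory means) because its stated role is to
improve membership estimation for subjects with missing follow-ups; the
placement is configurable. Subjects with no observed post-deployment waves
are excluded here and handled by the weighting stage.

**Estimation.** EM with class indicators and random effects as missing data:
the E-step yields posterior class probabilities and per-class BLUPs; the
M-step updates the membership logit by Newton–Raphson on fractional
responses, the class fixed effects by responsibility-weighted least squares
on BLUP-corrected outcomes, and `Ψ`, `σ²` by their conditional-expectation
formulas. All M-steps are exact, so the marginal log-likelihood is
non-decreasing (asserted in tests). Likelihood evaluations vectorize over
subjects grouped by number of observed waves. Starts comprise one
deterministic k-means start on crude per-subject level/slope summaries plus
configurable random perturbations of the one-class solution (the repetition/
iteration-capped gridsearch scheme standard in this literature; defaults 100
starts × 100 iterations, scaled down in the packaged simulations — see
"Problem sizes"). The best start is run to a relative log-likelihood change
below 1e-6 and then polished by L-BFGS-B on the marginal likelihood with `Ψ`
in log-Cholesky form (guaranteeing positive semi-definiteness) and `σ` on the
log scale. Classes are relabeled ascending in model-implied mean at the
average final observation time, making labels and downstream contrasts
deterministic; for four classes the shapes map onto low / increasing /
decreasing / high severity labels via midpoint severity and slope sign.

**Model comparison and selection.** For each fit the package reports the
log-likelihood, sample-size-adjusted BIC `−2ℓ + p·ln((n+2)/24)` (Sclove
adjustment; `n` counts subjects — whether the original analysis counted
subjects or observations is unstated, and subjects is the conventional
choice), relative entropy `1 − Σ(−p·ln p)/(n ln K)`, the smallest class
share, and a likelihood-ratio test against the (K−1)-class fit. The analytic
LRT scales `2ΔLL` by `(n − 1 − p̄)/n` (`p̄` the mean parameter count of the
two models) and refers it to a chi-square with the parameter-count
difference as degrees of freedom — an approximation to the corrected mixture
LRT whose exact published variant differs across software; a parametric
bootstrap mode (resimulate under the smaller model, refit both) is provided
as the calibrated cross-check. Selection is a deterministic rule encoding the
stated preference for parsimony: candidates whose smallest class falls below
a floor (default 3%) or whose entropy drops more than a margin (default
0.05) against the same-family K−1 model are excluded; lowest adjusted BIC
wins among the rest, ties to fewer classes.

## Response weighting

Response (at least one post-deployment assessment) is modeled from
pre-deployment severity, the exposure flags, the six PRS and ten principal
components with a cross-fitted stacked ensemble: regularized logistic
regression and gradient-boosted trees as base learners, combined by a
logistic meta-learner trained on inner out-of-fold base predictions, all
inside an outer stratified 5-fold split so every subject is scored by models
that never saw it. This is the smallest faithful stacking architecture; the
original ensemble's learner set is unreported, and composition, folds and a
fast logistic-only mode are configurable. Responders receive weight `1/p̂`,
truncated at the 1st/99th weight percentiles by default (an added safeguard
with an off switch). Each responder then contributes one record per class
with weight `posterior_ik × ipw_i`; per subject these sum to the subject's
IPW, conserving total mass. Weights are not renormalized — the regression's
point estimates are scale-invariant and inference is sandwich-based.

## Association models

Each PRS is tested in its own probability-weighted multinomial logistic
regression of class membership (low-severity reference) on the PRS plus sex,
age, the eight exposure flags and ten principal components, fit by
Newton–Raphson with step-halving to a score norm below 1e-8. Standard errors
are cluster-robust by subject by default — each subject appears in K
weighted records, and probability-weighted regression is known to understate
model-based uncertainty — with model-based covariance available for
comparison. The per-PRS omnibus test is a robust Wald chi-square on the K−1
PRS coefficients (the original test type is unstated; Wald was chosen).
Pairwise adjusted odds ratios exponentiate coefficient contrasts (reference
class contributing zero), giving exact reciprocal and reference-invariance
identities, with delta-method 95% CIs (multiplier 1.96). Quartile AORs refit
the model with indicator-coded sample quartiles of the standardized PRS
(rank-based ties). Multiplicity uses a Bonferroni threshold `α/m` (0.05/6 =
0.0083 for the six scores). Rates of new exposure across most-likely classes
are compared by 2×2 chi-square tests without continuity correction
(configurable).

## Pipeline and problem sizes

`run_all` executes generate → harmonize (recomputed from raw totals) → fit
the K×family grid → compare/select → classify → weight → associate, writing
every intermediate table, a class-mean trajectory figure, a quartile-AOR
figure and a manifest with seed, versions and SHA-256 checksums of all data
artifacts; reruns with the same configuration are byte-identical.

The packaged recovery simulations use n = 4353 subjects per replicate (the
modeled-sample size of the motivating design), a K = 4 mixture with the
default random intercept+slope structure, and a reduced multistart (a k-means
start plus 3 random starts, 25 EM iterations each, then polish) — ample here
because the generator's classes are well separated; the reproduction script
averages adjusted odds ratios over 20 replicates and reports Monte-Carlo
standard errors. Entropy and mean maximum posterior probability are reported
descriptively on synthetic runs; under the default generator the classes are
more separated than in real cohorts, so these run close to 1 and recovery
results should be read as verifying the estimation machinery, not as
evidence about attainable classification quality in field data.

## What the generator does and does not emulate

Emulated: the latent-class trajectory structure and prevalences, shared
random-effect covariance, percent-scale linear trajectories, wave-specific
abbreviated instruments, assessment-time jitter, PRS effect sizes on
membership, unit nonresponse, and severity-dependent correlated wave
attrition calibrated to the published pattern shares. Not emulated:
item-level responses (totals are generated directly), genotypes or PRS
construction (scores enter as standardized columns), differing deployment
lengths across units, non-normal symptom score distributions (real percent
scores are right-skewed with floor effects; here they are conditionally
normal with rare clipping), and any dependence between PRS and the
covariates. Consequently, passing recovery checks demonstrates correctness
of the estimators under the stated model, not robustness to the skew,
floor effects and measurement artifacts of real symptom data.

## Known limitations

* Quadratic or spline trajectories and class-specific covariance matrices
  are out of scope (three post-deployment waves identify only linear shapes).
* The analytic mixture LRT is an approximation; bootstrap mode is the
  reliable variant and is correspondingly slower.
* The three-step estimator that carries covariates inside the mixture is not
  implemented; the probability-weighted two-step approach is.
* EM plus polish finds local maxima; pathological starts are mitigated, not
  eliminated, by the k-means and multistart scheme.
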