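# Methods

## The model family

All analyses operate on trial-level binary accuracy records from a
three-condition (LV / HV / HVB) tone-training battery.  The working
model throughout is a logistic mixed-effects regression

    y_it ~ Bernoulli(logistic(x_it' β + z_it' u_i)),   u_i ~ N(0, Σ),

with subject-level random effects u_i.  The assumptions this carries:
conditional independence of trials given the subject effects, a logit
link, normal random effects, and fixed effects that act additively on
the log-odds scale.  No overdispersion beyond the random effects is
modelled, and items are not crossed random effects (subject is the only
grouping factor — a deliberate simplification matching the analyses
this package reimplements).

### Contrast coding

Categorical predictors enter as centred dummies: a 0/1 dummy against a
stated baseline minus its observed mean.  On balanced data the
three-level condition factor with LV baseline gives codes
{LV −1/3, HV 2/3, HVB −1/3} (HVB dummy analogous); the pooled
LV-vs-(HV ∪ HVB) contrast used by the Bayes-factor models gives
{LV −2/3, HV 1/3, HVB 1/3}; two-level factors give ±1/2.  Centring
constants always use the observed frequencies of the rows being
modelled, so imbalance from trial exclusions is absorbed into the
constants rather than silently biasing the intercept.  Training session
is numeric 1–6, centred; the pre/post factor is a centred two-level
contrast.  Centring means every main effect is evaluated as an average
over the other factors' levels; on balanced data the highest-order
interaction is invariant to the centring (a property the test suite
checks).

### Estimation

The marginal likelihood integrates u_i out numerically:

* **one random effect** — adaptive Gauss–Hermite quadrature, 15 nodes
  by default (8 in the batch battery).  The per-subject integrand mode
  and curvature are found by Newton iteration and the Hermite nodes are
  relocated and rescaled there, which keeps a modest node count
  accurate even for large subjects;
* **two or more random effects** — a Laplace approximation at the
  per-subject penalised mode.

The covariance Σ is parameterised by its Cholesky factor with logged
diagonal ("full"), or by log-SDs only ("no_correlations").  L-BFGS-B
maximises the likelihood with numerical gradients; convergence demands
optimizer success with relative likelihood tolerance 1e-8 and a small
projected gradient, within 500 iterations.  Non-convergence triggers a
deterministic fallback ladder — full covariance → correlations removed →
random intercept only — and the level reached is recorded on the
results object.  Standard errors come from the inverse numerical
observed information; inference is Wald, z = β/SE with a normal
reference, no degrees-of-freedom correction, and no multiple-testing
adjustment (mirroring the reporting conventions of the analyses
reproduced here).  With no random effects the fit reduces to
Newton–Raphson logistic regression, which the tests check against
statsmodels to 1e-4.

Numerical edge cases: random SDs are bounded below at e^-8 (an SD that
small is numerically a fixed-effects model, and the quadrature
short-circuits to it); |β| > 10 raises a quasi-separation warning and
flags the coefficient; rank-deficient designs are rejected up front
with the aliased term names.

## Informed Bayes factors

Evidence for a directional H1 against a point null is the
marginal-likelihood ratio

    B = ∫₀^∞ N(β; θ, SE²) · HN(θ; 0, x) dθ / N(β; 0, SE²),

computed from the closed form 2·N(β; 0, SE²+x²)·Φ(μ_post/σ_post) on the
log scale (a quadrature route is kept as a cross-check; the two agree
to 1e-6).  The half-normal prior has mode 0 and scale x, supported only
in the predicted direction; β keeps its observed sign, so an effect
opposite to prediction pushes B toward the null.  B < 1/3 and B > 3 are
the substantial-evidence conventions; boundary values are classed
ambiguous.

The scale x is never a default: it is derived from the data by four
rules — grand-mean log-odds minus task-chance log-odds for predicted
main effects (chance: logit 0 for 2AFC, −1.099 for four-way tone,
−4.263 for the 1/72 pinyin floor, −0.693 for three-interval oddity);
the mean session effect for session-by-condition interactions; the mean
aptitude effect for aptitude-by-condition interactions; and
(maxa − ba)/2 for three-way interactions, where maxa is the steepest
aptitude slope the scale permits (ceiling 71/72 minus chance, divided
by the observed range of the aptitude predictor — the observed rather
than theoretical range, configurable) and ba the baseline aptitude
effect.  In the batch battery ba is taken from the fitted aptitude main
effect of the same model.

**Robustness regions** report the maximal contiguous interval of scales
x preserving the conclusion at the scale actually used, found on a
0.01-resolution grid over (0, 50].  Regions reaching the smallest grid
point are reported from 0 (as x → 0⁺, B → 1, so only ambiguous regions
touch zero); substantial-null regions are open above (a more diffuse
prior only strengthens the null), so their upper endpoint is ∞.

**Sample-size projection** holds β and x fixed and shrinks
SE(n) = SE·√(n0/n), returning the smallest integer n at which B reaches
the criterion (1/3 by default), or a non-attainable verdict with the
limiting B when the estimate is too far from zero in the predicted
direction.

## The synthetic-data generator

The generator emulates the study design verbatim: 60 subjects (20 per
condition), six 288-trial training sessions, pre/post 72-trial oddity
(36/36 item novelty × 24/24/24 trial type), post-only 72-trial picture
identification (36/36 voice novelty), pre/post 72-word repetition,
36-picture naming, a pre/post 96-trial pitch-contour test, and a
pre/post 120-trial tone-continuum task (two blocks × six steps × ten).
Outcomes are drawn from the same logistic mixed model family the
analyses assume, so parameter-recovery tests are meaningful.

Default generative coefficients echo the effect sizes such batteries
report: training-session slope 0.5 log-odds, oddity pre-to-post 0.31,
repetition 0.40, trial-type offsets +0.40 (easy) and −0.14 (hard)
against neutral (reproducing the easy > neutral > hard ordering), a
large trained-voice advantage (−1.07 for untrained) in picture
identification, an aptitude slope of 0.07–0.15 per scaled unit, and
null condition-by-session and condition-by-aptitude interactions.
Random-effect SDs default to 0.5–0.8 for intercepts and 0.15–0.4 for
within-subject slopes, with identity correlations.  A latent per-subject
aptitude — a true proportion, Normal(0.55, 0.15) clipped to
[0.05, 0.98] — both drives the pitch-contour responses (through its
logit) and supplies the ×10-scaled, centred covariate in the other
tasks, reflecting the view of the pre-test score as a proxy for latent
ability.  Continuum slopes are drawn lognormal(log 1.3, 0.15), so about
70% of simulated subjects exceed the b1 = 1.2 screening threshold, the
failure rate such continua produce in practice.  `null_generative_params`
zeroes every condition effect for null-world calibration runs.

Dual-rater codings share a latent produced-tone label per trial (tied
to the simulated production outcome when available); each rater
reproduces it with probability `agreement` (default 0.90), codes 0
(unusable) at `unusable_rate` (default 0.034), and produces a 1–7
rating by discretised normal noise around a quality score.

What the generator does **not** emulate: item-level random variation,
counterbalancing version as anything beyond the novelty flags, reaction
times, learning within a session, serial dependence between trials, or
acoustic properties of stimuli.  Passing recovery and calibration tests
therefore shows the estimators are correct for the assumed model class,
not that real data satisfy those assumptions.

## Aptitude scoring

The pitch-contour score is the pre-test proportion correct ×10, centred
on the analysis sample; pre-test only, because the measure itself
improves with training.  The continuum slope fits per-step Tone-3
proportions with Y = 1/(1 + b0·b1^t) via OLS on
ln(1/Y − 1) = ln b0 + t·ln b1 — the parameterisation under which the
1.2 exclusion threshold and "smaller slope = more categorical" are both
coherent (b1 < 1 categorical, b1 = 1 flat, b1 > 1 reversed).  Per-step
proportions are computed from the binary responses (the alternative —
fitting raw trials — is not what the log-linearised curve fit operates
on); degenerate proportions of 0 or 1 receive a 1/(2·n_t) continuity
correction, and an exactly flat profile is returned as b1 = 1 with a
`flat` flag rather than an error.

## Production reliability

Trials where either rater coded tone 0 are removed (restricting to the
analysis rater is a flag), along with fully excluded subjects; the
removal percentage is reported over all trials to two decimals.  Tone
accuracy is exact label match; pinyin accuracy is exact match after
canonicalisation (lowercase, whitespace, tone digits and diacritics
stripped — the measure is segmental only).  Analyses default to rater
2's codings (the naive rater), configurable.  Agreement is unweighted
Cohen's kappa with Landis–Koch labels; the 1–7 rating's reliability is
the two-way mixed, consistency, average-measures ICC (ICC3k; the
variant is fixed because only the model and unit are conventionally
stated) with Cicchetti labels.  The rating feeds only the ICC — it is
carried through I/O but never analysed as an outcome.

## The battery and its defaults

`run_battery` chains simulate → reliability → aptitude → GLMM presets →
the twelve-row Bayes-factor battery, writing every stage artifact to
disk and a provenance block (seed, version, config hash) so a report is
reproducible byte for byte.  The BF battery fits pooled-contrast
models with a random intercept only (8 quadrature nodes) by default —
the scalar-quadrature route is fast and the pooled contrasts are
between-subject, so random slopes change the target coefficients
little; `random_slopes=True` restores slope terms.  A per-row H1-scale
derivation that fails (e.g. a negative fitted session effect in a small
simulation) is recorded in the row as `not_computable` with the reason,
never dropped.

Problem sizes in the shipped tests are the package's own scaling
choices: recovery runs at the picture-identification task's full size
(60 subjects × 72 trials, 20 replicates), null-world calibration at 12
subjects with shortened tasks (50 replicates), and the battery
round-trip at 12 subjects.

## Known limitations

* Laplace approximation error for multivariate random effects is not
  bounded by an oracle the way the scalar quadrature is; binary data
  with few trials per subject can bias variance components slightly
  downward.
* The robustness-region grid tops out at x = 50; regions genuinely
  extending beyond that are truncated unless the conclusion is
  substantial-null (where ∞ is exact by construction).
* The sample-size projection treats β and x as fixed while SE shrinks;
  it is a planning heuristic, not a design analysis.
* Kappa and ICC are two-rater only; no weighted kappa.
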