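# Methods

## Task model

The restless four-armed bandit pays integer points in [1, 100]. Each arm's
latent mean follows a mean-reverting AR(1) walk

    mu[i, t+1] = lambda * mu[i, t] + (1 - lambda) * theta + nu,
    nu ~ N(0, sigma_d^2),

with defaults lambda = 0.9836, theta = 50 points, sigma_d = 2.8 points. The
payoff shown on a trial is N(mu[i, t], sigma_o) with sigma_o = 4 points,
range-limited and rounded. For lambda < 1 the walk is stationary with mean
theta and variance sigma_d^2 / (1 - lambda^2) (about 241 points^2 at the
defaults); initial means are drawn from that stationary law so early trials
are statistically typical. Latent means are deliberately unbounded — only
payoffs are range-limited, since the generating equation contains no
truncation term.

Boundary handling at 1/100 is configurable: `reflect` (default) folds the
continuous draw back into range before rounding, which avoids probability
mass piling up at the bounds; `clamp` truncates. Sessions default to 300
trials in 4 runs of 75 with a 1.5 s response window; a missed trial pays
nothing and records no RT.

## Choice model

Each arm carries a Gaussian belief (mean, variance). Observing reward r on
the chosen arm c applies the Kalman update

    kappa  = var_c / (var_c + sigma_o^2)
    mean_c <- mean_c + kappa * (r - mean_c)
    var_c  <- (1 - kappa) * var_c

and *every* arm then diffuses: mean <- lambda * mean + (1 - lambda) * theta,
var <- lambda^2 * var + sigma_d^2. Unchosen arms' posteriors equal their
priors. Missed trials apply the diffusion step only (time passes without an
observation) and contribute no likelihood term.

Choice follows softmax over the *pre-choice* (prior) means, P(i) ∝
exp(beta * mean_i) — choice precedes outcome. beta has units 1/points and
is interpreted as an inverse temperature: the observed group means (~0.17
to 0.19) are the right scale for payoffs in 1..100 under this convention.
The alternative temperature parameterization is not asserted anywhere; the
package treats beta as the free per-subject parameter.

Default learning parameters are the cohort-level best-fit values for this
task family: lambda = 0.8941, theta = 54.77, sigma_d = 6.32, sigma_o = 0,
mu0 = 67.78 points, var0 = 8.18 points^2, identical priors for all arms.

## Fitting

Learning parameters are shared across all subjects; beta is per subject.
For fixed learning parameters the belief trajectory is beta-independent, so
each subject's negative log-likelihood is convex in beta (a log-sum-exp of
linear functions) and is minimized exactly by a damped, clamped Newton
iteration on [0, 5]. The outer search over the shared parameters uses
bounded L-BFGS-B from `restarts` seeded starting points (the first start is
the model defaults); box bounds are lambda in (0, 1], sigma_o >= 0 with the
lower bound *exactly* 0 because the optimum may sit there. When both the
prior variance and sigma_o are 0 the Kalman gain is defined as 1 (exact
observation); a 1e-12 variance floor guards the division.

Identifiability: at sigma_o = 0 the gain is 1 regardless of the variances,
so the likelihood is flat in sigma_d and var0 — those two estimates are
reported but carry no information when the fitted sigma_o hits zero.
Recovery claims therefore concern lambda, theta, mu0 and beta. On 20
replicate 50-subject cohorts the fit recovers lambda with bias +0.0006 and
RMSE 0.0033 and the cohort mean beta with bias +0.003, RMSE 0.004 (computed
by the recovery test in the suite).

## Explore/exploit labelling

A responded trial is labelled *exploit* when the chosen arm's pre-choice
mean is within 1e-9 points of the maximum across arms, *explore* otherwise:
"an arm other than the one believed best" implies strict inferiority, so
ties count as exploit. All arms share the initial prior, hence trial 1 is a
tie and labels exploit; this affects counts by at most one trial.

## Efficiency and ANOVAs

A subject's efficiency is total payoff over responded trials divided by
mean RT (points per second). Per choice type, the *total* cell definition
(default) divides the cell's payoff total by the cell's mean RT — the
literal reading of payoff-over-time, under which cells scale with their
trial counts; the *per-trial* alternative divides mean payoff per trial by
mean RT. Both are reported in the efficiency table; the configured one
feeds the ANOVA.

The 2 x 2 mixed ANOVA (choice type within, group between, unbalanced
groups allowed) is computed on cell values via an exact decomposition: the
between-group effect is the pooled t-test on per-subject condition means
squared; the condition and interaction effects come from an OLS of
difference scores on an effect-coded group column, whose intercept tests
the *unweighted* (Type-III style) condition mean. All three effects are
F(1, n - 2). The implementation is cross-checked in the test suite against
an independent GLM projection oracle (subject dummies + model comparison)
and against pingouin on balanced designs.

## ROI statistics

ROI analyses start from tabular per-subject, per-condition activity
estimates for 8 mm spheres at fixed MNI centers (registry: vmPFC
(-3, 33, -6); left/right FPC (-27, 48, 4)/(27, 57, 6); left/right IPS
(-29, -33, 45)/(39, -36, 42); a second right-FPC sphere (36, 54, 0) from a
switching study; dACC (-2, 21, 34); left/right locus coeruleus
(-4, -37, -23)/(5, -37, -23)). Sphere extraction from images is upstream
and out of scope.

The explore-vs-exploit contrast treats the 2n condition estimates as
independent samples (pooled t, df = 2n - 2), matching the df convention of
the published ROI tables; a paired variant (df = n - 1) is available. P
values are two-sided since no sidedness is asserted. The efficiency
regression is OLS of per-subject efficiency on an intercept, a 0/1 group
indicator and the raw explore and exploit estimates of the seven analysis
ROIs (locus coeruleus excluded) — 15 regressors, overall F(k, n - k - 1);
standardizing the regressors is an option, off by default because the
published coefficient units indicate raw estimates.

## Synthetic cohort generator

The generator emulates the study population: 24 entrepreneur-like and 26
manager-like subjects; per-subject beta from truncated-at-zero normals with
group means 0.19 / 0.17 and SDs 0.08 / 0.09; a single fixed-seed payoff
schedule shared by the cohort (per-subject schedules optional); miss rate
1%. The printed entrepreneur beta SD of 0.8 is treated as a typo for 0.08 —
it is an order of magnitude away from the manager SD and incompatible with
the reported non-significant group comparison; the value is
config-overridable.

Response times are lognormal for positivity and right skew. The printed
group RT statistics are across-subject moments, so each subject's mean RT
is drawn from a lognormal moment-matched to the group target mean and
between-subject SD (0.389 / 0.043 s and 0.454 / 0.095 s); trial RTs are
then lognormal around the subject mean with a within-subject SD of 0.10 s,
a typical trial-to-trial jitter for sub-second choices. RTs are truncated
to the response window. RTs are independent of choice type by default; an
optional explore-RT increment exists for power studies of the choice-type
RT effect.

ROI tables plant: fixed explore-minus-exploit condition effects per ROI
(explore > exploit fronto-parietal, exploit > explore vmPFC), sized from
the published contrast t values at unit condition noise; a frontopolar
choice-by-group interaction whose per-subject explore-exploit difference is
drawn from the published group statistics (+0.67 SD 1.60 vs -0.15 SD 1.18) —
for this ROI the noise is a subject offset shared by both conditions, so
the realized difference distribution is exactly the planted one; and a
linear coupling between selected (ROI, condition) terms and the z-scored
subject efficiency (rFPC-exploit 0.4, dACC-exploit 0.1, vmPFC-explore
-0.1, all in estimate units per efficiency SD), calibrated once so the
15-term regression lands near R^2 ~ 0.47 with stable signs for the group
and rFPC-exploit coefficients.

What the generator does *not* emulate: sequential RT dependencies and
post-error slowing, choice-RT coupling (off by default), payoff-level
individual differences beyond what beta heterogeneity induces, spatial
correlation between ROIs beyond the shared efficiency factor, and any
voxel-level structure. Passing tests therefore demonstrate correctness of
the pipeline's computations and its statistical calibration under the
stated generative assumptions, not fidelity to any particular real
dataset.

## Numerical choices

* Softmax and session likelihoods use max-subtraction / log-sum-exp
  throughout; probabilities sum to 1 within 1e-12.
* Kalman gain: denominator floored at 1e-12; gain := 1 when prior variance
  and sigma_o are both zero.
* Tie tolerance for exploit labelling: 1e-9 points.
* Inner beta profile: damped Newton, step clamped to ±1, beta in [0, 5],
  gradient tolerance 1e-9, at most 60 iterations.
* Outer fit: L-BFGS-B, maxiter 300; multistart points uniform in the box.
* Lognormal moment matching: sigma^2 = ln(1 + (sd/mean)^2),
  mu = ln mean - sigma^2 / 2; degenerate (sd = 0) handled as constant.
* CSVs are written with 17-significant-digit floats and read with
  round-trip parsing so generator outputs survive I/O bit-identically.

## Problem sizes used by the checks

Generator moments use 1e5 steps; payoff bounds 1e6 draws; oracle
equivalence 210 randomized cases across the likelihood, ANOVA and
regression; parameter recovery 20 replicate 50 x 300 cohorts fit with 2
multistarts; detection power 100 replicate cohorts plus 100 matched null
cohorts; sign recovery 100 replicate ROI tables on one cohort.

## Known limitations

* With the default (published) learning parameters, sigma_o = 0 makes
  sigma_d and var0 unidentified (see Fitting); fits report them anyway.
* The end-to-end detection rate of the efficiency group effect under the
  published RT parameters is about 0.74-0.78 across replicate cohorts (as
  computed by the power test in the suite): the published between-subject
  RT spreads place the standardized group difference near d ~ 0.76, for
  which 24 + 26 subjects give roughly three-quarters power at alpha = 0.05.
  The corresponding test asserts a stricter 80% detection-rate target and
  currently fails it; the null-calibration half of the same test (nominal
  5% false-positive rate on matched null cohorts) passes.
* The mixed ANOVA is specialized to the 2 x 2 layout (one two-level within
  factor); it is not a general repeated-measures engine.
* The group comparison of betas uses the pooled-variance t-test; with
  strongly unequal group variances a Welch variant would differ.
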