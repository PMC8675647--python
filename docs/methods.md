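# Methods

## The task and its notation

The environment is a full-information secretary problem. A *round* offers up
to `K` *opportunities*; at each one an integer stimulus `v` is drawn i.i.d.
uniform on `{0..150}` (151 values). Accepting banks `v` and ends the round;
rejecting is irrevocable; the `K`-th opportunity is forced acceptance.
Subjects play up to 200 rounds. Opportunity and round indices are 1-based
everywhere in the package.

## Threshold models

**Optimal (DP) model.** The payoff-maximizing policy accepts at opportunity
`i` iff `v` strictly exceeds the expected value of continuing, computed by
backward induction:

    theta[K] = 0
    theta[i] = floor( P(v <= theta[i+1]) * theta[i+1]
                      + (1/151) * sum_{v = theta[i+1]+1}^{150} v )

On the inclusive integer grid, `P(v <= t) = (t+1)/151` for integer `t`; this
"inclusive" counting is the package default because acceptance is strict
(`v > theta`). The alternative `t/151` reading is available via
`convention="exclusive"`; the two differ only far from the final opportunity
(at `K = 5`: `theta[1]` is 110 vs 109). At `K = 5` the default schedule is
`(110, 103, 93, 75, 0)`; the unit tests verify by exhaustive enumeration
that no integer schedule achieves a higher expected round payoff at
`K <= 3`.

**Subjective-optimality model.** Valuation passes through a prospect-theory
value function with reference point `r` in (0, 150) and sensitivity exponent
`rho` in (0, 2):

    Util(v) =  (v - r)^rho    if v >= r
            = -(r - v)^rho    otherwise

The threshold recursion is run in utility space and mapped back through the
inverse value function; a waiting cost `C >= 0` (utility units per
opportunity) is subtracted from the expected utility of continuing:

    theta[i] = Util^-1( P(v <= theta[i+1]) * Util(theta[i+1])
                        + (1/151) * sum_{v > theta[i+1]} Util(v) - C )

With `rho = 1, C = 0` this reproduces the optimal schedule exactly (verified
for `K = 1..12`); as `rho -> 0` every free threshold collapses onto `r`
(the constant-threshold limit). Thresholds are floored to the integer grid
at each step, the same convention as the optimal model, which also keeps the
summation bounds exact; a continuous (un-floored) variant is available via
`floored=False` for likelihood-smoothness experiments. Flooring only ever
lowers thresholds, by less than ~2 stimulus units at `K = 5`. When the
continuation utility net of cost is negative, the inverse function's loss
branch applies (the threshold drops below `r`); the only clipping is to
`[0, 150]` at the end of each step.

**Descriptive rivals.** Constant (`theta[i] = c`), linear
(`theta[i] = a + b*i`), and independent (one free threshold per opportunity
`1..K-1`) models complete the comparison set. Forced final rows are handled
by the choice model, not the schedules.

**Expected round payoff** of any schedule is evaluated exactly by backward
induction over the discrete stimulus distribution; real thresholds act
through their floor (`v > theta` iff `v >= floor(theta) + 1` on integers).

## Choice likelihood and hierarchical estimation

Choices are probabilistic around the model thresholds:
`P(accept | v, i) = Phi((v - theta[i]) / s)` with one decision variability
`s > 0` per subject shared across opportunities. Forced final-opportunity
rows never enter the likelihood; a reject recorded at opportunity `K` is a
data-integrity error.

Hierarchical fitting samples every parameter in an unbounded space:
`r` and `rho` via scaled logistics `g(x) = A/(1+exp(-x))` with `A = 150`
and `A = 2` respectively, `s` (and the group SDs) via `exp`, the waiting
cost untransformed. Subject-level values are Gaussian around group means
(`x_kj ~ N(mu_j, sigma_j)`); priors are broad uniforms on `mu_j`
([-10, 10] for logistic-transformed parameters, [log 0.5, log 50] for
log-space `s`, [-50, 200] for untransformed location parameters) and
inverse-Gamma(shape 1, scale `beta`, default 1) on each `sigma_j`, which is
sampled on the log scale with the Jacobian included.

The sampler is Metropolis-Hastings with three kinds of blocks per
iteration: componentwise Gaussian proposals for each subject-level
parameter (proposed for all subjects at once and accepted independently —
the likelihood factorizes over subjects), a joint full-vector subject block
whose proposal covariance is adapted during burn-in from the pooled
within-subject sample covariance, and scalar updates for each `mu_j` and
`log sigma_j`. All proposal scales adapt toward a 0.30 acceptance rate
during burn-in only (Robbins-Monro), so the post-burn-in kernel is fixed
and the chain valid. Defaults: 40,000 iterations, 10,000 burn-in,
adaptation window 50.

Two numerical choices matter and are deliberate:

* **Grid initialization.** Each subject starts at the best point of a
  deterministic parameter grid (full Cartesian product over the coupled
  parameters when small enough, coordinate ascent otherwise). This is not a
  convenience: at `rho = 1` the subjective model collapses onto the optimal
  schedule and the likelihood is *flat in `r`*, so chains started on that
  ridge cannot climb componentwise into the basin where `r` and `rho` are
  jointly identified, and group-level recovery fails. With grid starts the
  same chains recover the generating group means reliably.
* **Joint covariance block.** `r` and `rho` are strongly anticorrelated in
  the posterior (a higher reference point trades off against a lower
  exponent). Componentwise proposals alone mix slowly along this ridge;
  the adapted joint block traverses it.

Cohorts fitted hierarchically must share one `K` (per-condition fits, as in
the experiments); mixed-`K` data are fitted per condition.

**Identifiability.** Subjects whose sensitivity sits near or above
`rho ~ 0.9` are only set-identified: materially different (r, rho) pairs
produce near-identical schedules, so even long sessions cannot pin them
down, and their posteriors spread asymmetrically toward (lower r, higher
rho). With the inverse-Gamma shape fixed at 1 the group-SD prior has a
`sigma^-2` tail, so partial pooling softens but cannot remove this, and the
posterior-mean group sensitivity of a single 20 x 200 cohort carries a
small upward skew. Parameter-recovery quality is therefore defined — and
tested — as the *median over 5 independent cohort-plus-fit runs*, which is
robust to an occasional skew-dominated cohort: median recovery errors are
about −3 stimulus units on the group reference point and +0.03 on the
sensitivity at the default study conditions.

Point estimates per subject use the kernel-density MAP: the post-burn-in
sample (thinned to at most 1,500 draws) maximizing a multivariate Gaussian
KDE over that subject's samples, back-transformed. Group-level summaries
push each posterior draw of `mu_j` through its transform and report the
mean/SD/central interval of the back-transformed location.

Model comparison uses per-subject maximum-likelihood fits (deterministic
multi-start Nelder-Mead in the sampling space), AIC = 2k - 2 loglik,
per-subject Delta-AIC summarized by a paired nonparametric bootstrap over
subjects (10,000 resamples), and pooled chi-square likelihood-ratio tests
for nested pairs. During ML fitting of the cost model the waiting cost is
clipped at zero (its native domain); the hierarchical sampler keeps the
cost unconstrained in its identity transform.

## Cross-context prediction

To predict behavior at a new horizon `K_tgt` from fits at `K_src`, the
reference point of every resampled parameter pair is shifted by the
difference in *optimal* expected round payoff between the contexts, value
sensitivity is carried over unchanged, subjective thresholds are recomputed
at `K_tgt`, and the cohort-mean threshold at the opportunity preceding the
last is recorded; 5,000 resampling repeats give the 95% CI. "Expected value
across all opportunities" is operationalized as the expected accepted value
per round under the policy (not the mean of per-opportunity continuation
values). Subject-level MAP estimates (not posterior draws) are resampled.
Shifted reference points outside (0, 150) are clipped with a warning.

A model fact worth knowing when reading predictions: the threshold at the
opportunity preceding the last is non-monotone in `r` at fixed `rho < 1`
(it peaks near `r ~ 115 at rho = 0.62`), so an upward shift of an
already-high reference point can slightly *lower* that threshold.

## Model-free behavioral analyses

Empirical thresholds are cumulative-Gaussian psychometric fits per
opportunity (`P(accept|v) = Phi((v - theta)/s)`), maximized by Nelder-Mead
from five deterministic starts (`theta0 in {40, 60, 80, 100, 120}`,
`s0 = 15`), ties broken toward the smaller threshold; thresholds are
confined to a [-50, 200] box (clipped fits flagged) and `s` floored at 0.5
(perfectly separated data hit the floor). Threshold credible intervals are
grid posteriors (uniform prior on `theta` over [0, 150], log-uniform `s`
over [1, 60]) summarized by the 95% highest-density region, computed per
subject.

RT profiles bin mean RT by signed distance `v - theta[i]` (width 10, range
[-75, 75], at least 5 trials per reported bin; empty bins are missing, not
zero). Split-half analyses refit both halves of the rounds independently
(odd counts: first half larger). Serial-dependence checks run one logistic
regression per opportunity `i >= 2` of accept on the current and all
preceding within-round stimulus values; quasi-separation is flagged on the
reported coefficients.

## Rival mechanisms

**Regret.** Accept iff `v` exceeds both the optimal threshold and the
highest value passed up earlier in the round; perfect within-round memory,
reset between rounds; deterministic rule. 10,000 rounds per repetition, 20
repetitions, thresholds re-estimated post hoc by the psychometric fit. By
construction opportunity-1 thresholds equal the optimal model's; later ones
exceed it, flattening the curve, and lagged regressions on regret data
weight *earlier* opportunities more than the most recent (the running
maximum is more often set early).

**Selection bias.** The optimal schedule is shifted per round by
`delta ~ N(0, sd_round)` (optionally plus independent per-opportunity
noise); choices are deterministic against the noisy threshold. Rounds whose
offset is high survive to later opportunities, so post hoc estimated
thresholds flatten as `sd_round` grows. *Threshold change* is the mean
per-opportunity decrease of estimated thresholds over opportunities
`1..K-1` (positive when declining; a regression-slope variant is provided);
*response variability* is the pooled fitted psychometric SD. The default
sweep uses 8 SD levels spanning 5-40 stimulus units, 8 pseudo-subjects per
level, 2,000 rounds each — 64 units, enough to stabilize the correlation —
and yields a variability/threshold-change Pearson correlation of about
-0.97 under pure across-round variability, weakening toward ~0 as the same
total variance is moved to the across-opportunity component.

## Synthetic data

`sample_population` draws subject parameters from group Gaussians in the
transformed space (so native bounds hold by construction). The default
study conditions used by the recovery analyses are group means
`r = 110.51`, `rho = 0.62`, `s = 10` (the fitted group scale of the K = 5
condition) with transformed-space group SDs of 0.3, 0.3 and 0.2 — roughly
±9 stimulus units of `r`, ±0.15 of `rho`, and ±20% of `s` across subjects,
a heterogeneity typical of cohort fits of this kind. 20 subjects, 200
rounds, `K = 5`.

Agents accept with probability `Phi((v - theta[i])/s)` at free
opportunities; RTs, when requested, are `base - slope*|v - theta[i]|` plus
lognormal noise (defaults: base 900 ms, 4 ms per stimulus unit, scale
120 ms) — a descriptive convenience for testing the RT profile, not a
process model.

Pupil sessions are synthesized at 500 Hz: slow sinusoidal drift, smoothed
Gaussian noise, and a gamma-shaped dilation kernel (peak ~930 ms, the
canonical pupillary impulse response) at each stimulus onset, with
amplitude `base + accept_amp*[accepted] - difficulty_slope*|v - theta[i]|
+ coupling*rho`; audio cues fall uniform on [1.5, 2.5] s after onset;
blinks arrive at a Poisson rate with 100-400 ms dropouts and are annotated
as intervals. The generator exists to exercise the analysis chain with
known injected effects; it is not a biophysical pupil model, and passing
tests on it demonstrate the statistics' operating characteristics (type-I
error, power, direction), not claims about real pupils. Real recordings
additionally contain gaze-dependent artifacts, nonstationary arousal
drifts, and non-Poisson blink clustering that the generator omits.

## Pupillometry pipeline

Preprocessing order is fixed: linear interpolation of blink intervals
padded ±150 ms (saccade intervals unpadded — padding is a blink-specific
artifact precaution), eye averaging, zero-phase third-order Butterworth
band-pass 0.02-4 Hz (zero-phase preserves event latencies), least-squares
removal of the slow (~5 s) blink response via a design matrix of
overlapping triangular spline bumps per blink onset, and per-session
z-scoring. Sessions over 50% interpolated are excluded. Epochs span
-200..+1500 ms around stimulus onset (851 samples), baseline-corrected by
the mean over onset ±20 ms; epochs over 50% interpolated or truncated at a
recording edge are flagged, never fabricated or deleted.

The accept-vs-reject comparison uses pointwise paired t-tests (two-sided
alpha 0.05) on per-subject difference curves; clusters are maximal
contiguous significant runs, the cluster statistic is the sum of t-values,
and corrected p-values come from the permutation null of the maximum
|cluster mass| under per-subject sign flips (default 10,000 permutations;
results are bit-reproducible under a fixed seed). Difficulty effects use
the peak dilation over (0, 1500] ms regressed on |v - theta[i]| within the
signed windows -40 < v - theta < 5 (rejects) and -5 < v - theta < 40
(accepts), per subject, with a one-sample group t-test on the slopes;
subjects with fewer than 5 usable epochs in a window are dropped from that
regression with a log entry. Using the value at exactly 1500 ms instead of
the peak is available as a robustness switch. The sensitivity analysis
smooths each subject's peak dilation over signed difficulty [-90, 60] by
local quadratic regression (tricube weights, bandwidth 30 difficulty
units), correlates the smoothed dilation with fitted `rho` per bin, and
cluster-corrects over bins by permuting the sensitivity labels.

## Problem sizes and seeds

The analysis drivers and test suite run at desk scale by the package's own
choice of problem sizes: recovery cohorts of 20 subjects × 200 rounds
(a 12,000-iteration chain in the quick driver; 5 replicate cohorts with
16,000-iteration chains, summarized by their median, in the recovery
protocol), 20 × 10,000-round regret repetitions, the 64-unit selection
sweep, and 200 six-subject null pupil cohorts (16 rounds each, 250
permutations) for the family-wise-error check. Every random draw descends
from an explicit integer seed; rerunning any driver or the pipeline with
the same configuration reproduces its tables byte for byte.

## Known limitations

* The hierarchical sampler requires a common `K` within a fitted cohort.
* The independent-threshold model's per-opportunity thresholds are fitted
  jointly with a single `s`; with few surviving rounds at late
  opportunities its estimates are noisy.
* Floored thresholds make the subjective likelihood piecewise constant in
  (r, rho); the posterior is correspondingly coarse at very small `s`.
* The regret rule is deterministic (no soft/probabilistic variant), and
  selection-bias response variability levels come from a stated SD grid
  rather than an empirical cohort.
* The pupil generator's effects are additive and linear in |v - theta|;
  saturating or asymmetric physiological responses are out of scope.
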