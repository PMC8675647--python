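# subjopt — subjective optimality in finite sequential decision-making

`subjopt` models how decision makers solve a full-information secretary
problem: within each round, up to `K` integer stimuli drawn uniform on
{0..150} arrive one at a time; accepting banks the value and ends the
round, rejection is irrevocable, and the last opportunity is forced. The
payoff-maximizing policy is threshold-based and computable by backward
induction — at `K = 5` the optimal thresholds are (110, 103, 93, 75, 0) —
but people systematically deviate from it. The package implements a
computational account of those deviations: thresholds are still computed
by dynamic programming, but through a prospect-theory subjective value
function

    Util(v) =  (v − r)^ρ   if v ≥ r
            = −(r − v)^ρ   otherwise

with reference point `r`, value sensitivity `ρ` (ρ = 1 recovers the
objective optimum, ρ → 0 a constant threshold at `r`), and an optional
waiting cost `C` per opportunity subtracted from the expected utility of
continuing. Around the resulting schedule, choices are probabilistic:
P(accept | v at opportunity i) = Φ((v − θ[i]) / s).

For cognitive modelers, the package provides, on top of the threshold
machinery:

* hierarchical Bayesian estimation of (r, ρ, C, s) by Metropolis–Hastings
  with the scaled-logistic/log sampling transforms, plus kernel-density MAP
  point estimates, AIC/likelihood-ratio model comparison against constant,
  linear, independent-threshold and optimal rivals, and cross-context
  threshold prediction (shift `r` by the change in expected earnings,
  keep ρ);
* model-free behavioral analyses: cumulative-Gaussian psychometric
  thresholds per opportunity with HDI credible intervals, RT-vs-difficulty
  profiles, split-half stability, lagged choice regressions;
* simulations of two rival mechanisms for threshold flattening — regret
  (never accept below the best value passed up this round) and selection
  bias (round-level threshold variability) — and the
  variability/threshold-change correlation that discriminates them;
* a pupillometry pipeline (blink interpolation, band-pass, blink-response
  deconvolution, epoching, cluster-based sign-flip permutation tests,
  difficulty regressions, sensitivity-profile correlations);
* seeded synthetic-data generators for all of the above, so every analysis
  is testable without any recorded data.

See `docs/methods.md` for the full model and estimation details.

## Worked example

```python
import numpy as np
from subjopt import TaskSpec, ValueParams, optimal_thresholds, subjective_thresholds

spec = TaskSpec(K=5)
print(optimal_thresholds(spec).theta)
# (110.0, 103.0, 93.0, 75.0, 0.0)

p = ValueParams(r=110.51, rho=0.62, cost=0.0, s=10.0)
print(subjective_thresholds(spec, p).theta)
# (111.0, 109.0, 104.0, 88.0, 0.0)
```

The subjective schedule sits above the optimal one and declines with
accelerating steps (second differences −3, −11 over the free
opportunities): a decision maker with a high reference point and
compressive value sensitivity waits longer early on, and the curve is
concave — the signature that separates this account from a linear
threshold heuristic.

Fitting a synthetic cohort and recovering its generating parameters:

```python
from subjopt.synth import sample_population, simulate_cohort
from subjopt.hierarchical import HierarchicalSpec, fit_hierarchical, group_posterior
from subjopt import transforms

mus = {"r": transforms.to_sampling("r", 110.51),
       "rho": transforms.to_sampling("rho", 0.62),
       "s": float(np.log(10.0))}
rng = np.random.default_rng(1)
pop = sample_population(mus, {"r": 0.3, "rho": 0.3, "s": 0.2}, 20, rng)
data = simulate_cohort(pop, "subjective", TaskSpec(K=5, n_rounds=200), rng)
chain = fit_hierarchical(data, HierarchicalSpec(model_tag="subjective",
                                                n_iter=16_000, burn_in=5_000,
                                                seed=2))
print(group_posterior(chain)[["mean", "sd"]].round(3))
#           mean     sd
# param
# r      109.377  3.603
# rho      0.671  0.070
# s        9.652  0.537
```

A single cohort's posterior mean can sit a little off truth along the
correlated r/ρ ridge (some high-ρ subjects are only weakly identified);
the recovery protocol in `scripts/acceptance.py` therefore reports the
median over five independent cohort-plus-fit replicates, which lands
within about 1 stimulus unit of the generating reference point and 0.01
of the generating sensitivity at these conditions.

The numbered drivers under `analysis/` run each stage of the study and
write their tables under `results/`:

```
python analysis/01_threshold_schedules.py   # DP and subjective schedules, payoffs
python analysis/02_parameter_recovery.py    # hierarchical recovery (quick chain)
python analysis/03_model_comparison.py      # AIC / LRT across the model family
python analysis/04_context_prediction.py    # K=5 fits -> K=2 and K=10 thresholds
python analysis/05_rival_mechanisms.py      # regret + selection-bias sweep
python analysis/06_pupillometry.py          # full pupil chain on injected effects
```

For example, `05_rival_mechanisms.py` prints the selection-bias signature

```
selection bias: variability vs threshold change r = -0.972 (p = 1.49e-40)
```

— pseudo-subjects with the largest decision variability show the *smallest*
threshold decline, the opposite of what cohorts of real decision makers do,
which is what rules selection bias out as the source of threshold
flattening.

A thin CLI wraps the same functions (`subjopt generate|fit|compare|predict|
simulate|analyze-behavior|run`); `subjopt run --config cfg.yaml --out dir/`
executes a configured generate→fit→predict→analyze pipeline with full seed
stamping.

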