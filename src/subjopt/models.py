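"""Decision-threshold models for the finite sequential-choice task.

Under full information the payoff-maximizing policy is threshold-based: at
opportunity ``i`` accept any stimulus strictly above the expected value of
continuing, which backward induction (dynamic programming) delivers as the
schedule ``theta[1..K]`` with forced acceptance ``theta[K] = 0``.

The subjective-optimality model runs the same recursion through a
prospect-theory value function with reference point ``r`` and sensitivity
exponent ``rho``,

    Util(v) =  (v - r)**rho   if v >= r
            = -(r - v)**rho   otherwise,

optionally charging a waiting cost ``C`` per opportunity against the expected
utility of continuing, and maps back to stimulus units through the inverse
value function.  Setting rho = 1, C = 0 recovers the objective optimal model;
rho -> 0 collapses every threshold onto the reference point (the
constant-threshold limit).
"""

from __future__ import annotations

import math

import numpy as np

from .task import TaskSpec, ValueParams, LinearParams, ThresholdSchedule

__all__ = [
    "utility",
    "inverse_utility",
    "optimal_thresholds",
    "subjective_thresholds",
    "linear_thresholds",
    "constant_threshold",
    "expected_round_payoff",
    "threshold_curve_features",
]


def utility(v, p: ValueParams):
    """Subjective value of objective stimulus value(s) ``v``.

    Gains (v >= r) are valued (v - r)**rho, losses -(r - v)**rho.  Accepts
    scalars or arrays; the result is strictly increasing in v and shares the
    sign of (v - r).
    """
    if p.rho <= 0:
        raise ValueError("rho must be positive")
    v = np.asarray(v, dtype=float)
    d = v - p.r
    out = np.sign(d) * np.abs(d) ** p.rho
    return float(out) if out.ndim == 0 else out


def inverse_utility(u, p: ValueParams):
    """Stimulus value whose subjective value is ``u`` (inverse of `utility`)."""
    if p.rho <= 0:
        raise ValueError("rho must be positive")
    u = np.asarray(u, dtype=float)
    out = p.r + np.sign(u) * np.abs(u) ** (1.0 / p.rho)
    return float(out) if out.ndim == 0 else out


def _check_spec(spec: TaskSpec) -> None:
    if spec.K < 1:
        raise ValueError("TaskSpec.K must be >= 1")


def optimal_thresholds(spec: TaskSpec, convention: str = "inclusive") -> ThresholdSchedule:
    """Backward-induction thresholds of the payoff-maximizing policy.

    theta[K] = 0 (forced acceptance); for i < K,

        theta[i] = floor( P(v <= theta[i+1]) * theta[i+1]
                          + (1/n) * sum_{v=theta[i+1]+1}^{v_max} v )

    over the discrete uniform on {v_min..v_max}.  ``convention`` selects how
    P(v <= theta) is counted on the inclusive integer grid: ``"inclusive"``
    (default) uses (theta - v_min + 1)/n, matching strict acceptance of values
    above the threshold; ``"exclusive"`` uses (theta - v_min)/n.  The two
    differ only far from the final opportunity (theta[1] at K = 5: 110 vs 109).
    """
    _check_spec(spec)
    if convention not in ("inclusive", "exclusive"):
        raise ValueError(f"unknown convention {convention!r}")
    n = spec.n_values
    theta = [0.0] * spec.K
    theta[-1] = 0.0
    for i in range(spec.K - 2, -1, -1):
        t = int(theta[i + 1])
        count = t - spec.v_min + 1 if convention == "inclusive" else t - spec.v_min
        tail = sum(range(t + 1, spec.v_max + 1))
        theta[i] = float(math.floor((count / n) * t + tail / n))
    return ThresholdSchedule(K=spec.K, theta=tuple(theta), model_tag="optimal")


def subjective_thresholds(
    spec: TaskSpec,
    p: ValueParams,
    floored: bool = True,
    convention: str = "inclusive",
) -> ThresholdSchedule:
    """Thresholds of the subjective-optimality model (with waiting cost).

    Same backward recursion as `optimal_thresholds`, with utilities in place
    of values, the waiting cost subtracted from the expected utility of
    continuing, and the inverse value function mapping back to stimulus units:

        theta[i] = Util^-1( P(v <= theta[i+1]) * Util(theta[i+1])
                            + (1/n) * sum_{v>theta[i+1]} Util(v)  -  C )

    With rho = 1 and C = 0 this reproduces `optimal_thresholds` exactly.
    ``floored=True`` (default) floors each threshold to the integer grid, the
    same convention as the optimal model; ``floored=False`` keeps thresholds
    continuous (summation bounds still use the floored value).  Thresholds are
    clipped to [v_min, v_max] at the end of each step.
    """
    _check_spec(spec)
    n = spec.n_values
    grid = np.arange(spec.v_min, spec.v_max + 1, dtype=float)
    u_grid = utility(grid, p)
    # tail[j] = sum of Util(v) over grid indices > j
    tail = np.concatenate([np.cumsum(u_grid[::-1])[::-1][1:], [0.0]])
    theta = [0.0] * spec.K
    theta[-1] = 0.0
    for i in range(spec.K - 2, -1, -1):
        th_next = theta[i + 1]
        j = int(math.floor(th_next)) - spec.v_min  # grid index of floor(theta)
        count = j + 1 if convention == "inclusive" else j
        eu = (count / n) * utility(th_next, p) + tail[j] / n - p.cost
        th = inverse_utility(eu, p)
        th = min(max(th, float(spec.v_min)), float(spec.v_max))
        theta[i] = float(math.floor(th)) if floored else float(th)
    return ThresholdSchedule(
        K=spec.K,
        theta=tuple(theta),
        model_tag="subjective_cost" if p.cost > 0 else "subjective",
        params={"r": p.r, "rho": p.rho, "cost": p.cost},
    )


def linear_thresholds(lp: LinearParams, K: int) -> ThresholdSchedule:
    """Linear heuristic: theta[i] = a + b*i for opportunities i = 1..K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    theta = tuple(lp.a + lp.b * i for i in range(1, K + 1))
    return ThresholdSchedule(K=K, theta=theta, model_tag="linear",
                             params={"a": lp.a, "b": lp.b})


def constant_threshold(c: float, K: int) -> ThresholdSchedule:
    """A single threshold applied at every opportunity (forced final
    acceptance is handled by the choice model, not the schedule)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return ThresholdSchedule(K=K, theta=(float(c),) * K, model_tag="constant",
                             params={"c": float(c)})


def expected_round_payoff(sched: ThresholdSchedule, spec: TaskSpec) -> float:
    """Expected accepted value per round under accept-iff-v-strictly-above-
    threshold, with forced acceptance at opportunity K.

    Evaluated exactly on the discrete uniform stimulus distribution by
    backward induction; any real threshold acts through its floor (v > theta
    iff v >= floor(theta) + 1 on the integer grid).
    """
    if sched.K != spec.K:
        raise ValueError(f"schedule K={sched.K} does not match spec K={spec.K}")
    n = spec.n_values
    ev = (spec.v_min + spec.v_max) / 2.0  # forced final opportunity
    for i in range(spec.K - 1, 0, -1):  # opportunities K-1 .. 1
        t = math.floor(sched[i])
        t = min(max(t, spec.v_min - 1), spec.v_max)
        n_acc = spec.v_max - t
        if n_acc == 0:
            continue  # nothing accepted; ev unchanged
        mean_acc = (t + 1 + spec.v_max) / 2.0
        p_acc = n_acc / n
        ev = p_acc * mean_acc + (1.0 - p_acc) * ev
    return float(ev)


def threshold_curve_features(
    sched: ThresholdSchedule, include_final: bool = False
) -> dict:
    """First/second differences and mean slope of a threshold schedule.

    By default the forced-final theta[K] = 0 entry is excluded, matching
    per-opportunity comparisons over the free choices 1..K-1.  Returns a dict
    with ``first_diff`` (length m-1 for m retained opportunities),
    ``second_diff`` (length m-2) and ``mean_slope`` (mean first difference).
    """
    theta = np.asarray(sched.theta if include_final else sched.theta[:-1])
    if theta.size < 2:
        raise ValueError("schedule too short for difference features")
    d1 = np.diff(theta)
    d2 = np.diff(d1)
    return {
        "first_diff": d1,
        "second_diff": d2,
        "mean_slope": float(d1.mean()),
    }
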