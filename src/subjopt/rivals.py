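"""Rival mechanisms for threshold flattening: regret and selection bias.

Both mechanisms are simulated forward and their apparent (post hoc
estimated) thresholds compared with the optimal schedule.  The regret agent
refuses anything below the best value it has already passed up within the
round; the selection-bias agent follows the optimal schedule jittered by
round-level (and optionally opportunity-level) Gaussian offsets, so rounds
with high offsets survive to later opportunities and flatten the estimated
curve.  The discriminating statistic is the correlation between a unit's
response variability and its threshold change across opportunities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .task import TaskSpec
from .models import optimal_thresholds
from .behavior import fit_psychometric
from .io import CHOICE_COLUMNS

__all__ = [
    "SimulationResult",
    "simulate_regret",
    "simulate_selection_bias",
    "selection_bias_sweep",
    "variability_threshold_correlation",
    "threshold_change",
]


@dataclass
class SimulationResult:
    """One simulated unit: its dataset, post hoc threshold estimates and
    summary statistics."""

    data: pd.DataFrame
    est_thresholds: dict            # opportunity -> fitted psychometric mean
    est_variability: dict           # opportunity -> fitted psychometric SD
    settings: dict = field(default_factory=dict)

    @property
    def threshold_change(self) -> float:
        return threshold_change(self.est_thresholds)

    @property
    def response_variability(self) -> float:
        return float(np.mean(list(self.est_variability.values())))


def threshold_change(est: dict) -> float:
    """Mean per-opportunity decrease of estimated thresholds over
    opportunities 1..K-1 (positive when the curve declines)."""
    opps = sorted(est)
    th = np.array([est[i] for i in opps])
    if th.size < 2:
        raise ValueError("need at least two opportunities")
    return float(-np.diff(th).mean())


def threshold_change_slope(est: dict) -> float:
    """Alternative operationalization: negated least-squares slope of the
    estimated thresholds against opportunity index."""
    opps = np.array(sorted(est), dtype=float)
    th = np.array([est[i] for i in opps.astype(int)])
    return float(-np.polyfit(opps, th, 1)[0])


def _rows_to_frame(vals, stop, K, subject_id):
    lengths = stop + 1
    offsets = np.cumsum(lengths) - lengths
    total = int(lengths.sum())
    n = len(stop)
    round_col = np.repeat(np.arange(1, n + 1), lengths)
    opp_col = np.arange(total) - np.repeat(offsets, lengths) + 1
    value_col = vals[round_col - 1, opp_col - 1]
    accept_col = opp_col == np.repeat(lengths, lengths)
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "K": K,
            "round": round_col,
            "opportunity": opp_col,
            "value": value_col,
            "choice": np.where(accept_col, "accept", "reject"),
            "rt_ms": np.nan,
            "forced": opp_col == K,
        },
        columns=CHOICE_COLUMNS,
    )


def _estimate(df, K):
    est, var = {}, {}
    free = df[~df["forced"].astype(bool)]
    for i in range(1, K):
        g = free[free["opportunity"] == i]
        f = fit_psychometric(g["value"], g["choice"] == "accept", i)
        est[i] = f.threshold
        var[i] = f.variability
    return est, var


def simulate_regret(spec: TaskSpec, n_rounds: int = 10_000, n_reps: int = 20,
                    seed=0) -> list:
    """Simulate the regret agent: accept iff v exceeds both the optimal
    threshold and the highest value passed up earlier in the round (perfect
    within-round memory, reset between rounds).  Thresholds are re-estimated
    from the simulated choices; each repetition uses an independent stream.
    """
    if n_rounds < 1:
        raise ValueError("n_rounds must be >= 1")
    rng = np.random.default_rng(seed)
    theta_opt = np.asarray(optimal_thresholds(spec).theta)
    K = spec.K
    out = []
    for rep in range(n_reps):
        vals = rng.integers(spec.v_min, spec.v_max + 1, size=(n_rounds, K))
        if K > 1:
            # effective threshold at opportunity i: max(theta_opt[i], running
            # max of values seen before i within the round)
            prev_max = np.concatenate(
                [np.full((n_rounds, 1), -np.inf),
                 np.maximum.accumulate(vals[:, : K - 1], axis=1)], axis=1
            )[:, :K]
            eff = np.maximum(theta_opt[None, : K - 1], prev_max[:, : K - 1])
            acc = vals[:, : K - 1] > eff
            stop = np.where(acc.any(axis=1), acc.argmax(axis=1), K - 1)
        else:
            stop = np.zeros(n_rounds, dtype=int)
        df = _rows_to_frame(vals, stop, K, f"regret{rep:02d}")
        est, var = _estimate(df, K)
        out.append(SimulationResult(
            data=df, est_thresholds=est, est_variability=var,
            settings={"mechanism": "regret", "rep": rep, "n_rounds": n_rounds},
        ))
    return out


def simulate_selection_bias(spec: TaskSpec, sd_round: float,
                            sd_opportunity: float = 0.0,
                            n_rounds: int = 10_000, seed=0,
                            subject_id: str = "sel00") -> SimulationResult:
    """Simulate deterministic choices against the optimal schedule shifted by
    a per-round offset ~ N(0, sd_round) (plus optional independent
    per-opportunity noise ~ N(0, sd_opportunity)); thresholds are
    re-estimated post hoc from the surviving rounds."""
    if sd_round < 0 or sd_opportunity < 0:
        raise ValueError("offset SDs must be >= 0")
    rng = np.random.default_rng(seed)
    theta_opt = np.asarray(optimal_thresholds(spec).theta)
    K = spec.K
    vals = rng.integers(spec.v_min, spec.v_max + 1, size=(n_rounds, K))
    delta = rng.normal(0.0, sd_round, size=(n_rounds, 1)) if sd_round > 0 else 0.0
    eps = (rng.normal(0.0, sd_opportunity, size=(n_rounds, K - 1))
           if sd_opportunity > 0 else 0.0)
    theta_eff = theta_opt[None, : K - 1] + delta + eps
    acc = vals[:, : K - 1] > theta_eff
    stop = np.where(acc.any(axis=1), acc.argmax(axis=1), K - 1)
    df = _rows_to_frame(vals, stop, K, subject_id)
    est, var = _estimate(df, K)
    res = SimulationResult(
        data=df, est_thresholds=est, est_variability=var,
        settings={"mechanism": "selection", "sd_round": sd_round,
                  "sd_opportunity": sd_opportunity, "n_rounds": n_rounds},
    )
    res._round_offsets = np.broadcast_to(delta, (n_rounds, 1)).ravel().copy()
    res._stop = stop
    return res


def selection_bias_sweep(spec: TaskSpec | None = None,
                         sd_grid=None, n_per_level: int = 8,
                         n_rounds: int = 2000, seed=0,
                         opportunity_fraction: float = 0.0) -> pd.DataFrame:
    """Sweep the round-level offset SD and summarize each pseudo-subject.

    ``opportunity_fraction`` moves that share of the total offset variance
    from the across-round to the across-opportunity component.  Returns one
    row per pseudo-subject with its response variability (pooled fitted
    psychometric SD) and threshold change (mean per-opportunity decrease).
    """
    spec = spec or TaskSpec(K=5)
    if sd_grid is None:
        sd_grid = np.linspace(5.0, 40.0, 8)
    rng = np.random.default_rng(seed)
    rows = []
    for sd in sd_grid:
        var_total = float(sd) ** 2
        sd_o = np.sqrt(var_total * opportunity_fraction)
        sd_r = np.sqrt(var_total * (1.0 - opportunity_fraction))
        for k in range(n_per_level):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = simulate_selection_bias(
                spec, sd_round=sd_r, sd_opportunity=sd_o, n_rounds=n_rounds,
                seed=sub_seed, subject_id=f"sd{sd:05.1f}_{k}")
            rows.append({
                "sd_total": float(sd),
                "sd_round": float(sd_r),
                "sd_opportunity": float(sd_o),
                "unit": res.data["subject_id"].iloc[0],
                "response_variability": res.response_variability,
                "threshold_change": res.threshold_change,
            })
    return pd.DataFrame(rows)


def variability_threshold_correlation(summaries: pd.DataFrame) -> tuple:
    """Pearson correlation (r, p) between per-unit response variability and
    threshold change across opportunities."""
    if len(summaries) < 3:
        raise ValueError("need >= 3 units")
    x = summaries["response_variability"].to_numpy(dtype=float)
    y = summaries["threshold_change"].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = pearsonr(x, y)
    return float(r), float(p)
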