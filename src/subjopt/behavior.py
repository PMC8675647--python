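"""Model-free behavioral analyses.

The empirical decision threshold of an opportunity is the mean of a
cumulative-Gaussian psychometric function fitted to that opportunity's
accept/reject choices by maximum likelihood: P(accept | v) = Phi((v -
theta)/s).  The fitted mean is the value at which acceptance is equally
likely, and the SD is the subject's decision variability.  Supporting
analyses: grid-posterior credible intervals for the threshold, RT-vs-
difficulty profiles, split-half stability, and lagged logistic regressions
probing serial dependence on earlier within-round stimuli.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import log_ndtr

__all__ = [
    "PsychometricFit",
    "fit_psychometric",
    "fit_empirical_thresholds",
    "threshold_interval",
    "rt_difficulty_profile",
    "split_half_thresholds",
    "lagged_choice_regression",
]

_THETA_BOX = (-50.0, 200.0)
_S_MIN = 0.5
_STARTS = [(40.0, 15.0), (60.0, 15.0), (80.0, 15.0), (100.0, 15.0), (120.0, 15.0)]


@dataclass
class PsychometricFit:
    opportunity: int
    threshold: float
    variability: float
    loglik: float
    n: int
    clipped: bool = False
    interval: tuple | None = None


class DegenerateFitError(ValueError):
    """Choice data contain a single response category; the psychometric mean
    is unidentified."""


def _nll(x, v, acc):
    theta = x[0]
    s = _S_MIN + np.exp(x[1])
    z = (v - theta) / s
    return -np.sum(np.where(acc, log_ndtr(z), log_ndtr(-z)))


def fit_psychometric(values, accepted, opportunity: int = 0) -> PsychometricFit:
    """Cumulative-Gaussian ML fit via Nelder-Mead with 5 deterministic
    starts (theta0 in {40..120}, s0 = 15); ties break toward the smallest
    threshold.  The threshold is confined to the [-50, 200] fitting box
    (clipped fits are flagged); the variability floor is 0.5."""
    v = np.asarray(values, dtype=float)
    acc = np.asarray(accepted, dtype=bool)
    if len(v) < 10:
        raise ValueError(f"need >= 10 trials, got {len(v)}")
    if acc.all() or (~acc).all():
        raise DegenerateFitError(
            f"opportunity {opportunity}: all choices are "
            f"{'accept' if acc.all() else 'reject'}"
        )
    best = None
    for th0, s0 in _STARTS:
        res = minimize(_nll, np.array([th0, np.log(s0 - _S_MIN)]),
                       args=(v, acc), method="Nelder-Mead",
                       options={"maxiter": 1000, "xatol": 1e-6, "fatol": 1e-9})
        if (best is None or res.fun < best.fun - 1e-9
                or (abs(res.fun - best.fun) <= 1e-9 and res.x[0] < best.x[0])):
            best = res
    theta = float(best.x[0])
    clipped = not (_THETA_BOX[0] <= theta <= _THETA_BOX[1])
    theta = float(np.clip(theta, *_THETA_BOX))
    return PsychometricFit(
        opportunity=opportunity,
        threshold=theta,
        variability=float(_S_MIN + np.exp(best.x[1])),
        loglik=-float(best.fun),
        n=len(v),
        clipped=clipped,
    )


def fit_empirical_thresholds(df: pd.DataFrame, min_trials: int = 10) -> list:
    """Per-opportunity psychometric fits for one subject, opportunities
    1..K-1 (the forced K-th carries no choice information).  Opportunities
    with too few trials or one response category are skipped with a
    warning."""
    K = int(df["K"].iloc[0])
    free = df[~df["forced"].astype(bool)]
    fits = []
    for i in range(1, K):
        g = free[free["opportunity"] == i]
        if len(g) < min_trials:
            warnings.warn(f"opportunity {i}: only {len(g)} trials, skipped")
            continue
        try:
            fits.append(fit_psychometric(g["value"], g["choice"] == "accept", i))
        except DegenerateFitError as e:
            warnings.warn(str(e))
    return fits


def threshold_interval(values, accepted, level: float = 0.95,
                       n_theta: int = 301, n_s: int = 40) -> tuple:
    """Highest-density interval for the psychometric threshold from a
    fine-grid posterior (uniform prior on theta over [0, 150], log-uniform
    on s over [1, 60])."""
    v = np.asarray(values, dtype=float)
    acc = np.asarray(accepted, dtype=bool)
    if acc.all() or (~acc).all():
        raise DegenerateFitError("single-category data: interval undefined")
    thetas = np.linspace(0.0, 150.0, n_theta)
    ss = np.exp(np.linspace(np.log(1.0), np.log(60.0), n_s))
    z = (v[None, None, :] - thetas[:, None, None]) / ss[None, :, None]
    ll = np.where(acc[None, None, :], log_ndtr(z), log_ndtr(-z)).sum(axis=2)
    ll -= ll.max()
    post = np.exp(ll).sum(axis=1)          # marginal over s (log-uniform grid)
    post /= post.sum()
    order = np.argsort(post)[::-1]
    mass = np.cumsum(post[order])
    keep = order[: int(np.searchsorted(mass, level)) + 1]
    return (float(thetas[keep].min()), float(thetas[keep].max()))


def rt_difficulty_profile(df: pd.DataFrame, thresholds: dict,
                          bin_width: float = 10.0, lim: float = 75.0,
                          min_per_bin: int = 5) -> pd.DataFrame:
    """Mean RT per bin of signed distance v - theta[i], bins centered on 0.

    ``thresholds`` maps opportunity -> threshold.  Bins with fewer than
    ``min_per_bin`` trials are reported with NaN mean, never 0.
    """
    if df["rt_ms"].isna().all():
        raise ValueError("dataset has no response times")
    free = df[~df["forced"].astype(bool) & df["rt_ms"].notna()].copy()
    th = free["opportunity"].map(thresholds)
    free = free[th.notna()]
    d = free["value"].to_numpy(dtype=float) - th.dropna().to_numpy(dtype=float)
    edges = np.arange(-lim - bin_width / 2, lim + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2
    idx = np.digitize(d, edges) - 1
    rows = []
    rt = free["rt_ms"].to_numpy(dtype=float)
    for b, c in enumerate(centers):
        sel = idx == b
        n = int(sel.sum())
        rows.append({
            "bin_center": float(c),
            "n": n,
            "mean_rt": float(rt[sel].mean()) if n >= min_per_bin else np.nan,
        })
    return pd.DataFrame(rows)


def split_half_thresholds(df: pd.DataFrame, min_rounds: int = 40) -> dict:
    """Independent psychometric fits on the first and second halves of a
    subject's rounds (odd counts: the first half gets the extra round)."""
    rounds = np.sort(df["round"].unique())
    if len(rounds) < min_rounds:
        raise ValueError(f"need >= {min_rounds} rounds, got {len(rounds)}")
    cut = rounds[(len(rounds) + 1) // 2 - 1]     # last round of the first half
    first = fit_empirical_thresholds(df[df["round"] <= cut])
    second = fit_empirical_thresholds(df[df["round"] > cut])
    f1 = {f.opportunity: f for f in first}
    f2 = {f.opportunity: f for f in second}
    diffs = {i: f2[i].threshold - f1[i].threshold for i in f1 if i in f2}
    return {"first": first, "second": second, "difference": diffs}


def lagged_choice_regression(df: pd.DataFrame) -> dict:
    """Per-opportunity logistic regressions of accept on the current value
    and all preceding within-round values.

    For each opportunity i >= 2 (forced rows excluded) fits
    accept ~ v_i + v_{i-1} + ... + v_1 and returns coefficients and SEs.
    Quasi-separated fits are flagged, not dropped.
    """
    free = df[~df["forced"].astype(bool)]
    K = int(df["K"].iloc[0])
    wide = df.pivot_table(index="round", columns="opportunity", values="value")
    out = {}
    for i in range(2, K + 1):
        g = free[free["opportunity"] == i]
        if len(g) < 20:
            continue
        X = pd.DataFrame({"current": g["value"].to_numpy(dtype=float)})
        for lag in range(1, i):
            X[f"lag{lag}"] = wide.loc[g["round"], i - lag].to_numpy()
        X = sm.add_constant(X)
        y = (g["choice"] == "accept").astype(int).to_numpy()
        flagged = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            except Exception:
                res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=500)
        if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e3):
            flagged = True
        out[i] = {
            "coef": res.params.to_dict(),
            "se": res.bse.to_dict(),
            "n": len(g),
            "separation_flag": bool(flagged),
        }
    return out
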