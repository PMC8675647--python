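"""Choice likelihoods, per-subject fits, model comparison, and the
cross-context threshold prediction.

Choices are probabilistic around the model thresholds: the probability of
accepting stimulus v at opportunity i is Phi((v - theta[i]) / s) with s the
subject's decision variability.  Forced final-opportunity rows carry no
information and never enter the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr
from scipy.stats import chi2

from .task import TaskSpec, ValueParams
from .models import optimal_thresholds, subjective_thresholds, expected_round_payoff
from . import transforms

__all__ = [
    "accept_probability",
    "dataset_loglik",
    "FitResult",
    "fit_subjects_ml",
    "aic",
    "compare_models",
    "likelihood_ratio_test",
    "predict_context_thresholds",
]


def accept_probability(v, theta_i, s):
    """P(accept | stimulus v, threshold theta_i) = Phi((v - theta_i)/s)."""
    if np.any(np.asarray(s) <= 0):
        raise ValueError("decision variability s must be > 0")
    out = ndtr((np.asarray(v, dtype=float) - theta_i) / s)
    return float(out) if out.ndim == 0 else out


def _free_rows(df: pd.DataFrame) -> pd.DataFrame:
    bad = df.index[(~df["forced"].astype(bool)) & (df["opportunity"] == df["K"])]
    if len(bad):
        raise ValueError(
            f"row {bad[0]}: unforced row at opportunity K — corrupt dataset"
        )
    return df[~df["forced"].astype(bool)]


def dataset_loglik(df: pd.DataFrame, model_tag: str, params: dict,
                   task: TaskSpec | None = None) -> float:
    """Sum of Bernoulli log-probabilities of the observed free choices.

    One parameter set is applied to every row; thresholds are built per
    condition K present in the data.  Forced rows are excluded.  Empty data
    gives 0.
    """
    spec = transforms.model_spec(model_tag)
    base = task or TaskSpec()
    free = _free_rows(df)
    if free.empty:
        return 0.0
    s = float(params["s"])
    if s <= 0:
        raise ValueError("decision variability s must be > 0")
    total = 0.0
    for K, g in free.groupby("K"):
        tspec = TaskSpec(K=int(K), v_min=base.v_min, v_max=base.v_max,
                         n_rounds=base.n_rounds)
        theta = np.asarray(spec.build_schedule(params, tspec).theta)
        z = (g["value"].to_numpy(dtype=float) - theta[g["opportunity"].to_numpy() - 1]) / s
        acc = (g["choice"] == "accept").to_numpy()
        total += float(np.sum(np.where(acc, log_ndtr(z), log_ndtr(-z))))
    return total


# ---------------------------------------------------------------------------
# per-subject maximum-likelihood fits (used for AIC/LRT model comparison)

@dataclass
class FitResult:
    """Per-subject fits of one model: native parameters, log-likelihood,
    parameter count k, and AIC = 2k - 2*loglik."""

    model_tag: str
    subjects: list
    params: dict           # subject_id -> dict of native parameters
    loglik: dict           # subject_id -> float
    k: int                 # free parameters per subject
    extras: dict = field(default_factory=dict)

    @property
    def aic(self) -> dict:
        return {s: 2 * self.k - 2 * self.loglik[s] for s in self.subjects}

    @property
    def total_loglik(self) -> float:
        return float(sum(self.loglik.values()))


def _ml_starts(tag: str, df: pd.DataFrame, names: tuple) -> list:
    med = float(np.median(df.loc[~df["forced"].astype(bool), "value"])) if len(df) else 75.0
    starts = []
    if tag in ("subjective", "subjective_cost"):
        for r0 in (75.0, 95.0, 115.0):
            for rho0 in (0.5, 0.8, 1.2):
                d = {"r": r0, "rho": rho0, "s": 12.0}
                if tag == "subjective_cost":
                    d["cost"] = 1.0
                starts.append(d)
    elif tag == "constant":
        starts = [{"c": c0, "s": 15.0} for c0 in (med, 75.0, 100.0)]
    elif tag == "linear":
        starts = [{"a": a0, "b": b0, "s": 15.0} for a0 in (100.0,) for b0 in (-8.0, 0.0)]
    elif tag == "optimal":
        starts = [{"s": s0} for s0 in (8.0, 20.0)]
    elif tag == "independent":
        K = int(df["K"].iloc[0])
        base = {f"theta_{i}": 90.0 for i in range(1, K)}
        starts = [dict(base, s=15.0)]
    return [{n: d[n] for n in names} for d in starts]


def fit_subjects_ml(df: pd.DataFrame, model_tag: str,
                    task: TaskSpec | None = None) -> FitResult:
    """Deterministic multi-start Nelder-Mead ML fit, one subject at a time.

    Optimization runs in the unbounded sampling space of each parameter, so
    native bounds hold by construction.
    """
    subjects = list(df["subject_id"].unique())
    params, loglik = {}, {}
    k = None
    for subj in subjects:
        g = df[df["subject_id"] == subj]
        tspec = TaskSpec(K=int(g["K"].iloc[0])) if task is None else task
        names = transforms.model_spec(model_tag).names_for(tspec)
        k = len(names)

        def nll(x, g=g, names=names, tspec=tspec):
            p = {n: float(transforms.to_native(n, xi)) for n, xi in zip(names, x)}
            if "cost" in p:
                p["cost"] = max(p["cost"], 0.0)
            try:
                return -dataset_loglik(g, model_tag, p, tspec)
            except (ValueError, FloatingPointError):
                return np.inf

        best = None
        for st in _ml_starts(model_tag, g, names):
            x0 = np.array([transforms.to_sampling(n, st[n]) for n in names], dtype=float)
            res = minimize(nll, x0, method="Nelder-Mead",
                           options={"maxiter": 2000, "xatol": 1e-5, "fatol": 1e-7})
            if best is None or res.fun < best.fun:
                best = res
        p = {n: float(transforms.to_native(n, xi)) for n, xi in zip(names, best.x)}
        if "cost" in p:
            p["cost"] = max(p["cost"], 0.0)
        params[subj] = p
        loglik[subj] = -float(best.fun)
    return FitResult(model_tag=model_tag, subjects=subjects, params=params,
                     loglik=loglik, k=k)


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2*loglik."""
    return 2.0 * k - 2.0 * loglik


def compare_models(fit_a: FitResult, fit_b: FitResult, n_boot: int = 10_000,
                   rng=0) -> dict:
    """Per-subject Delta-AIC (A minus B; negative favors A) with a paired
    nonparametric bootstrap 95% CI over subjects."""
    if set(fit_a.subjects) != set(fit_b.subjects):
        raise ValueError("fits cover different subjects")
    subs = fit_a.subjects
    d = np.array([fit_a.aic[s] - fit_b.aic[s] for s in subs])
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, len(d), size=(n_boot, len(d)))
    boots = d[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "delta_aic": dict(zip(subs, d)),
        "mean": float(d.mean()),
        "ci95": (float(lo), float(hi)),
    }


_NESTED = {
    ("optimal", "subjective"), ("optimal", "subjective_cost"),
    ("subjective", "subjective_cost"), ("constant", "subjective"),
    ("constant", "subjective_cost"), ("constant", "linear"),
    ("constant", "independent"), ("linear", "independent"),
}


def likelihood_ratio_test(fit_nested: FitResult, fit_full: FitResult) -> dict:
    """Chi-square LRT on the pooled log-likelihoods of two nested fits."""
    if (fit_nested.model_tag, fit_full.model_tag) not in _NESTED:
        raise ValueError(
            f"{fit_nested.model_tag} is not nested in {fit_full.model_tag}"
        )
    n_sub = len(fit_nested.subjects)
    stat = max(0.0, 2.0 * (fit_full.total_loglik - fit_nested.total_loglik))
    df_ = (fit_full.k - fit_nested.k) * n_sub
    return {"statistic": stat, "df": df_, "p": float(chi2.sf(stat, df_)) if df_ else 1.0}


# ---------------------------------------------------------------------------
# cross-context prediction

def predict_context_thresholds(
    fitted_params: list,
    K_src: int,
    K_tgt: int,
    n_draws: int = 5000,
    cohort_size: int | None = None,
    rng=0,
) -> dict:
    """Predict the mean threshold at the opportunity preceding the last in a
    new context K_tgt from subjective-model fits obtained at K_src.

    Each of ``n_draws`` repeats resamples ``cohort_size`` (r, rho) pairs with
    replacement, shifts every reference point by the difference in optimal
    expected round payoff between the contexts, recomputes subjective
    thresholds at K_tgt, and records the cohort-mean threshold at opportunity
    K_tgt - 1.  Returns the point prediction (mean over draws) and the
    2.5/97.5-percentile interval.
    """
    if K_src < 2 or K_tgt < 2:
        raise ValueError("contexts need at least 2 opportunities")
    rng = np.random.default_rng(rng)
    pool = []
    for p in fitted_params:
        if isinstance(p, ValueParams):
            pool.append((p.r, p.rho, p.cost))
        else:
            pool.append((float(p["r"]), float(p["rho"]), float(p.get("cost", 0.0))))
    pool = np.array(pool)
    if cohort_size is None:
        cohort_size = len(pool)
    shift = expected_round_payoff(
        optimal_thresholds(TaskSpec(K=K_tgt)), TaskSpec(K=K_tgt)
    ) - expected_round_payoff(
        optimal_thresholds(TaskSpec(K=K_src)), TaskSpec(K=K_src)
    )
    clipped = 0
    # thresholds depend only on (r, rho, cost); cache per unique source row
    theta_last = np.empty(len(pool))
    for j, (r, rho, cost) in enumerate(pool):
        r2 = r + shift
        if not (1e-6 < r2 < 150 - 1e-6):
            clipped += 1
            r2 = float(np.clip(r2, 1e-6, 150 - 1e-6))
        p = ValueParams(r=r2, rho=float(np.clip(rho, 1e-6, 2 - 1e-6)),
                        cost=max(cost, 0.0), s=10.0)
        theta_last[j] = subjective_thresholds(TaskSpec(K=K_tgt), p)[K_tgt - 1]
    if clipped:
        import warnings

        warnings.warn(f"{clipped} shifted reference points clipped to (0, 150)")
    idx = rng.integers(0, len(pool), size=(n_draws, cohort_size))
    means = theta_last[idx].mean(axis=1)
    return {
        "prediction": float(means.mean()),
        "ci95": (float(np.percentile(means, 2.5)), float(np.percentile(means, 97.5))),
        "shift": float(shift),
        "draws": means,
    }
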