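"""Hierarchical Bayesian estimation by Metropolis-Hastings.

Subject-level parameters live in an unbounded sampling space (see
`subjopt.transforms`) and are drawn from group Gaussians x_kj ~ N(mu_j,
sigma_j).  Priors: broad uniforms on the group means mu_j; inverse-Gamma
(shape 1, configurable scale beta) on the group SDs sigma_j, which are
sampled on the log scale.  Proposals are componentwise Gaussians whose
scales adapt toward a 0.30 acceptance rate during burn-in only
(Robbins-Monro), so the post-burn-in kernel is fixed and the chain is valid.

The likelihood factorizes over subjects, so subject-level proposals for one
parameter are made for all subjects at once and accepted independently —
the cohort evaluator recomputes every subject's threshold schedule and
choice log-likelihood in a handful of vectorized array operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr
from scipy.stats import gaussian_kde

from .task import TaskSpec
from .models import optimal_thresholds
from . import transforms

__all__ = ["HierarchicalSpec", "PosteriorChain", "fit_hierarchical",
           "map_estimates", "group_posterior"]

_DEFAULT_MU_BOUNDS = {
    "logistic150": (-10.0, 10.0),
    "logistic2": (-10.0, 10.0),
    "log": (float(np.log(0.5)), float(np.log(50.0))),
    "identity": (-50.0, 200.0),
}


@dataclass(frozen=True)
class HierarchicalSpec:
    """Sampler configuration for one model fit."""

    model_tag: str = "subjective"
    n_iter: int = 40_000
    burn_in: int = 10_000
    proposal_scale: float = 0.15
    adapt_interval: int = 50
    target_accept: float = 0.30
    beta: float = 1.0                     # inverse-Gamma scale for group SDs
    mu_bounds: dict = field(default_factory=dict)   # per-param overrides
    floored: bool = True                  # integer-floored subjective thresholds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("n_iter must exceed burn_in")
        if self.proposal_scale <= 0:
            raise ValueError("zero-variance proposals are invalid")


@dataclass
class PosteriorChain:
    """Sampled chain (sampling space) with metadata.

    ``x`` has shape (n_saved, n_subjects, n_params); ``mu`` and ``sigma``
    (n_saved, n_params).  ``burn_in`` marks how many leading samples to drop.
    """

    model_tag: str
    param_names: tuple
    subjects: list
    x: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    burn_in: int
    seed: int
    accept_rates: dict

    def posterior(self):
        """Post-burn-in slices of (x, mu, sigma)."""
        return self.x[self.burn_in:], self.mu[self.burn_in:], self.sigma[self.burn_in:]

    def to_json(self, thin: int = 10) -> str:
        """Serialize the chain (thinned) with its metadata."""
        import json

        return json.dumps({
            "model_tag": self.model_tag,
            "param_names": list(self.param_names),
            "subjects": list(self.subjects),
            "burn_in": self.burn_in // thin,
            "seed": self.seed,
            "thin": thin,
            "x": self.x[::thin].astype(float).tolist(),
            "mu": self.mu[::thin].tolist(),
            "sigma": self.sigma[::thin].tolist(),
            "accept_rates": {k: {p: float(v) for p, v in d.items()}
                             for k, d in self.accept_rates.items()},
        })

    @classmethod
    def from_json(cls, text: str) -> "PosteriorChain":
        import json

        d = json.loads(text)
        return cls(
            model_tag=d["model_tag"],
            param_names=tuple(d["param_names"]),
            subjects=list(d["subjects"]),
            x=np.asarray(d["x"], dtype=np.float32),
            mu=np.asarray(d["mu"]),
            sigma=np.asarray(d["sigma"]),
            burn_in=d["burn_in"],
            seed=d["seed"],
            accept_rates=d.get("accept_rates", {}),
        )


class _CohortEval:
    """Vectorized cohort log-likelihood for one model and common K."""

    def __init__(self, df: pd.DataFrame, model_tag: str, spec: TaskSpec,
                 floored: bool = True):
        self.floored = floored
        Ks = df.groupby("subject_id")["K"].first()
        if Ks.nunique() != 1:
            raise ValueError("hierarchical fitting requires a common K across subjects")
        self.spec = TaskSpec(K=int(Ks.iloc[0]), v_min=spec.v_min, v_max=spec.v_max,
                             n_rounds=spec.n_rounds)
        self.model_tag = model_tag
        self.subjects = list(Ks.index)
        free = df[~df["forced"].astype(bool)]
        for subj, g in free.groupby("subject_id"):
            acc = g["choice"] == "accept"
            if acc.all() or (~acc).all():
                warnings.warn(f"subject {subj}: single-category choices")
        order = {s: i for i, s in enumerate(self.subjects)}
        free = free.assign(_si=free["subject_id"].map(order)).sort_values(
            ["_si", "round", "opportunity"], kind="stable")
        self.v = free["value"].to_numpy(dtype=float)
        self.acc = (free["choice"] == "accept").to_numpy()
        self.opp = free["opportunity"].to_numpy() - 1
        self.si = free["_si"].to_numpy()
        counts = np.bincount(self.si, minlength=len(self.subjects))
        self.offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.n_subj = len(self.subjects)
        self.grid = np.arange(self.spec.v_min, self.spec.v_max + 1, dtype=float)
        self._opt_theta = np.asarray(optimal_thresholds(self.spec).theta)

    def _theta_matrix(self, native: dict) -> np.ndarray:
        n, K = self.n_subj, self.spec.K
        tag = self.model_tag
        if tag == "optimal":
            return np.broadcast_to(self._opt_theta, (n, K))
        if tag == "constant":
            return np.repeat(np.asarray(native["c"], dtype=float)[:, None], K, axis=1)
        if tag == "linear":
            i = np.arange(1, K + 1)
            return np.asarray(native["a"])[:, None] + np.asarray(native["b"])[:, None] * i
        if tag == "independent":
            cols = [np.asarray(native[f"theta_{i}"], dtype=float) for i in range(1, K)]
            cols.append(np.zeros(n))
            return np.stack(cols, axis=1)
        # subjective family: vectorized floor recursion over the value grid
        r = np.asarray(native["r"], dtype=float)
        rho = np.asarray(native["rho"], dtype=float)
        cost = np.asarray(native.get("cost", np.zeros(n)), dtype=float)
        d = self.grid[None, :] - r[:, None]
        u = np.sign(d) * np.abs(d) ** rho[:, None]
        tail = np.concatenate(
            [np.cumsum(u[:, ::-1], axis=1)[:, ::-1][:, 1:], np.zeros((n, 1))], axis=1)
        m = self.grid.size
        rows = np.arange(n)
        theta = np.zeros((n, K))
        th_next = np.zeros(n)
        for i in range(K - 2, -1, -1):
            j = np.floor(th_next).astype(int) - self.spec.v_min
            d_next = th_next - r
            u_next = np.sign(d_next) * np.abs(d_next) ** rho
            eu = ((j + 1) / m) * u_next + tail[rows, j] / m - cost
            th = r + np.sign(eu) * np.abs(eu) ** (1.0 / rho)
            th_next = np.clip(th, self.spec.v_min, self.spec.v_max)
            if self.floored:
                th_next = np.floor(th_next)
            theta[:, i] = th_next
        return theta

    def loglik_single(self, k: int, native_k: dict) -> float:
        """Log-likelihood of subject ``k`` alone (scalar parameters)."""
        spec, tag = self.spec, self.model_tag
        K = spec.K
        if tag in ("subjective", "subjective_cost"):
            r = float(native_k["r"])
            rho = float(native_k["rho"])
            cost = float(native_k.get("cost", 0.0))
            d = self.grid - r
            u = np.sign(d) * np.abs(d) ** rho
            tail = np.concatenate([np.cumsum(u[::-1])[::-1][1:], [0.0]])
            m = self.grid.size
            theta = np.zeros(K)
            th_next = 0.0
            for i in range(K - 2, -1, -1):
                j = int(np.floor(th_next)) - spec.v_min
                dn = th_next - r
                eu = ((j + 1) / m) * (np.sign(dn) * abs(dn) ** rho) \
                    + tail[j] / m - cost
                th = r + np.sign(eu) * abs(eu) ** (1.0 / rho)
                th_next = min(max(th, spec.v_min), spec.v_max)
                if self.floored:
                    th_next = np.floor(th_next)
                theta[i] = th_next
        else:
            # simple models: reuse the vectorized builder with n = 1
            nat = {nm: np.asarray([v], dtype=float)
                   for nm, v in native_k.items()}
            saved = self.n_subj
            self.n_subj = 1
            try:
                theta = self._theta_matrix(nat)[0]
            finally:
                self.n_subj = saved
        lo = self.offsets[k]
        hi = self.offsets[k + 1] if k + 1 < self.n_subj else self.v.size
        s = float(native_k["s"])
        z = (self.v[lo:hi] - theta[self.opp[lo:hi]]) / s
        ll_row = np.where(self.acc[lo:hi], log_ndtr(z), log_ndtr(-z))
        return float(ll_row.sum())

    def loglik(self, native: dict) -> np.ndarray:
        """Per-subject choice log-likelihood for native parameter arrays."""
        theta = self._theta_matrix(native)
        s = np.asarray(native["s"], dtype=float)
        z = (self.v - theta[self.si, self.opp]) / s[self.si]
        ll_row = np.where(self.acc, log_ndtr(z), log_ndtr(-z))
        return np.add.reduceat(ll_row, self.offsets)


def _log_normal_pdf(x, mu, sigma):
    return -0.5 * ((x - mu) / sigma) ** 2 - np.log(sigma)


_INIT_GRIDS = {
    "r": [40.0, 60.0, 75.0, 90.0, 100.0, 110.0, 120.0, 130.0, 140.0],
    "rho": [0.15, 0.3, 0.45, 0.6, 0.75, 0.9, 1.0, 1.1, 1.3, 1.5, 1.7],
    "s": [5.0, 8.0, 12.0, 18.0, 25.0],
    "cost": [0.0, 0.5, 1.0, 2.0, 5.0],
    "c": [50.0, 70.0, 85.0, 100.0, 115.0],
    "a": [80.0, 100.0, 120.0],
    "b": [-15.0, -8.0, -3.0, 0.0],
}


def _grid_init(ev: "_CohortEval", names, rng, max_product: int = 4000) -> np.ndarray:
    """Per-subject best sampling-space start over a deterministic native grid.

    Uses the full Cartesian product of the per-parameter grids when small
    enough (this covers the coupled subjective-family parameters jointly);
    otherwise falls back to two coordinate-ascent sweeps.
    """
    import itertools

    grids = [ _INIT_GRIDS.get(nm, [70.0, 85.0, 100.0, 115.0]) for nm in names ]
    sizes = int(np.prod([len(g) for g in grids]))
    n_sub = ev.n_subj

    def eval_combo(native_vals):
        nat = {nm: np.full(n_sub, v) for nm, v in zip(names, native_vals)}
        return ev.loglik(nat)

    if sizes <= max_product:
        best_ll = np.full(n_sub, -np.inf)
        best = np.zeros((n_sub, len(names)))
        for combo in itertools.product(*grids):
            llc = eval_combo(combo)
            better = llc > best_ll
            if better.any():
                best_ll = np.where(better, llc, best_ll)
                best[better] = combo
    else:
        cur = np.array([g[len(g) // 2] for g in grids])
        best = np.tile(cur, (n_sub, 1))
        best_ll = eval_combo(cur)
        for _ in range(2):
            for j, g in enumerate(grids):
                for v in g:
                    cand = best.copy()
                    cand[:, j] = v
                    nat = {nm: cand[:, jj] for jj, nm in enumerate(names)}
                    llc = ev.loglik(nat)
                    better = llc > best_ll
                    best_ll = np.where(better, llc, best_ll)
                    best[better, j] = v
    x = np.empty_like(best)
    for j, nm in enumerate(names):
        x[:, j] = transforms.to_sampling(nm, best[:, j])
    return x


def _ml_init(ev: "_CohortEval", names, rng) -> np.ndarray:
    """Per-subject multi-start Nelder-Mead ML starts in sampling space.

    The subjective likelihood is bimodal per subject: a mirror basin at
    (low r, rho > 1) — convex gains — can produce schedules close to those
    of (high r, rho < 1), and a coarse grid alone picks the wrong basin for
    a sizable minority of subjects, which then locks the whole hierarchy
    onto the rho ~ 1 compromise.  Refining every canonical start with a
    short simplex search and keeping the best resolves the basin.
    """
    from scipy.optimize import minimize

    x = _grid_init(ev, names, rng)
    n_par = len(names)
    canonical = []
    if "r" in names and "rho" in names:
        base = {"s": 12.0, "cost": 0.5}
        for r0 in (75.0, 95.0, 115.0):
            for rho0 in (0.5, 0.8, 1.2):
                canonical.append({**base, "r": r0, "rho": rho0})

    def nll_subject(k, xv):
        nat = {nm: float(transforms.to_native(nm, xv[j]))
               for j, nm in enumerate(names)}
        try:
            return -ev.loglik_single(k, nat)
        except (ValueError, FloatingPointError, OverflowError):
            return np.inf

    for k in range(ev.n_subj):
        starts = [x[k].copy()]
        for c in canonical:
            starts.append(np.array([transforms.to_sampling(nm, c.get(nm, 90.0))
                                    for nm in names], dtype=float))
        best_val, best_x = np.inf, x[k].copy()
        for st in starts:
            res = minimize(lambda xv: nll_subject(k, xv), st,
                           method="Nelder-Mead",
                           options={"maxiter": 120 * n_par, "xatol": 1e-3,
                                    "fatol": 1e-4})
            if res.fun < best_val:
                best_val, best_x = float(res.fun), res.x
        x[k] = np.clip(best_x, -10.0, 10.0)
    return x + rng.normal(0, 0.02, x.shape)


def fit_hierarchical(df: pd.DataFrame, hspec: HierarchicalSpec,
                     task: TaskSpec | None = None) -> PosteriorChain:
    """Sample the hierarchical posterior of a choice model on cohort data.

    All subjects must share the same K.  Returns the full chain (including
    burn-in, marked); reproducible under a fixed ``hspec.seed``.
    """
    rng = np.random.default_rng(hspec.seed)
    ev = _CohortEval(df, hspec.model_tag, task or TaskSpec(),
                     floored=hspec.floored)
    names = transforms.model_spec(hspec.model_tag).names_for(ev.spec)
    n_par, n_sub = len(names), ev.n_subj
    bounds = []
    for nm in names:
        tkey = transforms.PARAM_TRANSFORM.get(nm, "identity")
        bounds.append(hspec.mu_bounds.get(nm, _DEFAULT_MU_BOUNDS[tkey]))
    bounds = np.array(bounds)

    def natives(xmat):
        return {nm: np.asarray(transforms.to_native(nm, xmat[:, j]))
                for j, nm in enumerate(names)}

    # initial state: per-subject maximum-likelihood starts (grid search plus
    # short simplex refinement).  Starting point matters twice over here: at
    # rho = 1 the subjective model collapses onto the optimal schedule and
    # the likelihood is flat in r (a ridge chains cannot climb out of
    # componentwise), and each subject's likelihood has a mirror basin at
    # (low r, rho > 1) that a coarse search can mistake for the global one.
    x = _ml_init(ev, names, rng)
    ll = ev.loglik(natives(x))
    mu = x.mean(axis=0)
    sigma = np.clip(x.std(axis=0), 0.2, 1.0)

    scale_x = np.full(n_par, hspec.proposal_scale)
    scale_mu = np.full(n_par, hspec.proposal_scale)
    scale_ls = np.full(n_par, hspec.proposal_scale)
    acc_x = np.zeros(n_par)
    acc_mu = np.zeros(n_par)
    acc_ls = np.zeros(n_par)

    # joint subject-level block: proposal covariance adapted during burn-in
    # from the pooled within-subject sample covariance (then frozen), so the
    # chain can traverse the correlated r-rho ridge efficiently
    joint_L = np.eye(n_par)
    joint_scale = hspec.proposal_scale
    acc_joint = 0.0
    snap_sum = np.zeros((n_sub, n_par))
    snap_sq = np.zeros((n_par, n_par))
    snap_n = 0

    chain_x = np.empty((hspec.n_iter, n_sub, n_par), dtype=np.float32)
    chain_mu = np.empty((hspec.n_iter, n_par))
    chain_sig = np.empty((hspec.n_iter, n_par))
    tot_acc_x = np.zeros(n_par)
    tot_acc_mu = np.zeros(n_par)

    for it in range(hspec.n_iter):
        # subject-level blocks, one parameter at a time, all subjects at once
        for j in range(n_par):
            x_prop = x.copy()
            x_prop[:, j] = x[:, j] + scale_x[j] * rng.standard_normal(n_sub)
            ll_prop = ev.loglik(natives(x_prop))
            logr = (ll_prop - ll
                    + _log_normal_pdf(x_prop[:, j], mu[j], sigma[j])
                    - _log_normal_pdf(x[:, j], mu[j], sigma[j]))
            take = np.log(rng.random(n_sub)) < logr
            x[take, j] = x_prop[take, j]
            ll = np.where(take, ll_prop, ll)
            rate = take.mean()
            acc_x[j] += rate
            tot_acc_x[j] += rate

        # joint subject-level block along the adapted covariance
        x_prop = x + joint_scale * (rng.standard_normal((n_sub, n_par)) @ joint_L.T)
        ll_prop = ev.loglik(natives(x_prop))
        logr = ll_prop - ll
        for j in range(n_par):
            logr = logr + (_log_normal_pdf(x_prop[:, j], mu[j], sigma[j])
                           - _log_normal_pdf(x[:, j], mu[j], sigma[j]))
        take = np.log(rng.random(n_sub)) < logr
        x[take] = x_prop[take]
        ll = np.where(take, ll_prop, ll)
        acc_joint += take.mean()

        # group means (uniform prior: reject outside bounds)
        for j in range(n_par):
            mu_p = mu[j] + scale_mu[j] * rng.standard_normal()
            if bounds[j, 0] <= mu_p <= bounds[j, 1]:
                logr = np.sum(_log_normal_pdf(x[:, j], mu_p, sigma[j])
                              - _log_normal_pdf(x[:, j], mu[j], sigma[j]))
                if np.log(rng.random()) < logr:
                    mu[j] = mu_p
                    acc_mu[j] += 1
                    tot_acc_mu[j] += 1

        # group SDs, sampled as log(sigma); prior InvGamma(1, beta) on sigma
        for j in range(n_par):
            ls_p = np.log(sigma[j]) + scale_ls[j] * rng.standard_normal()
            sig_p = np.exp(ls_p)
            logr = (np.sum(_log_normal_pdf(x[:, j], mu[j], sig_p)
                           - _log_normal_pdf(x[:, j], mu[j], sigma[j]))
                    + (-2.0 * np.log(sig_p) - hspec.beta / sig_p)
                    - (-2.0 * np.log(sigma[j]) - hspec.beta / sigma[j])
                    + ls_p - np.log(sigma[j]))  # log-scale Jacobian
            if np.log(rng.random()) < logr:
                sigma[j] = sig_p
                acc_ls[j] += 1

        # Robbins-Monro adaptation toward the target rate, burn-in only
        if it < hspec.burn_in:
            if (it + 1) % 10 == 0:
                snap_sum += x
                dev = x - snap_sum / (snap_n + 1)
                snap_sq += dev.T @ dev / n_sub
                snap_n += 1
            if (it + 1) % hspec.adapt_interval == 0:
                w = hspec.adapt_interval
                scale_x *= np.exp((acc_x / w - hspec.target_accept))
                scale_mu *= np.exp((acc_mu / w - hspec.target_accept))
                scale_ls *= np.exp((acc_ls / w - hspec.target_accept))
                joint_scale *= float(np.exp(acc_joint / w - hspec.target_accept))
                np.clip(scale_x, 1e-3, 10.0, out=scale_x)
                np.clip(scale_mu, 1e-3, 10.0, out=scale_mu)
                np.clip(scale_ls, 1e-3, 10.0, out=scale_ls)
                joint_scale = float(np.clip(joint_scale, 1e-3, 10.0))
                acc_x[:] = acc_mu[:] = acc_ls[:] = 0.0
                acc_joint = 0.0
                if snap_n >= 20:
                    cov = snap_sq / snap_n + 1e-6 * np.eye(n_par)
                    try:
                        joint_L = np.linalg.cholesky(cov)
                    except np.linalg.LinAlgError:
                        pass

        chain_x[it] = x
        chain_mu[it] = mu
        chain_sig[it] = sigma

    return PosteriorChain(
        model_tag=hspec.model_tag,
        param_names=names,
        subjects=ev.subjects,
        x=chain_x,
        mu=chain_mu,
        sigma=chain_sig,
        burn_in=hspec.burn_in,
        seed=hspec.seed,
        accept_rates={
            "subject": dict(zip(names, tot_acc_x / hspec.n_iter)),
            "mu": dict(zip(names, tot_acc_mu / hspec.n_iter)),
        },
    )


def group_posterior(chain: PosteriorChain) -> pd.DataFrame:
    """Back-transformed group-mean summaries, one row per parameter.

    Each posterior draw of mu_j is pushed through the parameter's transform;
    the table reports the mean, SD and central 95% interval of that
    back-transformed group location.
    """
    _, mu, _ = chain.posterior()
    rows = []
    for j, nm in enumerate(chain.param_names):
        g = np.asarray(transforms.to_native(nm, mu[:, j]))
        rows.append({
            "param": nm,
            "mean": float(g.mean()),
            "sd": float(g.std(ddof=1)),
            "q2.5": float(np.percentile(g, 2.5)),
            "q97.5": float(np.percentile(g, 97.5)),
        })
    return pd.DataFrame(rows).set_index("param")


def map_estimates(chain: PosteriorChain, max_kde_samples: int = 1500) -> dict:
    """Kernel-density MAP per subject: the post-burn-in sample maximizing a
    multivariate Gaussian KDE over that subject's samples (back-transformed).

    Long chains are thinned evenly to ``max_kde_samples`` before density
    evaluation.
    """
    xs, _, _ = chain.posterior()
    if xs.shape[0] == 0:
        raise ValueError("empty post-burn-in chain")
    step = max(1, xs.shape[0] // max_kde_samples)
    xs = xs[::step]
    out = {}
    for k, subj in enumerate(chain.subjects):
        samp = xs[:, k, :].T.astype(float)          # (n_par, n_samples)
        spread = samp.std(axis=1)
        if np.all(spread < 1e-12) or samp.shape[1] < 5:
            best = samp[:, 0]
        else:
            keep = spread > 1e-12                    # drop degenerate dims
            try:
                kde = gaussian_kde(samp[keep])
                best = samp[:, int(np.argmax(kde(samp[keep])))]
            except np.linalg.LinAlgError:
                best = samp[:, 0]
        out[subj] = {nm: float(transforms.to_native(nm, best[j]))
                     for j, nm in enumerate(chain.param_names)}
    return out
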