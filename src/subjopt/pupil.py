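"""Pupillometry pipeline: preprocessing, epoching, and the statistics that
link pupil dilation to choice, decision difficulty, and value sensitivity.

Preprocessing order is fixed: linear interpolation of blink intervals
(padded by 150 ms on each side; saccade intervals unpadded), averaging of
the two eyes, zero-phase third-order Butterworth band-pass 0.02-4 Hz,
least-squares removal of the slow (~5 s) blink response via a spline-basis
deconvolution, and per-session z-scoring.  Sessions with more than 50%
interpolated samples are excluded.  Epochs run -200..+1500 ms around
stimulus onset, baseline-corrected by the mean over onset +/- 20 ms.

Multiple comparisons over time (or difficulty bins) are controlled by a
cluster-based sign-flip permutation test on the maximum cluster mass (sum
of pointwise t-values within a contiguous significant run).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.stats import t as t_dist, pearsonr

__all__ = [
    "PupilSession",
    "PreprocResult",
    "EpochSet",
    "ClusterResult",
    "preprocess_pupil",
    "epoch_pupil",
    "cluster_permutation_test",
    "peak_difficulty_regression",
    "sensitivity_pupil_profile",
    "local_regression",
    "read_pupil",
    "write_pupil",
]


@dataclass
class PupilSession:
    """A raw annotated recording: two-eye diameter series at ``fs`` Hz,
    blink/saccade intervals (ms), and event markers."""

    fs: int
    time_ms: np.ndarray
    left: np.ndarray
    right: np.ndarray
    blinks: list
    saccades: list
    events: pd.DataFrame                  # time_ms, event, event_id
    trial_meta: pd.DataFrame | None = None

    def __post_init__(self):
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time must be strictly increasing")
        span = (self.time_ms[0], self.time_ms[-1])
        if ((self.events["time_ms"] < span[0]) | (self.events["time_ms"] > span[1])).any():
            raise ValueError("events outside the recording span")


@dataclass
class PreprocResult:
    fs: int
    time_ms: np.ndarray
    pupil: np.ndarray                     # cleaned, z-scored series
    interp_mask: np.ndarray               # True where interpolated
    excluded: bool
    interp_fraction: float


@dataclass
class EpochSet:
    """Baseline-corrected epochs around stimulus onsets.

    ``data`` is (n_epochs, n_times); ``times_ms`` spans -200..1500 ms (851
    samples at 500 Hz).  Excluded epochs (edge-truncated or > 50%
    interpolated) are flagged, not deleted.
    """

    data: np.ndarray
    times_ms: np.ndarray
    meta: pd.DataFrame                    # per-epoch metadata incl. excluded
    fs: int

    @property
    def included(self) -> np.ndarray:
        return ~self.meta["excluded"].to_numpy(dtype=bool)


@dataclass
class ClusterResult:
    clusters: list = field(default_factory=list)  # dicts: start, stop, mass, p
    n_perm: int = 0
    seed: int | None = None
    pointwise_t: np.ndarray | None = None

    @property
    def significant(self):
        return [c for c in self.clusters if c["p"] < 0.05]


def _interp_intervals(series: np.ndarray, time_ms: np.ndarray,
                      intervals, pad_ms: float) -> np.ndarray:
    mask = np.zeros(series.size, dtype=bool)
    for (t0, t1) in intervals:
        mask |= (time_ms >= t0 - pad_ms) & (time_ms <= t1 + pad_ms)
    if mask.any():
        good = ~mask
        series = series.copy()
        series[mask] = np.interp(time_ms[mask], time_ms[good], series[good])
    return series, mask


def _blink_basis(n: int, blink_onsets_idx, fs: int, n_basis: int = 8,
                 span_s: float = 5.0) -> np.ndarray:
    """Design matrix of overlapping triangular (linear B-spline) bumps over
    the ~5 s window after each blink onset."""
    width = span_s / (n_basis + 1) * 2.0
    centers = np.linspace(0, span_s - width / 2, n_basis)
    kern_len = int(span_s * fs)
    t = np.arange(kern_len) / fs
    basis = np.maximum(0.0, 1.0 - np.abs(t[None, :] - centers[:, None]) / (width / 2))
    X = np.zeros((n, n_basis))
    for i0 in blink_onsets_idx:
        i1 = min(i0 + kern_len, n)
        X[i0:i1] += basis[:, : i1 - i0].T
    return X


def preprocess_pupil(session: PupilSession, exclude_frac: float = 0.5,
                     pad_ms: float = 150.0) -> PreprocResult:
    """Run the full preprocessing chain on one session.

    Returns the cleaned z-scored trace with its interpolation mask and an
    exclusion verdict (interpolated fraction > ``exclude_frac``).
    """
    if session.fs != 500:
        raise ValueError("expected a 500 Hz recording; resample upstream")
    t = session.time_ms
    left, m1 = _interp_intervals(session.left, t, session.blinks, pad_ms)
    right, m2 = _interp_intervals(session.right, t, session.blinks, pad_ms)
    left, m3 = _interp_intervals(left, t, session.saccades, 0.0)
    right, m4 = _interp_intervals(right, t, session.saccades, 0.0)
    mask = m1 | m2 | m3 | m4
    pupil = 0.5 * (left + right)

    nyq = session.fs / 2.0
    b, a = butter(3, [0.02 / nyq, 4.0 / nyq], btype="bandpass")
    pupil = filtfilt(b, a, pupil)

    if session.blinks:
        onsets = np.searchsorted(t, [b0 for (b0, _) in session.blinks])
        X = _blink_basis(pupil.size, onsets, session.fs)
        coef, *_ = np.linalg.lstsq(X, pupil, rcond=None)
        pupil = pupil - X @ coef

    sd = pupil.std()
    pupil = (pupil - pupil.mean()) / (sd if sd > 0 else 1.0)
    frac = float(mask.mean())
    return PreprocResult(fs=session.fs, time_ms=t, pupil=pupil,
                         interp_mask=mask, excluded=frac > exclude_frac,
                         interp_fraction=frac)


def epoch_pupil(clean: PreprocResult, events: pd.DataFrame,
                trial_meta: pd.DataFrame | None = None,
                window_ms=(-200.0, 1500.0), baseline_ms: float = 20.0,
                exclude_frac: float = 0.5) -> EpochSet:
    """Cut baseline-corrected epochs around stimulus-onset events.

    Epochs needing > 50% interpolated samples, or truncated by the recording
    edge, are flagged excluded.  At 500 Hz the -200..1500 ms window holds
    851 samples.
    """
    stim = events[events["event"] == "stimulus"].reset_index(drop=True)
    n_pre = int(round(-window_ms[0] * clean.fs / 1000.0))
    n_post = int(round(window_ms[1] * clean.fs / 1000.0))
    n_len = n_pre + n_post + 1
    times = (np.arange(n_len) - n_pre) * (1000.0 / clean.fs)
    n_base = int(round(baseline_ms * clean.fs / 1000.0))

    data = np.full((len(stim), n_len), np.nan)
    meta_rows = []
    for e, row in stim.iterrows():
        i_on = int(np.searchsorted(clean.time_ms, row["time_ms"]))
        i0, i1 = i_on - n_pre, i_on + n_post + 1
        if i0 < 0 or i1 > clean.pupil.size:
            meta_rows.append({"event_id": row["event_id"], "excluded": True,
                              "interp_fraction": np.nan, "edge": True})
            continue
        seg = clean.pupil[i0:i1]
        base = clean.pupil[i_on - n_base: i_on + n_base + 1].mean()
        data[e] = seg - base
        frac = float(clean.interp_mask[i0:i1].mean())
        meta_rows.append({"event_id": row["event_id"],
                          "excluded": frac > exclude_frac,
                          "interp_fraction": frac, "edge": False})
    meta = pd.DataFrame(meta_rows)
    if trial_meta is not None:
        meta = meta.merge(trial_meta, on="event_id", how="left")
    return EpochSet(data=data, times_ms=times, meta=meta, fs=clean.fs)


def _cluster_masses(tvals: np.ndarray, crit: float):
    sig = np.abs(tvals) > crit
    clusters = []
    i = 0
    n = sig.size
    while i < n:
        if sig[i]:
            j = i
            while j + 1 < n and sig[j + 1]:
                j += 1
            clusters.append((i, j, float(tvals[i:j + 1].sum())))
            i = j + 1
        else:
            i += 1
    return clusters


def cluster_permutation_test(diff_curves: np.ndarray, alpha: float = 0.05,
                             n_perm: int = 10_000, seed=0,
                             times_ms: np.ndarray | None = None) -> ClusterResult:
    """Cluster-based sign-flip permutation test on paired difference curves.

    ``diff_curves`` is (n_subjects, n_times) of per-subject condition
    differences.  Pointwise one-sample t-tests at two-sided ``alpha`` define
    clusters as maximal contiguous significant runs; the cluster statistic
    is the sum of t-values, compared against the permutation null of the
    maximum |cluster mass| under random per-subject sign flips.
    """
    D = np.asarray(diff_curves, dtype=float)
    n_sub, n_time = D.shape
    if n_sub < 5:
        raise ValueError("need >= 5 subjects")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-values are coarse")
    sd = D.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise ValueError("constant difference curves: no pointwise tests possible")
    rng = np.random.default_rng(seed)
    crit = float(t_dist.ppf(1 - alpha / 2, n_sub - 1))

    def tvals(M):
        s = M.std(axis=0, ddof=1)
        s = np.where(s == 0, np.inf, s)
        return M.mean(axis=0) / (s / np.sqrt(n_sub))

    t_obs = tvals(D)
    clusters = _cluster_masses(t_obs, crit)

    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_sub)[:, None]
        t_p = tvals(D * signs)
        cl = _cluster_masses(t_p, crit)
        null_max[p] = max((abs(m) for (_, _, m) in cl), default=0.0)

    out = []
    for (i, j, mass) in clusters:
        p_corr = float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm))
        c = {"start": i, "stop": j, "mass": mass, "p": p_corr}
        if times_ms is not None:
            c["start_ms"] = float(times_ms[i])
            c["stop_ms"] = float(times_ms[j])
        out.append(c)
    return ClusterResult(clusters=out, n_perm=n_perm, seed=seed,
                         pointwise_t=t_obs)


def _peak_table(epochs: EpochSet, thresholds: dict) -> pd.DataFrame:
    """Per-epoch peak dilation over (0, 1500] ms plus signed difficulty."""
    sel = epochs.included
    post = epochs.times_ms > 0
    meta = epochs.meta.loc[sel].copy()
    meta["peak"] = epochs.data[sel][:, post].max(axis=1)
    meta["at1500"] = epochs.data[sel][:, -1]
    th = meta["opportunity"].map(thresholds)
    meta["signed_difficulty"] = meta["value"] - th
    return meta.dropna(subset=["signed_difficulty"])


def peak_difficulty_regression(epoch_sets: dict, thresholds: dict,
                               min_epochs: int = 5,
                               use_peak: bool = True) -> dict:
    """Per-subject regression of peak dilation on signed difficulty within
    the reject (-40 < v - theta < 5) and accept (-5 < v - theta < 40)
    windows, and a one-sample group t-test on the slopes.

    ``epoch_sets`` maps subject -> EpochSet (metadata must carry value,
    choice, opportunity); ``thresholds`` maps opportunity -> threshold (a
    per-subject dict of dicts is also accepted).
    """
    rows = []
    col = "peak" if use_peak else "at1500"
    for subj, ep in epoch_sets.items():
        th = thresholds[subj] if subj in thresholds else thresholds
        tab = _peak_table(ep, th)
        for cond, lo, hi in (("reject", -40.0, 5.0), ("accept", -5.0, 40.0)):
            g = tab[(tab["choice"] == cond)
                    & (tab["signed_difficulty"] > lo)
                    & (tab["signed_difficulty"] < hi)]
            if len(g) < min_epochs:
                warnings.warn(f"{subj}/{cond}: {len(g)} epochs, dropped")
                continue
            # slope on |difficulty| within the signed window
            x = np.abs(g["signed_difficulty"].to_numpy(dtype=float))
            y = g[col].to_numpy(dtype=float)
            slope = float(np.polyfit(x, y, 1)[0])
            rows.append({"subject": subj, "condition": cond, "slope": slope,
                         "n": len(g)})
    tab = pd.DataFrame(rows)
    slopes = tab.groupby("subject")["slope"].mean().to_numpy()
    if slopes.size >= 2:
        tstat = slopes.mean() / (slopes.std(ddof=1) / np.sqrt(slopes.size))
        p = float(2 * t_dist.sf(abs(tstat), slopes.size - 1))
    else:
        tstat, p = np.nan, np.nan
    return {"per_subject": tab, "group_slope": float(slopes.mean()),
            "t": float(tstat), "p": p, "n_subjects": int(slopes.size)}


def local_regression(x, y, grid, bandwidth: float = 30.0) -> np.ndarray:
    """Local quadratic regression with tricube weights (loess-style)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = np.full(len(grid), np.nan)
    for k, g in enumerate(grid):
        w = np.clip(1 - (np.abs(x - g) / bandwidth) ** 3, 0, None) ** 3
        sel = w > 0
        if sel.sum() < 4:
            continue
        X = np.stack([np.ones(sel.sum()), x[sel] - g, (x[sel] - g) ** 2], axis=1)
        W = w[sel]
        try:
            beta = np.linalg.solve((X.T * W) @ X, (X.T * W) @ y[sel])
        except np.linalg.LinAlgError:
            continue
        out[k] = beta[0]
    return out


def sensitivity_pupil_profile(epoch_sets: dict, thresholds: dict,
                              sensitivities: dict,
                              grid=None, bandwidth: float = 30.0,
                              alpha: float = 0.05, n_perm: int = 2000,
                              seed=0) -> dict:
    """Correlate value sensitivity with the pupil-difficulty profile.

    Each subject's peak dilations are smoothed over signed difficulty
    (default grid -90..60) by local quadratic regression; per-bin Pearson
    correlations between the smoothed dilation and the subjects' fitted
    value sensitivities are cluster-corrected by permuting the sensitivity
    labels.  Also returns median-split group curves.
    """
    subjects = sorted(epoch_sets)
    if len(subjects) < 8:
        raise ValueError("need >= 8 subjects for the correlation analysis")
    if grid is None:
        grid = np.arange(-90.0, 61.0, 2.0)
    grid = np.asarray(grid, dtype=float)
    curves = np.full((len(subjects), grid.size), np.nan)
    rho = np.array([float(sensitivities[s]) for s in subjects])
    for k, subj in enumerate(subjects):
        th = thresholds[subj] if subj in thresholds else thresholds
        tab = _peak_table(epoch_sets[subj], th)
        curves[k] = local_regression(tab["signed_difficulty"], tab["peak"],
                                     grid, bandwidth)
    valid = ~np.any(np.isnan(curves), axis=0)
    n = len(subjects)
    crit_r = _r_crit(alpha, n)

    def bin_corrs(r_labels):
        c = np.full(grid.size, np.nan)
        xm = r_labels - r_labels.mean()
        for b in np.where(valid)[0]:
            ym = curves[:, b] - curves[:, b].mean()
            denom = np.sqrt((xm ** 2).sum() * (ym ** 2).sum())
            c[b] = (xm * ym).sum() / denom if denom > 0 else 0.0
        return c

    r_obs = bin_corrs(rho)
    t_obs = _r_to_t(np.nan_to_num(r_obs), n)
    clusters = _cluster_masses(np.where(valid, t_obs, 0.0), _r_to_t(crit_r, n) - 1e-9)

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        r_p = bin_corrs(rng.permutation(rho))
        t_p = _r_to_t(np.nan_to_num(r_p), n)
        cl = _cluster_masses(np.where(valid, t_p, 0.0), _r_to_t(crit_r, n) - 1e-9)
        null_max[p] = max((abs(m) for (_, _, m) in cl), default=0.0)
    out_clusters = []
    for (i, j, mass) in clusters:
        p_corr = float((1 + np.sum(null_max >= abs(mass))) / (1 + n_perm))
        out_clusters.append({"start": i, "stop": j, "mass": mass, "p": p_corr,
                             "lo": float(grid[i]), "hi": float(grid[j])})

    med = np.median(rho)
    hi_grp = curves[rho > med].mean(axis=0) if np.any(rho > med) else None
    lo_grp = curves[rho <= med].mean(axis=0)
    return {
        "grid": grid,
        "curves": curves,
        "bin_correlation": r_obs,
        "clusters": ClusterResult(clusters=out_clusters, n_perm=n_perm, seed=seed,
                                  pointwise_t=t_obs),
        "high_group": hi_grp,
        "low_group": lo_grp,
        "median": float(med),
    }


def _r_to_t(r, n):
    r = np.clip(r, -0.999999, 0.999999)
    return r * np.sqrt((n - 2) / (1 - r ** 2))


def _r_crit(alpha, n):
    tc = t_dist.ppf(1 - alpha / 2, n - 2)
    return float(tc / np.sqrt(n - 2 + tc ** 2))


# ---------------------------------------------------------------------------
# plain-text session IO

def write_pupil(session: PupilSession, path) -> None:
    """Write a session as TSV: time_ms, pupil_left, pupil_right, blink_flag,
    event, event_id."""
    blink_flag = np.zeros(session.time_ms.size, dtype=int)
    for (b0, b1) in session.blinks:
        blink_flag |= ((session.time_ms >= b0) & (session.time_ms <= b1)).astype(int)
    ev_col = np.array([""] * session.time_ms.size, dtype=object)
    id_col = np.full(session.time_ms.size, -1)
    idx = np.searchsorted(session.time_ms, session.events["time_ms"].to_numpy())
    idx = np.clip(idx, 0, session.time_ms.size - 1)
    ev_col[idx] = session.events["event"].to_numpy()
    id_col[idx] = session.events["event_id"].to_numpy()
    pd.DataFrame({
        "time_ms": session.time_ms,
        "pupil_left": session.left,
        "pupil_right": session.right,
        "blink_flag": blink_flag,
        "event": ev_col,
        "event_id": id_col,
    }).to_csv(path, sep="\t", index=False)


def read_pupil(path, fs: int = 500) -> PupilSession:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"event": str})
    t = df["time_ms"].to_numpy(dtype=float)
    flag = df["blink_flag"].to_numpy(dtype=int)
    blinks = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], flag, [0]])))
    for i0, i1 in zip(edges[::2], edges[1::2]):
        blinks.append((float(t[i0]), float(t[min(i1, t.size) - 1])))
    ev = df[df["event"] != ""]
    events = pd.DataFrame({
        "time_ms": ev["time_ms"].to_numpy(dtype=float),
        "event": ev["event"].to_numpy(),
        "event_id": ev["event_id"].to_numpy(dtype=int),
    })
    return PupilSession(fs=fs, time_ms=t,
                        left=df["pupil_left"].to_numpy(dtype=float),
                        right=df["pupil_right"].to_numpy(dtype=float),
                        blinks=blinks, saccades=[], events=events)
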