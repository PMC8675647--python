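"""Synthetic cohorts: task rounds, model-following agents, RTs, pupil traces.

Everything downstream of data collection is exercised on data from this
module: stimuli are i.i.d. uniform integers on {0..150}, agents follow one of
the candidate threshold models with Gaussian decision noise, rounds force
acceptance at the last opportunity, and (optionally) response times and a
500 Hz pupil trace with blink artifacts and choice/difficulty-coupled
dilations are attached.  All draws flow from an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .task import TaskSpec, ValueParams
from . import transforms
from .io import CHOICE_COLUMNS, validate_choices

__all__ = [
    "EffectSpec",
    "sample_population",
    "simulate_agent_dataset",
    "simulate_cohort",
    "generate_pupil_session",
]

DEFAULT_RT_SPEC = {"base": 900.0, "slope": 4.0, "noise_scale": 120.0, "noise_shape": 0.45}


@dataclass(frozen=True)
class EffectSpec:
    """Effect structure injected into synthetic pupil sessions.

    All amplitudes are in z-units of the final normalized trace.  The
    dilation evoked by a stimulus is
    ``base_amp + accept_amp*[accepted] - difficulty_slope*|v - theta[i]|
    + coupling*rho``.
    """

    accept_amp: float = 0.0          # extra dilation before acceptance
    difficulty_slope: float = 0.0    # z-units per unit |v - theta|
    coupling: float = 0.0            # amplitude gain per unit value sensitivity
    blink_rate: float = 10.0         # blinks per minute
    noise_sd: float = 0.3            # measurement noise SD
    base_amp: float = 0.6

    def __post_init__(self) -> None:
        if self.blink_rate < 0:
            raise ValueError("blink rate must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be > 0")


def sample_population(group_means: dict, group_sds: dict, n_subjects: int, rng) -> list:
    """Draw subject-level `ValueParams` from group Gaussians.

    ``group_means`` / ``group_sds`` are keyed by parameter name (r, rho,
    cost, s) and live in the *sampling* (transformed) space; draws are
    back-transformed, so every subject satisfies the native bounds by
    construction.  Parameters absent from ``group_means`` take the
    `ValueParams` defaults.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(rng)
    draws = {}
    for name, mu in group_means.items():
        sd = group_sds.get(name, 0.0)
        x = rng.normal(mu, sd, size=n_subjects)
        draws[name] = np.asarray(transforms.to_native(name, x))
    out = []
    for k in range(n_subjects):
        kw = {name: float(vals[k]) for name, vals in draws.items()}
        if "cost" in kw:
            kw["cost"] = max(kw["cost"], 0.0)
        out.append(ValueParams(**kw))
    return out


def _threshold_vector(model_tag: str, params: dict, spec: TaskSpec,
                      floored: bool = True) -> np.ndarray:
    if model_tag in ("subjective", "subjective_cost") and not floored:
        from .models import subjective_thresholds

        p = ValueParams(r=params["r"], rho=params["rho"],
                        cost=max(float(params.get("cost", 0.0)), 0.0)
                        if model_tag == "subjective_cost" else 0.0,
                        s=float(params.get("s", 10.0)))
        sched = subjective_thresholds(spec, p, floored=False)
    else:
        sched = transforms.model_spec(model_tag).build_schedule(params, spec)
    return np.asarray(sched.theta, dtype=float)


def simulate_agent_dataset(
    params,
    model_tag: str,
    spec: TaskSpec,
    rng,
    subject_id: str = "s01",
    rt_spec: dict | None = None,
    validate: bool = True,
    floored: bool = True,
) -> pd.DataFrame:
    """Simulate one subject's full session as a tidy choice DataFrame.

    ``params`` is a `ValueParams` (for the optimal/subjective family) or a
    dict of the model's native parameters including the decision variability
    ``s``.  At opportunities i < K the agent accepts with probability
    Phi((v - theta[i]) / s); the K-th opportunity is forced.  If ``rt_spec``
    is given, RTs are base - slope*|v - theta[i]| plus lognormal noise.
    """
    rng = np.random.default_rng(rng)
    if isinstance(params, ValueParams):
        pdict = {"r": params.r, "rho": params.rho, "cost": params.cost, "s": params.s}
    else:
        pdict = dict(params)
    s = float(pdict["s"])
    if s <= 0:
        raise ValueError("decision variability s must be > 0")
    theta = _threshold_vector(model_tag, pdict, spec, floored=floored)

    n, K = spec.n_rounds, spec.K
    vals = rng.integers(spec.v_min, spec.v_max + 1, size=(n, K))
    if K > 1:
        p_acc = ndtr((vals[:, : K - 1] - theta[: K - 1]) / s)
        acc = rng.random((n, K - 1)) < p_acc
        stop = np.where(acc.any(axis=1), acc.argmax(axis=1), K - 1)  # 0-based
    else:
        stop = np.zeros(n, dtype=int)
    lengths = stop + 1
    offsets = np.cumsum(lengths) - lengths
    total = int(lengths.sum())
    round_col = np.repeat(np.arange(1, n + 1), lengths)
    opp_col = np.arange(total) - np.repeat(offsets, lengths) + 1
    value_col = vals[round_col - 1, opp_col - 1]
    accept_col = opp_col == np.repeat(lengths, lengths)
    forced_col = opp_col == K

    df = pd.DataFrame(
        {
            "subject_id": subject_id,
            "K": K,
            "round": round_col,
            "opportunity": opp_col,
            "value": value_col,
            "choice": np.where(accept_col, "accept", "reject"),
            "rt_ms": np.nan,
            "forced": forced_col,
        },
        columns=CHOICE_COLUMNS,
    )
    if rt_spec is not None:
        rt = dict(DEFAULT_RT_SPEC, **rt_spec)
        theta_row = theta[np.minimum(opp_col, K) - 1]
        diff = np.abs(value_col - theta_row)
        noise = rng.lognormal(np.log(rt["noise_scale"]), rt["noise_shape"], size=total)
        df["rt_ms"] = np.maximum(rt["base"] - rt["slope"] * diff + noise, 150.0)
    if validate:
        validate_choices(df, spec.v_min, spec.v_max)
    return df


def simulate_cohort(
    params_list,
    model_tag: str,
    spec: TaskSpec,
    rng,
    rt_spec: dict | None = None,
    floored: bool = True,
) -> pd.DataFrame:
    """Simulate one dataset per parameter set and concatenate."""
    rng = np.random.default_rng(rng)
    frames = []
    for k, p in enumerate(params_list, start=1):
        frames.append(
            simulate_agent_dataset(
                p, model_tag, spec, rng, subject_id=f"s{k:02d}", rt_spec=rt_spec,
                validate=False, floored=floored,
            )
        )
    df = pd.concat(frames, ignore_index=True)
    return validate_choices(df, spec.v_min, spec.v_max)


# ---------------------------------------------------------------------------
# pupil sessions

def _pupil_kernel(fs: int) -> np.ndarray:
    """Canonical pupillary impulse response: gamma-shaped, peak ~930 ms."""
    t = np.arange(0, 3.0, 1.0 / fs)
    n, t_max = 10.1, 0.930
    h = t ** n * np.exp(-n * t / t_max)
    return h / h.max()


def generate_pupil_session(
    data: pd.DataFrame,
    effects: EffectSpec,
    rng,
    schedule=None,
    rho: float = 1.0,
    fs: int = 500,
):
    """Synthesize a 500 Hz pupil session time-locked to one subject's choices.

    Each row of ``data`` becomes a stimulus onset followed by an audio cue
    uniform on [1.5, 2.5] s after onset.  The trace is slow drift plus
    smoothed noise plus a gamma-shaped dilation at every onset whose
    amplitude follows ``effects`` (choice, difficulty, and value-sensitivity
    coupling); blinks occur at the requested rate with 100-400 ms gaps and
    are annotated as intervals.  Returns a `subjopt.pupil.PupilSession`.
    """
    from .pupil import PupilSession  # local import to avoid a cycle

    rng = np.random.default_rng(rng)
    data = data.reset_index(drop=True)
    n_trials = len(data)
    K = int(data["K"].iloc[0])
    if schedule is None:
        from .models import optimal_thresholds

        schedule = optimal_thresholds(TaskSpec(K=K))
    theta = np.asarray(schedule.theta, dtype=float)

    cue_delay = rng.uniform(1.5, 2.5, size=n_trials)
    spacing = cue_delay + rng.uniform(1.6, 2.4, size=n_trials)  # response + ITI
    onsets = np.concatenate([[1.0], 1.0 + np.cumsum(spacing[:-1])])
    duration = onsets[-1] + 4.0
    n_samp = int(round(duration * fs))
    t_ms = np.arange(n_samp) * (1000.0 / fs)

    tt = np.arange(n_samp) / fs
    drift = 0.5 * np.sin(2 * np.pi * 0.012 * tt + rng.uniform(0, 2 * np.pi))
    drift += 0.3 * np.sin(2 * np.pi * 0.031 * tt + rng.uniform(0, 2 * np.pi))
    box = np.ones(int(0.05 * fs)) / int(0.05 * fs)
    noise = np.convolve(rng.normal(0, effects.noise_sd, n_samp), box, mode="same")

    kernel = _pupil_kernel(fs)
    signal = drift + noise
    opp = data["opportunity"].to_numpy()
    diff = np.abs(data["value"].to_numpy() - theta[np.minimum(opp, K) - 1])
    accepted = (data["choice"] == "accept").to_numpy()
    amps = (
        effects.base_amp
        + effects.accept_amp * accepted
        - effects.difficulty_slope * diff
        + effects.coupling * rho
    )
    for onset, amp in zip(onsets, amps):
        i0 = int(round(onset * fs))
        i1 = min(i0 + kernel.size, n_samp)
        signal[i0:i1] += amp * kernel[: i1 - i0]

    # blinks: Poisson count over the session, 100-400 ms dropouts
    n_blinks = rng.poisson(effects.blink_rate * duration / 60.0)
    blink_iv = []
    left = signal + rng.normal(0, 0.02, n_samp)
    right = signal + rng.normal(0, 0.02, n_samp)
    for _ in range(n_blinks):
        b0 = rng.uniform(0, duration - 0.5)
        b1 = b0 + rng.uniform(0.1, 0.4)
        i0, i1 = int(b0 * fs), int(b1 * fs)
        left[i0:i1] = -4.0
        right[i0:i1] = -4.0
        blink_iv.append((b0 * 1000.0, b1 * 1000.0))
    blink_iv.sort()

    events = pd.DataFrame(
        {
            "time_ms": np.concatenate([onsets * 1000.0, (onsets + cue_delay) * 1000.0]),
            "event": ["stimulus"] * n_trials + ["cue"] * n_trials,
            "event_id": np.concatenate([np.arange(n_trials)] * 2),
        }
    ).sort_values("time_ms", ignore_index=True)
    meta = data[["subject_id", "round", "opportunity", "value", "choice"]].copy()
    meta["event_id"] = np.arange(n_trials)

    return PupilSession(
        fs=fs,
        time_ms=t_ms,
        left=left,
        right=right,
        blinks=blink_iv,
        saccades=[],
        events=events,
        trial_meta=meta,
    )
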