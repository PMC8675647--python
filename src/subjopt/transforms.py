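"""Sampling-space transforms and the model registry used by the fitters.

Hierarchical estimation samples every parameter on an unbounded scale and
maps into its native range before touching the model: a scaled logistic
g(x) = A / (1 + exp(-x)) with A = 150 for the reference point and A = 2 for
the value-sensitivity exponent, exp() for the decision variability (and for
group-level SDs), and the identity for the waiting cost and the descriptive
models' threshold parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .task import TaskSpec, ValueParams, LinearParams, ThresholdSchedule
from . import models

__all__ = ["TRANSFORMS", "MODELS", "model_spec", "to_native", "to_sampling"]


@dataclass(frozen=True)
class Transform:
    name: str
    forward: Callable  # sampling space -> native
    inverse: Callable  # native -> sampling space


def _logistic(A):
    def fwd(x):
        return A / (1.0 + np.exp(-np.asarray(x, dtype=float)))

    def inv(y):
        y = np.asarray(y, dtype=float)
        return np.log(y / (A - y))

    return fwd, inv


_log150 = _logistic(150.0)
_log2 = _logistic(2.0)

TRANSFORMS = {
    "logistic150": Transform("logistic150", *_log150),
    "logistic2": Transform("logistic2", *_log2),
    "log": Transform("log", lambda x: np.exp(np.asarray(x, dtype=float)), np.log),
    "identity": Transform(
        "identity",
        lambda x: np.asarray(x, dtype=float),
        lambda y: np.asarray(y, dtype=float),
    ),
}

# transform attached to each native parameter name
PARAM_TRANSFORM = {
    "r": "logistic150",
    "rho": "logistic2",
    "s": "log",
    "cost": "identity",
    "c": "identity",
    "a": "identity",
    "b": "identity",
}


@dataclass(frozen=True)
class ModelSpec:
    """A fittable choice model: parameter names plus a schedule builder."""

    tag: str
    param_names: tuple
    build_schedule: Callable  # (params: dict, spec: TaskSpec) -> ThresholdSchedule

    def n_params(self, spec: TaskSpec) -> int:
        return len(self.names_for(spec))

    def names_for(self, spec: TaskSpec) -> tuple:
        if self.tag == "independent":
            return tuple(f"theta_{i}" for i in range(1, spec.K)) + ("s",)
        return self.param_names


def _sched_optimal(params, spec):
    return models.optimal_thresholds(spec)


def _sched_subjective(params, spec, cost=False):
    p = ValueParams(
        r=float(np.clip(params["r"], 1e-6, 150 - 1e-6)),
        rho=float(np.clip(params["rho"], 1e-6, 2 - 1e-6)),
        cost=max(float(params.get("cost", 0.0)), 0.0) if cost else 0.0,
        s=float(params.get("s", 10.0)),
    )
    return models.subjective_thresholds(spec, p)


def _sched_constant(params, spec):
    return models.constant_threshold(params["c"], spec.K)


def _sched_linear(params, spec):
    return models.linear_thresholds(LinearParams(params["a"], params["b"]), spec.K)


def _sched_independent(params, spec):
    theta = tuple(params[f"theta_{i}"] for i in range(1, spec.K)) + (0.0,)
    return ThresholdSchedule(K=spec.K, theta=theta, model_tag="independent")


MODELS = {
    "optimal": ModelSpec("optimal", ("s",), _sched_optimal),
    "constant": ModelSpec("constant", ("c", "s"), _sched_constant),
    "linear": ModelSpec("linear", ("a", "b", "s"), _sched_linear),
    "independent": ModelSpec("independent", (), _sched_independent),
    "subjective": ModelSpec("subjective", ("r", "rho", "s"), _sched_subjective),
    "subjective_cost": ModelSpec(
        "subjective_cost",
        ("r", "rho", "cost", "s"),
        lambda p, spec: _sched_subjective(p, spec, cost=True),
    ),
}


def model_spec(tag: str) -> ModelSpec:
    try:
        return MODELS[tag]
    except KeyError:
        raise ValueError(f"unknown model tag {tag!r}; known: {sorted(MODELS)}") from None


def _transform_for(name: str) -> Transform:
    key = PARAM_TRANSFORM.get(name, "identity")  # theta_i -> identity
    return TRANSFORMS[key]


def to_native(name: str, x):
    """Map a sampling-space value to the parameter's native range."""
    return _transform_for(name).forward(x)


def to_sampling(name: str, y):
    """Map a native parameter value to sampling space."""
    return _transform_for(name).inverse(y)
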