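"""Core domain types for the finite sequential-choice (secretary) task.

The task: within a *round*, a player sees up to ``K`` integer stimuli drawn
i.i.d. uniform on ``{v_min..v_max}`` (default 0..150), one per *opportunity*.
Accepting a stimulus ends the round and banks its face value; rejection is
irrevocable.  At the last opportunity acceptance is forced.  Opportunity and
round indices are 1-based throughout the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

__all__ = [
    "TaskSpec",
    "ValueParams",
    "LinearParams",
    "ThresholdSchedule",
]


@dataclass(frozen=True)
class TaskSpec:
    """Environment of one task condition.

    Parameters
    ----------
    K : int
        Opportunities per round (>= 1); the K-th is forced acceptance.
    v_min, v_max : int
        Inclusive integer stimulus bounds (0 and 150 in the experiments).
    n_rounds : int
        Rounds played per subject (200 in the experiments).
    """

    K: int = 5
    v_min: int = 0
    v_max: int = 150
    n_rounds: int = 200

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError(f"K must be >= 1, got {self.K}")
        if self.v_min > self.v_max:
            raise ValueError("v_min must not exceed v_max")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")

    @property
    def n_values(self) -> int:
        """Number of distinct stimulus values (151 for 0..150)."""
        return self.v_max - self.v_min + 1


@dataclass(frozen=True)
class ValueParams:
    """Subject-level parameters of the subjective-optimality model.

    ``r`` is the reference point dividing subjective gains from losses,
    ``rho`` the value-sensitivity exponent (rho = 1 is objective valuation,
    rho -> 0 categorical gain/loss valuation), ``cost`` the per-opportunity
    waiting cost in utility units, and ``s`` the SD of Gaussian noise around
    the decision thresholds (decision variability, stimulus units).

    The open bounds on ``r`` and ``rho`` are exactly the ranges reachable
    through the scaled-logistic fitting transforms.
    """

    r: float = 75.0
    rho: float = 1.0
    cost: float = 0.0
    s: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r < 150.0):
            raise ValueError(f"reference point r must lie in (0, 150), got {self.r}")
        if not (0.0 < self.rho < 2.0):
            raise ValueError(f"value sensitivity rho must lie in (0, 2), got {self.rho}")
        if self.cost < 0.0:
            raise ValueError(f"waiting cost must be >= 0, got {self.cost}")
        if self.s <= 0.0:
            raise ValueError(f"decision variability s must be > 0, got {self.s}")


@dataclass(frozen=True)
class LinearParams:
    """Intercept/slope of the linear-threshold heuristic: theta[i] = a + b*i."""

    a: float
    b: float


@dataclass(frozen=True)
class ThresholdSchedule:
    """Per-opportunity decision thresholds theta[1..K] (stimulus units).

    ``theta`` is stored as a plain tuple; ``theta[i - 1]`` is the threshold of
    the 1-based opportunity ``i``.  For the optimal and subjective models
    theta[K] = 0 encodes forced acceptance and the schedule is non-increasing.
    """

    K: int
    theta: tuple
    model_tag: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.theta) != self.K:
            raise ValueError(
                f"schedule length {len(self.theta)} does not match K={self.K}"
            )
        object.__setattr__(self, "theta", tuple(float(t) for t in self.theta))

    def __getitem__(self, i: int) -> float:
        """Threshold of the 1-based opportunity ``i``."""
        if not 1 <= i <= self.K:
            raise IndexError(f"opportunity {i} outside 1..{self.K}")
        return self.theta[i - 1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_tag": self.model_tag,
                "K": self.K,
                "theta": list(self.theta),
                "params": self.params,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdSchedule":
        d = json.loads(text)
        return cls(
            K=d["K"],
            theta=tuple(d["theta"]),
            model_tag=d.get("model_tag", ""),
            params=d.get("params", {}),
        )


def params_to_dict(p) -> dict:
    return asdict(p)
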