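"""Model parameters for the two-species and single-species timer models.

The two-species model describes organisms A and B that replicate in
quasi-discrete generations (a per-cell countdown "timer" drawn at birth from
a replication-time distribution ``R(tau)``) and die as inhomogeneous Poisson
processes with state-dependent per-capita rates::

    d_A = max(p2 - p1 * N_B/K, 0)
    d_B = max(p4 * N_A/K - p3 * (1 - N_B/K), 0)

``K`` sets the population scale (carrying capacity), ``b`` the per-capita
mean-field growth rate, and ``T = ln2 / b`` the mean doubling time. The
replication-time distribution is either exponential (the Poisson model) or
uniform on ``(T(1-w), T(1+w))`` with half-width fraction ``w``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Any

LN2 = math.log(2.0)

#: Parameter sets {p1, p2, p3, p4} designed (at b=1) for oscillation frequency
#: f0 = 1, steady state (0.5, 0.5) and damping |Re lambda| = 0.5, 0.2, 0.1.
PRESETS: dict[str, tuple[float, float, float, float]] = {
    "S0.5": (39.73, 20.86, 2.0, 4.0),
    "S0.2": (56.45, 29.23, 0.8, 2.8),
    "S0.1": (65.81, 33.91, 0.4, 2.4),
}

_DISTS = ("exponential", "uniform")
_POISSON_CONVENTIONS = ("rate", "mean")


@dataclass(frozen=True)
class ModelParams:
    """Rate and shape parameters of the two-species model.

    Parameters
    ----------
    p1, p2, p3, p4
        Death-rate coefficients (per unit time), all strictly positive.
    b
        Per-capita mean-field growth rate (per unit time). The mean doubling
        time is derived as ``T = ln2 / b`` and never set independently.
    K
        Carrying-capacity scale (organisms, positive integer).
    w
        Half-width fraction of the uniform doubling-time distribution,
        ``0 <= w < 1``. Ignored for the exponential distribution.
    replication_dist
        ``"uniform"`` (quasi-synchronous) or ``"exponential"`` (Poisson).
    poisson_convention
        For the exponential distribution only: ``"rate"`` sets the division
        hazard to ``b`` (mean timer ``1/b``) so the mean-field growth rate
        equals ``b`` for both distributions; ``"mean"`` sets the mean timer
        to ``T = ln2/b`` instead.
    """

    p1: float
    p2: float
    p3: float
    p4: float
    b: float = 1.0
    K: int = 100_000
    w: float = 0.02
    replication_dist: str = "uniform"
    poisson_convention: str = "rate"

    def __post_init__(self) -> None:
        for name in ("p1", "p2", "p3", "p4", "b"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (int(self.K) == self.K and self.K > 0):
            raise ValueError("K must be a positive integer")
        if not 0 <= self.w < 1:
            raise ValueError("w must satisfy 0 <= w < 1")
        if self.replication_dist not in _DISTS:
            raise ValueError(f"replication_dist must be one of {_DISTS}")
        if self.poisson_convention not in _POISSON_CONVENTIONS:
            raise ValueError(
                f"poisson_convention must be one of {_POISSON_CONVENTIONS}"
            )

    @property
    def T(self) -> float:
        """Mean doubling time ``ln2 / b``."""
        return LN2 / self.b

    @property
    def division_hazard(self) -> float:
        """Constant division hazard of the exponential (Poisson) model."""
        if self.poisson_convention == "rate":
            return self.b
        return 1.0 / self.T

    @classmethod
    def preset(cls, name: str, **overrides: Any) -> "ModelParams":
        """Build parameters from a named preset ("S0.5", "S0.2", "S0.1")."""
        try:
            p1, p2, p3, p4 = PRESETS[name]
        except KeyError:
            raise KeyError(
                f"unknown preset {name!r}; available: {sorted(PRESETS)}"
            ) from None
        return cls(p1=p1, p2=p2, p3=p3, p4=p4, **overrides)

    def with_(self, **overrides: Any) -> "ModelParams":
        return replace(self, **overrides)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        return cls(**d)


@dataclass(frozen=True)
class SingleSpeciesParams:
    """Parameters of the single-species logistic timer model.

    Replication uses the timer mechanism (mean doubling time ``T = ln2/b``);
    death is a Poisson process with per-capita rate ``b N / K``, so the
    mean-field limit is the logistic equation ``dx/dt = b x (1 - x)`` with
    fixed point ``N* = K``.
    """

    b: float = 1.0
    K: int = 100_000
    w: float = 0.02
    replication_dist: str = "uniform"
    poisson_convention: str = "rate"

    def __post_init__(self) -> None:
        if not self.b > 0:
            raise ValueError("b must be strictly positive")
        if not (int(self.K) == self.K and self.K > 0):
            raise ValueError("K must be a positive integer")
        if not 0 <= self.w < 1:
            raise ValueError("w must satisfy 0 <= w < 1")
        if self.replication_dist not in _DISTS:
            raise ValueError(f"replication_dist must be one of {_DISTS}")
        if self.poisson_convention not in _POISSON_CONVENTIONS:
            raise ValueError(
                f"poisson_convention must be one of {_POISSON_CONVENTIONS}"
            )

    @property
    def T(self) -> float:
        return LN2 / self.b

    @property
    def division_hazard(self) -> float:
        if self.poisson_convention == "rate":
            return self.b
        return 1.0 / self.T

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
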