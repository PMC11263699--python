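"""Deterministic layer: death-rate laws, mean-field ODEs, steady state,
Jacobian eigenvalues and linearization coefficients.

The mean-field limit of the stochastic model, in occupation fractions
``x_A = N_A/K`` and ``x_B = N_B/K``, is::

    dx_A/dt = x_A * (b - max(p2 - p1 x_B, 0))
    dx_B/dt = x_B * (b - max(p4 x_A - p3 (1 - x_B), 0))

The interior fixed point (both species present) is::

    x_A* = ((p1 - p2) p3 + b (p1 + p3)) / (p1 p4)
    x_B* = (p2 - b) / p1

and the Jacobian eigenvalues at that point are::

    lambda_± = (b p3 - p2 p3 ± sqrt(Delta)) / (2 p1)
    Delta    = (b - p2) * (b (2 p1 + p3)^2 - p3 (-4 p1^2 + 4 p1 p2 + p2 p3))

In the coexistence regime Delta < 0, so the system exhibits damped
oscillations with frequency ``f0 = Im(lambda)/(2 pi)`` and damping
coefficient ``|Re(lambda)|``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParams

TWO_PI = 2.0 * math.pi


class NonCoexistenceError(ValueError):
    """The interior (both species present) steady state does not exist."""


@dataclass(frozen=True)
class SteadyState:
    """Interior fixed point of the mean-field equations.

    ``coexists`` is True when both components are strictly positive;
    ``interior`` is True when, in addition, neither death-rate clamp is
    active at the fixed point (the regime the analytics assume).
    """

    x_A: float
    x_B: float
    coexists: bool
    interior: bool

    def __iter__(self):
        return iter((self.x_A, self.x_B))


@dataclass(frozen=True)
class EigenSummary:
    """Jacobian eigenvalue decomposition at the coexistence fixed point."""

    re_lambda: float      # shared real part (complex pair) / max real part
    im_lambda: float      # |Im lambda|, radians per unit time
    f0: float             # im_lambda / (2 pi), cycles per unit time
    discriminant: float
    x_star: tuple[float, float]
    lambdas: tuple[complex, complex]

    @property
    def damping(self) -> float:
        """Damping coefficient |Re lambda|."""
        return abs(self.re_lambda)


@dataclass(frozen=True)
class LinearCoeffs:
    """Coefficients of the dynamics linearized about the fixed point:
    dy_A/dt = a_AB y_B,  dy_B/dt = a_BA y_A + a_BB y_B.
    """

    a_AB: float
    a_BB: float
    a_BA: float

    def matrix(self) -> np.ndarray:
        return np.array([[0.0, self.a_AB], [self.a_BA, self.a_BB]])


def death_rate_A(x_B: float, params: ModelParams) -> float:
    """Per-capita death rate of species A, ``max(p2 - p1 x_B, 0)``."""
    if x_B < 0:
        raise ValueError("x_B must be non-negative")
    return max(params.p2 - params.p1 * x_B, 0.0)


def death_rate_B(x_A: float, x_B: float, params: ModelParams) -> float:
    """Per-capita death rate of species B, ``max(p4 x_A - p3 (1 - x_B), 0)``."""
    if x_A < 0 or x_B < 0:
        raise ValueError("x_A and x_B must be non-negative")
    return max(params.p4 * x_A - params.p3 * (1.0 - x_B), 0.0)


def meanfield_rhs(x_A: float, x_B: float, params: ModelParams) -> tuple[float, float]:
    """Right-hand side of the mean-field ODEs at ``(x_A, x_B)``."""
    return (
        x_A * (params.b - death_rate_A(x_B, params)),
        x_B * (params.b - death_rate_B(x_A, x_B, params)),
    )


def integrate_meanfield(
    x0: tuple[float, float],
    t_grid: np.ndarray,
    params: ModelParams,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> np.ndarray:
    """Integrate the mean-field ODEs over ``t_grid``.

    Returns an array of shape ``(len(t_grid), 2)``. Uses an adaptive
    stiff-capable integrator (LSODA) with tight tolerances; the dynamics are
    oscillatory but not stiff, and the tolerance supports envelope tests.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if min(x0) < 0:
        raise ValueError("initial fractions must be non-negative")

    def rhs(_t: float, x: np.ndarray) -> list[float]:
        return list(meanfield_rhs(x[0], x[1], params))

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        list(x0),
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"mean-field integration failed: {sol.message} "
            f"(reached t={sol.t[-1] if len(sol.t) else t_grid[0]})"
        )
    return sol.y.T


def steady_state(params: ModelParams) -> SteadyState:
    """Interior steady state of the mean-field equations.

    The closed-form point is returned even when a component is non-positive
    or a clamp would activate there; ``coexists`` / ``interior`` flag those
    situations.
    """
    p1, p2, p3, p4, b = params.p1, params.p2, params.p3, params.p4, params.b
    x_A = ((p1 - p2) * p3 + b * (p1 + p3)) / (p1 * p4)
    x_B = (p2 - b) / p1
    coexists = x_A > 0 and x_B > 0
    interior = coexists and (p2 - p1 * x_B) > 0 and (p4 * x_A - p3 * (1 - x_B)) > 0
    return SteadyState(x_A, x_B, coexists, interior)


def jacobian_eigenvalues(params: ModelParams) -> EigenSummary:
    """Eigenvalues of the mean-field Jacobian at the coexistence fixed point."""
    ss = steady_state(params)
    if not ss.coexists:
        raise NonCoexistenceError(
            f"no coexistence steady state: x* = ({ss.x_A:.4g}, {ss.x_B:.4g})"
        )
    p1, p2, p3, b = params.p1, params.p2, params.p3, params.b
    delta = (b - p2) * (
        b * (2 * p1 + p3) ** 2 - p3 * (-4 * p1**2 + 4 * p1 * p2 + p2 * p3)
    )
    base = (b * p3 - p2 * p3) / (2 * p1)
    if delta < 0:
        im = math.sqrt(-delta) / (2 * p1)
        lam = (complex(base, im), complex(base, -im))
        re = base
    else:
        root = math.sqrt(delta) / (2 * p1)
        lam = (complex(base + root), complex(base - root))
        re = base + root  # least stable branch
        im = 0.0
    return EigenSummary(
        re_lambda=re,
        im_lambda=im,
        f0=im / TWO_PI,
        discriminant=delta,
        x_star=(ss.x_A, ss.x_B),
        lambdas=lam,
    )


def linear_coeffs(params: ModelParams) -> LinearCoeffs:
    """Linearization coefficients about the coexistence fixed point.

    Closed forms (equivalent to ``a_AB = p1 x_A*``, ``a_BB = -p3 x_B*``,
    ``a_BA = -p4 x_B*``)::

        a_AB = (p3 (b - p2) + p1 (b + p3)) / p4
        a_BB = p3 (b - p2) / p1
        a_BA = p4 (b - p2) / p1
    """
    ss = steady_state(params)
    if not ss.coexists:
        raise NonCoexistenceError("linearization requires a coexistence state")
    p1, p2, p3, p4, b = params.p1, params.p2, params.p3, params.p4, params.b
    return LinearCoeffs(
        a_AB=(p3 * (b - p2) + p1 * (b + p3)) / p4,
        a_BB=p3 * (b - p2) / p1,
        a_BA=p4 * (b - p2) / p1,
    )
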