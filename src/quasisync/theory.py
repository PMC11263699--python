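"""Analytic layer: phase-diffusion decay rate, single-species variance and
spectrum, linearized two-species spectra under white or coloured demographic
noise, and the synchrony threshold.

Spectral convention
-------------------
All spectra are two-sided densities in angular frequency, normalised so that
``Var(X) = (1/2pi) * integral of S_X(omega) d omega`` over the real line.
Noise spectra are made even in ``omega`` by evaluating the Lorentzian at
``|omega|``; Lorentzian coefficients are chosen so that integrated powers
match the single-sided forms they are calibrated against.

Physics summary
---------------
Quasi-synchronous replication (division times uniform on
``(T(1-w), T(1+w))``) makes the cell-cycle phase distribution spread by the
division-time variance ``sigma0^2 = (wT)^2/3`` every generation. A Fourier
mode of the population at angular frequency ``omega`` is attenuated by
``exp(-sigma^2 omega^2 / 2)``, so synchrony-induced oscillations at
``omega0 = 2 pi / T`` decay at rate::

    gamma = (omega0^2 / 2) * (sigma0^2 / T) = 2 pi^2 w^2 / (3 T)

(~9.5 w^2 at T = ln2, 6.579... w^2 at T = 1). Demographic noise then has a
white (death-driven) part plus a Lorentzian of half-width ``gamma`` centred
at ``omega0`` — coloured noise that a resonant predator-prey system can
amplify dramatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .core import LinearCoeffs, steady_state
from .params import LN2, ModelParams

TWO_PI = 2.0 * math.pi

#: Coefficients of the single-species variance law Var(N) = K (C_VAR_WHITE +
#: C_VAR_SYNC / gamma) and of the matching spectrum approximation; these are
#: taken as given, not re-derived.
C_VAR_WHITE = 0.48
C_VAR_SYNC = 0.0125
C_SPEC_WHITE = 0.962
C_SPEC_LORENTZ = 0.0231336


def phase_attenuation(sigma2: float, omega: float) -> float:
    """Attenuation ``exp(-sigma^2 omega^2 / 2)`` of a population Fourier
    mode at angular frequency ``omega`` due to a Gaussian spread of
    cell-cycle phases with variance ``sigma2``."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    return math.exp(-0.5 * sigma2 * omega**2)


def decay_rate_gamma(w: float, T: float = LN2) -> float:
    """Exponential decay rate ``gamma = 2 pi^2 w^2 / (3 T)`` of
    synchrony-induced oscillations (phase diffusion)."""
    if w < 0:
        raise ValueError("w must be non-negative")
    if T <= 0:
        raise ValueError("T must be positive")
    return 2.0 * math.pi**2 * w**2 / (3.0 * T)


def single_species_variance(K: float, gamma: float) -> float:
    """Stationary variance ``K (0.48 + 0.0125 / gamma)`` of the
    single-species model at b = 1."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return K * (C_VAR_WHITE + C_VAR_SYNC / gamma)


def single_species_spectrum(f, K: float, gamma: float):
    """Demographic-noise spectrum of the single-species model at b = 1
    (two-sided density in ordinary frequency ``f``)::

        K [ 0.962 / (1 + (2 pi f)^2)
            + 0.0231336 / ((2 pi f - 2 pi/ln2)^2 + gamma^2) ]
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    omega = TWO_PI * np.asarray(f, dtype=float)
    omega0 = TWO_PI / LN2
    return K * (
        C_SPEC_WHITE / (1.0 + omega**2)
        + C_SPEC_LORENTZ / ((omega - omega0) ** 2 + gamma**2)
    )


@dataclass(frozen=True)
class NoiseSpectra:
    """Per-species demographic-noise spectra driving the linearized
    two-species dynamics (in organism units, i.e. for ``Delta N_s``).

    ``eta2_A``/``eta2_B`` evaluate ``<|eta_s|^2>(omega)``; the cross term is
    zero for both supported kinds. ``white_poisson`` uses the flat level
    ``2 b N_s*`` (= bK per species at the designed steady state x* = 0.5,
    birth and death contributing equally); ``coloured_surrogate`` adds a
    Lorentzian of half-width ``gamma`` at ``omega0 = 2 pi / T`` on top of a
    white death floor, with coefficients calibrated from the single-species
    spectrum constants rescaled to the species' mean abundance ``x_s* K``.
    """

    kind: str
    K: float
    b: float
    x_star: tuple[float, float]
    gamma: float = math.inf
    omega0: float = 0.0
    c_white: float = C_SPEC_WHITE
    c_lorentz: float = 0.0

    def _eta2(self, omega, x_s: float):
        omega = np.abs(np.asarray(omega, dtype=float))
        amp = x_s * self.K
        if self.kind == "white_poisson":
            return np.full_like(omega, 2.0 * self.b * amp)
        white = self.c_white * self.b * amp
        lor = self.c_lorentz * amp / ((omega - self.omega0) ** 2 + self.gamma**2)
        return white + lor

    def eta2_A(self, omega):
        return self._eta2(omega, self.x_star[0])

    def eta2_B(self, omega):
        return self._eta2(omega, self.x_star[1])

    def cross(self, omega):
        return np.zeros_like(np.asarray(omega, dtype=float))


def white_poisson_noise(
    K: float, b: float, x_star: tuple[float, float] = (0.5, 0.5)
) -> NoiseSpectra:
    """White demographic noise of the Poisson model, ``<|eta_s|^2> = 2 b
    N_s*`` (equals ``bK`` per species at the designed steady state)."""
    return NoiseSpectra(kind="white_poisson", K=K, b=b, x_star=tuple(x_star))


def coloured_noise_spectra(
    params: ModelParams,
    gamma: float | None = None,
    c_white: float = C_SPEC_WHITE,
    c_lorentz_base: float = C_SPEC_LORENTZ,
) -> NoiseSpectra:
    """Coloured-noise surrogate for quasi-synchronous replication.

    Per species ``s``::

        <|eta_s|^2>(omega) = x_s* K [ c_white * b
            + c_L / ((|omega| - omega0)^2 + gamma^2) ],
        c_L = c_lorentz_base * (1 + omega0^2) / 2,  omega0 = 2 pi / T

    ``gamma`` defaults to the phase-diffusion rate ``decay_rate_gamma(w, T)``.
    The factor ``(1 + omega0^2)`` undoes the single-species response at the
    peak and the ``1/2`` accounts for mirroring the Lorentzian to negative
    frequencies; both constants can be overridden. This is a surrogate form
    (white floor + Lorentzian), quantitatively calibrated only through the
    single-species constants, so two-species predictions built on it are
    trend/shape level rather than exact.
    """
    if params.replication_dist != "uniform":
        raise ValueError("coloured noise applies to the uniform distribution")
    T = params.T
    omega0 = TWO_PI / T
    if gamma is None:
        gamma = decay_rate_gamma(params.w, T)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    ss = steady_state(params)
    return NoiseSpectra(
        kind="coloured_surrogate",
        K=float(params.K),
        b=params.b,
        x_star=(ss.x_A, ss.x_B),
        gamma=float(gamma),
        omega0=omega0,
        c_white=c_white,
        c_lorentz=c_lorentz_base * (1.0 + omega0**2) / 2.0,
    )


def linear_spectrum_yA(omega, coeffs: LinearCoeffs, noise: NoiseSpectra):
    """Spectrum of the species-A fluctuation from the linearized dynamics::

        S_A(omega) = [ (a_BB^2 + omega^2) <|eta_A|^2>
                       - 2 a_AB a_BB <|eta_A eta_B|^2>
                       + a_AB^2 <|eta_B|^2> ]
                     / [ a_AB^2 a_BA^2 + 2 a_AB a_BA omega^2
                         + a_BB^2 omega^2 + omega^4 ]

    With noise in organism units the result is the spectrum of
    ``Delta N_A`` directly.
    """
    omega = np.asarray(omega, dtype=float)
    a_ab, a_bb, a_ba = coeffs.a_AB, coeffs.a_BB, coeffs.a_BA
    w2 = omega**2
    den = a_ab**2 * a_ba**2 + 2.0 * a_ab * a_ba * w2 + a_bb**2 * w2 + w2**2
    if np.any(den <= 0):
        raise ValueError("non-positive denominator: outside the stable regime")
    num = (
        (a_bb**2 + w2) * noise.eta2_A(omega)
        - 2.0 * a_ab * a_bb * noise.cross(omega)
        + a_ab**2 * noise.eta2_B(omega)
    )
    return num / den


def variance_from_spectrum(
    coeffs: LinearCoeffs,
    noise: NoiseSpectra,
    rtol: float = 1e-6,
) -> float:
    """Stationary variance of ``Delta N_A`` by numerical quadrature of the
    linearized spectrum, ``Var = (1/pi) * integral_0^inf S_A(omega)
    d omega`` (the spectrum is even)."""

    def f(omega: float) -> float:
        return float(linear_spectrum_yA(omega, coeffs, noise))

    points = [abs(coeffs.a_BB), math.sqrt(abs(coeffs.a_AB * coeffs.a_BA))]
    if noise.kind == "coloured_surrogate":
        g = noise.gamma
        points += [
            max(noise.omega0 - 10 * g, 0.0),
            noise.omega0,
            noise.omega0 + 10 * g,
        ]
    cut = max(points) * 3 + 10.0
    body, err1 = integrate.quad(
        f, 0.0, cut, points=sorted(set(points)), epsrel=rtol, limit=500
    )
    tail, err2 = integrate.quad(f, cut, np.inf, epsrel=rtol, limit=500)
    total = body + tail
    if total > 0 and (err1 + err2) > 1e-3 * total:
        raise RuntimeError(
            f"quadrature did not converge: value={total}, err={err1 + err2}"
        )
    return total / math.pi


def small_gamma_variance(
    coeffs: LinearCoeffs,
    gamma: float,
    K: float,
    D2: float | None = None,
) -> float:
    """Small-``gamma`` closed form for the variance of ``Delta N_A`` in the
    resonant regime (T = 1, b = ln2)::

        Var ~= K D2 pi^2 (a_BB^2 + a_AB^2 + 4 pi^2) (ln2)^2
               / [ gamma (a_AB^2 a_BA^2 + 4 (2 a_AB a_BA + a_BB^2) pi^2
                   + 16 pi^4) (4 pi^2 + (ln2)^2) ]

    The amplitude constant ``D2`` is supplied by the caller; when omitted it
    is self-calibrated so the formula agrees with ``variance_from_spectrum``
    at gamma = 1e-3.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if D2 is None:
        D2 = calibrate_d2(coeffs, K)
    a_ab, a_bb, a_ba = coeffs.a_AB, coeffs.a_BB, coeffs.a_BA
    pi2 = math.pi**2
    num = K * D2 * pi2 * (a_bb**2 + a_ab**2 + 4.0 * pi2) * LN2**2
    den = (
        gamma
        * (a_ab**2 * a_ba**2 + 4.0 * (2.0 * a_ab * a_ba + a_bb**2) * pi2 + 16.0 * pi2**2)
        * (4.0 * pi2 + LN2**2)
    )
    return num / den


def calibrate_d2(
    coeffs: LinearCoeffs, K: float, gamma_ref: float = 1e-3
) -> float:
    """Amplitude constant for ``small_gamma_variance``: matched against the
    quadrature of the coloured-surrogate spectrum at ``gamma_ref`` in the
    T = 1, b = ln2 regime."""
    omega0 = TWO_PI  # T = 1
    noise = NoiseSpectra(
        kind="coloured_surrogate",
        K=K,
        b=LN2,
        x_star=(0.5, 0.5),
        gamma=gamma_ref,
        omega0=omega0,
        c_white=C_SPEC_WHITE,
        c_lorentz=C_SPEC_LORENTZ * (1.0 + omega0**2) / 2.0,
    )
    target = variance_from_spectrum(coeffs, noise)
    unit = small_gamma_variance(coeffs, gamma_ref, K, D2=1.0)
    return target / unit


@dataclass(frozen=True)
class SynchronyThreshold:
    """Synchrony level below which coloured-noise amplification dominates."""

    w_c: float
    gamma_c: float
    c: float


def synchrony_threshold(coeffs: LinearCoeffs) -> SynchronyThreshold:
    """Threshold ``w_c = 0.55 c^(-1/4)`` (equivalently ``gamma_c =
    2/sqrt(c)``) with ``c = -a_AB a_BA a_BB^2 - a_BB^4 / 4``, below which the
    synchronous-replication contribution to Var(N_A) rivals the stochastic
    death contribution."""
    c = -coeffs.a_AB * coeffs.a_BA * coeffs.a_BB**2 - coeffs.a_BB**4 / 4.0
    if c <= 0:
        raise ValueError(f"threshold undefined: c = {c:.4g} <= 0")
    return SynchronyThreshold(
        w_c=0.55 * c**-0.25, gamma_c=2.0 / math.sqrt(c), c=c
    )
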