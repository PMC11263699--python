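"""Analytic layer: phase diffusion, variance laws, linearized spectra."""

import math

import numpy as np
import pytest
from scipy import integrate, linalg, signal

from quasisync import (
    linear_coeffs,
    coloured_noise_spectra,
    decay_rate_gamma,
    linear_spectrum_yA,
    phase_attenuation,
    single_species_spectrum,
    single_species_variance,
    small_gamma_variance,
    synchrony_threshold,
    variance_from_spectrum,
    white_poisson_noise,
)
from quasisync.params import LN2
from quasisync.theory import NoiseSpectra, calibrate_d2

OMEGA_DBL = 2 * math.pi / LN2  # replication angular frequency at b = 1


class TestPhaseDiffusion:
    def test_attenuation_limits_and_coefficient(self):
        assert phase_attenuation(0.0, 5.0) == 1.0
        # exponent coefficient at the doubling frequency is ~41.1
        coeff = -math.log(phase_attenuation(1.0, OMEGA_DBL))
        assert coeff == pytest.approx(41.1, abs=0.05)
        assert phase_attenuation(0.01, OMEGA_DBL) == pytest.approx(0.663, abs=2e-3)
        with pytest.raises(ValueError):
            phase_attenuation(-1.0, 1.0)

    def test_decay_rate_coefficients(self):
        # gamma / w^2 = 2 pi^2 / (3 T)
        assert decay_rate_gamma(1.0, LN2) == pytest.approx(9.5, abs=0.05)
        assert decay_rate_gamma(1.0, 1.0) == pytest.approx(6.579, abs=1e-3)
        assert decay_rate_gamma(0.0, 1.0) == 0.0
        assert decay_rate_gamma(0.04) == pytest.approx(16 * decay_rate_gamma(0.01))


class TestSingleSpecies:
    def test_variance_law(self):
        assert single_species_variance(1e5, 1e9) == pytest.approx(0.48e5, rel=1e-6)
        g = decay_rate_gamma(0.04)
        assert single_species_variance(1e5, g) == pytest.approx(1.303e5, rel=1e-3)
        assert single_species_variance(2e5, g) == pytest.approx(
            2 * single_species_variance(1e5, g)
        )
        with pytest.raises(ValueError):
            single_species_variance(1e5, 0.0)

    def test_spectrum_peak_and_decay(self):
        g = 0.05
        K = 1e5
        f = np.array([1 / LN2, 50.0])
        s = single_species_spectrum(f, K, g)
        assert s[0] == pytest.approx(K * 0.0231336 / g**2, rel=0.02)
        assert s[1] < 1e-2 * s[0]

    def test_spectrum_integrates_to_variance_law_scale(self):
        """Quadrature of the printed spectrum over the real frequency line
        reproduces the variance law's 1/gamma structure at the ~10% level
        (the two printed approximations are mutually consistent, not
        identical)."""
        K = 1.0
        for g in (1e-3, 1e-2, 1e-1):
            fn = lambda f: single_species_spectrum(f, K, g)  # noqa: E731
            body, _ = integrate.quad(
                fn, -20.0, 20.0, points=[0.0, 1 / LN2], limit=400
            )
            val = body + integrate.quad(fn, 20.0, np.inf)[0]
            val += integrate.quad(fn, -np.inf, -20.0)[0]
            assert val == pytest.approx(single_species_variance(K, g), rel=0.12)


class TestLinearSpectrum:
    def test_zero_frequency_value_with_white_noise(self, s05):
        lc = linear_coeffs(s05)
        noise = white_poisson_noise(1e5, 1.0)
        val = linear_spectrum_yA(0.0, lc, noise)
        # bK (a_BB^2 + a_AB^2) / (a_AB^2 a_BA^2)
        assert val == pytest.approx(2.51e4, rel=2e-3)

    def test_peak_near_natural_frequency(self, s05):
        lc = linear_coeffs(s05)
        noise = white_poisson_noise(1e5, 1.0)
        omega = np.linspace(0.05, 20, 4000)
        s = linear_spectrum_yA(omega, lc, noise)
        assert omega[np.argmax(s)] == pytest.approx(2 * math.pi, rel=0.05)

    def test_zero_noise_gives_zero_spectrum(self, s05):
        lc = linear_coeffs(s05)
        silent = NoiseSpectra(kind="white_poisson", K=0.0, b=1.0,
                              x_star=(0.5, 0.5))
        omega = np.linspace(0, 10, 50)
        assert np.all(linear_spectrum_yA(omega, lc, silent) == 0)

    def test_spectra_nonnegative(self, s05):
        lc = linear_coeffs(s05)
        omega = np.linspace(0, 50, 2000)
        for noise in (
            white_poisson_noise(1e5, 1.0),
            coloured_noise_spectra(s05.with_(w=0.05)),
        ):
            assert np.all(linear_spectrum_yA(omega, lc, noise) >= 0)
            assert np.all(noise.eta2_A(omega) >= 0)


class TestVarianceFromSpectrum:
    def test_white_noise_matches_lyapunov_solution(self, s05):
        """Independent oracle: stationary covariance of the linear SDE from
        the continuous Lyapunov equation."""
        lc = linear_coeffs(s05)
        K, b = 1e5, 1.0
        noise = white_poisson_noise(K, b)
        var = variance_from_spectrum(lc, noise)
        A = lc.matrix()
        Q = np.diag([b * K, b * K])
        P = linalg.solve_continuous_lyapunov(A, -Q)
        assert var == pytest.approx(P[0, 0], rel=1e-4)

    def test_white_noise_matches_euler_maruyama(self, s05):
        """Brute-force linearized-SDE simulation agrees within 5%."""
        lc = linear_coeffs(s05)
        K, b = 1e4, 1.0
        noise = white_poisson_noise(K, b)
        var = variance_from_spectrum(lc, noise)
        rng = np.random.default_rng(7)
        dt = 1e-3
        n_steps, n_rep, burn = 1_500_000, 16, 100_000
        A = lc.matrix()
        amp = math.sqrt(b * K * dt)
        y = np.zeros((2, n_rep))
        acc = 0.0
        acc2 = 0.0
        count = 0
        for k in range(n_steps):
            y = y + (A @ y) * dt + amp * rng.standard_normal((2, n_rep))
            if k >= burn and k % 20 == 0:
                acc += y[0].sum()
                acc2 += (y[0] ** 2).sum()
                count += n_rep
        sim_var = acc2 / count - (acc / count) ** 2
        assert sim_var == pytest.approx(var, rel=0.05)

    def test_coloured_variance_monotone_in_gamma(self, s05):
        lc = linear_coeffs(s05)
        p = s05.with_(w=0.05, K=100_000)
        variances = [
            variance_from_spectrum(lc, coloured_noise_spectra(p, gamma=g))
            for g in (1e-3, 1e-2, 1e-1, 1.0)
        ]
        assert all(a > b for a, b in zip(variances, variances[1:]))

    def test_coloured_flattens_to_white_floor_at_large_gamma(self, s05):
        p = s05.with_(w=0.05, K=100_000)
        noise = coloured_noise_spectra(p, gamma=1e4)
        omega = np.linspace(0, 30, 500)
        eta = noise.eta2_A(omega)
        floor = noise.c_white * noise.b * noise.x_star[0] * noise.K
        assert np.all(np.abs(eta / floor - 1) < 0.05)


class TestSmallGammaLimit:
    def test_inverse_gamma_scaling(self, s05):
        lc = linear_coeffs(s05)
        v1 = small_gamma_variance(lc, 1e-4, 1e5, D2=1.0)
        v2 = small_gamma_variance(lc, 5e-5, 1e5, D2=1.0)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_agrees_with_quadrature_at_small_gamma(self, s05):
        """Closed form (calibrated at gamma = 1e-3) tracks the quadrature of
        the coloured spectrum for smaller gamma (T = 1 regime, b = ln2)."""
        lc = linear_coeffs(s05.with_(b=LN2))
        K = 1e5
        d2 = calibrate_d2(lc, K)
        for g in (5e-4, 2e-4, 1e-4):
            noise = coloured_noise_spectra(
                s05.with_(b=LN2, K=int(K), w=0.05), gamma=g
            )
            quad_var = variance_from_spectrum(lc, noise)
            closed = small_gamma_variance(lc, g, K, D2=d2)
            assert closed == pytest.approx(quad_var, rel=0.10)


class TestSynchronyThreshold:
    def test_designed_set_threshold(self, s05):
        lc = linear_coeffs(s05)
        th = synchrony_threshold(lc)
        assert th.c == pytest.approx(39.455, abs=5e-3)
        assert th.w_c == pytest.approx(0.22, abs=5e-3)
        assert th.gamma_c == pytest.approx(2 / math.sqrt(th.c), rel=1e-12)

    def test_undefined_for_nonoscillatory_coeffs(self):
        from quasisync.core import LinearCoeffs

        flat = LinearCoeffs(a_AB=0.1, a_BB=-2.0, a_BA=-0.1)
        with pytest.raises(ValueError):
            synchrony_threshold(flat)


class TestColouredTwoPeakStructure:
    def test_detuned_vs_resonant_peak_count(self, s05):
        """With replication detuned from the natural frequency (b = 0.9) the
        linearized spectrum shows a sharp replication peak and a broad
        natural-frequency peak; in resonance (b = 0.7) they merge."""
        f = np.linspace(0.4, 2.2, 4000)
        omega = 2 * math.pi * f

        def n_peaks(b):
            p = s05.with_(b=b, w=0.08, K=100_000)
            s = linear_spectrum_yA(omega, linear_coeffs(p),
                                   coloured_noise_spectra(p))
            pk, _ = signal.find_peaks(s, prominence=0.02 * s.max())
            return len(pk)

        assert n_peaks(0.9) == 2
        assert n_peaks(0.7) == 1
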