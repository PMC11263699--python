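"""Estimation layer: coefficient of variation, smoothed periodograms,
oscillation decay-rate fitting, extinction statistics and parameter scans.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import NonCoexistenceError, steady_state
from .engine import TimeSeries, simulate, simulate_single_species
from .params import ModelParams, SingleSpeciesParams
from .theory import decay_rate_gamma


def steady_state_init(params: ModelParams) -> tuple[int, int]:
    """Initial counts at the mean-field fixed point (rounded).

    Stationary-fluctuation and extinction measurements start here: away from
    ``b = 1`` the transient from a generic start (e.g. 0.2 K per species)
    passes through population minima far below the fixed point and can wipe
    out a species before the stationary regime is reached.
    """
    ss = steady_state(params)
    if not ss.coexists:
        raise NonCoexistenceError("no coexistence fixed point to start from")
    return (int(round(ss.x_A * params.K)), int(round(ss.x_B * params.K)))


def default_burn_in(
    params: ModelParams | SingleSpeciesParams, t_max: float
) -> float:
    """Default discard window: ``max(0.2 t_max, 20/gamma)`` for
    quasi-synchronous runs (the timer-phase distribution equilibrates on the
    ``1/gamma`` timescale), ``0.2 t_max`` for the Poisson model."""
    if params.replication_dist == "uniform" and params.w > 0:
        return max(0.2 * t_max, 20.0 / decay_rate_gamma(params.w, params.T))
    return 0.2 * t_max


def _post_burn_in(series: TimeSeries, burn_in_fraction: float) -> np.ndarray:
    if not 0 <= burn_in_fraction < 1:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    start = int(math.floor(burn_in_fraction * len(series.t)))
    return series.counts[start:]


def coefficient_of_variation(
    series: TimeSeries,
    burn_in_fraction: float = 0.2,
    species: int = 0,
) -> float:
    """Std/mean of the species' counts over the post-burn-in window.

    Returns NaN for an extinct (zero-mean) window. Requires at least 100
    post-burn-in samples.
    """
    window = _post_burn_in(series, burn_in_fraction)[:, species]
    if len(window) < 100:
        raise ValueError(
            f"only {len(window)} samples after burn-in; need >= 100"
        )
    mean = window.mean()
    if mean == 0:
        return math.nan
    return float(window.std() / mean)


@dataclass(frozen=True)
class SpectrumEstimate:
    """Smoothed one-sided periodogram of a population time series.

    ``power`` integrates (trapezoid in ``frequency``) to the series variance
    before smoothing (``raw_power``), per the package-wide convention.
    """

    frequency: np.ndarray
    power: np.ndarray
    raw_power: np.ndarray
    smoothing_window: int
    n_samples: int
    dt_sample: float

    def peak(self, f_min: float = 0.0, f_max: float = math.inf
             ) -> tuple[float, float]:
        """(frequency, power) of the highest smoothed-spectrum point in
        [f_min, f_max]."""
        mask = (self.frequency >= f_min) & (self.frequency <= f_max)
        if not mask.any():
            raise ValueError("no frequencies in the requested band")
        idx = np.argmax(np.where(mask, self.power, -np.inf))
        return float(self.frequency[idx]), float(self.power[idx])


def periodogram(
    series: TimeSeries,
    smoothing_window: int | None = None,
    species: int = 0,
    burn_in_fraction: float = 0.0,
) -> SpectrumEstimate:
    """Mean-removed periodogram with moving-average smoothing.

    The density normalisation makes ``sum(raw_power) * df ~= Var(N)``.
    ``smoothing_window`` defaults to 1% of the spectral grid (odd, >= 1).
    """
    x = _post_burn_in(series, burn_in_fraction)[:, species].astype(float)
    fs = 1.0 / series.dt_sample
    freq, power = signal.periodogram(x, fs=fs, detrend="constant",
                                     scaling="density")
    freq, power = freq[1:], power[1:]  # drop the f=0 bin
    if smoothing_window is None:
        smoothing_window = max(1, int(round(0.01 * len(freq))))
    if smoothing_window % 2 == 0:
        smoothing_window += 1
    if smoothing_window > len(freq):
        raise ValueError("series too short for the smoothing window")
    if smoothing_window > 1:
        kernel = np.full(smoothing_window, 1.0 / smoothing_window)
        smoothed = np.convolve(power, kernel, mode="same")
    else:
        smoothed = power.copy()
    return SpectrumEstimate(
        frequency=freq,
        power=smoothed,
        raw_power=power,
        smoothing_window=smoothing_window,
        n_samples=len(x),
        dt_sample=series.dt_sample,
    )


@dataclass(frozen=True)
class DecayFit:
    """Result of an oscillation-envelope decay fit."""

    gamma: float
    f_peak: float
    t_window: tuple[float, float]
    r_squared: float


def fit_decay_rate(
    series: TimeSeries,
    f0_hint: float,
    species: int = 0,
    band: tuple[float, float] = (0.5, 1.5),
) -> DecayFit:
    """Exponential decay rate of oscillations near ``f0_hint``.

    Band-passes the series around the hint (relative band ``band * f0``),
    extracts the analytic-signal envelope and fits the log-envelope slope on
    the decaying segment (from after the filter transient down to where the
    envelope approaches the noise floor). Raises if no spectral peak is
    detectable near the hint.
    """
    x = series.counts[:, species].astype(float)
    x = x - x.mean()
    fs = 1.0 / series.dt_sample
    lo, hi = band[0] * f0_hint, band[1] * f0_hint
    if hi >= fs / 2:
        raise ValueError("f0_hint too close to the Nyquist frequency")

    spec = periodogram(series, species=species)
    in_band = (spec.frequency >= lo) & (spec.frequency <= hi)
    if not in_band.any() or (
        spec.power[in_band].max() < 3.0 * np.median(spec.power)
    ):
        raise ValueError(f"no detectable spectral peak near f = {f0_hint}")
    f_peak = float(spec.frequency[in_band][np.argmax(spec.power[in_band])])

    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    env = np.abs(signal.hilbert(bp))
    # smooth the envelope over ~2 oscillation periods
    win = max(3, int(round(2.0 / f0_hint / series.dt_sample)))
    env = np.convolve(env, np.full(win, 1.0 / win), mode="same")

    dt = series.dt_sample
    i0 = int(round(3.0 / f0_hint / dt))  # skip the filter transient
    if i0 >= len(env) - 10:
        raise ValueError("series too short for a decay fit")
    floor = np.median(env[int(0.8 * len(env)):])
    e0 = env[i0]
    # fit only the clean decay segment: near the noise floor the analytic
    # envelope of signal+noise no longer tracks the coherent amplitude
    stop_level = max(3.0 * floor, e0 * math.exp(-2.0))
    below = np.nonzero(env[i0:] < stop_level)[0]
    i1 = i0 + int(below[0]) if len(below) else len(env) - win
    if i1 - i0 < 10:
        i1 = min(i0 + max(10, (len(env) - i0) // 2), len(env) - 1)
    seg = np.log(np.clip(env[i0:i1], 1e-300, None))
    t_seg = series.t[i0:i1]
    slope, intercept = np.polyfit(t_seg, seg, 1)
    resid = seg - (slope * t_seg + intercept)
    ss_tot = np.sum((seg - seg.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / ss_tot) if ss_tot > 0 else 0.0
    return DecayFit(
        gamma=float(-slope),
        f_peak=f_peak,
        t_window=(float(series.t[i0]), float(series.t[i1 - 1])),
        r_squared=r2,
    )


def fit_decay_rate_hwhm(
    series: TimeSeries,
    f0_hint: float,
    species: int = 0,
    band: tuple[float, float] = (0.7, 1.3),
    smoothing_window: int | None = None,
) -> float:
    """Cross-check estimator: half-width at half-maximum (in angular
    frequency) of the smoothed spectral peak near ``f0_hint``.

    Choose ``smoothing_window`` narrower than the expected peak width; the
    default (1% of the grid) is too coarse for very sharp peaks.
    """
    spec = periodogram(series, species=species,
                       smoothing_window=smoothing_window)
    lo, hi = band[0] * f0_hint, band[1] * f0_hint
    mask = (spec.frequency >= lo) & (spec.frequency <= hi)
    if not mask.any():
        raise ValueError("no frequencies near the hint")
    f_band = spec.frequency[mask]
    p_band = spec.power[mask]
    ipk = int(np.argmax(p_band))
    half = p_band[ipk] / 2.0
    left = np.nonzero(p_band[:ipk] < half)[0]
    right = np.nonzero(p_band[ipk:] < half)[0]
    if not len(left) or not len(right):
        raise ValueError("peak half-width not resolved in the band")
    f_lo = f_band[left[-1]]
    f_hi = f_band[ipk + right[0]]
    return float(math.pi * (f_hi - f_lo))  # HWHM in omega = 2pi * FWHM_f / 2


@dataclass(frozen=True)
class ExtinctionResult:
    """Monte-Carlo extinction statistics over replicate runs.

    ``mean_time_to_extinction`` averages the non-censored (extinct within
    ``t_max``) replicates only; with finite ``t_max`` it is biased towards
    lower values, so the censoring count is reported alongside.
    """

    n_reps: int
    n_extinct: int
    probability: float
    mean_time_to_extinction: float | None
    censored: int
    extinct_species: tuple[str, ...]
    times: tuple[float, ...]


def _replicate_seed(master: int, index: int) -> int:
    """Counter-based per-replicate seed: extending the replicate set never
    reshuffles earlier replicates."""
    return int(
        np.random.SeedSequence([master, index]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def extinction_stats(
    params: ModelParams,
    n_reps: int,
    t_max: float,
    rng_seed: int = 0,
    sample_every: int = 512,
    init=None,
) -> ExtinctionResult:
    """First-passage statistics of either species hitting zero within
    ``t_max`` (an extinction event destroys coexistence even though the
    other species persists)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if init is None:
        init = steady_state_init(params)
    times: list[float] = []
    species: list[str] = []
    n_extinct = 0
    for i in range(n_reps):
        ts = simulate(
            params,
            t_max,
            sample_every=sample_every,
            init=init,
            rng_seed=_replicate_seed(rng_seed, i),
        )
        if ts.status != "completed":
            n_extinct += 1
            times.append(ts.meta["t_end"])
            species.append(ts.status.removeprefix("extinct_"))
    return ExtinctionResult(
        n_reps=n_reps,
        n_extinct=n_extinct,
        probability=n_extinct / n_reps,
        mean_time_to_extinction=(
            float(np.mean(times)) if times else None
        ),
        censored=n_reps - n_extinct,
        extinct_species=tuple(species),
        times=tuple(times),
    )


_SCAN_AXES = ("b", "K", "w")
_SCAN_METRICS = ("cv", "spectrum_peak", "extinction")


def scan(
    params_base: ModelParams,
    axis: str,
    values,
    metric: str = "cv",
    n_reps: int = 2,
    rng_seed: int = 0,
    t_max: float = 2500.0,
    burn_in: float | None = None,
    sample_every: int = 8,
) -> pd.DataFrame:
    """Sweep one model axis and estimate a fluctuation metric per value.

    Returns one row per value with the replicate mean, standard error and
    the seeds used. ``burn_in`` (time units, defaults to ``0.4 * t_max``) is
    discarded before computing cv/spectrum metrics.
    """
    if axis not in _SCAN_AXES:
        raise ValueError(f"axis must be one of {_SCAN_AXES}")
    if metric not in _SCAN_METRICS:
        raise ValueError(f"metric must be one of {_SCAN_METRICS}")
    values = list(values)
    if not values:
        raise ValueError("values must be non-empty")
    if burn_in is None:
        burn_in = 0.4 * t_max
    frac = burn_in / t_max
    rows = []
    for j, v in enumerate(values):
        params = params_base.with_(**{axis: int(v) if axis == "K" else v})
        estimates = []
        seeds = []
        for r in range(n_reps):
            seed = _replicate_seed(rng_seed, j * 10_000 + r)
            seeds.append(seed)
            if metric == "extinction":
                res = extinction_stats(params, 1, t_max, rng_seed=seed)
                estimates.append(res.probability)
                continue
            ts = simulate(params, t_max, sample_every=sample_every,
                          rng_seed=seed, init=steady_state_init(params))
            if metric == "cv":
                estimates.append(coefficient_of_variation(ts, frac))
            else:
                spec = periodogram(ts, burn_in_fraction=frac)
                estimates.append(spec.peak(0.2, 3.0)[1])
        est = np.asarray(estimates, dtype=float)
        rows.append(
            {
                axis: v,
                "metric": metric,
                "mean": float(np.nanmean(est)),
                "se": float(np.nanstd(est, ddof=1) / math.sqrt(len(est)))
                if len(est) > 1
                else math.nan,
                "n_reps": n_reps,
                "seeds": tuple(seeds),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["params_base"] = params_base.to_dict()
    df.attrs["master_seed"] = rng_seed
    df.attrs["t_max"] = t_max
    df.attrs["burn_in"] = burn_in
    return df
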