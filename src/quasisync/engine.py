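"""Stochastic simulation engine for the timer-based birth / state-dependent
death models (two-species predator-prey and single-species logistic).

The engine advances a fixed timestep ``dt`` (default 1/512). Timers live on
the ``dt`` grid: a fresh replication time ``tau`` drawn from the continuous
distribution is rounded to the nearest grid point, so the binned state is a
histogram with per-step cost independent of the population size. The grid
error is at most ``dt/2``, far below the width ``w T`` of the uniform
distribution for the default ``dt``.

An agent-level reference implementation (one record per cell) lives in
``quasisync.reference`` and is used as an independent cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from . import _kernels
from .params import ModelParams, SingleSpeciesParams

DEFAULT_DT = 1.0 / 512.0
DEFAULT_SAMPLE_EVERY = 8
#: Refuse to build initial populations above this size (memory cap).
MAX_INIT_CELLS = 200_000_000

_STATUS_TWO = {
    _kernels.STATUS_OK: "completed",
    _kernels.STATUS_EXTINCT_A: "extinct_A",
    _kernels.STATUS_EXTINCT_B: "extinct_B",
    _kernels.STATUS_EXTINCT_BOTH: "extinct_both",
}
_STATUS_ONE = {
    _kernels.STATUS_OK: "completed",
    _kernels.STATUS_EXTINCT_A: "extinct",
}


def timer_window(
    params: ModelParams | SingleSpeciesParams, dt: float
) -> tuple[int, np.ndarray, int]:
    """Newborn placement window on the timer grid.

    Returns ``(win0, probs, n_bins)``: after the per-step shift a newborn
    whose continuous timer rounds to ``j`` grid units is placed at index
    ``j - 1``; ``probs[i]`` is the probability of index ``win0 + i``.
    ``n_bins`` is the histogram length needed for the model. For the
    exponential distribution newborns enter the memoryless pool instead and
    the window is a placeholder.
    """
    T = params.T
    if params.replication_dist == "exponential":
        n_bins = int(round(T / dt)) + 1
        return 0, np.array([1.0]), n_bins
    lo = T * (1.0 - params.w)
    hi = T * (1.0 + params.w)
    jlo = max(int(round(lo / dt)), 1)
    jhi = max(int(round(hi / dt)), jlo)
    if jhi == jlo:
        probs = np.array([1.0])
    else:
        edges_lo = (np.arange(jlo, jhi + 1) - 0.5) * dt
        edges_hi = edges_lo + dt
        overlap = np.minimum(edges_hi, hi) - np.maximum(edges_lo, lo)
        probs = np.clip(overlap, 0.0, None)
        probs /= probs.sum()
    n_bins = jhi + 1
    return jlo - 1, probs, n_bins


@dataclass
class PopulationState:
    """Per-species timer-bin occupancy plus memoryless pools at one time.

    ``counts[s][k]`` is the number of cells of species ``s`` dividing after
    ``k`` more steps; ``pools[s]`` holds exponential-distribution cells born
    during the run (their division times are memoryless, so no bin is
    needed).
    """

    counts: tuple[np.ndarray, ...]
    pools: np.ndarray
    time: float
    dt: float

    @property
    def totals(self) -> tuple[int, ...]:
        return tuple(
            int(c.sum()) + int(p) for c, p in zip(self.counts, self.pools)
        )

    def copy(self) -> "PopulationState":
        return PopulationState(
            counts=tuple(c.copy() for c in self.counts),
            pools=self.pools.copy(),
            time=self.time,
            dt=self.dt,
        )


@dataclass
class TimeSeries:
    """Sampled population counts with uniform spacing and run metadata."""

    t: np.ndarray
    counts: np.ndarray  # shape (n_samples, n_species)
    meta: dict[str, Any]
    final_state: PopulationState | None = field(default=None, repr=False)

    @property
    def n_species(self) -> int:
        return self.counts.shape[1]

    @property
    def n_A(self) -> np.ndarray:
        return self.counts[:, 0]

    @property
    def n_B(self) -> np.ndarray:
        return self.counts[:, 1]

    @property
    def n(self) -> np.ndarray:
        """Counts of the only species (single-species series)."""
        if self.n_species != 1:
            raise ValueError("n is defined for single-species series only")
        return self.counts[:, 0]

    @property
    def dt_sample(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    @property
    def status(self) -> str:
        return self.meta.get("status", "completed")

    def to_frame(self):
        import pandas as pd

        cols = {"t": self.t}
        names = ["N_A", "N_B"] if self.n_species == 2 else ["N"]
        for i, name in enumerate(names):
            cols[name] = self.counts[:, i]
        return pd.DataFrame(cols)


def _init_bins(
    n0: int,
    n_bins: int,
    T: float,
    dt: float,
    init_mode: str,
    rng: np.random.Generator,
) -> np.ndarray:
    counts = np.zeros(n_bins, dtype=np.int64)
    if n0 == 0:
        return counts
    if init_mode == "uniform_timers":
        # independent timers uniform on [0, T), rounded to the grid
        bins = np.rint(rng.uniform(0.0, T, size=n0) / dt).astype(np.int64)
        np.clip(bins, 0, n_bins - 1, out=bins)
        counts += np.bincount(bins, minlength=n_bins)
    elif init_mode == "synchronized":
        counts[min(int(round(T / dt)), n_bins - 1)] = n0
    else:
        raise ValueError(f"unknown init_mode {init_mode!r}")
    return counts


def init_population(
    n0: Sequence[int],
    params: ModelParams | SingleSpeciesParams,
    dt: float = DEFAULT_DT,
    init_mode: str = "uniform_timers",
    rng_seed: int | np.random.Generator = 0,
) -> PopulationState:
    """Build an initial population state.

    ``init_mode="uniform_timers"`` assigns each cell an independent timer
    uniform on ``[0, T)`` (the fully desynchronised start);
    ``"synchronized"`` puts every cell at timer ``T`` (used for
    synchrony-decay experiments). Resuming a saved state is done by passing
    the ``PopulationState`` itself to ``simulate``.
    """
    if any(n < 0 for n in n0):
        raise ValueError("initial counts must be non-negative")
    if sum(int(n) for n in n0) > MAX_INIT_CELLS:
        raise MemoryError(f"initial population exceeds cap {MAX_INIT_CELLS}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    _, _, n_bins = timer_window(params, dt)
    counts = tuple(
        _init_bins(int(n), n_bins, params.T, dt, init_mode, rng) for n in n0
    )
    return PopulationState(
        counts=counts,
        pools=np.zeros(len(counts), dtype=np.int64),
        time=0.0,
        dt=dt,
    )


def _kernel_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1, dtype=np.uint32)[0])


def _pdiv(params: ModelParams | SingleSpeciesParams, dt: float) -> float:
    if params.replication_dist == "uniform":
        return -1.0
    return 1.0 - math.exp(-params.division_hazard * dt)


def step(
    state: PopulationState,
    params: ModelParams,
    rng_seed: int = 0,
) -> PopulationState:
    """Advance a two-species state by a single step ``dt`` (new state
    returned; the input is not modified)."""
    new = state.copy()
    win0, probs, _ = timer_window(params, state.dt)
    out = np.empty(2, dtype=np.int64)
    status, _, _, n_clamped = _kernels.run_two_species(
        new.counts[0],
        new.counts[1],
        new.pools,
        params.K,
        params.p1,
        params.p2,
        params.p3,
        params.p4,
        state.dt,
        _pdiv(params, state.dt),
        win0,
        probs,
        1,
        1,
        out,
        out.copy(),
        _kernel_seed(np.random.SeedSequence(rng_seed)),
    )
    if n_clamped:
        warnings.warn("death probability clamped to 1 (rate out of regime)")
    new.time = state.time + state.dt
    return new


def _run_meta(params, dt, sample_every, rng_seed, init_mode, status, steps_done):
    return {
        "params": params.to_dict(),
        "dt": dt,
        "sample_every": sample_every,
        "seed": rng_seed,
        "init_mode": init_mode,
        "status": status,
        "t_end": steps_done * dt,
    }


def simulate(
    params: ModelParams,
    t_max: float,
    sample_every: int = DEFAULT_SAMPLE_EVERY,
    init: Sequence[int] | PopulationState | None = None,
    rng_seed: int = 0,
    dt: float = DEFAULT_DT,
    init_mode: str = "uniform_timers",
) -> TimeSeries:
    """Simulate the two-species model up to ``t_max``.

    ``init`` may be a pair of initial counts (default ``(0.2 K, 0.2 K)``), or
    a saved :class:`PopulationState` to resume. The run terminates early with
    status ``"extinct_A"``/``"extinct_B"`` when a species hits zero.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    seq = np.random.SeedSequence(rng_seed)
    init_seq, kernel_seq = seq.spawn(2)
    if isinstance(init, PopulationState):
        state = init.copy()
        dt = state.dt
        mode = "from_state"
    else:
        if init is None:
            init = (int(round(0.2 * params.K)), int(round(0.2 * params.K)))
        state = init_population(
            init, params, dt, init_mode, np.random.default_rng(init_seq)
        )
        mode = init_mode
    nsteps = int(round(t_max / dt))
    nbuf = nsteps // sample_every + 1
    out_na = np.zeros(nbuf, dtype=np.int64)
    out_nb = np.zeros(nbuf, dtype=np.int64)
    win0, probs, _ = timer_window(params, dt)
    status, steps_done, nsamp, n_clamped = _kernels.run_two_species(
        state.counts[0],
        state.counts[1],
        state.pools,
        params.K,
        params.p1,
        params.p2,
        params.p3,
        params.p4,
        dt,
        _pdiv(params, dt),
        win0,
        probs,
        nsteps,
        sample_every,
        out_na,
        out_nb,
        _kernel_seed(kernel_seq),
    )
    if n_clamped:
        warnings.warn(
            f"death probability clamped to 1 in {n_clamped} steps "
            "(rates out of the intended regime)"
        )
    t0 = state.time
    state.time += steps_done * dt
    t = t0 + np.arange(nsamp) * sample_every * dt
    counts = np.stack([out_na[:nsamp], out_nb[:nsamp]], axis=1)
    meta = _run_meta(params, dt, sample_every, rng_seed, mode,
                     _STATUS_TWO[status], steps_done)
    meta["t_start"] = t0
    return TimeSeries(t=t, counts=counts, meta=meta, final_state=state)


def simulate_single_species(
    params: SingleSpeciesParams,
    t_max: float,
    sample_every: int = DEFAULT_SAMPLE_EVERY,
    init: int | PopulationState | None = None,
    rng_seed: int = 0,
    dt: float = DEFAULT_DT,
    init_mode: str = "uniform_timers",
) -> TimeSeries:
    """Simulate the single-species logistic timer model (death rate
    ``b N / K``). ``init`` defaults to ``K`` cells."""
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    seq = np.random.SeedSequence(rng_seed)
    init_seq, kernel_seq = seq.spawn(2)
    if isinstance(init, PopulationState):
        state = init.copy()
        dt = state.dt
        mode = "from_state"
    else:
        n0 = params.K if init is None else int(init)
        state = init_population(
            (n0,), params, dt, init_mode, np.random.default_rng(init_seq)
        )
        mode = init_mode
    nsteps = int(round(t_max / dt))
    nbuf = nsteps // sample_every + 1
    out_n = np.zeros(nbuf, dtype=np.int64)
    win0, probs, _ = timer_window(params, dt)
    status, steps_done, nsamp, n_clamped = _kernels.run_single_species(
        state.counts[0],
        state.pools,
        params.b,
        params.K,
        dt,
        _pdiv(params, dt),
        win0,
        probs,
        nsteps,
        sample_every,
        out_n,
        _kernel_seed(kernel_seq),
    )
    if n_clamped:
        warnings.warn("death probability clamped to 1 (rates out of regime)")
    t0 = state.time
    state.time += steps_done * dt
    t = t0 + np.arange(nsamp) * sample_every * dt
    meta = _run_meta(params, dt, sample_every, rng_seed, mode,
                     _STATUS_ONE[status], steps_done)
    meta["t_start"] = t0
    return TimeSeries(
        t=t, counts=out_n[:nsamp, None].copy(), meta=meta, final_state=state
    )
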