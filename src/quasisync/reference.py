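"""Agent-level reference implementation of the timer model.

Every cell is an explicit record (integer steps-to-division). This is the
slow but transparent counterpart of the binned histogram engine and shares
its grid convention, so the two implementations are distributionally
equivalent and cross-checked in the test suite. Intended for small
populations only.
"""

from __future__ import annotations

import numpy as np

from .engine import DEFAULT_DT
from .params import ModelParams, SingleSpeciesParams


def _fresh_timers(
    n: int,
    params: ModelParams | SingleSpeciesParams,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Steps-to-division for n newborn cells (post-shift convention: a cell
    whose timer rounds to j grid units is recorded as j - 1)."""
    if params.replication_dist == "exponential":
        tau = rng.exponential(1.0 / params.division_hazard, size=n)
        return np.maximum(np.ceil(tau / dt).astype(np.int64), 1) - 1
    T = params.T
    tau = rng.uniform(T * (1.0 - params.w), T * (1.0 + params.w), size=n)
    return np.maximum(np.rint(tau / dt).astype(np.int64), 1) - 1


def _init_timers(
    n0: int,
    params: ModelParams | SingleSpeciesParams,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    tau = rng.uniform(0.0, params.T, size=n0)
    return np.rint(tau / dt).astype(np.int64)


def agent_simulate(
    params: ModelParams,
    n_steps: int,
    init: tuple[int, int],
    dt: float = DEFAULT_DT,
    rng_seed: int = 0,
    sample_every: int = 1,
) -> np.ndarray:
    """Run the two-species model with per-agent bookkeeping.

    Returns sampled counts, shape ``(n_samples, 2)``. Deaths follow the same
    law as the binned engine: Binomial(N, clamp(d*dt,0,1)) victims per
    species, chosen uniformly at random (here: without replacement among
    explicit cells).
    """
    rng = np.random.default_rng(rng_seed)
    timers = [
        _init_timers(init[0], params, dt, rng),
        _init_timers(init[1], params, dt, rng),
    ]
    samples = []
    for s in range(n_steps):
        if s % sample_every == 0:
            samples.append((len(timers[0]), len(timers[1])))
        for i in (0, 1):
            t = timers[i]
            dividing = t == 0
            m = int(dividing.sum())
            t = t[~dividing] - 1
            if m:
                t = np.concatenate([t, _fresh_timers(2 * m, params, dt, rng)])
            timers[i] = t
        NA, NB = len(timers[0]), len(timers[1])
        xA, xB = NA / params.K, NB / params.K
        rates = (
            max(params.p2 - params.p1 * xB, 0.0),
            max(params.p4 * xA - params.p3 * (1.0 - xB), 0.0),
        )
        for i, rate in enumerate(rates):
            n = len(timers[i])
            p = min(rate * dt, 1.0)
            if n == 0 or p <= 0.0:
                continue
            d = rng.binomial(n, p)
            if d:
                keep = np.ones(n, dtype=bool)
                keep[rng.choice(n, size=d, replace=False)] = False
                timers[i] = timers[i][keep]
        if len(timers[0]) == 0 or len(timers[1]) == 0:
            break
    if n_steps % sample_every == 0:
        samples.append((len(timers[0]), len(timers[1])))
    return np.array(samples, dtype=np.int64)


def agent_simulate_single(
    params: SingleSpeciesParams,
    n_steps: int,
    init: int,
    dt: float = DEFAULT_DT,
    rng_seed: int = 0,
    sample_every: int = 1,
) -> np.ndarray:
    """Single-species agent-level run (death rate ``b N / K``)."""
    rng = np.random.default_rng(rng_seed)
    timers = _init_timers(init, params, dt, rng)
    samples = []
    for s in range(n_steps):
        if s % sample_every == 0:
            samples.append(len(timers))
        dividing = timers == 0
        m = int(dividing.sum())
        timers = timers[~dividing] - 1
        if m:
            timers = np.concatenate(
                [timers, _fresh_timers(2 * m, params, dt, rng)]
            )
        n = len(timers)
        p = min(params.b * (n / params.K) * dt, 1.0)
        if n and p > 0:
            d = rng.binomial(n, p)
            if d:
                keep = np.ones(n, dtype=bool)
                keep[rng.choice(n, size=d, replace=False)] = False
                timers = timers[keep]
        if len(timers) == 0:
            break
    if n_steps % sample_every == 0:
        samples.append(len(timers))
    return np.array(samples, dtype=np.int64)
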