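"""Numba kernels for the fixed-timestep binned simulation engine.

State per species is a histogram over timer bins of width ``dt``:
``counts[k]`` holds the number of cells that divide after ``k`` more steps.
For the exponential (Poisson) replication distribution, cells born during
the run live in a memoryless scalar "pool" (per-step division probability
``1 - exp(-hazard*dt)``); only the initial cohort occupies bins.

Step order (fixed for reproducibility): advance timers, divide, then kill.
Deaths follow the printed fixed-step algorithm: the number of deaths is a
single Binomial(N, clamp(d*dt, 0, 1)) draw per species, with the victims
assigned uniformly at random across cells. The assignment is done by
sweeping ordered uniform positions (generated via exponential spacings)
across the cumulative histogram, which costs O(deaths) random draws per
step instead of O(bins).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_EXTINCT_A = 1
STATUS_EXTINCT_B = 2
STATUS_EXTINCT_BOTH = 3


@njit(cache=True)
def _seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _remove_deaths(counts, pool, n_total, p):
    """Kill Binomial(n_total, p) cells chosen uniformly at random.

    ``counts`` is mutated in place; the memoryless pool is the last virtual
    bin. Returns (total removed, removed from pool). If a bin's allotment
    exceeds its occupancy (possible because positions sample cells with
    replacement), the excess is carried to the next occupied bin.
    """
    D = np.random.binomial(n_total, p)
    if D == 0:
        return 0, 0
    if D >= n_total:
        counts[:] = 0
        return n_total, pool
    pos = np.empty(D)
    s = 0.0
    for i in range(D):
        s -= np.log(1.0 - np.random.random())
        pos[i] = s
    s -= np.log(1.0 - np.random.random())
    scale = n_total / s
    cum = 0.0
    k = 0
    carry = 0
    removed = 0
    for i in range(counts.size):
        c = counts[i]
        if c > 0 or carry > 0:
            cum += c
            d = carry
            carry = 0
            while k < D and pos[k] * scale < cum:
                d += 1
                k += 1
            if d > c:
                carry = d - c
                d = c
            if d > 0:
                counts[i] = c - d
                removed += d
            if k >= D and carry == 0:
                break
        else:
            cum += c
    d_pool = (D - k) + carry
    if d_pool > pool:
        d_pool = pool
    removed += d_pool
    return removed, d_pool


@njit(cache=True)
def _advance_and_divide(counts, pool, pdiv, win0, win_probs):
    """Advance timers one step and perform divisions for one species.

    Returns (net population change, new pool). In uniform (binned) mode
    ``pdiv < 0`` and dividing cells place two daughters in the fresh-timer
    window; in exponential mode bin dividers re-enter the pool (two cells)
    and the pool itself divides with probability ``pdiv`` per cell.
    """
    m = counts[0]
    if m > 0 or counts.size > 0:
        for i in range(counts.size - 1):
            counts[i] = counts[i + 1]
        counts[counts.size - 1] = 0
    if pdiv < 0.0:
        if m > 0:
            born = np.random.multinomial(2 * m, win_probs)
            for j in range(born.size):
                counts[win0 + j] += born[j]
        return m, pool
    # exponential: dividing cohort cells and their daughters join the pool
    pool += 2 * m
    mp = 0
    if pool > 0 and pdiv > 0.0:
        mp = np.random.binomial(pool, pdiv)
        pool += mp
    return m + mp, pool


@njit(cache=True)
def run_two_species(
    counts_a,
    counts_b,
    pools,
    K,
    p1,
    p2,
    p3,
    p4,
    dt,
    pdiv,
    win0,
    win_probs,
    nsteps,
    sample_every,
    out_na,
    out_nb,
    seed,
):
    """Advance the two-species model ``nsteps`` steps, sampling every
    ``sample_every`` steps into ``out_na``/``out_nb``.

    Returns (status, steps_done, n_samples, n_clamped) where ``n_clamped``
    counts steps where a death probability had to be clamped to 1.
    """
    np.random.seed(seed)
    NA = counts_a.sum() + pools[0]
    NB = counts_b.sum() + pools[1]
    Kf = float(K)
    nsamp = 0
    n_clamped = 0
    status = STATUS_OK
    steps_done = 0
    for s in range(nsteps):
        if s % sample_every == 0:
            out_na[nsamp] = NA
            out_nb[nsamp] = NB
            nsamp += 1
        dA, pools[0] = _advance_and_divide(counts_a, pools[0], pdiv, win0, win_probs)
        NA += dA
        dB, pools[1] = _advance_and_divide(counts_b, pools[1], pdiv, win0, win_probs)
        NB += dB
        xA = NA / Kf
        xB = NB / Kf
        rate_a = p2 - p1 * xB
        if rate_a < 0.0:
            rate_a = 0.0
        rate_b = p4 * xA - p3 * (1.0 - xB)
        if rate_b < 0.0:
            rate_b = 0.0
        pa = rate_a * dt
        pb = rate_b * dt
        if pa > 1.0 or pb > 1.0:
            n_clamped += 1
            if pa > 1.0:
                pa = 1.0
            if pb > 1.0:
                pb = 1.0
        if pa > 0.0 and NA > 0:
            rem, dp = _remove_deaths(counts_a, pools[0], NA, pa)
            pools[0] -= dp
            NA -= rem
        if pb > 0.0 and NB > 0:
            rem, dp = _remove_deaths(counts_b, pools[1], NB, pb)
            pools[1] -= dp
            NB -= rem
        steps_done = s + 1
        if NA <= 0 or NB <= 0:
            if NA <= 0 and NB <= 0:
                status = STATUS_EXTINCT_BOTH
            elif NA <= 0:
                status = STATUS_EXTINCT_A
            else:
                status = STATUS_EXTINCT_B
            break
    if status == STATUS_OK and nsteps % sample_every == 0:
        out_na[nsamp] = NA
        out_nb[nsamp] = NB
        nsamp += 1
    return status, steps_done, nsamp, n_clamped


@njit(cache=True)
def run_single_species(
    counts,
    pool_arr,
    b,
    K,
    dt,
    pdiv,
    win0,
    win_probs,
    nsteps,
    sample_every,
    out_n,
    seed,
):
    """Advance the single-species logistic timer model (per-capita death
    rate ``b N / K``). Same contract as ``run_two_species``."""
    np.random.seed(seed)
    N = counts.sum() + pool_arr[0]
    Kf = float(K)
    nsamp = 0
    n_clamped = 0
    status = STATUS_OK
    steps_done = 0
    for s in range(nsteps):
        if s % sample_every == 0:
            out_n[nsamp] = N
            nsamp += 1
        dN, pool_arr[0] = _advance_and_divide(
            counts, pool_arr[0], pdiv, win0, win_probs
        )
        N += dN
        p = b * (N / Kf) * dt
        if p > 1.0:
            p = 1.0
            n_clamped += 1
        if p > 0.0 and N > 0:
            rem, dp = _remove_deaths(counts, pool_arr[0], N, p)
            pool_arr[0] -= dp
            N -= rem
        steps_done = s + 1
        if N <= 0:
            status = STATUS_EXTINCT_A
            break
    if status == STATUS_OK and nsteps % sample_every == 0:
        out_n[nsamp] = N
        nsamp += 1
    return status, steps_done, nsamp, n_clamped
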