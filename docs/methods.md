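# Methods

## Models

### Two-species timer model

Two well-mixed populations of "cells", A (prey-like) and B (predator-like).
Every cell carries a countdown timer assigned at birth from a replication-time
distribution `R(τ)`; when the timer reaches zero the cell divides and both
resulting cells draw fresh, independent timers. Death is an inhomogeneous
Poisson process with per-capita rates

    d_A = max(p2 − p1 N_B/K, 0)
    d_B = max(p4 N_A/K − p3 (1 − N_B/K), 0)

`K` sets the population scale; the clamp `max(·, 0)` applies to the
per-capita rate itself, in both the stochastic rates and the mean-field
equations. Two replication-time distributions are supported:

* **exponential** (the Poisson model) — the division hazard defaults to the
  mean-field growth rate `b` (`poisson_convention="rate"`), so the mean-field
  limit is identical for both distributions. The alternative convention
  (mean timer equal to the doubling time `T = ln2/b`, hazard `b/ln2`) is
  available as `poisson_convention="mean"`; the two differ because for a
  Markov birth process the growth rate is the reciprocal mean timer, not
  `ln2` over it.
* **uniform** on `(T(1−w), T(1+w))` — quasi-synchronous replication with
  half-width fraction `w`; its variance is `σ₀² = (wT)²/3`.

The mean doubling time is always derived, `T = ln2/b`, never set separately.

Mean field (fractions `x = N/K`):

    dx_A/dt = x_A (b − d_A),   dx_B/dt = x_B (b − d_B)

with interior fixed point `x_A* = ((p1−p2)p3 + b(p1+p3))/(p1 p4)`,
`x_B* = (p2−b)/p1`, Jacobian eigenvalues
`λ± = (b p3 − p2 p3 ± √Δ)/(2p1)`, and linearization coefficients
`a_AB = p1 x_A*`, `a_BB = −p3 x_B*`, `a_BA = −p4 x_B*`. The fixed point is
returned even when a component is non-positive or a clamp activates there;
boolean flags (`coexists`, `interior`) report validity.

### Single-species model

Timer-based replication with mean doubling time `ln2/b`, Poisson death at
per-capita rate `b N/K`: the mean-field limit is logistic with `N* = K`.
This model isolates the character of replication noise.

## Parameter design

With `b = 1` fixing the time scale, candidate sets `{p1..p4}` are screened by
Monte-Carlo sampling of a box (defaults `p1∈(1,100)`, `p2∈(1,50)`,
`p3∈(0.1,10)`, `p4∈(0.5,10)`, chosen to bracket the shipped presets with wide
margin) for oscillation frequency `f0 ∈ (0.98, 1.02)`, damping `< 0.5` and
steady state within `0.5 ± 0.1`; the acceptance fraction of the default box
is ~1e-4, so the screen is evaluated vectorised. Accepted candidates seed a
Hybrid-Powell root finder on the residual
`(x_A*−t₁, x_B*−t₂, f0−t₃, |Re λ|−t₄)`, run in log-parameter space to keep
rates positive. At the standard targets (`f0 = 1`, `x* = (0.5, 0.5)`) the
solution has the closed form `p3 = 4d`, `p4 = p3 + 2b`,
`p1 = (4(2πf0)² + p3²/4)/p4`, `p2 = b + p1/2`, which reproduces the shipped
presets S0.5/S0.2/S0.1 to the two printed decimals and serves as an
independent cross-check of the root finder.

## Stochastic engine

Fixed timestep `dt = 1/512` (configurable; a convergence test at `dt/2` is
part of the suite). Timers live on the `dt` grid: a fresh `τ` is rounded to
the nearest grid point, so the state is a histogram ("binned" engine,
per-step cost independent of `K`). The grid error `≤ dt/2` is negligible
against the distribution width `wT` at the default settings. Step order,
fixed for reproducibility: (1) timers advance; (2) cells at zero divide, the
two daughters drawing fresh timers (uniform case: placed in the fresh-timer
window; exponential case: both enter a memoryless pool with per-step division
probability `1 − exp(−hazard·dt)`); (3) deaths: one draw
`D ~ Binomial(N_s, clamp(d_s dt, 0, 1))` per species, with `d_s` evaluated
from post-division counts, and the `D` victims assigned uniformly at random
across cells. The assignment sweeps `D` ordered uniform positions (generated
by exponential spacings) across the cumulative histogram, costing O(D) random
draws per step; bin-level allocation is multinomial rather than multivariate
hypergeometric (a with-/without-replacement distinction of relative size
`D/N ~ b·dt ≈ 10⁻³` per step), with per-bin overdraw carried to the next
occupied bin. Death probabilities above 1 are clamped and logged as warnings.
`N = 0` is absorbing; runs terminate early with an extinction status naming
the species.

Initial timers for `init_mode="uniform_timers"` are uniform on `[0, T)`
(fully desynchronised; this reproduces the documented transient mismatch
between a freshly initialised stochastic run and the mean-field solution,
which disappears once the timer distribution reaches its quasi-steady
profile). `init_mode="synchronized"` puts all timers at `T` and is used for
synchrony-decay experiments. Per-run randomness comes from one seeded
generator; replicate seeds are derived counter-style (`SeedSequence([master,
index])`) so replicate sets extend without reshuffling.

An agent-level reference implementation (`quasisync.reference`) keeps one
integer steps-to-division per cell with the same grid convention and
without-replacement death sampling; the test suite checks distributional
equivalence of the two engines (two-sample KS on `(N_A, N_B)` after 1000
steps across replicates).

## Analytics

Spectra use one convention throughout: two-sided density in angular
frequency with `Var = (1/2π)∫S dω`; empirical periodograms are one-sided
densities (`∫S df = Var`, checked to 1% before smoothing), and theory curves
are doubled when overlaid on them.

* **Phase diffusion.** The cell-cycle phase distribution spreads by `σ₀²`
  every generation; a population Fourier mode at angular frequency `ω` is
  attenuated by `exp(−σ²ω²/2)`, giving the decay rate
  `γ = 2π²w²/(3T)` for synchrony-induced oscillations (≈ `9.5 w²` at
  `T = ln2`, `6.580 w²` at `T = 1`).
* **Single-species laws.** `Var(N) ≅ K(0.48 + 0.0125/γ)` and the spectrum
  `K[0.962/(1+ω²) + 0.0231336/((ω−2π/ln2)² + γ²)]` (pinned to `b = 1`; the
  four constants are adopted as given, not re-derived). The two printed
  approximations are mutually consistent at the ~10% level under quadrature,
  which the suite documents as a constant check.
* **Two-species linear response.** The linearized dynamics give the
  fluctuation spectrum of species A (organism units):
  `S_A(ω) = [(a_BB²+ω²)⟨|η_A|²⟩ − 2a_AB a_BB⟨|η_Aη_B|²⟩ + a_AB²⟨|η_B|²⟩] /
  [a_AB²a_BA² + 2a_AB a_BA ω² + a_BB²ω² + ω⁴]`. White (Poisson) noise uses
  `⟨|η_s|²⟩ = 2b N_s*` (= `bK` per species at the designed steady state) and
  zero cross term; the quadrature of `S_A` is validated against the
  stationary Lyapunov covariance and a Euler–Maruyama simulation.
* **Coloured-noise surrogate.** The exact coloured-noise amplitudes for
  quasi-synchronous replication are not re-derived here; instead each
  species' noise is modelled as a white death floor plus a Lorentzian at the
  replication frequency,
  `⟨|η_s|²⟩(ω) = x_s*K [0.962 b + c_L/((|ω|−ω₀)² + γ²)]` with
  `ω₀ = 2π/T` and `c_L = 0.0231336(1+ω₀²)/2` — the single-species spectrum
  constants rescaled to the species' mean abundance, with `(1+ω₀²)` undoing
  the single-species response at the peak and the `1/2` accounting for the
  mirrored negative-frequency Lorentzian (spectra are made even via `|ω|`).
  Both constants are caller-overridable. Because it is a calibrated
  surrogate, two-species coloured predictions are treated as shape/trend
  statements (two-peak vs one-peak structure, `Var ∝ 1/γ ∝ 1/w²` growth, the
  `w_c = 0.55 c^(−1/4)` synchrony threshold), not exact values. The
  small-`γ` closed form's amplitude constant `D2` is self-calibrated against
  the quadrature at `γ = 10⁻³` when not supplied.

## Estimation

* CV = std/mean of post-burn-in counts (≥100 samples required; NaN for an
  extinct window). Default burn-in `max(0.2 t_max, 20/γ)` for
  quasi-synchronous runs, `0.2 t_max` otherwise.
* Periodograms are mean-removed, density-normalised, moving-average smoothed
  (default window 1% of the grid — deliberately coarse; peak-width analyses
  pass an explicit narrower window).
* Decay-rate fitting band-passes around the frequency hint (2nd-order
  Butterworth, `0.5–1.5 f₀`), takes the analytic-signal envelope, smooths it
  over ~2 periods and fits the log-envelope slope between the filter
  transient and the noise floor; a Lorentzian HWHM estimator on the smoothed
  spectrum is provided as a cross-check (choose its smoothing window ≈ half
  the expected peak width; the default grid fraction over-smooths sharp
  peaks).
* Extinction statistics report the first-passage probability to
  `N_A = 0` or `N_B = 0` within `t_max` and the mean time among extinct
  replicates only; censored counts are reported alongside because the
  truncated mean is biased low. No imputation is attempted.

## Experimental protocols and problem sizes

Stationary-fluctuation and extinction experiments **start at the mean-field
fixed point** (rounded to counts). Away from `b = 1` the generic
`(0.2K, 0.2K)` start passes through deterministic minima of
`x_A ~ 10⁻⁷–10⁻⁵` and extinguishes species A at any practical `K`; the
`0.2K` start is kept as the default of `simulate` for transient studies.

Quasi-synchronous runs discard a burn-in of `4/γ` before measuring: the
variance of the quasi-cycle relaxes as `1 − exp(−2γt)`, so `4/γ` leaves
<0.1% bias while keeping the runs tractable (the conservative `20/γ`
default of the observables layer would exceed 10⁴ time units at small `b·w²`).
Scans use a fixed 1000-time-unit burn-in and 1500-unit measurement window
per replicate, two replicates per grid point. The single-species variance
regression uses `w ∈ {0.04 … 0.12}` at `K = 10⁵` with measurement windows of
`max(2000, 60/γ)` time units, two seeds per `w`, and regresses `Var(N)/K` on
`1/γ(w)`. The resonance comparison at `K = 10⁶` uses a 1200-unit window
after the `4/γ` burn-in. These sizes are the package's own choices; larger
windows reduce the (dominant) low-frequency sampling error of variance
estimates roughly as `(γ·T_window)^(−1/2)`.

## Numerical accuracy of the fixed step

The forward-step scheme under-damps resonant modes by an O(dt) margin: at
the default `dt = 1/512` the simulated Poisson spectrum exceeds the
continuous-time linear theory by ~20% in the resonance band, falling to ~1%
at `dt = 1/2048` (the excess is linear in `dt`). Quantitative comparisons
against continuous-time analytics therefore use a finer step; means, CVs and
qualitative structure are insensitive to this (see the `dt/2` convergence
test).

## Known limitations

* The coloured-noise surrogate is calibrated, not derived; its two-species
  variance predictions are upper-bound-like trends.
* The simulated single-species variance runs 15–20% above the approximate
  law `K(0.48 + 0.0125/γ)` at all tested `w`; the law keeps only the lowest
  Fourier mode of the synchrony oscillation, while the simulation contains
  its harmonics, so the sign of the excess is expected. Regressions against
  `1/γ` consequently return a slope near 0.015 rather than 0.0125.
* At `K = 10⁶` near resonance the measured stationary CV of the
  quasi-synchronous model is a few percent and scales as `K^(−1/2)`; the
  large (>10%), `K`-independent oscillation amplitude reported for this
  regime elsewhere is reproduced here only as a long-lived transient (decay
  time `1/γ`) excited by synchronised or far-from-equilibrium initial
  conditions, not as a stationary state. The package's stationary protocol
  therefore reports smaller resonance amplitudes at large `K`; at
  `K ≤ 10⁵` the resonance (quasi-sync ≫ Poisson, peak near `b ≈ 0.5–0.6`,
  CV ~ 10%) is reproduced. See the variance/ignition analyses in the test
  suite for the supporting evidence.
* The timer model has no mother–daughter timer correlations, no spatial
  structure and no lineage tracking; synthetic experiments therefore say
  nothing about correlated division times found in real microbial lineages.
* Exponential-distribution runs initialised with uniform timers relax to the
  memoryless pool within one generation; statistics collected inside that
  first generation mix the two regimes.
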