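# quasisync

Stochastic population dynamics with **quasi-synchronous replication**: a
simulator and analytics toolkit for birth–death models in which organisms
replicate in quasi-discrete generations (per-cell countdown timers drawn
from a narrow distribution) while death is a state-dependent Poisson
process.

## The problem

Predator–prey models with demographic noise exhibit *quasi-cycles*:
sustained oscillations driven by the resonant amplification of intrinsic
birth/death fluctuations, even when the deterministic limit only shows
damped oscillations. Classical treatments assume Markovian (exponential)
replication times. Real microorganisms do not replicate this way — division
times cluster around a generation time `T` — and this correlation
concentrates demographic noise into a narrow band around the replication
frequency `1/T`. When that frequency is in tune with the system's natural
oscillatory frequency, the coloured noise is amplified far more strongly
than white Poisson noise, and species coexistence can be destabilised.

`quasisync` is written for theoretical ecologists / stochastic-kinetics
researchers who want to simulate these non-Markovian models exactly and
compare against the linear-noise analytics.

## The model

Two species A and B with counts `N_A, N_B`. Each cell has a timer assigned
at birth from `R(τ)` (exponential, or uniform on `(T(1−w), T(1+w))`); at
zero the cell divides and both cells draw fresh timers. Per-capita death
rates

    d_A = max(p2 − p1 N_B/K, 0),    d_B = max(p4 N_A/K − p3 (1 − N_B/K), 0)

with carrying-capacity scale `K` and mean-field growth rate `b = ln2/T`.
The mean-field fixed point, Jacobian eigenvalues `λ±` (oscillation frequency
`f₀ = Im λ/2π`, damping `|Re λ|`), linearized fluctuation spectra under
white or coloured noise, the phase-diffusion decay rate `γ = 2π²w²/(3T)` of
synchrony, and the single-species variance law `Var(N) ≅ K(0.48 + 0.0125/γ)`
are implemented in `quasisync.core` and `quasisync.theory`. A fixed-step
(`dt = 1/512`) binned simulation engine with an agent-level reference
implementation lives in `quasisync.engine` / `quasisync.reference`;
estimators (CV, periodograms, decay fitting, extinction statistics, scans)
in `quasisync.observables`; the automated parameter-design procedure in
`quasisync.design`. See `docs/methods.md` for the full method description.

## Worked example

```python
import quasisync as qs
from quasisync.observables import steady_state_init

# design a parameter set: frequency 1, steady state (0.5, 0.5), damping 0.5
res = qs.refine_params((30., 16., 1., 3.), qs.DesignTargets(damping=0.5))
print([round(p, 2) for p in res.p])

# detune the growth rate towards the resonance (replication frequency
# 1/T = b/ln2 close to the natural oscillation frequency)
params = qs.ModelParams(*res.p, b=0.6, K=100_000, w=0.02)
eig = qs.jacobian_eigenvalues(params)
print(f"f0 = {eig.f0:.4f}, damping = {abs(eig.re_lambda):.4f}")

# quasi-synchronous vs Poisson fluctuation amplitude at identical parameters
ts = qs.simulate(params, 3000.0, rng_seed=1, init=steady_state_init(params))
cv_sync = qs.coefficient_of_variation(ts, burn_in_fraction=0.6)
poisson = params.with_(replication_dist="exponential")
tp = qs.simulate(poisson, 3000.0, rng_seed=1, init=steady_state_init(poisson))
cv_poisson = qs.coefficient_of_variation(tp, burn_in_fraction=0.6)
print(f"CV quasi-sync = {100*cv_sync:.1f}%  vs  Poisson = {100*cv_poisson:.1f}%")
```

Output (about a minute; the runs cover 3000 time units at `dt = 1/512`):

```
[39.73, 20.86, 2.0, 4.0]
f0 = 0.8969, damping = 0.5101
CV quasi-sync = 9.2%  vs  Poisson = 1.3%
```

The designed rates match the fast-damping preset (`"S0.5"`) to the printed
decimals. Near resonance, division times clustered to ±2% of the doubling
time make the stationary fluctuations of `N_A` seven-fold larger than under
Poissonian replication at identical parameters, because replication noise is
concentrated in a narrow Lorentzian at the replication frequency instead of
being spread white.

A CLI mirrors the library:

```bash
quasisync params refine --damping 0.5            # JSON parameter block
quasisync simulate --preset S0.5 --K 300000 --w 0.02 --b 1 --tmax 5000 \
    --seed 1 --out run.csv                       # CSV + JSON sidecar
quasisync theory spectrum --preset S0.5 --noise coloured --w 0.08 --b 0.9
quasisync scan --preset S0.5 --K 100000 --w 0.02 --axis b \
    --values 0.3,0.5,0.7,0.9 --metric cv --tmax 2500 --seed 1
quasisync run config.toml --out results/        # TOML/YAML experiment file
```

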