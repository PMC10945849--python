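# dlv — disordered Lotka–Volterra communities with strong interactions

`dlv` simulates and analyzes generalized Lotka–Volterra communities whose
pairwise interaction coefficients are drawn once from a random ensemble,
in the regime where interactions are *strong* (their statistics do not
shrink with the number of species) and a weak immigration flux keeps
every species alive. In that regime the community generically settles
into **chaotic turnover**: a handful of dominant species carry almost all
of the abundance at any moment, while every species alternates between
long periods of rarity and short booms. The package is aimed at
theoretical ecologists and microbial-community modelers who want a
self-contained, reproducible implementation of that dynamics and of the
statistics used to characterize it (effective diversity, abundance
distributions and their power-law exponents, turnover timescales,
dominance biases, dynamical phases).

## The model

Abundances `x_i` of `S` species evolve as

    dx_i/dt = x_i (1 − x_i − Σ_{j≠i} α_ij x_j) + λ,

with unit growth rate and carrying capacity, immigration rate `λ ≪ 1`,
and couplings `α_ij = μ + σ z_ij`, where the residuals `z_ij` are
standard Gaussian with an optional correlation `γ` between `z_ij` and
`z_ji`. Integration uses a fixed-step Euler scheme applied to `ln x`
(`Δt = 0.01`), which keeps every abundance strictly positive.

On top of the community simulation the package provides:

- **Observables** — reciprocal-Simpson effective size `S_eff`, the
  dominant component (top `round(S_eff)` species) and its turnover
  timescale `τ_dom`, Bray–Curtis closeness to few-species
  quasi-equilibria, the collective correlation `ρ` with its critical
  value `ρ_c = (1−μ)/(σ S̄_eff)`, abundance fluctuation / species
  abundance distributions (AFD/SAD) with power-law fitting, dominance
  statistics, AFD typicality, and the selection-coefficient
  decomposition of relative-abundance dynamics.
- **Focal-species reduction** — a one-dimensional logistic SDE
  `dx/dt = x(−k + u η(t) − x) + λ` with Ornstein–Uhlenbeck noise `η`
  (correlation time `τ`), whose parameters map onto community
  observables (`k = μX̄ − 1`, `u ≈ σX̄/√S̄_eff`, `τ = τ_dom`), plus its
  stationary density under the unified colored noise approximation
  (UCNA), with power-law exponent `ν = 1 + k/(u²τ)`, and a
  moment-matching fitter for abundance time series.
- **Phases** — an equilibrium / cycle / chaos / divergence classifier
  (recurrence counting, cross-validated against a Benettin-style maximal
  Lyapunov estimator) and a `(μ, σ)` grid scanner for chaos-probability
  maps.

## Worked example

```python
import dlv

# reference configuration: S=500, mu=0.5, sigma=0.3, lam=1e-8
traj = dlv.reference_run(seed=1, t_run=4000.0)
summary = dlv.summarize(traj)
print(f"X_bar  = {summary.X_bar:.2f}")
print(f"Seff   = {summary.Seff_bar:.2f}")
print(f"share  = {summary.dominant_share:.0%}")
print(f"tau    = {summary.tau_dom:.1f}")
nu = dlv.fit_power_law(dlv.afd_sad(traj)).nu
print(f"nu     = {nu:.2f}")
```

prints (a few minutes on one core)

```
X_bar  = 2.60
Seff   = 8.63
share  = 88%
tau    = 34.7
nu     = 1.18
```

meaning: the 500-species community carries a total abundance of about
2.6 carrying-capacity units; roughly 9 species are effectively present
at any time and together hold ~90 % of the abundance; the dominant
composition decorrelates over ~30 time units; and each species'
long-run abundance histogram follows `x^(−1.18)` between the immigration
floor and the carrying-capacity ceiling. The implied mean negative
growth rate of a typical species is `k = μX̄ − 1 ≈ 0.3 > 0`: most
species, most of the time, are declining toward rarity and are rescued
only by immigration — the signature of boom-bust dynamics.

Short narrative scripts, one per capability, live in `examples/`.
A thin CLI mirrors the library: `dlv simulate`, `dlv analyze`,
`dlv focal`, `dlv scan`, `dlv experiment` (see `dlv --help`).

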