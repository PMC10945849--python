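# Methods

This note records the model, the estimators, and the numerical and
design choices behind `dlv`, at the level of detail a maintainer needs
to judge what the package's outputs do and do not show.

## Model and regime

The community is `S` species with abundances `x_i(t)` obeying

    dx_i/dt = x_i (1 − x_i − Σ_{j≠i} α_ij x_j) + λ.

Growth rate and carrying capacity are fixed to 1 (time is measured in
inverse growth rates, abundance in carrying capacities); heterogeneity
in either is out of scope. `α_ij = μ + σ z_ij` with standard-Gaussian
residuals; a correlation `γ ∈ [−1, 1]` between `z_ij` and `z_ji` is
supported in the sampler (Cholesky construction per unordered pair, so
`γ = ±1` are bit-exact symmetric/antisymmetric) although the analyses
target `γ = 0`. The diagonal is stored as zero and is contractually
unread — self-limitation lives in the logistic term. A poison mode
(`InteractionMatrix.poison_diagonal`) sets it to NaN so tests catch any
consumer that touches it.

The package targets the *strong-interaction* regime: `μ, σ = O(1)`, not
scaled down with `S`, so net competition `S μ ≫ 1` and only a few
species can be simultaneously abundant. Immigration `λ` (default 1e-8)
sets the rarity floor and prevents extinction; it stands in for a seed
bank or metacommunity dispersal. The reference configuration is
`(S, μ, σ, λ) = (500, 0.5, 0.3, 1e-8)`.

The net interaction bias is `z_i = S^(−1/2) Σ_{j≠i} z_ij`, normalized so
that `z_i` is unit-variance as `S → ∞` and the net competition near
carrying capacity decomposes as `Sμ + √S σ z_i`.

## Integration

Fixed-step Euler on `y = ln x`:

    y ← y + Δt (1 − x − A x + λ/x),   x = e^y,

with `Δt = 0.01`. Positivity is automatic; the immigration term is kept
inside the log-domain derivative rather than operator-split. Halving
`Δt` moves the time-averaged `X̄` and `S̄_eff` by under 2 % (tested).
Divergence (possible for large `σ`, where mutualistic feedback loops are
unbounded) is detected on `ln x` *before* exponentiation, against
`ln(divergence_threshold)` (default threshold 1e3), so a runaway state
can never overflow into NaN; the trajectory is flagged and truncated.

Defaults: burn-in 2,000 time units (≫ 10 turnover times, since
`τ_dom ≈ 30`), storage stride 1.0 time unit (resolves booms, which last
tens of time units), both config-exposed. Initial conditions are
`x_i ~ U(λ, 2/S)`. Two independent seed streams (interaction matrix,
initial condition) let ensembles vary either alone; `split_seed`
derives both from one master seed.

## Observables

- **Effective size** `S_eff = 1/Σ p_i²` (reciprocal Simpson). The
  dominant component is the `round(S_eff)` most-abundant species
  (round-half-up, minimum 1, ties to the lower index). Rounding was
  chosen over floor/ceil as the symmetric option; on the reference run
  it reproduces a ~90 % dominant share.
- **Bray–Curtis similarity**: the abundance-weighted mean of min/mean
  ratios, which reduces algebraically to `2 Σ min(x_i, y_i) / Σ (x_i +
  y_i)`; both forms are tested equal.
- **Closeness to equilibrium**: the system restricted to the dominant
  component at time `t` is integrated with `λ = 0` (same log-Euler)
  until `max_i |dx_i/dt| < 1e−9` or `t_max = 1e4`; the result is the
  Bray–Curtis similarity between observed and equilibrated
  compositions. Non-convergence and divergence are flagged, not raised.
- **Collective correlation** `ρ(t) = −Σ_{i≠j} z_ij p_i p_j` (diagonal
  excluded, since `z_ii` is undefined). The time-averaged total
  abundance satisfies `X̄ ≈ [μ + (1−μ)/S̄_eff − σρ̄]^(−1)`, obtained by
  averaging the exact `d ln X/dt` equation and factorizing the
  averages; its relative error on the reference run is under 5 %
  (tested, typically well under 1 %). Boom-bust requires
  `ρ̄ ≥ ρ_c = (1−μ)/(σ S̄_eff)`.
- **AFD/SAD**: log-spaced bins over `[λ/10, 10]` (12 bins/decade).
  Each species' AFD is its time-normalized histogram; SADs are snapshot
  histograms. The power-law exponent ν is the negative least-squares
  slope of log density vs log abundance on `[100λ, 0.01]`, the section
  bounded below by immigration and above by the carrying capacity.
  Density is estimated at geometric bin centers; for log-spaced bins
  the center-estimate bias of an exact power law is a constant factor,
  so the slope is unbiased (verified by recovering ν ∈ {1.1, 1.3, 1.5}
  from inverse-CDF synthetic samples to < 0.05). A truncated-Pareto
  conditional MLE (`fit_power_law_mle`) is exposed as an alternative.
- **ACF and τ_dom**: mean-subtracted, FFT-based, biased normalization
  (divide by full length, which tapers the noisy tail). The
  abundance-vector ACF is the variance-weighted mean of per-species
  ACFs. τ is a least-squares fit of `exp(−t/τ)` over lags with
  ACF > 0.05; the threshold avoids fitting the irregular tail.
- **Dominance statistics**: per-frame membership in the dominant
  component gives each species' dominance-time fraction; bias is the
  fraction over the species median (1 at the median rank by
  construction); Σ_i fraction_i equals the time-averaged dominant-set
  size (counting identity, tested). Lower net interaction bias `z_i`
  correlates with higher dominance bias, as implied by the mean
  selection coefficient `s̄_i ≈ −σ z_i/S` — note the *negative* sign:
  less-competed species boom more.
- **Typicality** `θ_i = 1 − sup|F̄ − F_i|` (Kolmogorov–Smirnov on the
  binned AFD CDFs).
- **Selection decomposition**: `s_i(t) = −σ Σ_{j≠i} z_ij p_j`, reference
  proportion `π = 1/S_eff − σρ`. The exact reduction of the abundance
  equation to proportions is
  `dp_i/dt = X p_i [(1−μ)(1/S_eff − p_i) + s_i − σρ] + (λS/X)(1/S −
  p_i)` — the frequency-dependent terms carry a `(1−μ)` factor — and
  the finite-difference consistency check uses this exact form
  (correlation > 0.99 at fine storage stride).

## Focal-species reduction

Any one species' growth rate `g_i = 1 − Σ_{j≠i} α_ij x_j` is, for a
Gaussian coupling ensemble, conditionally Gaussian with mean
`a(t) = 1 − μ Σ x_j` and SD `b(t) = σ √(Σ x_j²)`; the standardized
residual `η_i = (g_i − a)/b` is empirically close to N(0,1) across
species and time in the chaotic phase (KS distance < 0.05 on the
reference run, tested). Freezing `a, b` at their time averages gives
the focal model

    dx/dt = x (−k + u η(t) − x) + λ,

with `k = −ā = μX̄ − 1`, `u = b̄`, and η an Ornstein–Uhlenbeck process
of unit variance and correlation time `τ = τ_dom` (the noise and
abundance ACF timescales agree within 30 %, tested). The familiar
closed form `u = σX̄/√S̄_eff` pulls the time average inside the square
root and is implemented in `effective_params` (operating on a summary);
`effective_params_from_trajectory` computes the exact `−ā, b̄`. The
distinction matters for boom statistics: the stationary mean of the
focal model responds steeply (roughly exponentially) to `u`, so a 4 %
difference in `u` moves the naive-closure value `μS⟨x⟩ − 1` by tens of
percent. That naive closure comes out negative (≈ −0.3 to −0.5) even
though `k > 0` — the self-consistency failure that distinguishes the
strong-interaction regime, where the few dominant species control
`a, b`, from weak-interaction mean-field theory.

- **OU noise**: exact conditional-Gaussian (AR(1)) discretization,
  `η' = c η + √(1−c²) N(0,1)`, `c = e^(−Δt/τ)`, started from the
  stationary law — stationary variance is exactly 1 for any step size
  (an Euler discretization inflates it by O(Δt/τ); tested).
- **Focal SDE**: same log-Euler scheme, with the full-resolution
  time-mean accumulated inside the kernel. The colored noise makes the
  equation a random ODE, so no stochastic-calculus correction arises.
- **UCNA stationary density**: for `dx/dt = F(x) + u g(x) η` with
  `F = −x(k+x) + λ`, `g = x`, adiabatic elimination gives
  `P*(x) ∝ (h/g) exp(∫ F h/(D g²))` with `h = 1 + τ(x + λ/x)` and
  white-noise intensity `D = u²τ`. The density is evaluated by
  cumulative quadrature of the exponent on a log grid (default
  `[λ/100, 100]`, 4096 points) and normalized by log-sum-exp trapezoid
  weights. Contract checks (all tested): normalization to 1e−6,
  mid-window log-log slope = −ν with `ν = 1 + k/(u²τ)`, exponential
  cutoffs at both ends, and convergence to the exact white-noise
  Fokker–Planck solution as τ → 0 at fixed D. UCNA is exact only in
  the τ → 0 and τ → ∞ limits; at intermediate τ its boom tail (hence
  its implied mean abundance) deviates from simulation.
- **Series fitting** (`fit_effective_params`): τ from an exponential
  fit to the ACF of the abundance itself — the log-abundance ACF
  carries the longer integrated-noise memory of the rare phase and
  overestimates τ by ~2×. `(k, u)` by two-stage grid search (9×9 broad,
  5×5 refinement with noise-averaged objective) minimizing the L1
  distance between empirical log-abundance CDFs of data and matched-
  length simulations. The initial guess `k₀ = λ/exp(q₁₀(ln x))` uses a
  low quantile because the mean of `ln x` is inflated by the boom tail.
  Self-recovery on simulated series (k=0.26, u=0.25, τ=30, 1e5 time
  units) is within 20 % per parameter (tested). Moment matching was
  chosen over likelihood deliberately: the model is a reduction, not a
  generative claim, and the grid search is transparent and testable.

## Phase classification

Order of tests: (i) the integrator's divergence flag; (ii) equilibrium
if the largest per-species SD of `ln x` over the trailing half of the
recording is below `ε_eq = 1e−4`; (iii) recurrence counting on
`ln p` restricted to species above 1e−4 relative abundance in the
reference frame, with `ε_rec = 0.5` in max-norm, from 3 reference
frames. A recurrence is a return to the ε-neighborhood after an
excursion of at least 5 time units. Regularly spaced recurrences (CV of
intervals < 0.1, ≥ 3 events) ⇒ cycle; irregular or absent recurrences ⇒
chaos; a window that never leaves any reference neighborhood is a
(possibly still relaxing) stationary composition ⇒ equilibrium. All
constants are config-exposed (`ClassifierSettings`). Near phase
boundaries long chaotic transients exist; classification windows are
the trailing 50 % of the recording, and scans of slowly-relaxing
regions need long transients (the weak-disorder cells relax over
thousands of time units).

The classifier ships with a cross-check: a Benettin-style two-trajectory
maximal Lyapunov estimator in log-abundance space (companion offset ε,
renormalized every Δ time units; rate ± SE over episodes), and a
validation suite pairing labels with exponent signs (≥ 90 % agreement,
tested; also cross-checked against a tangent-space linearization
oracle). Finite-time exponents in the chaotic phase are small
(≈ 0.006 at S=150–200, ≈ 0.017 at S=500) and fluctuate strongly on
windows of a few thousand time units, so sign resolution needs windows
matched to the exponent magnitude.

Phase scans draw independent matrix and initial-condition seeds per
replicate from a per-cell `SeedSequence`, classify each, and report
label counts and chaos probability; per-cell results persist
incrementally to CSV, making long scans resumable. Scan replicates
default to shorter runs (burn 500, record 2,000) than analysis runs —
labels need far less data than converged statistics.

## Problem sizes and what the tests show

Desk-scale defaults are used throughout: the shared test trajectory is
one reference-configuration run of 10,000 recorded time units (the
headline time averages equilibrate over ~100 turnover times ≈ 3,000
units); the reproduction script uses three independent 20,000-unit
runs; scaled structural checks (dominance scaling, phase structure,
Lyapunov agreement) use S = 100–400. At these scales the *mean*
dominance fraction halves when S doubles (a counting identity), while
the *median* converges to the 1/S law only on much longer horizons —
the tests assert the former and monotonicity of the latter.

The synthetic-data generators (`make_fixture`) produce exactly what the
estimators assume: iid truncated power-law samples (inverse CDF), exact
OU paths, focal-model paths at known parameters, and small chaotic
communities. Passing tests therefore demonstrate internal correctness
and self-consistency of the model chain, not agreement with any
empirical community: real abundance data carry sampling noise,
compositional normalization, measurement error and non-stationarity
that none of the generators emulate.

## Known limitations

- Connectance is 1 (fully connected couplings); sparse or structured
  interaction networks are not supported.
- No demographic stochasticity; the only noise is deterministic chaos.
- The UCNA density is quantitatively rough at intermediate τ (its
  exponent `1 + k/(u²τ)` underestimates the simulated AFD slope).
- The recurrence classifier's constants are heuristic; near phase
  boundaries (multiple-attractor region) labels depend on the
  transient length, and hysteresis is not mapped.
- `fit_effective_params` assumes a stationary boom-bust series with
  `k > 0`; it flags, but cannot rescue, series that are too short or
  fluctuation-free.
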