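# Methods

`synchrolek` models the evolution of collective synchrony in lekking
displays (synchronously flashing fireflies, claw-waving fiddler crabs,
chorusing frogs and crickets) as a two-timescale system: a fast
within-lifetime oscillator layer and a slow generational layer in which
the oscillators' *phase-lag strategies* evolve.

## Fast layer: Sakaguchi–Kuramoto oscillators with strategy lags

Each of the `N` displaying individuals carries a phase `θ_i` obeying

    dθ_i/dt = ω + (K/N) Σ_j sin(θ_j − θ_i + α_i),

with a universal intrinsic frequency `ω`, uniform all-to-all coupling
`K ≥ 0`, and a per-individual phase lag `α_i` — the strategy. `α_i = 0`
steers toward the group phase (a *cooperator*); `α_i ≠ 0` steers toward
a consistent offset from it (a *cheater*, taking part in the collective
display while standing out from it). Synchrony is measured by the order
parameter `R e^{iφ} = (1/N) Σ_j e^{iθ_j}`.

Two deliberate conventions:

- **The coupling sum includes the self term** `j = i` (contributing
  `sin(α_i)/N`). This is required for the full model to agree exactly
  with the two-cluster reduction below; it also lets every right-hand
  side be evaluated in O(N) through the mean-field identity
  `u_i = K R sin(φ − θ_i + α_i)`.
- **Phases are wrapped to (−π, π]**, and every phase difference is
  wrapped before entering a strategy function.

The drive `u_i` is also the *control effort* the individual spends
adjusting to neighbours; its cost is `c_i = (1/T)∫|u_i|² dt`. Intrinsic
oscillation is free — everyone oscillates regardless.

Integration uses adaptive explicit Runge–Kutta (SciPy RK45) with
relative tolerance 1e-8 and absolute tolerance 1e-10 by default, sampled
at Δt = 0.1 for stored histories. Solver failure raises rather than
passing silently. "After transients have decayed" is operationalized
everywhere as the trailing 10% of the integration horizon; all payoff,
cost and synchrony averages use that window (trapezoidal quadrature).

## Payoffs

The benefit of displaying factorizes as `b_i = g(R)·f(θ_i − φ)`:
a group attractiveness term (how many mates the collective signal
recruits; `g(R) = R` by default, any positive nondecreasing `g` is
accepted) times an individual strategy function `f`, the product of a
mate-attraction factor (minimized in sync — deviants stand out to
mates) and a policing tolerance factor (maximized in sync — deviants
stand out to enforcers). Net payoff is `p_i = b_i − β c_i` with β = 1 by
default; the cost is nearly uniform across individuals at a
frequency-locked equilibrium, so β is not a sensitive parameter.

Shipped strategy shapes (all 2π-periodic, nonnegative):

| kind | f(Δθ) | shape |
|---|---|---|
| `binary_baseline` / `no_policing` | `1 − cos Δθ` | attraction only; max at antiphase |
| `symmetric_policing` | `1 − cos 4Δθ` on `|Δθ| < π/2`, else 0 | twin peaks at ±π/4 |
| `asymmetric_policing` | same, restricted to `0 < Δθ < π/2` | only leading pays |
| `strong_policing` | `A·exp(κ(cos Δθ − 1))` | unique max at 0 |

The symmetric form is the reading of `cos(4(Δθ − π/4)) + 1` restricted
to its central support: it is nonnegative, vanishes at 0 and ±π/2 and
peaks at ±π/4, i.e. a *moderate* lead or lag pays while extreme
deviation earns nothing. The support halfwidth is configurable; the
peaks sit at half of it.

`strong_policing` has no canonical algebraic form — the regime it must
realize is "policing outweighs any attraction gain from deviating, so
there is no net benefit to being out of sync". We use a von Mises-shaped
tolerance `A·exp(κ(cosΔθ − 1))` with defaults `A = 2`, `κ = 25`
(tolerance width ≈ 1/√κ = 0.2 rad). The defaults follow from
mutation–selection balance: near Δθ = 0 the log-fitness curvature is
`A·κ·R`, and the equilibrium lag spread satisfies
`σ⁴ ≈ n_mutate·σ_mutate²/(A·κ)`; `A·κ = 50` puts σ ≈ 0.05 rad and the
equilibrium order parameter ≈ 0.999 — a population dynamically
indistinguishable from a cheater-free one, which is what "strong"
means here. A raised cosine (curvature O(1)) equilibrates at σ ≈ 0.15
and R ≈ 0.98, i.e. only *moderate* policing; and shapes like cos²Δθ are
unusable because they reward antiphase as much as sync. Both parameters
are exposed in configuration.

Deviations `Δθ` are always measured against the *global* mean phase φ.
When the population splits into clusters a per-cluster reference would
differ; local-cluster order parameters are out of scope.

## Binary (cooperator/cheater) layer

With lags restricted to `{0, α_ch}` and each type internally
synchronized, the system reduces exactly to the gap
`Δθ₀ = θ_ch − θ_co`:

    K⁻¹ dΔθ₀/dt = n_co sin(−Δθ₀ + α_ch) + n_ch sin(α_ch) − n_ch sin(Δθ₀),

with equilibrium `Δθ₀* = α_ch`, stable iff

    n_ch < 1/(1 − cos α_ch).

For `α_ch < π/2` the bound exceeds 1: no admissible cheater fraction can
destroy synchrony. At the clustered equilibrium with `g(R) = R` and
`f = 1 − cos`, payoffs are closed-form
(`p_co = R(1 − cos φ)`, `p_ch = R(1 − cos(α_ch − φ))`,
`R e^{iφ} = n_co + n_ch e^{iα_ch}`); the uniform effort cost cancels
from every payoff difference and is omitted. The replicator flow
`dn_x/dt = k n_x (p_x − p̄)` (or its discrete map with strength `k₁`,
guarded so growth factors stay positive) then drives any persistent
mixed population to a 50–50 split: the minority always earns more,
because the mean phase sits closer to the majority cluster.

The analytic bound is cross-checked two independent ways:

1. numerically differentiating the gap RHS at the equilibrium and
   bisecting the cheater fraction where the eigenvalue changes sign;
2. a full-model *critical-fraction sweep*: for each `α_ch`, fast-layer
   simulations over increasing cheater fractions, recording the first
   whose equilibrium (window-averaged) `R` falls below an incoherence
   threshold of 0.1. No numeric cutoff is canonical; 0.1 cleanly
   separates the clustered states (whose `R = |n_co + n_ch e^{iα_ch}|`
   stays well above it except very near antiphase) from desynchronized
   ones, and it is recorded in sweep metadata.

Sweep initialization is cluster-exact plus wrapped-normal noise of
s.d. 0.05, so the sweep probes stability of the synchronized solution —
the statement the linear analysis makes. The sweep horizon defaults to
400 time units, longer than a display lifetime, because the boundary is
an asymptotic statement: just above it the instability growth rate
`K(n_ch(1 − cos α_ch) − 1)` can be ~0.01, and the seed noise needs
several e-foldings to reach O(1). Desk-scale sweeps use N = 200; N =
1000 reproduces the full-scale setting at proportional cost.

## Generational layer: Fermi selection and mutation

With a continuous lag distribution there is no closed-form payoff; each
generation plays one display lifetime (`T = 100`, `ω = 0`, `K = 1`) from
a fresh near-synchronized phase draw (wrapped normal, s.d. 0.1 —
offspring inherit strategies, not phases), and payoffs are averaged over
the trailing 10%. Reproduction follows the Fermi rule: parent
probabilities proportional to `e^{p_i}` (the shared `max_j e^{p_j}`
denominator cancels under normalization and guards overflow), with
multinomial resampling at fixed group size. A without-replacement subset
of exactly `round(0.1·N)` offspring then mutates by `N(0, 0.05²)` kicks
(fixed-size selection has lower variance than Bernoulli and matches the
"select 10%" protocol). With two lag values present, no mutation and
weak selection, this machinery reduces to the discrete replicator map to
first order in payoff differences — an identity the test suite checks by
simulation.

One global seed spawns four independent streams (initial lags, per-
generation phases, selection, mutation), so components are testable in
isolation and every run replays bit-identically from its manifest.

### Outcome classification

Four regimes are distinguished at the end of a run, in this order:

- **extinct** — window-averaged `R < 0.2` for 20 consecutive
  generations (extinction has no explicit mechanism in the payoff; low
  synchrony means low attractiveness means no recruits; the
  threshold-with-patience rule is monotone in that cause and recorded in
  run metadata).
- **stable_bimodal** — the final lag histogram (bin width 0.05 rad,
  lightly boxcar-smoothed circularly) has two peaks ≥ 0.3 rad apart
  with an inter-peak trough below 50% of the smaller peak.
- **drifting** — the fitted slope of the (unwrapped circular) lag mean
  over the final third exceeds 2.5e-3 rad/generation. The threshold must
  exceed the *neutral* diffusion of the mean: a uniform shift of all
  lags changes no payoff, so the mean random-walks under resampling with
  per-generation steps ~σ_α/√N (≈0.007 at N = 200), producing spurious
  final-third slopes up to ~0.002 with no directed drift at all. 2.5e-3
  asks for a net displacement of ~0.25 rad over a 100-generation
  window — above that floor, and several-fold below the ~0.004–0.012
  ratchet that one-sided policing actually produces.
- **stable_unimodal** otherwise.

Bimodality is tested before drift because a split population's circular
mean is dominated by cluster-size sampling noise, which would make a
drift-first test meaningless.

### What the generator emulates — and what it does not

The synthetic initial conditions (normal lag distributions, exact binary
mixtures, clustered or uniform phases) represent idealized populations:
no spatial structure, no heterogeneous frequencies or coupling, no
observation noise, and phase resets between generations. Passing tests
therefore demonstrate the model's internal consistency and its
phase-diagram structure, not that any real lek sits in a particular
regime.

### Desk-scale behaviour of the four regimes

At the desk scale used by the test suite (N = 200, 300 generations)
the four policing regimes behave as follows; the first two points are
honest limitations of that scale, not of the model:

- *No policing*: the lag distribution spreads and synchrony collapses,
  but the early spread is mutation-limited (variance input
  `n_mutate·σ_mutate²` = 2.5e-4 rad²/generation) until disruptive
  selection takes over near σ² ≈ 0.03–0.05, so extinction completes at
  generation ~320–430 — reproducibly extinct, on a timescale somewhat
  longer than a 300-generation budget.
- *Symmetric policing*: the population splits into clusters at ±π/4 and
  the split is metastable: cluster imbalance is payoff-neutral to first
  order (the peaks are critical points of `f`), so cluster sizes — and
  with them the population mean lag — random-walk at a rate ∝ 1/√N. At
  N = 200 roughly half of the seeds survive 300 generations; at the
  full scale N = 1000 the drift is √5 slower. Survival also requires the
  policing gap to be narrow enough and the initial mean close enough to
  zero, consistent with the model's qualitative predictions.
- *One-sided policing*: a ratchet — only leading the group pays, the
  mean lag climbs at ~0.004–0.012 rad/generation until it nears π/2,
  where even a unimodal population cannot synchronize (`cos ᾱ ≤ 0`) and
  the run ends extinct.
- *Strong policing*: unimodal, `R ≥ 0.998` throughout; indistinguishable
  from a cheater-free population.

## Numerical choices and degenerate inputs

- `R` of a single oscillator is exactly 1; at `R < 1e-12` the mean phase
  is undefined and flagged, and benefits vanish anyway since `g(0) = 0`.
- Discrete replicator steps validate the positivity of
  `1 + k₁(p − p̄)` at every application; the default `k₁ = 0.1`.
- The replicator flow clips `n_ch` to [0, 1] inside the RHS; boundaries
  are exact fixed points.
- Empty phase sets, mismatched array lengths, negative couplings,
  non-finite payoffs, unknown strategy kinds and unknown configuration
  keys are all rejected with specific messages.
- Runs at the full scale (N = 1000, long sweeps) are configuration
  switches; defaults keep the complete test suite around a minute on a
  single CPU.

## Known limitations

- Global-`R` synchrony measure: a perfect cooperator in a split
  population responds to the global mean phase, not its local cluster.
- All-to-all coupling only; no spatial or network structure.
- Universal `ω` and `K`; heterogeneous frequencies and per-individual
  coupling costs are out of scope (with uniform `K`, cheaters and
  cooperators cannot be told apart from the phase distribution alone).
- Generalized binary mixtures with `α_co ≠ 0` are accepted as
  parameters, but the analytic results asserted by the test suite are
  the `α_co = 0` ones.
- The attraction function is symmetric in the sign of the deviation;
  mate preference for advanced over delayed signalers is not modelled.
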