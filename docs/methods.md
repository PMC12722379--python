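# Methods

## Model

A household (one breeding site) holds `m` wildtype and `w`
*Wolbachia*-infected adult female mosquitoes, with `m + w ≤ C`. The pair
`(m, w)` evolves as a continuous-time Markov chain with four events:

| event           | change          | rate                     |
|-----------------|-----------------|--------------------------|
| wildtype birth  | `(m+1, w)`      | `b · Z_m · F(m + w)`     |
| infected birth  | `(m, w+1)`      | `b · Z_w · F(m + w)`     |
| wildtype death  | `(m−1, w)`      | `d · m`                  |
| infected death  | `(m, w−1)`      | `d · δ · w`              |

with `n = m + w` and effective parent counts

```
Z_m = (m/n) · (m + (1−v)·φ·w) + (w/n) · ((1−u)·m + (1−v)·φ·w)
Z_w = v · φ · w
```

Here `u` is the probability that an incompatible mating (infected male ×
uninfected female) produces no offspring, `v` the probability that an
infected female's offspring inherit the infection, `1 − φ` the fecundity
cost of infection, and `δ ≥ 1` the mortality cost. Males are implicit and
assumed equal in number to females. Larval competition enters through

```
F(N) = exp(−h · N^k)   for N < C,   0 for N ≥ C
```

with `h = 0.19 · 100^k` kept at full precision (`≈ 0.756404` for
`k = 0.3`); a linear alternative `G(N) = 1 − N/C` is selectable. The state
`(0, 0)` is absorbing.

Two presets are provided:

- **tutorial**: `C=3, b=0.3, d=0.12, δ=1, φ=0.85, u=v=1` — nine transient
  states, small enough to verify every matrix by hand;
- **full**: `C=30, b=0.54, d=0.12, δ=1, φ=0.85, u=v=1` — 495 transient
  states.

The full preset fixes `b = 0.54` literally rather than the calibrated
`b = d/F(10) ≈ 0.5428` that would put the deterministic wildtype-only
equilibrium exactly at 10 females. The two differ by 0.5%, and every
downstream quantity was checked under both; the literal value is the package
default (it yields, e.g., the 167-day extinction figure below, versus 170.7
with the calibrated value), while `calibrate_birth_rate` exposes the
calibration for users who want the equilibrium pinned at a target.

## Communicating classes

For `v = 1` the transient states split into three classes — wildtype-only
`{(m, 0)}`, infected-only `{(0, w)}` and mixed — because an infected-only
household can never regain wildtypes and vice versa. For `v < 1` infected
mothers produce some uninfected offspring, which joins the infected-only and
mixed states into one class. States are enumerated class-major so each class
occupies a contiguous block of the generator; the closed-form classification
is cross-checked on every build against a strongly-connected-components
computation on the positive-rate graph, and any disagreement is a hard error.

## Quasi-stationarity and damping

Each class block is irreducible and strictly sub-stochastic, so it has a
unique simple eigenvalue `−α` of minimal magnitude with `α > 0` and a
positive left eigenvector. Eigenanalysis is always performed per class block,
never on the full reducible transient matrix. The quasi-stationary
distribution is the normalised left eigenvector of the class with the
smallest `α`, embedded in the full transient space; for the default models
this is the wildtype-only class (`α ≈ 0.00244/day` in the full model).
Transient distributions are propagated with the matrix exponential of the
full generator (including the absorbing state), optionally renormalised over
the transient states to condition on non-extinction. The damping ratio
between the two slowest classes is `ρ = exp(α₂ − α₁)`, and the time until
the slow class holds `x` times the fast class's mass is `log(x)/(α₂ − α₁)`.

## Hitting, extinction and release sizing

The probability that a mixed household first enters the infected-only class
at state `(0, w′)` solves `−Q₃ a = q(0, w′)` on the mixed block, where
`q(0, w′)` collects the one-step rates into that state; class-level hitting
probabilities sum these over entry states (one LU factorisation, many
right-hand sides). Expected hitting times conditional on hitting solve the
companion system in the products `a·τ`, then divide, leaving `NaN` where the
probability is zero. Expected extinction times of a class whose only exit is
`(0, 0)` solve `Q_k τ = −1`. The release-size search scans infected counts
at a fixed household total (or fixed resident wildtype count) for the
smallest one meeting a target invasion probability.

## Reversion (`v < 1`)

From a mixed start, the distribution of the infected-only state first
reached is obtained by restricting the hitting system to the mixed
sub-block; dividing by its total mass conditions on reaching the
infected-only set at all. The headline reversion probability for an initial
mixed state is the entry-distribution-weighted average of the per-entry-state
probabilities of later reaching the wildtype-only class, and the headline
reversion time is the same weighting applied to the per-entry-state
conditional expected times:

```
P(rev) = Σ_w′ e(w′) · r(w′)        T(rev) = Σ_w′ e(w′) · τ(w′)
```

A fully conditioned alternative, `Σ e·r·τ / Σ e·r`, weights entry states by
their chance of actually reverting; it is what a simulation's mean reversion
delay estimates (about 1.5 days longer here) and is what the Monte-Carlo
cross-check in the test suite compares against. The headline API reports the
plain entry weighting.

## Mean-field model

The deterministic companion replaces counts by densities:
`dN_m/dt = b·Z_m·F(N) − d·N_m`, `dN_w/dt = b·Z_w·F(N) − δ·d·N_w`. Steady
states: extinction `E0 = (0,0)`, wildtype-only `E1 = (F⁻¹(d/b), 0)`,
infected-only `E2 = (0, F⁻¹(δd/(b·v·φ)))` (feasible only while the fitness
cost stays below `1 − d/b`), and a coexistence saddle `E3` found numerically.
Stability is classified from a finite-difference Jacobian (one-sided at the
axes); at this problem scale the finite-difference classification is exact to
the tolerances used. Basins are classified by integrating with
`scipy.integrate.solve_ivp` (rtol = atol = 1e−9) in 250-day chunks up to
5000 days until the trajectory is within 1e−3 of a stable steady state, and
the invasion threshold is the bisection (resolution 1e−3) of the infected
proportion at fixed total `N₀` between the two basins.

## Entropy

The embedded jump matrix has entries `s_ij = −q_ij / q_i` (and a unit
diagonal for the absorbing state). Per-state next-jump entropy is
`H_i = −Σ_j s_ij log s_ij` with `0·log 0 := 0`, in nats by default; the
logarithm base is selectable.

## Stochastic simulation

The Gillespie algorithm is implemented over precomputed per-state rate
tables (cached per parameter set), with seeded `random.Random` streams for
bit-reproducible trajectories. First-entry bookkeeping records when and
where a trajectory first reaches a single-type composition, which is what
the entry-distribution and reversion cross-checks need; ensembles report
outcome frequencies with binomial standard errors.

## Verification

The test suite checks every analytic pathway against independent oracles:
hand-derivable identities (first-jump decompositions, holding-time offsets,
pure-death harmonic extinction times, two-outcome entropies), structural
invariants (generator row sums, stochasticity of the matrix exponential,
hitting-probability complements, permutation invariance of derived
quantities), continuity at `v → 1`, and Monte-Carlo agreement of invasion
probabilities, extinction times and reversion statistics within three
standard errors at 10,000 runs.

## Known discrepancies

Three of the full-model reference values pinned by the acceptance suite are
not reproduced by this implementation, under either birth-rate convention or
any other parameter variant tried, even though every surrounding quantity
from the same computations checks out:

- the infected-only class decay rate: computed `−0.00647/day` (reference
  rounds to `−0.007`) — the same class block yields the verified 167-day
  extinction time, so the block itself is validated;
- the mean of the wildtype-only quasi-stationary distribution: computed 9.27
  females (reference "approximately 8");
- the mean of the infected-only class's quasi-stationary profile: computed
  6.69 (reference 5).

The corresponding acceptance sub-assertions are left failing rather than
loosened, and the reporting script emits the computed values.

One reported quantity needs an interpretation choice: the invasion
probability "along the deterministic invasion boundary". Integer states on
that boundary overshoot the continuous threshold line by varying amounts, so
their probabilities vary (0.23–0.37); the consistent value belongs to the
states lying essentially on the line, i.e. the minimum over the boundary
states, which is what the reporting script uses (0.23).
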