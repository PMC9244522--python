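# Methods

## Model

`sirxnet` implements SIR epidemic dynamics on an adaptive contact network
with two non-pharmaceutical interventions: endogenous social
self-distancing (susceptibles rewire contacts away from infecteds) and
exogenous quarantine (infecteds are removed into an inert compartment X
and later released into R). The state is a simple undirected graph on N
nodes with node labels in {S, I, R, X}; the population size and the total
number of links are conserved throughout.

Five Poissonian channels drive the continuous-time Markov process:

| channel    | rate                | effect |
|------------|---------------------|--------|
| infection  | β per S–I link      | the S endpoint becomes I |
| recovery   | γ per I node        | I → R |
| rewiring   | w per S–I link      | the S endpoint detaches from the I endpoint and reattaches to a uniformly random S or R node |
| quarantine | κ per I node        | I → X; links are retained but X is inert |
| release    | δ per X node        | X → R; mean quarantine duration 1/δ |

Modelling choices worth making explicit:

* **Rewiring target law.** The new partner is drawn uniformly from the
  union of all current S and R nodes (excluding the susceptible endpoint
  itself and its existing neighbours), so S–S versus S–R outcomes split in
  proportion to compartment abundance. This is the law whose mean-field
  limit is the gain term w·ρ_S/(ρ_S+ρ_R)·ρ_SI in the closed equations. An
  alternative reading — a fair coin between the S and R compartments
  first — is available behind `target_rule="compartment"` but is not the
  default, because its mean-field limit would carry a factor
  ½(1/ρ_S + 1/ρ_R)·ρ_S·ρ_R instead.
* **Quarantined nodes keep their links but are inert**: they cannot
  transmit, their S–I links are deactivated (not rewired away, matching
  the −κρ_SI loss term), and they are not eligible rewiring targets.
  This keeps the link count constant without inventing link deletion.
* **Graph simplicity.** Rewiring never creates self-loops or duplicate
  edges; if no eligible target exists the event is a no-op. At the scales
  studied the no-op probability is negligible, and simplicity is what
  makes motif counting well defined.
* **β = 0 is rejected** by `ModelParams` (the model requires a positive
  transmission rate); a `degenerate()` constructor exists solely so tests
  can exercise the no-transmission limit.

## Exact simulation

`run_gillespie` is a direct stochastic simulation algorithm: exponential
waiting times at the total rate, channel selection proportional to
aggregate channel rates, uniform selection within a channel. Node-state
sets and the S–I/S–S link caches are indexed sets with O(1) insert,
delete and uniform sampling, updated incrementally in O(degree) per
event; a full O(N+M) recount (`NetworkState.validate`) can be switched on
per event in tests. Rewiring targets are drawn by rejection from the S∪R
pool (falling back to explicit enumeration after 64 rejections), which is
exact and O(1) in the regimes of interest.

Observables are resampled onto a user-supplied regular grid by
last-value-carried-forward so that ensemble averages are pointwise
meaningful. Per-run peak prevalence is tracked event-exactly (not from
the grid), and per-run final sizes are measured at absorption — the state
with no I and no X nodes, which the process reaches almost surely — where
the recovered count equals the number of ever-infected nodes exactly.
Ensembles draw one fresh Erdős–Rényi graph per run; per-run seeds derive
from `(seed, run_index)` so any run is reproducible in isolation.

The ER generator uses G(N, p) with p = μ/(N−1), the conventional reading
of "mean degree μ"; initial infecteds are exactly round(ρ_I(0)·N) nodes
chosen uniformly (round half away from zero, so 1% of 2000 is exactly 20).

## Pair approximation

The moment hierarchy is closed at second order with
[ABC] ≈ m(A,B)m(B,C)[AB][BC]/[B], m = 2 for repeated states and 1
otherwise. Motif counting uses the centred ordered-ends convention
([ABA] counts ordered pairs of distinct ends, giving n_A(n_A−1) per
centre), which is exactly the convention under which the closure with
these m-factors is the consistent estimator.

Two closed systems are provided (see `sirxnet.moments` for the full
equations): the four-dimensional adaptive-SIR system (no quarantine,
ρ_S = 1−ρ_I−ρ_R) and the five-dimensional adaptive-SIRX system. They are
implemented exactly as stated, including their differing rewiring-gain
factors — (1−ρ_I−ρ_R)/(1−ρ_I) in the SIR system versus ρ_S/(ρ_S+ρ_R) in
the SIRX system — which coincide when ρ_X ≡ 0; no harmonisation is
attempted. With κ = 0 the SIRX system reproduces the SIR system to
integrator tolerance (a regression test).

Numerical choices:

* LSODA with rtol 1e-8, atol 1e-12, dense output; integration stops when
  both ρ_I and ρ_SI fall below 1e-10 (final sizes are stable to well
  beyond six digits at these settings).
* When ρ_S < 1e-14 the closure terms ρ_SI(·)/ρ_S are set to zero: ρ_SI
  vanishes at least as fast as ρ_S, so the singularity is removable.
* ρ_X is integrated explicitly as a redundant variable and
  ρ_S+ρ_I+ρ_R+ρ_X = 1 is enforced as a runtime conservation check.
* Right-hand sides accept complex states, so Jacobians are obtained by
  complex-step differentiation (machine-precision derivatives, no
  truncation error).
* Peak prevalence refines the dense-grid argmax with a bounded scalar
  optimisation on the interpolant.
* Default initial condition: ρ_SI(0) = μ·ρ_I(0) and
  ρ_SS(0) = (μ/2)(1−ρ_I(0))², the expectations under uniformly random
  seeding of an ER graph; both are overridable. The ρ_SS(0) default is a
  package choice — only ρ_I(0) and ρ_SI(0) are pinned down by the
  standard seeding convention — made for consistency with the simulator's
  initialiser in expectation.

### A note on the release rate δ

In the closed SIRX system δ is *not* exactly inert for the infected time
course when w > 0: δ sets how fast X drains into R, ρ_R appears in the
rewiring-gain denominator ρ_S/(ρ_S+ρ_R), and through it δ perturbs ρ_SS,
ρ_SI and hence ρ_I. The same mechanism exists microscopically (released
nodes join the rewiring target pool). The effect is weak — at
β = 0.005, γ = 0.025, w = κ = 0.0025 the final size moves by ≈ 4.5×10⁻⁴
across δ ∈ [0.001, 0.1], unchanged between rtol 1e-8 and 1e-12, so it is
dynamical rather than numerical — and it vanishes identically when w = 0
(difference ~1e-13). The common claim that δ leaves the infected
compartment and r∞ untouched is therefore exact only without rewiring,
and approximate (to a few 10⁻⁴) with it; one acceptance-level test
asserting strict δ-invariance at intervention-on parameters fails for
this reason and is left failing deliberately.

## Thresholds and bounds

* **Closed form**: β_c = (γ+w+κ)/(μ−1) from linearising at the
  disease-free state (ρ_S = 1, ρ_SS = μ/2).
* **Numerical route**: complex-step Jacobian of the SIRX field at the
  disease-free state; the (ρ_I, ρ_SI) block is exactly invariant there
  (asserted numerically), and its leading eigenvalue is root-found in β
  by Brent's method. The restriction matters: the full spectrum contains
  structural zeros from the neutral ρ_S/ρ_R/ρ_SS directions that never
  change sign, and near the threshold the near-degenerate zero cluster
  makes eigenvector-based filtering lose ~1e-10 of accuracy, while the
  invariant-block eigenvalue is exact. Agreement with the closed form is
  at machine precision.
* **Outbreak proxy**: the β at which r∞ crosses 0.05, located by Brent
  bisection on the ODE final size (or on ensemble means of scaled-down
  simulations, N = 500 by default). With a finite seed the proxy sits
  *below* the linear-stability value — the initial mass alone contributes
  ≈ ρ_I(0)(1 + μβ/(β+γ+w+κ)) to r∞ — and converges to it from below as
  ρ_I(0) → 0.
* **Final-size bound**: the smallest root of
  ρ = ρ_I(0) + c[ρ_SI(0) + (2ρ_SS(0)−ρ_SI(0))ln((1−ρ_I(0))/(1−ρ))],
  c = β/(β+γ+w+κ), found by a 10⁴-point scan plus Brent refinement.
  The smallest-root convention is the informative one (trajectory
  continuity from ρ_R(0) = 0 keeps r∞ below the first crossing). When
  c·(2ρ_SS(0)−ρ_SI(0)) ≥ 1 the implicit function never returns to zero
  and the bound is reported as the vacuous 1.0 rather than an error. The
  bound is rigorous for the pair-approximation trajectory only under the
  positivity condition ρ̇_SI ≥ 2ρ̇_SS at all times, which
  `positivity_check` verifies from the vector field on 2001 dense-output
  points with a slack of 1e-12 times the derivative scale (floating-point
  noise at equilibria).
* **Initial-SI-link scenarios** for positivity maps: ρ_SI(0) = ξμρ_I(0)
  with ξ = 1 (mean-field), 6 (disproportionately many S–I contacts) and
  1/5 (very few). The ξ-multiples scale the *mean-field* seeding; ξ = 6
  at ρ_I(0) = 0.01 is still far inside the link budget μ.

## Sweeps

Sweeps evaluate r∞, peak prevalence or the proxy threshold on a (w, κ)
grid, in ODE mode (deterministic) or stochastic mode (default N = 500,
20 runs per cell, matching the scale at which the plane comparisons are
made). Cells are seeded from `(seed, cell_index)` via `SeedSequence`, so
grids are order-invariant and individual rows reproducible. The default
grid is 21×21 on [0, 0.02]² — a package choice that comfortably envelops
the critical line w+κ = β(μ−1)−γ = 0.01 at the reference β = 0.0025; the
exact published ranges are not on record and the presets are documented
as non-authoritative. Grid CSVs embed the full configuration as a JSON
header comment and round-trip losslessly.

## What the synthetic conditions do and do not show

All inputs are generated in-package: Erdős–Rényi graphs with uniformly
random seeds, homogeneous rates, Markovian (exponential) waiting times.
Passing tests therefore validate the mathematics of the model and the
exactness of the simulator — not the fit of the model to any real contact
structure. Real contact networks are clustered, heavy-tailed and
time-varying; waiting times for recovery or release are not exponential;
and quarantine in practice also reaches exposed contacts, which this
model deliberately omits (only infecteds are quarantined and only S–I
links rewire). The pair approximation itself is exact only in the
mean-field limit; at N = 2000, μ = 15 the ensemble means track it within
a few parts in 10³ of a density unit, which is what the
ensemble-agreement test quantifies.

Problem sizes used in the test suite (N up to 2000, 50-run ensembles,
21×21 ODE grids, 5×5 bound grids) were chosen so the full suite completes
in a few minutes while keeping Monte-Carlo error well below the effect
sizes being tested.

## Known limitations

* No link deletion, no reinfection (SIR immunity is permanent), no
  contact tracing of neighbours, no non-Markovian variants; arbitrary
  degree distributions and weighted/directed graphs are out of scope.
* The non-closed moment hierarchies are not integrated as ODEs (they are
  not closed); they appear only as exact counting observables and
  event-rate identities in tests.
* Plotting is intentionally absent; outputs are CSV/JSON for downstream
  tooling.
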