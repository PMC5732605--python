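# Methods

## Model and numerical scheme

A temporal–causal network is specified declaratively by connection weights
ω<sub>X,Y</sub>, per-state combination functions c<sub>Y</sub>(..) and speed
factors η<sub>Y</sub>. The engine integrates the coupled difference equations

    Y(t+Δt) = Y(t) + η_Y [ c_Y(ω_{X1,Y} X1(t), …, ω_{Xk,Y} Xk(t)) − Y(t) ] Δt

with a first-order synchronous Euler scheme: every state — including every
reified weight state — is updated from the same time-t snapshot. The
simultaneous difference equations imply this Jacobi-style update; a
sequential (Gauss–Seidel) update would also break the exact equivalence
between the reified and direct simulation paths (below). Higher-order or
adaptive integrators are deliberately out of scope: the first-order
difference equation *is* the model definition, not an approximation of one.

Defaults: Δt = 0.01. With the homophily parameters used throughout
(α = 20, η = 0.3) the largest derivative scale is ≈ η·α/4 ≈ 1.5 per unit
weight, so Δt = 0.01 resolves it comfortably. Values are clipped to [0, 1]
after each step (`clip_unit_interval=True` by default): the homophily
derivative vanishes analytically at Ω ∈ {0, 1}, but Euler can overshoot the
boundary by O(Δt); clipping makes the boundaries exactly absorbing, as in
the continuous model. Clipping can be disabled for models that legitimately
leave the unit interval (e.g. oscillators with negative weights).

Degenerate dynamic scaled sum: when a state's incoming weights sum to below
1e−6 the aggregated impact is defined as 0 ("no remaining input") and a
warning is logged once per run, rather than raising — the homophily model
reaches this state routinely for persons cut off from every cluster.
Exact threshold ties |X_A − X_B| = τ_h have derivative exactly 0 and need no
special-casing. Non-finite values abort the run with the offending state and
time; with clipping enabled they cannot occur, so the check runs at recording
points only.

## Reification and the equivalence oracle

Each adaptive weight becomes a state Ω<sub>X,Y</sub> = `W[X->Y]` (the naming
is deterministic and collision-checked against user ids) with unit-weight
inputs and initial value equal to the connection's initial weight, so
Ω(t) = ω(t) for all t. Static incoming connections of a lifted target keep
their weight folded in before the lifted combiner, matching
c\*(V₁, V₂, W) = c(W·V₁, V₂) where V₂ already contains its static weight.

`simulate_direct` integrates the same models with in-place weight updates and
no Ω-states. Both paths intentionally share the compiled combination-function
evaluators and aggregate in connection-declaration order with plain
sequential sums, so their trajectories agree *bitwise*; the test suite
asserts agreement at 1e−12. This ordering contract is why the engine does not
vectorise its inner sums: differing summation orders would degrade the
equivalence from exact to ≈1e−13 over long runs.

## Adaptation principles

Homophily uses c(V₁, V₂, W) = W + αW(1−W)(τ_h − |V₁−V₂|). The amplification
factor α generalises the unit-amplification form of the rule (β = αW(1−W));
α = 20, τ_h = 0.025, state speed 0.5 and connection speed 0.3 are the
canonical experiment's values and the fixture defaults. Homophily acts per
directed connection; the two directions of a mutual pair co-evolve
identically only when their initial weights coincide (the generator has a
`symmetric_weights` switch for that study).

More-becomes-more excludes a weight's own value from its peer aggregate:
renaming the adapting connection as the (k+1)-th peer gives k+1 equations in
which each weight tracks the other k. With the scaled sum (λ = k) the update
is exact peer averaging, which conserves the total weight — this is the
derived oracle behind the Method B check: at equilibrium all weights are
equal, and conservation pins the common value at the mean of the initial
weights. The engine supports weights that both adapt and carry contagion, or
adapt only (the star fixture clamps all states, since the principle reads
only the other weights).

## Verification methods

* **Method A** detects stationary points in a recorded trajectory — slope
  sign changes (maxima/minima) and |slope| < `slope_tol` runs (plateaus,
  recorded at the run's end where the values are most converged) — and
  substitutes the simulated values into c<sub>Y</sub>(..) = Y(t). The default
  residual tolerance is 0.05 (exposed as a flag); at a true equilibrium of an
  analytically solvable model the residual is below 1e−6. Extremum residuals
  are limited by the recording granularity (the detected peak sits within one
  recorded step of the true one), which is why small Δt and stride matter for
  oscillating models.
* **Method B** is implemented exactly where explicit solving works: the
  linear scaled-sum more-becomes-more system (an explicit (k+1)×(k+1) solve
  of k equilibrium rows plus the conservation row — not a hard-coded answer)
  and the symmetric logistic fixed point w = c(w, …, w), found by bisection
  on [0, 1] after a sign-change scan. For general logistic networks explicit
  solving is not available, which is precisely Method A's niche.

The fixed-point uniqueness argument applies to the monotonically *decreasing*
per-weight response f(V) = [1/(1+κe^{σV}) − μ]ν with the peer total frozen.
The diagonal residual g(w) = c(w, …, w) − w is **not** globally monotone: for
a steep sigmoid with a high threshold (e.g. σ = 5, τ = 1, k = 3) g has an
exact root at 0 plus two interior crossings — the classic bistable regime.
The solver therefore reports the number of strict sign changes on a grid
(10⁴ points in the uniqueness checks), raises a dedicated error for the
identity-map case (scaled sum with λ = k, where every w is a fixed point),
and returns an exact endpoint root when no interior bracket exists.
Uniqueness is asserted, and tested, in the single-crossing regime
(σ = 3, τ = 0.5, k = 3, where the slope of c at 0 exceeds 1).

* **Equal-equilibrium theorem check**: symmetry and monotonicity of the
  combiner are established on a seeded grid (48 random points plus corners,
  tolerance 1e−12, all permutations); if either fails the check is skipped
  with a stated reason. Otherwise random initialisations of the fully
  connected equal-weight network are integrated to near-equilibrium
  (final drift below 1e−5) and the spread max−min of the final state values
  is compared against 1e−3. Non-convergent runs are counted inconclusive,
  not failed — the theorem speaks only about joint stationary points.

* **Cluster extraction** operationalises the qualitative clustering
  observation: the weight matrix is symmetrised by the maximum of the two
  directions, pairs at or above the threshold (default 0.5; ties connect)
  are linked, and clusters are connected components. `intra_min`/`inter_max`
  are `None` when no within- or between-cluster pair exists (singleton or
  single-cluster partitions) rather than inventing a value.

## Synthetic fixtures: what they emulate and what they do not

The homophily fixture reproduces the canonical experiment's *structure and
dynamics*: 10 persons, fully connected (90 directed connections, no
self-connections), contagion by the dynamic scaled sum, all weights adaptive
under homophily with α = 20, τ_h = 0.025, η = 0.5/0.3. The published initial
weight table is not available in machine-readable form, so initial
conditions are seeded random draws: state values U(0.3, 0.7) — moderate,
unsaturated activation levels — and weights U(0.1, 0.9), spread over the
interior of the unit interval. The state range matters dynamically: weights
between persons that differ widely collapse early, and if the persons later
merge into one cluster the weight must climb back at the slow interior rate
η·α·τ_h·W(1−W) ≈ 0.15·W(1−W); drawing initial states across the full unit
interval therefore leaves a substantial fraction of runs still in transit at
t = 100, whereas the moderate range reaches the fully bimodal end state
(every weight within 0.05 of {0, 1}) in ≥ 18 of 20 seeds at that horizon,
the calibration the fixture is specified to meet. Consequently the fixture
typically forms 1–2 clusters rather than the three of the published plot,
whose exact initial table, Δt and horizon are unknowable from the text;
passing tests demonstrate the qualitative law (bimodal weight limits, clean
cluster structure), not a curve-level reproduction.

Problem sizes used in tests and the acceptance script — two-state clamped
runs to t = 200, the 10-state fixture to t = 100 across 20 seeds, random
3–5-state networks to t = 5 for the equivalence check — were chosen as the
smallest sizes at which the respective properties are exhibited cleanly.

## Known limitations

* No symbolic equilibrium solving for arbitrary combiners, and no formal
  attractor/stability classification; "attracting" is probed only through
  the theorem check's convergence heuristic.
* Hybrid homophily + more-becomes-more adaptation of the *same* connection
  is rejected (one principle per connection); distinct connections of one
  network may use different principles.
* The logistic exponent clamp at ±500 is a non-semantic overflow guard.
* Combination functions are restricted to the named families plus the
  lifted/homophily forms; arbitrary user code is not accepted through the
  JSON interface (library users can still pass callables to the analysis
  helpers that accept them).
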