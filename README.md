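# tcnet — adaptive temporal–causal network modelling

`tcnet` simulates and analyses **temporal–causal networks**: directed graphs
whose node activation levels evolve in continuous time under weighted causal
impacts, and whose connection weights may themselves evolve ("adaptive"
networks). It is aimed at modellers of social and cognitive contagion
processes who want both a declarative simulation engine and the matching
mathematical verification toolkit.

## The model

Each state *Y* carries an activation level *Y(t)*. A connection *X → Y* has
weight ω<sub>X,Y</sub>; the impacts ω<sub>X,Y</sub>·X(t) of all states
connected to *Y* are aggregated by a per-state combination function
c<sub>Y</sub>(..) and paced by a speed factor η<sub>Y</sub>:

```
Y(t+Δt) = Y(t) + η_Y [ c_Y(ω_{X1,Y} X1(t), …, ω_{Xk,Y} Xk(t)) − Y(t) ] Δt
```

integrated by synchronous (Jacobi-style) Euler steps. The combination-function
library covers sum, product, complement product, min/max, simple and advanced
logistic sums, scaled sums (including a *dynamic* scaled sum whose scaling
factor is the current sum of the incoming weights), and blended variants.

An adaptive weight is *reified* into a first-class state Ω<sub>X,Y</sub>
(column name `W[X->Y]`) with unit-weight links from its source, its target and
itself, and the target's combination function is lifted:
c\*(V₁, …, V<sub>k</sub>, W₁, …, W<sub>k</sub>) = c(W₁V₁, …, W<sub>k</sub>V<sub>k</sub>).
Two adaptation principles are built in:

* **Homophily** — `dΩ/dt = η · α Ω(1−Ω)(τ_h − |X_A − X_B|)`: connections
  strengthen when the endpoint levels are closer than the threshold τ_h and
  weaken otherwise; Ω = 0 and Ω = 1 are absorbing.
* **More-becomes-more** (preferential attachment) —
  `dω_{A,B}/dt = η [ c(ω_{C1,B}, …, ω_{Ck,B}) − ω_{A,B} ]`: a weight into a
  target follows the aggregate of the *other* incoming weights (scaled-sum
  averaging or logistic).

The analysis toolkit implements the stationary-point criterion
c<sub>Y</sub>(..) = Y(t), verification by substitution of simulated
stationary points (Method A), analytic equilibrium solving for the linear
more-becomes-more system and the symmetric logistic fixed point (Method B),
the equal-equilibrium theorem check for symmetric monotonic combiners, and
cluster extraction from converged weight matrices.

## Worked example

Hold two persons' states equal and let the connection between them adapt by
homophily (α = 20, τ_h = 0.025, connection speed 0.3):

```python
import tcnet as tc

net = tc.NetworkSpec(
    states=[tc.StateConfig("A", clamped=True), tc.StateConfig("B", clamped=True)],
    connections=[tc.Connection("A", "B", weight=0.5, adaptive=True)],
    adaptation=[tc.AdaptationBlock("homophily", "all",
                                   {"alpha": 20.0, "tau_h": 0.025, "eta": 0.3})],
)
rnet = tc.apply_adaptation(net)              # one Omega-state: W[A->B]
traj = tc.simulate(rnet, {"A": 0.6, "B": 0.6},
                   tc.SimulationSettings(dt=0.01, t_end=60.0, record_stride=1000))
for t in (0.0, 10.0, 20.0, 60.0):
    print(f"t={t:5.1f}  W[A->B] = {traj.at_time(t)['W[A->B]']:.6f}")
```

```
t=  0.0  W[A->B] = 0.500000
t= 10.0  W[A->B] = 0.817632
t= 20.0  W[A->B] = 0.952632
t= 60.0  W[A->B] = 0.999877
```

Because |X_A − X_B| = 0 < τ_h the weight grows logistically and saturates at
the absorbing boundary 1; clamping the states 0.6 apart instead drives it to
0. For the more-becomes-more averaging system, Method B predicts the common
equilibrium weight analytically:

```python
tc.solve_equilibrium_linear_mbm(2, [0.2, 0.5, 0.8])   # -> [0.5 0.5 0.5]
```

i.e. all three weights meet at the mean of their initial values, which the
simulated system reproduces (the averaging rule conserves the total weight).

The same workflow is available from a shell via the `tcnet` CLI
(`generate-fixture`, `simulate`, `verify`, `solve-equilibrium`, `clusters`).

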