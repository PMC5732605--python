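"""Mathematical analysis and verification of temporal-causal network models.

The central criterion: a state Y is stationary at t iff

    c_Y(omega_{X1,Y} X1(t), .., omega_{Xk,Y} Xk(t)) = Y(t),

increasing iff the aggregated impact exceeds Y(t) and decreasing iff it falls
below; an equilibrium is a joint stationary point of all states.  Two
verification methods build on it:

* Method A (substitution): locate stationary points in a simulated trajectory
  (peaks, dips, plateaus) and substitute the simulated values into the
  criterion; residuals below a tolerance (default 0.05) corroborate the
  implementation without solving anything.
* Method B (equation solving): solve the equilibrium equations analytically
  and compare predictions with simulation.  Implemented for the two cases
  that admit it: the linear scaled-sum system of the more-becomes-more model
  (all weights equal; the common value follows from weight conservation) and
  the symmetric fixed point w = c(w, .., w) of logistic combiners (bisection,
  with a uniqueness scan of the residual's sign changes).

The module also classifies homophily stationary points (Omega = 0, Omega = 1,
or endpoint difference exactly at the threshold), checks the
equal-equilibrium theorem for symmetric monotonic combiners on fully
connected equal-weight networks, and extracts the cluster partition a
converged homophily weight matrix induces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np

from .combinations import CombinationFunctionSpec, classify_properties, make_evaluator
from .engine import (
    SimulationSettings,
    Trajectory,
    aggregate_impacts,
    compile_network,
    simulate,
)
from .errors import (
    IdentityMapError,
    InputMismatchError,
    NoFixedPointError,
    UsageError,
)
from .model import Connection, NetworkSpec, ReifiedNetwork, StateConfig, StateId

__all__ = [
    "INCREASING",
    "DECREASING",
    "STATIONARY",
    "ZERO",
    "ONE",
    "THRESHOLD_DIFF",
    "NOT_STATIONARY",
    "StationaryPointRecord",
    "VerificationReport",
    "ClusterPartition",
    "TheoremReport",
    "classify_step",
    "detect_stationary_points",
    "verify_method_A",
    "solve_equilibrium_linear_mbm",
    "solve_symmetric_fixed_point",
    "count_fixed_point_sign_changes",
    "mbm_logistic_response",
    "classify_homophily_stationary",
    "check_equal_equilibrium_theorem",
    "extract_clusters",
    "weights_at",
]

INCREASING = "increasing"
DECREASING = "decreasing"
STATIONARY = "stationary"

ZERO = "ZERO"
ONE = "ONE"
THRESHOLD_DIFF = "THRESHOLD_DIFF"
NOT_STATIONARY = "NOT_STATIONARY"


def classify_step(agg: float, value: float) -> str:
    """Three-way criterion: compare aggregated impact with the state value.

    Exact comparison; callers supply their own tolerances where needed.
    """
    if agg > value:
        return INCREASING
    if agg < value:
        return DECREASING
    return STATIONARY


@dataclass
class StationaryPointRecord:
    state: StateId
    time: float
    value: float
    kind: str  # "maximum" | "minimum" | "plateau"
    residual: float  # |c(impacts) - value|; NaN when no network was supplied


@dataclass
class VerificationReport:
    records: list[StationaryPointRecord]
    tolerance: float
    passed: bool
    failures: list[StationaryPointRecord]


@dataclass
class ClusterPartition:
    clusters: list[set[StateId]]
    intra_min: float | None
    inter_max: float | None


@dataclass
class TheoremReport:
    skipped: bool
    reason: str | None
    spreads: list[float] = field(default_factory=list)  # max-min per converged trial
    inconclusive: int = 0
    passed: bool | None = None


def _residuals_at(
    net: NetworkSpec | ReifiedNetwork | None, traj: Trajectory, row: int
) -> dict[StateId, float]:
    if net is None:
        return {}
    snapshot = dict(zip(traj.columns, traj.data[row]))
    aggs = aggregate_impacts(net, snapshot)
    return {s: abs(a - snapshot[s]) for s, a in aggs.items()}


def detect_stationary_points(
    traj: Trajectory,
    state: StateId,
    slope_tol: float = 1e-4,
    net: NetworkSpec | ReifiedNetwork | None = None,
) -> list[StationaryPointRecord]:
    """Locate stationary points of one state's simulated trace.

    Interior sign changes of the finite-difference slope are flagged as
    maxima (+ to -) or minima (- to +); maximal runs with |slope| < slope_tol
    are flagged as plateaus, recorded at the end of the run.  When ``net`` is
    given each record carries the substitution residual |c(..) - Y(t)|.
    """
    y = traj.value(state)
    t = traj.times
    if t.size < 3:
        raise UsageError("stationary-point detection needs at least 3 recorded times")
    slopes = np.diff(y) / np.diff(t)

    records: list[StationaryPointRecord] = []

    def residual(row: int) -> float:
        res = _residuals_at(net, traj, row)
        return res.get(state, float("nan"))

    for i in range(1, slopes.size):
        if slopes[i - 1] > 0 and slopes[i] < 0:
            records.append(
                StationaryPointRecord(state, float(t[i]), float(y[i]), "maximum", residual(i))
            )
        elif slopes[i - 1] < 0 and slopes[i] > 0:
            records.append(
                StationaryPointRecord(state, float(t[i]), float(y[i]), "minimum", residual(i))
            )

    flat = np.abs(slopes) < slope_tol
    i = 0
    while i < flat.size:
        if flat[i]:
            j = i
            while j + 1 < flat.size and flat[j + 1]:
                j += 1
            end = j + 1  # slope j covers [t_j, t_{j+1}]
            records.append(
                StationaryPointRecord(
                    state, float(t[end]), float(y[end]), "plateau", residual(end)
                )
            )
            i = j + 1
        i += 1

    return records


def verify_method_A(
    traj: Trajectory,
    net: NetworkSpec | ReifiedNetwork,
    tolerance: float = 0.05,
    slope_tol: float = 1e-4,
) -> VerificationReport:
    """Method A: substitute simulated stationary values into the criterion.

    For every stationary point of every evolving state the aggregated impact
    is recomputed from the simulated snapshot and compared with the state
    value; the report fails if any residual reaches ``tolerance``.
    """
    names = set(net.state_ids if isinstance(net, ReifiedNetwork) else net.state_ids)
    missing = names.difference(traj.columns)
    if missing:
        raise InputMismatchError(
            f"trajectory is missing states {sorted(missing)!r} of the network"
        )

    comp = compile_network(net)
    evolving = [comp.names[i] for i, _e, _a in comp.updates]
    records: list[StationaryPointRecord] = []
    for state in evolving:
        records.extend(detect_stationary_points(traj, state, slope_tol, net=net))
    failures = [r for r in records if not (r.residual < tolerance)]
    return VerificationReport(
        records=records,
        tolerance=tolerance,
        passed=not failures,
        failures=failures,
    )


def solve_equilibrium_linear_mbm(
    k: int, initial_weights: Sequence[float]
) -> np.ndarray:
    """Method B for the scaled-sum more-becomes-more system.

    The joint stationary equations ((sum of the other k weights)/k = each
    weight, k+1 equations) force all weights equal; the averaging update
    conserves the total weight, which pins the common value at the mean of
    the initial weights.  The (k+1)x(k+1) system (k equilibrium rows plus the
    conservation row) is solved explicitly.
    """
    if k < 1:
        raise UsageError(f"k must be >= 1, got {k}")
    w0 = np.asarray(initial_weights, dtype=float)
    if w0.size != k + 1:
        raise UsageError(f"expected {k + 1} initial weights, got {w0.size}")

    n = k + 1
    a = np.empty((n, n))
    # first k rows: (sum_{j != i} w_j)/k - w_i = 0
    a[:k] = 1.0 / k
    for i in range(k):
        a[i, i] = -1.0
    a[k] = 1.0  # conservation of the total weight
    b = np.zeros(n)
    b[k] = w0.sum()
    return np.linalg.solve(a, b)


def _symmetric_residual(fn, k: int) -> Callable[[float], float]:
    ev = fn if callable(fn) else make_evaluator(fn)
    return lambda w: ev([w] * k) - w


def count_fixed_point_sign_changes(
    fn: CombinationFunctionSpec | Callable[[Sequence[float]], float],
    k: int,
    grid_points: int = 10_000,
) -> int:
    """Strict sign changes of g(w) = c(w, .., w) - w on a uniform grid in [0, 1]."""
    g = _symmetric_residual(fn, k)
    vals = np.array([g(w) for w in np.linspace(0.0, 1.0, grid_points)])
    sign = np.sign(vals)
    return int(np.sum(sign[:-1] * sign[1:] < 0))


def solve_symmetric_fixed_point(
    fn: CombinationFunctionSpec | Callable[[Sequence[float]], float],
    k: int,
    tol: float = 1e-12,
    scan_points: int = 1001,
) -> float:
    """Solve w = c(w, .., w) (k equal arguments) by bisection on [0, 1].

    Scans a grid for a strict sign change of g(w) = c(w, .., w) - w and
    bisects the first bracket; falls back to an exact endpoint root when the
    scan finds no bracket.  Raises :class:`IdentityMapError` when g vanishes
    identically (the scaled sum with lambda = k: every w is a fixed point)
    and :class:`NoFixedPointError` when there is neither a bracket nor an
    endpoint root.  For a monotonically decreasing residual the fixed point
    is unique; in bistable regimes :func:`count_fixed_point_sign_changes`
    reports how many crossings exist and the first is returned.
    """
    if k < 1:
        raise UsageError(f"k must be >= 1, got {k}")
    g = _symmetric_residual(fn, k)
    ws = np.linspace(0.0, 1.0, scan_points)
    gs = np.array([g(w) for w in ws])

    if np.all(np.abs(gs) < 1e-13):
        raise IdentityMapError(
            "c(w, .., w) = w identically: every value is a fixed point"
        )

    bracket = None
    for i in range(scan_points - 1):
        if gs[i] * gs[i + 1] < 0:
            bracket = (float(ws[i]), float(ws[i + 1]))
            break
    if bracket is None:
        if abs(gs[0]) < 1e-13:
            return 0.0
        if abs(gs[-1]) < 1e-13:
            return 1.0
        raise NoFixedPointError(
            "g(w) = c(w, .., w) - w has no sign change and no endpoint root on [0, 1]"
        )

    lo, hi = bracket
    glo = g(lo)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        gm = g(mid)
        if gm == 0.0 or hi - lo < tol:
            return mid
        if (gm > 0) == (glo > 0):
            lo, glo = mid, gm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def mbm_logistic_response(v: float, sigma: float, kappa: float, mu: float, nu: float) -> float:
    """f(V) = [1/(1 + kappa e^{sigma V}) - mu] nu.

    The per-weight response of the logistic more-becomes-more stationary
    equations; monotonically non-increasing in V for kappa, sigma, nu > 0,
    which is what makes the joint fixed point unique.
    """
    return (1.0 / (1.0 + kappa * np.exp(sigma * v)) - mu) * nu


def classify_homophily_stationary(
    omega: float, v_a: float, v_b: float, tau_h: float, tol: float = 0.0
) -> str:
    """Which of the three homophily stationary-point types applies, if any.

    The derivative factorises as alpha * Omega * (1 - Omega) * (tau_h -
    |X_A - X_B|), so a stationary point requires Omega = 0, Omega = 1, or the
    endpoint difference exactly at the threshold.  Weight-boundary labels
    take precedence when both hold.
    """
    if tol < 0:
        raise UsageError(f"tolerance must be >= 0, got {tol}")
    if abs(omega) <= tol:
        return ZERO
    if abs(omega - 1.0) <= tol:
        return ONE
    if abs(abs(v_a - v_b) - tau_h) <= tol:
        return THRESHOLD_DIFF
    return NOT_STATIONARY


def fully_connected_network(
    n: int,
    combiner: CombinationFunctionSpec,
    speed: float = 0.5,
    weight: float = 1.0,
) -> NetworkSpec:
    """Fully connected n-state network (no self-connections), equal weights."""
    ids = [f"X{i + 1}" for i in range(n)]
    states = [StateConfig(id=s, speed=speed, combiner=combiner) for s in ids]
    conns = [
        Connection(a, b, weight) for a in ids for b in ids if a != b
    ]
    return NetworkSpec(states=states, connections=conns)


def check_equal_equilibrium_theorem(
    fn: CombinationFunctionSpec,
    n: int,
    trials: int = 10,
    seed: int = 0,
    t_end: float = 60.0,
    dt: float = 0.01,
    speed: float = 0.5,
    equal_tol: float = 1e-3,
    slope_tol: float = 1e-5,
) -> TheoremReport:
    """Check the equal-equilibrium theorem by simulation.

    For a fully connected n-state network with equal unit weights and a
    combination function that is symmetric and monotonic, every joint
    stationary point has all state values equal.  ``trials`` random
    initialisations are integrated to near-equilibrium and the spread
    (max - min) of the final state values is compared with ``equal_tol``.
    Runs whose final derivative magnitude exceeds ``slope_tol`` are counted
    as inconclusive rather than failures.  If the combiner fails the
    symmetry/monotonicity precondition the check is skipped with a reason.
    """
    props = classify_properties(fn, arity=n - 1)
    if not (props["symmetric"] and props["monotonic"]):
        missing = [p for p in ("symmetric", "monotonic") if not props[p]]
        return TheoremReport(
            skipped=True,
            reason=f"precondition failed: combination function is not {' and '.join(missing)}",
        )

    net = fully_connected_network(n, fn, speed=speed)
    settings = SimulationSettings(dt=dt, t_end=t_end, record_stride=max(1, int(1.0 / dt)))
    rng = np.random.default_rng(seed)
    spreads: list[float] = []
    inconclusive = 0
    for _ in range(trials):
        init = {s: float(v) for s, v in zip(net.state_ids, rng.uniform(0, 1, n))}
        traj = simulate(net, init, settings)
        final = traj.final()
        aggs = aggregate_impacts(net, final)
        max_drift = max(abs(a - final[s]) for s, a in aggs.items())
        if max_drift > slope_tol:
            inconclusive += 1
            continue
        vals = [final[s] for s in net.state_ids]
        spreads.append(max(vals) - min(vals))

    passed = bool(spreads) and all(s < equal_tol for s in spreads)
    return TheoremReport(
        skipped=False,
        reason=None,
        spreads=spreads,
        inconclusive=inconclusive,
        passed=passed,
    )


def _symmetrised(weights: Mapping[tuple[StateId, StateId], float]):
    sym: dict[frozenset, float] = {}
    states: list[StateId] = []
    seen = set()
    for (a, b), w in weights.items():
        if a == b:
            raise UsageError("cluster extraction expects distinct ordered pairs")
        for s in (a, b):
            if s not in seen:
                seen.add(s)
                states.append(s)
        key = frozenset((a, b))
        sym[key] = max(sym.get(key, float("-inf")), float(w))
    return states, sym


def extract_clusters(
    weights: Mapping[tuple[StateId, StateId], float], threshold: float = 0.5
) -> ClusterPartition:
    """Partition states by the connected components of strong weights.

    The weight map is symmetrised by the maximum of the two directions;
    pairs with symmetrised weight >= threshold (ties connect) are linked and
    clusters are the connected components.  ``intra_min``/``inter_max``
    summarise the symmetrised weights within and between clusters (``None``
    when no such pair exists).
    """
    states, sym = _symmetrised(weights)
    g = nx.Graph()
    g.add_nodes_from(states)
    for key, w in sym.items():
        if w >= threshold:
            a, b = tuple(key)
            g.add_edge(a, b)
    clusters = [set(c) for c in nx.connected_components(g)]
    cluster_of = {s: i for i, c in enumerate(clusters) for s in c}

    intra = [w for key, w in sym.items() if len({cluster_of[s] for s in key}) == 1]
    inter = [w for key, w in sym.items() if len({cluster_of[s] for s in key}) > 1]
    return ClusterPartition(
        clusters=clusters,
        intra_min=min(intra) if intra else None,
        inter_max=max(inter) if inter else None,
    )


def weights_at(traj: Trajectory, t: float) -> dict[tuple[StateId, StateId], float]:
    """Extract the ``W[src->tgt]`` columns of a trajectory at time ~t."""
    snapshot = traj.at_time(t)
    out: dict[tuple[StateId, StateId], float] = {}
    for name, v in snapshot.items():
        if name.startswith("W[") and name.endswith("]") and "->" in name:
            src, tgt = name[2:-1].split("->", 1)
            out[(src, tgt)] = v
    return out
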