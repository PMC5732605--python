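"""Synchronous Euler integration of the temporal-causal difference equations.

Every non-clamped state Y (including reified Omega-states) follows

    Y(t + dt) = Y(t) + eta_Y * [aggimpact_Y(t) - Y(t)] * dt

with aggimpact_Y(t) = c_Y(omega_{X1,Y} X1(t), .., omega_{Xk,Y} Xk(t)).  The
update is synchronous (Jacobi-style): every state reads the same time-t
snapshot, which the simultaneous difference equations imply and which the
reified/direct equivalence relies on.

The engine supports the dynamic scaled sum used by the homophily contagion
model: a state whose combiner is ``ssum`` with ``lam="dynamic"`` recomputes
the scaling factor each step as the sum of its current incoming connection
weights.  If that sum degenerates to ~0 (a state cut off from everybody, as
happens between homophily clusters), the aggregated impact is defined as 0
and a warning is logged once per run.

Aggregation accumulates in connection-declaration order with plain sequential
sums; :mod:`tcnet.adaptation` mirrors that order so direct weight-update
simulations reproduce reified ones exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .combinations import DYNAMIC, make_evaluator
from .errors import IntegrationDivergedError, SchemaError, UsageError
from .model import NetworkSpec, ReifiedNetwork, StateId

__all__ = [
    "SimulationSettings",
    "Trajectory",
    "impact",
    "agg_impact",
    "aggregate_impacts",
    "euler_step",
    "simulate",
]

_log = logging.getLogger(__name__)

DEGENERATE_LAMBDA = 1e-6


@dataclass
class SimulationSettings:
    """Euler integration settings: step size, horizon, recording, clipping."""

    dt: float = 0.01
    t_end: float = 10.0
    record_stride: int = 1
    clip_unit_interval: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise UsageError(f"dt must be > 0, got {self.dt}")
        if self.t_end <= 0 or self.dt > self.t_end:
            raise UsageError(f"t_end must be >= dt > 0, got t_end={self.t_end}")
        if int(self.record_stride) < 1:
            raise UsageError(f"record_stride must be >= 1, got {self.record_stride}")
        self.record_stride = int(self.record_stride)

    @property
    def n_steps(self) -> int:
        return int(round(self.t_end / self.dt))


@dataclass
class Trajectory:
    """Recorded time grid and the value of every state at every grid point."""

    times: np.ndarray
    columns: tuple[StateId, ...]
    data: np.ndarray  # shape (len(times), len(columns))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (self.times.size, len(self.columns)):
            raise UsageError("trajectory data shape does not match times/columns")

    def index_of(self, sid: StateId) -> int:
        try:
            return self.columns.index(sid)
        except ValueError:
            raise KeyError(sid) from None

    def value(self, sid: StateId) -> np.ndarray:
        """The full time series of one state."""
        return self.data[:, self.index_of(sid)]

    def at_time(self, t: float) -> dict[StateId, float]:
        """State values at the recorded time closest to ``t``."""
        i = int(np.argmin(np.abs(self.times - t)))
        return dict(zip(self.columns, self.data[i]))

    def final(self) -> dict[StateId, float]:
        return dict(zip(self.columns, self.data[-1]))

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.data, columns=list(self.columns))
        frame.insert(0, "t", self.times)
        return frame


# ---------------------------------------------------------------------------
# compilation


class CompiledNetwork:
    """Index-based update plan for a (possibly reified) network."""

    def __init__(self, net: NetworkSpec | ReifiedNetwork):
        if isinstance(net, ReifiedNetwork):
            base, omegas = net.base, net.omegas
        else:
            if net.adaptation:
                raise UsageError(
                    "network declares adaptation blocks; reify it first "
                    "(tcnet.apply_adaptation) or use simulate_direct"
                )
            base, omegas = net, []
        self.net = net
        self.names: list[StateId] = base.state_ids + [om.id for om in omegas]
        self.index: dict[StateId, int] = {n: i for i, n in enumerate(self.names)}
        self.omega_init: dict[StateId, float] = {om.id: om.init for om in omegas}
        omega_of = {(om.source, om.target): om.id for om in omegas}
        self.warned_degenerate = [False]

        # (state index, speed factor, aggregation closure)
        self.updates: list[tuple[int, float, Callable]] = []
        for cfg in base.states:
            if cfg.clamped:
                continue
            conns = base.incoming(cfg.id)
            if not conns:
                continue  # validation guarantees clamped, defensive only
            terms = []
            for c in conns:
                oid = omega_of.get(c.pair)
                if oid is not None:
                    terms.append((self.index[c.source], self.index[oid], 1.0))
                else:
                    terms.append((self.index[c.source], -1, c.weight))
            agg = self._make_agg(cfg.combiner, tuple(terms))
            self.updates.append((self.index[cfg.id], cfg.speed, agg))

        for om in omegas:
            terms = tuple((self.index[inp], -1, 1.0) for inp in om.inputs)
            agg = self._make_agg(om.combiner, terms)
            self.updates.append((self.index[om.id], om.speed, agg))

    def _make_agg(self, combiner, terms) -> Callable:
        if combiner.family == "ssum" and combiner.param("lam") == DYNAMIC:
            warned = self.warned_degenerate

            def agg(cur, terms=terms, warned=warned):
                s = 0.0
                lam = 0.0
                for vi, wi, w in terms:
                    ww = w if wi < 0 else cur[wi]
                    s += cur[vi] * ww
                    lam += ww
                if lam < DEGENERATE_LAMBDA:
                    if not warned[0]:
                        _log.warning(
                            "dynamic scaled sum: incoming weights sum to ~0; "
                            "aggregated impact defined as 0"
                        )
                        warned[0] = True
                    return 0.0
                return s / lam

            return agg

        ev = make_evaluator(combiner)

        def agg(cur, terms=terms, ev=ev):
            return ev([cur[vi] * (w if wi < 0 else cur[wi]) for vi, wi, w in terms])

        return agg

    def initial_vector(self, init: Mapping[StateId, float], clip: bool) -> list[float]:
        cur = []
        for name in self.names:
            if name in init:
                v = float(init[name])
            elif name in self.omega_init:
                v = float(self.omega_init[name])
            else:
                raise UsageError(f"initial value for state {name!r} is missing")
            if clip and not 0.0 <= v <= 1.0:
                raise UsageError(
                    f"initial value {v} of state {name!r} is outside [0, 1] "
                    "while clipping is enabled"
                )
            cur.append(v)
        return cur


def compile_network(net: NetworkSpec | ReifiedNetwork) -> CompiledNetwork:
    return CompiledNetwork(net)


# ---------------------------------------------------------------------------
# operations


def impact(weight: float, source_value: float) -> float:
    """The causal impact of a state on a target: impact = omega * X(t)."""
    return weight * source_value


def agg_impact(
    target: StateId,
    net: NetworkSpec | ReifiedNetwork,
    current: Mapping[StateId, float],
) -> float:
    """Aggregated impact on ``target`` given a snapshot of state values.

    Applies the target's (possibly lifted) combination function to its
    incoming impacts in declaration order; dynamic scaled sums resolve their
    scaling factor from the snapshot.
    """
    comp = compile_network(net)
    if target not in comp.index:
        raise SchemaError(f"unknown state {target!r}")
    cur = [float(current.get(n, comp.omega_init.get(n, math.nan))) for n in comp.names]
    for i, _eta, agg in comp.updates:
        if i == comp.index[target]:
            return agg(cur)
    raise UsageError(f"state {target!r} has no incoming connections to aggregate")


def aggregate_impacts(
    net: NetworkSpec | ReifiedNetwork, current: Mapping[StateId, float]
) -> dict[StateId, float]:
    """Aggregated impacts of all evolving states for one snapshot."""
    comp = compile_network(net)
    cur = [float(current.get(n, comp.omega_init.get(n, math.nan))) for n in comp.names]
    return {comp.names[i]: agg(cur) for i, _eta, agg in comp.updates}


def euler_step(
    net: NetworkSpec | ReifiedNetwork,
    current: Mapping[StateId, float],
    dt: float,
    clip_unit_interval: bool = True,
    time: float = 0.0,
) -> dict[StateId, float]:
    """One synchronous Euler step: every state updated from the same snapshot."""
    if dt <= 0:
        raise UsageError(f"dt must be > 0, got {dt}")
    comp = compile_network(net)
    cur = comp.initial_vector(current, clip=False)
    nxt = list(cur)
    for i, eta, agg in comp.updates:
        y = cur[i]
        v = y + eta * (agg(cur) - y) * dt
        if clip_unit_interval:
            v = 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)
        if not math.isfinite(v):
            raise IntegrationDivergedError(comp.names[i], time + dt)
        nxt[i] = v
    return dict(zip(comp.names, nxt))


def simulate(
    net: NetworkSpec | ReifiedNetwork,
    init: Mapping[StateId, float],
    settings: SimulationSettings,
) -> Trajectory:
    """Integrate the network and record the trajectory.

    ``init`` must cover all base states; Omega-states default to their
    connection's initial weight and may be overridden by their ``W[src->tgt]``
    id.  The run is deterministic given (net, init, settings).
    """
    comp = compile_network(net)
    clip = settings.clip_unit_interval
    dt = settings.dt
    stride = settings.record_stride
    n_steps = settings.n_steps

    cur = comp.initial_vector(init, clip=clip)
    rows = [list(cur)]
    rec_times = [0.0]
    updates = comp.updates

    for step in range(1, n_steps + 1):
        nxt = list(cur)
        for i, eta, agg in updates:
            y = cur[i]
            v = y + eta * (agg(cur) - y) * dt
            if clip:
                v = 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)
            nxt[i] = v
        cur = nxt
        if step % stride == 0:
            t = step * dt
            for i, v in enumerate(cur):
                if not math.isfinite(v):
                    raise IntegrationDivergedError(comp.names[i], t)
            rows.append(list(cur))
            rec_times.append(t)

    return Trajectory(
        times=np.array(rec_times), columns=tuple(comp.names), data=np.array(rows)
    )
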