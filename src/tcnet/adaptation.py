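"""Adaptation principles for evolving connections: homophily and more-becomes-more.

Homophily ("birds of a feather flock together"): a connection weight
Omega_{A,B} strengthens while the endpoint states agree to within a threshold
and weakens otherwise,

    dOmega/dt = eta * [alpha * Omega * (1 - Omega) * (tau_h - |X_A - X_B|)],

so 0 and 1 are absorbing weight values and the threshold difference is the
only interior stationary point.

More-becomes-more (preferential attachment): the weight of a connection into
a popular target grows with the strengths of the *other* connections into the
same target,

    d omega_{A,B}/dt = eta * [c(omega_{C1,B}, .., omega_{Ck,B}) - omega_{A,B}],

where C_1..C_k are the other states connected to B and c is a scaled sum with
lambda = k (averaging, which conserves the total weight) or an advanced
logistic sum.  A weight's own value is excluded from its peer aggregate.

Both principles are wired onto a base network by reifying each adaptive
weight into an Omega-state (:func:`apply_homophily`,
:func:`apply_more_becomes_more`, :func:`apply_adaptation`).
:func:`simulate_direct` integrates the same models with in-place weight
updates and no Omega-states; because Omega_{X,Y}(t) = omega_{X,Y}(t) by
construction, it reproduces the reified trajectories exactly and serves as an
equivalence oracle for the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .combinations import DYNAMIC, CombinationFunctionSpec, make_evaluator
from .engine import (
    DEGENERATE_LAMBDA,
    SimulationSettings,
    Trajectory,
)
from .errors import ConfigError, IntegrationDivergedError, UsageError
from .model import (
    AdaptationBlock,
    NetworkSpec,
    OmegaState,
    ReifiedNetwork,
    StateId,
    omega_state_id,
)

__all__ = [
    "AdaptationBlock",
    "apply_homophily",
    "apply_more_becomes_more",
    "apply_adaptation",
    "simulate_direct",
]


@dataclass(frozen=True)
class _WeightRule:
    """Resolved update rule for one adaptive connection weight."""

    source: StateId
    target: StateId
    speed: float
    combiner: CombinationFunctionSpec
    # "endpoints": aggregate (source value, target value, own weight);
    # "peers": aggregate the listed peer weights (more-becomes-more).
    kind: str
    peers: tuple[tuple[StateId, StateId], ...] = ()
    init: float = 0.0


def _selected_pairs(net: NetworkSpec, block: AdaptationBlock) -> list:
    if block.pairs == "all":
        conns = list(net.connections)
        if block.principle == "homophily":
            conns = [c for c in conns if c.source != c.target]
        return conns
    conns = []
    for s, t in block.pairs:
        try:
            conns.append(net.connection(s, t))
        except KeyError:
            raise ConfigError(
                f"adaptation block refers to non-existent connection {s!r}->{t!r}"
            ) from None
    return conns


def _resolve_block(net: NetworkSpec, block: AdaptationBlock) -> list[_WeightRule]:
    conns = _selected_pairs(net, block)
    eta = float(block.params.get("eta", 1.0))
    if not 0.0 <= eta <= 1.0:
        raise ConfigError(f"connection speed factor eta must be in [0, 1], got {eta}")

    if block.principle == "homophily":
        alpha = float(block.params.get("alpha", 20.0))
        tau_h = float(block.params.get("tau_h", block.params.get("tau", 0.025)))
        spec = CombinationFunctionSpec("homophily", {"alpha": alpha, "tau_h": tau_h})
        rules = []
        for c in conns:
            if c.source == c.target:
                raise ConfigError(
                    f"homophily cannot be applied to self-connection {c.source!r}"
                )
            rules.append(
                _WeightRule(c.source, c.target, eta, spec, "endpoints", init=c.weight)
            )
        return rules

    # more becomes more
    combiner = block.params.get("combiner")
    by_target: dict[StateId, list] = {}
    for c in conns:
        by_target.setdefault(c.target, []).append(c)
    rules = []
    for c in conns:
        peers = tuple(p.pair for p in by_target[c.target] if p.pair != c.pair)
        if not peers:
            raise ConfigError(
                f"more-becomes-more weight {c.source!r}->{c.target!r} has no peer "
                "connections into the same target to aggregate"
            )
        k = len(peers)
        if combiner is None:
            spec = CombinationFunctionSpec("ssum", {"lam": float(k)})
        elif combiner.family == "ssum" and combiner.param("lam") is None:
            spec = CombinationFunctionSpec("ssum", {"lam": float(k)})
        else:
            spec = combiner
        rules.append(_WeightRule(c.source, c.target, eta, spec, "peers", peers, c.weight))
    return rules


def _resolve_blocks(
    net: NetworkSpec, blocks: Sequence[AdaptationBlock]
) -> list[_WeightRule]:
    rules: list[_WeightRule] = []
    seen: set[tuple[StateId, StateId]] = set()
    for block in blocks:
        for rule in _resolve_block(net, block):
            pair = (rule.source, rule.target)
            if pair in seen:
                raise ConfigError(
                    f"connection {pair[0]!r}->{pair[1]!r} is adapted by more than one block"
                )
            seen.add(pair)
            rules.append(rule)
    for c in net.connections:
        if c.adaptive and c.pair not in seen:
            raise ConfigError(
                f"adaptive connection {c.source!r}->{c.target!r} is not covered by "
                "any adaptation block"
            )
    return rules


def _reify(net: NetworkSpec, rules: Sequence[_WeightRule]) -> ReifiedNetwork:
    omega_id = {(r.source, r.target): omega_state_id(r.source, r.target) for r in rules}
    omegas = []
    for r in rules:
        oid = omega_id[(r.source, r.target)]
        if r.kind == "endpoints":
            inputs = (r.source, r.target, oid)
        else:
            inputs = tuple(omega_id[p] for p in r.peers)
        omegas.append(
            OmegaState(
                id=oid,
                source=r.source,
                target=r.target,
                speed=r.speed,
                combiner=r.combiner,
                inputs=inputs,
                init=r.init,
            )
        )
    return ReifiedNetwork(base=net, omegas=omegas)


def apply_homophily(net: NetworkSpec, block: AdaptationBlock) -> ReifiedNetwork:
    """Reify the block's connections with the homophily weight combiner.

    Each Omega-state aggregates (source value, target value, own value); each
    direction of a mutual connection evolves independently.
    """
    if block.principle != "homophily":
        raise ConfigError(f"expected a homophily block, got {block.principle!r}")
    return _reify(net, _resolve_block(net, block))


def apply_more_becomes_more(net: NetworkSpec, block: AdaptationBlock) -> ReifiedNetwork:
    """Reify the block's connections with the more-becomes-more combiner.

    Each weight's Omega-state aggregates the Omega-states of all *other*
    selected connections into the same target (scaled sum with lambda = peer
    count unless the block names a combiner).
    """
    if block.principle != "more_becomes_more":
        raise ConfigError(f"expected a more_becomes_more block, got {block.principle!r}")
    return _reify(net, _resolve_block(net, block))


def apply_adaptation(
    net: NetworkSpec, blocks: Sequence[AdaptationBlock] | None = None
) -> ReifiedNetwork:
    """Reify all adaptation blocks of ``net`` (or the given ones) jointly."""
    if blocks is None:
        blocks = net.adaptation
    return _reify(net, _resolve_blocks(net, blocks))


# ---------------------------------------------------------------------------
# direct (non-reified) simulation: the equivalence oracle


def simulate_direct(
    net: NetworkSpec,
    blocks: Sequence[AdaptationBlock] | None,
    init: Mapping[StateId, float],
    settings: SimulationSettings,
) -> Trajectory:
    """Integrate with in-place weight updates instead of Omega-states.

    Same contract as :func:`tcnet.engine.simulate` on the reified network:
    state values and connection weights are updated synchronously from the
    time-t snapshot, weights evolve per the adaptation rules, and the
    trajectory reports weights under their ``W[src->tgt]`` column names.

    The aggregation order (connection declaration order) and the shared
    combination-function evaluators make this numerically identical to the
    reified run, not merely close.
    """
    if blocks is None:
        blocks = net.adaptation
    rules = _resolve_blocks(net, blocks)
    clip = settings.clip_unit_interval
    dt = settings.dt

    state_ids = net.state_ids
    sidx = {s: i for i, s in enumerate(state_ids)}
    widx = {(r.source, r.target): j for j, r in enumerate(rules)}

    xs = []
    for s in net.states:
        if s.id not in init:
            raise UsageError(f"initial value for state {s.id!r} is missing")
        v = float(init[s.id])
        if clip and not 0.0 <= v <= 1.0:
            raise UsageError(
                f"initial value {v} of state {s.id!r} is outside [0, 1] "
                "while clipping is enabled"
            )
        xs.append(v)
    ws = [
        float(init.get(omega_state_id(r.source, r.target), r.init)) for r in rules
    ]

    # per-state aggregation plans over (source index, weight slot or -1, static weight)
    state_plans = []
    for cfg in net.states:
        if cfg.clamped:
            continue
        conns = net.incoming(cfg.id)
        if not conns:
            continue
        terms = tuple(
            (sidx[c.source], widx.get(c.pair, -1), c.weight) for c in conns
        )
        dynamic = cfg.combiner.family == "ssum" and cfg.combiner.param("lam") == DYNAMIC
        ev = None if dynamic else make_evaluator(cfg.combiner)
        state_plans.append((sidx[cfg.id], cfg.speed, terms, dynamic, ev))

    weight_plans = []
    for j, r in enumerate(rules):
        ev = make_evaluator(r.combiner)
        if r.kind == "endpoints":
            args = (sidx[r.source], sidx[r.target])
        else:
            args = tuple(widx[p] for p in r.peers)
        weight_plans.append((j, r.speed, r.kind, args, ev))

    columns = tuple(state_ids) + tuple(
        omega_state_id(r.source, r.target) for r in rules
    )
    rows = [xs + ws]
    rec_times = [0.0]

    for step in range(1, settings.n_steps + 1):
        new_xs = list(xs)
        for i, eta, terms, dynamic, ev in state_plans:
            if dynamic:
                s = 0.0
                lam = 0.0
                for vi, wj, w in terms:
                    ww = w if wj < 0 else ws[wj]
                    s += xs[vi] * ww
                    lam += ww
                agg = 0.0 if lam < DEGENERATE_LAMBDA else s / lam
            else:
                agg = ev([xs[vi] * (w if wj < 0 else ws[wj]) for vi, wj, w in terms])
            y = xs[i]
            v = y + eta * (agg - y) * dt
            if clip:
                v = 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)
            new_xs[i] = v

        new_ws = list(ws)
        for j, eta, kind, args, ev in weight_plans:
            w = ws[j]
            if kind == "endpoints":
                c = ev([xs[args[0]] * 1.0, xs[args[1]] * 1.0, w * 1.0])
            else:
                c = ev([ws[p] * 1.0 for p in args])
            v = w + eta * (c - w) * dt
            if clip:
                v = 0.0 if v < 0.0 else (1.0 if v > 1.0 else v)
            new_ws[j] = v

        xs, ws = new_xs, new_ws
        if step % settings.record_stride == 0:
            t = step * dt
            for name, v in zip(columns, xs + ws):
                if not math.isfinite(v):
                    raise IntegrationDivergedError(name, t)
            rows.append(xs + ws)
            rec_times.append(t)

    return Trajectory(times=np.array(rec_times), columns=columns, data=np.array(rows))
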