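"""Domain model: temporal-causal network specifications and weight reification.

A temporal-causal network is a directed labelled graph.  Every connection
X -> Y carries a weight omega_{X,Y}; every state Y has a speed factor eta_Y
and a combination function c_Y(..) that aggregates its incoming impacts
omega_{X,Y} * X(t).  Clamped states model externally held inputs: their value
never updates.

Adaptive connections are handled by *reification*: a time-varying weight
omega_{X,Y} becomes a first-class state Omega_{X,Y} (named ``W[X->Y]``) with
unit-weight incoming connections from its source, its target and itself, its
own combination function (the adaptation principle), and initial value equal
to the connection's initial weight, so Omega_{X,Y}(t) = omega_{X,Y}(t).  The
target's combination function is lifted accordingly (see
:func:`lift_combination`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

from .combinations import CombinationFunctionSpec
from .errors import ConfigError, SchemaError

__all__ = [
    "StateId",
    "Connection",
    "StateConfig",
    "NetworkSpec",
    "OmegaState",
    "ReifiedNetwork",
    "omega_state_id",
    "build_network",
    "lift_combination",
    "reify_adaptive_weights",
]

StateId = str


@dataclass(frozen=True)
class Connection:
    """A directed weighted connection; ``adaptive`` marks a dynamic weight."""

    source: StateId
    target: StateId
    weight: float = 1.0
    adaptive: bool = False

    @property
    def pair(self) -> tuple[StateId, StateId]:
        return (self.source, self.target)


@dataclass
class StateConfig:
    """Per-state configuration: speed factor, combiner, clamped flag."""

    id: StateId
    speed: float = 1.0
    combiner: CombinationFunctionSpec | None = None
    clamped: bool = False


@dataclass
class AdaptationBlock:
    """Declaration of an adaptation principle over a set of connections.

    ``principle`` is ``"homophily"`` or ``"more_becomes_more"``; ``pairs`` is
    the literal string ``"all"`` or a list of directed (source, target)
    pairs; ``params`` carries the principle parameters (homophily: ``alpha``,
    ``tau_h``, ``eta``; more-becomes-more: ``combiner``, ``eta``).
    """

    principle: str
    pairs: str | Sequence[tuple[StateId, StateId]] = "all"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.principle not in ("homophily", "more_becomes_more"):
            raise SchemaError(f"unknown adaptation principle {self.principle!r}")
        if self.pairs != "all":
            self.pairs = [(str(s), str(t)) for s, t in self.pairs]


@dataclass
class NetworkSpec:
    """A validated temporal-causal network specification."""

    states: list[StateConfig]
    connections: list[Connection]
    adaptation: list[AdaptationBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- queries -----------------------------------------------------------

    @property
    def state_ids(self) -> list[StateId]:
        return [s.id for s in self.states]

    def state(self, sid: StateId) -> StateConfig:
        for s in self.states:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def incoming(self, target: StateId) -> list[Connection]:
        """Incoming connections of ``target`` in declaration order."""
        return [c for c in self.connections if c.target == target]

    def connection(self, source: StateId, target: StateId) -> Connection:
        for c in self.connections:
            if c.source == source and c.target == target:
                return c
        raise KeyError((source, target))

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        seen: set[StateId] = set()
        for s in self.states:
            if not s.id or any(ch.isspace() for ch in s.id):
                raise SchemaError(f"state id {s.id!r} must be a non-empty token without whitespace")
            if s.id in seen:
                raise SchemaError(f"duplicate state id {s.id!r}")
            seen.add(s.id)
            if not s.clamped and s.speed < 0:
                raise SchemaError(f"state {s.id!r}: speed factor must be >= 0, got {s.speed}")

        pairs: set[tuple[StateId, StateId]] = set()
        for c in self.connections:
            for endpoint in (c.source, c.target):
                if endpoint not in seen:
                    raise SchemaError(
                        f"connection {c.source!r}->{c.target!r} references unknown state {endpoint!r}"
                    )
            if c.pair in pairs:
                raise SchemaError(f"duplicate connection {c.source!r}->{c.target!r}")
            pairs.add(c.pair)

        n_in = {s.id: 0 for s in self.states}
        for c in self.connections:
            n_in[c.target] += 1
        for s in self.states:
            if s.clamped:
                continue
            if n_in[s.id] == 0:
                raise SchemaError(
                    f"state {s.id!r} has no incoming connections and must be clamped"
                )
            if s.combiner is None:
                raise SchemaError(
                    f"non-clamped state {s.id!r} with incoming connections needs a "
                    "combination function"
                )


def omega_state_id(source: StateId, target: StateId) -> StateId:
    """Deterministic name of the reified weight state for source -> target."""
    return f"W[{source}->{target}]"


@dataclass(frozen=True)
class OmegaState:
    """A reified connection weight: an evolving state Omega_{source,target}.

    ``inputs`` lists the states wired into the Omega-state with unit weight
    (source, target and the Omega-state itself for homophily; the peer
    Omega-states for more-becomes-more); ``init`` is the connection's initial
    weight, so the Omega value and the weight coincide at t = 0 and, by the
    update rule, at every later time.
    """

    id: StateId
    source: StateId
    target: StateId
    speed: float
    combiner: CombinationFunctionSpec
    inputs: tuple[StateId, ...]
    init: float


@dataclass
class ReifiedNetwork:
    """A network whose adaptive weights have been turned into Omega-states."""

    base: NetworkSpec
    omegas: list[OmegaState] = field(default_factory=list)

    def __post_init__(self) -> None:
        base_ids = set(self.base.state_ids)
        seen: set[StateId] = set()
        for om in self.omegas:
            if om.id in base_ids:
                raise ConfigError(
                    f"reified weight state {om.id!r} collides with an existing state id"
                )
            if om.id in seen:
                raise ConfigError(f"duplicate reified weight state {om.id!r}")
            seen.add(om.id)

    @property
    def omega_states(self) -> dict[tuple[StateId, StateId], StateId]:
        return {(om.source, om.target): om.id for om in self.omegas}

    @property
    def state_ids(self) -> list[StateId]:
        return self.base.state_ids + [om.id for om in self.omegas]

    def omega(self, source: StateId, target: StateId) -> OmegaState:
        for om in self.omegas:
            if om.source == source and om.target == target:
                return om
        raise KeyError((source, target))

    @property
    def lifted_combiners(self) -> dict[StateId, CombinationFunctionSpec]:
        """Per-target lifted combination functions c*.

        Only targets with at least one adaptive incoming connection appear;
        the flags follow the declaration order of the incoming connections.
        """
        adaptive = self.omega_states
        lifted: dict[StateId, CombinationFunctionSpec] = {}
        for s in self.base.states:
            if s.clamped or s.combiner is None:
                continue
            flags = [c.pair in adaptive for c in self.base.incoming(s.id)]
            if any(flags):
                lifted[s.id] = lift_combination(s.combiner, flags)
        return lifted


def lift_combination(
    c: CombinationFunctionSpec, adaptive_flags: Sequence[bool]
) -> CombinationFunctionSpec:
    """Lift ``c`` to take one extra weight argument per adaptive position.

    The lifted function satisfies c*(V1, .., Vk, W1, .., Wm) =
    c(.., Wi Vi, ..) with the W's consumed in flag order; evaluating with all
    W = 1 recovers c.  With no adaptive flags the original spec is returned
    unchanged.
    """
    flags = tuple(bool(f) for f in adaptive_flags)
    if not any(flags):
        return c
    return CombinationFunctionSpec("lifted", {"base": c, "flags": flags})


def build_network(spec_document: Mapping) -> NetworkSpec:
    """Build and validate a :class:`NetworkSpec` from a plain document.

    The document is the parsed JSON dialect (see :mod:`tcnet.fileio`):
    ``{"states": [..], "connections": [..], "adaptation": [..]}``.
    """
    if not isinstance(spec_document, Mapping):
        raise SchemaError("network document must be a mapping")
    try:
        raw_states = list(spec_document["states"])
    except KeyError:
        raise SchemaError("network document is missing 'states'") from None

    states = []
    for raw in raw_states:
        combiner = raw.get("combiner")
        if combiner is not None and not isinstance(combiner, CombinationFunctionSpec):
            combiner = CombinationFunctionSpec(
                combiner["family"], combiner.get("params", {})
            )
        states.append(
            StateConfig(
                id=str(raw["id"]),
                speed=float(raw.get("speed", 1.0)),
                combiner=combiner,
                clamped=bool(raw.get("clamped", False)),
            )
        )

    connections = [
        Connection(
            source=str(raw["source"]),
            target=str(raw["target"]),
            weight=float(raw.get("weight", 1.0)),
            adaptive=bool(raw.get("adaptive", False)),
        )
        for raw in spec_document.get("connections", [])
    ]

    adaptation = []
    for raw in spec_document.get("adaptation", []):
        if isinstance(raw, AdaptationBlock):
            adaptation.append(raw)
            continue
        raw = dict(raw)
        principle = raw.pop("principle")
        pairs = raw.pop("pairs", "all")
        if pairs != "all":
            pairs = [tuple(p) for p in pairs]
        combiner = raw.get("combiner")
        if combiner is not None and not isinstance(combiner, CombinationFunctionSpec):
            raw["combiner"] = CombinationFunctionSpec(
                combiner["family"], combiner.get("params", {})
            )
        adaptation.append(AdaptationBlock(principle, pairs, raw))

    return NetworkSpec(states=states, connections=connections, adaptation=adaptation)


def reify_adaptive_weights(
    net: NetworkSpec,
    weight_combiner_factory: (
        CombinationFunctionSpec
        | Mapping[tuple[StateId, StateId], CombinationFunctionSpec]
        | Callable[[StateId, StateId], CombinationFunctionSpec]
    ),
    speed: float = 1.0,
) -> ReifiedNetwork:
    """Turn every adaptive connection of ``net`` into an Omega-state.

    Each Omega-state is wired from the connection's source, its target and
    itself (all with weight 1) and carries the combination function produced
    by ``weight_combiner_factory`` for its (source, target) pair; the factory
    may be a single spec, a mapping or a callable.  A network without adaptive
    connections reifies to itself with no Omega-states.
    """

    def combiner_for(pair: tuple[StateId, StateId]) -> CombinationFunctionSpec:
        f = weight_combiner_factory
        if isinstance(f, CombinationFunctionSpec):
            return f
        if isinstance(f, Mapping):
            try:
                return f[pair]
            except KeyError:
                raise ConfigError(
                    f"adaptive connection {pair[0]!r}->{pair[1]!r} has no weight "
                    "combination function"
                ) from None
        spec = f(*pair)
        if spec is None:
            raise ConfigError(
                f"adaptive connection {pair[0]!r}->{pair[1]!r} has no weight "
                "combination function"
            )
        return spec

    omegas = []
    for conn in net.connections:
        if not conn.adaptive:
            continue
        oid = omega_state_id(conn.source, conn.target)
        omegas.append(
            OmegaState(
                id=oid,
                source=conn.source,
                target=conn.target,
                speed=speed,
                combiner=combiner_for(conn.pair),
                inputs=(conn.source, conn.target, oid),
                init=conn.weight,
            )
        )
    return ReifiedNetwork(base=net, omegas=omegas)


def strip_reification(rnet: ReifiedNetwork) -> NetworkSpec:
    """Recover the base network (weight values as at declaration time)."""
    return replace(rnet.base)
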