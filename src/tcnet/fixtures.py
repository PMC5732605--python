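"""Seeded synthetic-network generators.

The homophily fixture emulates the canonical experiment: a fully connected
network of 10 persons whose activation levels interact by social contagion
(dynamic scaled sum: the scaling factor is the sum of the connection weights
involved, recomputed each step) while every one of the 90 directed
connection weights adapts by the homophily principle (amplification 20,
threshold 0.025, state speed 0.5, connection speed 0.3).  The published
initial weight table exists only as an image, so initial weights (and state
values) are drawn from a seeded uniform distribution instead; the fixture is
a statistical stand-in for that table, deterministic per seed.

The more-becomes-more fixture is the star model: k+1 source states all
connected to one target, with every incoming weight adapting toward the
aggregate of the other incoming weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .combinations import DYNAMIC, CombinationFunctionSpec
from .errors import UsageError
from .model import (
    AdaptationBlock,
    Connection,
    NetworkSpec,
    StateConfig,
    StateId,
)

__all__ = ["FixtureConfig", "generate_homophily_fixture", "generate_mbm_fixture"]


@dataclass
class FixtureConfig:
    """Parameters of the homophily fixture generator.

    The dynamics parameters mirror the canonical 10-state experiment
    (alpha = 20, tau_h = 0.025, state speed 0.5, connection speed 0.3).
    Initial state values default to U(0.3, 0.7) — moderate, unsaturated
    activation levels — and initial weights to U(0.1, 0.9), spread over the
    interior of the unit interval; see docs/methods.md for the rationale.
    """

    n_states: int = 10
    init_state_range: tuple[float, float] = (0.3, 0.7)
    init_weight_range: tuple[float, float] = (0.1, 0.9)
    symmetric_weights: bool = False
    alpha: float = 20.0
    tau_h: float = 0.025
    eta_state: float = 0.5
    eta_conn: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise UsageError(f"n_states must be >= 2, got {self.n_states}")
        lo, hi = self.init_state_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise UsageError(f"init_state_range must be ordered within [0, 1], got {lo, hi}")
        lo, hi = self.init_weight_range
        if not 0.0 < lo <= hi < 1.0:
            raise UsageError(f"init_weight_range must be ordered within (0, 1), got {lo, hi}")


def generate_homophily_fixture(
    cfg: FixtureConfig | None = None,
) -> tuple[NetworkSpec, dict[StateId, float]]:
    """Fully connected homophily network plus initial state values.

    All n*(n-1) directed connections (no self-connections) are adaptive under
    a single homophily block; contagion between states uses the dynamic
    scaled sum.  Deterministic for a given seed; the seed drives first the
    state values, then the weights in connection declaration order.
    """
    cfg = cfg or FixtureConfig()
    rng = np.random.default_rng(cfg.seed)
    ids = [f"X{i + 1}" for i in range(cfg.n_states)]

    contagion = CombinationFunctionSpec("ssum", {"lam": DYNAMIC})
    states = [
        StateConfig(id=s, speed=cfg.eta_state, combiner=contagion) for s in ids
    ]
    init = {
        s: float(v)
        for s, v in zip(ids, rng.uniform(*cfg.init_state_range, cfg.n_states))
    }

    if cfg.symmetric_weights:
        upper = {}
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                upper[(a, b)] = float(rng.uniform(*cfg.init_weight_range))

        def draw(a: str, b: str) -> float:
            return upper[(a, b)] if (a, b) in upper else upper[(b, a)]

    else:

        def draw(a: str, b: str) -> float:
            return float(rng.uniform(*cfg.init_weight_range))

    connections = [
        Connection(a, b, weight=draw(a, b), adaptive=True)
        for a in ids
        for b in ids
        if a != b
    ]

    block = AdaptationBlock(
        "homophily",
        "all",
        {"alpha": cfg.alpha, "tau_h": cfg.tau_h, "eta": cfg.eta_conn},
    )
    net = NetworkSpec(states=states, connections=connections, adaptation=[block])
    return net, init


def generate_mbm_fixture(
    k: int,
    combiner: CombinationFunctionSpec | None = None,
    init_weights: list[float] | None = None,
    eta: float = 0.3,
    seed: int = 0,
) -> tuple[NetworkSpec, dict[StateId, float]]:
    """Star-shaped more-becomes-more model: k+1 weights into one target.

    Source states C1..C_{k+1} and the target B are clamped (the principle
    drives the weights from the other weights, not from state values);
    ``init_weights`` (length k+1) default to seeded uniform draws in (0, 1).
    """
    if k < 1:
        raise UsageError(f"k must be >= 1, got {k}")
    if init_weights is None:
        rng = np.random.default_rng(seed)
        init_weights = [float(w) for w in rng.uniform(0.1, 0.9, k + 1)]
    if len(init_weights) != k + 1:
        raise UsageError(f"expected {k + 1} initial weights, got {len(init_weights)}")

    sources = [f"C{i + 1}" for i in range(k + 1)]
    states = [StateConfig(id=s, clamped=True) for s in sources]
    states.append(StateConfig(id="B", clamped=True))
    connections = [
        Connection(s, "B", weight=float(w), adaptive=True)
        for s, w in zip(sources, init_weights)
    ]
    params: dict = {"eta": eta}
    if combiner is not None:
        params["combiner"] = combiner
    block = AdaptationBlock("more_becomes_more", "all", params)
    net = NetworkSpec(states=states, connections=connections, adaptation=[block])
    init = {s: 0.5 for s in sources}
    init["B"] = 0.5
    return net, init
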