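"""Combination functions: the per-state aggregators of a temporal-causal network.

A combination function c_Y(V_1, .., V_k) maps the incoming causal impacts
omega_{X_i,Y} * X_i(t) on a state Y to one aggregated impact.  This module
implements the standard library of families (sum, product, complement product,
min/max, simple and advanced logistic sums, scaled sums with and without
interaction terms, the advanced product/min-max blends), the homophily
weight-update function

    c(V1, V2, W) = W + alpha * W * (1 - W) * (tau_h - |V1 - V2|)

used for adaptive connection weights, and the "lifted" form c* that a static
combination function takes when some of its arguments carry adaptive weights:

    c*(V1, .., Vk, W1, .., Wm) = c(W1 V1, .., Wk Vk)

with one extra W argument per adaptive position (static positions keep their
weight folded into V by the caller).

Evaluators are compiled once per spec (:func:`make_evaluator`) so the
simulation engine can call them in its inner loop; sums are accumulated in
argument order, which the engine relies on for exact reproducibility between
the reified and the direct update paths.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ParameterError, UsageError

__all__ = [
    "FAMILIES",
    "CombinationFunctionSpec",
    "make_evaluator",
    "evaluate",
    "evaluate_homophily",
    "classify_properties",
]

FAMILIES = frozenset(
    {
        "sum",
        "product",
        "cproduct",
        "min",
        "max",
        "slogistic",
        "alogistic",
        "ssum",
        "sisum",
        "aproduct",
        "aminmax",
        "aproduct_ssum",
        "homophily",
        "lifted",
    }
)

# Logistic exponents are clamped before exponentiation to avoid overflow.
# Non-semantic guard: the clamp only acts where the logistic is saturated to
# well below double precision.
_EXP_CLAMP = 500.0

DYNAMIC = "dynamic"


def _exp(x: float) -> float:
    if x > _EXP_CLAMP:
        x = _EXP_CLAMP
    elif x < -_EXP_CLAMP:
        x = -_EXP_CLAMP
    return math.exp(x)


def _seq_sum(vals: Sequence[float]) -> float:
    # plain sequential accumulation; order is part of the engine contract
    s = 0.0
    for v in vals:
        s += v
    return s


@dataclass(frozen=True)
class CombinationFunctionSpec:
    """A named combination-function family with its parameters.

    Parameters are family specific: ``sigma`` (steepness) and ``tau``
    (threshold) for the logistic families, ``lam`` (scaling factor, or the
    string ``"dynamic"``) for the scaled sums, ``beta`` for the advanced
    blends, ``mu`` (interaction coefficients) for ``sisum``, ``alpha``
    (amplification) and ``tau_h`` (homophily threshold) for ``homophily``,
    and ``base``/``flags`` for the ``lifted`` form.
    """

    family: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ParameterError(f"unknown combination-function family {self.family!r}")
        object.__setattr__(self, "params", dict(self.params))

    def param(self, name: str, default=None):
        return self.params.get(name, default)

    def require(self, name: str):
        if name not in self.params:
            raise ParameterError(
                f"{self.family} combination function requires parameter {name!r}"
            )
        return self.params[name]


def _homophily(v1: float, v2: float, w: float, alpha: float, tau_h: float) -> float:
    return w + alpha * w * (1.0 - w) * (tau_h - abs(v1 - v2))


def _check_sigma_tau(fn: CombinationFunctionSpec) -> tuple[float, float]:
    sigma = float(fn.require("sigma"))
    tau = float(fn.require("tau"))
    if sigma < 0:
        raise ParameterError(f"steepness sigma must be >= 0, got {sigma}")
    if tau < 0:
        raise ParameterError(f"threshold tau must be >= 0, got {tau}")
    return sigma, tau


def _check_lam(fn: CombinationFunctionSpec) -> float:
    lam = fn.require("lam")
    if lam == DYNAMIC:
        raise UsageError(
            "dynamic scaling factor lambda is resolved by the simulation engine; "
            "it cannot be evaluated directly"
        )
    lam = float(lam)
    if lam <= 0:
        raise ParameterError(f"scaling factor lambda must be > 0, got {lam}")
    return lam


def _check_beta(fn: CombinationFunctionSpec) -> float:
    beta = float(fn.require("beta"))
    if not 0.0 <= beta <= 1.0:
        raise ParameterError(f"beta must be in [0, 1], got {beta}")
    return beta


def _product(vals: Sequence[float]) -> float:
    p = 1.0
    for v in vals:
        p *= v
    return p


def _cproduct(vals: Sequence[float]) -> float:
    p = 1.0
    for v in vals:
        p *= 1.0 - v
    return 1.0 - p


def make_evaluator(fn: CombinationFunctionSpec) -> Callable[[Sequence[float]], float]:
    """Compile ``fn`` into a fast callable ``vals -> c(vals)``.

    Parameter validation happens here, once, so the returned closure is cheap
    enough for the Euler inner loop.
    """
    family = fn.family

    if family == "sum":
        return _seq_sum
    if family == "product":
        return _product
    if family == "cproduct":
        return _cproduct
    if family == "min":
        return lambda vals: min(vals)
    if family == "max":
        return lambda vals: max(vals)

    if family == "slogistic":
        sigma, tau = _check_sigma_tau(fn)

        def slog(vals, sigma=sigma, tau=tau):
            return 1.0 / (1.0 + _exp(-sigma * (_seq_sum(vals) - tau)))

        return slog

    if family == "alogistic":
        sigma, tau = _check_sigma_tau(fn)
        mu = 1.0 / (1.0 + _exp(sigma * tau))
        nu = 1.0 + _exp(-sigma * tau)

        def alog(vals, sigma=sigma, tau=tau, mu=mu, nu=nu):
            return (1.0 / (1.0 + _exp(-sigma * (_seq_sum(vals) - tau))) - mu) * nu

        return alog

    if family == "ssum":
        lam = _check_lam(fn)

        def ssum(vals, lam=lam):
            return _seq_sum(vals) / lam

        return ssum

    if family == "sisum":
        lam = _check_lam(fn)
        mu = fn.param("mu") or {}
        if isinstance(mu, Mapping):
            terms = [(int(i), int(j), float(c)) for (i, j), c in mu.items()]
        else:  # list of [i, j, coefficient]
            terms = [(int(i), int(j), float(c)) for i, j, c in mu]

        def sisum(vals, lam=lam, terms=terms):
            s = _seq_sum(vals) / lam
            for i, j, c in terms:
                s += c * vals[i] * vals[j]
            return s

        return sisum

    if family == "aproduct":
        beta = _check_beta(fn)

        def aproduct(vals, beta=beta):
            return beta * _cproduct(vals) + (1.0 - beta) * _product(vals)

        return aproduct

    if family == "aminmax":
        beta = _check_beta(fn)

        def aminmax(vals, beta=beta):
            return beta * max(vals) + (1.0 - beta) * min(vals)

        return aminmax

    if family == "aproduct_ssum":
        # aproduct_beta(V0, ssum_lam(V1, .., Vk)); V0 is the first incoming
        # impact in declaration order.
        beta = _check_beta(fn)
        lam = _check_lam(fn)

        def aps(vals, beta=beta, lam=lam):
            if len(vals) < 2:
                raise UsageError("aproduct_ssum needs at least two arguments")
            a = vals[0]
            b = _seq_sum(vals[1:]) / lam
            return beta * (1.0 - (1.0 - a) * (1.0 - b)) + (1.0 - beta) * a * b

        return aps

    if family == "homophily":
        alpha = float(fn.param("alpha", 1.0))
        tau_h = float(fn.require("tau_h"))
        if alpha <= 0:
            raise ParameterError(f"amplification alpha must be > 0, got {alpha}")
        if not 0.0 < tau_h < 1.0:
            raise ParameterError(f"homophily threshold tau_h must be in (0, 1), got {tau_h}")

        def homo(vals, alpha=alpha, tau_h=tau_h):
            if len(vals) != 3:
                raise UsageError("homophily combination function takes (V1, V2, W)")
            return _homophily(vals[0], vals[1], vals[2], alpha, tau_h)

        return homo

    if family == "lifted":
        base = fn.require("base")
        flags = tuple(bool(f) for f in fn.require("flags"))
        if not any(flags):
            # no adaptive arguments: c* is c itself
            return make_evaluator(base)
        base_ev = make_evaluator(base)
        k = len(flags)
        m = sum(flags)

        def lifted(vals, base_ev=base_ev, flags=flags, k=k, m=m):
            if len(vals) != k + m:
                raise UsageError(
                    f"lifted combination function takes {k} values plus {m} weights, "
                    f"got {len(vals)} arguments"
                )
            ws = vals[k:]
            merged = []
            wi = 0
            for f, v in zip(flags, vals[:k]):
                if f:
                    merged.append(ws[wi] * v)
                    wi += 1
                else:
                    merged.append(v)
            return base_ev(merged)

        return lifted

    raise ParameterError(f"unknown combination-function family {family!r}")


def evaluate(fn: CombinationFunctionSpec, values: Sequence[float]) -> float:
    """Evaluate ``c(V_1, .., V_k)`` for a combination-function spec."""
    values = [float(v) for v in values]
    if not values:
        raise UsageError("combination functions take at least one argument")
    return make_evaluator(fn)(values)


def evaluate_homophily(fn: CombinationFunctionSpec, v1: float, v2: float, w: float) -> float:
    """Evaluate the homophily weight update c(V1, V2, W).

    The result exceeds ``w`` exactly when the endpoint states are closer than
    the threshold (|V1 - V2| < tau_h) and 0 < w < 1; the boundary weights 0
    and 1 are fixed because of the W(1-W) factor.
    """
    if fn.family != "homophily":
        raise UsageError(f"expected a homophily spec, got family {fn.family!r}")
    return make_evaluator(fn)([float(v1), float(v2), float(w)])


def _default_grid(arity: int, n_points: int = 48) -> np.ndarray:
    rng = np.random.default_rng(2023)
    grid = rng.uniform(0.0, 1.0, size=(n_points, arity))
    corners = np.array(
        [np.zeros(arity), np.ones(arity), np.eye(arity)[0] if arity > 1 else np.ones(arity)]
    )
    return np.vstack([grid, corners])


def classify_properties(
    fn: CombinationFunctionSpec | Callable[[Sequence[float]], float],
    arity: int,
    grid: np.ndarray | None = None,
    tol: float = 1e-12,
) -> dict:
    """Check structural properties of a combination function on a grid.

    Returns ``{"symmetric": bool, "monotonic": bool}``: symmetric if no
    permutation of any grid point changes the value (within ``tol``), and
    monotonic if no coordinatewise-dominating pair of grid points violates
    the ordering.  These are the two hypotheses of the equal-equilibrium
    theorem for fully connected networks.
    """
    if arity < 1:
        raise UsageError("arity must be >= 1")
    ev = fn if callable(fn) else make_evaluator(fn)
    if grid is None:
        grid = _default_grid(arity)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim == 1:
        grid = grid.reshape(-1, arity)
    if grid.size == 0:
        raise UsageError("grid must be non-empty")
    if grid.shape[1] != arity:
        raise UsageError(f"grid points must have {arity} coordinates")

    points = [tuple(float(x) for x in row) for row in grid]
    values = [float(ev(list(p))) for p in points]

    symmetric = True
    perms = list(itertools.permutations(range(arity)))
    for p, base in zip(points, values):
        for perm in perms[1:]:
            if abs(ev([p[i] for i in perm]) - base) > tol:
                symmetric = False
                break
        if not symmetric:
            break

    monotonic = True
    for (p, vp), (q, vq) in itertools.combinations(zip(points, values), 2):
        if all(a <= b for a, b in zip(p, q)):
            lo, hi = vp, vq
        elif all(b <= a for a, b in zip(p, q)):
            lo, hi = vq, vp
        else:
            continue
        if lo > hi + tol:
            monotonic = False
            break

    return {"symmetric": symmetric, "monotonic": monotonic}
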