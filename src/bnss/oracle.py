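"""Exact brute-force reference dynamics for small networks.

Enumerates the full transition structure over all Omega = 2^N states of a
network — a functional map for deterministic networks, a row-stochastic
transition matrix when free nodes induce uniform branching over their 2^F
draw outcomes — along with recurrent classes and exact stationary
distributions.  The per-state sweep is the same code the simulation
engine uses, so oracle semantics are bit-identical to the engine's in
both update modes.

Also provides reproducible random-network generation and the bundled toy
fixtures used throughout the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .engine import CompiledNetwork, UpdateMode
from .errors import InvalidSpecError, NotStochasticError, TooLargeError
from .model_io import FREE, BooleanNetwork, RuleExpr, parse_network

__all__ = [
    "ExactDynamics",
    "StationaryDistribution",
    "GeneratorSpec",
    "enumerate_dynamics",
    "stationary_distribution",
    "generate_random_network",
    "toy_fixtures",
    "toy_summaries",
    "state_to_int",
    "int_to_state",
    "frozen_partition",
    "pair_synchrony",
    "dynamics_to_json",
]


def state_to_int(values: Sequence[bool]) -> int:
    """Encode a state vector as an integer (node i -> bit i)."""
    s = 0
    for i, v in enumerate(values):
        if v:
            s |= 1 << i
    return s


def int_to_state(s: int, n: int) -> tuple[bool, ...]:
    return tuple(bool((s >> i) & 1) for i in range(n))


@dataclass(frozen=True)
class ExactDynamics:
    """Exhaustive transition structure of a small network.

    ``successors[s]`` lists ``(s', probability)`` pairs with probabilities
    in {2^-F, ..., 1} summing to 1; for deterministic networks every list
    is a single pair with probability 1 and ``deterministic_map`` holds
    the successor function as an array.
    """

    network: BooleanNetwork
    mode: UpdateMode
    n: int
    successors: tuple[tuple[tuple[int, float], ...], ...]
    recurrent_classes: tuple[frozenset[int], ...]
    transient_states: frozenset[int]
    deterministic_map: np.ndarray | None = None

    @property
    def n_states(self) -> int:
        return 1 << self.n

    @property
    def is_deterministic(self) -> bool:
        return self.deterministic_map is not None

    def successor(self, s: int) -> int:
        """Deterministic successor (single-branch transitions only)."""
        if self.deterministic_map is None:
            raise NotStochasticError("network is stochastic; no functional successor")
        return int(self.deterministic_map[s])

    def clamp_consistent_states(self) -> list[int]:
        """States whose clamped bits carry their clamp values."""
        net = self.network
        fixed = {net.index(v): val for v, val in net.clamps.items()}
        out = []
        for s in range(self.n_states):
            if all(bool((s >> i) & 1) == val for i, val in fixed.items()):
                out.append(s)
        return out


def enumerate_dynamics(
    network: BooleanNetwork,
    mode: UpdateMode = UpdateMode.SYNCHRONOUS,
    cap: int = 16,
    matrix_cap: int = 12,
) -> ExactDynamics:
    """Enumerate transitions over all 2^N states under ``mode``.

    Free nodes branch uniformly over their 2^F draw combinations (clamped
    free nodes do not draw); clamped nodes are forced at every step.
    Raises :class:`TooLargeError` above ``cap`` nodes (``matrix_cap`` for
    networks with free nodes, which need the stochastic-matrix path).
    """
    mode = UpdateMode(mode)
    compiled = CompiledNetwork(network)
    n = network.n
    n_free = compiled.n_draws
    limit = cap if n_free == 0 else matrix_cap
    if n > limit:
        raise TooLargeError(f"{n} nodes exceeds the exact-enumeration cap of {limit}")
    n_states = 1 << n
    p = 1.0 / (1 << n_free)
    draw_combos = list(product((False, True), repeat=n_free))
    successors: list[tuple[tuple[int, float], ...]] = []
    det_map = np.empty(n_states, dtype=np.int64) if n_free == 0 else None
    graph = nx.DiGraph()
    graph.add_nodes_from(range(n_states))
    for s in range(n_states):
        values = int_to_state(s, n)
        probs: dict[int, float] = {}
        for draws in draw_combos:
            t = state_to_int(compiled.sweep(values, mode, draws))
            probs[t] = probs.get(t, 0.0) + p
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-12:
            raise NotStochasticError(f"row {s} sums to {total}")
        successors.append(tuple(sorted(probs.items())))
        if det_map is not None:
            det_map[s] = next(iter(probs))
        graph.add_edges_from((s, t) for t in probs)
    condensation = nx.condensation(graph)
    recurrent = []
    transient: set[int] = set()
    for comp in condensation.nodes:
        members = condensation.nodes[comp]["members"]
        if condensation.out_degree(comp) == 0:
            recurrent.append(frozenset(members))
        else:
            transient |= set(members)
    recurrent.sort(key=min)
    return ExactDynamics(
        network=network,
        mode=mode,
        n=n,
        successors=tuple(successors),
        recurrent_classes=tuple(recurrent),
        transient_states=frozenset(transient),
        deterministic_map=det_map,
    )


@dataclass(frozen=True)
class StationaryDistribution:
    """Exact stationary distribution of one recurrent class.

    For periodic classes (e.g. deterministic cycles) this is the unique
    invariant distribution, i.e. the long-run visit frequencies
    (time-average).
    """

    states: tuple[int, ...]
    probabilities: tuple[float, ...]

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.states, self.probabilities))


def stationary_distribution(dynamics: ExactDynamics) -> list[StationaryDistribution]:
    """Solve pi = pi P on each recurrent class by direct linear solve."""
    out = []
    for cls in dynamics.recurrent_classes:
        states = sorted(cls)
        index = {s: i for i, s in enumerate(states)}
        m = len(states)
        P = np.zeros((m, m))
        for s in states:
            for t, prob in dynamics.successors[s]:
                P[index[s], index[t]] = prob  # recurrent classes are closed
        A = P.T - np.eye(m)
        A[-1, :] = 1.0
        b = np.zeros(m)
        b[-1] = 1.0
        try:
            pi = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            pi, *_ = np.linalg.lstsq(np.vstack([P.T - np.eye(m), np.ones(m)]),
                                     np.append(np.zeros(m), 1.0), rcond=None)
        residual = np.abs(pi @ P - pi).max()
        if residual > 1e-12:
            raise NotStochasticError(f"stationary solve residual {residual}")
        out.append(StationaryDistribution(tuple(states), tuple(float(x) for x in pi)))
    return out


def reachable_recurrent_classes(
    dynamics: ExactDynamics, initial_states: Iterable[int] | None = None
) -> list[frozenset[int]]:
    """Recurrent classes reachable from the given initial states
    (default: all clamp-consistent states)."""
    if initial_states is None:
        initial_states = dynamics.clamp_consistent_states()
    graph = nx.DiGraph()
    graph.add_nodes_from(range(dynamics.n_states))
    for s in range(dynamics.n_states):
        graph.add_edges_from((s, t) for t, _ in dynamics.successors[s])
    reach: set[int] = set()
    for s0 in initial_states:
        reach |= nx.descendants(graph, s0)
        reach.add(s0)
    return [cls for cls in dynamics.recurrent_classes if cls <= reach]


def frozen_partition(
    dynamics: ExactDynamics, initial_states: Iterable[int] | None = None
) -> tuple[dict[str, bool], frozenset[str]]:
    """Ground-truth frozen/variable partition from the exact dynamics.

    A node is frozen iff its bit has the same value in every state of
    every reachable recurrent class; this is what ensemble classification
    converges to once burn-in passes all transients.
    """
    classes = reachable_recurrent_classes(dynamics, initial_states)
    recurrent_states = [s for cls in classes for s in cls]
    frozen: dict[str, bool] = {}
    variable: set[str] = set()
    for i, node in enumerate(dynamics.network.nodes):
        bits = {bool((s >> i) & 1) for s in recurrent_states}
        if len(bits) == 1:
            frozen[node] = bits.pop()
        else:
            variable.add(node)
    return frozen, frozenset(variable)


def pair_synchrony(
    dynamics: ExactDynamics,
    pair: tuple[str, str],
    initial_states: Iterable[int] | None = None,
) -> str:
    """Synchronization verdict for a node pair over all reachable
    recurrent states; same vocabulary as ``JointCensus.verdict``."""
    ia = dynamics.network.index(pair[0])
    ib = dynamics.network.index(pair[1])
    combos = set()
    for cls in reachable_recurrent_classes(dynamics, initial_states):
        for s in cls:
            combos.add((bool((s >> ia) & 1), bool((s >> ib) & 1)))
    if not (True, False) in combos and not (False, True) in combos:
        return "synchronized_equal"
    if not (True, True) in combos and not (False, False) in combos:
        return "synchronized_opposite"
    return "unsynchronized"


def dynamics_to_json(dynamics: ExactDynamics) -> str:
    """Snapshot export: states, transition triples, recurrent classes and
    per-class stationary probabilities."""
    stationary = stationary_distribution(dynamics)
    obj = {
        "nodes": list(dynamics.network.nodes),
        "mode": dynamics.mode.value,
        "n_states": dynamics.n_states,
        "transitions": [
            [s, t, p] for s in range(dynamics.n_states) for t, p in dynamics.successors[s]
        ],
        "recurrent_classes": [sorted(cls) for cls in dynamics.recurrent_classes],
        "stationary": [
            {"states": list(d.states), "probabilities": list(d.probabilities)}
            for d in stationary
        ],
    }
    return json.dumps(obj)


# ---------------------------------------------------------------------------
# random-network generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorSpec:
    """Specification of a random Boolean network fixture."""

    n: int
    k: int
    free_fraction: float = 0.0
    seed: int = 0
    weight_and: float = 1.0
    weight_or: float = 1.0
    p_negate: float = 0.3

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidSpecError("n must be >= 1")
        if not 1 <= self.k < self.n:
            raise InvalidSpecError("k must satisfy 1 <= k < n")
        if not 0.0 <= self.free_fraction <= 1.0:
            raise InvalidSpecError("free_fraction must lie in [0, 1]")
        if self.weight_and < 0 or self.weight_or < 0 or self.weight_and + self.weight_or == 0:
            raise InvalidSpecError("operator weights must be non-negative and not both zero")


def generate_random_network(spec: GeneratorSpec) -> BooleanNetwork:
    """Generate a reproducible random network per ``spec``.

    Each ruled node gets an expression over ``k`` distinct regulators:
    literals (negated with probability ``p_negate``) folded left to right
    with AND/OR drawn from the operator weights.  ``free_fraction`` of
    the nodes (rounded) are marked FREE instead.
    """
    rng = np.random.default_rng(spec.seed)
    nodes = tuple(f"v{i}" for i in range(spec.n))
    n_free = int(round(spec.free_fraction * spec.n))
    free_set = set(rng.choice(spec.n, size=n_free, replace=False).tolist())
    p_and = spec.weight_and / (spec.weight_and + spec.weight_or)
    rules: dict = {}
    for i, node in enumerate(nodes):
        if i in free_set:
            rules[node] = FREE
            continue
        regulators = rng.choice(spec.n, size=spec.k, replace=False)
        literals = []
        for r in regulators:
            lit = RuleExpr.var(nodes[int(r)])
            if rng.random() < spec.p_negate:
                lit = RuleExpr.not_(lit)
            literals.append(lit)
        expr = literals[0]
        for lit in literals[1:]:
            if rng.random() < p_and:
                expr = RuleExpr.and_(expr, lit)
            else:
                expr = RuleExpr.or_(expr, lit)
        rules[node] = expr
    return BooleanNetwork(nodes, rules, {}, name=f"random_n{spec.n}_k{spec.k}_s{spec.seed}")


# ---------------------------------------------------------------------------
# toy fixtures
# ---------------------------------------------------------------------------

_TOY_SOURCES = {
    "T1": "A = NOT B\nB = A\n",
    "T2": "A = A OR B\nB = A AND B\n",
    "T3prime": "C = RANDOM\nA = C\nB = C\n",
    "CONST": "A = True\nB = False\n",
    "MIX6": (
        "IN = RANDOM\n"
        "CL = RANDOM\n"
        "clamp CL = True\n"
        "X = IN AND CL\n"
        "Y = X OR Z\n"
        "Z = NOT Y\n"
        "W = Y AND NOT Z\n"
    ),
}


def toy_fixtures() -> dict[str, BooleanNetwork]:
    """The bundled toy networks.

    T1: two-node negation loop (synchronous: one 4-cycle; sequential:
    one 2-cycle plus two transient states).  T2: deterministic with three
    fixed points.  T3prime: one free driver copied by two followers.
    CONST: constant rules.  MIX6: six nodes mixing a clamped free node,
    a free input and logic.
    """
    return {name: parse_network(src, name=name) for name, src in _TOY_SOURCES.items()}


def toy_summaries() -> dict[str, dict]:
    """Documented exact-dynamics summaries of the toy fixtures, keyed by
    (toy, update mode); values were computed with this oracle."""
    return {
        "T1": {
            "n_nodes": 2,
            "n_free": 0,
            "synchronous": {"n_recurrent_classes": 1, "recurrent_sizes": [4], "n_transient": 0},
            "sequential": {"n_recurrent_classes": 1, "recurrent_sizes": [2], "n_transient": 2},
        },
        "T2": {
            "n_nodes": 2,
            "n_free": 0,
            "synchronous": {"n_recurrent_classes": 3, "recurrent_sizes": [1, 1, 1], "n_transient": 1},
            "sequential": {"n_recurrent_classes": 3, "recurrent_sizes": [1, 1, 1], "n_transient": 1},
        },
        "T3prime": {
            "n_nodes": 3,
            "n_free": 1,
            "synchronous": {"n_recurrent_classes": 1, "recurrent_sizes": [4], "n_transient": 4},
            "sequential": {"n_recurrent_classes": 1, "recurrent_sizes": [2], "n_transient": 6},
        },
        "CONST": {
            "n_nodes": 2,
            "n_free": 0,
            "synchronous": {"n_recurrent_classes": 1, "recurrent_sizes": [1], "n_transient": 3},
            "sequential": {"n_recurrent_classes": 1, "recurrent_sizes": [1], "n_transient": 3},
        },
        "MIX6": {
            # CL is marked FREE but clamped, so only IN draws randomness
            "n_nodes": 6,
            "n_free": 2,
            "synchronous": {"n_recurrent_classes": 1, "recurrent_sizes": [20], "n_transient": 44},
            "sequential": {"n_recurrent_classes": 1, "recurrent_sizes": [3], "n_transient": 61},
        },
    }
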