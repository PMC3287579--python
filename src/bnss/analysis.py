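"""State-space analyses of simulated trajectories.

Implements the visit-frequency census over distinct states (states are
identified by Hamming distance 0 over all nodes), per-run cardinality
statistics, the frozen/variable node dichotomy, synchrony grouping of
variable nodes, pairwise joint-state censuses, response-efficiency curves
and wild-vs-mutant network comparison.

``burn_in`` arguments index into the *recorded* state list of a
trajectory (with ``record_initial=True`` the row index equals the update
index t).  The default is 0 everywhere; for transient-sensitive analyses
a burn-in of about 4 updates is recommended, as the networks studied
settle after an initial period of roughly 3-4 updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .engine import SimulationConfig, Trajectory, TrajectoryEnsemble, run_ensemble
from .errors import LengthMismatchError, UnknownNodeError, ValidationError
from .model_io import BooleanNetwork, apply_clamp

__all__ = [
    "StateCensus",
    "CensusEntry",
    "CardinalityStats",
    "FrozenVariablePartition",
    "SynchronyGroup",
    "JointCensus",
    "EfficiencyCurve",
    "NetworkReport",
    "NetworkComparison",
    "hamming",
    "census",
    "pooled_census",
    "cardinality_stats",
    "top_states",
    "classify_nodes",
    "true_counts",
    "synchrony_groups",
    "joint_census",
    "efficiency_curve",
    "compare_networks",
]


def hamming(a: Sequence[bool], b: Sequence[bool]) -> int:
    """Number of positions where two state vectors differ (0 iff identical)."""
    if len(a) != len(b):
        raise LengthMismatchError(f"state lengths differ: {len(a)} != {len(b)}")
    return int(sum(bool(x) != bool(y) for x, y in zip(a, b)))


@dataclass(frozen=True)
class CensusEntry:
    state: tuple[bool, ...]
    visit_times: tuple[int, ...]  # sorted recorded-row indices
    count: int


@dataclass(frozen=True)
class StateCensus:
    """Distinct visited states with their visit times and counts."""

    entries: tuple[CensusEntry, ...]
    total_recorded: int

    def __post_init__(self) -> None:
        if sum(e.count for e in self.entries) != self.total_recorded:
            raise ValidationError("census counts do not sum to total recorded states")

    @property
    def cardinality(self) -> int:
        return len(self.entries)

    def counts(self) -> dict[tuple[bool, ...], int]:
        return {e.state: e.count for e in self.entries}


def _census_rows(rows: np.ndarray) -> StateCensus:
    seen: dict[bytes, list[int]] = {}
    order: list[bytes] = []
    for idx, row in enumerate(rows):
        key = np.packbits(row).tobytes()
        if key not in seen:
            seen[key] = []
            order.append(key)
        seen[key].append(idx)
    entries = []
    for key in order:
        times = seen[key]
        state = tuple(bool(v) for v in rows[times[0]])
        entries.append(CensusEntry(state=state, visit_times=tuple(times), count=len(times)))
    return StateCensus(entries=tuple(entries), total_recorded=int(rows.shape[0]))


def census(trajectory: Trajectory, burn_in: int = 0) -> StateCensus:
    """Group a trajectory's recorded states (row ``burn_in`` on) into
    Hamming-distance-0 equivalence classes over all nodes."""
    if not 0 <= burn_in < trajectory.n_recorded:
        raise ValidationError("burn_in must be < number of recorded states")
    return _census_rows(trajectory.states[burn_in:])


def pooled_census(ensemble: TrajectoryEnsemble, burn_in: int = 0) -> StateCensus:
    """Census over all runs pooled; visit times are row indices into the
    concatenation of the runs' post-burn-in states."""
    rows = np.concatenate([t.states[burn_in:] for t in ensemble])
    return _census_rows(rows)


@dataclass(frozen=True)
class CardinalityStats:
    """Per-run census cardinalities with mean and sample SD (n-1)."""

    per_run: tuple[int, ...]
    mean: float
    sd: float  # NaN for a single run

    @staticmethod
    def from_values(values: Sequence[int]) -> "CardinalityStats":
        arr = np.asarray(values, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
        return CardinalityStats(tuple(int(v) for v in values), float(arr.mean()), sd)


def cardinality_stats(ensemble: TrajectoryEnsemble, burn_in: int = 0) -> CardinalityStats:
    """Mean and sample standard deviation of per-run census cardinality."""
    if len(ensemble) == 0:
        raise ValidationError("empty ensemble")
    return CardinalityStats.from_values(
        [census(t, burn_in).cardinality for t in ensemble]
    )


def top_states(c: StateCensus, k: int) -> list[tuple[tuple[bool, ...], int]]:
    """The ``min(k, cardinality)`` most visited states.

    Sorted by count descending; ties broken by earliest first visit, then
    by lexicographic state order.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    ranked = sorted(
        c.entries, key=lambda e: (-e.count, e.visit_times[0], e.state)
    )
    return [(e.state, e.count) for e in ranked[:k]]


@dataclass(frozen=True)
class FrozenVariablePartition:
    """Frozen nodes (with their constant value) vs variable nodes."""

    frozen: Mapping[str, bool]
    variable: frozenset[str]
    burn_in: int = 0

    def __post_init__(self) -> None:
        if set(self.frozen) & self.variable:
            raise ValidationError("frozen and variable sets overlap")


def classify_nodes(ensemble: TrajectoryEnsemble, burn_in: int = 0) -> FrozenVariablePartition:
    """Classify each node as frozen or variable across the whole ensemble.

    A node is frozen iff its value is identical at every recorded row
    >= ``burn_in`` in *every* run; the partition is per network, not per
    run, so adding runs can only shrink the frozen set.
    """
    if len(ensemble) == 0:
        raise ValidationError("empty ensemble")
    rows = np.concatenate([t.states[burn_in:] for t in ensemble])
    nodes = ensemble.network.nodes
    frozen: dict[str, bool] = {}
    variable: set[str] = set()
    for j, node in enumerate(nodes):
        col = rows[:, j]
        if col.all():
            frozen[node] = True
        elif not col.any():
            frozen[node] = False
        else:
            variable.add(node)
    return FrozenVariablePartition(frozen=frozen, variable=frozenset(variable), burn_in=burn_in)


def true_counts(trajectory: Trajectory, burn_in: int = 0) -> dict[str, int]:
    """Per-node count of recorded rows >= ``burn_in`` with value True."""
    rows = trajectory.states[burn_in:]
    return {
        node: int(rows[:, j].sum()) for j, node in enumerate(trajectory.network.nodes)
    }


@dataclass(frozen=True)
class SynchronyGroup:
    """Maximal set of variable nodes with exactly equal value sequences;
    ``negated`` members follow the exact complement of the group sequence."""

    nodes: tuple[str, ...]
    negated: frozenset[str] = frozenset()


def synchrony_groups(
    ensemble: TrajectoryEnsemble,
    burn_in: int = 0,
    include_complementary: bool = False,
) -> list[SynchronyGroup]:
    """Partition the VARIABLE nodes into synchrony groups.

    Grouping requires exact equality of the recorded value sequences
    (post burn-in, concatenated across runs); no tolerance.  With
    ``include_complementary``, a node whose sequence is the exact
    negation of a group's joins that group flagged as negated.  Frozen
    nodes are excluded.  Groups are ordered by first member's
    declaration order; members keep declaration order.
    """
    part = classify_nodes(ensemble, burn_in)
    rows = np.concatenate([t.states[burn_in:] for t in ensemble])
    nodes = ensemble.network.nodes
    variable = [v for v in nodes if v in part.variable]
    key_to_group: dict[bytes, list[str]] = {}
    order: list[bytes] = []
    negated: dict[bytes, list[str]] = {}
    for node in variable:
        col = rows[:, nodes.index(node)]
        key = np.packbits(col).tobytes()
        if key in key_to_group:
            key_to_group[key].append(node)
            continue
        if include_complementary:
            comp_key = np.packbits(~col).tobytes()
            if comp_key in key_to_group:
                negated.setdefault(comp_key, []).append(node)
                continue
        key_to_group[key] = [node]
        order.append(key)
    groups = []
    for key in order:
        members = key_to_group[key] + negated.get(key, [])
        groups.append(
            SynchronyGroup(nodes=tuple(members), negated=frozenset(negated.get(key, ())))
        )
    return groups


@dataclass(frozen=True)
class JointCensus:
    """2x2 joint census of one node pair over an ensemble."""

    pair: tuple[str, str]
    counts: Mapping[tuple[bool, bool], int]
    burn_in: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def verdict(self) -> str:
        tt = self.counts[(True, True)]
        tf = self.counts[(True, False)]
        ft = self.counts[(False, True)]
        ff = self.counts[(False, False)]
        if tf == 0 and ft == 0:
            return "synchronized_equal"
        if tt == 0 and ff == 0:
            return "synchronized_opposite"
        return "unsynchronized"


def joint_census(
    ensemble: TrajectoryEnsemble, pair: tuple[str, str], burn_in: int = 0
) -> JointCensus:
    """Count the joint values of a node pair over all recorded
    post-burn-in states in all runs."""
    a, b = pair
    ia = ensemble.network.index(a)
    ib = ensemble.network.index(b)
    rows = np.concatenate([t.states[burn_in:] for t in ensemble])
    counts = {
        (True, True): int((rows[:, ia] & rows[:, ib]).sum()),
        (True, False): int((rows[:, ia] & ~rows[:, ib]).sum()),
        (False, True): int((~rows[:, ia] & rows[:, ib]).sum()),
        (False, False): int((~rows[:, ia] & ~rows[:, ib]).sum()),
    }
    return JointCensus(pair=(a, b), counts=counts, burn_in=burn_in)


@dataclass(frozen=True)
class EfficiencyCurve:
    """Per-update fraction of runs with the output node True."""

    output_node: str
    times: tuple[int, ...]
    fractions: tuple[float, ...]
    n_runs: int

    def __post_init__(self) -> None:
        if any(not 0.0 <= f <= 1.0 for f in self.fractions):
            raise ValidationError("efficiency fractions must lie in [0, 1]")


def efficiency_curve(ensemble: TrajectoryEnsemble, output_node: str) -> EfficiencyCurve:
    """For each recorded update index, the fraction of runs in which the
    output node is True."""
    j = ensemble.network.index(output_node)
    stacked = ensemble.stacked()  # (runs, rows, N)
    fractions = stacked[:, :, j].mean(axis=0)
    times = ensemble.trajectories[0].times
    return EfficiencyCurve(
        output_node=output_node,
        times=tuple(int(t) for t in times),
        fractions=tuple(float(f) for f in fractions),
        n_runs=len(ensemble),
    )


# ---------------------------------------------------------------------------
# wild-vs-mutant comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NetworkReport:
    """Per-network summary used in mutant comparisons."""

    label: str
    network: BooleanNetwork
    cardinality: CardinalityStats
    partition: FrozenVariablePartition
    top: list[tuple[tuple[bool, ...], int]]
    efficiency: EfficiencyCurve | None = None


@dataclass(frozen=True)
class NetworkComparison:
    base: NetworkReport
    mutants: tuple[NetworkReport, ...]
    variable_intersection: frozenset[str]

    @property
    def reports(self) -> tuple[NetworkReport, ...]:
        return (self.base, *self.mutants)


def compare_networks(
    base: BooleanNetwork,
    mutant_nodes: Sequence[str],
    config: SimulationConfig,
    burn_in: int = 0,
    output_node: str | None = None,
    top_k: int = 2,
) -> NetworkComparison:
    """Compare the base network against single-node False-clamp mutants.

    Each mutant holds one of ``mutant_nodes`` False on top of the base
    clamps.  Every network gets cardinality statistics, a frozen/variable
    partition, the ``top_k`` most visited states of the pooled census and
    (optionally) an efficiency curve; the report also carries the
    intersection of the variable sets across all networks.
    """
    for node in mutant_nodes:
        if node not in base.nodes:
            raise UnknownNodeError(f"unknown mutant node {node!r}")

    def report(network: BooleanNetwork, label: str) -> NetworkReport:
        ensemble = run_ensemble(network, config)
        part = classify_nodes(ensemble, burn_in)
        return NetworkReport(
            label=label,
            network=network,
            cardinality=cardinality_stats(ensemble, burn_in),
            partition=part,
            top=top_states(pooled_census(ensemble, burn_in), top_k),
            efficiency=efficiency_curve(ensemble, output_node) if output_node else None,
        )

    base_report = report(base, base.name)
    mutant_reports = tuple(
        report(apply_clamp(base, node, False), f"{node}_mutant") for node in mutant_nodes
    )
    intersection = frozenset(base_report.partition.variable)
    for rep in mutant_reports:
        intersection &= rep.partition.variable
    return NetworkComparison(
        base=base_report, mutants=mutant_reports, variable_intersection=intersection
    )
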