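"""Stochastic trajectory generation under the hybrid update scheme.

Ruled nodes update deterministically from their Boolean rules; free nodes
receive a fresh independent Bernoulli(1/2) value at every update; clamped
nodes keep their clamp value at every update, including t = 0.

Two update modes are provided.  SYNCHRONOUS evaluates every rule against
the old state; SEQUENTIAL updates nodes in declaration order, each rule
reading the partially updated state.  In SEQUENTIAL mode the random draw
for a free node happens at the node's position in the sweep; because free
draws are independent, both modes consume draws in declaration order, and
the exact-dynamics oracle enumerates them in that same order so its
semantics are bit-identical to the engine's.

Reproducibility: the random stream of run ``i`` is derived from
``SeedSequence(seed, spawn_key=(i,))``, so ensembles are independent of
the execution order of their runs.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .model_io import FREE, BooleanNetwork, NetworkState, compile_rule

__all__ = [
    "UpdateMode",
    "SimulationConfig",
    "Trajectory",
    "TrajectoryEnsemble",
    "CompiledNetwork",
    "random_initial_state",
    "step",
    "simulate",
    "run_ensemble",
    "ensemble_to_tsv",
    "ensemble_from_tsv",
    "ensemble_to_json",
]


class UpdateMode(str, Enum):
    SYNCHRONOUS = "synchronous"
    SEQUENTIAL = "sequential"


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a simulation run or ensemble.

    ``updates`` is the number of update sweeps t_m; a trajectory records
    t_m + 1 states when ``record_initial`` (the default), else t_m.
    ``initial=None`` draws a random initial condition per run.
    """

    updates: int
    mode: UpdateMode = UpdateMode.SYNCHRONOUS
    seed: int = 0
    n_runs: int = 1
    initial: NetworkState | None = None
    record_initial: bool = True

    def __post_init__(self) -> None:
        if self.updates < 1:
            raise ValidationError("updates must be >= 1")
        if self.n_runs < 1:
            raise ValidationError("n_runs must be >= 1")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        object.__setattr__(self, "mode", UpdateMode(self.mode))


class CompiledNetwork:
    """Index-compiled form of a network for fast sweeps."""

    def __init__(self, network: BooleanNetwork):
        self.network = network
        index = {node: i for i, node in enumerate(network.nodes)}
        self.n = network.n
        self.clamp_idx = tuple(index[v] for v in network.nodes if v in network.clamps)
        self.clamp_val = tuple(bool(network.clamps[network.nodes[i]]) for i in self.clamp_idx)
        # kind per node: ('clamp', value) | ('free', draw_slot) | ('rule', fn)
        kinds: list[tuple] = []
        slot = 0
        for i, node in enumerate(network.nodes):
            if node in network.clamps:
                kinds.append(("clamp", bool(network.clamps[node])))
            elif network.rules[node] is FREE:
                kinds.append(("free", slot))
                slot += 1
            else:
                kinds.append(("rule", compile_rule(network.rules[node], index)))
        self.kinds = tuple(kinds)
        self.n_draws = slot

    def sweep(
        self, values: Sequence[bool], mode: UpdateMode, draws: Sequence[bool]
    ) -> tuple[bool, ...]:
        """One update sweep; ``draws`` supplies free-node values in order."""
        if mode is UpdateMode.SYNCHRONOUS:
            old = values
            return tuple(
                kind[1] if kind[0] == "clamp"
                else bool(draws[kind[1]]) if kind[0] == "free"
                else kind[1](old)
                for kind in self.kinds
            )
        cur = list(values)
        for i, kind in enumerate(self.kinds):
            if kind[0] == "clamp":
                cur[i] = kind[1]
            elif kind[0] == "free":
                cur[i] = bool(draws[kind[1]])
            else:
                cur[i] = kind[1](cur)
        return tuple(cur)

    def clamp_values(self, values: Sequence[bool]) -> tuple[bool, ...]:
        """Force clamp values onto a state vector."""
        out = list(bool(v) for v in values)
        for i, val in zip(self.clamp_idx, self.clamp_val):
            out[i] = val
        return tuple(out)


@dataclass(frozen=True)
class Trajectory:
    """Recorded state sequence of one run."""

    network: BooleanNetwork
    config: SimulationConfig
    states: np.ndarray  # bool array, shape (n_recorded, N)
    times: np.ndarray  # int array, update index of each recorded state
    run_index: int = 0

    @property
    def n_recorded(self) -> int:
        return self.states.shape[0]

    def state_at(self, row: int) -> NetworkState:
        return NetworkState(tuple(bool(v) for v in self.states[row]), t=int(self.times[row]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            np.array_equal(self.states, other.states)
            and np.array_equal(self.times, other.times)
            and self.run_index == other.run_index
        )


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Trajectories sharing one network and configuration."""

    network: BooleanNetwork
    config: SimulationConfig
    trajectories: tuple[Trajectory, ...]

    def __post_init__(self) -> None:
        lengths = {t.n_recorded for t in self.trajectories}
        if len(lengths) > 1:
            raise ValidationError("ensemble trajectories have unequal lengths")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def stacked(self) -> np.ndarray:
        """All states as one bool array of shape (n_runs, n_recorded, N)."""
        return np.stack([t.states for t in self.trajectories])


def _run_rng(seed: int, run_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(run_index,)))


def random_initial_state(
    network: BooleanNetwork, rng: np.random.Generator
) -> NetworkState:
    """Sample an initial state: unclamped nodes i.i.d. Bernoulli(1/2),
    clamped nodes at their clamp value."""
    values = [bool(b) for b in rng.random(network.n) < 0.5]
    for node, val in network.clamps.items():
        values[network.index(node)] = bool(val)
    return NetworkState(tuple(values), t=0)


def step(
    network: BooleanNetwork,
    state: NetworkState,
    mode: UpdateMode = UpdateMode.SYNCHRONOUS,
    rng: np.random.Generator | None = None,
    _compiled: CompiledNetwork | None = None,
) -> NetworkState:
    """Apply one update sweep, returning the state at t + 1."""
    compiled = _compiled or CompiledNetwork(network)
    if compiled.n_draws and rng is None:
        raise ValidationError("network has free nodes: an rng is required")
    draws = (
        [bool(b) for b in rng.random(compiled.n_draws) < 0.5] if compiled.n_draws else []
    )
    new = compiled.sweep(state.values, UpdateMode(mode), draws)
    return NetworkState(new, t=state.t + 1)


def simulate(
    network: BooleanNetwork, config: SimulationConfig, run_index: int = 0
) -> Trajectory:
    """Generate one trajectory of ``config.updates`` sweeps.

    Fully reproducible given ``(config.seed, run_index)``.
    """
    compiled = CompiledNetwork(network)
    rng = _run_rng(config.seed, run_index)
    if config.initial is None:
        state = random_initial_state(network, rng)
    else:
        if len(config.initial.values) != network.n:
            raise ValidationError("initial state length does not match network")
        state = NetworkState(compiled.clamp_values(config.initial.values), t=0)
    rows: list[tuple[bool, ...]] = []
    times: list[int] = []
    if config.record_initial:
        rows.append(state.values)
        times.append(0)
    mode = UpdateMode(config.mode)
    for _ in range(config.updates):
        state = step(network, state, mode, rng, _compiled=compiled)
        rows.append(state.values)
        times.append(state.t)
    return Trajectory(
        network=network,
        config=config,
        states=np.array(rows, dtype=bool),
        times=np.array(times, dtype=int),
        run_index=run_index,
    )


def run_ensemble(network: BooleanNetwork, config: SimulationConfig) -> TrajectoryEnsemble:
    """Generate ``config.n_runs`` trajectories with independent random
    streams derived from ``(seed, run_index)``."""
    trajectories = tuple(simulate(network, config, run_index=i) for i in range(config.n_runs))
    return TrajectoryEnsemble(network=network, config=config, trajectories=trajectories)


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------


def ensemble_to_tsv(ensemble: TrajectoryEnsemble) -> str:
    """One row per recorded state: ``run``, ``t``, then one 0/1 column per node."""
    out = io.StringIO()
    out.write("run\tt\t" + "\t".join(ensemble.network.nodes) + "\n")
    for traj in ensemble:
        for row, t in zip(traj.states, traj.times):
            out.write(
                f"{traj.run_index}\t{int(t)}\t" + "\t".join("1" if v else "0" for v in row) + "\n"
            )
    return out.getvalue()


def ensemble_from_tsv(text: str, network: BooleanNetwork, config: SimulationConfig) -> TrajectoryEnsemble:
    """Read back :func:`ensemble_to_tsv` output (round-trip reader)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split("\t")
    if header[:2] != ["run", "t"] or tuple(header[2:]) != tuple(network.nodes):
        raise ValidationError("TSV header does not match network nodes")
    by_run: dict[int, list[tuple[int, list[bool]]]] = {}
    for ln in lines[1:]:
        parts = ln.split("\t")
        run, t = int(parts[0]), int(parts[1])
        by_run.setdefault(run, []).append((t, [p == "1" for p in parts[2:]]))
    trajectories = []
    for run in sorted(by_run):
        entries = sorted(by_run[run])
        trajectories.append(
            Trajectory(
                network=network,
                config=config,
                states=np.array([v for _, v in entries], dtype=bool),
                times=np.array([t for t, _ in entries], dtype=int),
                run_index=run,
            )
        )
    return TrajectoryEnsemble(network=network, config=config, trajectories=tuple(trajectories))


def ensemble_to_json(ensemble: TrajectoryEnsemble) -> str:
    obj = {
        "nodes": list(ensemble.network.nodes),
        "runs": [
            {
                "run": traj.run_index,
                "times": [int(t) for t in traj.times],
                "states": [[int(v) for v in row] for row in traj.states],
            }
            for traj in ensemble
        ],
    }
    return json.dumps(obj)
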