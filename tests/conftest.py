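from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from bnss.engine import SimulationConfig, Trajectory, UpdateMode, simulate
from bnss.model_io import BooleanNetwork, NetworkState, parse_network
from bnss.oracle import ExactDynamics, state_to_int, toy_fixtures


@pytest.fixture(scope="session")
def toys() -> dict[str, BooleanNetwork]:
    return toy_fixtures()


@pytest.fixture
def t1(toys):
    return toys["T1"]


@pytest.fixture
def t2(toys):
    return toys["T2"]


@pytest.fixture
def t3prime(toys):
    return toys["T3prime"]


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------


def empirical_distribution(trajectory: Trajectory, burn_in: int = 0) -> dict[int, float]:
    """Relative visit frequency of each state (as integer code)."""
    rows = trajectory.states[burn_in:]
    counts: dict[int, int] = {}
    for row in rows:
        s = state_to_int(tuple(bool(v) for v in row))
        counts[s] = counts.get(s, 0) + 1
    total = rows.shape[0]
    return {s: c / total for s, c in counts.items()}


def total_variation(p: dict[int, float], q: dict[int, float]) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


def absorption_bound(dynamics: ExactDynamics, max_steps: int = 200) -> int | None:
    """Number of sweeps after which every branch from every clamp-consistent
    start state is surely inside a recurrent class, or None if > max_steps."""
    recurrent = set().union(*dynamics.recurrent_classes)
    frontier = set(dynamics.clamp_consistent_states())
    for k in range(max_steps + 1):
        if frontier <= recurrent:
            return k
        frontier = {t for s in frontier for t, _ in dynamics.successors[s]}
    return None


def explicit_config(values, updates: int, mode=UpdateMode.SYNCHRONOUS, seed: int = 0,
                    n_runs: int = 1) -> SimulationConfig:
    return SimulationConfig(
        updates=updates,
        mode=mode,
        seed=seed,
        n_runs=n_runs,
        initial=NetworkState(tuple(bool(v) for v in values)),
    )
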