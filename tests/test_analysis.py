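import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bnss.analysis import (
    CensusEntry,
    StateCensus,
    cardinality_stats,
    census,
    classify_nodes,
    compare_networks,
    efficiency_curve,
    hamming,
    joint_census,
    pooled_census,
    synchrony_groups,
    top_states,
    true_counts,
)
from bnss.engine import SimulationConfig, TrajectoryEnsemble, run_ensemble, simulate
from bnss.errors import LengthMismatchError, UnknownNodeError, ValidationError
from bnss.model_io import apply_clamp, parse_network
from bnss.oracle import GeneratorSpec, generate_random_network
from conftest import explicit_config


class TestHamming:
    def test_identity(self):
        assert hamming((True, False, True), (True, False, True)) == 0

    def test_all_differ(self):
        assert hamming((True, True), (False, False)) == 2

    @given(st.lists(st.booleans(), min_size=1, max_size=20), st.data())
    @settings(max_examples=50, deadline=None)
    def test_symmetry(self, a, data):
        b = data.draw(st.lists(st.booleans(), min_size=len(a), max_size=len(a)))
        assert hamming(a, b) == hamming(b, a)

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatchError):
            hamming((True,), (True, False))


class TestCensus:
    def test_t1_nine_recorded_states(self, t1):
        # brute force: TT,FT,FF,TF,TT,FT,FF,TF,TT
        c = census(simulate(t1, explicit_config((True, True), updates=8)))
        assert c.total_recorded == 9
        assert c.cardinality == 4
        assert c.counts() == {
            (True, True): 3,
            (False, True): 2,
            (False, False): 2,
            (True, False): 2,
        }

    def test_constant_network_two_states(self):
        net = parse_network("A = True")
        c = census(simulate(net, explicit_config((False,), updates=5)))
        assert c.counts() == {(False,): 1, (True,): 5}

    def test_visit_times_recorded(self, t1):
        c = census(simulate(t1, explicit_config((True, True), updates=8)))
        entry = next(e for e in c.entries if e.state == (True, True))
        assert entry.visit_times == (0, 4, 8)

    def test_burn_in_bounds(self, t1):
        traj = simulate(t1, explicit_config((True, True), updates=4))
        with pytest.raises(ValidationError):
            census(traj, burn_in=5)

    def test_conservation_and_disjointness(self, t3prime):
        traj = simulate(t3prime, SimulationConfig(updates=40, seed=8))
        c = census(traj, burn_in=3)
        assert sum(e.count for e in c.entries) == c.total_recorded == 38
        all_times = sorted(t for e in c.entries for t in e.visit_times)
        assert all_times == list(range(38))  # each recorded row in exactly one entry


class TestCardinalityStats:
    def test_deterministic_identical_inits_sd_zero(self, t2):
        ens = run_ensemble(t2, explicit_config((True, False), updates=10, n_runs=30))
        stats = cardinality_stats(ens)
        assert stats.sd == 0.0

    def test_t1_full_cycle_from_any_init(self, t1):
        ens = run_ensemble(t1, SimulationConfig(updates=6, seed=13, n_runs=20))
        stats = cardinality_stats(ens)
        assert stats.per_run == (4,) * 20
        assert stats.mean == 4.0
        assert stats.sd == 0.0

    def test_single_run_sd_is_nan(self, t1):
        ens = run_ensemble(t1, SimulationConfig(updates=5, seed=1))
        assert np.isnan(cardinality_stats(ens).sd)

    def test_sample_sd_uses_n_minus_1(self, t1, t3prime):
        ens = run_ensemble(t3prime, SimulationConfig(updates=12, seed=3, n_runs=10))
        stats = cardinality_stats(ens)
        assert stats.sd == pytest.approx(np.std(stats.per_run, ddof=1))
        assert min(stats.per_run) <= stats.mean <= max(stats.per_run)

    def test_cardinality_bound(self, t3prime):
        # per-run cardinality <= min(recorded states, 2^N)
        ens = run_ensemble(t3prime, SimulationConfig(updates=100, seed=5, n_runs=10))
        for traj in ens:
            card = census(traj).cardinality
            assert card <= min(traj.n_recorded, 2**t3prime.n)


class TestTopStates:
    @staticmethod
    def _census(entries):
        return StateCensus(
            entries=tuple(
                CensusEntry(state=s, visit_times=tuple(ts), count=len(ts))
                for s, ts in entries
            ),
            total_recorded=sum(len(ts) for _, ts in entries),
        )

    def test_ranked_by_count(self):
        c = self._census([
            ((True, True), [0, 2, 3, 5, 7]),
            ((True, False), [1, 4, 6]),
            ((False, False), [8]),
        ])
        assert [s for s, _ in top_states(c, 2)] == [(True, True), (True, False)]

    def test_tie_break_by_first_visit(self):
        c = self._census([
            ((True, True), [2, 5, 8]),
            ((False, False), [0, 4, 7]),
        ])
        assert top_states(c, 1)[0][0] == (False, False)

    def test_k_exceeding_entries(self):
        c = self._census([((True,), [0])])
        assert len(top_states(c, 5)) == 1

    def test_t3prime_recurrent_states_carry_all_visits(self, t3prime):
        traj = simulate(t3prime, SimulationConfig(updates=400, seed=17))
        c = census(traj, burn_in=1)
        top4 = top_states(c, 4)
        # the exact chain has 4 recurrent states (A == B); they take every visit
        assert sum(count for _, count in top4) == c.total_recorded
        for state, _ in top4:
            assert state[1] == state[2]  # nodes (C, A, B): A == B


class TestClassifyNodes:
    def test_constant_network_all_frozen(self):
        net = parse_network("A = True\nB = False")
        ens = run_ensemble(net, SimulationConfig(updates=10, seed=0, n_runs=5))
        part = classify_nodes(ens, burn_in=1)
        assert part.frozen == {"A": True, "B": False}
        assert part.variable == frozenset()

    def test_t2_cross_run_classification(self, t2):
        # runs from (F,F) and (T,F) are both fixed points; A differs across
        # runs (variable), B is False in both (frozen)
        cfg1 = explicit_config((False, False), updates=10)
        cfg2 = explicit_config((True, False), updates=10)
        ens = TrajectoryEnsemble(
            network=t2, config=cfg1,
            trajectories=(simulate(t2, cfg1), simulate(t2, cfg2)),
        )
        part = classify_nodes(ens)
        assert part.variable == frozenset({"A"})
        assert part.frozen == {"B": False}

    def test_partition_covers_all_nodes_disjointly(self, t3prime):
        ens = run_ensemble(t3prime, SimulationConfig(updates=30, seed=2, n_runs=10))
        part = classify_nodes(ens, burn_in=1)
        assert set(part.frozen) | part.variable == set(t3prime.nodes)
        assert not set(part.frozen) & part.variable

    def test_clamped_node_always_frozen_at_clamp_value(self, t3prime):
        net = apply_clamp(t3prime, "C", True)
        ens = run_ensemble(net, SimulationConfig(updates=20, seed=6, n_runs=10))
        part = classify_nodes(ens)
        assert part.frozen["C"] is True

    def test_adding_runs_never_grows_frozen_set(self, toys):
        net = toys["MIX6"]
        cfg_big = SimulationConfig(updates=15, seed=21, n_runs=12)
        big = run_ensemble(net, cfg_big)
        prev = None
        for k in (1, 3, 6, 12):
            sub = TrajectoryEnsemble(net, cfg_big, big.trajectories[:k])
            frozen = set(classify_nodes(sub, burn_in=1).frozen)
            if prev is not None:
                assert frozen <= prev
            prev = frozen


class TestTrueCounts:
    def test_constant_true_twenty_of_twenty(self):
        net = parse_network("A = True")
        traj = simulate(net, SimulationConfig(updates=20, seed=0))
        assert true_counts(traj, burn_in=1)["A"] == 20

    def test_t1_cycle_counts(self, t1):
        # enumerate cycle over t=0..7: A True 4 times, B True 4 times
        traj = simulate(t1, explicit_config((True, True), updates=7))
        counts = true_counts(traj)
        assert counts == {"A": 4, "B": 4}

    def test_all_false_node_zero(self):
        net = parse_network("A = False")
        traj = simulate(net, explicit_config((False,), updates=10))
        assert true_counts(traj)["A"] == 0


class TestSynchronyGroups:
    def test_t3prime_followers_grouped(self, t3prime):
        ens = run_ensemble(t3prime, SimulationConfig(updates=30, seed=4, n_runs=5))
        groups = synchrony_groups(ens, burn_in=1)
        as_sets = {frozenset(g.nodes) for g in groups}
        assert frozenset({"A", "B"}) in as_sets
        assert frozenset({"C"}) in as_sets

    def test_complementary_joins_with_negation_flag(self):
        # B copies A's previous value, C copies its negation: exact complements
        net = parse_network("A = RANDOM\nB = A\nC = NOT A")
        ens = run_ensemble(net, SimulationConfig(updates=40, seed=19, n_runs=4))
        groups = synchrony_groups(ens, burn_in=1, include_complementary=True)
        target = next(g for g in groups if "B" in g.nodes)
        assert set(target.nodes) == {"B", "C"}
        assert target.negated == frozenset({"C"})
        # without the flag they are separate groups
        plain = synchrony_groups(ens, burn_in=1)
        assert all(not g.negated for g in plain)
        assert {frozenset(g.nodes) for g in plain} >= {frozenset({"B"}), frozenset({"C"})}

    def test_frozen_nodes_excluded(self):
        net = parse_network("A = True\nB = True\nC = RANDOM")
        ens = run_ensemble(net, SimulationConfig(updates=20, seed=1, n_runs=5))
        groups = synchrony_groups(ens, burn_in=1)
        members = {n for g in groups for n in g.nodes}
        assert "A" not in members and "B" not in members


class TestJointCensus:
    def test_self_pair(self, t3prime):
        ens = run_ensemble(t3prime, SimulationConfig(updates=20, seed=0, n_runs=3))
        jc = joint_census(ens, ("A", "A"))
        assert jc.counts[(True, False)] == 0 and jc.counts[(False, True)] == 0
        assert jc.verdict == "synchronized_equal"

    def test_t3prime_pair_ab_synchronized_equal(self, t3prime):
        ens = run_ensemble(t3prime, SimulationConfig(updates=20, seed=7, n_runs=10))
        jc = joint_census(ens, ("A", "B"), burn_in=1)
        assert jc.counts[(True, False)] == 0 and jc.counts[(False, True)] == 0
        assert jc.verdict == "synchronized_equal"
        assert jc.total == 10 * 20

    def test_t3prime_pair_ac_unsynchronized(self, t3prime):
        # A_t = C_{t-1} is independent of C_t: all four cells fill up
        ens = run_ensemble(t3prime, SimulationConfig(updates=200, seed=3, n_runs=5))
        jc = joint_census(ens, ("A", "C"), burn_in=1)
        assert all(v > 0 for v in jc.counts.values())
        assert jc.verdict == "unsynchronized"

    def test_unknown_node(self, t3prime):
        ens = run_ensemble(t3prime, SimulationConfig(updates=5, seed=0))
        with pytest.raises(UnknownNodeError):
            joint_census(ens, ("A", "nope"))


class TestEfficiencyCurve:
    def test_forced_by_clamped_input(self):
        net = apply_clamp(parse_network("In = RANDOM\nOut = In"), "In", True)
        ens = run_ensemble(net, SimulationConfig(updates=10, seed=5, n_runs=20))
        curve = efficiency_curve(ens, "Out")
        assert all(f == 1.0 for f in curve.fractions[1:])

    def test_free_output_near_half(self):
        # binomial oracle at 300 runs: 3 sigma ~ 0.0866
        net = parse_network("Out = RANDOM")
        ens = run_ensemble(net, SimulationConfig(updates=20, seed=23, n_runs=300))
        curve = efficiency_curve(ens, "Out")
        assert all(abs(f - 0.5) < 0.0866 for f in curve.fractions[1:])

    def test_clamped_true_output_identically_one(self, t3prime):
        net = apply_clamp(t3prime, "B", True)
        ens = run_ensemble(net, SimulationConfig(updates=15, seed=2, n_runs=10))
        curve = efficiency_curve(ens, "B")
        assert curve.fractions == (1.0,) * 16

    def test_curve_shape(self, t3prime):
        ens = run_ensemble(t3prime, SimulationConfig(updates=12, seed=1, n_runs=7))
        curve = efficiency_curve(ens, "A")
        assert len(curve.fractions) == 13
        assert curve.n_runs == 7
        assert all(0.0 <= f <= 1.0 for f in curve.fractions)

    def test_unknown_output_node(self, t3prime):
        ens = run_ensemble(t3prime, SimulationConfig(updates=5, seed=0))
        with pytest.raises(UnknownNodeError):
            efficiency_curve(ens, "nope")


class TestCompareNetworks:
    def test_constant_base_cardinalities(self):
        net = parse_network("A = True\nB = False")
        cmp = compare_networks(net, ["A"], SimulationConfig(updates=10, seed=0, n_runs=5))
        for rep in cmp.reports:
            assert all(c <= 2 for c in rep.cardinality.per_run)

    def test_t3prime_mutant_c_all_frozen(self, t3prime):
        cmp = compare_networks(
            t3prime, ["C"], SimulationConfig(updates=30, seed=9, n_runs=10), burn_in=1
        )
        mutant = cmp.mutants[0]
        assert mutant.partition.frozen == {"C": False, "A": False, "B": False}
        assert mutant.partition.variable == frozenset()
        assert cmp.variable_intersection == frozenset()
        # clamping shrinks the visited state set
        assert mutant.cardinality.mean <= cmp.base.cardinality.mean

    def test_efficiency_included_when_requested(self, t3prime):
        cmp = compare_networks(
            t3prime, [], SimulationConfig(updates=10, seed=0, n_runs=4),
            output_node="A",
        )
        assert cmp.base.efficiency is not None
        assert cmp.base.efficiency.output_node == "A"

    def test_unknown_mutant_node(self, t3prime):
        with pytest.raises(UnknownNodeError):
            compare_networks(t3prime, ["zzz"], SimulationConfig(updates=5, seed=0))


class TestPropertiesOnRandomNetworks:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_census_conservation_and_bound(self, seed):
        net = generate_random_network(GeneratorSpec(n=7, k=2, free_fraction=0.3, seed=seed))
        ens = run_ensemble(net, SimulationConfig(updates=25, seed=seed, n_runs=6))
        pooled = pooled_census(ens, burn_in=2)
        assert sum(e.count for e in pooled.entries) == pooled.total_recorded
        for traj in ens:
            c = census(traj)
            assert c.cardinality <= min(traj.n_recorded, 2**net.n)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_partition_is_a_partition(self, seed):
        net = generate_random_network(GeneratorSpec(n=6, k=2, free_fraction=0.2, seed=seed))
        ens = run_ensemble(net, SimulationConfig(updates=20, seed=seed, n_runs=8))
        part = classify_nodes(ens, burn_in=1)
        assert set(part.frozen) | part.variable == set(net.nodes)
        assert not set(part.frozen) & part.variable
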