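"""Solver, metric and witness tests for the knapsack core."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ktcc.errors import InvalidInstanceError, SizeLimitError
from ktcc.knapsack import (
    DecisionResult,
    Instance,
    Item,
    brute_force_decision,
    compute_constrainedness,
    frame_to_instances,
    instances_to_frame,
    read_instances_json,
    solve_decision,
    solve_optimization,
    verify_witness,
    write_instances_json,
)


def make(values, weights, c, p, iid="x"):
    return Instance(
        items=tuple(Item(v, w) for v, w in zip(values, weights)),
        capacity=c,
        target_profit=p,
        id=iid,
    )


# strategy: small random instances with positive integer payloads
@hst.composite
def instances(draw, max_items=10):
    n = draw(hst.integers(2, max_items))
    values = draw(hst.lists(hst.integers(1, 60), min_size=n, max_size=n))
    weights = draw(hst.lists(hst.integers(1, 60), min_size=n, max_size=n))
    c = draw(hst.integers(1, sum(weights)))
    p = draw(hst.integers(1, sum(values)))
    return make(values, weights, c, p)


class TestConstrainedness:
    def test_alpha_p_is_profit_over_total_value(self):
        inst = make([10, 20, 30], [5, 5, 5], c=10, p=30)
        ap, ac = compute_constrainedness(inst)
        assert ap == 0.5

    def test_alpha_c_boundary_when_capacity_equals_total_weight(self):
        inst = make([1, 1, 1, 1], [10, 10, 10, 10], c=40, p=1)
        _, ac = compute_constrainedness(inst)
        assert ac == 1.0

    @given(instances())
    @settings(max_examples=100, derandomize=True)
    def test_matches_exact_rational_oracle(self, inst):
        ap, ac = compute_constrainedness(inst)
        assert ap == pytest.approx(
            float(Fraction(inst.target_profit, sum(inst.values))), abs=1e-12
        )
        assert ac == pytest.approx(
            float(Fraction(inst.capacity, sum(inst.weights))), abs=1e-12
        )

    def test_empty_instance_rejected(self):
        with pytest.raises(InvalidInstanceError):
            Instance(items=(), capacity=1, target_profit=1)

    def test_non_integer_fields_rejected(self):
        with pytest.raises(InvalidInstanceError):
            Item(1.5, 2)
        with pytest.raises(InvalidInstanceError):
            make([1], [1], c=0, p=1)


class TestBruteForce:
    def test_known_satisfiable_instance_and_canonical_witness(self):
        # subsets enumerated by bitmask; {0,1} (mask 3) is the first hit
        res = brute_force_decision(make([4, 5, 6], [3, 4, 5], c=7, p=9))
        assert res.satisfiable
        assert res.witness == frozenset({0, 1})

    def test_profit_above_total_value_is_unsatisfiable(self):
        res = brute_force_decision(make([4, 5], [1, 1], c=2, p=10))
        assert not res.satisfiable and res.witness is None

    def test_single_cheap_item_suffices(self):
        res = brute_force_decision(make([5, 9], [2, 50], c=3, p=4))
        assert res.satisfiable

    def test_size_guard(self):
        inst = make([1] * 26, [1] * 26, c=1, p=1)
        with pytest.raises(SizeLimitError):
            brute_force_decision(inst)


class TestBranchAndBound:
    @given(instances())
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_verdict_matches_exhaustive_enumeration(self, inst):
        assert solve_decision(inst).satisfiable == brute_force_decision(inst).satisfiable

    @given(instances())
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_witness_soundness_and_node_bound(self, inst):
        res = solve_decision(inst)
        if res.satisfiable:
            assert verify_witness(inst, res.witness)
        assert res.effort_nodes <= 2 ** (inst.n_items + 1) - 1

    def test_all_items_overweight_prunes_immediately(self):
        inst = make([10, 10, 10], [50, 60, 70], c=5, p=1)
        res = solve_decision(inst)
        assert not res.satisfiable
        assert res.effort_nodes <= inst.n_items + 1

    def test_deterministic_effort_counters(self):
        inst = make([7, 9, 4, 8, 2, 6], [13, 21, 8, 17, 5, 11], c=30, p=20)
        a, b = solve_decision(inst), solve_decision(inst)
        assert a == b

    @given(instances(max_items=8), hst.integers(1, 100))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_satisfiability_monotone_in_profit_and_capacity(self, inst, delta):
        res = solve_decision(inst)
        if res.satisfiable:
            # lowering the target or raising the capacity cannot break it
            if inst.target_profit > 1:
                easier = make(
                    inst.values, inst.weights, inst.capacity, inst.target_profit - 1
                )
                assert solve_decision(easier).satisfiable
            roomier = make(
                inst.values, inst.weights, inst.capacity + delta, inst.target_profit
            )
            assert solve_decision(roomier).satisfiable


class TestWitness:
    def test_valid_witness_accepted(self):
        assert verify_witness(make([4, 5, 6], [3, 4, 5], c=7, p=9), {0, 1})

    def test_empty_subset_fails_positive_target(self):
        assert not verify_witness(make([4], [3], c=7, p=1), set())

    def test_out_of_range_and_duplicate_indices_rejected(self):
        inst = make([4], [3], c=7, p=1)
        with pytest.raises(IndexError):
            verify_witness(inst, {5})
        with pytest.raises(IndexError):
            verify_witness(inst, [0, 0])


class TestOptimization:
    def test_known_optimum(self):
        best, subset = solve_optimization([(4, 3), (5, 4), (6, 5)], capacity=7)
        assert best == 9
        assert sum((4, 5, 6)[i] for i in subset) == 9

    def test_zero_capacity(self):
        best, subset = solve_optimization([(4, 3)], capacity=0)
        assert best == 0 and subset == frozenset()

    def test_everything_fits(self):
        best, subset = solve_optimization([(4, 3), (5, 4)], capacity=100)
        assert best == 9 and subset == frozenset({0, 1})

    @given(instances(max_items=8))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_decision_consistency(self, inst):
        best, subset = solve_optimization(inst.items, inst.capacity)
        assert sum(inst.weights[i] for i in subset) <= inst.capacity
        assert sum(inst.values[i] for i in subset) == best
        assert (best >= inst.target_profit) == solve_decision(inst).satisfiable


class TestInstanceIO:
    def test_csv_frame_round_trip(self):
        insts = [
            make([4, 5, 6], [3, 4, 5], c=7, p=9, iid="a"),
            make([10, 20], [2, 3], c=4, p=12, iid="b"),
        ]
        assert frame_to_instances(instances_to_frame(insts)) == insts

    def test_json_round_trip(self, tmp_path):
        insts = [make([4, 5], [3, 4], c=7, p=9, iid="a")]
        path = tmp_path / "inst.json"
        write_instances_json(insts, path)
        assert read_instances_json(path) == insts

    def test_inconsistent_capacity_rows_rejected(self):
        insts = [make([4, 5], [3, 4], c=7, p=9, iid="a")]
        frame = instances_to_frame(insts)
        frame.loc[1, "capacity"] = 99
        with pytest.raises(InvalidInstanceError):
            frame_to_instances(frame)
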