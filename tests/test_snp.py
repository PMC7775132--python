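import numpy as np
import pytest

from spicseg import Mask2D
from spicseg.snp import (
    ALL,
    CONSUMED,
    BoundaryGrid,
    Guard,
    Neuron,
    SNPRule,
    SNPSystem,
    SystemState,
    boundary_pixels,
    build_network,
    classify,
    network_depth,
    network_score,
    normalize_boundary,
    relay_rule,
    run,
    step,
    train,
    trainable_edges,
)


from _snp_oracle import fire, forget, make_system, oracle_step, rule_catalog


class TestGuards:
    def test_primitives(self):
        assert Guard.exact(3).matches(3) and not Guard.exact(3).matches(2)
        assert Guard.at_least(2).matches(5) and not Guard.at_least(2).matches(1)
        prog = Guard.progression(1, 2)  # odd counts
        assert prog.matches(1) and prog.matches(5) and not prog.matches(4)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            Guard.exact(1).matches(-1)


class TestRuleValidation:
    def test_forget_cannot_produce_or_delay(self):
        with pytest.raises(ValueError):
            SNPRule(kind="forget", guard=Guard.exact(1), consume=1, produce=1)
        with pytest.raises(ValueError):
            SNPRule(kind="forget", guard=Guard.exact(1), consume=1, delay=1)

    def test_plasticity_needs_targets(self):
        with pytest.raises(ValueError):
            SNPRule(kind="syn_plastic", guard=Guard.exact(1), consume=1, alpha="+")


class TestStepSemantics:
    def test_fire_consumes_and_delivers(self):
        """Neuron with 2 pulses, guard {2}, c=2, p=1, two successors:
        after one step it holds 0 and each successor gains 1."""
        sys_ = make_system({0: [fire(Guard.exact(2), c=2, p=1)], 1: [], 2: []},
                           {0: 2, 1: 0, 2: 0}, [(0, 1), (0, 2)])
        state = SystemState.initial(sys_)
        step(sys_, state)
        assert state.pulses == {0: 0, 1: 1, 2: 1}
        assert state.halted

    def test_delayed_fire_and_closed_window(self):
        """d=2: successors unchanged at steps t and t+1, +p at t+2; the
        firing neuron is closed during [t, t+d-1] and loses arrivals."""
        sys_ = make_system(
            {0: [fire(Guard.at_least(1), d=2)], 1: [fire(Guard.at_least(1))], 2: []},
            {0: 1, 1: 1, 2: 0}, [(0, 2), (1, 0)])
        state = SystemState.initial(sys_)
        step(sys_, state)  # t=0: 0 fires (delayed), closes; 1 fires into 0 -> lost
        assert state.pulses == {0: 0, 1: 0, 2: 0}
        assert state.audit["lost"] == 1
        step(sys_, state)  # t=1: still pending
        assert state.pulses[2] == 0
        step(sys_, state)  # t=2: delivery
        assert state.pulses[2] == 1
        assert state.halted

    def test_forget_produces_nothing(self):
        sys_ = make_system({0: [forget(3)], 1: []}, {0: 3, 1: 0}, [(0, 1)])
        state = SystemState.initial(sys_)
        step(sys_, state)
        assert state.pulses == {0: 0, 1: 0}
        assert state.audit["emitted"] == 0

    def test_lowest_index_rule_wins(self):
        sys_ = make_system({0: [forget(2), fire(Guard.exact(2), c=2)], 1: []},
                           {0: 2, 1: 0}, [(0, 1)])
        state = SystemState.initial(sys_)
        step(sys_, state)
        assert state.pulses[1] == 0  # the forget rule (index 0) was applied

    def test_plasticity_creates_then_complement_deletes(self):
        plastic = SNPRule(kind="syn_plastic", guard=Guard.exact(1), consume=1,
                          alpha="+-", k_limit=2, target_set=frozenset({1, 2}))
        sys_ = make_system({0: [plastic], 1: [], 2: []}, {0: 1, 1: 0, 2: 0}, [])
        state = SystemState.initial(sys_)
        step(sys_, state)
        assert set(sys_.syn) == {(0, 1), (0, 2)}  # created at t
        step(sys_, state)
        assert set(sys_.syn) == set()  # complement deletes at t+1

    def test_plasticity_empty_pool_only_consumes(self):
        plastic = SNPRule(kind="syn_plastic", guard=Guard.exact(1), consume=1,
                          alpha="+", k_limit=1, target_set=frozenset({1}))
        sys_ = make_system({0: [plastic], 1: []}, {0: 1, 1: 0}, [(0, 1)])
        state = SystemState.initial(sys_)
        step(sys_, state)
        assert state.pulses[0] == 0 and set(sys_.syn) == {(0, 1)}

    def test_stepping_halted_system_is_an_error(self):
        sys_ = make_system({0: []}, {0: 0}, [])
        state = SystemState.initial(sys_)
        assert state.halted
        with pytest.raises(RuntimeError):
            step(sys_, state)


def test_engine_matches_transition_oracle():
    """Sampled exhaustive check: random 3-neuron systems with <= 2 rules
    per neuron and <= 3 initial pulses agree with the hand-coded oracle
    over 6 synchronous steps, with pulse accounting audited."""
    cat = rule_catalog()
    rng = np.random.default_rng(7)
    for trial in range(400):
        n = 3
        idx = rng.integers(0, len(cat), size=(n, 2))
        n_rules = rng.integers(0, 3, size=n)
        pulses0 = {i: int(rng.integers(0, 4)) for i in range(n)}
        edges = [(i, j) for i in range(n) for j in range(n)
                 if i != j and rng.random() < 0.5]
        neuron_rules = {i: [cat[k][0] for k in idx[i][: n_rules[i]]] for i in range(n)}
        sys_ = make_system(neuron_rules, pulses0, edges)
        state = SystemState.initial(sys_)

        o_rules = {i: [cat[k][1] for k in idx[i][: n_rules[i]]] for i in range(n)}
        o_pulses = dict(pulses0)
        o_closed = {i: 0 for i in range(n)}
        o_pending = []
        for t in range(6):
            if state.halted:
                break
            step(sys_, state)
            o_pulses, o_closed, o_pending = oracle_step(
                o_rules, o_pulses, o_closed, o_pending, set(edges), t)
            assert state.pulses == o_pulses, (trial, t)
            assert state.closed_for == o_closed, (trial, t)
        # pulse accounting: what's in the system now equals what was
        # there initially, minus consumption, plus weighted deliveries
        total_now = sum(state.pulses.values()) + sum(a for _, _, a in state.pending)
        assert total_now == (sum(pulses0.values()) - state.audit["consumed"]
                             + state.audit["delivered"]
                             + sum(a for _, _, a in state.pending))


class TestBoundaryEncoding:
    def test_square_ring_count(self):
        m = np.zeros((10, 10), dtype=np.uint8)
        m[3:7, 3:7] = 1
        ring = boundary_pixels(Mask2D(m))
        assert ring.area() == 12

    def test_all_zero(self):
        assert boundary_pixels(Mask2D(np.zeros((5, 5), dtype=np.uint8))).area() == 0

    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=np.uint8)
        m[2, 2] = 1
        np.testing.assert_array_equal(boundary_pixels(Mask2D(m)).pixels, m)

    def test_border_pixels_are_boundary(self):
        m = np.ones((4, 4), dtype=np.uint8)
        ring = boundary_pixels(Mask2D(m))
        assert ring.area() == 12  # all but the 2x2 interior

    def test_normalize_identity_pattern(self):
        cells = (np.arange(35).reshape(5, 7) % 3 == 0).astype(np.uint8)
        cells[0, 0] = cells[-1, -1] = 1  # pin the bounding box
        grid = normalize_boundary(Mask2D(cells))
        np.testing.assert_array_equal(grid.cells, cells)

    def test_normalize_matches_pooling_oracle(self, rng):
        """Bounding-box pooling equals an explicit double loop."""
        m = np.zeros((50, 70), dtype=np.uint8)
        rr, cc = np.mgrid[0:50, 0:70]
        ring = np.abs(np.hypot(rr - 25, cc - 35) - 20) < 1.0
        m[ring] = 1
        grid = normalize_boundary(Mask2D(m))
        rows, cols = np.nonzero(m)
        r0, r1, c0, c1 = rows.min(), rows.max(), cols.min(), cols.max()
        hb, wb = r1 - r0 + 1, c1 - c0 + 1
        want = np.zeros((5, 7), dtype=np.uint8)
        for r, c in zip(rows, cols):
            want[(r - r0) * 5 // hb, (c - c0) * 7 // wb] = 1
        np.testing.assert_array_equal(grid.cells, want)

    def test_empty_boundary_rejected(self):
        with pytest.raises(ValueError):
            normalize_boundary(Mask2D(np.zeros((5, 5), dtype=np.uint8)))


class TestNetwork:
    def test_module_sizes_and_weights(self):
        sys_ = build_network()
        labels = set(sys_.neurons)
        assert len([l for l in labels if l < 100]) == 35
        assert len([l for l in labels if 100 <= l < 200]) == 3
        assert len([l for l in labels if 200 <= l < 300]) == 12
        assert len([l for l in labels if l >= 300]) == 20
        assert all(w == 1.0 for w in sys_.syn.values())

    def test_initial_pulses_equal_grid_ones(self, rng):
        cells = (rng.random((5, 7)) < 0.4).astype(np.uint8)
        sys_ = build_network(BoundaryGrid(cells))
        total = sum(sys_.neurons[i].pulses for i in range(35))
        assert total == int(cells.sum())

    def test_unknown_weight_edge_rejected(self):
        with pytest.raises(ValueError, match="unknown synapse"):
            build_network(weights={(1, 2): 0.5})

    def test_zero_grid_halts_immediately(self):
        sys_ = build_network(BoundaryGrid(np.zeros((5, 7), dtype=np.uint8)))
        counts, halted, steps = run(sys_)
        assert halted and steps == 0 and all(v == 0 for v in counts.values())

    def test_halting_within_drain_bound(self, rng):
        cells = (rng.random((5, 7)) < 0.6).astype(np.uint8)
        grid = BoundaryGrid(cells)
        sys_ = build_network(grid)
        depth = network_depth(sys_)
        counts, halted, steps = run(sys_)
        assert halted
        assert steps <= depth + grid.total_pulses()

    def test_run_deterministic(self, rng):
        cells = (rng.random((5, 7)) < 0.5).astype(np.uint8)
        a = network_score(BoundaryGrid(cells))
        b = network_score(BoundaryGrid(cells))
        assert a == b

    def test_score_monotone_in_pulse_count(self):
        scores = []
        for z in (5, 12, 20, 30):
            cells = np.zeros(35, dtype=np.uint8)
            cells[:z] = 1
            scores.append(network_score(BoundaryGrid(cells.reshape(5, 7)))[0])
        assert all(a < b for a, b in zip(scores, scores[1:]))


def random_grid(rng, z):
    cells = np.zeros(35, dtype=np.uint8)
    cells[rng.choice(35, size=z, replace=False)] = 1
    return BoundaryGrid(cells.reshape(5, 7))


class TestTraining:
    def make_separable(self, rng, n=10):
        grids = [random_grid(rng, int(rng.integers(6, 12))) for _ in range(n)]
        grids += [random_grid(rng, int(rng.integers(20, 30))) for _ in range(n)]
        return grids, [0] * n + [1] * n

    def test_separable_reaches_perfect_accuracy(self, rng):
        grids, labels = self.make_separable(rng)
        trained = train(grids, labels, epochs=50)
        assert trained.history[-1] == 0
        assert len(trained.history) <= 50
        preds = [int(network_score(g, trained.weights)[0] >= trained.threshold)
                 for g in grids]
        assert preds == labels

    def test_zero_epochs_keeps_unit_weights(self, rng):
        grids, labels = self.make_separable(rng, n=2)
        trained = train(grids, labels, epochs=0)
        assert all(w == 1.0 for w in trained.weights.values())
        assert set(trained.weights) == set(trainable_edges())

    def test_deterministic(self, rng):
        grids, labels = self.make_separable(rng, n=4)
        a = train(grids, labels, epochs=10, seed=3)
        b = train(grids, labels, epochs=10, seed=3)
        assert a.weights == b.weights and a.threshold == b.threshold

    def test_single_class_rejected(self, rng):
        grids = [random_grid(rng, 5), random_grid(rng, 6)]
        with pytest.raises(ValueError):
            train(grids, [1, 1], epochs=5)

    def test_weights_json_round_trip(self, rng):
        grids, labels = self.make_separable(rng, n=3)
        trained = train(grids, labels, epochs=5)
        from spicseg.snp import TrainedWeights

        back = TrainedWeights.from_json(trained.to_json())
        assert back.weights == trained.weights
        assert back.threshold == trained.threshold


class TestClassify:
    def test_zero_counts_non_spiculated(self):
        label, score = classify({315: 0, 316: 0}, threshold=1.0)
        assert label == 0 and score == 0.0

    def test_score_monotone_in_counts(self):
        lo = classify({315: 1, 316: 2}, threshold=0.0)[1]
        hi = classify({315: 2, 316: 2}, threshold=0.0)[1]
        assert hi > lo
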