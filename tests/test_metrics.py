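import math

import numpy as np
import pytest

from batplant.metrics import (
    ModulePartition,
    StructureReport,
    UndefinedMetricError,
    barber_modularity,
    compartments,
    connectance,
    find_modules,
    normalized_modularity,
    structure_report,
    wnodf,
    wnodf_raw,
    wnodf_sm,
)
from batplant.netcore import ValidationError, WeightedBipartiteNetwork
from batplant.synthetic import generate_perfect
from conftest import random_hygienic_net
from oracles import barber_q_oracle, exhaustive_best_q, wnodf_oracle


class TestConnectance:
    def test_half_filled(self):
        net = WeightedBipartiteNetwork(
            ["b1", "b2"], ["p1", "p2", "p3"], np.array([[1, 1, 0], [0, 0, 1]])
        )
        assert connectance(net) == 0.5

    def test_full_matrix_is_one(self):
        net = WeightedBipartiteNetwork(
            ["b1", "b2"], ["p1", "p2"], np.ones((2, 2), dtype=int)
        )
        assert connectance(net) == 1.0


class TestCompartments:
    def test_block_diagonal_counts_blocks(self):
        for k in (1, 2, 3):
            net = generate_perfect("block", k=k, block_size=2)
            assert compartments(net)[0] == k

    def test_supergeneralist_glues_network(self):
        # one bat interacting with every plant -> a single compartment
        W = np.array([[1, 1, 1], [1, 0, 0], [0, 0, 1]])
        net = WeightedBipartiteNetwork(["b1", "b2", "b3"], ["p1", "p2", "p3"], W)
        assert compartments(net)[0] == 1

    def test_labels_ordered_by_size_then_row(self):
        net = generate_perfect("block", k=2, block_size=2)
        n, labels = compartments(net)
        assert n == 2
        # first block holds rows 0,1 and cols 0,1 (node ids 4,5)
        assert labels.tolist() == [0, 0, 1, 1, 0, 0, 1, 1]


class TestWnodf:
    def test_perfectly_nested_is_one(self, tiny_nested):
        assert wnodf(tiny_nested) == 1.0

    def test_checkerboard_ties_are_zero(self, checkerboard):
        assert wnodf(checkerboard) == 0.0

    def test_single_cell_matrix_undefined(self):
        net = WeightedBipartiteNetwork(["b1"], ["p1"], np.array([[3]]))
        with pytest.raises(UndefinedMetricError):
            wnodf(net)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            net = random_hygienic_net(rng)
            assert wnodf_raw(net) == pytest.approx(wnodf_oracle(net.weights), abs=1e-9)

    def test_ties_never_increase_wnodf(self, tiny_nested):
        # flattening the strictly nested weights into ties can only lose score
        tied = tiny_nested.with_weights(np.array([[1, 1], [1, 0]]))
        assert wnodf(tied) <= wnodf(tiny_nested)


class TestBarberModularity:
    def test_single_module_is_zero(self):
        rng = np.random.default_rng(5)
        net = random_hygienic_net(rng)
        part = ModulePartition(np.zeros(net.n_rows), np.zeros(net.n_cols))
        assert barber_modularity(net, part) == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_identity_pair(self, checkerboard):
        part = ModulePartition([0, 1], [0, 1])
        assert barber_modularity(checkerboard, part) == pytest.approx(0.5)

    def test_two_block_planted_partition(self):
        net = generate_perfect("block", k=2, block_size=2)
        part = ModulePartition([0, 0, 1, 1], [0, 0, 1, 1])
        assert barber_modularity(net, part) == pytest.approx(0.5)

    def test_size_mismatch_raises(self, checkerboard):
        with pytest.raises(ValidationError):
            barber_modularity(checkerboard, ModulePartition([0], [0, 1]))

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            net = random_hygienic_net(rng)
            g = rng.integers(0, 3, net.n_rows)
            h = rng.integers(0, 3, net.n_cols)
            assert barber_modularity(net, ModulePartition(g, h)) == pytest.approx(
                barber_q_oracle(net.weights, g, h), abs=1e-12
            )

    def test_normalized_at_most_exceeds_raw(self):
        net = generate_perfect("block", k=2, block_size=2)
        part = ModulePartition([0, 0, 1, 1], [0, 0, 1, 1])
        assert normalized_modularity(net, part) == pytest.approx(1.0)


class TestFindModules:
    def test_recovers_planted_two_blocks(self):
        net = generate_perfect("block", k=2, block_size=2)
        part = find_modules(net, reps=5, seed=0)
        assert part.Q == pytest.approx(0.5)
        assert part.row_assign.tolist() == part.col_assign.tolist()
        assert len(set(part.row_assign)) == 2

    def test_single_cell_network(self):
        net = WeightedBipartiteNetwork(["b1"], ["p1"], np.array([[1]]))
        part = find_modules(net, reps=1, seed=0)
        assert part.n_modules == 1
        assert part.Q == pytest.approx(0.0)

    def test_reps_below_one_rejected(self):
        net = generate_perfect("block", k=2, block_size=2)
        with pytest.raises(ValidationError):
            find_modules(net, reps=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        net = random_hygienic_net(rng, max_rows=5, max_cols=7)
        p1 = find_modules(net, reps=4, seed=99)
        p2 = find_modules(net, reps=4, seed=99)
        assert p1.Q == p2.Q
        assert p1.row_assign.tolist() == p2.row_assign.tolist()
        assert p1.col_assign.tolist() == p2.col_assign.tolist()

    def test_attains_exhaustive_optimum_on_tiny_networks(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            net = random_hygienic_net(rng, max_rows=3, max_cols=5)
            part = find_modules(net, reps=10, seed=int(rng.integers(2**31)))
            assert part.Q == pytest.approx(exhaustive_best_q(net.weights), abs=1e-9)

    def test_canonical_ids_ordered_by_module_weight(self):
        net = generate_perfect("block", k=2, block_size=2)
        W = net.weights.copy()
        W[2:, 2:] *= 5  # second block now much heavier
        part = find_modules(net.with_weights(W), reps=5, seed=0)
        assert part.row_assign.tolist() == [1, 1, 0, 0]


class TestWnodfSm:
    def test_single_module_equals_wnodf(self):
        rng = np.random.default_rng(8)
        net = random_hygienic_net(rng)
        part = ModulePartition(np.zeros(net.n_rows), np.zeros(net.n_cols))
        assert wnodf_sm(net, part) == pytest.approx(wnodf(net))

    def test_internally_nested_blocks_score_one(self):
        W = np.zeros((4, 4), dtype=int)
        W[:2, :2] = [[2, 1], [1, 0]]
        W[2:, 2:] = [[2, 1], [1, 0]]
        net = WeightedBipartiteNetwork(
            [f"b{i}" for i in range(4)], [f"p{j}" for j in range(4)], W
        )
        part = ModulePartition([0, 0, 1, 1], [0, 0, 1, 1])
        assert wnodf_sm(net, part) == pytest.approx(1.0)

    def test_no_same_module_pair_is_undefined(self):
        net = WeightedBipartiteNetwork(
            ["b1", "b2"], ["p1", "p2"], np.array([[1, 0], [0, 1]])
        )
        part = ModulePartition([0, 1], [0, 1])
        assert math.isnan(wnodf_sm(net, part))


class TestPermutationInvariance:
    def test_metrics_stable_under_joint_permutation(self):
        rng = np.random.default_rng(19)
        for _ in range(10):
            net = random_hygienic_net(rng)
            pr, pc = rng.permutation(net.n_rows), rng.permutation(net.n_cols)
            perm = WeightedBipartiteNetwork(
                [net.row_labels[i] for i in pr],
                [net.col_labels[j] for j in pc],
                net.weights[np.ix_(pr, pc)],
            )
            assert connectance(perm) == pytest.approx(connectance(net))
            assert wnodf(perm) == pytest.approx(wnodf(net))
            assert compartments(perm)[0] == compartments(net)[0]
            assert find_modules(perm, reps=8, seed=3).Q == pytest.approx(
                find_modules(net, reps=8, seed=3).Q, abs=1e-9
            )


class TestStructureReport:
    def test_composition_consistent_with_parts(self):
        net = generate_perfect("block", k=2, block_size=2)
        report, part = structure_report(net, reps=5, seed=0)
        assert report.plant_richness == net.n_cols
        assert report.bat_richness == net.n_rows
        assert report.connectance == pytest.approx(connectance(net))
        assert report.wnodf == pytest.approx(wnodf(net))
        assert report.modularity == pytest.approx(part.Q)
        assert report.n_compartments == 2

    def test_json_roundtrip(self):
        net = generate_perfect("block", k=2, block_size=2)
        report, _ = structure_report(net, reps=5, seed=0)
        report.z_scores["wnodf"] = -2.1
        back = StructureReport.from_json(report.to_json())
        assert back.to_dict() == report.to_dict()
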