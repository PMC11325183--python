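"""Adaptive tree: density threshold, DBSCAN, ε-sweep hierarchy, export."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import welltree as wt
from welltree.errors import (
    InsufficientDataError,
    InvalidArgumentError,
    NodeNotFoundError,
    TreeValidationError,
)
from welltree.evaluate import maximal_depth_branches, well_recovery
from welltree.reference import brute_force_dbscan
from welltree.tree import NOISE, TreeNode

# two tight triplets far apart; integer coordinates keep all distance
# comparisons exact in floating point
SIX_POINTS = np.array([0.0, 1.0, 2.0, 50.0, 51.0, 52.0]).reshape(-1, 1)


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """Identical clusterings up to relabeling (noise must match exactly)."""
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == NOISE, b == NOISE):
        return False
    mapping: dict[int, int] = {}
    back: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == NOISE:
            continue
        if mapping.setdefault(x, y) != y or back.setdefault(y, x) != x:
            return False
    return True


class TestHypersphereVolume:
    def test_low_dimensional_closed_forms(self):
        assert wt.hypersphere_volume(1.0, 2) == pytest.approx(np.pi)
        assert wt.hypersphere_volume(1.0, 3) == pytest.approx(4 * np.pi / 3)
        assert wt.hypersphere_volume(2.0, 1) == pytest.approx(4.0)

    def test_matches_monte_carlo_rejection_estimate(self):
        """V_10(1.5) against uniform-cube rejection sampling."""
        r, d, n = 1.5, 10, 1_000_000
        rng = np.random.default_rng(31)
        pts = rng.uniform(-r, r, size=(n, d))
        inside = np.count_nonzero((pts**2).sum(axis=1) <= r * r)
        p_hat = inside / n
        mc = p_hat * (2 * r) ** d
        se = np.sqrt(p_hat * (1 - p_hat) / n) * (2 * r) ** d
        assert abs(wt.hypersphere_volume(r, d) - mc) < 3 * se

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(InvalidArgumentError):
            wt.hypersphere_volume(0.0, 3)


class TestMinDensity:
    @pytest.mark.parametrize("radius", [0.5, 1.0, 5.1])
    def test_ten_dim_minpts4_closed_form(self, radius):
        # V_10(R) = pi^5 R^10 / 120, so 4 points per ball is 480/(pi^5 R^10)
        expected = 480.0 / (np.pi**5 * radius**10)
        assert wt.min_density(4, radius, 10) == pytest.approx(
            expected, rel=1e-12
        )

    def test_single_point_unit_circle(self):
        assert wt.min_density(1, 1.0, 2) == pytest.approx(1 / np.pi)

    def test_linear_in_minpts(self):
        assert wt.min_density(8, 0.7, 6) == pytest.approx(
            2 * wt.min_density(4, 0.7, 6)
        )


class TestDBSCAN:
    def test_two_triplets(self):
        level = wt.dbscan(SIX_POINTS, eps=1.5, minpts=2)
        assert level.n_clusters == 2
        assert list(level.assignment) == [0, 0, 0, 1, 1, 1]

    def test_all_noise_when_eps_too_small(self):
        level = wt.dbscan(SIX_POINTS, eps=0.5, minpts=2)
        assert level.n_clusters == 0
        assert np.all(level.assignment == NOISE)

    def test_one_cluster_when_eps_huge(self):
        level = wt.dbscan(SIX_POINTS, eps=100.0, minpts=2)
        assert level.n_clusters == 1
        assert np.all(level.assignment == 0)

    def test_empty_input(self):
        level = wt.dbscan(np.empty((0, 3)), eps=1.0, minpts=2)
        assert level.n_clusters == 0 and level.assignment.size == 0

    def test_core_points_have_enough_neighbors(self, two_well_samples):
        eps, minpts = 1.0, 4
        level = wt.dbscan(two_well_samples.points, eps, minpts)
        pts = two_well_samples.points
        for i in np.flatnonzero(level.assignment != NOISE):
            nb = np.count_nonzero(
                np.linalg.norm(pts - pts[i], axis=1) <= eps
            )
            cluster = level.assignment[i]
            # every clustered point is core or touches a core neighbor
            if nb >= minpts:
                continue
            core_nb = [
                j
                for j in range(len(pts))
                if np.linalg.norm(pts[j] - pts[i]) <= eps
                and np.count_nonzero(
                    np.linalg.norm(pts - pts[j], axis=1) <= eps
                ) >= minpts
            ]
            assert core_nb and level.assignment[min(core_nb)] == cluster

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_brute_force_oracle(self, trial):
        """Memberships identical to the distance-matrix reference."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(5, 300))
        dim = int(rng.integers(1, 11))
        pts = rng.normal(size=(n, dim)) * rng.uniform(0.5, 3.0)
        eps = float(rng.uniform(0.05, 2.0))
        minpts = int(rng.integers(1, 8))
        fast = wt.dbscan(pts, eps, minpts)
        brute = brute_force_dbscan(pts, eps, minpts)
        assert fast.n_clusters == brute.n_clusters
        assert np.array_equal(fast.assignment, brute.assignment)

    @pytest.mark.parametrize("trial", range(10))
    def test_core_partition_matches_sklearn(self, trial):
        """Independent cross-check against sklearn's DBSCAN on core points."""
        from sklearn.cluster import DBSCAN as SkDBSCAN

        rng = np.random.default_rng(2000 + trial)
        pts = rng.normal(size=(int(rng.integers(20, 200)), 3))
        eps = float(rng.uniform(0.3, 1.5))
        minpts = int(rng.integers(2, 6))
        ours = wt.dbscan(pts, eps, minpts)
        sk = SkDBSCAN(eps=eps, min_samples=minpts).fit(pts)
        core = np.zeros(len(pts), dtype=bool)
        core[sk.core_sample_indices_] = True
        assert same_partition(ours.assignment[core], sk.labels_[core])
        # noise sets agree exactly (border handling may differ by design)
        assert np.array_equal(ours.assignment == NOISE, sk.labels_ == -1)

    @given(
        data=st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False),
            min_size=1,
            max_size=40,
        ),
        eps=st.floats(min_value=0.01, max_value=10.0, allow_nan=False),
        minpts=st.integers(min_value=1, max_value=5),
    )
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_oracle_equivalence_property(self, data, eps, minpts):
        pts = np.array(data).reshape(-1, 1)
        fast = wt.dbscan(pts, eps, minpts)
        brute = brute_force_dbscan(pts, eps, minpts)
        assert np.array_equal(fast.assignment, brute.assignment)


class TestEpsilonMonotonicity:
    @pytest.mark.parametrize("trial", range(8))
    def test_clusters_nest_as_eps_grows(self, trial):
        rng = np.random.default_rng(300 + trial)
        pts = np.concatenate(
            [rng.normal(size=(80, 2)), rng.normal(size=(80, 2)) + 8.0]
        )
        small = wt.dbscan(pts, 0.6, 4)
        large = wt.dbscan(pts, 0.9, 4)
        for cid in range(small.n_clusters):
            members = np.flatnonzero(small.assignment == cid)
            parents = set(large.assignment[members])
            assert NOISE not in parents
            assert len(parents) == 1


class TestBuildTree:
    def test_six_point_two_branch_tree(self):
        schedule = wt.EpsilonSchedule(eps_init=0.5, delta_eps=0.5, minpts=2)
        tree = wt.build_tree(SIX_POINTS, schedule)
        assert tree.complete
        leaves = tree.leaves()
        assert len(leaves) == 2
        member_sets = {frozenset(l.members) for l in leaves}
        assert member_sets == {frozenset({0, 1, 2}), frozenset({3, 4, 5})}
        root = tree.node(tree.root_id)
        assert root.members == frozenset(range(6))

    def test_single_well_tree_is_a_path(self):
        rng = np.random.default_rng(41)
        pts = rng.normal(size=(200, 2))
        tree = wt.build_tree(
            pts, wt.EpsilonSchedule(eps_init=0.5, delta_eps=0.25, minpts=4)
        )
        assert tree.complete
        for node in tree.nodes.values():
            assert len(node.children) <= 1

    def test_identical_points_root_at_level_zero(self):
        pts = np.zeros((4, 3))
        tree = wt.build_tree(
            pts, wt.EpsilonSchedule(eps_init=0.5, delta_eps=0.1, minpts=4)
        )
        assert tree.complete and tree.levels_run == 1
        assert tree.node(tree.root_id).members == frozenset(range(4))

    def test_too_few_frames(self):
        with pytest.raises(InsufficientDataError):
            wt.build_tree(
                np.zeros((3, 2)),
                wt.EpsilonSchedule(eps_init=1.0, delta_eps=0.1, minpts=4),
            )

    def test_incomplete_sweep_is_flagged_forest(self):
        pts = np.array([[0.0], [0.1], [0.2], [100.0], [100.1], [100.2]])
        tree = wt.build_tree(
            pts,
            wt.EpsilonSchedule(
                eps_init=0.15, delta_eps=0.05, minpts=2, max_levels=3
            ),
        )
        assert not tree.complete
        assert tree.root_id is None
        assert len(tree.top_ids) == 2

    def test_determinism(self, two_well_samples, fixture_schedule):
        a = wt.build_tree(two_well_samples.points, fixture_schedule)
        b = wt.build_tree(two_well_samples.points, fixture_schedule)
        assert {n.id: n.members for n in a.nodes.values()} == {
            n.id: n.members for n in b.nodes.values()
        }

    def test_collapsed_nodes_record_eps_interval(self, two_well_tree):
        spans = [
            n.eps_last - n.eps_first for n in two_well_tree.nodes.values()
        ]
        assert max(spans) > 0  # at least one run of identical clusters


class TestWellRecoveryAcrossModules:
    @pytest.mark.parametrize("n_wells", [2, 3, 4])
    def test_one_deep_branch_per_well_and_merge_order(
        self, n_wells, fixture_schedule
    ):
        spec = wt.line_spec(n_wells, seed=n_wells)
        samples = wt.sample_gaussian_wells(spec, 250 * n_wells,
                                           seed=50 + n_wells)
        tree = wt.build_tree(samples.points, fixture_schedule)
        recovery = well_recovery(tree, samples.well_assignment, spec)
        assert recovery.one_branch_per_well
        assert recovery.min_purity >= 0.95
        assert recovery.merge_order_matches
        assert list(recovery.merge_eps) == sorted(recovery.merge_eps)

    def test_fringe_fragments_are_not_deep_branches(self, two_well_tree):
        deep = maximal_depth_branches(two_well_tree)
        assert len(deep) == 2
        assert len(deep) <= len(two_well_tree.leaves())


class TestValidateTree:
    def test_fixture_tree_nests_exactly(self, two_well_tree):
        report = wt.validate_tree(two_well_tree)
        assert report.single_root
        assert report.containment_fraction == 1.0
        assert report.exact_nesting

    def test_overlapping_siblings_rejected(self, fixture_schedule):
        nodes = {
            0: TreeNode(0, 1.0, 1.0, frozenset({0, 1})),
            1: TreeNode(1, 1.0, 1.0, frozenset({1, 2})),
            2: TreeNode(2, 2.0, 2.0, frozenset({0, 1, 2})),
        }
        nodes[0].parent = 2
        nodes[1].parent = 2
        nodes[2].children = [0, 1]
        bad = wt.ConformationTree(
            nodes=nodes, root_id=2, complete=True, n_frames=3,
            schedule=fixture_schedule, levels_run=2, top_ids=(2,),
        )
        with pytest.raises(TreeValidationError, match="siblings"):
            wt.validate_tree(bad)
        report = wt.validate_tree(bad, strict=False)
        assert not report.exact_nesting

    def test_non_nested_child_reported_with_node_id(self, fixture_schedule):
        nodes = {
            0: TreeNode(0, 1.0, 1.0, frozenset({0, 5})),
            1: TreeNode(1, 2.0, 2.0, frozenset({0, 1, 2})),
        }
        nodes[0].parent = 1
        nodes[1].children = [0]
        bad = wt.ConformationTree(
            nodes=nodes, root_id=1, complete=False, n_frames=6,
            schedule=fixture_schedule, levels_run=2, top_ids=(1,),
        )
        with pytest.raises(TreeValidationError, match="node 0"):
            wt.validate_tree(bad)

    def test_single_node_tree_valid(self, fixture_schedule):
        tree = wt.ConformationTree(
            nodes={0: TreeNode(0, 1.0, 1.0, frozenset({0, 1, 2, 3}))},
            root_id=0, complete=True, n_frames=4,
            schedule=fixture_schedule, levels_run=1, top_ids=(0,),
        )
        report = wt.validate_tree(tree)
        assert report.single_root and report.containment_fraction == 1.0


class TestExport:
    def test_newick_parses_with_dendropy(self, two_well_tree):
        import dendropy

        nwk = wt.to_newick(two_well_tree)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        expected = {f"n{l.id}" for l in two_well_tree.leaves()}
        assert taxa == expected

    def test_newick_branch_lengths_are_eps_spans(self, two_well_tree):
        import dendropy

        parsed = dendropy.Tree.get(
            data=wt.to_newick(two_well_tree), schema="newick"
        )
        total = sum(
            e.length for e in parsed.preorder_edge_iter() if e.length
        )
        by_hand = sum(
            two_well_tree.node(n.parent).eps_first - n.eps_first
            for n in two_well_tree.nodes.values()
            if n.parent is not None
        )
        assert total == pytest.approx(by_hand)

    def test_incomplete_forest_has_no_newick(self):
        pts = np.array([[0.0], [0.1], [9.0], [9.1]])
        tree = wt.build_tree(
            pts,
            wt.EpsilonSchedule(
                eps_init=0.2, delta_eps=0.1, minpts=2, max_levels=2
            ),
        )
        assert not tree.complete
        with pytest.raises(InvalidArgumentError):
            wt.to_newick(tree)

    def test_node_table_round_trip(self, two_well_tree, tmp_path):
        path = tmp_path / "nodes.tsv"
        wt.write_node_table(two_well_tree, path)
        back = wt.read_node_table(path)
        assert back.complete
        assert back.root_id == two_well_tree.root_id
        assert {n.id: n.members for n in back.nodes.values()} == {
            n.id: n.members for n in two_well_tree.nodes.values()
        }

    def test_dot_contains_all_edges(self, two_well_tree):
        dot = wt.to_dot(two_well_tree)
        n_edges = sum(
            len(n.children) for n in two_well_tree.nodes.values()
        )
        assert dot.count("->") == n_edges

    def test_unknown_node_lookup(self, two_well_tree):
        with pytest.raises(NodeNotFoundError):
            two_well_tree.node(10_000)
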