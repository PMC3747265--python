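import numpy as np
import pytest

from conftest import random_tree
from primereval.compare import (PairedDistances, binned_profile,
                                compare_trees, inverse_density_weights,
                                mds_embed, normalize_max1, pair_distances,
                                pearson, slope_through_origin,
                                sliding_window_placement,
                                wrmsd_superimpose, _prune_leaf,
                                _place_taxon, _edge_node_distance)
from primereval.io import SequenceLibrary, SequenceRecord
from primereval.phylo import DistanceMatrix, patristic_matrix
from primereval.simulate import SimulationConfig, simulate_library


def pd_of(pairs):
    xs, ys = zip(*pairs)
    return PairedDistances(np.array(xs, float), np.array(ys, float))


class TestNormalize:
    def test_simple_division(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 2, 4], [2, 0, 2], [4, 2, 0.0]]))
        out = normalize_max1(dm)
        assert out.max() == 1.0
        assert out[("a", "b")] == 0.5

    def test_idempotent(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]]))
        out = normalize_max1(normalize_max1(dm))
        np.testing.assert_allclose(out.data, dm.data)

    def test_all_zero_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            normalize_max1(dm)

    def test_normalization_preserves_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = 6
            a = rng.random((n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0)
            b = rng.random((n, n))
            b = (b + b.T) / 2
            np.fill_diagonal(b, 0)
            ids = [f"s{i}" for i in range(n)]
            d1, d2 = DistanceMatrix(ids, a), DistanceMatrix(ids, b)
            r_raw = pearson(pair_distances(d1, d2))
            r_norm = pearson(pair_distances(normalize_max1(d1),
                                            normalize_max1(d2)))
            assert r_raw == pytest.approx(r_norm, abs=1e-12)


class TestPairDistances:
    def test_identical_matrices_on_diagonal(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]]))
        paired = pair_distances(dm, dm)
        np.testing.assert_allclose(paired.x, paired.y)

    def test_tuple_count(self):
        ids = list("abcd")
        data = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(ids, data)
        assert len(pair_distances(dm, dm)) == 6  # n(n-1)/2

    def test_disjoint_ids_rejected(self):
        d1 = DistanceMatrix(["a", "b", "c"], np.ones((3, 3)) - np.eye(3))
        d2 = DistanceMatrix(["x", "y", "z"], np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValueError):
            pair_distances(d1, d2)


class TestPearsonSlope:
    def test_perfect_line(self):
        assert pearson(pd_of([(0, 0), (1, 1), (2, 2)])) == \
            pytest.approx(1.0)

    def test_two_point_anticorrelation(self):
        assert pearson(pd_of([(0, 1), (1, 0)])) == pytest.approx(-1.0)

    def test_zero_variance_is_nan(self):
        assert np.isnan(pearson(pd_of([(1, 1), (1, 2)])))

    def test_two_pass_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.random(1000)
        y = 0.3 * x + rng.random(1000)
        got = pearson(PairedDistances(x, y))
        # independent two-pass formula
        sx = np.sqrt(np.sum((x - x.mean()) ** 2))
        sy = np.sqrt(np.sum((y - y.mean()) ** 2))
        expected = np.sum((x - x.mean()) * (y - y.mean())) / (sx * sy)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_slope_exact_proportionality(self):
        assert slope_through_origin(pd_of([(1, 2), (2, 4), (3, 6)])) == \
            pytest.approx(2.0)

    def test_slope_least_squares(self):
        assert slope_through_origin(pd_of([(1, 1), (2, 1)])) == \
            pytest.approx(0.6)  # (1+2)/(1+4)

    def test_slope_identity(self):
        pairs = [(x, x) for x in (0.1, 0.5, 0.9)]
        assert slope_through_origin(pd_of(pairs)) == pytest.approx(1.0)

    def test_slope_all_zero_x(self):
        with pytest.raises(ValueError):
            slope_through_origin(pd_of([(0, 1), (0, 2)]))


class TestBinnedProfile:
    def test_single_bin_mean_std(self):
        prof = binned_profile(pd_of([(0.005, 0.1), (0.007, 0.3)]))
        assert len(prof) == 1
        assert prof.iloc[0]["mean"] == pytest.approx(0.2)
        assert prof.iloc[0]["std"] == pytest.approx(0.1414, abs=5e-5)

    def test_identity_line_zero_spread(self):
        xs = np.linspace(0, 1, 50)
        prof = binned_profile(PairedDistances(xs, xs))
        stds = prof["std"].dropna()
        assert np.allclose(stds, 0.0, atol=1e-12)

    def test_count_weighted_means_reproduce_global_mean(self):
        rng = np.random.default_rng(3)
        x = rng.random(500)
        y = rng.random(500)
        prof = binned_profile(PairedDistances(x, y))
        weighted = (prof["mean"] * prof["count"]).sum() / prof["count"].sum()
        assert weighted == pytest.approx(y.mean(), abs=1e-9)

    def test_flag_beyond_08(self):
        prof = binned_profile(pd_of([(0.95, 0.1), (0.2, 0.3)]))
        assert prof[prof.bin_start > 0.8].flagged.all()
        assert not prof[prof.bin_start < 0.8].flagged.any()

    def test_bad_width(self):
        with pytest.raises(ValueError):
            binned_profile(pd_of([(0.1, 0.1)]), width=0)

    def test_x_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            binned_profile(pd_of([(1.5, 0.1)]))


class TestMDS:
    def test_right_triangle_345(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        pts = mds_embed(dm, dims=2)
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(sorted(pdist(pts)), [3, 4, 5],
                                   atol=1e-9)

    def test_two_points_one_dim(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]]))
        pts = mds_embed(dm, dims=1)
        assert sorted(pts.ravel()) == pytest.approx([-0.5, 0.5])

    def test_deterministic(self):
        tree = random_tree(12, seed=8)
        dm = patristic_matrix(tree)
        np.testing.assert_array_equal(mds_embed(dm), mds_embed(dm))

    def test_dims_bound(self):
        dm = DistanceMatrix(["a", "b"], np.array([[0, 1], [1, 0.0]]))
        with pytest.raises(ValueError):
            mds_embed(dm, dims=2)


class TestWRMSD:
    def test_identical_configurations(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        assert wrmsd_superimpose(pts, pts) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance(self):
        pts = np.random.default_rng(1).normal(size=(7, 2))
        rot = np.array([[0, -1], [1, 0.0]])  # 90 degrees
        assert wrmsd_superimpose(pts, pts @ rot.T) == \
            pytest.approx(0.0, abs=1e-9)

    def test_reflection_and_translation_invariance(self):
        pts = np.random.default_rng(2).normal(size=(5, 2))
        mirrored = pts * np.array([-1, 1]) + np.array([10.0, -3.0])
        assert wrmsd_superimpose(pts, mirrored) == \
            pytest.approx(0.0, abs=1e-9)

    def test_one_dim_residual(self):
        x = np.array([[0.0], [1.0]])
        y = np.array([[0.0], [2.0]])
        assert wrmsd_superimpose(x, y) == pytest.approx(0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        assert wrmsd_superimpose(a, b) == \
            pytest.approx(wrmsd_superimpose(b, a), abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            wrmsd_superimpose(np.zeros((3, 2)), np.zeros((4, 2)))

    def test_bad_weights(self):
        pts = np.zeros((3, 2))
        with pytest.raises(ValueError):
            wrmsd_superimpose(pts, pts, weights=np.zeros(3))

    def test_inverse_density_weights_shape(self):
        pts = np.random.default_rng(4).normal(size=(10, 3))
        w = inverse_density_weights(pts)
        assert w.shape == (10,)
        assert w.mean() == pytest.approx(1.0)
        assert np.all(w > 0)


class TestCompareTrees:
    def test_self_comparison_fixed_point(self):
        tree = random_tree(15, seed=5)
        rep = compare_trees(tree, tree)
        assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert rep.slope_through_origin == pytest.approx(1.0, abs=1e-12)
        assert rep.wrmsd <= 1e-8
        assert rep.rf == 0 and rep.wrf1 == 0 and rep.wrf2 == 0

    def test_rf_parity_on_binary_trees(self):
        # symmetric difference of equally-sized split sets has even size
        for seed in range(10):
            t1 = random_tree(10, seed=seed)
            t2 = random_tree(10, seed=seed + 200)
            rep = compare_trees(t1, t2)
            assert rep.rf % 2 == 0

    def test_composition_consistency(self):
        t1, t2 = random_tree(10, seed=1), random_tree(10, seed=77)
        rep = compare_trees(t1, t2)
        pm1 = normalize_max1(patristic_matrix(t1))
        pm2 = normalize_max1(patristic_matrix(t2))
        manual = pearson(pair_distances(pm1, pm2))
        assert rep.pearson_r == pytest.approx(manual, abs=1e-12)
        assert rep.wrf2 >= rep.wrf1 - 1e-12

    def test_too_few_shared_leaves(self):
        with pytest.raises(ValueError):
            compare_trees(random_tree(3, seed=0), random_tree(3, seed=1))


class TestSlidingWindow:
    def test_full_window_additive_zero(self):
        # with window distances taken from the tree itself, every taxon
        # returns to its original edge
        tree = random_tree(10, seed=6)
        pm = patristic_matrix(tree)
        for taxon in tree.leaf_names():
            pruned, orig = _prune_leaf(tree, taxon)
            wd = {i: pm[(taxon, i)] for i in tree.leaf_names() if i != taxon}
            assert _edge_node_distance(orig, _place_taxon(wd, pruned)) == 0

    def test_full_alignment_window_low_displacement(self):
        cfg = SimulationConfig(n_taxa=10, seed=2, mean_branch_length=0.03)
        tree, lib = simulate_library(cfg)
        prof = sliding_window_placement(lib, tree,
                                        window=lib.alignment_length)
        mean_rows = prof[prof.taxon == "<mean>"]
        assert len(mean_rows) == 1
        assert mean_rows.node_distance.iloc[0] <= 1.0

    def test_constructed_displacement(self):
        # make one taxon's window identical to a distant taxon's: it must
        # be pulled away from its original edge
        cfg = SimulationConfig(n_taxa=10, seed=4, mean_branch_length=0.05)
        tree, lib = simulate_library(cfg)
        pm = patristic_matrix(tree)
        a = lib.ids[0]
        far = max(lib.ids[1:], key=lambda j: pm[(a, j)])
        window = (0, 400)
        recs = []
        for rec in lib:
            seq = rec.aligned_seq
            if rec.id == a:
                seq = (lib[far].aligned_seq[window[0]:window[1]]
                       + seq[window[1]:])
            recs.append(SequenceRecord(rec.id, seq, rec.taxonomy))
        doctored = SequenceLibrary(recs)
        prof = sliding_window_placement(doctored, tree, window=400,
                                        step=10_000)
        row = prof[(prof.taxon == a) & (prof.window_start == 0)]
        assert row.node_distance.iloc[0] > 0

    def test_node_distances_nonnegative(self):
        cfg = SimulationConfig(n_taxa=8, seed=9)
        tree, lib = simulate_library(cfg)
        prof = sliding_window_placement(lib, tree, window=500, step=500)
        assert (prof.node_distance >= 0).all()

    def test_too_few_taxa(self):
        lib = SequenceLibrary([SequenceRecord(f"s{i}", "ACGT")
                               for i in range(3)])
        tree = random_tree(3, seed=0)
        with pytest.raises(ValueError):
            sliding_window_placement(lib, tree)
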