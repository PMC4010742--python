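import itertools

import numpy as np
import pytest
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree

from microtrace import morpho, trace
from microtrace.imgio import Volume
from microtrace.trace import (GeodesicGraph, PatchDictionary, SeedSet, candidate_positions,
                              classify_seeds, dice_and_trace, extract_patches,
                              geodesic_distance, grow_mst, learn_dictionary, omp_code)
from tests.conftest import planted_sparse_model


class TestPatches:
    def test_constant_volume_columns_flagged_degenerate(self):
        v = Volume(np.full((6, 12, 12), 500, np.uint16))
        Y, deg = extract_patches(v, [(3, 6, 6), (2, 4, 4)], (3, 5, 5),
                                 return_degenerate=True)
        assert np.all(Y == 0) and np.all(deg)

    def test_standardized_columns_zero_mean_unit_norm(self):
        rng = np.random.default_rng(0)
        v = Volume(rng.integers(0, 4000, (8, 16, 16)).astype(np.uint16))
        Y = extract_patches(v, [(4, 8, 8), (2, 3, 3)], (3, 5, 5))
        assert np.allclose(Y.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(np.linalg.norm(Y, axis=0), 1, atol=1e-12)

    def test_tube_patch_energy_exceeds_background(self, arbor_phantom):
        spec, channels, truth = arbor_phantom
        v = channels[1]
        sp = np.array(spec.spacing)
        node = np.round(truth.arbors[0].positions_um[5] / sp).astype(int)
        bg = np.array([2, 2, 2])
        half = np.array((3, 7, 7)) // 2

        def raw_energy(p):
            sl = tuple(slice(c - h, c + h + 1) for c, h in zip(p, half))
            return float(np.sum(v.data[sl].astype(float) ** 2))

        assert raw_energy(node) > raw_energy(bg)

    def test_patch_larger_than_volume_rejected(self):
        v = Volume(np.zeros((2, 4, 4), np.uint16))
        with pytest.raises(ValueError, match="larger"):
            extract_patches(v, [(1, 2, 2)], (3, 7, 7))


class TestOmp:
    def test_identity_basis_single_atom(self):
        D = np.eye(8)
        g = omp_code(3 * D[:, [5]], D, 1)
        assert g[5, 0] == pytest.approx(3.0)
        assert np.count_nonzero(g) == 1

    def test_exact_two_atom_recovery_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(1)
        # low-coherence dictionary (mutual coherence < 0.5)
        while True:
            D = rng.standard_normal((24, 8))
            D /= np.linalg.norm(D, axis=0)
            coh = np.abs(D.T @ D - np.eye(8)).max()
            if coh < 0.5:
                break
        y = 2.0 * D[:, 1] - 1.5 * D[:, 6]
        g = omp_code(y[:, None], D, 2)[:, 0]
        assert set(np.flatnonzero(g)) == {1, 6}
        # exhaustive oracle over all 2-subsets
        best, arg = np.inf, None
        for pair in itertools.combinations(range(8), 2):
            coef, *_ = np.linalg.lstsq(D[:, pair], y, rcond=None)
            r = np.sum((y - D[:, pair] @ coef) ** 2)
            if r < best:
                best, arg = r, pair
        assert set(arg) == {1, 6}

    def test_matches_reference_omp_on_random_signals(self):
        from sklearn.linear_model import OrthogonalMatchingPursuit
        rng = np.random.default_rng(3)
        D = rng.standard_normal((40, 15))
        D /= np.linalg.norm(D, axis=0)
        Y = rng.standard_normal((40, 12))
        G = omp_code(Y, D, 4)
        ref = OrthogonalMatchingPursuit(n_nonzero_coefs=4, fit_intercept=False)
        for i in range(Y.shape[1]):
            ref.fit(D, Y[:, i])
            assert np.allclose(G[:, i], ref.coef_, atol=1e-8)

    def test_zero_sparsity_gives_zero_codes(self):
        D = np.eye(5)
        assert np.all(omp_code(np.ones((5, 3)), D, 0) == 0)

    def test_sparsity_above_atom_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            omp_code(np.ones((5, 1)), np.eye(5), 6)


class TestLearnDictionary:
    def test_planted_model_objective_collapses(self):
        Y, H, _, _ = planted_sparse_model(200)
        pdic = learn_dictionary(Y, H, n_atoms=8, T=2, beta=0.0, iterations=10, seed=0)
        assert pdic.objective_history[-1] <= 0.01 * np.sum(Y ** 2)

    def test_objective_monotone_non_increasing(self):
        Y, H, _, _ = planted_sparse_model(201, n=64, n_atoms=16, N=300)
        pdic = learn_dictionary(Y, H, n_atoms=16, T=2, beta=1.5, iterations=8, seed=1)
        assert np.all(np.diff(pdic.objective_history) <= 1e-8)

    def test_beta_zero_reduces_to_pure_reconstruction(self):
        Y, H, _, _ = planted_sparse_model(202, n=40, n_atoms=10, N=200)
        pdic = learn_dictionary(Y, H, n_atoms=10, T=2, beta=0.0, iterations=5, seed=2)
        # coding in the returned D alone reproduces the stored training codes
        G = omp_code(Y, pdic.D, 2)
        assert np.allclose(G, pdic.Gamma)

    def test_unit_norm_atoms_and_sparsity_cap(self):
        Y, H, _, _ = planted_sparse_model(203, n=40, n_atoms=10, N=200)
        pdic = learn_dictionary(Y, H, n_atoms=10, T=3, beta=1.0, iterations=5, seed=3)
        assert np.allclose(np.linalg.norm(pdic.D, axis=0), 1, atol=1e-9)
        assert np.all((pdic.Gamma != 0).sum(axis=0) <= 3)

    def test_missing_class_rejected(self):
        Y = np.random.default_rng(0).standard_normal((10, 50))
        H = np.zeros((2, 50))
        H[0] = 1
        with pytest.raises(ValueError, match="class"):
            learn_dictionary(Y, H, n_atoms=5, T=2)


class TestClassifySeeds:
    def test_constructed_classifier_marks_class1_codes_as_seeds(self):
        rng = np.random.default_rng(2)
        D = rng.standard_normal((27, 6))
        D /= np.linalg.norm(D, axis=0)
        L = np.zeros((2, 6))
        L[0, :3] = 1.0   # atoms 0-2 vote seed, others background
        pdic = PatchDictionary(D=D, L=L, Gamma=np.zeros((6, 0)),
                               patch_shape=(3, 3, 3), T=2, beta=1.0)
        v = Volume(np.zeros((5, 7, 7), np.uint16))
        v.data[2, 3, 3] = 900   # any non-constant patch codes onto some atom
        ss = classify_seeds(v, pdic, [(2, 3, 3)])
        G = omp_code(extract_patches(v, [(2, 3, 3)], (3, 3, 3)), D, 2)
        expected = (L @ G)[0, 0] > (L @ G)[1, 0]
        assert bool(ss.is_seed[0]) == bool(expected)

    def test_empty_candidate_list(self):
        pdic = PatchDictionary(D=np.eye(27), L=np.zeros((2, 27)),
                               Gamma=np.zeros((27, 0)), patch_shape=(3, 3, 3),
                               T=2, beta=1.0)
        ss = classify_seeds(Volume(np.zeros((5, 7, 7), np.uint16)), pdic, [])
        assert len(ss.positions) == 0 and len(ss.seed_positions) == 0

    def test_phantom_centerline_f1_at_least_0p9(self, noisy_microglia_phantom):
        spec, channels, truth = noisy_microglia_phantom(11)
        v = channels[1]
        sp = np.array(spec.spacing)
        cl = np.vstack([a.positions_um / sp for a in truth.arbors])
        tree = cKDTree(cl)
        cand_tr = candidate_positions(v, percentile=70)
        d_tr, _ = tree.query(cand_tr)
        rng = np.random.default_rng(0)
        pos = cand_tr[d_tr <= 1.5]
        neg = cand_tr[d_tr > 3.0]
        n_each = min(len(pos), len(neg), 250)
        pos = pos[rng.choice(len(pos), n_each, replace=False)]
        neg = neg[rng.choice(len(neg), n_each, replace=False)]
        H = np.zeros((2, 2 * n_each))
        H[0, :n_each] = 1
        H[1, n_each:] = 1
        Y = extract_patches(v, np.vstack([pos, neg]), (3, 7, 7))
        pdic = learn_dictionary(Y, H, n_atoms=48, T=5, beta=1.0, iterations=10, seed=0)

        spec2, channels2, truth2 = noisy_microglia_phantom(12)
        v2 = channels2[1]
        cl2 = np.vstack([a.positions_um / sp for a in truth2.arbors])
        cand = candidate_positions(v2, percentile=70)
        ss = classify_seeds(v2, pdic, cand)
        d, _ = cKDTree(cl2).query(cand)
        is_true = d <= 2.0
        pred = ss.is_seed
        tp = np.sum(pred & is_true)
        prec = tp / max(np.sum(pred), 1)
        rec = tp / max(np.sum(is_true), 1)
        f1 = 2 * prec * rec / max(prec + rec, 1e-9)
        assert f1 >= 0.9


class TestGeodesic:
    def test_uniform_volume_straight_chain_cost(self):
        v = Volume(np.full((5, 9, 9), 100, np.uint16), spacing=(1, 1, 1), depth=14)
        c, path = geodesic_distance(v, (2, 0, 0), (2, 8, 8))
        w = 1 / (1 + 1.0)   # I == I_ref
        assert c == pytest.approx(8 * np.sqrt(2) * w)
        assert len(path) == 9

    def test_same_voxel_zero_cost(self):
        v = Volume(np.full((3, 5, 5), 10, np.uint16))
        c, path = geodesic_distance(v, (1, 2, 2), (1, 2, 2))
        assert c == 0 and path == [(1, 2, 2)]

    def test_path_follows_bright_l_shaped_tube(self):
        img = np.full((3, 21, 21), 10, np.uint16)
        img[1, 2, 2:19] = 3000    # horizontal limb
        img[1, 2:19, 18] = 3000   # vertical limb
        v = Volume(img, spacing=(1, 1, 1), depth=14)
        c, path = geodesic_distance(v, (1, 18, 18), (1, 2, 2))
        on_tube = sum(img[p] == 3000 for p in path)
        assert on_tube / len(path) > 0.9
        # tube route beats the straight diagonal: w_bright << w_dark
        g = GeodesicGraph(v)
        w_dark = 1 / (1 + (10 / g.i_ref) ** 2)
        w_bright = 1 / (1 + (3000 / g.i_ref) ** 2)
        straight = 16 * np.sqrt(2) * w_dark
        tube = 32 * w_bright
        assert tube < straight
        assert c == pytest.approx(tube, rel=0.2)

    def test_max_cost_gives_infinite_signal(self):
        v = Volume(np.full((3, 5, 5), 10, np.uint16))
        c, path = geodesic_distance(v, (0, 0, 0), (2, 4, 4), max_cost=0.1)
        assert np.isinf(c) and path == []


class TestGrowMst:
    def test_straight_tube_seeds_chain_in_arc_length_order(self):
        img = np.zeros((5, 9, 41), np.uint16)
        img[2, 4, :] = 2000
        v = Volume(img, spacing=(1, 1, 1), depth=14)
        seeds = np.array([[2, 4, 10], [2, 4, 20], [2, 4, 30], [2, 4, 40]])
        traces, info = grow_mst(np.array([[2, 4, 0]]), seeds, v)
        t = traces[0]
        counts = np.bincount(t.parents[t.parents >= 0], minlength=t.n_nodes)
        assert counts.max() == 1   # pure path, no branching
        # exhaustive MST oracle on the seed geodesic-distance matrix
        g = GeodesicGraph(v)
        pts = np.vstack([[2, 4, 0], seeds])
        M = np.zeros((5, 5))
        for i in range(5):
            d, _ = g.distances([g.lin(pts[i])])
            M[i] = [d[g.lin(p)] for p in pts]
        assert sum(info["tree_costs"]) == pytest.approx(minimum_spanning_tree(M).sum())

    def test_zero_seeds_gives_k_single_node_trees(self):
        v = Volume(np.full((4, 8, 8), 50, np.uint16))
        traces, info = grow_mst(np.array([[1, 2, 2], [2, 5, 5], [3, 3, 6]]),
                                np.zeros((0, 3), int), v)
        assert len(traces) == 3
        assert all(t.n_nodes == 1 for t in traces)

    def test_tree_cost_equals_bruteforce_mst_on_random_instance(self):
        rng = np.random.default_rng(4)
        img = (rng.random((12, 20, 20)) * 3000).astype(np.uint16)
        v = Volume(img, spacing=(1, 1, 1), depth=14)
        pts = np.unique(rng.integers([0, 0, 0], v.shape, size=(12, 3)), axis=0)
        traces, info = grow_mst(pts[:1], pts[1:], v)
        g = GeodesicGraph(v)
        n = len(pts)
        M = np.zeros((n, n))
        for i in range(n):
            d, _ = g.distances([g.lin(pts[i])])
            M[i] = [d[g.lin(p)] for p in pts]
        assert sum(info["tree_costs"]) == pytest.approx(minimum_spanning_tree(M).sum())

    def test_y_tube_branch_point_recovered(self):
        img = np.zeros((5, 40, 40), np.uint16)
        img[2, 20, 2:20] = 2000                      # trunk
        for k in range(16):
            img[2, 20 - k, min(19 + k, 39)] = 2000   # upper limb
            img[2, min(20 + k, 39), min(19 + k, 39)] = 2000   # lower limb
        v = Volume(img, spacing=(1, 1, 1), depth=14)
        seeds = np.array([[2, 8, 31], [2, 32, 31], [2, 12, 27], [2, 28, 27]])
        traces, _ = grow_mst(np.array([[2, 20, 2]]), seeds, v)
        t = traces[0]
        counts = np.bincount(t.parents[t.parents >= 0], minlength=t.n_nodes)
        branch_nodes = np.flatnonzero(counts >= 2)
        assert len(branch_nodes) >= 1
        bp = t.positions_um[branch_nodes]
        true_bif = np.array([2, 20, 19])
        assert np.min(np.linalg.norm(bp - true_bif, axis=1)) <= 3.0

    def test_k_conservation_with_unreachable_seeds(self):
        v = Volume(np.full((4, 10, 10), 50, np.uint16))
        far = np.array([[3, 9, 9]])
        traces, info = grow_mst(np.array([[0, 0, 0], [0, 5, 5]]), far, v,
                                max_link_cost=0.05)
        assert len(traces) == 2
        assert len(info["unassigned"]) == 1


class TestDiceAndTrace:
    def test_single_microglia_large_dice_reduces_to_grow_mst(self, arbor_phantom):
        spec, channels, truth = arbor_phantom
        v = channels[1]
        sp = np.array(spec.spacing)
        root = np.round(truth.centroids_vox[0]).astype(int)
        nodes = truth.arbors[0].positions_um / sp
        seeds = np.round(nodes[::5]).astype(int)
        direct, _ = grow_mst(root[None], seeds, v, max_link_cost=12.0)
        diced, _ = dice_and_trace(v, root[None], seeds, max_arbor_um=200,
                                  margin_um=10, max_link_cost=12.0)
        assert np.array_equal(direct[0].positions_um, diced[0].positions_um)
        assert np.array_equal(direct[0].parents, diced[0].parents)

    def test_two_distant_microglia_give_disjoint_trees(self):
        img = np.zeros((5, 20, 60), np.uint16)
        img[2, 10, 2:22] = 2000
        img[2, 10, 38:58] = 2000
        v = Volume(img, spacing=(1, 1, 1), depth=14)
        roots = np.array([[2, 10, 2], [2, 10, 57]])
        seeds = np.array([[2, 10, 10], [2, 10, 21], [2, 10, 38], [2, 10, 50]])
        traces, info = dice_and_trace(v, roots, seeds, max_arbor_um=22,
                                      margin_um=4, max_link_cost=15.0)
        assert len(traces) == 2
        xs0 = traces[0].positions_um[:, 2]
        xs1 = traces[1].positions_um[:, 2]
        assert xs0.max() < 30 and xs1.min() > 30
        assert info["n_attached"] == [2, 2]

    def test_seed_conservation_between_adjacent_microglia(self):
        img = np.zeros((5, 20, 40), np.uint16)
        img[2, 10, :] = 2000
        v = Volume(img, spacing=(1, 1, 1), depth=14)
        roots = np.array([[2, 10, 5], [2, 10, 34]])
        seeds = np.array([[2, 10, 12], [2, 10, 19], [2, 10, 20], [2, 10, 27]])
        traces, info = dice_and_trace(v, roots, seeds, max_arbor_um=25,
                                      margin_um=5, max_link_cost=20.0)
        assert sum(info["n_attached"]) == len(seeds)   # each seed exactly once

    def test_dice_order_independent(self):
        img = np.zeros((5, 20, 40), np.uint16)
        img[2, 10, :] = 2000
        v = Volume(img, spacing=(1, 1, 1), depth=14)
        roots = np.array([[2, 10, 5], [2, 10, 34]])
        seeds = np.array([[2, 10, 12], [2, 10, 20], [2, 10, 27]])
        kw = dict(max_arbor_um=25, margin_um=5, max_link_cost=20.0)
        t1, _ = dice_and_trace(v, roots, seeds, **kw)
        t2, _ = dice_and_trace(v, roots, seeds, dice_order=[1, 0], **kw)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.positions_um, b.positions_um)
            assert np.array_equal(a.parents, b.parents)

    def test_dice_smaller_than_patch_rejected(self):
        v = Volume(np.zeros((5, 20, 20), np.uint16))
        with pytest.raises(ValueError, match="dice"):
            dice_and_trace(v, np.array([[2, 10, 10]]), np.zeros((0, 3), int),
                           max_arbor_um=1.0, margin_um=0.5)


class TestTopologyRecovery:
    def test_single_arbor_cable_length_and_branch_nodes(self, arbor_phantom):
        spec, channels, truth = arbor_phantom
        v = channels[1]
        sp = np.array(spec.spacing)
        arb = truth.arbors[0]
        nodes_vox = arb.positions_um / sp
        children = arb.children()
        nch = np.array([len(c) for c in children])
        tips = np.flatnonzero(nch == 0)
        branches = np.flatnonzero(nch >= 2)
        sel = sorted(set(range(0, arb.n_nodes, 5)) | set(tips.tolist())
                     | set(branches.tolist()))
        seeds = np.round(nodes_vox[sel]).astype(int)
        root = np.round(nodes_vox[0]).astype(int)
        traces, info = grow_mst(root[None], seeds, v)
        assert len(traces) == 1
        rec = traces[0]
        cable = morpho.arbor_features(rec).cable_length_um
        cable_true = morpho.arbor_features(arb).cable_length_um
        assert abs(cable - cable_true) / cable_true <= 0.10
        rec_nodes = rec.positions_um / sp
        d, _ = cKDTree(rec_nodes).query(nodes_vox[branches])
        assert np.mean(d <= 3.0) >= 0.9
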