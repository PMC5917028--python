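"""Cluster trees, weighted PCA and the iterative reclassification."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import pipshape as ps
from pipshape.errors import ContractError, ParameterError

from conftest import random_feature_vectors


def dist_df(points, ids=None):
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    ids = ids or [f"s{i}" for i in range(len(pts))]
    return pd.DataFrame(d, index=ids, columns=ids)


def brute_force_average_linkage(d):
    """O(n^3) agglomeration oracle: merge the closest pair, recompute
    average-linkage distances from scratch over the original matrix."""
    d = np.asarray(d, dtype=float)
    n = len(d)
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                avg = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if avg < best[0]:
                    best = (avg, (i, j))
        h, (i, j) = best
        heights.append(h)
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [clusters[i] + clusters[j]]
        )
    return sorted(heights)


class TestClusterTree:
    def test_three_points_on_a_line(self):
        tree = ps.cluster_tree(dist_df([0.0, 1.0, 10.0]))
        cut = tree.cut(2)
        assert cut["s0"] == cut["s1"] != cut["s2"]
        assert tree.root.height == pytest.approx(9.5)  # average linkage

    def test_two_tight_clusters_recovered(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([
            rng.normal(0, 0.05, (8, 2)),
            rng.normal(5, 0.05, (7, 2)),
        ])
        truth = [0] * 8 + [1] * 7
        cut = ps.cluster_tree(dist_df(pts)).cut(2)
        labels = [cut[f"s{i}"] for i in range(15)]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_average_linkage_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(0, 1, (12, 3))
        df = dist_df(pts)
        tree = ps.cluster_tree(df, linkage="average")
        heights = sorted(tree.linkage_matrix[:, 2])
        oracle = brute_force_average_linkage(df.to_numpy())
        assert np.abs(np.array(heights) - np.array(oracle)).max() < 1e-10

    def test_newick_export_parses(self):
        import dendropy

        tree = ps.cluster_tree(dist_df([0.0, 1.0, 3.0, 10.0]))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert len(parsed.leaf_nodes()) == 4

    def test_asymmetric_matrix_rejected(self):
        df = dist_df([0.0, 1.0, 2.0])
        df.iloc[0, 1] = 5.0
        with pytest.raises(ContractError):
            ps.cluster_tree(df)


class TestPCA:
    def test_two_seeds_single_component_distance(self):
        rng = np.random.default_rng(1)
        feats = random_feature_vectors(2, rng)
        omega = ps.default_weight_schedule()[0]
        pca = ps.pca_embed(feats, omega)
        gap = abs(pca.scores.iloc[0, 0] - pca.scores.iloc[1, 0])
        assert gap == pytest.approx(
            ps.weighted_distance(feats[0], feats[1], omega), rel=1e-9
        )

    def test_uniform_weights_match_eigendecomposition(self):
        rng = np.random.default_rng(2)
        feats = random_feature_vectors(20, rng)
        omega = np.full(42, 1.0 / 42)
        pca = ps.pca_embed(feats, omega, n_components=5)
        x = np.vstack([f.v for f in feats]) / np.sqrt(42)
        xc = x - x.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(xc.T @ xc / (len(feats) - 1)))[::-1]
        assert pca.explained_variance == pytest.approx(evals[:5], rel=1e-8)

    def test_duplication_stability(self):
        """Appending a seed at the centroid leaves the scatter matrix (and
        hence the component directions) untouched; duplicating a generic
        seed of an anisotropic cloud perturbs directions only mildly."""
        rng = np.random.default_rng(3)
        base = random_feature_vectors(20, rng)
        # anisotropic structure with clear spectral gaps
        direction = rng.normal(0, 1, 42)
        for i, f in enumerate(base):
            f.v[:] = np.abs(f.v + (i - 10) * 0.2 * direction)
            f.v[0::7] = np.abs(f.v[0::7]) + 2.0
        omega = np.full(42, 1.0 / 42)
        pca1 = ps.pca_embed(base, omega, n_components=2)
        centroid = ps.FeatureVector(
            v=np.mean([f.v for f in base], axis=0), seed_id="centroid"
        )
        pca2 = ps.pca_embed(base + [centroid], omega, n_components=2)
        for c1, c2 in zip(pca1.components, pca2.components):
            assert min(np.abs(c1 - c2).max(), np.abs(c1 + c2).max()) < 1e-8
        dup = ps.FeatureVector(v=base[0].v.copy(), seed_id="dup")
        pca3 = ps.pca_embed(base + [dup], omega, n_components=1)
        c1, c3 = pca1.components[0], pca3.components[0]
        assert min(np.abs(c1 - c3).max(), np.abs(c1 + c3).max()) < 0.05

    def test_full_rank_scores_reproduce_weighted_distances(self):
        rng = np.random.default_rng(4)
        feats = random_feature_vectors(10, rng)
        for omega in ps.default_weight_schedule().iterations:
            pca = ps.pca_embed(feats, omega)  # full rank
            s = pca.scores.to_numpy()
            d_scores = np.linalg.norm(s[:, None] - s[None, :], axis=-1)
            d_eq1 = ps.distance_matrix(feats, omega).to_numpy()
            mask = d_eq1 > 0
            assert np.abs(d_scores[mask] / d_eq1[mask] - 1.0).max() < 1e-9

    def test_component_range_validated(self):
        rng = np.random.default_rng(5)
        feats = random_feature_vectors(5, rng)
        with pytest.raises(ParameterError):
            ps.pca_embed(feats, np.full(42, 1 / 42), n_components=10)


def three_size_varieties(rng, n_per=8, spread=0.01):
    """Varieties that differ in overall size only."""
    feats = []
    for g, base in enumerate([1.0, 1.6, 2.4]):
        for i in range(n_per):
            v = np.full(42, 0.05)
            v[0::7] = base + rng.normal(0, spread)
            feats.append(
                ps.FeatureVector(v=v, seed_id=f"g{g}_{i}", label=f"G{g}")
            )
    return feats


class TestIterativeClassify:
    def test_size_only_signal_resolved_in_first_iteration(self):
        rng = np.random.default_rng(11)
        feats = three_size_varieties(rng)
        schedule = ps.default_weight_schedule()
        result = ps.iterative_classify(feats, schedule, k1=3)
        truth = [f.label for f in feats]
        pred1 = [result.iteration_labels[0][f.seed_id] for f in feats]
        predf = [result.final_labels[f.seed_id] for f in feats]
        assert adjusted_rand_score(truth, pred1) == 1.0
        assert adjusted_rand_score(truth, predf) == 1.0

    def test_single_iteration_reduces_to_cut_tree(self):
        rng = np.random.default_rng(12)
        feats = random_feature_vectors(12, rng)
        omega = ps.default_weight_schedule()[0]
        schedule = ps.WeightSchedule(iterations=[omega])
        result = ps.iterative_classify(feats, schedule, k1=3)
        cut = ps.cluster_tree(ps.distance_matrix(feats, omega)).cut(3)
        grouping = [cut[f.seed_id] for f in feats]
        labels = [result.final_labels[f.seed_id] for f in feats]
        assert adjusted_rand_score(grouping, labels) == 1.0

    def test_input_order_does_not_change_final_grouping(self):
        rng = np.random.default_rng(13)
        feats = three_size_varieties(rng, n_per=6)
        schedule = ps.default_weight_schedule()
        r1 = ps.iterative_classify(feats, schedule, k1=3)
        perm = list(np.random.default_rng(99).permutation(len(feats)))
        r2 = ps.iterative_classify([feats[i] for i in perm], schedule, k1=3)
        ids = [f.seed_id for f in feats]
        g1 = [r1.final_labels[i] for i in ids]
        g2 = [r2.final_labels[i] for i in ids]
        assert adjusted_rand_score(g1, g2) == 1.0

    def test_degenerate_k1_is_rejected_not_crashing(self):
        rng = np.random.default_rng(14)
        feats = random_feature_vectors(6, rng)
        schedule = ps.default_weight_schedule()
        with pytest.raises(ParameterError):
            ps.iterative_classify(feats, schedule, k1=6)
        result = ps.iterative_classify(feats, schedule, k1=5)
        assert len(set(result.iteration_labels[0].values())) == 5

    def test_seven_variety_benchmark_majority_pure_branches(self):
        """Study-sized seven-variety assemblage: at least 90% of seeds end
        in final branches dominated (>50%) by a single variety."""
        assemblage = ps.generate_assemblage(
            ps.default_archetypes(),
            [13, 12, 13, 10, 10, 11, 14],
            rng_seed=1001,
            grid=100,
        )
        feats = [ps.extract_features(m)[0] for m in assemblage.meshes]
        result = ps.iterative_classify(feats, ps.default_weight_schedule(), k1=3)
        truth = {f.seed_id: f.label for f in feats}
        branches = {}
        for f in feats:
            branches.setdefault(result.final_labels[f.seed_id], []).append(
                truth[f.seed_id]
            )
        pure_seeds = sum(
            len(mem)
            for mem in branches.values()
            if max(mem.count(l) for l in set(mem)) / len(mem) > 0.5
        )
        assert pure_seeds / len(feats) >= 0.90
        # later iterations must refine, never coarsen, the grouping
        assert len(set(result.final_labels.values())) >= 3

    def test_final_tree_keeps_all_leaves_and_monotone_heights(self):
        rng = np.random.default_rng(15)
        feats = three_size_varieties(rng, n_per=6)
        result = ps.iterative_classify(feats, ps.default_weight_schedule(), k1=3)
        leaves = result.final_tree.root.leaves()
        assert sorted(leaves) == sorted(f.seed_id for f in feats)
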