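"""Isomap embedding, weighted SVM, LOOCV grid search, ROC, group stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mprad.classify import (
    FeatureTable,
    IsoSVMConfig,
    _geodesic_matrix,
    fit_weighted_svm,
    group_stats,
    isomap_embed,
    loocv_grid_search,
    roc_analysis,
)


def _table(x, y):
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] != len(y):
        x = x.T
    df = pd.DataFrame(x, columns=[f"f{i}" for i in range(x.shape[1])])
    return FeatureTable(tuple(f"s{i}" for i in range(len(y))),
                        np.asarray(y), df)


class TestIsomapEmbed:
    def test_line_ordering_preserved(self, rng):
        # points on a straight line in 5-D: the 1-D embedding must
        # reproduce the arc-length ordering (|rank correlation| = 1)
        t = np.sort(rng.random(30))
        v = rng.standard_normal(5)
        x = t[:, None] * v[None, :]
        emb = isomap_embed(x, k=5, d_embed=1, standardize=False)
        rho = sps.spearmanr(emb[:, 0], t).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_duplicated_point_identical_coordinates(self, rng):
        x = rng.standard_normal((20, 3))
        x[7] = x[3]
        emb = isomap_embed(x, k=4, d_embed=2)
        assert np.allclose(emb[7], emb[3], atol=1e-8)

    def test_geodesics_match_independent_dijkstra(self, rng):
        # 1-D curve rolled through 5-D; independent oracle = networkx
        # Dijkstra on the identical symmetrized k-NN graph
        import networkx as nx
        from sklearn.neighbors import kneighbors_graph

        t = np.sort(rng.random(40)) * 3 * np.pi
        x = np.stack([np.cos(t), np.sin(t), t / 3, 0.1 * t, 0.05 * t**2],
                     axis=1)
        geo = _geodesic_matrix(x, k=6)
        g_sparse = kneighbors_graph(x, n_neighbors=6, mode="distance")
        g_sparse = g_sparse.maximum(g_sparse.T)
        g = nx.from_scipy_sparse_array(g_sparse)
        ref = dict(nx.all_pairs_dijkstra_path_length(g))
        for i in range(40):
            for j in range(40):
                assert geo[i, j] == pytest.approx(ref[i].get(j, np.inf))

    def test_disconnected_graph_repaired(self, rng):
        # two tight, far-apart clusters with tiny k: graph is
        # disconnected until the shortest inter-cluster edge is added
        a = rng.standard_normal((10, 2)) * 0.1
        b = rng.standard_normal((10, 2)) * 0.1 + 100
        x = np.vstack([a, b])
        geo = _geodesic_matrix(x, k=2)
        assert np.isfinite(geo).all()

    def test_too_few_subjects_raises(self, rng):
        with pytest.raises(ValueError, match="more subjects than neighbors"):
            isomap_embed(rng.standard_normal((5, 2)), k=5)


class TestWeightedSvm:
    def test_separable_training_accuracy(self, rng):
        x = np.concatenate([rng.standard_normal(20) - 5,
                            rng.standard_normal(20) + 5])[:, None]
        y = np.array([0] * 20 + [1] * 20)
        for ratio in (1.0, 4.0):
            clf = fit_weighted_svm(x, y, ratio)
            assert (clf.predict(x) == y).all()

    def test_symmetric_data_boundary_at_midpoint(self, rng):
        half = rng.standard_normal(50)
        x = np.concatenate([half - 1, half + 1])[:, None]
        y = np.array([0] * 50 + [1] * 50)
        clf = fit_weighted_svm(x, y, ratio=1.0)
        # midpoint of the symmetric construction is 0
        boundary = -clf.intercept_[0] / clf.coef_[0, 0]
        assert abs(boundary) < 0.15

    def test_benign_sensitivity_nondecreasing_in_ratio(self, rng):
        # raising the benign misclassification cost can only improve the
        # benign-class training recall on imbalanced overlapping data
        x = np.concatenate([rng.standard_normal(15) - 0.5,
                            rng.standard_normal(60) + 0.5])[:, None]
        y = np.array([0] * 15 + [1] * 60)
        recalls = []
        for ratio in (1.0, 2.0, 4.0):
            clf = fit_weighted_svm(x, y, ratio)
            pred = clf.predict(x)
            recalls.append((pred[y == 0] == 0).mean())
        assert recalls == sorted(recalls)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_weighted_svm(np.zeros((5, 1)), np.zeros(5, dtype=int), 1.0)


class TestLoocvGridSearch:
    def test_separable_table_auc_one_smallest_ratio(self, rng):
        x = np.concatenate([rng.random(10), rng.random(10) + 10])
        y = np.array([0] * 10 + [1] * 10)
        res = loocv_grid_search(_table(x, y), IsoSVMConfig(k=5))
        assert res["auc"] == 1.0
        assert res["best_ratio"] == 1.0  # tie-break toward parsimony
        assert all(a == 1.0 for a in res["auc_per_ratio"].values())

    def test_shuffled_labels_near_chance(self, rng):
        # labels independent of features: each shuffled replicate must sit
        # inside a generous null band (the grid search reports the best of
        # seven correlated AUCs, which biases single draws upward), and
        # the replicate mean must stay close to 0.5
        x = rng.standard_normal(60)
        aucs = []
        for _ in range(5):
            y = rng.permutation([0] * 30 + [1] * 30)
            res = loocv_grid_search(_table(x, y), IsoSVMConfig(k=10))
            aucs.append(res["auc"])
            assert 0.25 <= res["auc"] <= 0.75
        assert 0.4 <= np.mean(aucs) <= 0.65

    def test_strict_per_fold_embedding_close_to_transductive(self, rng):
        x = np.concatenate([rng.standard_normal(20),
                            rng.standard_normal(20) + 2.0])
        y = np.array([0] * 20 + [1] * 20)
        trans = loocv_grid_search(_table(x, y), IsoSVMConfig(k=8))
        strict = loocv_grid_search(
            _table(x, y), IsoSVMConfig(k=8, embed_per_fold=True)
        )
        assert abs(trans["auc"] - strict["auc"]) <= 0.1

    def test_degenerate_labels_raise(self, rng):
        x = rng.random(12)
        with pytest.raises(ValueError, match="both classes"):
            loocv_grid_search(_table(x, np.zeros(12, dtype=int)))


class TestRocAnalysis:
    def test_perfect_scores(self):
        res = roc_analysis(np.array([0.1, 0.2, 0.8, 0.9]),
                           np.array([0, 0, 1, 1]))
        assert res["auc"] == 1.0
        assert res["sensitivity"] == 1.0 and res["specificity"] == 1.0

    def test_ordered_toy_pairs(self):
        assert roc_analysis(np.array([1, 2, 3, 4]),
                            np.array([0, 0, 1, 1]))["auc"] == 1.0
        # scores {1,3,2,4}: 3 of 4 positive/negative pairs correctly ordered
        assert roc_analysis(np.array([1, 3, 2, 4]),
                            np.array([0, 0, 1, 1]))["auc"] == 0.75

    def test_constant_scores_chance_by_midrank(self):
        res = roc_analysis(np.ones(10), np.array([0, 1] * 5))
        assert res["auc"] == 0.5

    def test_auc_equals_bruteforce_pair_counting(self, rng):
        scores = rng.standard_normal(50)
        scores[25:30] = scores[:5]  # inject ties
        y = rng.integers(0, 2, size=50)
        y[:2], y[-2:] = 0, 1
        res = roc_analysis(scores, y)
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert res["auc"] == pytest.approx(wins / (len(pos) * len(neg)))

    def test_delong_ci_brackets_auc_and_shrinks(self, rng):
        def ci_width(n):
            s = np.concatenate([rng.standard_normal(n),
                                rng.standard_normal(n) + 1])
            y = np.array([0] * n + [1] * n)
            r = roc_analysis(s, y)
            assert r["auc_ci95"][0] <= r["auc"] <= r["auc_ci95"][1]
            return r["auc_ci95"][1] - r["auc_ci95"][0]

        assert ci_width(200) < ci_width(20)

    def test_youden_point_maximizes_j(self, rng):
        scores = rng.standard_normal(40)
        y = rng.integers(0, 2, size=40)
        y[0], y[1] = 0, 1
        res = roc_analysis(scores, y)
        j_best = res["sensitivity"] + res["specificity"] - 1
        for t in np.unique(scores):
            sens = (scores[y == 1] >= t).mean()
            spec = (scores[y == 0] < t).mean()
            assert sens + spec - 1 <= j_best + 1e-12


class TestGroupStats:
    def test_identical_distributions(self, rng):
        vals = rng.standard_normal(30)
        x = np.concatenate([vals, vals])
        y = np.array([0] * 30 + [1] * 30)
        res = group_stats(_table(x, y), "f0")
        assert res["p_value"] == pytest.approx(1.0)
        assert res["auc"] == pytest.approx(0.5)

    def test_huge_shift_detected(self, rng):
        x = np.concatenate([rng.standard_normal(20),
                            rng.standard_normal(20) + 10])
        y = np.array([0] * 20 + [1] * 20)
        res = group_stats(_table(x, y), "f0")
        assert res["p_value"] < 1e-10
        assert res["auc"] == 1.0
        assert res["logit_p"] < 0.05 or res["logit_coef"] == np.inf

    def test_welch_matches_textbook_formula(self, rng):
        g0 = rng.standard_normal(50)
        g1 = rng.standard_normal(50) + 1
        x = np.concatenate([g0, g1])
        y = np.array([0] * 50 + [1] * 50)
        res = group_stats(_table(x, y), "f0")
        # hand-computed Welch statistic and Satterthwaite df
        v0, v1 = g0.var(ddof=1) / 50, g1.var(ddof=1) / 50
        t = (g1.mean() - g0.mean()) / np.sqrt(v0 + v1)
        df = (v0 + v1) ** 2 / (v0**2 / 49 + v1**2 / 49)
        p = 2 * sps.t.sf(abs(t), df)
        assert res["t_statistic"] == pytest.approx(t)
        assert res["p_value"] == pytest.approx(p)

    def test_zero_variance_feature_flagged(self):
        x = np.ones(20)
        y = np.array([0] * 10 + [1] * 10)
        res = group_stats(_table(x, y), "f0")
        assert res["t_test_defined"] is False
        assert res["auc"] == 0.5  # still computed

    def test_sem_uses_sample_sd(self, rng):
        g0 = rng.standard_normal(25)
        g1 = rng.standard_normal(25) + 1
        x, y = np.concatenate([g0, g1]), np.array([0] * 25 + [1] * 25)
        res = group_stats(_table(x, y), "f0")
        assert res["sem_benign"] == pytest.approx(g0.std(ddof=1) / 5)


def test_feature_table_roundtrip_and_validation():
    df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
    t = FeatureTable(("s0", "s1"), np.array([0, 1]), df)
    frame = t.to_frame()
    t2 = FeatureTable.from_frame(frame)
    assert t2.feature_names == ["a", "b"]
    assert np.array_equal(t2.labels, t.labels)
    with pytest.raises(ValueError, match="missing"):
        FeatureTable(("s0",), np.array([1]),
                     pd.DataFrame({"a": [np.nan]}))
    with pytest.raises(ValueError, match="labels"):
        FeatureTable(("s0",), np.array([2]), pd.DataFrame({"a": [1.0]}))
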