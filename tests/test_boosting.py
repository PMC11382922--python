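"""Binning, gradients, histograms, split search and the centralized ensemble."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pufedboost.boosting import (
    BoostConfig,
    BoostedModel,
    BoostedTreesClassifier,
    GradientPair,
    Histogram,
    Tree,
    TreeNode,
    assign_leaf_weights,
    build_histogram,
    compute_gradients,
    find_best_split,
    fit_boosting,
    quantile_bin,
)
from pufedboost.data import ParameterError


class TestQuantileBin:
    def test_constant_feature_single_bin(self):
        edges, codes = quantile_bin(np.full(10, 3.5), n_bins=8)
        assert edges[0].size == 0
        assert np.all(codes == 0)

    def test_quantile_edges_1_to_100(self):
        values = np.arange(1, 101, dtype=float)
        edges, _ = quantile_bin(values, n_bins=4)
        expected = np.quantile(values, [0.25, 0.5, 0.75])  # sorted interpolation
        assert np.allclose(edges[0], expected)

    def test_saturated_binning_is_lossless(self):
        rng = np.random.default_rng(0)
        values = rng.choice([1.0, 2.5, 7.0, 9.0], size=50)
        _, codes = quantile_bin(values, n_bins=8)
        # one bin per distinct value
        df = pd.DataFrame({"v": values, "c": codes[:, 0]})
        assert df.groupby("v")["c"].nunique().max() == 1
        assert df["c"].nunique() == 4

    def test_code_is_count_of_edges_leq_value(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal(200)
        edges, codes = quantile_bin(values, n_bins=16)
        manual = np.array([(edges[0] <= v).sum() for v in values])
        assert np.array_equal(codes[:, 0], manual)

    def test_too_few_bins_rejected(self):
        with pytest.raises(ParameterError):
            quantile_bin(np.arange(5.0), n_bins=1)


class TestGradients:
    @pytest.mark.parametrize(
        "y,margin,g,h",
        [
            (1, 0.0, -0.5, 0.25),
            (0, 0.0, 0.5, 0.25),
            (1, 2.0, -0.11920, 0.10499),
        ],
    )
    def test_logistic_derivatives(self, y, margin, g, h):
        grads = compute_gradients(np.array([y]), np.array([margin]))
        assert grads.g[0] == pytest.approx(g, abs=1e-5)
        assert grads.h[0] == pytest.approx(h, abs=1e-5)

    def test_extreme_margins_keep_h_positive(self):
        grads = compute_gradients(np.array([1, 0]), np.array([1e9, -1e9]))
        assert np.all(grads.h > 0)
        assert np.all(np.isfinite(grads.g))


class TestHistogram:
    def _random_fixture(self, n=50, d=3, seed=0):
        rng = np.random.default_rng(seed)
        codes = rng.integers(0, 4, size=(n, d)).astype(np.int32)
        grads = GradientPair(g=rng.standard_normal(n), h=rng.random(n) + 0.1)
        return codes, grads

    def test_singleton(self):
        codes = np.array([[3, 0]], dtype=np.int32)
        grads = GradientPair(g=np.array([0.7]), h=np.array([0.2]))
        hist = build_histogram(codes, grads, np.array([0]), [4, 4])
        assert hist.G[0][3] == 0.7 and hist.H[0][3] == 0.2 and hist.count[0][3] == 1
        assert hist.G[0][:3].sum() == 0 and hist.count[1].sum() == 1

    def test_conservation(self):
        codes, grads = self._random_fixture()
        hist = build_histogram(codes, grads, np.arange(50), [4, 4, 4])
        for k in range(3):
            assert hist.count[k].sum() == 50
            assert hist.G[k].sum() == pytest.approx(grads.g.sum())
            assert hist.H[k].sum() == pytest.approx(grads.h.sum())

    def test_matches_brute_force(self):
        codes, grads = self._random_fixture(seed=5)
        node = np.arange(0, 50, 2)
        hist = build_histogram(codes, grads, node, [4, 4, 4])
        for k in range(3):
            for q in range(4):
                members = [i for i in node if codes[i, k] == q]
                assert hist.G[k][q] == pytest.approx(sum(grads.g[i] for i in members))
                assert hist.H[k][q] == pytest.approx(sum(grads.h[i] for i in members))
                assert hist.count[k][q] == len(members)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_additive_over_disjoint_nodes(self, seed):
        codes, grads = self._random_fixture(seed=seed)
        rng = np.random.default_rng(seed + 1)
        mask = rng.random(50) < 0.5
        a = build_histogram(codes, grads, np.flatnonzero(mask), [4, 4, 4])
        b = build_histogram(codes, grads, np.flatnonzero(~mask), [4, 4, 4])
        whole = build_histogram(codes, grads, np.arange(50), [4, 4, 4])
        merged = a + b
        for k in range(3):
            assert np.allclose(merged.G[k], whole.G[k])
            assert np.allclose(merged.H[k], whole.H[k])
            assert np.array_equal(merged.count[k], whole.count[k])

    def test_empty_node_all_zero(self):
        codes, grads = self._random_fixture()
        hist = build_histogram(codes, grads, np.array([], dtype=int), [4, 4, 4])
        assert all(h.sum() == 0 for h in hist.G + hist.H)


def _exhaustive_best_split(hist, parent_g, parent_h, parent_count, config):
    """Independent oracle: enumerate every (feature, boundary) candidate."""
    best = None
    for k in range(len(hist.G)):
        for q in range(len(hist.G[k]) - 1):
            gl = hist.G[k][: q + 1].sum()
            hl = hist.H[k][: q + 1].sum()
            nl = int(hist.count[k][: q + 1].sum())
            nr = parent_count - nl
            if nl < config.min_child_samples or nr < config.min_child_samples:
                continue
            gr, hr = parent_g - gl, parent_h - hl
            lam = config.reg_lambda
            gain = 0.5 * (
                gl**2 / (hl + lam) + gr**2 / (hr + lam)
                - parent_g**2 / (parent_h + lam)
            ) - config.gamma
            if gain > 0 and (best is None or gain > best[2]):
                best = (k, q, gain)
    return best


class TestSplitSearch:
    def test_hand_example(self):
        hist = Histogram(
            G=[np.array([-2.0, 2.0])], H=[np.array([1.0, 1.0])],
            count=[np.array([5, 5])],
        )
        best = find_best_split(hist, 0.0, 2.0, 10, BoostConfig(reg_lambda=1.0))
        assert best.feature == 0 and best.bin == 0
        assert best.gain == pytest.approx(2.0)

    def test_single_bin_no_split(self):
        hist = Histogram(G=[np.array([1.0])], H=[np.array([1.0])], count=[np.array([7])])
        assert find_best_split(hist, 1.0, 1.0, 7, BoostConfig()) is None

    def test_tie_breaks_to_lower_feature(self):
        col = (np.array([-2.0, 2.0]), np.array([1.0, 1.0]), np.array([5, 5]))
        hist = Histogram(G=[col[0], col[0].copy()], H=[col[1], col[1].copy()],
                         count=[col[2], col[2].copy()])
        best = find_best_split(hist, 0.0, 2.0, 10, BoostConfig())
        assert best.feature == 0 and best.bin == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = int(rng.integers(1, 10))
        config = BoostConfig(min_child_samples=int(rng.integers(1, 4)))
        G, H, C = [], [], []
        for _ in range(d):
            nb = int(rng.integers(1, 16))
            G.append(rng.standard_normal(nb))
            H.append(rng.random(nb) + 0.05)
            C.append(rng.integers(1, 20, size=nb))
        hist = Histogram(G=G, H=H, count=C)
        pg = sum(g.sum() for g in G) / d
        ph = sum(h.sum() for h in H) / d
        pc = int(C[0].sum())
        got = find_best_split(hist, pg, ph, pc, config)
        want = _exhaustive_best_split(hist, pg, ph, pc, config)
        if want is None:
            assert got is None
        else:
            assert (got.feature, got.bin) == want[:2]
            assert got.gain == pytest.approx(want[2])


class TestEnsemble:
    def test_empty_ensemble_predicts_half(self):
        X = pd.DataFrame({"a": [0.0, 1.0, -1.0]})
        model = fit_boosting(X, np.array([1, 0, 1]), BoostConfig(n_trees=0))
        assert np.allclose(model.predict_proba(X), 0.5)

    def test_separable_1d(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-1, 1, 80)
        y = (x > 0).astype(int)
        # lossless binning (n_bins ≥ #distinct) so the class boundary is splittable
        model = fit_boosting(x[:, None], y, BoostConfig(n_trees=5, max_depth=1, n_bins=128))
        pred = (model.predict_proba(x[:, None]) >= 0.5).astype(int)
        assert np.array_equal(pred, y)

    def test_leaf_weight_closed_form(self):
        tree = Tree(nodes=[TreeNode(id=0, is_leaf=True, n_samples=2, cover=1.0)])
        grads = GradientPair(g=np.array([-1.5, -0.5]), h=np.array([0.4, 0.6]))
        assign_leaf_weights(tree, np.zeros(2, dtype=np.intp), grads, BoostConfig(reg_lambda=1.0))
        assert tree.nodes[0].weight == pytest.approx(1.0)  # -G/(H+λ) = 2/2

    def test_manual_stump_probabilities(self):
        model = BoostedModel(
            feature_names=["x"], edges=[np.array([0.0])],
            config=BoostConfig(n_trees=1, learning_rate=1.0),
        )
        nodes = [
            TreeNode(id=0, is_leaf=False, n_samples=2, cover=0.5, feature="x",
                     bin=0, threshold=0.0, left=1, right=2),
            TreeNode(id=1, is_leaf=True, n_samples=1, cover=0.25, weight=-1.0),
            TreeNode(id=2, is_leaf=True, n_samples=1, cover=0.25, weight=1.0),
        ]
        model.trees.append(Tree(nodes=nodes))
        p = model.predict_proba(np.array([[-1.0], [1.0]]))
        assert p[0] == pytest.approx(1 / (1 + np.e))
        assert p[1] == pytest.approx(1 / (1 + np.exp(-1)))

    def test_prediction_invariant_to_column_order(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
        y = (X["a"] + X["c"] > 0).astype(int).to_numpy()
        model = fit_boosting(X, y, BoostConfig(n_trees=5))
        shuffled = X[["d", "b", "a", "c"]]
        assert np.array_equal(model.predict_proba(X), model.predict_proba(shuffled))

    def test_heavy_regularization_flattens_predictions(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((50, 3))
        y = (X[:, 0] > 0).astype(int)
        model = fit_boosting(X, y, BoostConfig(n_trees=10, reg_lambda=1e9))
        assert np.allclose(model.predict_proba(X), 0.5, atol=1e-6)

    def test_deterministic_serialization(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 5))
        y = (X[:, 1] > 0).astype(int)
        a = fit_boosting(X, y, BoostConfig(n_trees=6))
        b = fit_boosting(X, y, BoostConfig(n_trees=6))
        assert a.to_json() == b.to_json()

    def test_json_round_trip(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 3))
        y = (X[:, 0] > 0).astype(int)
        model = fit_boosting(X, y, BoostConfig(n_trees=4))
        back = BoostedModel.from_json(model.to_json())
        assert back.to_json() == model.to_json()
        assert np.array_equal(back.predict_proba(X), model.predict_proba(X))

    def test_missing_feature_named_in_error(self):
        X = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]})
        model = fit_boosting(X, np.array([0, 1]), BoostConfig(n_trees=2))
        with pytest.raises(Exception, match="'a'"):
            model.predict_proba(pd.DataFrame({"b": [1.0]}))


class TestEstimatorSurface:
    def test_sklearn_contract(self):
        from sklearn.base import clone

        rng = np.random.default_rng(6)
        X = rng.standard_normal((80, 4))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        clf = BoostedTreesClassifier(n_trees=5)
        cloned = clone(clf)
        cloned.fit(X, y)
        assert cloned.predict(X).shape == (80,)
        proba = cloned.predict_proba(X)
        assert proba.shape == (80, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert cloned.get_params()["n_trees"] == 5

    def test_cross_check_against_xgboost(self):
        """Behavioral oracle: both learners master the same separable task."""
        xgboost = pytest.importorskip("xgboost")
        rng = np.random.default_rng(7)
        n = 400
        X = rng.standard_normal((n, 6))
        y = (X[:, 0] + X[:, 1] + X[:, 2] > 0).astype(int)
        Xt = rng.standard_normal((n, 6))
        yt = (Xt[:, 0] + Xt[:, 1] + Xt[:, 2] > 0).astype(int)
        ours = BoostedTreesClassifier(n_trees=30).fit(X, y)
        theirs = xgboost.XGBClassifier(
            n_estimators=30, max_depth=3, learning_rate=0.3, reg_lambda=1.0,
            tree_method="hist", max_bin=32,
        ).fit(X, y)
        acc_ours = (ours.predict(Xt) == yt).mean()
        acc_theirs = (theirs.predict(Xt) == yt).mean()
        assert acc_ours >= 0.85
        assert abs(acc_ours - acc_theirs) < 0.1
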