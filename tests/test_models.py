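"""Base classifiers: kNN hierarchy, linear net, posterior contracts."""

import numpy as np
import pandas as pd
import pytest

import protpanel as pp
from protpanel.models import (
    ClassPosterior,
    HierarchicalKnnModel,
    Standardizer,
    _kneighbors,
    fit_hierarchical,
    fit_nn,
    load_model,
    save_model,
)
from protpanel.panel import GROUPS


def table_from(X, groups, panel):
    return pd.DataFrame(
        {"sample_id": [f"s{i}" for i in range(len(X))], "group": groups}
        | {c: X[:, j] for j, c in enumerate(panel.columns)}
    )


def identity_scaler(d):
    return Standardizer(mean=np.zeros(d), sd=np.ones(d),
                        kept=np.ones(d, dtype=bool))


class TestKnnCore:
    def test_equidistant_tie_prefers_smallest_index(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 2.0]])
        nn = _kneighbors(X, np.zeros(2), k=1)
        assert nn[0] == 0
        # deterministic on repeat
        assert _kneighbors(X, np.zeros(2), k=1)[0] == 0

    def test_matches_sklearn_without_ties(self):
        from sklearn.neighbors import NearestNeighbors

        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 5))
        q = rng.normal(size=5)
        mine = set(_kneighbors(X, q, k=7))
        ref = set(
            NearestNeighbors(n_neighbors=7).fit(X).kneighbors(q[None])[1][0]
        )
        assert mine == ref


class TestHierarchicalKnn:
    def test_one_nn_memorizes_training_labels(self, panel):
        X = np.array([[0.0] * 7, [10.0] * 7, [20.0] * 7])
        table = table_from(X, list(GROUPS), panel)
        model = fit_hierarchical(table, k=1, panel=panel)
        for x, group in zip(X, GROUPS):
            assert model.predict(x).predicted_class == group

    def test_posterior_product_rule(self, panel):
        """Stage-1 vote 2/5 healthy, stage-2 vote 3/5 localized ->
        posterior (0.4, 0.36, 0.24)."""
        d = 7
        model = HierarchicalKnnModel(
            k1=5, k2=5,
            scaler=identity_scaler(d),
            X1=np.zeros((5, d)),
            healthy1=np.array([True, True, False, False, False]),
            X2=np.zeros((5, d)),
            localized2=np.array([True, True, True, False, False]),
            feature_names=panel.columns,
        )
        post = model.predict(np.zeros(d))
        assert post.probabilities == pytest.approx([0.4, 0.36, 0.24])

    def test_unanimous_stage1(self, panel):
        d = 7
        model = HierarchicalKnnModel(
            k1=5, k2=None, scaler=identity_scaler(d),
            X1=np.zeros((5, d)), healthy1=np.ones(5, dtype=bool),
            X2=None, localized2=None, feature_names=panel.columns,
        )
        assert model.predict(np.zeros(d)).probabilities == pytest.approx(
            [1.0, 0.0, 0.0]
        )

    def test_hierarchical_consistency(self, small_table, panel):
        model = fit_hierarchical(small_table, k=5, panel=panel)
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = model.predict(rng.uniform(0, 1200, size=7)).probabilities
            assert p[1] + p[2] == pytest.approx(1.0 - p[0], abs=1e-12)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_k_equals_labeled_size_gives_class_prior(self, panel):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(9, 7))
        table = table_from(X, [g for g in GROUPS for _ in range(3)], panel)
        model = fit_hierarchical(table, k=9, panel=panel)
        post = model.predict(rng.normal(size=7))
        assert post.probabilities[0] == pytest.approx(3 / 9)

    def test_k_clipped_with_warning(self, panel):
        X = np.random.default_rng(3).normal(size=(4, 7))
        table = table_from(X, ["healthy", "healthy", "localized", "metastatic"],
                           panel)
        with pytest.warns(UserWarning, match="clipped"):
            model = fit_hierarchical(table, k=11, panel=panel)
        assert model.k1 == 3

    def test_even_k_rejected(self, small_table, panel):
        with pytest.raises(ValueError, match="odd"):
            fit_hierarchical(small_table, k=4, panel=panel)

    def test_empty_labeled_set_rejected(self, small_table, panel):
        with pytest.raises(ValueError, match="empty"):
            fit_hierarchical(small_table.iloc[:0], panel=panel)

    def test_zero_variance_feature_dropped_with_warning(self, panel):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(9, 7))
        X[:, 2] = 7.0  # constant feature
        table = table_from(X, [g for g in GROUPS for _ in range(3)], panel)
        with pytest.warns(UserWarning, match="zero-variance"):
            model = fit_hierarchical(table, k=3, panel=panel)
        assert model.scaler.kept.sum() == 6
        model.predict(np.zeros(7))  # still full-dimension input

    def test_dimension_mismatch_rejected(self, small_table, panel):
        model = fit_hierarchical(small_table, k=3, panel=panel)
        with pytest.raises(ValueError, match="features"):
            model.predict(np.zeros(5))

    def test_missing_stage2_splits_uniformly(self, panel):
        X = np.random.default_rng(6).normal(size=(6, 7))
        table = table_from(X, ["healthy"] * 3 + ["localized"] * 3, panel)
        model = fit_hierarchical(table, k=3, panel=panel)
        p = model.predict(X[4]).probabilities
        assert p[1] == pytest.approx(p[2])


class TestTwoLayerNet:
    def test_zero_weights_uniform_posterior(self, panel):
        model = pp.TwoLayerNetModel(
            W1=np.zeros((7, 8)), b1=np.zeros(8),
            W2=np.zeros((8, 3)), b2=np.zeros(3),
            scaler=identity_scaler(7), hyper=pp.NetHyper(),
            feature_names=panel.columns,
        )
        assert model.predict(np.ones(7)).probabilities == pytest.approx(
            [1 / 3] * 3
        )

    def test_posterior_simplex_on_random_inputs(self, small_table, panel):
        model = fit_nn(small_table, rng=np.random.default_rng(0), panel=panel)
        X = np.random.default_rng(1).uniform(0, 1200, size=(1000, 7))
        probs = model.predict_matrix(X)
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_separable_cohort_reaches_perfect_training_accuracy(
        self, zero_noise_table, panel
    ):
        model = fit_nn(zero_noise_table, rng=np.random.default_rng(0),
                       panel=panel)
        X = zero_noise_table[panel.columns].to_numpy(float)
        pred = [GROUPS[i] for i in model.predict_matrix(X).argmax(axis=1)]
        assert (pred == zero_noise_table["group"]).all()

    def test_single_class_degenerate_limit(self, panel):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(5, 7))
        table = table_from(X, ["localized"] * 5, panel)
        model = fit_nn(table, rng=np.random.default_rng(0), panel=panel)
        probs = model.predict_matrix(rng.normal(size=(50, 7)))
        assert np.all(probs[:, 1] >= 1 - 1e-6)

    def test_deterministic_given_seed(self, small_table, panel):
        m1 = fit_nn(small_table, rng=np.random.default_rng(9), panel=panel)
        m2 = fit_nn(small_table, rng=np.random.default_rng(9), panel=panel)
        assert np.array_equal(m1.W1, m2.W1) and np.array_equal(m1.W2, m2.W2)

    def test_linear_activation_collapse(self, small_table, panel):
        """Identity hidden activation: the composed input->logit map is
        affine, so its rank cannot exceed min(input dim, classes)."""
        wide = fit_nn(small_table, hyper=pp.NetHyper(hidden=16),
                      rng=np.random.default_rng(0), panel=panel)
        composed = wide.W1 @ wide.W2
        assert np.linalg.matrix_rank(composed) <= min(7, 3)

    def test_translation_absorbed_by_standardization(self, small_table, panel):
        shift = np.full(7, 123.0)
        translated = small_table.copy()
        translated[panel.columns] = translated[panel.columns] + shift
        m0 = fit_nn(small_table, rng=np.random.default_rng(3), panel=panel)
        m1 = fit_nn(translated, rng=np.random.default_rng(3), panel=panel)
        X = np.random.default_rng(4).uniform(0, 1200, size=(20, 7))
        assert np.allclose(
            m0.predict_matrix(X), m1.predict_matrix(X + shift), atol=1e-10
        )


class TestPosteriorType:
    def test_rejects_invalid_vectors(self):
        with pytest.raises(ValueError):
            ClassPosterior(np.array([0.5, 0.5, 0.5]))

    def test_argmax_tie_breaks_by_class_order(self):
        post = ClassPosterior(np.array([0.4, 0.4, 0.2]))
        assert post.predicted_class == "healthy"


class TestSerialization:
    def test_round_trip_both_models(self, small_table, panel, tmp_path):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1200, size=(10, 7))
        for name, model in [
            ("hknn", fit_hierarchical(small_table, k=5, panel=panel)),
            ("nn", fit_nn(small_table, rng=np.random.default_rng(1),
                          panel=panel)),
        ]:
            path = tmp_path / f"{name}.json"
            save_model(model, path)
            loaded = load_model(path)
            for x in X:
                assert np.allclose(
                    model.predict(x).probabilities,
                    loaded.predict(x).probabilities,
                )
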