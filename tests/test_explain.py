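"""Shapley attributions: axioms, oracle agreement, rankings."""

from itertools import permutations
from math import factorial

import numpy as np
import pytest

import protpanel as pp
from protpanel.explain import (
    ShapExplanation,
    shapley_exact,
    shapley_sampling,
    top_features,
)


def permutation_oracle(f, x, background, p):
    """Average marginal contribution over all p! orderings (value cache
    keyed by coalition); the factorial-enumeration reference."""
    cache = {}

    def v(S):
        key = frozenset(S)
        if key not in cache:
            H = background.copy()
            for i in key:
                H[:, i] = x[i]
            cache[key] = float(np.mean(f(H)))
        return cache[key]

    phi = np.zeros(p)
    for order in permutations(range(p)):
        S = []
        for i in order:
            phi[i] += v(S + [i]) - v(S)
            S.append(i)
    return phi / factorial(p)


class TestExactAxioms:
    def test_additive_model(self):
        f = lambda X: X[:, 0] + X[:, 1]
        ex = shapley_exact(f, np.array([1.0, 1.0]), np.zeros((1, 2)))
        assert ex.phi == pytest.approx([1.0, 1.0])
        assert ex.base_value == pytest.approx(0.0)

    def test_symmetry_on_product_model(self):
        f = lambda X: X[:, 0] * X[:, 1]
        ex = shapley_exact(f, np.array([1.0, 1.0]), np.zeros((1, 2)))
        assert ex.phi == pytest.approx([0.5, 0.5])

    def test_efficiency(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=5)
        f = lambda X: np.tanh(X @ w)
        x = rng.normal(size=5)
        bg = rng.normal(size=(8, 5))
        ex = shapley_exact(f, x, bg)
        assert ex.base_value + ex.phi.sum() == pytest.approx(
            float(f(x[None, :])[0]), abs=1e-9
        )

    def test_dummy_feature_gets_zero(self):
        f = lambda X: X[:, 0] + 3 * X[:, 2]
        x = np.array([1.0, 5.0, 2.0])
        bg = np.array([[0.0, 5.0, 1.0], [2.0, 5.0, 0.0]])  # x1 constant = 5
        ex = shapley_exact(f, x, bg)
        assert ex.phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=4)
        b = rng.normal(size=4)
        f = lambda X: np.sin(X @ a)
        g = lambda X: np.cos(X @ b)
        x = rng.normal(size=4)
        bg = rng.normal(size=(6, 4))
        phi_f = shapley_exact(f, x, bg).phi
        phi_g = shapley_exact(g, x, bg).phi
        phi_sum = shapley_exact(lambda X: f(X) + g(X), x, bg).phi
        assert phi_sum == pytest.approx(phi_f + phi_g, abs=1e-10)

    def test_matches_factorial_oracle_at_panel_scale(self):
        """Exact enumeration equals the 7!-permutation brute force to 1e-9."""
        rng = np.random.default_rng(42)
        w = rng.normal(size=7)
        f = lambda X: np.tanh(X @ w) + 0.1 * (X**2).sum(axis=1)
        x = rng.normal(size=7)
        bg = rng.normal(size=(5, 7))
        ex = shapley_exact(f, x, bg)
        oracle = permutation_oracle(f, x, bg.copy(), 7)
        assert np.abs(ex.phi - oracle).max() < 1e-9

    def test_background_order_and_duplication_invariance(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=4)
        f = lambda X: X @ w
        x = rng.normal(size=4)
        bg = rng.normal(size=(6, 4))
        base = shapley_exact(f, x, bg).phi
        shuffled = shapley_exact(f, x, bg[::-1].copy()).phi
        doubled = shapley_exact(f, x, np.vstack([bg, bg])).phi
        assert base == pytest.approx(shuffled, abs=1e-12)
        assert base == pytest.approx(doubled, abs=1e-12)

    def test_guards(self):
        f = lambda X: X.sum(axis=1)
        with pytest.raises(ValueError, match="sampling"):
            shapley_exact(f, np.zeros(13), np.zeros((1, 13)))
        with pytest.raises(ValueError, match="background"):
            shapley_exact(f, np.zeros(3), np.zeros((0, 3)))


class TestSampling:
    def test_seeded_determinism(self):
        f = lambda X: X.sum(axis=1)
        x = np.ones(4)
        bg = np.zeros((2, 4))
        a = shapley_sampling(f, x, bg, n_samples=1,
                             rng=np.random.default_rng(5))
        b = shapley_sampling(f, x, bg, n_samples=1,
                             rng=np.random.default_rng(5))
        assert a.phi == pytest.approx(b.phi)

    def test_null_player(self):
        f = lambda X: X[:, 0]
        x = np.array([2.0, 7.0])
        bg = np.array([[0.0, 7.0]])
        ex = shapley_sampling(f, x, bg, n_samples=50,
                              rng=np.random.default_rng(0))
        assert ex.phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_converges_to_exact(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=7)
        f = lambda X: np.tanh(X @ w)
        x = rng.normal(size=7)
        bg = rng.normal(size=(4, 7))
        exact = shapley_exact(f, x, bg).phi
        approx = shapley_sampling(f, x, bg, n_samples=20000,
                                  rng=np.random.default_rng(1)).phi
        assert np.abs(approx - exact).max() < 0.02

    def test_error_shrinks_with_sample_size(self):
        """Monte-Carlo error roughly halves per 4x samples (n^-1/2)."""
        rng = np.random.default_rng(4)
        w = rng.normal(size=6)
        f = lambda X: np.tanh(X @ w) + 0.2 * X[:, 0] * X[:, 1]
        x = rng.normal(size=6)
        bg = rng.normal(size=(4, 6))
        exact = shapley_exact(f, x, bg).phi

        def rms_err(n, seed):
            est = shapley_sampling(f, x, bg, n_samples=n,
                                   rng=np.random.default_rng(seed)).phi
            return np.sqrt(np.mean((est - exact) ** 2))

        small = np.mean([rms_err(100, s) for s in range(5)])
        large = np.mean([rms_err(6400, s) for s in range(5)])
        assert large < small / 2  # expected factor 8

    def test_invalid_sample_count(self):
        with pytest.raises(ValueError):
            shapley_sampling(lambda X: X.sum(axis=1), np.zeros(2),
                             np.zeros((1, 2)), n_samples=0)


class TestTopFeatures:
    def _expl(self, phi, cls="healthy"):
        return ShapExplanation(sample_id="s", explained_class=cls,
                               base_value=0.0, phi=np.asarray(phi, float),
                               method="exact", n_evaluations=0)

    def test_single_explanation_ranking(self, panel):
        ex = self._expl([0.3, -0.2, 0.1, 0.0, 0.0, 0.0, 0.0])
        ranking, top3 = top_features([ex], "healthy", panel=panel)
        assert top3 == ["MMP3", "MMP28", "CTSK"]
        assert len(ranking) == 7

    def test_all_zero_ties_break_by_panel_order(self, panel):
        ex = self._expl(np.zeros(7))
        ranking, _ = top_features([ex], "healthy", panel=panel)
        assert ranking == list(panel.proteases)

    def test_empty_input_rejected(self, panel):
        with pytest.raises(ValueError, match="no explanations"):
            top_features([], "healthy", panel=panel)

    def test_top3_consistency_on_default_cohort(self, default_table, panel):
        """Healthy-class attributions share structure across test samples.

        On the shipped synthetic calibration the rank-2..4 healthy effects
        are of comparable size, so per-sample top-3 membership fluctuates;
        the check pins (a) a common top-3 set far above the ~3% chance
        rate and (b) a stable class-level aggregate ranking led by MMP3
        and drawn from the healthy-elevated markers.
        """
        state = pp.split_dataset(default_table, seed=1)
        indexed = default_table.set_index("sample_id", drop=False)
        labeled = indexed.loc[state.labeled_ids]
        model = pp.fit_hierarchical(labeled, k=5, panel=panel)
        background = labeled[panel.columns].to_numpy(float)
        test = indexed.loc[state.test_ids]
        healthy = test[test["group"] == "healthy"].head(15)
        top_sets, explanations = [], []
        for _, row in healthy.iterrows():
            x = row[panel.columns].to_numpy(float)
            fn = pp.class_predict_fn(model, 0)
            ex = shapley_exact(fn, x, background, explained_class="healthy")
            explanations.append(ex)
            _, top3 = top_features([ex], "healthy", panel=panel)
            top_sets.append(frozenset(top3))
        most_common = max(set(top_sets), key=top_sets.count)
        assert top_sets.count(most_common) / len(top_sets) >= 0.4
        _, aggregate_top3 = top_features(explanations, "healthy", panel=panel)
        healthy_elevated = {"MMP3", "MMP28", "CTSK", "MMP24", "ADAM10/12"}
        assert "MMP3" in aggregate_top3
        assert set(aggregate_top3) <= healthy_elevated
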