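"""Shapley axioms, the exact enumerator and the sampling estimator."""

import numpy as np
import pytest

from polyutr import dependence, exact_shapley, mean_abs_ranking, sampled_shapley
from polyutr.attribution import ShapMatrix, threshold_mean_phi


class TestExactShapleyAxioms:
    def test_hand_enumerated_product_model(self):
        # f = x1*x2 at (1,1), single background row (0,0): phi = (0.5, 0.5)
        phi, base = exact_shapley(
            lambda X: X[:, 0] * X[:, 1], np.array([1.0, 1.0]), np.zeros((1, 2))
        )
        assert phi == pytest.approx([0.5, 0.5])
        assert base == 0.0

    def test_additivity_axiom_on_additive_model(self):
        phi, _ = exact_shapley(
            lambda X: X[:, 0] + 2 * X[:, 1], np.array([3.0, 4.0]), np.zeros((1, 2))
        )
        assert phi == pytest.approx([3.0, 8.0])

    def test_symmetry_axiom(self):
        f = lambda X: X[:, 0] * X[:, 1] + X[:, 0] + X[:, 1]
        phi, _ = exact_shapley(f, np.array([2.0, 2.0]), np.zeros((3, 2)))
        assert phi[0] == pytest.approx(phi[1])

    def test_dummy_axiom(self):
        f = lambda X: X[:, 0] ** 2  # feature 1 ignored
        rng = np.random.default_rng(0)
        phi, _ = exact_shapley(f, np.array([1.5, -2.0]), rng.normal(size=(5, 2)))
        assert phi[1] == pytest.approx(0.0, abs=1e-12)

    def test_efficiency_axiom(self):
        rng = np.random.default_rng(1)
        f = lambda X: np.sin(X[:, 0]) + X[:, 1] * X[:, 2]
        x = rng.normal(size=3)
        bg = rng.normal(size=(7, 3))
        phi, base = exact_shapley(f, x, bg)
        assert phi.sum() + base == pytest.approx(float(f(x[None, :])[0]))

    def test_linearity_axiom(self):
        rng = np.random.default_rng(2)
        f = lambda X: X[:, 0] * X[:, 1]
        g = lambda X: np.abs(X[:, 1]) - X[:, 0]
        x = rng.normal(size=2)
        bg = rng.normal(size=(4, 2))
        phi_f, _ = exact_shapley(f, x, bg)
        phi_g, _ = exact_shapley(g, x, bg)
        phi_fg, _ = exact_shapley(lambda X: f(X) + g(X), x, bg)
        assert phi_fg == pytest.approx(phi_f + phi_g)

    def test_too_many_features_directed_to_sampler(self):
        with pytest.raises(ValueError, match="sampled_shapley"):
            exact_shapley(lambda X: X.sum(1), np.zeros(21), np.zeros((1, 21)))


class TestSampledShapley:
    def test_agrees_with_exact_within_three_standard_errors(self):
        rng = np.random.default_rng(3)
        f = lambda X: X[:, 0] * X[:, 1] + np.sin(X[:, 2]) - 0.5 * X[:, 3] ** 2
        misses = 0
        for case in range(40):
            x = rng.normal(size=4)
            bg = rng.normal(size=(5, 4))
            phi_exact, _ = exact_shapley(f, x, bg)
            sm = sampled_shapley(f, x[None, :], bg, n_permutations=200, seed=case)
            within = np.abs(sm.phi[0] - phi_exact) <= 3 * sm.standard_errors[0] + 1e-12
            misses += int(not within.all())
        # ~0.3% exceedance expected per feature at 3 SE; allow a small margin
        assert misses <= 3

    def test_error_shrinks_with_more_permutations(self):
        rng = np.random.default_rng(4)
        f = lambda X: X[:, 0] * X[:, 1] * X[:, 2]
        x = rng.normal(size=3)
        bg = rng.normal(size=(4, 3))
        phi_exact, _ = exact_shapley(f, x, bg)
        errs = [
            np.abs(
                sampled_shapley(f, x[None, :], bg, n_permutations=p, seed=0).phi[0]
                - phi_exact
            ).max()
            for p in (100, 10000)
        ]
        assert errs[1] <= errs[0]

    def test_efficiency_holds_exactly_by_telescoping(self):
        rng = np.random.default_rng(5)
        f = lambda X: np.exp(X[:, 0]) - X[:, 1]
        x = rng.normal(size=2)
        bg = rng.normal(size=(6, 2))
        sm = sampled_shapley(f, x[None, :], bg, n_permutations=20, seed=0)
        assert sm.phi[0].sum() + sm.base_value == pytest.approx(float(f(x[None, :])[0]))

    def test_same_seed_identical_estimates(self):
        f = lambda X: X[:, 0] ** 2 + X[:, 1]
        x = np.array([[1.0, 2.0]])
        bg = np.zeros((3, 2))
        a = sampled_shapley(f, x, bg, n_permutations=50, seed=8).phi
        b = sampled_shapley(f, x, bg, n_permutations=50, seed=8).phi
        assert np.array_equal(a, b)


class TestSummaries:
    def _shap(self, phi, X, names):
        return ShapMatrix(phi=phi, base_value=0.0, X=X, feature_names=names)

    def test_zero_column_ranks_last(self):
        phi = np.array([[1.0, 0.0, -2.0], [0.5, 0.0, 1.0]])
        sm = self._shap(phi, np.zeros((2, 3)), ("a", "b", "c"))
        ranking = mean_abs_ranking(sm)
        assert ranking.iloc[-1]["feature"] == "b"
        assert ranking.iloc[0]["feature"] == "c"

    def test_anticorrelated_phi_gives_negative_rho(self):
        vals = np.arange(10.0)
        sm = self._shap((-vals)[:, None], vals[:, None], ("v",))
        assert dependence(sm, "v").spearman_rho == pytest.approx(-1.0)

    def test_zero_phi_gives_zero_summaries(self):
        sm = self._shap(np.zeros((5, 1)), np.arange(5.0)[:, None], ("v",))
        dep = dependence(sm, "v", window=(1, 3))
        assert dep.spearman_rho == 0.0
        assert dep.mean_phi_in_window == 0.0 and dep.mean_phi_outside == 0.0

    def test_window_contrast_and_threshold_mean(self):
        vals = np.array([5.0, 15.0, 25.0, 40.0])
        phi = np.array([-1.0, 2.0, 2.0, -3.0])
        sm = self._shap(phi[:, None], vals[:, None], ("polya_position",))
        dep = dependence(sm, "polya_position", window=(10, 30))
        assert dep.mean_phi_in_window == pytest.approx(2.0)
        assert dep.mean_phi_outside == pytest.approx(-2.0)
        assert threshold_mean_phi(sm, "polya_position", 20) == pytest.approx(-0.5)
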