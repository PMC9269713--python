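"""LR-PCA: eigendecomposition, projection, Wald logistic selection."""

import numpy as np
import pytest
import statsmodels.api as sm

from mammocad.lrpca import (
    POOLED_TAG,
    CoefficientRecord,
    LRFit,
    PCABasis,
    fit_binomial_lr,
    fit_classwise_pca,
    fit_pca,
    lr_pca_reduce,
    project,
    retained_energy,
    select_significant,
)
from mammocad.simulate import FeatureSimConfig, gen_feature_table

# Published Wald p-values of one benchmark 50-component logistic fit,
# used to check selection soundness against a real coefficient table.
BENCHMARK_P_COLUMN = [
    5.14e-15, 0.0, 4.77e-29, 2.59e-41, 2.96e-38, 0.030837, 1.51e-43,
    0.995623, 1.74e-19, 0.22944, 0.028801, 0.1055, 5.69e-13, 4.61e-17,
    0.431973, 0.065923, 0.931964, 2.78e-9, 0.07108, 4.21e-12, 9.31e-7,
    8.47e-6, 2.40e-31, 9.74e-7, 2.35e-21, 0.476501, 0.519277, 0.008865,
    0.347413, 6.34e-11, 0.151915, 0.602287, 0.023249, 0.503072, 0.869595,
    1.55e-9, 0.132437, 0.012377, 0.559178, 0.003284, 0.002104, 5.67e-11,
    0.000697, 0.802873, 0.002125, 0.125403, 0.1293, 0.01845, 0.072918,
    0.000822,
]


# --------------------------------------------------------------------------
# PCA fitting
# --------------------------------------------------------------------------

class TestFitPca:
    def test_diagonal_covariance_recovers_axes(self):
        # sample covariance is exactly diag(4, 1)
        c = 1 / np.sqrt(3)
        X = np.array([[-2.0, c], [2.0, c], [0.0, -2 * c]])
        basis = fit_pca(X)
        first = basis.components[0]
        np.testing.assert_allclose(first.eigenvalue, 4.0, atol=1e-10)
        np.testing.assert_allclose(first.direction, [1.0, 0.0], atol=1e-10)

    def test_eigenvalue_sum_equals_trace(self, rng):
        X = rng.standard_normal((30, 6))
        basis = fit_pca(X)
        cov = np.cov(X, rowvar=False, ddof=1)
        total = sum(c.eigenvalue for c in basis.components)
        np.testing.assert_allclose(total, np.trace(cov), atol=1e-8)

    @pytest.mark.parametrize("shape", [(20, 8), (50, 10)])
    def test_matches_svd_oracle(self, rng, shape):
        X = rng.standard_normal(shape)
        basis = fit_pca(X)
        Xc = X - X.mean(axis=0)
        _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
        lam_oracle = s**2 / (shape[0] - 1)
        for j in range(min(shape) - 1):
            np.testing.assert_allclose(
                abs(basis.components[j].eigenvalue), lam_oracle[j], atol=1e-8
            )
            dot = abs(np.dot(basis.components[j].direction, Vt[j]))
            np.testing.assert_allclose(dot, 1.0, atol=1e-8)

    def test_sign_convention_largest_entry_positive(self, rng):
        X = rng.standard_normal((40, 5))
        for comp in fit_pca(X).components:
            k = np.argmax(np.abs(comp.direction))
            assert comp.direction[k] > 0

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="2 samples"):
            fit_pca(np.ones((1, 4)))


class TestClasswisePca:
    def test_binary_blocks_concatenate_to_fifty(self, rng):
        X = rng.standard_normal((120, 60))
        y = np.array(["a"] * 60 + ["b"] * 60)
        basis = fit_classwise_pca(X, y, k_per_class=25)
        assert len(basis.components[: basis.K]) == 50
        tags = [c.class_tag for c in basis.components]
        assert tags[:25] == ["a"] * 25 and tags[25:] == ["b"] * 25

    def test_identical_distributions_give_similar_spectra(self, rng):
        X = rng.standard_normal((400, 10)) * np.arange(1, 11)
        y = np.array(["a", "b"] * 200)
        basis = fit_classwise_pca(X, y, k_per_class=1)
        lam_a = basis.components[0].eigenvalue
        lam_b = basis.components[1].eigenvalue
        assert abs(lam_a - lam_b) / max(lam_a, lam_b) < 0.3

    def test_k1_blocks_align_with_class_major_axes(self, rng):
        n = 300
        a = np.column_stack([rng.standard_normal(n) * 5, rng.standard_normal(n)])
        b = np.column_stack([rng.standard_normal(n), rng.standard_normal(n) * 5])
        X = np.vstack([a, b])
        y = np.array(["a"] * n + ["b"] * n)
        basis = fit_classwise_pca(X, y, k_per_class=1)
        assert abs(basis.components[0].direction[0]) > 0.99  # class a: x-axis
        assert abs(basis.components[1].direction[1]) > 0.99  # class b: y-axis

    def test_small_class_error_names_class(self, rng):
        X = rng.standard_normal((5, 3))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError, match="'b'"):
            fit_classwise_pca(X, y, k_per_class=1)


class TestProject:
    def test_training_scores_are_centered(self, rng):
        X = rng.standard_normal((60, 8))
        scores = project(X, fit_pca(X))
        np.testing.assert_allclose(scores.values.mean(axis=0), 0.0, atol=1e-8)

    def test_training_score_covariance_is_eigenvalue_diagonal(self, rng):
        X = rng.standard_normal((80, 6))
        basis = fit_pca(X)
        S = project(X, basis).values
        cov = np.cov(S, rowvar=False, ddof=1)
        lam = np.array([c.eigenvalue for c in basis.components])
        np.testing.assert_allclose(cov, np.diag(lam), atol=1e-6 * lam.max())

    def test_mean_row_maps_to_zero(self, rng):
        X = rng.standard_normal((30, 5))
        basis = fit_pca(X)
        scores = project(X.mean(axis=0, keepdims=True), basis)
        np.testing.assert_allclose(scores.values, 0.0, atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        basis = fit_pca(rng.standard_normal((20, 5)))
        with pytest.raises(ValueError, match="dimensionality"):
            project(rng.standard_normal((4, 7)), basis)


class TestRetainedEnergy:
    def test_full_spectrum_is_unity_and_monotone(self, rng):
        basis = fit_pca(rng.standard_normal((40, 6)))
        fracs = [retained_energy(basis, k) for k in range(1, 7)]
        assert fracs[-1] == pytest.approx(1.0)
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_closed_form_on_diag_3_1(self):
        c = 1 / np.sqrt(3)
        X = np.array([[-np.sqrt(3), c], [np.sqrt(3), c], [0.0, -2 * c]])
        basis = fit_pca(X)  # covariance diag(3, 1)
        assert retained_energy(basis, 1) == pytest.approx(0.75, abs=1e-10)

    def test_per_class_mode_reports_per_tag(self, rng):
        X = rng.standard_normal((100, 6))
        y = np.array(["a", "b"] * 50)
        basis = fit_classwise_pca(X, y, k_per_class=3)
        out = retained_energy(basis, 3)
        assert set(out) == {"a", "b"}
        assert all(0 < v <= 1 for v in out.values())

    def test_out_of_range_k_rejected(self, rng):
        basis = fit_pca(rng.standard_normal((20, 4)))
        with pytest.raises(ValueError, match="out of range"):
            retained_energy(basis, 99)


# --------------------------------------------------------------------------
# Binomial logistic regression
# --------------------------------------------------------------------------

class TestBinomialLR:
    def test_symmetric_toy_gives_null_coefficient(self):
        X = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        y = [0, 1, 1, 0]
        fit = fit_binomial_lr(X, y)
        (coef,) = fit.coefficients
        assert coef.estimate == pytest.approx(0.0, abs=1e-10)
        assert coef.t_statistic == pytest.approx(0.0, abs=1e-10)
        assert coef.p_value == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_newton_mle_oracle(self, seed):
        r = np.random.default_rng(seed)
        n, k = r.integers(30, 60), int(r.integers(1, 4))
        X = r.standard_normal((n, k))
        beta = r.uniform(-1, 1, size=k)
        y = (r.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(int)
        if y.min() == y.max():
            pytest.skip("degenerate label draw")
        fit = fit_binomial_lr(X, y)
        if fit.firth_used:
            pytest.skip("separated draw; unpenalized oracle undefined")
        oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        mine = np.r_[fit.intercept.estimate, [c.estimate for c in fit.coefficients]]
        se = np.r_[
            fit.intercept.standard_error,
            [c.standard_error for c in fit.coefficients],
        ]
        np.testing.assert_allclose(mine, oracle.params, atol=1e-6)
        np.testing.assert_allclose(se, oracle.bse, atol=1e-6)
        np.testing.assert_allclose(fit.p_values(), oracle.pvalues[1:], atol=1e-6)

    def test_fifty_columns_give_fifty_records_plus_intercept(self, rng):
        X = rng.standard_normal((400, 50))
        y = (rng.random(400) < 0.5).astype(int)
        fit = fit_binomial_lr(X, y)
        assert len(fit.coefficients) == 50
        assert fit.intercept.index == "intercept"
        assert [c.index for c in fit.coefficients] == list(range(50))

    def test_t_sign_matches_estimate_sign(self, rng):
        X = rng.standard_normal((200, 4))
        y = (rng.random(200) < 1 / (1 + np.exp(-X[:, 0]))).astype(int)
        fit = fit_binomial_lr(X, y)
        for c in fit.coefficients:
            assert np.sign(c.t_statistic) == np.sign(c.estimate)
            assert 0 <= c.p_value <= 1
            assert c.standard_error > 0

    def test_separated_data_uses_firth_and_stays_finite(self):
        X = np.linspace(-2, 2, 40).reshape(-1, 1)
        y = (X.ravel() > 0).astype(int)
        fit = fit_binomial_lr(X, y)
        assert fit.firth_used
        assert np.isfinite(fit.coefficients[0].estimate)
        assert fit.coefficients[0].p_value < 0.05  # the signal is real

    def test_constant_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            fit_binomial_lr(rng.standard_normal((20, 2)), np.zeros(20))

    def test_too_many_columns_rejected(self, rng):
        with pytest.raises(ValueError, match="K"):
            fit_binomial_lr(rng.standard_normal((10, 12)),
                            (rng.random(10) < 0.5).astype(int))


def _fit_from_p(p_values):
    recs = tuple(
        CoefficientRecord(index=j, estimate=1.0, standard_error=1.0,
                          t_statistic=1.0, p_value=p)
        for j, p in enumerate(p_values)
    )
    inter = CoefficientRecord("intercept", 0.0, 1.0, 0.0, 1.0)
    return LRFit(coefficients=recs, intercept=inter, converged=True, iterations=1)


class TestSelectSignificant:
    def test_benchmark_table_selected_iff_below_alpha(self):
        fit = _fit_from_p(BENCHMARK_P_COLUMN)
        sel = select_significant(fit, alpha=0.05)
        for j, p in enumerate(BENCHMARK_P_COLUMN):
            assert (j in sel.selected) == (p < 0.05)
        assert 0 in sel.selected       # p = 5.14e-15
        assert 7 not in sel.selected   # p = 0.995623
        assert len(sel.selected) == 30

    def test_all_insignificant_gives_empty_selection(self):
        sel = select_significant(_fit_from_p([1.0] * 10))
        assert sel.selected == ()

    def test_intercept_never_selected(self):
        sel = select_significant(_fit_from_p([0.0] * 5))
        assert "intercept" not in sel.selected


# --------------------------------------------------------------------------
# Full reduction
# --------------------------------------------------------------------------

class TestLrPcaReduce:
    def test_alpha_one_keeps_all_components(self, rng):
        X = rng.standard_normal((100, 20))
        y = (rng.random(100) < 0.5).astype(int)
        res = lr_pca_reduce(X, y, mode="pooled", K=10, alpha=1.0)
        assert res.train_scores.shape == (100, 10)

    def test_transform_is_deterministic_on_training_rows(self, rng):
        X = rng.standard_normal((80, 15))
        y = (rng.random(80) < 0.5).astype(int)
        res = lr_pca_reduce(X, y, X_other=X, mode="pooled", K=8, alpha=1.0)
        np.testing.assert_array_equal(res.train_scores, res.other_scores)

    def test_selected_components_span_planted_subspace(self):
        X, y, dirs = gen_feature_table(FeatureSimConfig(seed=0))
        res = lr_pca_reduce(X, y, mode="pooled", K=50)
        sel = list(res.selection.selected)
        assert {0, 1, 2} <= set(sel)
        V = np.stack(
            [c.direction for c in res.basis.components[:50]], axis=1
        )[:, sel]
        Q, _ = np.linalg.qr(V)
        angles = np.degrees(np.arccos(np.clip(np.linalg.svd(dirs @ Q)[1], 0, 1)))
        assert angles.max() < 10.0

    def test_pooled_scores_remove_multicollinearity(self):
        X, y, _ = gen_feature_table(FeatureSimConfig(seed=3))
        res = lr_pca_reduce(X, y, mode="pooled", K=50, alpha=1.0)
        corr = np.corrcoef(res.train_scores, rowvar=False)
        off = corr - np.diag(np.diag(corr))
        assert np.max(np.abs(off)) < 1e-6

    def test_basis_fit_on_training_rows_only(self, rng):
        X_tr = rng.standard_normal((60, 10))
        y = (rng.random(60) < 0.5).astype(int)
        X_te = rng.standard_normal((20, 10)) + 100.0  # far outside training
        res = lr_pca_reduce(X_tr, y, X_te, mode="pooled", K=5, alpha=1.0)
        mu = np.stack([c.fit_mean for c in res.basis.components[:5]])
        # the stored means come from training rows, untouched by X_other
        np.testing.assert_allclose(mu, np.tile(X_tr.mean(0), (5, 1)), atol=1e-10)

    def test_unknown_mode_rejected(self, rng):
        X = rng.standard_normal((20, 4))
        with pytest.raises(ValueError, match="mode"):
            lr_pca_reduce(X, np.array([0, 1] * 10), mode="sideways", K=2)


def test_basis_invariants_unit_norm_and_orthogonal(rng):
    X = rng.standard_normal((50, 12))
    basis = fit_pca(X)
    V = np.stack([c.direction for c in basis.components], axis=1)
    np.testing.assert_allclose(np.linalg.norm(V, axis=0), 1.0, atol=1e-10)
    np.testing.assert_allclose(V.T @ V, np.eye(12), atol=1e-8)
    lam = np.abs([c.eigenvalue for c in basis.components])
    assert np.all(np.diff(lam) <= 1e-12)  # sorted descending by magnitude
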