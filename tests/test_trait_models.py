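"""PLSR fitting, LooCV component selection, VIP and trait candidacy."""

import numpy as np
import pandas as pd
import pytest

from leafspec.spectral_indices import NDSIMap
from leafspec.trait_models import (
    compute_vip,
    evaluate_cv,
    fit_plsr,
    loocv_predictions,
    loocv_rmsep,
    predict,
    select_components,
    select_model_traits,
)


def random_problem(n=50, p=10, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestFit:
    def test_full_components_match_least_squares(self):
        """At k = P on full-rank data PLSR reproduces the OLS fit."""
        X, y = random_problem(n=50, p=10, seed=1, noise=0.5)
        model = fit_plsr(X, y, k=10)
        Xc = np.column_stack([np.ones(len(y)), X])
        beta = np.linalg.lstsq(Xc, y, rcond=None)[0]
        ols_pred = Xc @ beta
        assert np.max(np.abs(predict(model, X) - ols_pred)) <= 1e-8

    def test_single_predictor_equals_simple_regression(self):
        X, y = random_problem(n=30, p=1, seed=2, noise=0.3)
        model = fit_plsr(X, y, k=1)
        x = X[:, 0]
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        assert np.allclose(predict(model, X), slope * x + intercept, atol=1e-10)

    def test_constant_response_predicts_mean(self):
        X, _ = random_problem(n=20, p=5, seed=3)
        y = np.full(20, 4.2)
        model = fit_plsr(X, y, k=3)
        assert np.allclose(predict(model, X), 4.2)
        assert np.count_nonzero(model.t_sq) == 0

    def test_infeasible_component_count_rejected(self):
        X, y = random_problem(n=10, p=5, seed=4)
        with pytest.raises(ValueError):
            fit_plsr(X, y, k=6)
        with pytest.raises(ValueError):
            fit_plsr(X, y, k=0)

    def test_matches_reference_nipals_implementation(self):
        """Cross-check against scikit-learn's PLS regression (no scaling)."""
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_problem(n=40, p=15, seed=5, noise=1.0)
        for k in (1, 3, 7):
            model = fit_plsr(X, y, k=k)
            ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, y)
            assert np.allclose(
                predict(model, X), ref.predict(X).ravel(), atol=1e-8
            )


class TestLooCV:
    def test_curve_length_capped(self):
        X, y = random_problem(n=20, p=40, seed=6, noise=0.5)
        assert loocv_rmsep(X, y, max_k=30).size == 18  # N - 2
        X, y = random_problem(n=50, p=8, seed=6, noise=0.5)
        assert loocv_rmsep(X, y, max_k=30).size == 8  # P

    def test_noise_free_linear_signal_reaches_zero_error(self):
        X, y = random_problem(n=40, p=6, seed=7, noise=0.0)
        curve = loocv_rmsep(X, y, max_k=6)
        assert curve[-1] == pytest.approx(0.0, abs=1e-8)

    def test_sample_order_invariance(self):
        X, y = random_problem(n=25, p=6, seed=8, noise=0.5)
        curve = loocv_rmsep(X, y, max_k=6)
        perm = np.random.default_rng(0).permutation(25)
        curve_p = loocv_rmsep(X[perm], y[perm], max_k=6)
        assert np.allclose(curve, curve_p, atol=1e-10)

    def test_held_out_sample_not_used(self):
        """Perturbing y[i] must not change sample i's LooCV prediction."""
        X, y = random_problem(n=15, p=4, seed=9, noise=0.5)
        base = loocv_predictions(X, y, max_k=3)
        y2 = y.copy()
        y2[4] += 100.0
        other = loocv_predictions(X, y2, max_k=3)
        assert np.allclose(base[4], other[4], atol=1e-10)

    @pytest.mark.parametrize(
        "curve, expected",
        [([3.0, 2.0, 2.0, 4.0], 2), ([5.0], 1), ([5, 4, 3, 2, 1], 5)],
    )
    def test_component_selection(self, curve, expected):
        assert select_components(np.array(curve, float)) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ValueError):
            select_components(np.array([]))


class TestEvaluate:
    def test_perfect_model_scores(self):
        X, y = random_problem(n=30, p=5, seed=10, noise=0.0)
        res = evaluate_cv(X, y, max_k=5)
        assert res.r2_cv == pytest.approx(1.0, abs=1e-6)
        assert res.nrmse == pytest.approx(0.0, abs=1e-6)

    def test_nrmse_invariant_under_affine_rescaling(self):
        X, y = random_problem(n=30, p=6, seed=11, noise=1.0)
        a = evaluate_cv(X, y, k=4, max_k=6)
        b = evaluate_cv(X, 3.0 * y + 7.0, k=4, max_k=6)
        assert b.rmsep == pytest.approx(3.0 * a.rmsep, rel=1e-9)
        assert b.nrmse == pytest.approx(a.nrmse, rel=1e-9)
        assert b.r2_cv == pytest.approx(a.r2_cv, rel=1e-9)

    def test_zero_range_rejected(self):
        X, _ = random_problem(n=10, p=3, seed=12)
        with pytest.raises(ValueError):
            evaluate_cv(X, np.ones(10))


class TestVIP:
    @pytest.mark.parametrize("seed,k", [(1, 2), (2, 5), (3, 8)])
    def test_squared_vip_averages_to_one(self, seed, k):
        X, y = random_problem(n=40, p=12, seed=seed, noise=1.0)
        vip = compute_vip(fit_plsr(X, y, k=k))
        assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-10)

    def test_equal_weights_give_unit_vip(self):
        # identical predictive columns share the weight vector evenly
        rng = np.random.default_rng(13)
        x = rng.normal(size=50)
        X = np.column_stack([x, x, x]) + 0.0
        y = 2.0 * x
        vip = compute_vip(fit_plsr(X, y, k=1))
        assert np.allclose(vip, 1.0, atol=1e-10)

    def test_informative_band_outranks_noise_band(self):
        rng = np.random.default_rng(14)
        signal = rng.normal(size=200)
        noise = rng.normal(size=(200, 4))
        X = np.column_stack([signal, noise])
        y = signal + 0.1 * rng.normal(size=200)
        vip = compute_vip(fit_plsr(X, y, k=2))
        assert vip[0] > vip[1:].max()

    def test_degenerate_model_rejected(self):
        X, _ = random_problem(n=10, p=3, seed=15)
        model = fit_plsr(X, np.full(10, 1.0), k=2)
        with pytest.raises(ValueError):
            compute_vip(model)


class TestTraitCandidacy:
    @staticmethod
    def _map_with_best(r2_best: float, significant: bool = True) -> NDSIMap:
        r = np.array([np.sqrt(r2_best), 0.1])
        p_adj = np.array([0.001 if significant else 0.5, 0.9])
        return NDSIMap(
            wavelengths=np.array([500.0, 600.0, 700.0]),
            i_idx=np.array([0, 0]),
            j_idx=np.array([1, 2]),
            r=r,
            p_adj=p_adj,
            n=50,
            trait="x",
        )

    def test_weakly_sensitive_trait_excluded(self):
        rng = np.random.default_rng(16)
        table = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})
        maps = {"a": self._map_with_best(0.10), "b": self._map_with_best(0.40)}
        assert select_model_traits(maps, table) == ["b"]

    def test_correlated_pair_keeps_higher_scoring_trait(self):
        rng = np.random.default_rng(17)
        a = rng.normal(size=60)
        table = pd.DataFrame({"a": a, "b": a + 0.3 * rng.normal(size=60)})
        maps = {"a": self._map_with_best(0.30), "b": self._map_with_best(0.50)}
        assert abs(table["a"].corr(table["b"])) > 0.5
        assert select_model_traits(maps, table) == ["b"]

    def test_insignificant_maps_yield_empty_list(self):
        table = pd.DataFrame({"a": np.arange(10.0)})
        maps = {"a": self._map_with_best(0.60, significant=False)}
        assert select_model_traits(maps, table) == []
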