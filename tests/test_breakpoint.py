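"""PCA extraction and the two-segment r^2-product breakpoint search."""

import numpy as np
import pytest
from scipy.stats import linregress

import metaboaging as m
from metaboaging.breakpoint import detect_breakpoint, fit_pca, recover_breakpoint_stats
from metaboaging.errors import DataError

from conftest import make_cohort_table


def brute_force_breakpoint(ages, scores, min_segment):
    """Independent exhaustive reimplementation using scipy.linregress."""
    order = np.argsort(ages, kind="stable")
    x, y = ages[order], scores[order]
    n = len(x)
    best = None
    for k in range(min_segment, n - min_segment + 1):
        f1 = linregress(x[:k], y[:k])
        f2 = linregress(x[k:], y[k:])
        prod = f1.rvalue**2 * f2.rvalue**2
        if best is None or prod > best[0] + 1e-15:
            best = (prod, k, f1, f2)
    prod, k, f1, f2 = best
    if abs(f1.slope - f2.slope) < 1e-10:
        inter = np.nan
    else:
        inter = (f2.intercept - f1.intercept) / (f1.slope - f2.slope)
    return k, prod, inter


class TestDetectBreakpoint:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(30, 90)
        ages = rng.uniform(20, 70, n)
        scores = rng.normal(size=n) + 0.02 * ages
        ms = int(n // 3)
        res = detect_breakpoint(ages, scores, min_segment=ms)
        k, prod, inter = brute_force_breakpoint(ages, scores, ms)
        assert res.split_index == k
        assert res.r2_product == pytest.approx(prod, abs=1e-10)
        if np.isfinite(inter):
            assert res.intersection_age == pytest.approx(inter, abs=1e-8)

    def test_noiseless_hinge_recovered_within_age_spacing(self):
        # hinge at 32 with ages covering it densely below the 1/3 boundary
        rng = np.random.default_rng(1)
        ages = np.sort(rng.uniform(20, 50, 105))
        scores = np.where(ages < 32, -0.1 * (ages - 32), -0.01 * (ages - 32))
        res = detect_breakpoint(ages, scores)
        spacing = np.max(np.diff(ages))
        assert abs(res.intersection_age - 32.0) <= spacing

    def test_perfectly_linear_scores_flagged_parallel(self):
        ages = np.linspace(20, 70, 60)
        scores = 0.5 * ages - 3.0
        res = detect_breakpoint(ages, scores)
        assert res.no_intersection
        assert np.isnan(res.intersection_age)
        assert res.r2_product == pytest.approx(1.0, abs=1e-12)
        assert res.split_index == 20  # ties resolved toward the smallest split

    def test_trace_length_and_r2_bounds(self):
        rng = np.random.default_rng(2)
        n, ms = 75, 25
        ages = rng.uniform(20, 70, n)
        scores = rng.normal(size=n)
        res = detect_breakpoint(ages, scores, min_segment=ms)
        assert len(res.search_trace) == n - 2 * ms + 1
        assert 0.0 <= res.r2_first <= 1.0
        assert 0.0 <= res.r2_second <= 1.0
        assert res.r2_product == pytest.approx(res.r2_first * res.r2_second)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(20, 70, 60)
        scores = rng.normal(size=60) - 0.03 * ages
        ids = np.array([f"S{i:03d}" for i in range(60)])
        res = detect_breakpoint(ages, scores, min_segment=20, subject_ids=ids)
        perm = rng.permutation(60)
        res2 = detect_breakpoint(ages[perm], scores[perm], min_segment=20, subject_ids=ids[perm])
        assert res.split_index == res2.split_index
        assert res.intersection_age == pytest.approx(res2.intersection_age, abs=1e-12)

    def test_preconditions(self):
        with pytest.raises(DataError):
            detect_breakpoint(np.arange(10.0), np.arange(10.0), min_segment=2)
        with pytest.raises(DataError):
            detect_breakpoint(np.arange(10.0), np.arange(10.0), min_segment=6)


class TestFitPca:
    def _table(self, X, names):
        cols = {n: X[:, i] for i, n in enumerate(names)}
        roles = {n: "metabolite" for n in names}
        return make_cohort_table(cols, roles)

    def test_rank_one_two_variables(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        t = self._table(np.column_stack([x, 2.0 * x + 1.0]), ["a", "b"])
        res = fit_pca(t, ["a", "b"], n_components=1)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(res.loadings["PC1"].abs(), 1.0, atol=1e-10)
        assert (res.loadings.loc[res.sign_anchor] >= 0).all()

    def test_completeness_identity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(50, 4))
        t = self._table(X, list("abcd"))
        res = fit_pca(t, list("abcd"))
        # with all components kept, per-variable loadings^2 sum to 1
        np.testing.assert_allclose((res.loadings**2).sum(axis=1), 1.0, atol=1e-10)
        # and loadings reconstruct the correlation matrix
        R = np.corrcoef(X, rowvar=False)
        np.testing.assert_allclose(res.loadings.to_numpy() @ res.loadings.to_numpy().T, R, atol=1e-10)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 5))
        X[:, 1] += X[:, 0]
        t = self._table(X, list("abcde"))
        res = fit_pca(t, list("abcde"), n_components=2)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = PCA(n_components=2).fit(Z)
        np.testing.assert_allclose(
            res.explained_variance_ratio, ref.explained_variance_ratio_, atol=1e-10
        )
        for j in range(2):
            a = res.scores.to_numpy()[:, j]
            b = ref.transform(Z)[:, j]
            assert abs(np.corrcoef(a, b)[0, 1]) == pytest.approx(1.0, abs=1e-10)

    def test_scores_zero_mean_and_variance_eigenvalue(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(45, 3))
        t = self._table(X, list("abc"))
        res = fit_pca(t, list("abc"))
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)
        ev = res.scores.var(axis=0, ddof=1).to_numpy()
        np.testing.assert_allclose(
            ev / 3.0, res.explained_variance_ratio, atol=1e-10
        )

    def test_degenerate_inputs(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(30, 2))
        t = self._table(np.column_stack([X[:, 0], np.full(30, 2.0)]), ["a", "b"])
        with pytest.raises(DataError, match="constant"):
            fit_pca(t, ["a", "b"])
        t2 = self._table(np.column_stack([X[:, 0], X[:, 0]]), ["a", "b"])
        with pytest.raises(DataError, match="rank"):
            fit_pca(t2, ["a", "b"], n_components=2)

    def test_bcaa_family_dominates_pc1(self, transformed_cohort):
        table, _, _ = transformed_cohort
        panel = list(m.AGING_PANEL) + ["bmi"]
        res = fit_pca(table.arm("train"), panel, n_components=1)
        load = res.loadings["PC1"].abs()
        bcaa = ["valine", "leucine", "isoleucine", "3_hydroxyisobutyrate"]
        others = [v for v in panel if v not in bcaa]
        assert load[bcaa].mean() > load[others].mean()


class TestRecovery:
    def test_noiseless_identifiable_tau_is_exact(self):
        st = recover_breakpoint_stats(m.recovery_config(42.0, noise_scale=0.0, seed=1), n_seeds=5)
        assert st["n_valid"] == 5
        assert st["rmse"] < 0.5  # bounded by adjacent-age spacing

    def test_rmse_degrades_with_noise(self):
        lo = recover_breakpoint_stats(m.recovery_config(40.0, noise_scale=0.1, seed=2), n_seeds=25)
        hi = recover_breakpoint_stats(m.recovery_config(40.0, noise_scale=1.0, seed=2), n_seeds=25)
        assert lo["rmse"] < hi["rmse"]

    def test_smaller_cohort_degrades_rmse(self):
        full = recover_breakpoint_stats(
            m.recovery_config(40.0, noise_scale=1.0, seed=3, n_subjects=105), n_seeds=30
        )
        half = recover_breakpoint_stats(
            m.recovery_config(40.0, noise_scale=1.0, seed=3, n_subjects=51), n_seeds=30
        )
        assert half["rmse"] > full["rmse"] * 0.8  # monotone degradation, MC slack
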