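"""Core regression/F-statistic/GC-value machinery, checked against
independent normal-equations oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cagc.gc import (
    bvgc,
    f_statistic,
    fit_ar,
    gc_from_f,
    gc_value,
    mvgc,
    naive_significance,
)
from cagc.recording import FluorescenceRecording
from cagc.simulate import benchmark_network, simulate_var


def oracle_ols(target, regressor_series, L):
    """Independent normal-equations OLS: solve X'X b = X'y directly."""
    T = len(target)
    cols = [np.ones(T - L)]
    for s in [target] + list(regressor_series):
        for q in range(1, L + 1):
            cols.append(s[L - q : T - q])
    X = np.column_stack(cols)
    y = target[L:]
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    return beta, resid


class TestFitAr:
    def test_constant_series_reproduced_exactly(self):
        fit = fit_ar(np.full(50, 3.7), L=2)
        assert np.allclose(fit.residuals, 0.0, atol=1e-10)
        # intercept + self-lags reproduce the constant
        assert np.isclose(fit.coefficients @ np.array([1.0, 3.7, 3.7]), 3.7)

    def test_independent_driver_coefficient_near_zero(self, rng):
        x, y = rng.normal(size=2000), rng.normal(size=2000)
        fit = fit_ar(x, drivers=[y], L=1)
        b1 = fit.coefficients[2]
        se = np.sqrt(fit.sigma2 / np.sum((y[:-1] - y[:-1].mean()) ** 2))
        assert abs(b1) < 3 * se

    def test_matches_normal_equations_oracle(self, rng):
        y = rng.normal(size=200)
        x = np.zeros(200)
        for t in range(1, 200):
            x[t] = 0.5 * x[t - 1] + 0.4 * y[t - 1] + 0.1 * rng.normal()
        fit = fit_ar(x, drivers=[y], L=1)
        beta, resid = oracle_ols(x, [y], 1)
        assert np.allclose(fit.coefficients, beta, atol=1e-8)
        assert np.allclose(fit.residuals, resid, atol=1e-8)

    def test_underdetermined_raises(self, rng):
        x = rng.normal(size=10)
        with pytest.raises(ValueError, match="underdetermined"):
            fit_ar(x, drivers=[rng.normal(size=10)] * 3, L=3)

    def test_nonfinite_raises(self):
        x = np.ones(50)
        x[10] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_ar(x, L=1)


class TestFStatistic:
    def test_zero_when_no_improvement(self, rng):
        # an all-zero driver cannot reduce the residual: F clips to 0
        x = rng.normal(size=100)
        red = fit_ar(x, L=1)
        full = fit_ar(x, drivers=[np.zeros(100)], L=1)
        assert f_statistic(red, full) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        # seeded 2-neuron coupled VAR, T=100, L=2
        y = rng.normal(size=100)
        x = np.zeros(100)
        for t in range(2, 100):
            x[t] = 0.3 * x[t - 1] - 0.2 * x[t - 2] + 0.5 * y[t - 1] + rng.normal()
        red = fit_ar(x, L=2)
        full = fit_ar(x, drivers=[y], L=2)
        F = f_statistic(red, full)
        _, r_red = oracle_ols(x, [], 2)
        _, r_full = oracle_ols(x, [y], 2)
        rss_r, rss_f = r_red @ r_red, r_full @ r_full
        T_regr, Mf, Mr = 98, 5, 3
        F_oracle = ((rss_r - rss_f) / (Mf - Mr)) / (rss_f / (T_regr - Mf))
        assert np.isclose(F, F_oracle, atol=1e-8)

    def test_null_distribution_is_analytic_f(self, rng):
        samples = []
        for _ in range(500):
            x, y = rng.normal(size=150), rng.normal(size=150)
            samples.append(f_statistic(fit_ar(x, L=1), fit_ar(x, drivers=[y], L=1)))
        ks = stats.kstest(samples, stats.f(1, 146).cdf)
        assert ks.pvalue > 0.01

    def test_mismatched_windows_raise(self, rng):
        x = rng.normal(size=100)
        with pytest.raises(ValueError, match="mismatched"):
            f_statistic(fit_ar(x, L=1), fit_ar(x, drivers=[x[::-1]], L=2))


class TestGCValue:
    def test_clipped_to_zero_when_ratio_below_one(self, rng):
        x, y = rng.normal(size=60), rng.normal(size=60)
        red = fit_ar(x, L=1)
        full = fit_ar(x, drivers=[y], L=1)
        if red.sigma2 <= full.sigma2:
            assert gc_value(red, full) == 0.0

    def test_equals_f_transform_on_random_instances(self, rng):
        # log-variance-ratio definition vs F-transform on 100 seeded regressions
        for _ in range(100):
            T = int(rng.integers(50, 300))
            L = int(rng.integers(1, 4))
            x, y = rng.normal(size=T), rng.normal(size=T)
            x[1:] += 0.3 * y[:-1]
            red = fit_ar(x, L=L)
            full = fit_ar(x, drivers=[y], L=L)
            gc_direct = gc_value(red, full)
            gc_via_f = gc_from_f(f_statistic(red, full), full.n_params, red.n_params, full.T_regr)
            assert abs(gc_direct - gc_via_f) < 1e-10

    def test_strong_coupling_large_gc(self, rng):
        y = rng.normal(size=5000)
        x = np.zeros(5000)
        for t in range(1, 5000):
            x[t] = 0.9 * y[t - 1] + 0.1 * rng.normal()
        red = fit_ar(x, L=1)
        full = fit_ar(x, drivers=[y], L=1)
        gc = gc_value(red, full)
        assert gc > 1.0
        # oracle: ln of dof-corrected residual-variance ratio
        _, rr = oracle_ols(x, [], 1)
        _, rf = oracle_ols(x, [y], 1)
        oracle = np.log((rr @ rr / (4999 - 2)) / (rf @ rf / (4999 - 3)))
        assert np.isclose(gc, oracle, rtol=1e-8)


class TestGCFromF:
    def test_zero_f_clips_to_zero(self):
        assert gc_from_f(0.0, Mf=5, Mr=3, T_regr=500) == 0.0

    @settings(derandomize=True, max_examples=100)
    @given(
        f1=st.floats(0, 50),
        f2=st.floats(0, 50),
        L=st.integers(1, 5),
        extra=st.integers(1, 200),
    )
    def test_monotone_in_f(self, f1, f2, L, extra):
        Mr = L + 1
        Mf = 2 * L + 1
        T_regr = Mf + extra
        lo, hi = sorted([f1, f2])
        assert gc_from_f(lo, Mf, Mr, T_regr) <= gc_from_f(hi, Mf, Mr, T_regr)

    def test_round_trip_inverts_algebraically(self, rng):
        for _ in range(50):
            Mr, Mf, T_regr = 3, 5, int(rng.integers(10, 500))
            F = float(rng.uniform(0.5, 20))
            gc = gc_from_f(F, Mf, Mr, T_regr)
            if gc > 0:
                dfn, dfd = Mf - Mr, T_regr - Mf
                F_back = (np.exp(gc) * (T_regr - Mr) / dfd - 1.0) * dfd / dfn
                assert np.isclose(F_back, F, atol=1e-10)

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            gc_from_f(1.0, Mf=3, Mr=5, T_regr=100)


class TestPairwiseMatrices:
    def test_two_neuron_directed_coupling(self, rng):
        y = rng.normal(size=1000)
        x = np.zeros(1000)
        for t in range(1, 1000):
            x[t] = 0.2 * x[t - 1] + 0.5 * y[t - 1] + rng.normal()
        rec = FluorescenceRecording(signal=np.vstack([x, y]), dt=1.0)
        res = naive_significance(bvgc(rec, 1), p=0.05, bonferroni=False)
        assert res.significant[0, 1]  # y -> x
        assert not res.significant[1, 0]

    def test_white_noise_bonferroni_rarely_fires(self):
        dirty = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            rec = FluorescenceRecording(signal=r.normal(size=(10, 500)), dt=1.0)
            res = bvgc(rec, 1)
            dirty += int(np.nansum(res.significant) > 0)
        assert dirty <= 2

    def test_diagonal_is_nan(self, var_recording):
        res = bvgc(var_recording, 2)
        assert np.all(np.isnan(np.diag(res.F)))
        assert np.all(np.isnan(np.diag(res.gc)))

    def test_permutation_equivariance(self, rng):
        rec = simulate_var(benchmark_network(), 600, seed=11).recording
        perm = rng.permutation(rec.n_neurons)
        rec_p = rec.select_neurons(perm)
        res = mvgc(rec, 2)
        res_p = mvgc(rec_p, 2)
        assert np.allclose(res.F[np.ix_(perm, perm)], res_p.F, atol=1e-8, equal_nan=True)

    def test_mvgc_rejects_indirect_chain_link(self, rng):
        # chain z -> y -> x: BVGC sees spurious z -> x, MVGC rejects it
        T = 3000
        z = rng.normal(size=T)
        y = np.zeros(T)
        x = np.zeros(T)
        for t in range(1, T):
            y[t] = 0.6 * z[t - 1] + 0.5 * rng.normal()
            x[t] = 0.6 * y[t - 1] + 0.5 * rng.normal()
        rec = FluorescenceRecording(signal=np.vstack([x, y, z]), dt=1.0)
        rb = naive_significance(bvgc(rec, 2), p=0.05)
        rm = naive_significance(mvgc(rec, 2), p=0.05)
        assert rb.significant[0, 2]  # z -> x reported pairwise
        assert not rm.significant[0, 2]  # conditioned away
        assert rm.significant[0, 1] and rm.significant[1, 2]  # true links kept

    def test_duplicated_neuron_suppresses_mvgc(self):
        sim = simulate_var(benchmark_network(), 3000, seed=5)
        rec = sim.recording
        net = sim.truth
        base = mvgc(rec, 2)
        dup = FluorescenceRecording(
            signal=np.vstack([rec.signal, rec.signal[0]]), dt=rec.dt
        )
        dup_res = mvgc(dup, 2)
        # links driven by the duplicated neuron lose MVGC value
        targets = np.nonzero(net.A[:, 0])[0]
        for i in targets:
            assert dup_res.gc[i, 0] < base.gc[i, 0]

    def test_mvgc_overfitting_guard(self, rng):
        rec = FluorescenceRecording(signal=rng.normal(size=(10, 30)), dt=1.0)
        with pytest.raises(ValueError, match="overfitting"):
            mvgc(rec, 3)


class TestNaiveSignificance:
    def test_all_unit_pvalues_empty_mask(self, var_recording):
        import dataclasses

        res = bvgc(var_recording, 1)
        res = dataclasses.replace(res, pvalues=np.ones_like(res.pvalues))
        out = naive_significance(res, p=0.05)
        assert not out.significant.any()

    def test_bonferroni_threshold_arithmetic(self, rng):
        rec = FluorescenceRecording(signal=rng.normal(size=(10, 300)), dt=1.0)
        res = bvgc(rec, 1)
        out = naive_significance(res, p=0.05, bonferroni=True)
        assert "m=90" in out.threshold_info
        # oracle: direct cutoff comparison on the p-value list
        expected = res.pvalues < 0.05 / 90
        expected &= np.isfinite(res.pvalues)
        assert np.array_equal(out.significant, expected)

    def test_invalid_p_raises(self, var_recording):
        with pytest.raises(ValueError):
            naive_significance(bvgc(var_recording, 1), p=1.5)
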