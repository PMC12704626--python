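"""Pseudobulk DEG tests: TMM against a naive direct-formula implementation,
OLS fits against statsmodels, and the support rules."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from stratwas.deg import (deg_support_nonstratified, deg_support_stratified, fit_de,
                          log_cpm, tmm_factors)


def naive_tmm(Y, m_trim=0.30, a_trim=0.05):
    """Independent loop-based reimplementation of the TMM definition."""
    Y = np.asarray(Y, float)
    lib = Y.sum(axis=0)
    uqs = []
    for j in range(Y.shape[1]):
        cpm = Y[Y[:, j] > 0, j] / lib[j] * 1e6
        uqs.append(np.quantile(cpm, 0.75))
    ref = int(np.argmin([abs(u - np.mean(uqs)) for u in uqs]))
    logf = []
    for j in range(Y.shape[1]):
        M, A, w = [], [], []
        for g in range(Y.shape[0]):
            if Y[g, j] > 0 and Y[g, ref] > 0:
                pk, pr = Y[g, j] / lib[j], Y[g, ref] / lib[ref]
                M.append(np.log2(pk / pr))
                A.append(0.5 * np.log2(pk * pr))
                w.append(1.0 / ((lib[j] - Y[g, j]) / (lib[j] * Y[g, j])
                                + (lib[ref] - Y[g, ref]) / (lib[ref] * Y[g, ref])))
        M, A, w = map(np.array, (M, A, w))
        if np.allclose(M, M[0]):
            logf.append(M[0])
            continue
        lo_m, hi_m = np.quantile(M, [m_trim, 1 - m_trim])
        lo_a, hi_a = np.quantile(A, [a_trim, 1 - a_trim])
        keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        logf.append(np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    f = 2.0 ** np.array(logf)
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_samples_give_unit_factors(self, rng):
        col = rng.poisson(50, 200)
        Y = np.tile(col[:, None], (1, 4))
        np.testing.assert_allclose(tmm_factors(Y), 1.0, atol=1e-12)

    def test_exact_doubling_absorbed_by_library_size(self, rng):
        a = rng.poisson(60, 300) + 1
        Y = np.column_stack([a, 2 * a, a])
        np.testing.assert_allclose(tmm_factors(Y), 1.0, atol=1e-9)

    def test_geometric_mean_is_one(self, rng):
        for _ in range(20):
            Y = rng.negative_binomial(5, 0.1, size=(100, 6)) + 1
            f = tmm_factors(Y)
            assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(30):
            Y = rng.negative_binomial(4, 0.05, size=(rng.integers(50, 150), 5))
            Y[Y.sum(axis=1) == 0, 0] = 1  # avoid all-zero genes only; zeros allowed
            if (Y.sum(axis=0) == 0).any():
                continue
            np.testing.assert_allclose(tmm_factors(Y), naive_tmm(Y), atol=1e-6)

    def test_all_zero_sample_rejected(self):
        Y = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValueError, match="s2"):
            tmm_factors(Y)


class TestFitDE:
    def _matrix(self, rng, n=60, genes=5):
        counts = pd.DataFrame(rng.negative_binomial(10, 0.1, size=(genes, n)) + 1,
                              index=[f"G{i}" for i in range(genes)])
        return log_cpm(counts)

    def test_coefficient_matches_statsmodels(self, rng):
        lcpm = self._matrix(rng)
        y = rng.integers(0, 2, 60).astype(float)
        cov = pd.DataFrame({"age": rng.normal(70, 5, 60), "sex": rng.integers(0, 2, 60)})
        res = fit_de(lcpm, y, cov)
        X = sm.add_constant(np.column_stack([y, cov.age, cov.sex]))
        for i, g in enumerate(lcpm.index):
            fit = sm.OLS(lcpm.loc[g].to_numpy(), X).fit()
            assert res.logFC.iloc[i] == pytest.approx(fit.params[1], abs=1e-10)
            assert res.p.iloc[i] == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_constructed_logfc_recovered(self, rng):
        n = 80
        y = np.repeat([0.0, 1.0], n // 2)
        base = rng.normal(8, 0.05, size=(1, n))
        lcpm = pd.DataFrame(base + y[None, :] * 1.0, index=["G0"])
        cov = pd.DataFrame({"age": rng.normal(0, 1, n)})
        res = fit_de(lcpm, y, cov)
        assert res.logFC[0] == pytest.approx(1.0, abs=0.05)

    def test_collinear_covariate_rejected(self, rng):
        lcpm = self._matrix(rng)
        y = rng.integers(0, 2, 60).astype(float)
        cov = pd.DataFrame({"dup": y})
        with pytest.raises(ValueError, match="collinear"):
            fit_de(lcpm, y, cov)

    def test_constant_apoe4_dropped_in_stratified_scope(self, rng):
        lcpm = self._matrix(rng)
        y = rng.integers(0, 2, 60).astype(float)
        cov = pd.DataFrame({"apoe4_dosage": np.ones(60), "age": rng.normal(0, 1, 60)})
        res = fit_de(lcpm, y, cov, scope="carrier")
        assert len(res) == len(lcpm)

    def test_null_type_one_error(self, rng):
        genes = 200
        counts = pd.DataFrame(rng.negative_binomial(10, 0.1, size=(genes, 80)) + 1,
                              index=[f"G{i}" for i in range(genes)])
        lcpm = log_cpm(counts)
        y = rng.permutation(np.repeat([0.0, 1.0], 40))
        cov = pd.DataFrame({"age": rng.normal(0, 1, 80)})
        res = fit_de(lcpm, y, cov)
        frac = (res.p < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / genes)


class TestSupportRules:
    def test_nonstratified_threshold(self):
        assert deg_support_nonstratified(0.01)
        assert not deg_support_nonstratified(0.2)
        assert not deg_support_nonstratified(np.nan)

    @pytest.mark.parametrize("p,fc,fc_o,expected", [
        (0.01, 0.4, -0.1, True),    # opposite direction
        (0.01, 0.9, 0.5, True),     # 0.9 >= 1.5*0.5 = 0.75
        (0.01, 0.6, 0.5, False),    # same sign, 0.6 < 0.75
        (0.20, 0.9, -0.5, False),   # not significant
        (0.01, 0.4, np.nan, False),  # missing other stratum
    ])
    def test_stratified_rule_table(self, p, fc, fc_o, expected):
        assert deg_support_stratified(p, fc, fc_o) is expected

    def test_support_is_asymmetric(self):
        # carrier supported, non-carrier (swapped roles) not
        assert deg_support_stratified(0.01, 0.9, 0.5)
        assert not deg_support_stratified(0.01, 0.5, 0.9)
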