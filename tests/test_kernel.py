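"""Kernel-machine score test: null model, statistic, spectrum, set runner."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2

import pathassoc as pa
from pathassoc.kernel import (fit_null_logistic, linear_kernel, skat_statistic,
                              null_spectrum, score_test_1df, run_set_tests,
                              results_frame, SeparationError, SetTestEngine)
from pathassoc.quadform import quadform_pvalue
from conftest import make_samples


class TestNullModel:
    def test_intercept_only_case_fraction(self):
        df = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(1030)],
            "status": [1] * 494 + [0] * 536,
            "age": 65.0, "institution": "x", "ethnicity": "Caucasian",
        })
        null = fit_null_logistic(pa.SampleTable(df), covariates=())
        np.testing.assert_allclose(null.fitted_means, 494 / 1030, rtol=1e-10)

    def test_matches_direct_likelihood_maximization(self, rng, samples200):
        null = fit_null_logistic(samples200, ("age", "institution"))
        X, y = null.design, null.y

        def negll(beta):
            eta = X @ beta
            return np.sum(np.log1p(np.exp(eta))) - y @ eta

        def grad(beta):
            mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
            return X.T @ (mu - y)

        res = minimize(negll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                       options={"gtol": 1e-10, "maxiter": 2000})
        np.testing.assert_allclose(null.coefficients, res.x, atol=1e-6)

    def test_separation_detected(self):
        df = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(40)],
            "status": [0] * 20 + [1] * 20,
            "age": [50.0] * 20 + [80.0] * 20,    # age == 30*y + 50: separating
            "institution": "x", "ethnicity": "Caucasian",
        })
        with pytest.raises(SeparationError):
            fit_null_logistic(pa.SampleTable(df), ("age",))


class TestKernelAlgebra:
    def test_identity_genotypes(self):
        np.testing.assert_array_equal(linear_kernel(np.eye(2)), np.eye(2))

    def test_psd_and_symmetric(self, rng):
        g = rng.binomial(2, 0.3, (30, 8)).astype(float)
        k = linear_kernel(g)
        np.testing.assert_allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() >= -1e-10

    def test_duplicated_samples_duplicate_rows(self, rng):
        g = rng.binomial(2, 0.4, (5, 3)).astype(float)
        g2 = np.vstack([g, g[0]])
        k = linear_kernel(g2)
        np.testing.assert_allclose(k[0], k[5])

    def test_statistic_is_brute_force_quadratic_form(self, rng):
        samples = make_samples(20, rng)
        null = fit_null_logistic(samples, ("age",))
        g = rng.binomial(2, 0.3, (20, 4)).astype(float)
        r = samples.status - null.fitted_means
        assert skat_statistic(null, linear_kernel(g)) == pytest.approx(
            float(r @ g @ g.T @ r))

    def test_single_snp_statistic_is_squared_score(self, rng):
        samples = make_samples(50, rng)
        null = fit_null_logistic(samples, ("age",))
        g = rng.binomial(2, 0.25, 50).astype(float)
        q = skat_statistic(null, linear_kernel(g[:, None]))
        assert q == pytest.approx(float(g @ null.residuals) ** 2)


class TestSpectrum:
    def _null(self, rng, n):
        return fit_null_logistic(make_samples(n, rng), ("age",))

    def test_single_snp_rank_one(self, rng):
        null = self._null(rng, 40)
        g = rng.binomial(2, 0.3, 40).astype(float)
        lam = null_spectrum(null, g[:, None])
        v, X = null.weights, null.design
        P0 = np.diag(v) - (v[:, None] * X) @ np.linalg.solve(
            X.T @ (X * v[:, None]), X.T * v[None, :])
        assert lam.size == 1
        assert lam[0] == pytest.approx(float(g @ P0 @ g))

    def test_trace_identity_and_explicit_eigenvalues(self, rng):
        null = self._null(rng, 30)
        g = rng.binomial(2, 0.35, (30, 4)).astype(float)
        lam = null_spectrum(null, g)
        v, X = null.weights, null.design
        P0 = np.diag(v) - (v[:, None] * X) @ np.linalg.solve(
            X.T @ (X * v[:, None]), X.T * v[None, :])
        m = P0 @ (g @ g.T)
        assert lam.sum() == pytest.approx(np.trace(m))
        ev = np.linalg.eigvals(m).real
        ev = np.sort(ev[ev > 1e-10 * ev.max()])[::-1]
        np.testing.assert_allclose(lam, ev, rtol=1e-8)


class TestSetTests:
    def test_rank_one_equivalence_to_score_test(self, rng):
        samples = make_samples(150, rng)
        null = fit_null_logistic(samples, ("age", "institution"))
        g = rng.binomial(2, 0.3, 150).astype(float)
        lam = null_spectrum(null, g[:, None])
        q = float(g @ null.residuals) ** 2
        p_kernel, _ = quadform_pvalue(q, lam)
        _, p_score = score_test_1df(null, g)
        assert p_kernel == pytest.approx(p_score, abs=1e-8)

    def test_snp_order_within_set_irrelevant(self, rng, small_cohort):
        gm, samples, ann = small_cohort
        h = pa.PathwayHierarchy.from_annotation(ann)
        null = fit_null_logistic(samples.aligned_to(gm), ("age",))
        ids = h.genes["TLR1"]
        e1 = SetTestEngine(null, gm, {"s": ids})
        e2 = SetTestEngine(null, gm, {"s": list(reversed(ids))})
        q1, p1, _ = e1.test("s")
        q2, p2, _ = e2.test("s")
        assert q1 == pytest.approx(q2) and p1 == pytest.approx(p2, abs=1e-10)

    def test_hierarchy_structure_of_results(self, small_cohort):
        gm, samples, ann = small_cohort
        h = pa.PathwayHierarchy.from_annotation(ann)
        res = run_set_tests(gm.subset(snps=h.pathway), samples, h,
                            covariates=("age", "institution"))
        frame = results_frame(res)
        assert (frame["level"] == "pathway").sum() == 1
        assert (frame["level"] == "gene").sum() == 4
        single = frame[frame["set"] == "IL6R"]
        assert not single["tested"].iloc[0] and np.isnan(single["p_value"].iloc[0])

    def test_missing_snp_raises_with_ids(self, small_cohort):
        gm, samples, ann = small_cohort
        h = pa.PathwayHierarchy.from_annotation(ann)
        with pytest.raises(KeyError, match="TLR1"):
            run_set_tests(gm.subset(snps=h.pathway[:3]), samples, h,
                          covariates=("age",))

    def test_stratified_runs_cover_both_ethnicities(self, small_cohort):
        gm, samples, ann = small_cohort
        h = pa.PathwayHierarchy.from_annotation(ann)
        res = run_set_tests(gm.subset(snps=h.pathway), samples, h,
                            covariates=("age",), strata="ethnicity")
        strata = {r.stratum for r in res}
        assert strata == {"Caucasian", "African American"}

    def test_davies_close_to_residual_permutation(self, rng):
        samples = make_samples(200, rng, balanced=True)
        null = fit_null_logistic(samples, ("age",))
        g = rng.binomial(2, rng.uniform(0.2, 0.4, 5), (200, 5)).astype(float)
        lam = null_spectrum(null, g)
        r = null.residuals
        q_obs = float(r @ g @ g.T @ r)
        p_davies, _ = quadform_pvalue(q_obs, lam)
        n_perm = 2000
        qs = np.empty(n_perm)
        for b in range(n_perm):
            rp = r[rng.permutation(200)]
            s = g.T @ rp
            qs[b] = s @ s
        p_perm = (1 + np.sum(qs >= q_obs)) / (n_perm + 1)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_davies - p_perm) <= 3 * se + 1e-3
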