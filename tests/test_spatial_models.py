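"""OLS, LM diagnostics, ML spatial error/lag fits, and model comparison."""

import numpy as np
import pytest

import spatscreen as ss


@pytest.fixture(scope="module")
def sem_fit(study_fixture):
    """One SEM dataset at study scale plus its OLS and SEM fits."""
    w, x, beta, names, *_ = study_fixture
    y, _ = ss.simulate_outcome(w, x, ss.DgpConfig("sem", tuple(beta), 0.69, seed=101))
    design = ss.RegressionDesign(y, x, names)
    ols = ss.fit_ols(design)
    sem = ss.fit_spatial_error(design, w, ols=ols)
    return w, design, ols, sem, beta


class TestOls:
    def test_noiseless_line_recovered_exactly(self):
        x = np.column_stack([np.ones(30), np.linspace(0, 10, 30)])
        y = 2.0 + 3.0 * x[:, 1]
        res = ss.fit_ols(ss.RegressionDesign(y, x, ["Intercept", "x"]))
        assert res.beta == pytest.approx([2.0, 3.0], abs=1e-10)
        assert res.r2 == pytest.approx(1.0)

    def test_matches_pinv_oracle(self):
        rng = np.random.default_rng(7)
        x = np.column_stack([np.ones(60), rng.normal(size=(60, 4))])
        y = rng.normal(size=60)
        res = ss.fit_ols(ss.RegressionDesign(y, x, ["Intercept", "a", "b", "c", "d"]))
        beta_oracle = np.linalg.pinv(x) @ y
        assert np.allclose(res.beta, beta_oracle, atol=1e-10)
        assert np.allclose(x.T @ res.residuals, 0.0, atol=1e-8)

    def test_duplicate_column_raises_collinearity(self):
        x = np.column_stack([np.ones(20), np.arange(20.0), np.arange(20.0)])
        with pytest.raises(ss.CollinearityError, match="a|b"):
            ss.RegressionDesign(np.random.default_rng(0).normal(size=20), x, ["Intercept", "a", "b"])

    def test_aic_consistent_with_loglik(self, sem_fit):
        _, _, ols, _, _ = sem_fit
        k = len(ols.beta) + 1
        assert ols.aic == pytest.approx(2 * k - 2 * ols.log_likelihood)
        assert 0 <= ols.r2 <= 1

    def test_vif_detects_near_collinear_pair(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=200)
        b = a + 0.05 * rng.normal(size=200)
        c = rng.normal(size=200)
        x = np.column_stack([np.ones(200), a, b, c])
        d = ss.RegressionDesign(rng.normal(size=200), x, ["Intercept", "a", "b", "c"])
        vif = ss.variance_inflation(d)
        assert vif["a"] > 10 and vif["b"] > 10
        assert vif["c"] < 2


class TestLmDiagnostics:
    def test_statistics_nonnegative_and_sarma_identity(self, sem_fit):
        w, design, ols, _, _ = sem_fit
        d = ss.lm_diagnostics(ols, design, w)
        for v in (d.lm_error, d.lm_lag, d.rlm_error, d.rlm_lag, d.sarma):
            assert v >= 0
        assert d.sarma == pytest.approx(d.rlm_error + d.lm_lag, abs=1e-8)
        assert d.sarma == pytest.approx(d.rlm_lag + d.lm_error, abs=1e-8)

    def test_sem_dgp_flags_error_dependence(self, sem_fit):
        w, design, ols, _, _ = sem_fit
        d = ss.lm_diagnostics(ols, design, w)
        assert d.lm_error > 3.84 and d.p_lm_error < 0.01

    def test_requires_row_standardized(self, sem_fit, w3):
        _, design, ols, _, _ = sem_fit
        with pytest.raises(ValueError, match="row-standardized"):
            ss.lm_diagnostics(ols, design, w3)


class TestSpatialErrorModel:
    def test_recovers_lambda_at_study_scale(self, sem_fit):
        _, _, _, sem, _ = sem_fit
        assert sem.converged
        assert sem.spatial_param == pytest.approx(0.69, abs=0.12)
        assert sem.search_interval[0] < sem.spatial_param < sem.search_interval[1]

    def test_loglik_never_below_ols(self, sem_fit):
        _, _, ols, sem, _ = sem_fit
        assert sem.log_likelihood >= ols.log_likelihood - 1e-8
        assert sem.lr_statistic >= 0
        assert sem.lr_statistic == pytest.approx(
            2 * (sem.log_likelihood - ols.log_likelihood), abs=1e-8
        )

    def test_null_evaluation_reduces_to_ols(self, study_fixture):
        """With lambda fixed at 0 the whitening is the identity, so beta,
        sigma2 and logL all collapse to OLS."""
        w, x, beta, names, *_ = study_fixture
        y, _ = ss.simulate_outcome(w, x, ss.DgpConfig("csr", tuple(beta), 0.0, seed=55))
        design = ss.RegressionDesign(y, x, names)
        ols = ss.fit_ols(design)
        sem0 = ss.fit_spatial_error(design, w, ols=ols, at_param=0.0)
        assert np.allclose(sem0.beta, ols.beta, atol=1e-10)
        assert sem0.log_likelihood == pytest.approx(ols.log_likelihood, abs=1e-8)

    def test_declusters_residuals(self, sem_fit):
        w, design, ols, sem, _ = sem_fit
        assert abs(ss.moran_i(sem.residuals, w)) < abs(ss.moran_i(ols.residuals, w))

    def test_residual_moran_nonsignificant_after_sem(self, sem_fit):
        w, _, ols, sem, _ = sem_fit
        rm_ols = ss.moran_permutation_test(ols.residuals, w, 199, seed=0)
        rm_sem = ss.moran_permutation_test(sem.residuals, w, 199, seed=0)
        assert rm_ols.p_sim < 0.05
        assert rm_sem.p_sim > 0.05


class TestSpatialLagModel:
    def test_recovers_rho_at_study_scale(self, study_fixture):
        w, x, beta, names, *_ = study_fixture
        y, _ = ss.simulate_outcome(w, x, ss.DgpConfig("slm", tuple(beta), 0.59, seed=77))
        design = ss.RegressionDesign(y, x, names)
        slm = ss.fit_spatial_lag(design, w)
        assert slm.converged
        assert slm.spatial_param == pytest.approx(0.59, abs=0.12)

    def test_null_evaluation_reduces_to_ols(self, study_fixture):
        w, x, beta, names, *_ = study_fixture
        y, _ = ss.simulate_outcome(w, x, ss.DgpConfig("csr", tuple(beta), 0.0, seed=56))
        design = ss.RegressionDesign(y, x, names)
        ols = ss.fit_ols(design)
        slm0 = ss.fit_spatial_lag(design, w, ols=ols, at_param=0.0)
        assert np.allclose(slm0.beta, ols.beta, atol=1e-10)
        assert slm0.log_likelihood == pytest.approx(ols.log_likelihood, abs=1e-8)

    def test_loglik_dominates_ols(self, study_fixture):
        w, x, beta, names, *_ = study_fixture
        y, _ = ss.simulate_outcome(w, x, ss.DgpConfig("slm", tuple(beta), 0.59, seed=78))
        design = ss.RegressionDesign(y, x, names)
        ols = ss.fit_ols(design)
        slm = ss.fit_spatial_lag(design, w, ols=ols)
        assert slm.log_likelihood >= ols.log_likelihood - 1e-8


class TestBreuschPagan:
    def test_nonnegative_and_homoskedastic_null(self):
        rng = np.random.default_rng(5)
        x = np.column_stack([np.ones(400), rng.normal(size=(400, 2))])
        y = x @ np.array([1.0, 0.5, -0.5]) + rng.normal(size=400)
        d = ss.RegressionDesign(y, x, ["Intercept", "a", "b"])
        e = ss.fit_ols(d).residuals
        stat, p = ss.breusch_pagan_studentized(e, d)
        assert stat >= 0
        assert p > 0.01  # homoskedastic data should rarely reject

    def test_power_against_covariate_driven_variance(self):
        """Variance proportional to a covariate at study scale: the
        studentized test should reject decisively."""
        rng = np.random.default_rng(6)
        n = 640
        a = rng.uniform(0.5, 3.0, size=n)
        x = np.column_stack([np.ones(n), a])
        y = 2 + a + rng.normal(size=n) * np.sqrt(a)
        d = ss.RegressionDesign(y, x, ["Intercept", "a"])
        e = ss.fit_ols(d).residuals
        stat, p = ss.breusch_pagan_studentized(e, d)
        assert p < 0.05


class TestCompareModels:
    def test_sem_dgp_prefers_sem(self, sem_fit):
        w, design, ols, sem, _ = sem_fit
        slm = ss.fit_spatial_lag(design, w, ols=ols)
        report = ss.compare_models(ols, sem, slm)
        assert report["preferred"] in ("sem", "slm")
        assert report["ranking"][-1] == "ols"

    def test_mismatched_n_rejected(self, sem_fit):
        _, design, ols, sem, _ = sem_fit
        x = np.column_stack([np.ones(30), np.arange(30.0)])
        small = ss.fit_ols(ss.RegressionDesign(np.random.default_rng(1).normal(size=30), x, ["Intercept", "x"]))
        with pytest.raises(ValueError, match="different n"):
            ss.compare_models(ols, small)


def test_island_units_dropped_from_fit_with_log(caplog):
    from shapely.geometry import box

    ids, geoms = ss.make_lattice(ss.LatticeSpec(rows=4, cols=4))
    ids.append("isl")
    geoms.append(box(99, 99, 100, 100))
    w = ss.build_queen_weights(geoms, ids).row_standardized()
    rng = np.random.default_rng(3)
    x = np.column_stack([np.ones(17), rng.normal(size=17)])
    y = x @ np.array([1.0, 2.0]) + rng.normal(size=17)
    design = ss.RegressionDesign(y, x, ["Intercept", "x"])
    with caplog.at_level("WARNING"):
        res = ss.fit_spatial_error(design, w)
    assert len(res.residuals) == 16
    assert any("isl" in rec.message for rec in caplog.records)
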