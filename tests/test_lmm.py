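"""Maximum-likelihood linear mixed model: parameter recovery, closed-form
and cross-package oracles, trajectory/slope evaluation, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from dusjm.data import AnalysisDataset
from dusjm.lmm import (
    LongitudinalSpec,
    MixedModel,
    RankDeficientError,
    fit_lmm,
)

from conftest import STREAM, simple_long_dataset


def _sim_linear(rng, n_units, n_obs, beta0=5.7, beta1=-0.12,
                sd0=0.5, sd1=0.15, sigma=0.3):
    """Random-intercept+slope data on a fixed visit grid."""
    rows, surv = [], []
    times = np.linspace(0.5, 12, n_obs)
    for i in range(n_units):
        b0 = rng.normal(0, sd0)
        b1 = rng.normal(0, sd1)
        y = beta0 + b0 + (beta1 + b1) * times + rng.normal(0, sigma, n_obs)
        uid = f"U{i:04d}"
        for t, yy in zip(times, y):
            rows.append({"unit_id": uid, "patient_id": uid, "time": t,
                         "log_value": yy})
        surv.append({"unit_id": uid, "start": 0.0, "stop": 12.0, "event": False})
    ds = AnalysisDataset("per_series", STREAM, pd.DataFrame(rows),
                         pd.DataFrame(surv), None)
    return ds


LINEAR_SPEC = LongitudinalSpec("per_series", "linear", ())
INTERCEPT_SPEC = LongitudinalSpec("per_series", "none", ())


class TestEstimation:
    def test_random_intercept_recovery(self, rng):
        """beta=2, sd_b=0.5, sigma=0.3 recovered within 3 Monte-Carlo SEs."""
        n, m = 100, 5
        b = rng.normal(0, 0.5, n)
        rows, surv = [], []
        for i in range(n):
            for j in range(m):
                rows.append({"unit_id": f"U{i:03d}", "patient_id": f"U{i:03d}",
                             "time": float(j), "log_value":
                             2.0 + b[i] + rng.normal(0, 0.3)})
            surv.append({"unit_id": f"U{i:03d}", "start": 0.0, "stop": 12.0,
                         "event": False})
        ds = AnalysisDataset("per_series", STREAM, pd.DataFrame(rows),
                             pd.DataFrame(surv), None)
        res = MixedModel(ds, INTERCEPT_SPEC).fit()
        se_beta = np.sqrt(0.5**2 / n + 0.3**2 / (n * m))
        assert abs(res.beta[0] - 2.0) < 3 * se_beta
        assert abs(np.sqrt(res.D[0, 0]) - 0.5) < 3 * 0.5 / np.sqrt(2 * (n - 1))
        assert abs(res.sigma - 0.3) < 3 * 0.3 / np.sqrt(2 * n * (m - 1))

    def test_balanced_oneway_matches_closed_form_likelihood(self, rng):
        """ML variance components equal the maximiser of the balanced
        one-way likelihood written in terms of SSW/SSB (independent oracle)."""
        n, m = 40, 5
        b = rng.normal(0, 0.4, n)
        y = 1.5 + b[:, None] + rng.normal(0, 0.25, (n, m))
        rows = [{"unit_id": f"U{i:03d}", "patient_id": f"U{i:03d}",
                 "time": float(j), "log_value": y[i, j]}
                for i in range(n) for j in range(m)]
        surv = [{"unit_id": f"U{i:03d}", "start": 0.0, "stop": 12.0,
                 "event": False} for i in range(n)]
        ds = AnalysisDataset("per_series", STREAM, pd.DataFrame(rows),
                             pd.DataFrame(surv), None)
        res = MixedModel(ds, INTERCEPT_SPEC).fit()

        ybar_i = y.mean(axis=1)
        ybar = y.mean()
        ssw = float(((y - ybar_i[:, None]) ** 2).sum())
        ssb = float(m * ((ybar_i - ybar) ** 2).sum())

        def nll(par):
            s2e, s2b = np.exp(par)
            tau = s2e + m * s2b  # variance of unit means * m
            return 0.5 * (n * (m - 1) * np.log(s2e) + n * np.log(tau)
                          + ssw / s2e + ssb / tau)

        opt = optimize.minimize(nll, np.log([0.05, 0.1]), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        s2e, s2b = np.exp(opt.x)
        assert res.sigma**2 == pytest.approx(s2e, abs=1e-6)
        assert res.D[0, 0] == pytest.approx(s2b, abs=1e-5)

    def test_zero_noise_exact_fit(self):
        """Data exactly on per-unit lines: sigma collapses, fit is exact."""
        times = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        y_by, t_by = {}, {}
        rng = np.random.default_rng(0)
        for i in range(8):
            a, bslope = rng.normal(5, 0.5), rng.normal(-0.1, 0.05)
            y_by[f"U{i}"] = a + bslope * times
            t_by[f"U{i}"] = times
        ds = simple_long_dataset(y_by, t_by)
        res = MixedModel(ds, LINEAR_SPEC).fit()
        assert res.sigma < 1e-4
        assert np.max(np.abs(res.fitted_values() - res.model.y)) < 1e-6

    def test_matches_statsmodels_mixedlm(self, basic_ds):
        """Independent cross-check on the study-sized spline dataset: the
        marginal likelihood agrees with statsmodels MixedLM at statsmodels'
        own estimates, and our optimum is at least as good."""
        import warnings

        import statsmodels.api as sm

        from dusjm.lmm import chol_pack

        model = MixedModel(basic_ds)
        res = model.fit()
        df = basic_ds.long.sort_values(["unit_id", "time"],
                                       kind="mergesort").reset_index(drop=True)
        X, Z = res.spec.design_matrices(df, basic_ds.basis)
        md = sm.regression.mixed_linear_model.MixedLM(
            df["log_value"].values, X, groups=df["unit_id"].values, exog_re=Z)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_res = md.fit(reml=False, method="lbfgs", maxiter=1000)
        L = np.linalg.cholesky(np.asarray(sm_res.cov_re))
        theta_sm = np.concatenate([chol_pack(L), [0.5 * np.log(sm_res.scale)]])
        ll_at_sm, *_ = model.profile_loglik(theta_sm)
        assert ll_at_sm == pytest.approx(sm_res.llf, abs=1e-6)
        assert res.loglik >= sm_res.llf - 1e-3

    def test_rank_deficient_design_named(self, basic_ds):
        ds2 = AnalysisDataset(
            basic_ds.variant, basic_ds.stream,
            basic_ds.long.assign(age=1.0),  # constant column collides with intercept
            basic_ds.survival, basic_ds.basis,
            unit_covariates=basic_ds.unit_covariates)
        with pytest.raises(RankDeficientError, match="age|intercept"):
            MixedModel(ds2).fit()

    def test_row_shuffle_invariance(self, toy_ds, linear_spec):
        res1 = MixedModel(toy_ds, linear_spec).fit()
        shuffled = AnalysisDataset(
            toy_ds.variant, toy_ds.stream,
            toy_ds.long.sample(frac=1.0, random_state=9).reset_index(drop=True),
            toy_ds.survival, toy_ds.basis)
        res2 = MixedModel(shuffled, linear_spec).fit()
        assert np.allclose(res1.beta, res2.beta, atol=1e-8)
        assert res1.sigma == pytest.approx(res2.sigma, abs=1e-8)
        assert res1.loglik == pytest.approx(res2.loglik, abs=1e-6)

    def test_nested_model_loglik_ordering(self, toy_ds):
        """Richer fixed-effects structure cannot fit worse (ML)."""
        rich = MixedModel(toy_ds, LongitudinalSpec("basic", "spline",
                                                   ())).fit()
        poor = MixedModel(toy_ds, LongitudinalSpec("basic", "linear",
                                                   ())).fit()
        # the spline model nests the linear one (its span includes t)
        assert rich.loglik >= poor.loglik - 1e-6

    def test_reml_flag(self, toy_ds, linear_spec):
        ml = MixedModel(toy_ds, linear_spec).fit(reml=False)
        reml = MixedModel(toy_ds, linear_spec).fit(reml=True)
        assert reml.sigma >= ml.sigma - 1e-8  # REML corrects downward bias


class TestTrajectory:
    def test_intercept_at_reference(self, toy_lmm):
        m0 = toy_lmm.subject_trajectory(np.zeros(2), {}, 0.0)
        assert m0 == pytest.approx(toy_lmm.beta[0], abs=1e-12)

    def test_linear_in_b(self, toy_lmm, rng):
        b1 = rng.normal(size=2)
        b2 = rng.normal(size=2)
        t = 3.7
        z = toy_lmm.spec.z_row(t, None)[0]
        lhs = toy_lmm.subject_trajectory(b1 + b2, {}, t) \
            - toy_lmm.subject_trajectory(b1, {}, t)
        assert lhs == pytest.approx(float(z @ b2), abs=1e-12)

    def test_matches_design_matrix_product(self, basic_ds, rng):
        res = fit_lmm(basic_ds)
        covs = {"age": 70.0, "sex_male": 1.0, "baseline_reintervention": 0.0}
        b = rng.normal(size=3)
        for t in rng.uniform(0, 12, size=100):
            x = res.spec.x_row(t, basic_ds.basis, covs)[0]
            z = res.spec.z_row(t, basic_ds.basis)[0]
            expected = float(x @ res.beta + z @ b)
            assert res.subject_trajectory(b, covs, float(t)) == pytest.approx(
                expected, abs=1e-12)

    def test_slope_central_difference(self, basic_ds, rng):
        res = fit_lmm(basic_ds)
        covs = {"age": 65.0, "sex_male": 0.0, "baseline_reintervention": 1.0}
        b = rng.normal(size=3)
        h = 1e-5
        knot = basic_ds.basis.interior_knots[0]
        for t in rng.uniform(0.2, 11.8, size=100):
            if abs(t - knot) < 2 * h:
                continue
            num = (res.subject_trajectory(b, covs, float(t + h))
                   - res.subject_trajectory(b, covs, float(t - h))) / (2 * h)
            assert abs(res.subject_slope(b, covs, float(t)) - num) < 1e-6

    def test_linear_spec_slope_constant(self, toy_lmm):
        b = np.array([0.3, -0.05])
        s1 = toy_lmm.subject_slope(b, {}, 1.0)
        s2 = toy_lmm.subject_slope(b, {}, 9.0)
        assert s1 == pytest.approx(s2, abs=1e-12)
        assert s1 == pytest.approx(toy_lmm.beta[1] + b[1], abs=1e-12)

    def test_slope_jump_at_first_reintervention(self, reint_ds):
        res = fit_lmm(reint_ds)
        uid = next(u for u, ints in reint_ds.unit_interventions.items() if ints)
        t0 = reint_ds.unit_interventions[uid][0]
        covs = reint_ds.unit_covariates[uid]
        b = np.zeros(res.spec.q)
        before = res.subject_slope(b, covs, t0 - 1e-6, interventions=())
        after = res.subject_slope(b, covs, t0 + 1e-6,
                                  interventions=(t0,))
        tsr_idx = res.spec.fixed_names.index("time_since_reint")
        assert after - before == pytest.approx(res.beta[tsr_idx], abs=1e-9)


class TestDiagnostics:
    def test_exact_fit_residuals_zero(self):
        times = np.array([0.0, 1.0, 3.0, 6.0, 9.0])
        y_by = {f"U{i}": 5 + 0.1 * i - 0.05 * times for i in range(6)}
        ds = simple_long_dataset(y_by, {f"U{i}": times for i in range(6)})
        res = MixedModel(ds, LINEAR_SPEC).fit()
        d = res.residual_diagnostics()
        assert np.max(np.abs(d["residuals"])) < 1e-6

    def test_standardized_residual_mean_small(self, rng):
        ds = _sim_linear(rng, 100, 5)
        res = MixedModel(ds, LINEAR_SPEC).fit()
        d = res.residual_diagnostics()
        assert abs(np.mean(d["std_residuals"])) < 0.1
        # conditional residuals are shrunk by the EB fit, so their SD sits
        # somewhat below 1
        assert 0.6 < np.std(d["std_residuals"]) <= 1.05
        assert d["shapiro_p"] > 1e-4  # well-specified Gaussian model

    def test_qq_ordinates_non_decreasing(self, toy_lmm):
        d = toy_lmm.residual_diagnostics()
        assert np.all(np.diff(d["qq_sample"]) >= 0)
        assert np.all(np.diff(d["qq_theoretical"]) >= 0)


def test_fixed_effect_ci_coverage():
    """95% Wald CIs for the fixed effects cover truth in >= 44/50 seeded
    replicates (n=100 units)."""
    truth = np.array([5.7, -0.12])
    hits = np.zeros(2, dtype=int)
    for rep in range(50):
        rng = np.random.default_rng(5000 + rep)
        ds = _sim_linear(rng, 100, 5)
        res = MixedModel(ds, LINEAR_SPEC).fit()
        se = np.sqrt(np.diag(res.vcov_beta))
        cover = np.abs(res.beta - truth) <= 1.959963984540054 * se
        hits += cover.astype(int)
    assert np.all(hits >= 44)


def test_log_transform_contract(paper_cohort):
    """Building from value vs exp(log value) yields identical datasets and
    therefore bit-identical fits."""
    from dusjm.data import DUSMeasurement, build_basic_dataset

    c = paper_cohort
    meas2 = [DUSMeasurement(m.patient_id, m.time, m.site, m.modality,
                            float(np.exp(np.log(m.value))))
             for m in c.measurements]
    ds1 = build_basic_dataset(c.patients, c.measurements, c.lesions, STREAM)
    ds2 = build_basic_dataset(c.patients, meas2, c.lesions, STREAM)
    pd.testing.assert_frame_equal(ds1.long, ds2.long)
    r1, r2 = fit_lmm(ds1), fit_lmm(ds2)
    assert np.array_equal(r1.beta, r2.beta)
    assert r1.loglik == r2.loglik
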