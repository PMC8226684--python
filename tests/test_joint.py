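"""Joint model: likelihood factorisation, quadrature oracles, HR transform,
and reporting."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from dusjm.data import AnalysisDataset
from dusjm.joint import (
    HazardSpec,
    JointModel,
    hr_per_20pct,
    joint_loglik,
    table2_report,
)
from dusjm.lmm import LongitudinalSpec, MixedModel

from conftest import STREAM


@pytest.fixture(scope="module")
def tiny_ds():
    """Two units, intercept-only random effect (1-dim b), one interval each."""
    rows = []
    for uid, ys in (("A", [5.6, 5.5, 5.9]), ("B", [5.0, 4.8, 4.9])):
        for t, y in zip([0.5, 2.0, 4.0], ys):
            rows.append({"unit_id": uid, "patient_id": uid, "time": t,
                         "log_value": y})
    surv = pd.DataFrame([
        {"unit_id": "A", "start": 0.0, "stop": 6.0, "event": False},
        {"unit_id": "B", "start": 0.0, "stop": 4.5, "event": True},
    ])
    ds = AnalysisDataset("per_series", STREAM, pd.DataFrame(rows), surv, None)
    ds.validate()
    return ds


TINY_SPEC = LongitudinalSpec("per_series", "none", ())
TINY_PARAMS = dict(beta=np.array([5.4]), D=np.array([[0.16]]), sigma=0.2,
                   gamma=np.zeros(0), xi=np.array([-2.0, 0.1]), alpha=-0.8)


def tiny_loglik_bruteforce(ds, params):
    """Independent oracle: per-unit trapezoid integration over b on a dense
    grid, with the longitudinal density, Weibull hazard and Gaussian prior
    written out directly."""
    beta = float(params["beta"][0])
    sd_b = float(np.sqrt(params["D"][0, 0]))
    sigma = float(params["sigma"])
    xi0, xi1 = params["xi"]
    alpha = float(params["alpha"])
    k = np.exp(xi1)
    lam = np.exp(xi0)
    total = 0.0
    bs = np.linspace(-8 * sd_b, 8 * sd_b, 20001)
    for uid, g in ds.long.groupby("unit_id"):
        y = g["log_value"].values
        srow = ds.survival[ds.survival["unit_id"] == uid].iloc[0]
        stop, event = float(srow["stop"]), bool(srow["event"])
        lik_long = np.prod(stats.norm.pdf(y[:, None] - beta - bs[None, :],
                                          scale=sigma), axis=0)
        # h(t|b) = lam k t^(k-1) exp(alpha (beta + b)); m(t|b) constant in t
        haz_mult = np.exp(alpha * (beta + bs))
        H = lam * stop**k * haz_mult
        lik_surv = np.exp(-H)
        if event:
            lik_surv = lik_surv * lam * k * stop ** (k - 1) * haz_mult
        integrand = lik_long * lik_surv * stats.norm.pdf(bs, scale=sd_b)
        total += np.log(np.trapezoid(integrand, bs))
    return total


class TestQuadrature:
    def test_matches_bruteforce_grid(self, tiny_ds):
        ll_gh = joint_loglik(tiny_ds, TINY_PARAMS, TINY_SPEC,
                             HazardSpec(baseline="weibull"), n_gh=9)
        ll_grid = tiny_loglik_bruteforce(tiny_ds, TINY_PARAMS)
        assert ll_gh == pytest.approx(ll_grid, abs=1e-5)

    def test_refinement_converged(self, tiny_ds):
        ll3 = joint_loglik(tiny_ds, TINY_PARAMS, TINY_SPEC,
                           HazardSpec(baseline="weibull"), n_gh=3)
        ll41 = joint_loglik(tiny_ds, TINY_PARAMS, TINY_SPEC,
                            HazardSpec(baseline="weibull"), n_gh=41)
        assert abs(ll3 - ll41) < 1e-4

    def test_refinement_on_fitted_model(self, toy_ds, linear_spec, toy_joint):
        """Increasing the GH order moves the fitted 60-unit loglik by less
        than 1e-3 (about 1e-5 per unit)."""
        m15 = JointModel(toy_ds, linear_spec,
                         HazardSpec(baseline="weibull"), n_gh=15)
        assert m15.loglik(toy_joint.params) == pytest.approx(
            toy_joint.loglik, abs=1e-3)


class TestFactorization:
    def test_alpha_zero_factorizes(self, toy_ds, linear_spec, toy_lmm):
        """At alpha=0 the joint likelihood equals separately computed
        longitudinal + hazard likelihoods (the key correctness oracle)."""
        jm = JointModel(toy_ds, linear_spec,
                        HazardSpec(baseline="weibull"), n_gh=9)

        def nll_hz(v):
            return -jm.hazard_loglik(np.zeros(0), v, 0.0,
                                     np.zeros((jm.n_units, jm.q)), toy_lmm.beta)

        r = optimize.minimize(nll_hz, jm._init_xi(), method="BFGS")
        params = jm.pack(toy_lmm.beta, toy_lmm.D, toy_lmm.sigma,
                         np.zeros(0), r.x, 0.0)
        assert jm.loglik(params) == pytest.approx(toy_lmm.loglik - r.fun,
                                                  abs=1e-6)

    def test_joint_at_least_two_stage(self, toy_joint):
        assert toy_joint.loglik >= toy_joint.init_loglik - 1e-6


class TestHRTransform:
    def test_null_association(self):
        r = hr_per_20pct(0.0, 0.1)
        assert r.hr == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high
        assert r.p_value == pytest.approx(1.0)

    def test_unit_association_exact(self):
        r = hr_per_20pct(1.0, 0.0)
        assert r.hr == pytest.approx(1.25, abs=1e-12)  # 1/0.8
        assert r.ci_low == r.hr == r.ci_high

    def test_monotone_in_alpha(self):
        hrs = [hr_per_20pct(a, 0.2).hr for a in np.linspace(-2, 2, 21)]
        assert np.all(np.diff(hrs) > 0)

    def test_slope_label(self):
        assert "within 1 month" in hr_per_20pct(1.0, 0.5, slope=True).scale_label

    def test_negative_se_rejected(self):
        with pytest.raises(ValueError):
            hr_per_20pct(1.0, -0.1)


class TestBaselines:
    def test_weibull_and_piecewise_alpha_agree(self, toy_ds, linear_spec,
                                               toy_lmm, toy_joint):
        """Baseline-family robustness: alpha estimates within one joint SE."""
        pw = JointModel(toy_ds, linear_spec,
                        HazardSpec(baseline="piecewise", n_internal_knots=3),
                        n_gh=9).fit(init=toy_lmm)
        se = max(toy_joint.se_alpha, pw.se_alpha)
        assert abs(pw.alpha - toy_joint.alpha) < se

    def test_piecewise_bins_from_event_quantiles(self, toy_ds, linear_spec):
        jm = JointModel(toy_ds, linear_spec,
                        HazardSpec(baseline="piecewise", n_internal_knots=3))
        ev = toy_ds.survival.loc[toy_ds.survival["event"], "stop"].values
        assert np.allclose(jm._edges, np.quantile(ev, [0.25, 0.5, 0.75]))


class TestInvariances:
    def test_series_label_permutation(self, series_ds):
        """Relabelling the independent series leaves the likelihood value
        unchanged."""
        lspec = LongitudinalSpec.for_dataset(series_ds)
        hspec = HazardSpec(baseline="weibull")
        jm1 = JointModel(series_ds, lspec, hspec, n_gh=5)
        mapping = {u: f"Q{i:03d}" for i, u in
                   enumerate(reversed(series_ds.units))}
        ds2 = AnalysisDataset(
            series_ds.variant, series_ds.stream,
            series_ds.long.assign(
                unit_id=series_ds.long["unit_id"].map(mapping)),
            series_ds.survival.assign(
                unit_id=series_ds.survival["unit_id"].map(mapping)),
            series_ds.basis)
        jm2 = JointModel(ds2, lspec, hspec, n_gh=5)
        lres = MixedModel(series_ds, lspec).fit()
        params = jm1.pack(lres.beta, lres.D, lres.sigma, np.zeros(0),
                          jm1._init_xi(), -0.5)
        assert jm1.loglik(params) == pytest.approx(jm2.loglik(params),
                                                   abs=1e-9)

    def test_no_events_rejected(self, tiny_ds):
        ds = AnalysisDataset(
            tiny_ds.variant, tiny_ds.stream, tiny_ds.long,
            tiny_ds.survival.assign(event=False), tiny_ds.basis)
        with pytest.raises(ValueError, match="at least one event"):
            JointModel(ds, TINY_SPEC, HazardSpec(baseline="weibull"))


class TestReporting:
    def test_table2_layout(self, toy_joint):
        fits = {(STREAM, "basic", "value"): toy_joint}
        df = table2_report(fits)
        assert len(df) == 6  # Value + Slope rows for three model variants
        cell = df.loc[(df["model"] == "Basic model")
                      & (df["association"] == "Value"), "vf_mid_hr"].iloc[0]
        assert "(" in cell and "–" in cell
        assert (df.loc[df["association"] == "Slope", "vf_mid_hr"] == "—").all()

    def test_protective_alpha_prints_hr_above_one(self, toy_joint):
        """alpha < 0 (higher values protect) renders as HR > 1 per 20%
        decrease, the presentation used for surveillance values."""
        assert toy_joint.alpha < 0
        assert toy_joint.hr_per_20pct().hr > 1.0

    def test_summary_mentions_association(self, toy_joint):
        assert "association=value" in toy_joint.summary()

    def test_json_round_trip(self, tmp_path, toy_joint):
        p = tmp_path / "fit.json"
        toy_joint.to_json(p)
        import json

        d = json.loads(p.read_text())
        assert d["alpha"] == pytest.approx(toy_joint.alpha)
        assert np.allclose(d["params"], toy_joint.params)


def test_slope_discriminant_simulation():
    """When the generator ties the hazard to the slope only, the fitted
    slope-association HR exceeds the value-association HR."""
    from dusjm import data as dmod
    from dusjm.simulate import preset, simulate_cohort

    cfg = preset("strong_slope").replace(n_patients=120, curvature=0.0,
                                         single_event=True, seed=77)
    c = simulate_cohort(cfg).cohort
    ds = dmod.build_basic_dataset(c.patients, c.measurements, c.lesions, STREAM)
    lspec = LongitudinalSpec("basic", "linear", ())
    fits = {}
    for assoc in ("value", "slope"):
        fits[assoc] = JointModel(
            ds, lspec, HazardSpec(baseline="weibull", association=assoc),
            n_gh=9).fit(compute_se=True)
    assert fits["slope"].hr_per_20pct().hr > fits["value"].hr_per_20pct().hr
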