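"""Joint model linking the log-DUS trajectory to the lesion hazard.

The longitudinal submodel (see :mod:`dusjm.lmm`) and a relative-risk
survival submodel

    h_i(t | b_i) = h0(t) * exp( gamma' w_i + alpha * f_i(t | b_i) )

share the subject random effects b_i, where f is either the current value
m_i(t) or the current slope m_i'(t) of the subject-specific log trajectory.
The marginal likelihood integrates b_i out by adaptive Gauss-Hermite
quadrature centred on the longitudinal empirical-Bayes posterior of b_i
(recomputed from the current longitudinal parameters at every evaluation,
so the likelihood factorises exactly at alpha = 0); cumulative hazards over
each risk interval use the 15-point Gauss-Kronrod rule.  The baseline h0 is
piecewise-constant with knots at event-time quantiles, or Weibull.

Recurrent-event units (the reintervention variant) contribute their risk
intervals as conditionally independent given b_i.

Hazard ratios are reported per 20% decrease of the raw PSV/VF value:
a 20% decrease is a change of ln(0.8) on the log scale, and
``hr_per_20pct`` maps the association per unit *decrease* of the log
trajectory, a = -alpha for the hazard above, to HR = 0.8^(-a).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .data import AnalysisDataset
from .lmm import (
    ConvergenceError,
    LongitudinalSpec,
    MixedModel,
    MixedModelResults,
    chol_pack,
    chol_unpack,
)

# 15-point Gauss-Kronrod rule on [-1, 1] (QUADPACK K15)
_GK_X = np.array([
    -0.991455371120813, -0.949107912342759, -0.864864423359769,
    -0.741531185599394, -0.586087235467691, -0.405845151377397,
    -0.207784955007898, 0.0,
    0.207784955007898, 0.405845151377397, 0.586087235467691,
    0.741531185599394, 0.864864423359769, 0.949107912342759,
    0.991455371120813,
])
_GK_W = np.array([
    0.022935322010529, 0.063092092629979, 0.104790010322250,
    0.140653259715525, 0.169004726639267, 0.190350578064785,
    0.204432940075298, 0.209482141084728,
    0.204432940075298, 0.190350578064785, 0.169004726639267,
    0.140653259715525, 0.104790010322250, 0.063092092629979,
    0.022935322010529,
])


@dataclass(frozen=True)
class HazardSpec:
    """Relative-risk submodel: baseline family, covariates, association."""

    baseline: str = "piecewise"  # "piecewise" | "weibull"
    n_internal_knots: int = 3
    covariates: tuple[str, ...] = ()
    association: str = "value"  # "value" | "slope"

    def __post_init__(self):
        if self.baseline not in ("piecewise", "weibull"):
            raise ValueError(f"unknown baseline family {self.baseline!r}")
        if self.association not in ("value", "slope"):
            raise ValueError(f"unknown association {self.association!r}")
        if self.baseline == "piecewise" and self.n_internal_knots < 1:
            raise ValueError("piecewise baseline needs >= 1 internal knot")


@dataclass(frozen=True)
class HazardRatioResult:
    hr: float
    ci_low: float
    ci_high: float
    p_value: float
    scale_label: str


def hr_per_20pct(alpha: float, se_alpha: float, slope: bool = False
                 ) -> HazardRatioResult:
    """HR (95% CI, Wald p) per 20% decrease of the raw value.

    ``alpha`` is the association per unit decrease of the log trajectory
    (log-value per month for the slope association): HR = 0.8^(-alpha),
    CI from alpha -/+ 1.96 se.
    """
    if se_alpha < 0:
        raise ValueError("se_alpha must be >= 0")
    l8 = np.log(0.8)
    hr = float(np.exp(-alpha * l8))
    lo = float(np.exp(-(alpha - 1.959963984540054 * se_alpha) * l8))
    hi = float(np.exp(-(alpha + 1.959963984540054 * se_alpha) * l8))
    lo, hi = min(lo, hi), max(lo, hi)
    if se_alpha == 0:
        p = 1.0 if alpha == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(alpha) / se_alpha))
    label = "per 20% decrease within 1 month" if slope else "per 20% decrease"
    return HazardRatioResult(hr, lo, hi, p, label)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class JointModel:
    """Shared-random-effects joint model for one analysis dataset."""

    def __init__(
        self,
        dataset: AnalysisDataset,
        long_spec: LongitudinalSpec | None = None,
        hazard_spec: HazardSpec | None = None,
        n_gh: int = 9,
        n_gk: int = 15,
    ):
        if n_gk != 15:
            raise ValueError("cumulative hazards use the fixed 15-point Kronrod rule")
        self.dataset = dataset
        self.lspec = long_spec or LongitudinalSpec.for_dataset(dataset)
        self.hspec = hazard_spec or HazardSpec()
        self.n_gh = int(n_gh)

        surv = dataset.survival.copy()
        surv["unit_id"] = surv["unit_id"].astype(str)
        if int(surv["event"].sum()) < 1:
            raise ValueError("joint model needs at least one event")
        self.units = sorted(surv["unit_id"].unique())
        self._uidx = {u: i for i, u in enumerate(self.units)}
        N = len(self.units)
        self.n_units = N

        # longitudinal stack (sorted by unit lexicographically, matching units)
        self._lmm = MixedModel(dataset, self.lspec)
        if list(map(str, self._lmm.unit_ids)) != [
            u for u in self.units if u in set(map(str, self._lmm.unit_ids))
        ]:
            raise AssertionError("unit ordering mismatch")
        q = self.lspec.q
        self.q = q
        p = self._lmm.X.shape[1]
        self.p = p
        self._A = np.zeros((N, q, q))
        self._nobs = np.zeros(N)
        self._long_units = []
        for uid, sl in zip(self._lmm.unit_ids, self._lmm._blocks()):
            i = self._uidx[str(uid)]
            Zi = self._lmm.Z[sl]
            self._A[i] = Zi.T @ Zi
            self._nobs[i] = sl.stop - sl.start
            self._long_units.append((i, sl))

        # hazard covariates per unit
        r = len(self.hspec.covariates)
        self.W = np.zeros((N, r))
        first = surv.drop_duplicates("unit_id").set_index("unit_id")
        for u in self.units:
            for j, cname in enumerate(self.hspec.covariates):
                self.W[self._uidx[u], j] = float(first.loc[u, cname])

        # piecewise baseline bin edges from event-time quantiles
        ev_times = surv.loc[surv["event"].astype(bool), "stop"].values
        if self.hspec.baseline == "piecewise":
            qs = np.linspace(0, 1, self.hspec.n_internal_knots + 2)[1:-1]
            edges = np.unique(np.quantile(ev_times, qs))
            self._edges = edges
            self.n_xi = len(edges) + 1
        else:
            self._edges = None
            self.n_xi = 2

        # Gauss-Kronrod stack over risk intervals, grouped by unit
        gs, gw, gu = [], [], []
        ev_t, ev_u = [], []
        for u in self.units:
            g = surv[surv["unit_id"] == u].sort_values("start")
            i = self._uidx[u]
            for _, row in g.iterrows():
                a, b = float(row["start"]), float(row["stop"])
                mid, half = 0.5 * (a + b), 0.5 * (b - a)
                gs.append(mid + half * _GK_X)
                gw.append(half * _GK_W)
                gu.append(np.full(15, i))
                if bool(row["event"]):
                    ev_t.append(b)
                    ev_u.append(i)
        self._gs = np.concatenate(gs)
        self._gw = np.concatenate(gw)
        self._gu = np.concatenate(gu)
        self._gstarts = np.searchsorted(self._gu, np.arange(N))
        self._ev_t = np.array(ev_t)
        self._ev_u = np.array(ev_u, dtype=int)
        self.n_events = len(ev_t)

        # time-varying designs at GK nodes and event times
        self._Xs, self._Zs = self._designs(self._gs, self._gu)
        self._Xe, self._Ze = self._designs(self._ev_t, self._ev_u)
        self._logt_s = np.log(np.maximum(self._gs, 1e-12))
        self._logt_e = np.log(np.maximum(self._ev_t, 1e-12))
        if self._edges is not None:
            self._bin_s = np.searchsorted(self._edges, self._gs, side="right")
            self._bin_e = np.searchsorted(self._edges, self._ev_t, side="right")

        # Gauss-Hermite grid
        gh_x, gh_w = np.polynomial.hermite.hermgauss(self.n_gh)
        grids = np.meshgrid(*([gh_x] * q), indexing="ij")
        self._T = np.column_stack([g.ravel() for g in grids])  # (K, q)
        lw = np.meshgrid(*([np.log(gh_w) + gh_x**2] * q), indexing="ij")
        self._logw = sum(g.ravel() for g in lw)
        self.n_nodes = self._T.shape[0]

        self.n_params = (
            p + q * (q + 1) // 2 + 1 + r + self.n_xi + 1
        )

    # -- design helpers -----------------------------------------------------

    def _designs(self, times: np.ndarray, uidx: np.ndarray):
        deriv = self.hspec.association == "slope"
        X = np.zeros((len(times), self.p))
        Z = np.zeros((len(times), self.q))
        ds = self.dataset
        for i in np.unique(uidx):
            u = self.units[int(i)]
            sel = uidx == i
            ints = ds.unit_interventions.get(u, ())
            covs = ds.unit_covariates.get(u, {})
            X[sel] = self.lspec.x_row(times[sel], ds.basis, covs, ints, deriv=deriv)
            Z[sel] = self.lspec.z_row(times[sel], ds.basis, ints, deriv=deriv)
        return X, Z

    # -- parameter packing --------------------------------------------------

    def pack(self, beta, D, sigma, gamma, xi, alpha) -> np.ndarray:
        L = np.linalg.cholesky(np.asarray(D))
        return np.concatenate([
            np.asarray(beta, float).ravel(),
            chol_pack(L),
            [np.log(float(sigma))],
            np.asarray(gamma, float).ravel(),
            np.asarray(xi, float).ravel(),
            [float(alpha)],
        ])

    def unpack(self, params: np.ndarray) -> dict:
        p, q = self.p, self.q
        nL = q * (q + 1) // 2
        r = self.W.shape[1]
        k = 0
        beta = params[k:k + p]; k += p
        L = chol_unpack(params[k:k + nL], q); k += nL
        sigma = float(np.exp(params[k])); k += 1
        gamma = params[k:k + r]; k += r
        xi = params[k:k + self.n_xi]; k += self.n_xi
        alpha = float(params[k])
        return {"beta": beta, "L": L, "D": L @ L.T, "sigma": sigma,
                "gamma": gamma, "xi": xi, "alpha": alpha}

    # -- likelihood ---------------------------------------------------------

    def _log_h0(self, xi: np.ndarray, logt: np.ndarray, bins) -> np.ndarray:
        if self.hspec.baseline == "weibull":
            kshape = np.exp(xi[1])
            return xi[0] + xi[1] + (kshape - 1.0) * logt
        return xi[bins]

    def loglik(self, params: np.ndarray) -> float:
        """Joint marginal log-likelihood at the packed parameter vector."""
        th = self.unpack(np.asarray(params, float))
        beta, L, sigma = th["beta"], th["L"], th["sigma"]
        gamma, xi, alpha = th["gamma"], th["xi"], th["alpha"]
        q, N, K = self.q, self.n_units, self.n_nodes
        lmm = self._lmm

        try:
            Dinv = np.linalg.inv(L @ L.T)
        except np.linalg.LinAlgError:
            return -np.inf

        # longitudinal sufficient statistics at beta
        r0 = lmm.y - lmm.X @ beta
        ssr0 = np.zeros(N)
        c = np.zeros((N, q))
        for i, sl in self._long_units:
            ri = r0[sl]
            ssr0[i] = ri @ ri
            c[i] = lmm.Z[sl].T @ ri

        # adaptive centering: longitudinal-only posterior of b_i
        P = self._A / sigma**2 + Dinv[None, :, :]
        try:
            Lp = np.linalg.cholesky(P)
        except np.linalg.LinAlgError:
            return -np.inf
        bhat = np.linalg.solve(P, (c / sigma**2)[..., None])[..., 0]
        Cmat = np.transpose(np.linalg.inv(Lp), (0, 2, 1))  # C C' = P^-1
        logdetC = -np.log(np.diagonal(Lp, axis1=1, axis2=2)).sum(axis=1)

        B = bhat[:, None, :] + np.sqrt(2.0) * np.einsum(
            "iqr,kr->ikq", Cmat, self._T
        )  # (N, K, q)

        # longitudinal log density
        cb = np.einsum("iq,ikq->ik", c, B)
        qf = np.einsum("ikq,iqr,ikr->ik", B, self._A, B)
        ll_long = (
            -0.5 * self._nobs[:, None] * np.log(2 * np.pi * sigma**2)
            - (ssr0[:, None] - 2 * cb + qf) / (2 * sigma**2)
        )

        # random-effects prior
        sol = np.linalg.solve(L, B.reshape(-1, q).T)  # (q, N*K)
        prior_quad = (sol**2).sum(axis=0).reshape(N, K)
        logdetL = float(np.log(np.diag(L)).sum())
        ll_prior = -0.5 * q * np.log(2 * np.pi) - logdetL - 0.5 * prior_quad

        # survival
        gw = self.W @ gamma if self.W.shape[1] else np.zeros(N)
        bins_s = self._bin_s if self._edges is not None else None
        bins_e = self._bin_e if self._edges is not None else None
        f_s = self._Xs @ beta
        f_e = self._Xe @ beta if len(self._ev_t) else np.zeros(0)
        logh_s = (
            self._log_h0(xi, self._logt_s, bins_s)[:, None]
            + gw[self._gu][:, None]
            + alpha * (f_s[:, None] + np.einsum("mq,mkq->mk", self._Zs, B[self._gu]))
        )
        with np.errstate(over="ignore"):
            integ = self._gw[:, None] * np.exp(np.minimum(logh_s, 700.0))
        H = np.add.reduceat(integ, self._gstarts, axis=0)  # (N, K)
        ll_surv = -H
        if len(self._ev_t):
            logh_e = (
                self._log_h0(xi, self._logt_e, bins_e)[:, None]
                + gw[self._ev_u][:, None]
                + alpha * (f_e[:, None] + np.einsum("mq,mkq->mk", self._Ze, B[self._ev_u]))
            )
            np.add.at(ll_surv, self._ev_u, logh_e)

        logW = 0.5 * q * np.log(2.0) + logdetC[:, None] + self._logw[None, :]
        per_unit = logsumexp(logW + ll_long + ll_prior + ll_surv, axis=1)
        if not np.all(np.isfinite(per_unit)):
            return -np.inf
        return float(per_unit.sum())

    def hazard_loglik(self, gamma, xi, alpha, b_by_unit: np.ndarray,
                      beta: np.ndarray) -> float:
        """Survival-part log-likelihood with the random effects fixed
        (used for two-stage initialisation and the alpha=0 factorisation)."""
        gamma = np.asarray(gamma, float)
        xi = np.asarray(xi, float)
        gw = self.W @ gamma if self.W.shape[1] else np.zeros(self.n_units)
        bins_s = self._bin_s if self._edges is not None else None
        bins_e = self._bin_e if self._edges is not None else None
        beta = np.asarray(beta, float)
        f_s = self._Xs @ beta + np.einsum("mq,mq->m", self._Zs, b_by_unit[self._gu])
        logh_s = self._log_h0(xi, self._logt_s, bins_s) + gw[self._gu] + alpha * f_s
        with np.errstate(over="ignore"):
            H = float(np.sum(self._gw * np.exp(np.minimum(logh_s, 700.0))))
        ll = -H
        if len(self._ev_t):
            f_e = self._Xe @ beta + np.einsum(
                "mq,mq->m", self._Ze, b_by_unit[self._ev_u]
            )
            ll += float(
                np.sum(self._log_h0(xi, self._logt_e, bins_e) + gw[self._ev_u]
                       + alpha * f_e)
            )
        return ll

    # -- fitting ------------------------------------------------------------

    def _init_xi(self) -> np.ndarray:
        total_time = float(self._gw.sum())  # integral of 1 over all intervals
        rate = max(self.n_events / max(total_time, 1e-9), 1e-6)
        if self.hspec.baseline == "weibull":
            return np.array([np.log(rate), 0.0])
        return np.full(self.n_xi, np.log(rate))

    def two_stage_init(self, lmm_results: MixedModelResults | None = None
                       ) -> np.ndarray:
        lres = lmm_results or self._lmm.fit()
        modes = lres.eb_modes()
        b = np.zeros((self.n_units, self.q))
        for uid, (m, _) in modes.items():
            b[self._uidx[str(uid)]] = m
        r = self.W.shape[1]

        def nll(v):
            gamma, xi, alpha = v[:r], v[r:r + self.n_xi], v[-1]
            out = -self.hazard_loglik(gamma, xi, alpha, b, lres.beta)
            return out if np.isfinite(out) else 1e12

        v0 = np.concatenate([np.zeros(r), self._init_xi(), [0.0]])
        res = optimize.minimize(nll, v0, method="BFGS",
                                options={"maxiter": 400, "gtol": 1e-6})
        gamma, xi, alpha = res.x[:r], res.x[r:r + self.n_xi], float(res.x[-1])
        return self.pack(lres.beta, lres.D, lres.sigma, gamma, xi, alpha)

    def fit(
        self,
        init: MixedModelResults | np.ndarray | None = None,
        maxiter: int = 300,
        gtol: float = 5e-4,
        compute_se: bool = True,
    ) -> "JointModelResults":
        """Maximise the joint likelihood from the two-stage starting values."""
        if isinstance(init, np.ndarray):
            params0 = init
        else:
            params0 = self.two_stage_init(init)
        ll0 = self.loglik(params0)
        if not np.isfinite(ll0):
            raise ConvergenceError("joint likelihood not finite at start values")

        def nll(v):
            out = -self.loglik(v)
            return out if np.isfinite(out) else 1e12

        # lower bounds keep log-scale parameters away from degeneracy
        lb = np.full(self.n_params, -np.inf)
        k = self.p
        for i in range(self.q):
            for j in range(i + 1):
                if i == j:
                    lb[k] = np.log(1e-6)
                k += 1
        lb[k] = np.log(1e-6)  # log sigma
        res = optimize.minimize(
            nll, params0, method="L-BFGS-B", jac="3-point",
            bounds=list(zip(lb, np.full(self.n_params, np.inf))),
            options={"maxiter": maxiter, "ftol": 1e-11, "gtol": gtol},
        )
        params = res.x
        ll = -res.fun
        if ll < ll0 - 1e-6:
            params, ll = params0, ll0
        se_flagged = False
        vcov = np.full((self.n_params, self.n_params), np.nan)
        if compute_se:
            H = _central_hessian(self.loglik, params)
            try:
                vcov = np.linalg.inv(-H)
                if np.any(np.diag(vcov) <= 0):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                se_flagged = True
                vcov = np.linalg.pinv(-H)
                warnings.warn(
                    "observed information not positive definite at the optimum; "
                    "standard errors are flagged", RuntimeWarning,
                )
        th = self.unpack(params)
        return JointModelResults(
            model=self, params=params, loglik=float(ll), vcov=vcov,
            beta=th["beta"], D=th["D"], sigma=th["sigma"],
            gamma=th["gamma"], xi=th["xi"], alpha=th["alpha"],
            converged=bool(res.success or ll >= ll0), se_flagged=se_flagged,
            quadrature={"n_gh": self.n_gh, "rule": "adaptive-GH", "n_gk": 15},
            init_loglik=float(ll0),
        )


def _central_hessian(f, x: np.ndarray, rel_h: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, float)
    p = len(x)
    h = rel_h * np.maximum(np.abs(x), 1.0)
    H = np.zeros((p, p))
    f0 = f(x)
    fp = np.zeros(p)
    fm = np.zeros(p)
    for i in range(p):
        e = np.zeros(p); e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class JointModelResults:
    """Jointly estimated parameters with SEs from the observed information."""

    model: JointModel
    params: np.ndarray
    loglik: float
    vcov: np.ndarray
    beta: np.ndarray
    D: np.ndarray
    sigma: float
    gamma: np.ndarray
    xi: np.ndarray
    alpha: float
    converged: bool
    se_flagged: bool
    quadrature: dict
    init_loglik: float = np.nan

    @property
    def alpha_index(self) -> int:
        return self.model.n_params - 1

    @property
    def se_alpha(self) -> float:
        return float(np.sqrt(self.vcov[self.alpha_index, self.alpha_index]))

    @property
    def wald_p_alpha(self) -> float:
        return float(2 * stats.norm.sf(abs(self.alpha) / self.se_alpha))

    def alpha_ci(self, level: float = 0.95) -> tuple[float, float]:
        zcrit = stats.norm.ppf(0.5 + level / 2)
        return (self.alpha - zcrit * self.se_alpha,
                self.alpha + zcrit * self.se_alpha)

    def hr_per_20pct(self) -> HazardRatioResult:
        """HR per 20% decrease (per 20% decrease within 1 month for the
        slope association); the protective direction alpha < 0 maps to
        HR > 1."""
        return hr_per_20pct(
            -self.alpha, self.se_alpha, slope=self.model.hspec.association == "slope"
        )

    # -- hazard evaluation (used by dynamic prediction) ---------------------

    def log_h0(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        m = self.model
        if m.hspec.baseline == "weibull":
            return m._log_h0(self.xi, np.log(np.maximum(t, 1e-12)), None)
        bins = np.searchsorted(m._edges, t, side="right")
        return m._log_h0(self.xi, None, bins)

    def hazard(self, t, b, covs: dict | None = None, interventions=()):
        """h(t | b) for a subject with the given covariates/interventions."""
        m = self.model
        t = np.atleast_1d(np.asarray(t, float))
        deriv = m.hspec.association == "slope"
        x = m.lspec.x_row(t, m.dataset.basis, covs or {}, interventions, deriv=deriv)
        z = m.lspec.z_row(t, m.dataset.basis, interventions, deriv=deriv)
        f = x @ self.beta + z @ np.asarray(b, float)
        gw = 0.0
        if m.hspec.covariates:
            gw = float(np.dot(self.gamma,
                              [float((covs or {})[c]) for c in m.hspec.covariates]))
        return np.exp(self.log_h0(t) + gw + self.alpha * f)

    def cumulative_hazard(self, a: float, b_t: float, b, covs=None,
                          interventions=()) -> float:
        """Integral of h(s|b) over (a, b_t] by composite Gauss-Kronrod,
        split at baseline knots and reintervention times."""
        if b_t <= a:
            return 0.0
        m = self.model
        cuts = [a, b_t]
        if m._edges is not None:
            cuts += [e for e in m._edges if a < e < b_t]
        cuts += [i for i in interventions if a < i < b_t]
        cuts = sorted(set(cuts))
        total = 0.0
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
            s = mid + half * _GK_X
            total += float(np.sum(half * _GK_W *
                                  self.hazard(s, b, covs, interventions)))
        return total

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        hr = self.hr_per_20pct()
        m = self.model
        lines = [
            f"Joint model — variant={m.lspec.variant}, stream={m.dataset.stream}, "
            f"association={m.hspec.association}, baseline={m.hspec.baseline}",
            f"units: {m.n_units}  events: {m.n_events}  "
            f"log-likelihood: {self.loglik:.4f}",
            f"alpha: {self.alpha: .4f}  (SE {self.se_alpha:.4f}, "
            f"p {self.wald_p_alpha:.4f}){'  [SEs flagged]' if self.se_flagged else ''}",
            f"HR {hr.scale_label}: {hr.hr:.2f} ({hr.ci_low:.2f}–{hr.ci_high:.2f})",
            f"sigma: {self.sigma:.4f}",
        ]
        for name, g in zip(m.hspec.covariates, self.gamma):
            lines.append(f"  hazard {name:<22} {g: .4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        m = self.model
        return {
            "variant": m.lspec.variant,
            "stream": list(m.dataset.stream),
            "association": m.hspec.association,
            "baseline": m.hspec.baseline,
            "params": self.params.tolist(),
            "beta": self.beta.tolist(),
            "D": self.D.tolist(),
            "sigma": self.sigma,
            "gamma": self.gamma.tolist(),
            "xi": self.xi.tolist(),
            "alpha": self.alpha,
            "se_alpha": None if self.se_flagged else self.se_alpha,
            "vcov": self.vcov.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "quadrature": self.quadrature,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def fit_joint(
    ds: AnalysisDataset,
    long_spec: LongitudinalSpec | None = None,
    hazard_spec: HazardSpec | None = None,
    init: MixedModelResults | None = None,
    n_gh: int = 9,
    **fit_kwargs,
) -> JointModelResults:
    """Build and fit the joint model for one dataset."""
    return JointModel(ds, long_spec, hazard_spec, n_gh=n_gh).fit(init=init,
                                                                 **fit_kwargs)


def joint_loglik(ds: AnalysisDataset, params: dict,
                 long_spec: LongitudinalSpec | None = None,
                 hazard_spec: HazardSpec | None = None, n_gh: int = 9) -> float:
    """Evaluate the joint marginal log-likelihood at explicit parameters
    (dict with beta, D, sigma, gamma, xi, alpha)."""
    m = JointModel(ds, long_spec, hazard_spec, n_gh=n_gh)
    v = m.pack(params["beta"], params["D"], params["sigma"],
               params.get("gamma", np.zeros(len(m.hspec.covariates))),
               params["xi"], params["alpha"])
    return m.loglik(v)


# ---------------------------------------------------------------------------
# table of hazard ratios across streams/variants/associations
# ---------------------------------------------------------------------------

VARIANT_LABELS = {
    "basic": "Basic model",
    "reintervention": "Reintervention model",
    "per_series": "Per series model",
}


def table2_report(fits: dict) -> pd.DataFrame:
    """HR (95% CI) and p per 20% decrease: rows Value/Slope per model
    variant, columns per measurement stream.

    ``fits`` maps (stream, variant, association) -> JointModelResults, where
    stream is a (site, modality) pair; missing cells render as em-dashes.
    """
    streams = [("mid", "psv"), ("distal", "psv"), ("mid", "vf"), ("distal", "vf")]
    rows = []
    for variant in ("basic", "reintervention", "per_series"):
        for association in ("value", "slope"):
            row = {"model": VARIANT_LABELS[variant],
                   "association": association.capitalize()}
            for stream in streams:
                key = f"{stream[1]}_{stream[0]}"
                fit = fits.get((stream, variant, association))
                if fit is None:
                    row[f"{key}_hr"] = "—"
                    row[f"{key}_p"] = "—"
                else:
                    hr = fit.hr_per_20pct()
                    row[f"{key}_hr"] = f"{hr.hr:.2f} ({hr.ci_low:.2f}–{hr.ci_high:.2f})"
                    row[f"{key}_p"] = (
                        "<0.001" if hr.p_value < 0.001 else f"{hr.p_value:.3f}"
                    )
            rows.append(row)
    return pd.DataFrame(rows)


def render_table2_text(df: pd.DataFrame) -> str:
    return df.to_string(index=False)
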