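"""Dynamic patient-specific lesion-free probabilities.

Given a fitted joint model and one subject's measurement history up to a
time t at which the circuit is still lesion-free, the lesion-free
probability at a horizon u >= t is

    pi(u | t) = S(u | b, theta) / S(t | b, theta)

evaluated at the empirical-Bayes mode b of the random effects given the
history and survival to t (first-order plug-in).  Optional Monte-Carlo
bands propagate parameter uncertainty: draw theta from N(theta_hat, vcov)
on the estimation scale (so covariance matrices stay valid), draw b from
the Laplace approximation of its conditional posterior, recompute the
ratio, and take the 2.5/97.5 percentiles.

Each new DUS measurement advances t, re-solves the posterior mode and
updates the whole curve — the surveillance use-case: after every visit the
predicted risk is refreshed and the next visit can be scheduled
accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .joint import JointModelResults, _GK_X, _GK_W


@dataclass(frozen=True)
class SubjectHistory:
    """Measurement history of one lesion-free subject up to time t."""

    covariates: dict
    measurements: tuple  # ((time, log_value), ...)
    t: float  # months; last time known lesion-free
    interventions: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "measurements",
                           tuple((float(a), float(b)) for a, b in self.measurements))
        if any(m[0] > self.t + 1e-9 for m in self.measurements):
            raise ValueError("measurement after the last lesion-free time t")

    def updated(self, time: float, log_value: float) -> "SubjectHistory":
        if (float(time), float(log_value)) in self.measurements and \
                abs(time - self.t) <= 1e-12:
            return self  # idempotent re-application of the same measurement
        if time <= self.t:
            raise ValueError(
                f"out-of-order update: new time {time} not after t={self.t}"
            )
        return replace(
            self, measurements=self.measurements + ((float(time), float(log_value)),),
            t=float(time),
        )


@dataclass
class DynamicPrediction:
    t: float
    grid: np.ndarray
    pi: np.ndarray
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_mc: int | None = None

    def __post_init__(self):
        if np.any(np.diff(self.pi) > 1e-12):
            raise AssertionError("lesion-free probability must be non-increasing")
        if np.any((self.pi < -1e-12) | (self.pi > 1 + 1e-12)):
            raise AssertionError("probabilities outside [0, 1]")


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _log_posterior_b(res: JointModelResults, th: dict, hist: SubjectHistory,
                     b: np.ndarray) -> float:
    m = res.model
    beta, L, sigma = th["beta"], th["L"], th["sigma"]
    alpha, gamma, xi = th["alpha"], th["gamma"], th["xi"]
    ll = 0.0
    if hist.measurements:
        times = np.array([x[0] for x in hist.measurements])
        ys = np.array([x[1] for x in hist.measurements])
        x = m.lspec.x_row(times, m.dataset.basis, hist.covariates, hist.interventions)
        z = m.lspec.z_row(times, m.dataset.basis, hist.interventions)
        r = ys - x @ beta - z @ b
        ll += -0.5 * len(ys) * np.log(2 * np.pi * sigma**2) - r @ r / (2 * sigma**2)
    ll += -_cum_hazard(res, th, b, hist, 0.0, hist.t)
    sol = np.linalg.solve(L, b)
    ll += -0.5 * len(b) * np.log(2 * np.pi) - np.log(np.diag(L)).sum() \
        - 0.5 * sol @ sol
    return float(ll)


def _cum_hazard(res: JointModelResults, th: dict, b, hist: SubjectHistory,
                a: float, t2: float) -> float:
    """GK integral of the subject hazard over (a, t2], split at baseline
    knots and reinterventions."""
    if t2 <= a + 1e-14:
        return 0.0
    m = res.model
    cuts = [a, t2]
    if m._edges is not None:
        cuts += [e for e in m._edges if a < e < t2]
    cuts += [i for i in hist.interventions if a < i < t2]
    cuts = sorted(set(cuts))
    deriv = m.hspec.association == "slope"
    gw = 0.0
    if m.hspec.covariates:
        gw = float(np.dot(th["gamma"],
                          [float(hist.covariates[c]) for c in m.hspec.covariates]))
    total = 0.0
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        s = mid + half * _GK_X
        x = m.lspec.x_row(s, m.dataset.basis, hist.covariates, hist.interventions,
                          deriv=deriv)
        z = m.lspec.z_row(s, m.dataset.basis, hist.interventions, deriv=deriv)
        f = x @ th["beta"] + z @ np.asarray(b, float)
        logt = np.log(np.maximum(s, 1e-12))
        if m.hspec.baseline == "weibull":
            lh0 = m._log_h0(th["xi"], logt, None)
        else:
            lh0 = m._log_h0(th["xi"], None,
                            np.searchsorted(m._edges, s, side="right"))
        total += float(np.sum(half * _GK_W * np.exp(lh0 + gw + th["alpha"] * f)))
    return total


def _mode_and_cov(res: JointModelResults, th: dict, hist: SubjectHistory
                  ) -> tuple[np.ndarray, np.ndarray]:
    q = res.model.q

    def nlp(b):
        out = -_log_posterior_b(res, th, hist, b)
        return out if np.isfinite(out) else 1e12

    r = optimize.minimize(nlp, np.zeros(q), method="BFGS",
                          options={"gtol": 1e-7, "maxiter": 200})
    bhat = r.x
    # Laplace covariance by central-difference Hessian
    h = 1e-4
    H = np.zeros((q, q))
    f0 = nlp(bhat)
    fp = np.zeros(q); fm = np.zeros(q)
    for i in range(q):
        e = np.zeros(q); e[i] = h
        fp[i] = nlp(bhat + e); fm[i] = nlp(bhat - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(q):
        for j in range(i):
            ei = np.zeros(q); ei[i] = h
            ej = np.zeros(q); ej[j] = h
            H[i, j] = H[j, i] = (
                nlp(bhat + ei + ej) - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j]
                + nlp(bhat - ei - ej)
            ) / (2 * h * h)
    try:
        cov = np.linalg.inv(H)
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        cov = np.linalg.inv(H + np.eye(q) * 1e-6)
    return bhat, cov


def _curve(res: JointModelResults, th: dict, b, hist: SubjectHistory,
           grid: np.ndarray) -> np.ndarray:
    """pi(u|t) on the grid via cumulative hazard increments (monotone by
    construction)."""
    incr = np.zeros(len(grid))
    prev = hist.t
    for i, u in enumerate(grid):
        incr[i] = _cum_hazard(res, th, b, hist, prev, float(u))
        prev = float(u)
    return np.exp(-np.cumsum(incr))


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def predict_lesion_free(
    res: JointModelResults,
    hist: SubjectHistory,
    grid,
    n_mc: int = 0,
    seed: int | None = None,
) -> DynamicPrediction:
    """Lesion-free probability curve pi(u|t) on ``grid`` (all u >= t)."""
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < hist.t - 1e-9):
        raise ValueError("grid points must not precede the conditioning time t")
    th = res.model.unpack(res.params)
    bhat, bcov = _mode_and_cov(res, th, hist)
    pi = np.clip(_curve(res, th, bhat, hist, grid), 0.0, 1.0)

    lo = hi = None
    if n_mc and n_mc > 0:
        rng = np.random.default_rng(seed)
        vc = np.asarray(res.vcov)
        # draw on the estimation scale; clip tiny negative eigenvalues
        w, V = np.linalg.eigh(0.5 * (vc + vc.T))
        Lv = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        Lb = np.linalg.cholesky(0.5 * (bcov + bcov.T))
        draws = np.empty((n_mc, len(grid)))
        for d in range(n_mc):
            th_d = res.model.unpack(res.params + Lv @ rng.standard_normal(len(res.params)))
            b_d = bhat + Lb @ rng.standard_normal(len(bhat))
            draws[d] = _curve(res, th_d, b_d, hist, grid)
        lo = np.minimum(np.percentile(draws, 2.5, axis=0), pi)
        hi = np.maximum(np.percentile(draws, 97.5, axis=0), pi)
        lo, hi = np.clip(lo, 0, 1), np.clip(hi, 0, 1)
    return DynamicPrediction(t=hist.t, grid=grid, pi=pi, ci_low=lo, ci_high=hi,
                             n_mc=n_mc or None)


def update_prediction(
    res: JointModelResults,
    hist: SubjectHistory,
    new_measurement: tuple[float, float],
    grid,
    n_mc: int = 0,
    seed: int | None = None,
) -> tuple[DynamicPrediction, SubjectHistory]:
    """Append a measurement, advance t, and recompute the curve.

    Pure function of its inputs; re-applying the identical measurement is a
    no-op on the history and reproduces the same curve.
    """
    new_hist = hist.updated(*new_measurement)
    return predict_lesion_free(res, new_hist, grid, n_mc=n_mc, seed=seed), new_hist
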