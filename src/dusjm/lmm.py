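"""Linear mixed-effects submodel for log-transformed duplex values.

The repeated log(PSV)/log(VF) measurements are modelled as

    y_ij = x(t_ij)' beta + z(t_ij)' b_i + e_ij,   b_i ~ N(0, D),  e_ij ~ N(0, s^2)

where the time columns of x and z are either the two-column natural cubic
spline (basic and per-series variants) or linear time plus the
time-since-reintervention covariate (reintervention variant), and the basic
and reintervention variants additionally adjust the fixed effects for age,
sex and reintervention at baseline.

Estimation is by maximum likelihood (REML available as a flag): beta is
profiled out by GLS and the marginal likelihood is maximised over the
log-Cholesky factor of D and log residual SD.  ML is the default because
the joint model downstream needs one coherent likelihood across submodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .data import AnalysisDataset, BASELINE_COVARIATES, time_since_reintervention
from .splines import SplineBasis


class ConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class RankDeficientError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LongitudinalSpec:
    """Fixed- and random-effects design of one longitudinal submodel.

    ``time_structure`` is "spline" (two natural-spline columns) or "linear";
    ``covariates`` are baseline fixed effects; ``reint_covariate`` adds
    time-since-reintervention to both the fixed and random parts.
    """

    variant: str
    time_structure: str
    covariates: tuple[str, ...] = ()
    reint_covariate: bool = False

    @classmethod
    def for_dataset(
        cls, ds: AnalysisDataset, time_structure: str | None = None,
        covariates: tuple[str, ...] | None = None,
    ) -> "LongitudinalSpec":
        if ds.variant == "basic":
            return cls(
                "basic",
                time_structure or "spline",
                BASELINE_COVARIATES if covariates is None else tuple(covariates),
            )
        if ds.variant == "reintervention":
            return cls(
                "reintervention",
                time_structure or "linear",
                BASELINE_COVARIATES if covariates is None else tuple(covariates),
                reint_covariate=True,
            )
        if ds.variant == "per_series":
            return cls("per_series", time_structure or "spline", ())
        raise ValueError(f"unknown variant {ds.variant!r}")

    # -- column names -------------------------------------------------------

    @property
    def time_names(self) -> tuple[str, ...]:
        if self.time_structure == "spline":
            return ("ns1", "ns2")
        if self.time_structure == "none":  # intercept-only (one-way layout)
            return ()
        return ("t",)

    @property
    def fixed_names(self) -> tuple[str, ...]:
        names = ("intercept",) + self.time_names
        if self.reint_covariate:
            names += ("time_since_reint",)
        return names + self.covariates

    @property
    def random_names(self) -> tuple[str, ...]:
        names = ("intercept",) + self.time_names
        if self.reint_covariate:
            names += ("time_since_reint",)
        return names

    @property
    def q(self) -> int:
        return len(self.random_names)

    # -- design evaluation --------------------------------------------------

    def _time_cols(self, t: np.ndarray, basis: SplineBasis | None,
                   deriv: bool) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if self.time_structure == "spline":
            if basis is None:
                raise ValueError("spline time structure requires a SplineBasis")
            return basis.deriv(t) if deriv else basis.design(t)
        if self.time_structure == "none":
            return np.zeros((t.size, 0))
        return (np.ones((t.size, 1)) if deriv else t[:, None])

    def time_design(
        self, t, basis: SplineBasis | None, interventions=(), deriv: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """(x_rows, z_rows) of the design at arbitrary times for one unit.

        ``interventions`` are that unit's reintervention times on the unit
        clock (used only when the spec has the time-since-reintervention
        covariate).  With ``deriv=True`` the time columns are replaced by
        their derivatives and the intercept/baseline columns by zero.
        """
        t = np.atleast_1d(np.asarray(t, dtype=float))
        tc = self._time_cols(t, basis, deriv)
        icol = np.zeros((t.size, 1)) if deriv else np.ones((t.size, 1))
        cols = [icol, tc]
        if self.reint_covariate:
            if deriv:
                tsr = np.array(
                    [1.0 if any(i <= ti + 1e-12 for i in interventions) else 0.0
                     for ti in t]
                )
            else:
                tsr = np.array([time_since_reintervention(ti, interventions) for ti in t])
            cols.append(tsr[:, None])
        z = np.column_stack(cols)
        return z, z.copy()  # fixed part shares the time columns; covariates appended below

    def x_row(self, t, basis, covs: dict, interventions=(), deriv: bool = False
              ) -> np.ndarray:
        zx, _ = self.time_design(t, basis, interventions, deriv)
        if self.covariates:
            cv = np.array([0.0 if deriv else float(covs[c]) for c in self.covariates])
            zx = np.column_stack([zx, np.tile(cv, (zx.shape[0], 1))])
        return zx

    def z_row(self, t, basis, interventions=(), deriv: bool = False) -> np.ndarray:
        z, _ = self.time_design(t, basis, interventions, deriv)
        return z

    def design_matrices(self, df: pd.DataFrame, basis: SplineBasis | None
                        ) -> tuple[np.ndarray, np.ndarray]:
        """(X, Z) for observed longitudinal rows (time/covariate columns)."""
        t = df["time"].values
        tc = self._time_cols(t, basis, deriv=False)
        cols = [np.ones((len(df), 1)), tc]
        if self.reint_covariate:
            cols.append(df["time_since_reint"].values[:, None])
        Z = np.column_stack(cols)
        X = Z
        if self.covariates:
            X = np.column_stack([Z] + [df[c].values[:, None] for c in self.covariates])
        return X, Z


def _check_rank(X: np.ndarray, names) -> None:
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        _, Rd = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1])
               if abs(Rd[j, j]) < 1e-8 * max(1.0, abs(Rd[0, 0]))]
        raise RankDeficientError(
            f"design is rank deficient (rank {r} < {X.shape[1]}); "
            f"collinear column(s): {bad or 'unidentified'}"
        )


# ---------------------------------------------------------------------------
# log-Cholesky packing
# ---------------------------------------------------------------------------


def chol_pack(L: np.ndarray) -> np.ndarray:
    q = L.shape[0]
    out = []
    for i in range(q):
        for j in range(i + 1):
            out.append(np.log(L[i, j]) if i == j else L[i, j])
    return np.array(out)


def chol_unpack(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    k = 0
    for i in range(q):
        for j in range(i + 1):
            L[i, j] = np.exp(theta[k]) if i == j else theta[k]
            k += 1
    return L


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class MixedModel:
    """ML linear mixed model for one analysis dataset."""

    def __init__(self, dataset: AnalysisDataset, spec: LongitudinalSpec | None = None):
        self.dataset = dataset
        self.spec = spec or LongitudinalSpec.for_dataset(dataset)
        df = dataset.long.sort_values(["unit_id", "time"], kind="mergesort")
        self._df = df.reset_index(drop=True)
        self.y = self._df["log_value"].values.astype(float)
        self.X, self.Z = self.spec.design_matrices(self._df, dataset.basis)
        _check_rank(self.X, self.spec.fixed_names)
        units = self._df["unit_id"].values
        self.unit_ids, starts = np.unique(units, return_index=True)
        order = np.argsort(starts)
        self.unit_ids = self.unit_ids[order]
        self._starts = np.sort(starts)
        self._stops = np.append(self._starts[1:], len(units))
        if len(self.unit_ids) < 2:
            raise ValueError("need >= 2 longitudinal units")

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def _blocks(self):
        for a, b in zip(self._starts, self._stops):
            yield slice(a, b)

    def profile_loglik(self, theta: np.ndarray, reml: bool = False):
        """Profile (over beta) marginal loglik at variance parameters theta."""
        q = self.spec.q
        L = chol_unpack(theta[: q * (q + 1) // 2], q)
        sigma2 = np.exp(2.0 * theta[-1])
        D = L @ L.T
        p = self.X.shape[1]
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        logdet = 0.0
        chols = []
        for sl in self._blocks():
            Zi = self.Z[sl]
            Vi = Zi @ D @ Zi.T + sigma2 * np.eye(Zi.shape[0])
            ci = cho_factor(Vi, lower=True)
            chols.append((sl, ci))
            logdet += 2.0 * np.sum(np.log(np.diag(ci[0])))
            Xi = self.X[sl]
            ViX = cho_solve(ci, Xi)
            XtVX += Xi.T @ ViX
            XtVy += ViX.T @ self.y[sl]
        beta = np.linalg.solve(XtVX, XtVy)
        quad = 0.0
        for sl, ci in chols:
            r = self.y[sl] - self.X[sl] @ beta
            quad += r @ cho_solve(ci, r)
        n = len(self.y)
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
        if reml:
            sign, ld = np.linalg.slogdet(XtVX)
            ll += 0.5 * p * np.log(2 * np.pi) - 0.5 * ld
        return ll, beta, np.linalg.inv(XtVX), D, np.sqrt(sigma2)

    def _start_theta(self) -> np.ndarray:
        beta0, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        resid = self.y - self.X @ beta0
        v = max(float(np.var(resid)), 1e-4)
        q = self.spec.q
        L0 = np.eye(q) * np.sqrt(v / 2)
        return np.concatenate([chol_pack(L0), [0.5 * np.log(v / 2)]])

    def fit(self, reml: bool = False, start: np.ndarray | None = None,
            maxiter: int = 500) -> "MixedModelResults":
        theta0 = self._start_theta() if start is None else np.asarray(start, float)

        def nll(th):
            try:
                ll = self.profile_loglik(th, reml)[0]
            except (np.linalg.LinAlgError, ValueError):
                return 1e12
            with np.errstate(all="ignore"):
                return -ll if np.isfinite(ll) else 1e12

        q = self.spec.q
        ntheta = q * (q + 1) // 2 + 1
        lb = np.full(ntheta, -np.inf)
        ub = np.full(ntheta, np.inf)
        k = 0
        for i in range(q):  # keep log-diagonals and log-sigma bounded below
            for j in range(i + 1):
                if i == j:
                    lb[k] = np.log(1e-7)
                k += 1
        lb[-1] = np.log(1e-7)
        with np.errstate(all="ignore"):
            res = optimize.minimize(
                nll, theta0, method="L-BFGS-B", bounds=list(zip(lb, ub)),
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
            )
            at_bound = np.any(np.isclose(res.x, lb, atol=1e-9))
            if not res.success and not at_bound:
                # line-search roundoff near the optimum is common with a
                # tight ftol; polish derivative-free before giving up
                polish = optimize.minimize(
                    nll, res.x, method="Nelder-Mead",
                    options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 4000},
                )
                if polish.fun <= res.fun + 1e-9:
                    res = polish
        if res.fun >= 1e11:
            raise ConvergenceError(f"LMM did not converge: {res.message}",
                                   trace=res)
        ll, beta, vcov_beta, D, sigma = self.profile_loglik(res.x, reml)
        return MixedModelResults(
            model=self, spec=self.spec, basis=self.dataset.basis,
            beta=beta, D=D, sigma=float(sigma), loglik=float(ll),
            vcov_beta=vcov_beta, theta=res.x, reml=reml, converged=bool(res.success),
        )


@dataclass
class MixedModelResults:
    """Fitted longitudinal submodel (beta, D, sigma, loglik, vcov_beta)."""

    model: MixedModel
    spec: LongitudinalSpec
    basis: SplineBasis | None
    beta: np.ndarray
    D: np.ndarray
    sigma: float
    loglik: float
    vcov_beta: np.ndarray
    theta: np.ndarray
    reml: bool = False
    converged: bool = True

    # -- empirical Bayes ----------------------------------------------------

    def eb_modes(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-unit posterior mode and covariance of the random effects."""
        m = self.model
        Dinv = np.linalg.inv(self.D)
        out = {}
        for uid, sl in zip(m.unit_ids, m._blocks()):
            Zi = m.Z[sl]
            r = m.y[sl] - m.X[sl] @ self.beta
            P = Zi.T @ Zi / self.sigma**2 + Dinv
            cov = np.linalg.inv(P)
            out[str(uid)] = (cov @ (Zi.T @ r) / self.sigma**2, cov)
        return out

    # -- trajectory and slope ----------------------------------------------

    def subject_trajectory(self, b, covs: dict | None, t, interventions=()):
        """m(t) = x(t)'beta + z(t)'b on the log-value scale."""
        covs = covs or {}
        x = self.spec.x_row(t, self.basis, covs, interventions)
        z = self.spec.z_row(t, self.basis, interventions)
        out = x @ self.beta + z @ np.asarray(b, dtype=float)
        return float(out[0]) if np.isscalar(t) else out

    def subject_slope(self, b, covs: dict | None, t, interventions=()):
        """Analytic time derivative m'(t) (log-value per month)."""
        covs = covs or {}
        x = self.spec.x_row(t, self.basis, covs, interventions, deriv=True)
        z = self.spec.z_row(t, self.basis, interventions, deriv=True)
        out = x @ self.beta + z @ np.asarray(b, dtype=float)
        return float(out[0]) if np.isscalar(t) else out

    # -- diagnostics --------------------------------------------------------

    def fitted_values(self) -> np.ndarray:
        m = self.model
        modes = self.eb_modes()
        fit = m.X @ self.beta
        for uid, sl in zip(m.unit_ids, m._blocks()):
            fit[sl] += m.Z[sl] @ modes[str(uid)][0]
        return fit

    def residual_diagnostics(self) -> dict:
        """Standardized conditional residuals, normal quantiles, fitted
        values, and a Shapiro-Wilk summary."""
        fitted = self.fitted_values()
        resid = self.model.y - fitted
        std = resid / self.sigma
        n = len(std)
        order = np.argsort(std)
        theo = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sw_stat, sw_p = stats.shapiro(std) if 3 <= n <= 5000 else (np.nan, np.nan)
        return {
            "fitted": fitted,
            "residuals": resid,
            "std_residuals": std,
            "qq_sample": std[order],
            "qq_theoretical": theo,
            "shapiro_stat": float(sw_stat),
            "shapiro_p": float(sw_p),
        }

    def summary(self) -> str:
        lines = [
            f"Linear mixed model ({'REML' if self.reml else 'ML'}) — "
            f"variant={self.spec.variant}, time={self.spec.time_structure}",
            f"log-likelihood: {self.loglik:.4f}   sigma: {self.sigma:.4f}",
            "fixed effects:",
        ]
        ses = np.sqrt(np.diag(self.vcov_beta))
        for name, b, se in zip(self.spec.fixed_names, self.beta, ses):
            lines.append(f"  {name:<24} {b: .4f}  (SE {se:.4f})")
        lines.append("random-effects covariance D:")
        for row in self.D:
            lines.append("  " + "  ".join(f"{v: .5f}" for v in row))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "variant": self.spec.variant,
            "time_structure": self.spec.time_structure,
            "fixed_names": list(self.spec.fixed_names),
            "beta": self.beta.tolist(),
            "D": self.D.tolist(),
            "sigma": self.sigma,
            "loglik": self.loglik,
            "reml": self.reml,
            "converged": self.converged,
        }


def fit_lmm(ds: AnalysisDataset, spec: LongitudinalSpec | None = None,
            reml: bool = False) -> MixedModelResults:
    """Convenience wrapper: build and fit the mixed model for a dataset."""
    return MixedModel(ds, spec).fit(reml=reml)
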