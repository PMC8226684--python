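"""Simulation studies validating the joint-model estimation machinery.

The study's printed hazard ratios cannot be recomputed without the original
23 patients' measurements, so the package validates its estimator the way a
methods paper would: by closure of the simulate -> build -> fit loop.

* :func:`alpha_recovery_study` — does the Wald 95% CI for the association
  cover the generating value at (about) its nominal rate?
* :func:`null_calibration_study` — with no true association, does the Wald
  test reject at (about) its nominal level?
* :func:`factorization_gap` — at alpha=0 the joint likelihood must equal
  independently fitted longitudinal and hazard likelihoods exactly.

All studies use linear-trajectory single-event scalings of the paper-like
generator with a random-intercept+slope longitudinal submodel and a Weibull
baseline (see docs/methods.md for the problem-size choices).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from . import data as dmod
from .joint import HazardSpec, JointModel
from .lmm import LongitudinalSpec, MixedModel
from .simulate import estimation_check_config, simulate_cohort

_STREAM = ("mid", "vf")
_LSPEC = LongitudinalSpec("basic", "linear", ())
_HSPEC = HazardSpec(baseline="weibull", covariates=(), association="value")


def _fit_one(n_units: int, alpha_true: float, seed: int, n_gh: int = 9):
    cfg = estimation_check_config(n_units, alpha_value=alpha_true, seed=seed)
    c = simulate_cohort(cfg).cohort
    ds = dmod.build_basic_dataset(c.patients, c.measurements, c.lesions, _STREAM)
    lres = MixedModel(ds, _LSPEC).fit()
    return JointModel(ds, _LSPEC, _HSPEC, n_gh=n_gh).fit(init=lres)


def alpha_recovery_study(
    n_units: int = 200,
    n_replicates: int = 25,
    alpha_true: float = -1.3,
    seed: int = 0,
    n_gh: int = 9,
) -> dict:
    """Coverage of the Wald 95% CI for the value association.

    Returns the per-replicate estimates and the fraction of replicates whose
    own CI covers ``alpha_true``.
    """
    covered, estimates = [], []
    for rep in range(n_replicates):
        res = _fit_one(n_units, alpha_true, seed=(seed * 1009 + rep) % 2**31,
                       n_gh=n_gh)
        lo, hi = res.alpha_ci()
        covered.append(lo <= alpha_true <= hi)
        estimates.append({"alpha": res.alpha, "se": res.se_alpha,
                          "ci": [lo, hi], "covered": bool(covered[-1])})
    return {
        "alpha_true": alpha_true,
        "n_units": n_units,
        "n_replicates": n_replicates,
        "coverage": float(np.mean(covered)),
        "estimates": estimates,
    }


def null_calibration_study(
    n_units: int = 100,
    n_replicates: int = 100,
    level: float = 0.05,
    seed: int = 0,
    n_gh: int = 9,
) -> dict:
    """Empirical size of the Wald test of no association (alpha_true = 0)."""
    rejected, pvals = [], []
    for rep in range(n_replicates):
        res = _fit_one(n_units, 0.0, seed=(seed * 2003 + rep) % 2**31, n_gh=n_gh)
        p = res.wald_p_alpha
        pvals.append(p)
        rejected.append(p < level)
    return {
        "n_units": n_units,
        "n_replicates": n_replicates,
        "level": level,
        "rejection_rate": float(np.mean(rejected)),
        "p_values": pvals,
    }


def factorization_gap(n_units: int = 60, seed: int = 5, n_gh: int = 9) -> float:
    """|joint loglik at alpha=0  -  (LMM loglik + hazard-only loglik)|.

    The hazard-only part is maximised independently over its own
    parameters; at alpha=0 the joint likelihood factorises exactly, so any
    gap measures quadrature/implementation error.
    """
    cfg = estimation_check_config(n_units, alpha_value=-1.3, seed=seed)
    c = simulate_cohort(cfg).cohort
    ds = dmod.build_basic_dataset(c.patients, c.measurements, c.lesions, _STREAM)
    lres = MixedModel(ds, _LSPEC).fit()
    jm = JointModel(ds, _LSPEC, _HSPEC, n_gh=n_gh)

    def nll_hz(v):
        out = -jm.hazard_loglik(np.zeros(0), v, 0.0,
                                np.zeros((jm.n_units, jm.q)), lres.beta)
        return out if np.isfinite(out) else 1e12

    r = optimize.minimize(nll_hz, jm._init_xi(), method="BFGS",
                          options={"gtol": 1e-9})
    params = jm.pack(lres.beta, lres.D, lres.sigma, np.zeros(0), r.x, 0.0)
    return float(abs(jm.loglik(params) - (lres.loglik - r.fun)))
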