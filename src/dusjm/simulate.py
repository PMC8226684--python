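"""Synthetic surveillance cohorts with the structure the analysis assumes.

The generator inverts the joint model: each patient gets random effects
b_i = (b0, b1) on a log-value trajectory

    m_i(t) = mu0 + b0 + (mu1 + b1) t + A (exp(-t/tau) - 1) + ln(rho) R_i(t)

(mu0 population log-value at baseline, mu1 monthly drift, A the amplitude of
the early post-procedural maturation transient, rho the value-restoration
factor of a reintervention and R_i(t) the number of reinterventions up to t).
Lesion (stenosis/occlusion) times are drawn by inverting the trajectory-
linked hazard

    h_i(t) = exp( xi0 + a_v (m_i(t) - mu0) + a_s m_i'(t) )

via the uniform / cumulative-hazard inversion with a bracketed root-find.
After each lesion a reintervention follows after a random delay, restoring
the trajectory level and resuming risk; lesion-free follow-up is right-
censored at the administrative horizon.  Visits follow the surveillance
schedule (every 2 weeks for 2 months, then 3, 6 and 12 months) with jitter
and missed visits; measured values add residual noise on the log scale.

Baseline covariates (age, sex, comorbidities) are drawn at the prevalences
of the study cohort; they do not enter the simulated hazard or trajectory.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import roots_legendre

from .data import (
    Cohort,
    DUSMeasurement,
    InterventionEvent,
    LesionEvent,
    PatientRecord,
)

_GL_X, _GL_W = roots_legendre(7)

#: comorbidity prevalences of the study cohort (23 patients)
COMORBIDITY_PREVALENCE = {
    "hypertension": 18 / 23,
    "diabetes": 16 / 23,
    "hyperlipidemia": 17 / 23,
    "cerebrovascular_accident": 4 / 23,
    "coronary_artery_disease": 7 / 23,
    "dialysis_dependent": 2 / 23,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 23
    seed: int = 42
    # visit schedule: every 2 weeks for 2 months, then 3/6/12 months
    visit_times: tuple = (0.5, 1.0, 1.5, 2.0, 3.0, 6.0, 12.0)
    visit_jitter_sd_days: float = 2.0
    missed_visit_prob: float = 0.12
    # trajectory (log mL/min for the default VF stream)
    intercept: float = 5.7
    slope: float = -0.12
    curvature: float = 0.4
    curvature_scale: float = 1.5  # months
    sd_intercept: float = 0.55
    sd_slope: float = 0.18
    corr_b: float = -0.2
    sigma_true: float = 0.25
    # hazard (log monthly rate at the reference trajectory)
    baseline_log_rate: float = -3.5
    alpha_value: float = -1.3
    alpha_slope: float = 0.0
    # reintervention
    reint_delay_range: tuple = (0.25, 1.0)
    restoration_factor: float = 1.3
    single_event: bool = False
    # censoring
    horizon: float = 12.0
    # covariates
    age_mean: float = 66.0
    age_sd: float = 13.0
    male_prob: float = 9 / 23
    baseline_reint_prob: float = 0.2
    # stream
    site: str = "mid"
    modality: str = "vf"

    def __post_init__(self):
        if self.sigma_true <= 0 or self.sd_intercept <= 0 or self.sd_slope <= 0:
            raise ValueError("all SDs must be positive")
        if not 0 <= self.missed_visit_prob <= 1:
            raise ValueError("missed_visit_prob must be in [0, 1]")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @property
    def D_true(self) -> np.ndarray:
        off = self.corr_b * self.sd_intercept * self.sd_slope
        return np.array([[self.sd_intercept**2, off], [off, self.sd_slope**2]])

    @property
    def association(self) -> str:
        if self.alpha_slope != 0 and self.alpha_value == 0:
            return "slope"
        if self.alpha_value != 0:
            return "value"
        return "none"

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


PRESETS = ("paper_like", "strong_slope", "null")


def preset(name: str) -> SimulationConfig:
    """Named study conditions.

    ``paper_like``: 23 patients, ~70% with at least one lesion, value
    association.  ``strong_slope``: hazard tied to the slope only.
    ``null``: no trajectory-hazard association.
    """
    if name == "paper_like":
        return SimulationConfig()
    if name == "strong_slope":
        return SimulationConfig(alpha_value=0.0, alpha_slope=-5.6,
                                baseline_log_rate=-3.0)
    if name == "null":
        return SimulationConfig(alpha_value=0.0, alpha_slope=0.0,
                                baseline_log_rate=-2.3)
    raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")


def estimation_check_config(n_patients: int, alpha_value: float = -1.3,
                            seed: int = 0) -> SimulationConfig:
    """paper_like scaled for estimation checks: linear trajectories
    (no maturation transient), one lesion per patient, n as given."""
    return SimulationConfig(
        n_patients=n_patients, seed=seed, curvature=0.0, single_event=True,
        alpha_value=alpha_value,
        baseline_log_rate=-3.5 if alpha_value != 0 else -2.3,
    )


# ---------------------------------------------------------------------------
# latent trajectory and hazard
# ---------------------------------------------------------------------------


def _traj(cfg: SimulationConfig, b, shifts, t):
    t = np.asarray(t, dtype=float)
    m = (cfg.intercept + b[0] + (cfg.slope + b[1]) * t
         + cfg.curvature * (np.exp(-t / cfg.curvature_scale) - 1.0))
    if shifts:
        m = m + np.log(cfg.restoration_factor) * np.searchsorted(
            np.asarray(shifts), t, side="right"
        )
    return m


def _slope(cfg: SimulationConfig, b, t):
    t = np.asarray(t, dtype=float)
    return (cfg.slope + b[1]
            - (cfg.curvature / cfg.curvature_scale) * np.exp(-t / cfg.curvature_scale))


def _hazard(cfg: SimulationConfig, b, shifts, t):
    t = np.asarray(t, dtype=float)
    lp = np.full(t.shape, cfg.baseline_log_rate)
    if cfg.alpha_value:
        lp = lp + cfg.alpha_value * (_traj(cfg, b, shifts, t) - cfg.intercept)
    if cfg.alpha_slope:
        lp = lp + cfg.alpha_slope * _slope(cfg, b, t)
    return np.exp(np.minimum(lp, 700.0))


def _cum_hazard_cells(cfg, b, shifts, start, stop, step=0.05):
    """Cell boundaries and per-cell Gauss-Legendre cumulative hazard."""
    cuts = [start] + [s for s in shifts if start < s < stop] + [stop]
    edges = [start]
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        n = max(int(np.ceil((hi - lo) / step)), 1)
        edges.extend(np.linspace(lo, hi, n + 1)[1:])
    edges = np.asarray(edges)
    mid = 0.5 * (edges[:-1] + edges[1:])
    half = 0.5 * np.diff(edges)
    s = mid[:, None] + half[:, None] * _GL_X[None, :]
    h = _hazard(cfg, b, shifts, s.ravel()).reshape(s.shape)
    cell = half * (h * _GL_W[None, :]).sum(axis=1)
    return edges, np.concatenate([[0.0], np.cumsum(cell)])


def event_time_oracle(cfg: SimulationConfig, b, covs, u: float,
                      start: float = 0.0, shifts=()) -> float | None:
    """Solve H(T) = -ln(u) for the event time T by bracketed root-finding
    on the integrated hazard (tolerance 1e-8 months); ``None`` marks
    censoring at the horizon."""
    if not 0.0 < u < 1.0:
        raise ValueError("u must be in (0, 1)")
    target = -np.log(u)
    edges, cumH = _cum_hazard_cells(cfg, b, list(shifts), start, cfg.horizon)
    if cumH[-1] < target:
        return None
    i = int(np.searchsorted(cumH, target))  # first edge with cumH >= target
    lo, hi = edges[i - 1], edges[i]
    base = cumH[i - 1]

    def f(t):
        if t <= lo:
            return base - target
        mid, half = 0.5 * (lo + t), 0.5 * (t - lo)
        s = mid + half * _GL_X
        return base + half * float(np.sum(_GL_W * _hazard(cfg, b, list(shifts), s))) \
            - target

    if f(hi) <= 0:  # numerical edge: target sits at the boundary
        return float(hi)
    return float(brentq(f, lo, hi, xtol=1e-8))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedCohort:
    cohort: Cohort
    truth: dict = field(default_factory=dict)


def _draw_covariates(rng, cfg, pid) -> PatientRecord:
    age = float(np.clip(rng.normal(cfg.age_mean, cfg.age_sd), 30.0, 95.0))
    sex = "male" if rng.random() < cfg.male_prob else "female"
    com = {k: bool(rng.random() < p) for k, p in COMORBIDITY_PREVALENCE.items()}
    return PatientRecord(
        patient_id=pid, age=age, sex=sex,
        baseline_reintervention=bool(rng.random() < cfg.baseline_reint_prob),
        censor_time=cfg.horizon, comorbidities=com,
    )


def simulate_cohort(cfg: SimulationConfig, seed: int | None = None
                    ) -> SimulatedCohort:
    """Draw one cohort; bit-identical under a fixed config and seed."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    patients, measurements, lesions, interventions = [], [], [], []
    b_all, event_log = {}, []

    for j in range(cfg.n_patients):
        pid = f"P{j + 1:03d}"
        rec = _draw_covariates(rng, cfg, pid)
        patients.append(rec)
        b = rng.multivariate_normal(np.zeros(2), cfg.D_true)
        b_all[pid] = b.tolist()

        shifts: list[float] = []
        start = 0.0
        while True:
            u = float(rng.uniform())
            T = event_time_oracle(cfg, b, {}, u, start=start, shifts=shifts)
            if T is None:
                break
            lesions.append(LesionEvent(pid, T))
            event_log.append({"patient": pid, "lesion": T, "risk_start": start})
            if cfg.single_event:
                break
            delay = float(rng.uniform(*cfg.reint_delay_range))
            rt = T + delay
            if rt >= cfg.horizon:
                break
            interventions.append(InterventionEvent(pid, rt))
            shifts.append(rt)
            start = rt

        # surveillance visits
        jitter = rng.normal(0.0, cfg.visit_jitter_sd_days / 30.4375,
                            size=len(cfg.visit_times))
        missed = rng.random(len(cfg.visit_times)) < cfg.missed_visit_prob
        for v, dj, miss in zip(cfg.visit_times, jitter, missed):
            t = v + dj
            if miss or not 0.0 < t <= cfg.horizon:
                continue
            y = _traj(cfg, b, shifts, t) + rng.normal(0.0, cfg.sigma_true)
            measurements.append(
                DUSMeasurement(pid, float(t), cfg.site, cfg.modality,
                               float(np.exp(y)))
            )

    cohort = Cohort(patients, sorted(measurements, key=lambda m: (m.patient_id, m.time)),
                    sorted(lesions, key=lambda e: (e.patient_id, e.time)),
                    sorted(interventions, key=lambda e: (e.patient_id, e.time)))
    truth = {
        "config": dataclasses.asdict(cfg),
        "b": b_all,
        "events": event_log,
    }
    return SimulatedCohort(cohort=cohort, truth=truth)


def simulate_multistream(cfg: SimulationConfig, seed: int | None = None,
                         cross_stream_corr: float = 0.7) -> SimulatedCohort:
    """All four site x modality streams sharing one event process.

    Stream-specific random effects are correlated across streams by drawing
    b_stream = sqrt(c) b_shared + sqrt(1-c) b_own; PSV streams are placed on
    the log cm/s scale.  The hazard is driven by the primary stream of
    ``cfg`` (default mid-stent VF), matching a surveillance cohort where the
    four streams reflect the same underlying circuit patency.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    base = simulate_cohort(cfg, seed=int(rng.integers(2**31 - 1)))
    cohort = base.cohort
    intercepts = {"psv": 4.1, "vf": cfg.intercept}
    extra: list[DUSMeasurement] = []
    shifts_by_pid = {}
    for iv in cohort.interventions:
        shifts_by_pid.setdefault(iv.patient_id, []).append(iv.time)
    c = float(cross_stream_corr)
    for site in ("mid", "distal"):
        for modality in ("psv", "vf"):
            if (site, modality) == (cfg.site, cfg.modality):
                continue
            scfg = cfg.replace(site=site, modality=modality,
                               intercept=intercepts[modality])
            for pid, b_shared in base.truth["b"].items():
                b_own = rng.multivariate_normal(np.zeros(2), cfg.D_true)
                b = np.sqrt(c) * np.asarray(b_shared) + np.sqrt(1 - c) * b_own
                shifts = shifts_by_pid.get(pid, [])
                for m in cohort.measurements:
                    if m.patient_id != pid or (m.site, m.modality) != (cfg.site,
                                                                       cfg.modality):
                        continue
                    y = _traj(scfg, b, shifts, m.time) + rng.normal(0, cfg.sigma_true)
                    extra.append(DUSMeasurement(pid, m.time, site, modality,
                                                float(np.exp(y))))
    cohort.measurements = sorted(
        cohort.measurements + extra,
        key=lambda m: (m.patient_id, m.time, m.modality, m.site),
    )
    return SimulatedCohort(cohort=cohort, truth=base.truth)
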