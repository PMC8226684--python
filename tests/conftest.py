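import numpy as np
import pandas as pd
import pytest

from dusjm import data as dmod
from dusjm.data import AnalysisDataset
from dusjm.joint import HazardSpec, JointModel
from dusjm.lmm import LongitudinalSpec, MixedModel
from dusjm.simulate import estimation_check_config, preset, simulate_cohort

STREAM = ("mid", "vf")


@pytest.fixture(scope="session")
def paper_cohort():
    """Default study-sized cohort (23 patients, value association)."""
    return simulate_cohort(preset("paper_like")).cohort


@pytest.fixture(scope="session")
def basic_ds(paper_cohort):
    c = paper_cohort
    return dmod.build_basic_dataset(c.patients, c.measurements, c.lesions, STREAM)


@pytest.fixture(scope="session")
def reint_ds(paper_cohort):
    c = paper_cohort
    return dmod.build_reintervention_dataset(
        c.patients, c.measurements, c.lesions, c.interventions, STREAM)


@pytest.fixture(scope="session")
def series_ds(paper_cohort):
    c = paper_cohort
    return dmod.build_series_dataset(
        c.patients, c.measurements, c.lesions, c.interventions, STREAM)


@pytest.fixture(scope="session")
def linear_spec():
    return LongitudinalSpec("basic", "linear", ())


@pytest.fixture(scope="session")
def toy_cohort():
    """Linear-trajectory single-event cohort for joint-model checks."""
    return simulate_cohort(estimation_check_config(60, seed=5)).cohort


@pytest.fixture(scope="session")
def toy_ds(toy_cohort):
    c = toy_cohort
    return dmod.build_basic_dataset(c.patients, c.measurements, c.lesions, STREAM)


@pytest.fixture(scope="session")
def toy_lmm(toy_ds, linear_spec):
    return MixedModel(toy_ds, linear_spec).fit()


@pytest.fixture(scope="session")
def toy_joint(toy_ds, linear_spec, toy_lmm):
    """Fitted Weibull-baseline value-association joint model (60 units)."""
    model = JointModel(toy_ds, linear_spec,
                       HazardSpec(baseline="weibull", association="value"),
                       n_gh=9)
    return model.fit(init=toy_lmm)


def make_patient(pid="P1", age=65.0, sex="female", breint=False, censor=12.0,
                 **comorbidities):
    return dmod.PatientRecord(pid, age, sex, breint, censor,
                              comorbidities=comorbidities)


def make_measurements(pid, times, values, site="mid", modality="vf"):
    return [dmod.DUSMeasurement(pid, t, site, modality, v)
            for t, v in zip(times, values)]


def simple_long_dataset(y_by_unit, times_by_unit, variant="per_series",
                        stop=12.0, events=None):
    """Hand-built AnalysisDataset from per-unit series (no covariates)."""
    rows, surv = [], []
    for k, (uid, ys) in enumerate(sorted(y_by_unit.items())):
        ts = times_by_unit[uid]
        for t, y in zip(ts, ys):
            rows.append({"unit_id": uid, "patient_id": uid, "time": float(t),
                         "log_value": float(y)})
        surv.append({"unit_id": uid, "start": 0.0, "stop": float(stop),
                     "event": bool(events[uid]) if events else False})
    long = pd.DataFrame(rows)
    basis = None
    try:
        from dusjm.splines import make_ncs_basis
        basis = make_ncs_basis(long["time"].values)
    except Exception:
        basis = None
    ds = AnalysisDataset(variant, STREAM, long, pd.DataFrame(surv), basis)
    ds.validate()
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
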