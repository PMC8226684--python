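"""Domain types, long-format I/O and construction of the analysis datasets.

The surveillance data are long-format duplex-ultrasound (DUS) measurements —
peak systolic velocity (PSV, cm/s) and volume flow (VF, mL/min) at the mid
and distal stent segments — together with per-patient baseline covariates,
stenosis/occlusion (lesion) events and reintervention times.  Three analysis
datasets are built from one measurement stream:

* ``basic`` — one survival unit per patient, time to the first lesion,
  longitudinal model adjusted for age, sex and reintervention at baseline,
  natural-spline time.
* ``reintervention`` — recurrent lesions as counting-process intervals with
  risk suspended between a lesion and the following reintervention; the
  longitudinal model gains time-since-reintervention as a time-varying
  covariate and uses linear time.
* ``per_series`` — every inter-reintervention span is an independent unit
  with its own clock starting at zero and no subject-level covariates.

Times are in months since the index procedure; 1 month = 30.4375 days.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .splines import SplineBasis, make_ncs_basis

MONTH_DAYS = 30.4375

SITES = ("mid", "distal")
MODALITIES = ("psv", "vf")
#: the four analysed measurement streams
STREAMS = tuple((s, m) for m in MODALITIES for s in SITES)

COMORBIDITY_FLAGS = (
    "hypertension",
    "diabetes",
    "hyperlipidemia",
    "cerebrovascular_accident",
    "coronary_artery_disease",
    "dialysis_dependent",
)


class SchemaError(ValueError):
    """A required column is missing or a schema entry is unusable."""


class ValidationError(ValueError):
    """A row violates a domain invariant (e.g. non-positive DUS value)."""


def days_to_months(days: float) -> float:
    """Convert days since procedure to months (1 month = 30.4375 days)."""
    days = float(days)
    if days < 0:
        raise ValidationError(f"negative time in days: {days}")
    return days / MONTH_DAYS


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    age: float
    sex: str  # "male" | "female"
    baseline_reintervention: bool
    censor_time: float  # months; last follow-up contact for lesion-free patients
    site_of_care: str | None = None
    comorbidities: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.age <= 0:
            raise ValidationError(f"{self.patient_id}: age must be > 0, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"{self.patient_id}: unknown sex {self.sex!r}")
        if self.censor_time < 0:
            raise ValidationError(
                f"{self.patient_id}: censor_time must be >= 0, got {self.censor_time}"
            )


@dataclass(frozen=True)
class DUSMeasurement:
    patient_id: str
    time: float  # months since procedure
    site: str  # "mid" | "distal"
    modality: str  # "psv" | "vf"
    value: float  # cm/s for PSV, mL/min for VF; must be positive (log scale)

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError(f"{self.patient_id}: negative time {self.time}")
        if self.site not in SITES:
            raise ValidationError(f"{self.patient_id}: unknown site {self.site!r}")
        if self.modality not in MODALITIES:
            raise ValidationError(
                f"{self.patient_id}: unknown modality {self.modality!r}"
            )
        if not self.value > 0:
            raise ValidationError(
                f"{self.patient_id} t={self.time}: DUS value must be positive "
                f"(log transform), got {self.value}"
            )


@dataclass(frozen=True)
class LesionEvent:
    patient_id: str
    time: float  # months
    kind: str = "stenosis"  # "stenosis" | "occlusion"

    def __post_init__(self):
        if not self.time > 0:
            raise ValidationError(
                f"{self.patient_id}: lesion time must be > 0, got {self.time}"
            )
        if self.kind not in ("stenosis", "occlusion"):
            raise ValidationError(f"{self.patient_id}: unknown lesion kind {self.kind!r}")


@dataclass(frozen=True)
class InterventionEvent:
    patient_id: str
    time: float  # months

    def __post_init__(self):
        if self.time < 0:
            raise ValidationError(
                f"{self.patient_id}: intervention time must be >= 0, got {self.time}"
            )


@dataclass
class SurvivalRecord:
    """Counting-process risk interval (start, stop] for one unit."""

    unit_id: str
    start: float
    stop: float
    event: bool
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.start < self.stop):
            raise ValidationError(
                f"{self.unit_id}: need 0 <= start < stop, got ({self.start}, {self.stop}]"
            )


# ---------------------------------------------------------------------------
# cohort container and I/O
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {
    "patient_id": "patient_id",
    "time": "time",
    "time_unit": "months",  # "months" | "days" | name of a per-row unit column
    "site": "site",
    "modality": "modality",
    "value": "value",
    # wide format: map value column name -> (site, modality); overrides
    # site/modality/value columns when given
    "value_columns": None,
}


def _as_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer, float, np.floating)):
        return bool(int(x))
    s = str(x).strip().lower()
    if s in ("1", "true", "t", "yes", "y"):
        return True
    if s in ("0", "false", "f", "no", "n", ""):
        return False
    raise ValidationError(f"cannot parse boolean value {x!r}")


def _require(df: pd.DataFrame, cols, what: str):
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def load_measurements(path, schema: dict | None = None) -> list[DUSMeasurement]:
    """Parse the long-format (or schema-mapped wide) measurement CSV."""
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, [sch["patient_id"], sch["time"]], "measurements")

    unit = sch["time_unit"]
    if unit in df.columns:  # per-row unit column
        units = df[unit].astype(str).str.lower()
    elif unit in ("days", "months"):
        units = pd.Series([unit] * len(df))
    else:
        raise SchemaError(f"measurements: unknown time_unit {unit!r}")

    out: list[DUSMeasurement] = []
    for i, row in df.reset_index(drop=True).iterrows():
        t = float(row[sch["time"]])
        if str(units.iloc[i]) == "days":
            t = days_to_months(t)
        pid = str(row[sch["patient_id"]])
        try:
            if sch["value_columns"]:
                for col, (site, modality) in sch["value_columns"].items():
                    if col not in df.columns:
                        raise SchemaError(f"measurements: missing value column {col!r}")
                    v = row[col]
                    if pd.isna(v):
                        continue
                    out.append(DUSMeasurement(pid, t, site, modality, float(v)))
            else:
                _require(df, [sch["site"], sch["modality"], sch["value"]], "measurements")
                out.append(
                    DUSMeasurement(
                        pid,
                        t,
                        str(row[sch["site"]]).lower(),
                        str(row[sch["modality"]]).lower(),
                        float(row[sch["value"]]),
                    )
                )
        except ValidationError as e:
            raise ValidationError(f"measurements row {i}: {e}") from e
    return out


def load_patients(path) -> list[PatientRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ["patient_id", "age", "sex", "baseline_reintervention", "censor_time"],
             "patients")
    out = []
    for i, row in df.reset_index(drop=True).iterrows():
        com = {
            k: _as_bool(row[k]) for k in COMORBIDITY_FLAGS if k in df.columns
        }
        try:
            out.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]).lower(),
                    baseline_reintervention=_as_bool(row["baseline_reintervention"]),
                    censor_time=float(row["censor_time"]),
                    site_of_care=(
                        str(row["site_of_care"])
                        if "site_of_care" in df.columns
                        and not pd.isna(row["site_of_care"])
                        and str(row["site_of_care"]) != "" else None
                    ),
                    comorbidities=com,
                )
            )
        except ValidationError as e:
            raise ValidationError(f"patients row {i}: {e}") from e
    ids = [p.patient_id for p in out]
    if len(set(ids)) != len(ids):
        raise ValidationError("patients: duplicate patient_id")
    return out


def load_lesions(path) -> list[LesionEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ["patient_id", "time"], "lesions")
    out = [
        LesionEvent(
            str(r["patient_id"]), float(r["time"]),
            str(r["kind"]) if "kind" in df.columns else "stenosis",
        )
        for _, r in df.iterrows()
    ]
    _check_ordered(out)
    return out


def load_interventions(path) -> list[InterventionEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require(df, ["patient_id", "time"], "interventions")
    return [
        InterventionEvent(str(r["patient_id"]), float(r["time"]))
        for _, r in df.iterrows()
    ]


def _check_ordered(lesions: list[LesionEvent]):
    by = {}
    for e in lesions:
        by.setdefault(e.patient_id, []).append(e.time)
    for pid, ts in by.items():
        if len(set(ts)) != len(ts):
            raise ValidationError(f"{pid}: lesion times must be strictly ordered")


@dataclass
class Cohort:
    """The four long-format tables of one surveillance cohort."""

    patients: list[PatientRecord]
    measurements: list[DUSMeasurement]
    lesions: list[LesionEvent]
    interventions: list[InterventionEvent]

    def stream(self, site: str, modality: str) -> list[DUSMeasurement]:
        return [m for m in self.measurements if m.site == site and m.modality == modality]

    def frames(self) -> dict[str, pd.DataFrame]:
        pats = pd.DataFrame(
            [
                {
                    "patient_id": p.patient_id,
                    "age": p.age,
                    "sex": p.sex,
                    "baseline_reintervention": int(p.baseline_reintervention),
                    "censor_time": p.censor_time,
                    "site_of_care": p.site_of_care or "",
                    **{k: int(p.comorbidities.get(k, False)) for k in COMORBIDITY_FLAGS},
                }
                for p in self.patients
            ]
        )
        meas = pd.DataFrame(
            [
                {
                    "patient_id": m.patient_id,
                    "time": m.time,
                    "time_unit": "months",
                    "site": m.site,
                    "modality": m.modality,
                    "value": m.value,
                }
                for m in self.measurements
            ]
        )
        les = pd.DataFrame(
            [{"patient_id": e.patient_id, "time": e.time, "kind": e.kind}
             for e in self.lesions]
        )
        ints = pd.DataFrame(
            [{"patient_id": e.patient_id, "time": e.time} for e in self.interventions]
        )
        return {"patients": pats, "measurements": meas, "lesions": les,
                "interventions": ints}

    def write(self, directory) -> dict[str, Path]:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in self.frames().items():
            p = d / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths

    @classmethod
    def read(cls, directory, schema: dict | None = None) -> "Cohort":
        d = Path(directory)
        les = d / "lesions.csv"
        ints = d / "interventions.csv"
        return cls(
            patients=load_patients(d / "patients.csv"),
            measurements=load_measurements(d / "measurements.csv", schema),
            lesions=load_lesions(les) if les.exists() else [],
            interventions=load_interventions(ints) if ints.exists() else [],
        )


def load_long_table(
    measurements_path, patients_path, lesions_path=None, interventions_path=None,
    schema: dict | None = None,
) -> Cohort:
    """Load a cohort from its component CSVs (see :class:`Cohort`)."""
    return Cohort(
        patients=load_patients(patients_path),
        measurements=load_measurements(measurements_path, schema),
        lesions=load_lesions(lesions_path) if lesions_path else [],
        interventions=load_interventions(interventions_path) if interventions_path else [],
    )


# ---------------------------------------------------------------------------
# analysis datasets
# ---------------------------------------------------------------------------

BASELINE_COVARIATES = ("age", "sex_male", "baseline_reintervention")


@dataclass
class AnalysisDataset:
    """Paired longitudinal table and counting-process survival table.

    ``long`` columns: unit_id, patient_id, time (unit clock, months),
    log_value, plus covariates (and ``time_since_reint`` for the
    reintervention variant).  ``survival`` columns: unit_id, start, stop,
    event, plus covariates.  ``basis`` is the natural-spline time basis
    (``None`` for the reintervention variant, which uses linear time).
    """

    variant: str  # "basic" | "reintervention" | "per_series"
    stream: tuple[str, str]
    long: pd.DataFrame
    survival: pd.DataFrame
    basis: SplineBasis | None
    unit_interventions: dict[str, tuple[float, ...]] = field(default_factory=dict)
    unit_covariates: dict[str, dict] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(BASELINE_COVARIATES) if self.variant in ("basic", "reintervention") else ()

    @property
    def units(self) -> list[str]:
        return list(self.survival["unit_id"].drop_duplicates())

    def validate(self) -> None:
        surv_units = set(self.survival["unit_id"])
        long_units = set(self.long["unit_id"])
        if not long_units <= surv_units:
            raise ValidationError(
                f"longitudinal units without survival rows: {sorted(long_units - surv_units)}"
            )
        last_stop = self.survival.groupby("unit_id")["stop"].max()
        for uid, g in self.long.groupby("unit_id"):
            if g["time"].max() > last_stop[uid] + 1e-9:
                raise ValidationError(
                    f"{uid}: longitudinal time beyond last risk interval stop"
                )
        for uid, g in self.survival.groupby("unit_id"):
            g = g.sort_values("start")
            if (g["start"].values[1:] < g["stop"].values[:-1] - 1e-9).any():
                raise ValidationError(f"{uid}: overlapping risk intervals")
        if self.basis is not None:
            lo, hi = self.basis.boundary_knots
            for k in self.basis.interior_knots:
                if not lo < k < hi:
                    raise ValidationError("interior knot outside boundary knots")

    # -- serialization ------------------------------------------------------

    def write(self, directory, prefix: str | None = None) -> dict[str, Path]:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        prefix = prefix or f"{self.variant}_{self.stream[1]}_{self.stream[0]}"
        paths = {
            "longitudinal": d / f"{prefix}_long.csv",
            "survival": d / f"{prefix}_survival.csv",
            "meta": d / f"{prefix}_meta.json",
        }
        self.long.to_csv(paths["longitudinal"], index=False)
        self.survival.to_csv(paths["survival"], index=False)
        meta = {
            "variant": self.variant,
            "stream": list(self.stream),
            "interior_knots": list(self.basis.interior_knots) if self.basis else None,
            "boundary_knots": list(self.basis.boundary_knots) if self.basis else None,
            "unit_interventions": {k: list(v) for k, v in self.unit_interventions.items()},
            "unit_covariates": self.unit_covariates,
            "log": self.log,
        }
        paths["meta"].write_text(json.dumps(meta, indent=1, sort_keys=True))
        return paths

    @classmethod
    def read(cls, directory, prefix: str) -> "AnalysisDataset":
        d = Path(directory)
        meta = json.loads((d / f"{prefix}_meta.json").read_text())
        basis = None
        if meta["interior_knots"] is not None:
            basis = SplineBasis(
                tuple(meta["interior_knots"]), tuple(meta["boundary_knots"])
            )
        ds = cls(
            variant=meta["variant"],
            stream=tuple(meta["stream"]),
            long=pd.read_csv(d / f"{prefix}_long.csv", float_precision="round_trip"),
            survival=pd.read_csv(d / f"{prefix}_survival.csv", float_precision="round_trip"),
            basis=basis,
            unit_interventions={k: tuple(v) for k, v in meta["unit_interventions"].items()},
            unit_covariates=meta["unit_covariates"],
            log=list(meta["log"]),
        )
        ds.survival["event"] = ds.survival["event"].astype(bool)
        ds.long["unit_id"] = ds.long["unit_id"].astype(str)
        ds.survival["unit_id"] = ds.survival["unit_id"].astype(str)
        ds.validate()
        return ds


def _covariate_row(p: PatientRecord) -> dict:
    return {
        "age": p.age,
        "sex_male": 1.0 if p.sex == "male" else 0.0,
        "baseline_reintervention": 1.0 if p.baseline_reintervention else 0.0,
    }


def _by_patient(events, censor: dict[str, float], what: str):
    out: dict[str, list[float]] = {}
    for e in events:
        if e.patient_id not in censor:
            raise ValidationError(f"{what} for unknown patient {e.patient_id}")
        if e.time > censor[e.patient_id] + 1e-9:
            raise ValidationError(
                f"{e.patient_id}: {what} at {e.time} after censor_time "
                f"{censor[e.patient_id]}"
            )
        out.setdefault(e.patient_id, []).append(e.time)
    return {k: sorted(v) for k, v in out.items()}


def time_since_reintervention(t, interventions) -> float:
    """t minus the time of the last intervention at or before t; 0 before any."""
    prior = [i for i in interventions if i <= t]
    return float(t - max(prior)) if prior else 0.0


def build_basic_dataset(records, measurements, lesions, stream) -> AnalysisDataset:
    """Time to first lesion; spline time; adjusted for age/sex/baseline reint."""
    site, modality = stream
    censor = {p.patient_id: p.censor_time for p in records}
    les = _by_patient(lesions, censor, "lesion")
    log: list[str] = []

    long_rows, surv_rows, unit_covs = [], [], {}
    for p in records:
        T = min(les.get(p.patient_id, [np.inf])[0], p.censor_time)
        event = bool(les.get(p.patient_id)) and les[p.patient_id][0] <= p.censor_time
        if T <= 0:
            log.append(f"{p.patient_id}: zero follow-up, unit dropped")
            continue
        covs = _covariate_row(p)
        unit_covs[p.patient_id] = covs
        surv_rows.append(
            {"unit_id": p.patient_id, "start": 0.0, "stop": T, "event": event, **covs}
        )
        n_obs = 0
        for m in measurements:
            if m.patient_id == p.patient_id and m.site == site and m.modality == modality:
                if m.time <= T + 1e-9:  # closed right endpoint at the event
                    long_rows.append(
                        {
                            "unit_id": p.patient_id,
                            "patient_id": p.patient_id,
                            "time": min(m.time, T),
                            "log_value": float(np.log(m.value)),
                            **covs,
                        }
                    )
                    n_obs += 1
        if n_obs == 0:
            log.append(f"{p.patient_id}: no measurement before first event/censoring; "
                       "unit retained with empty longitudinal history")

    long = pd.DataFrame(long_rows)
    if len(long) == 0:
        raise ValidationError(f"no measurements for stream {stream}")
    basis = make_ncs_basis(long["time"].values)
    ds = AnalysisDataset(
        variant="basic", stream=tuple(stream), long=long,
        survival=pd.DataFrame(surv_rows), basis=basis,
        unit_covariates=unit_covs, log=log,
    )
    ds.validate()
    return ds


def build_reintervention_dataset(
    records, measurements, lesions, interventions, stream
) -> AnalysisDataset:
    """Recurrent lesions; risk suspended between a lesion and the next
    reintervention; linear time plus time-since-reintervention covariate."""
    site, modality = stream
    censor = {p.patient_id: p.censor_time for p in records}
    les = _by_patient(lesions, censor, "lesion")
    ints = _by_patient(interventions, censor, "intervention")
    log: list[str] = []

    long_rows, surv_rows = [], []
    unit_covs, unit_ints = {}, {}
    for p in records:
        covs = _covariate_row(p)
        pid = p.patient_id
        p_les = les.get(pid, [])
        p_ints = ints.get(pid, [])
        unit_covs[pid] = covs
        unit_ints[pid] = tuple(p_ints)

        intervals = []
        risk_start = 0.0
        for L in p_les:
            if risk_start is None:
                log.append(f"{pid}: lesion at {L} while off risk (no prior "
                           "reintervention); ignored in survival table")
                continue
            if L <= risk_start + 1e-12:
                log.append(f"{pid}: lesion at {L} coincides with risk start; dropped")
            else:
                intervals.append((risk_start, L, True))
            nxt = [i for i in p_ints if i >= L]
            risk_start = nxt[0] if nxt else None
        if risk_start is not None and risk_start < p.censor_time - 1e-12:
            intervals.append((risk_start, p.censor_time, False))
        if not intervals:
            log.append(f"{pid}: no risk interval, unit dropped")
            continue

        for (a, b, ev) in intervals:
            surv_rows.append(
                {"unit_id": pid, "start": a, "stop": b, "event": ev, **covs}
            )
        last_stop = intervals[-1][1]
        for m in measurements:
            if m.patient_id == pid and m.site == site and m.modality == modality:
                if m.time <= last_stop + 1e-9:
                    t = min(m.time, last_stop)
                    long_rows.append(
                        {
                            "unit_id": pid,
                            "patient_id": pid,
                            "time": t,
                            "log_value": float(np.log(m.value)),
                            "time_since_reint": time_since_reintervention(t, p_ints),
                            **covs,
                        }
                    )

    long = pd.DataFrame(long_rows)
    if len(long) == 0:
        raise ValidationError(f"no measurements for stream {stream}")
    ds = AnalysisDataset(
        variant="reintervention", stream=tuple(stream), long=long,
        survival=pd.DataFrame(surv_rows), basis=None,
        unit_interventions=unit_ints, unit_covariates=unit_covs, log=log,
    )
    ds.validate()
    return ds


def build_series_dataset(
    records, measurements, lesions, interventions, stream
) -> AnalysisDataset:
    """Independent inter-reintervention series, each on its own clock from 0,
    no subject-level covariates."""
    site, modality = stream
    censor = {p.patient_id: p.censor_time for p in records}
    les = _by_patient(lesions, censor, "lesion")
    ints = _by_patient(interventions, censor, "intervention")
    log: list[str] = []

    long_rows, surv_rows = [], []
    for p in records:
        pid = p.patient_id
        p_les = les.get(pid, [])
        p_ints = [i for i in ints.get(pid, []) if i < p.censor_time - 1e-12]
        starts = [0.0] + p_ints
        bounds = p_ints + [p.censor_time]
        p_meas = sorted(
            (m for m in measurements
             if m.patient_id == pid and m.site == site and m.modality == modality),
            key=lambda m: m.time,
        )
        # assign each measurement to the series whose clock it falls in; a
        # measurement taken exactly at a reintervention opens the new series
        assigned: dict[int, list[DUSMeasurement]] = {k: [] for k in range(len(starts))}
        for m in p_meas:
            k = int(np.searchsorted(np.asarray(starts), m.time + 1e-12) - 1)
            assigned[max(k, 0)].append(m)

        for k, (s, nxt) in enumerate(zip(starts, bounds)):
            uid = f"{pid}#s{k}"
            in_series = [L for L in p_les if s < L <= nxt + 1e-12]
            if in_series:
                end_abs, event = in_series[0], True
            else:
                end_abs, event = nxt, False
            if end_abs <= s + 1e-12:
                log.append(f"{uid}: zero-length series dropped")
                continue
            # closed right endpoint at the lesion; measurements between a
            # terminal lesion and the next reintervention precede re-treatment
            # and belong to no risk series
            rows = [m for m in assigned[k] if m.time <= end_abs + 1e-12]
            for m in assigned[k]:
                if m.time > end_abs + 1e-12:
                    log.append(
                        f"{uid}: measurement at {m.time} between lesion ({end_abs}) "
                        "and next series boundary dropped"
                    )
            if not rows:
                log.append(f"{uid}: series with no measurement dropped")
                continue
            surv_rows.append(
                {"unit_id": uid, "start": 0.0, "stop": end_abs - s, "event": event}
            )
            for m in rows:
                long_rows.append(
                    {
                        "unit_id": uid,
                        "patient_id": pid,
                        "time": min(m.time, end_abs) - s,
                        "log_value": float(np.log(m.value)),
                    }
                )

    long = pd.DataFrame(long_rows)
    if len(long) == 0:
        raise ValidationError(f"no measurements for stream {stream}")
    basis = make_ncs_basis(long["time"].values)
    ds = AnalysisDataset(
        variant="per_series", stream=tuple(stream), long=long,
        survival=pd.DataFrame(surv_rows), basis=basis, log=log,
    )
    ds.validate()
    return ds
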