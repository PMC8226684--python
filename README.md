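# dusjm — joint models for duplex surveillance after deep venous arterialization

Patients who receive a percutaneous deep venous arterialization (pDVA) for
no-option chronic limb-threatening ischemia must currently return to the
clinic every two weeks, because the arterialized circuit can silently
develop a stenosis or occlusion at any time.  Each visit produces duplex
ultrasound (DUS) measurements — peak systolic velocity (PSV, cm/s) and
volume flow (VF, mL/min) at the mid and distal stented vein — and the
question that decides the next visit is always the same: *given this
patient's measurements so far, how likely is the circuit to stay open?*

`dusjm` answers that question with shared-random-effects joint models for
vascular surgeons, surveillance programme designers and biostatisticians
working with repeated DUS (or comparable graft-surveillance) series.  It
couples

* a **linear mixed-effects submodel** for the log-transformed values,
  `y_ij = x(t_ij)'β + z(t_ij)'b_i + e_ij`, with natural-cubic-spline or
  linear time, and
* a **relative-risk submodel** for lesion events,
  `h_i(t|b_i) = h0(t) exp(γ'w_i + α f_i(t|b_i))`,

linked through the *current value* `f = m_i(t)` or *current slope*
`f = m_i'(t)` of the subject-specific trajectory.  Estimation is joint
maximum likelihood (adaptive Gauss–Hermite quadrature over `b_i`,
Gauss–Kronrod cumulative hazards).  Associations are reported as hazard
ratios per 20% decrease of the measured value, `HR = 0.8^(−a)` for the
coefficient `a` per unit decrease of the log value — e.g. HR 1.34 means a
34% higher lesion hazard whenever the value sits 20% lower.  From a fitted
model, dynamic predictions give each patient a lesion-free probability
curve `π(u|t)` that updates with every new measurement.

Reinterventions (repeat endovascular treatments that restore values) are
handled three ways, fitted as separate model variants: `basic` (time to
first lesion), `reintervention` (recurrent events, time-since-
reintervention as a time-varying covariate) and `per_series`
(inter-reintervention spans as independent series).  A synthetic-cohort
generator with known ground truth, exact baseline descriptives (Fisher,
Mann–Whitney, median/IQR) and a CLI complete the package.

## Worked example

```python
import numpy as np
from dusjm import (preset, simulate_cohort, build_basic_dataset,
                   JointModel, HazardSpec, SubjectHistory,
                   predict_lesion_free)

cohort = simulate_cohort(preset("paper_like"), seed=42).cohort
ds = build_basic_dataset(cohort.patients, cohort.measurements,
                         cohort.lesions, ("mid", "vf"))
res = JointModel(ds, hazard_spec=HazardSpec(association="value"),
                 n_gh=5).fit()
print(res.summary())
```

prints (abridged):

```
Joint model — variant=basic, stream=('mid', 'vf'), association=value, baseline=piecewise
units: 23  events: 18  log-likelihood: -94.0572
alpha: -1.2764  (SE 0.3874, p 0.0010)
HR per 20% decrease: 1.33 (1.12–1.58)
sigma: 0.2444
```

The generating association was α = −1.3 (HR 1.34 per 20% decrease); the
fit on this 23-patient cohort recovers it: every 20% drop in mid-stent
volume flow carries a 1.33-fold (95% CI 1.12–1.58) higher hazard of
stenosis or occlusion.  Updating a patient-specific prediction:

```python
covs = {"age": 65.0, "sex_male": 0.0, "baseline_reintervention": 0.0}
hist = SubjectHistory(covariates=covs, measurements=((0.6, 5.7),), t=0.6)
grid = np.arange(0.6, 15.01, 0.25)
print(predict_lesion_free(res, hist, grid).pi[-1])   # pi(15 | 0.6) -> 0.275
```

A single low early measurement (log VF 5.7) gives a 15-month lesion-free
probability of 0.275; after appending a reassuring follow-up value with
`hist.updated(2.7, 6.7)` the curve is recomputed and the probability
rises to 0.771 — the behaviour that lets a surveillance programme stretch
visit intervals for low-risk patients and tighten them for high-risk
ones.

The same pipeline runs from the shell:

```sh
dusjm report --preset paper_like --seed 42 --out out/
dusjm table1 --patients out/patients.csv --lesions out/lesions.csv --out t1.csv
dusjm fit --data out/ --variant reintervention --association slope --out fit.json
dusjm predict --data out/ --fit fit.json --patient P003 --mc 500 --out pred.csv
```

`report` writes the cohort tables, baseline descriptives, outcome-group
trend curves with 95% bands, joint fits with their HR table, and a
three-panel dynamic-prediction figure; identical seeds give byte-identical
numeric artifacts.

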