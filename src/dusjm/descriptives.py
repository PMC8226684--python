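"""Baseline descriptive statistics: Fisher exact tests on 2x2 tables,
Mann-Whitney U tests, medians with interquartile ranges, and the baseline
characteristics table comparing lesion vs lesion-free patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import COMORBIDITY_FLAGS, LesionEvent, PatientRecord


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: rows exposure present/absent, columns group (no-lesion, lesion)."""

    a: int  # exposed, no-lesion
    b: int  # exposed, lesion
    c: int  # unexposed, no-lesion
    d: int  # unexposed, lesion

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if int(v) != v or v < 0:
                raise ValueError(f"counts must be non-negative integers, got {v}")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    kind: str  # "fisher" | "mann_whitney"
    p_value: float
    summary_total: str
    summary_no_lesion: str
    summary_lesion: str


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value, point-probability convention.

    Sums hypergeometric probabilities of every table with the observed
    margins whose point probability does not exceed the observed table's
    (within a 1e-12 relative tolerance for float ties), and clamps to 1.
    """
    if isinstance(table, ContingencyTable2x2):
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = np.asarray(table, dtype=int)
    ContingencyTable2x2(int(a), int(b), int(c), int(d))  # validate
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    # hypergeometric over x = count in cell (1,1)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    xs = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(xs, n, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    return min(p, 1.0)


def mann_whitney_u(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact permutation distribution when the pooled sample has at most 20
    observations and no ties; otherwise the normal approximation with tie
    and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if pooled.size <= 20 and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(min(res.pvalue, 1.0))


def median_iqr(x) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear-interpolation (type-7) quartiles."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(med), float(q1), float(q3)


def _fmt_count(k: int, n: int) -> str:
    return f"{k} ({0 if n == 0 else round(100 * k / n):.0f})"


def _fmt_median(x) -> str:
    m, q1, q3 = median_iqr(x)
    return f"{m:.0f} ({q1:.0f}–{q3:.0f})"


def table1_report(
    records: list[PatientRecord], lesions: list[LesionEvent]
) -> pd.DataFrame:
    """Baseline characteristics compared between patients who developed a
    stenosis/occlusion and those who remained lesion-free.

    Counts (%) with Fisher exact p-values for binary variables; median (IQR)
    with Mann-Whitney p-values for continuous ones.
    """
    lesion_ids = {e.patient_id for e in lesions}
    groups = {
        "no": [p for p in records if p.patient_id not in lesion_ids],
        "yes": [p for p in records if p.patient_id in lesion_ids],
    }
    n_no, n_yes = len(groups["no"]), len(groups["yes"])
    rows: list[GroupComparison] = []

    def binary_row(name: str, flag) -> None:
        no_have = [p for p in groups["no"] if flag(p) is not None]
        yes_have = [p for p in groups["yes"] if flag(p) is not None]
        if not no_have and not yes_have:
            return  # variable recorded for nobody
        a = sum(bool(flag(p)) for p in no_have)
        b = sum(bool(flag(p)) for p in yes_have)
        c, d = len(no_have) - a, len(yes_have) - b
        p_val = fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))
        rows.append(
            GroupComparison(
                name, "fisher", p_val,
                _fmt_count(a + b, len(no_have) + len(yes_have)),
                _fmt_count(a, len(no_have)), _fmt_count(b, len(yes_have)),
            )
        )

    def continuous_row(name: str, getter) -> None:
        xs = [getter(p) for p in groups["no"] if getter(p) is not None]
        ys = [getter(p) for p in groups["yes"] if getter(p) is not None]
        p_val = mann_whitney_u(xs, ys)
        rows.append(
            GroupComparison(
                name, "mann_whitney", p_val,
                _fmt_median(xs + ys), _fmt_median(xs), _fmt_median(ys),
            )
        )

    binary_row("men", lambda p: p.sex == "male")
    continuous_row("age", lambda p: p.age)
    for flag in COMORBIDITY_FLAGS:
        binary_row(flag, lambda p, f=flag: p.comorbidities.get(f))
    binary_row("baseline_reintervention", lambda p: p.baseline_reintervention)

    df = pd.DataFrame(
        [
            {
                "variable": r.variable,
                "test": r.kind,
                f"total (n={n_no + n_yes})": r.summary_total,
                f"no lesion (n={n_no})": r.summary_no_lesion,
                f"lesion (n={n_yes})": r.summary_lesion,
                "p_value": round(r.p_value, 3),
            }
            for r in rows
        ]
    )
    return df


def render_table1_text(df: pd.DataFrame) -> str:
    return df.to_string(index=False)
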