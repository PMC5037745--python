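"""Group comparisons and survival analysis for the methylation cohort.

Two halves: (i) clinical-table style group comparisons — per-group mean,
SEM and n with a pooled-variance (Student) unpaired t-test, reconstructable
from printed summaries alone; (ii) overall-survival analysis — Kaplan-Meier
product-limit curves and the log-rank test between methylation groups.

Published clinical tables sometimes label their "±" dispersion SD when the
values behave as SEMs; ``dispersion`` flags select the interpretation, and
summary-based tests accept either.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

CLINICAL_COLUMNS = {
    "patient_id": str,
    "age": float,
    "sex": str,        # 'M' / 'F'
    "stage": str,      # 'I'..'IV'
    "grade": str,      # 'G1'..'G4'
    "h_pylori": bool,
    "meth_percent": float,
    "os_months": float,  # diagnosis to death (or censoring)
    "event": int,        # 1 = death observed
}

STAGES = ("I", "II", "III", "IV")
GRADES = ("G1", "G2", "G3", "G4")


class ClinicalInputError(ValueError):
    """Raised for malformed clinical tables."""


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check a clinical table against the documented column contract."""
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ClinicalInputError(f"clinical table missing columns {sorted(missing)}")
    if (df["os_months"] < 0).any():
        raise ClinicalInputError("negative overall-survival time")
    if not df["event"].isin([0, 1]).all():
        raise ClinicalInputError("event flag must be 0/1")
    if not df["stage"].isin(STAGES).all():
        raise ClinicalInputError(f"stage must be one of {STAGES}")
    if not df["grade"].isin(GRADES).all():
        raise ClinicalInputError(f"grade must be one of {GRADES}")
    return df


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_cohort(df)


def write_clinical_tsv(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df).to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass(frozen=True)
class GroupSummary:
    """n, mean and dispersion of one group; sd and sem interconvert by sqrt(n)."""

    n: int
    mean: float
    sem: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ClinicalInputError("GroupSummary needs n >= 2")
        if self.sem < 0:
            raise ClinicalInputError("negative dispersion")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ClinicalInputError("need >= 2 values per group")
        return cls(n=arr.size, mean=float(arr.mean()), sem=float(stats.sem(arr, ddof=1)))

    @classmethod
    def from_printed(
        cls, n: int, mean: float, plus_minus: float, dispersion: str = "sem"
    ) -> "GroupSummary":
        """Build from a printed "mean ± value (n)" entry.

        ``dispersion`` says what the ± value is: ``"sem"`` (default) or
        ``"sd"``.
        """
        if dispersion == "sem":
            return cls(n=n, mean=mean, sem=plus_minus)
        if dispersion == "sd":
            return cls(n=n, mean=mean, sem=plus_minus / math.sqrt(n))
        raise ClinicalInputError(f"dispersion must be 'sem' or 'sd', got {dispersion!r}")


class TTestResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def pooled_t_test_from_summaries(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Student (pooled-variance) unpaired t-test from group summaries.

    Degenerate zero-variance case: p = 1 for equal means, p = 0 otherwise.
    """
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if pooled_var == 0:
        if np.isclose(a.mean, b.mean):
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.inf if a.mean > b.mean else -math.inf, df, 0.0)
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return TTestResult(float(t), df, float(p))


class GroupComparison(NamedTuple):
    group_a: GroupSummary
    group_b: GroupSummary
    label_a: str
    label_b: str
    pvalue: float


def summarize_groups(
    cohort: pd.DataFrame,
    covariate: str,
    value_col: str = "meth_percent",
) -> GroupComparison:
    """One clinical-table row: per-group mean ± SEM (n) and the pooled t p.

    ``covariate`` must partition the cohort into exactly two groups, each
    with n >= 2; composite stage/grade splits (I-II vs III-IV, G1-2 vs
    G3-4) are handled by :func:`binarize_covariate` upstream.
    """
    groups = cohort.groupby(covariate, sort=True)[value_col]
    labels = list(groups.groups)
    if len(labels) != 2:
        raise ClinicalInputError(
            f"covariate {covariate!r} has {len(labels)} levels; need exactly 2"
        )
    summaries = {}
    for label, values in groups:
        if len(values) < 2:
            raise ClinicalInputError(
                f"group {label!r} of {covariate!r} has n={len(values)} < 2"
            )
        summaries[label] = GroupSummary.from_values(values.to_numpy())
    a, b = summaries[labels[0]], summaries[labels[1]]
    res = pooled_t_test_from_summaries(a, b)
    return GroupComparison(a, b, str(labels[0]), str(labels[1]), res.pvalue)


def binarize_covariate(cohort: pd.DataFrame, covariate: str) -> pd.Series:
    """Standard two-level splits: age >=60/<60, sex, stage I-II/III-IV, grade low/high."""
    if covariate == "age":
        return pd.Series(
            np.where(cohort["age"] >= 60, ">=60", "<60"), index=cohort.index
        )
    if covariate == "sex":
        return cohort["sex"]
    if covariate == "stage":
        return pd.Series(
            np.where(cohort["stage"].isin(["I", "II"]), "I-II", "III-IV"),
            index=cohort.index,
        )
    if covariate == "grade":
        return pd.Series(
            np.where(cohort["grade"].isin(["G1", "G2"]), "low", "high"),
            index=cohort.index,
        )
    if covariate == "h_pylori":
        return pd.Series(
            np.where(cohort["h_pylori"], "positive", "negative"), index=cohort.index
        )
    raise ClinicalInputError(f"no standard binarization for covariate {covariate!r}")


def clinical_table(
    cohort: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "stage", "grade", "h_pylori"),
    value_col: str = "meth_percent",
) -> pd.DataFrame:
    """Clinical-parameters-vs-methylation table: one row per covariate level."""
    rows = []
    work = cohort.copy()
    for cov in covariates:
        key = f"_{cov}_bin"
        work[key] = binarize_covariate(work, cov)
        cmp_ = summarize_groups(work, key, value_col=value_col)
        for label, summ in (
            (cmp_.label_a, cmp_.group_a),
            (cmp_.label_b, cmp_.group_b),
        ):
            rows.append(
                {
                    "covariate": cov,
                    "group": label,
                    "n": summ.n,
                    "mean": round(summ.mean, 2),
                    "sem": round(summ.sem, 2),
                    "p": round(cmp_.pvalue, 3),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    """Kaplan-Meier step function with its risk table and median survival."""

    times: np.ndarray       # event times (steps)
    survival: np.ndarray    # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    median: float | None    # first t with S(t) <= 0.5; None if never reached

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMResult:
    """Product-limit survival estimator.

    Survival starts at 1 and is non-increasing; the median is the first
    event time at which S(t) drops to 0.5 or below (no interpolation),
    absent when the curve never reaches 0.5.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ClinicalInputError("empty survival input")
    if (times < 0).any():
        raise ClinicalInputError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    event_rows = table[table["observed"] > 0]
    ev_times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev_times, kmf.survival_function_.columns[0]]
    surv = surv.to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    n_events = event_rows["observed"].to_numpy(dtype=int)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(ev_times[below[0]]) if below.size else None
    return KMResult(ev_times, surv, at_risk, n_events, median)


class LogrankResult(NamedTuple):
    chi_square: float
    pvalue: float


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> LogrankResult:
    """Two-group log-rank test (1 df) over pooled event times.

    With no events in either group the test is undefined and p = 1 by
    convention.
    """
    ta, ea = np.asarray(times_a, float), np.asarray(events_a, int)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ClinicalInputError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        return LogrankResult(0.0, 1.0)
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):  # degenerate risk sets
        return LogrankResult(0.0, 1.0)
    return LogrankResult(chi2, p)


def survival_by_group(
    cohort: pd.DataFrame, group_col: str = "meth_group"
) -> dict[str, KMResult]:
    """Kaplan-Meier estimate per level of ``group_col``."""
    out = {}
    for label, grp in cohort.groupby(group_col, sort=True):
        out[str(label)] = km_estimate(grp["os_months"], grp["event"])
    return out
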