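"""DLT classification, analysis sets, exposure metrics and safety tables.

Implements the bookkeeping conventions of a phase-1 oncology trial:

* a dose-limiting toxicity (DLT) is a treatment-related adverse event, not
  attributable to the underlying disease, of sufficient severity (default
  CTCAE grade >= 3), with onset within the evaluation window (default 42
  days after the first administration; day 1 = day of first dose);
* the dose-determining set contains patients who received >= 90% of the
  planned cycle-1 activity and were observed >= 42 days, or who
  discontinued earlier because of a cycle-1 DLT;
* exposure duration in weeks is (last dose date - first dose date + 42
  days) / 7;
* safety tables count patients once per category at their worst grade,
  reported as "n (percentage)" with percentages to one decimal, rounded
  half away from zero.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "AdverseEvent",
    "PatientRecord",
    "classify_dlt",
    "dose_determining_membership",
    "exposure_duration_weeks",
    "tabulate_counts",
    "safety_summary",
]

DLT_WINDOW_DAYS = 42


@dataclass(frozen=True)
class AdverseEvent:
    """One graded adverse event; onset_day counts from first administration."""

    term: str
    grade: int
    onset_day: int
    related: bool = False
    serious: bool = False
    disease_attributable: bool = False

    def __post_init__(self) -> None:
        if self.grade not in (1, 2, 3, 4, 5):
            raise ValueError(f"grade must be 1-5, got {self.grade}")
        if self.onset_day < 1:
            raise ValueError(f"onset_day must be >= 1, got {self.onset_day}")


@dataclass
class PatientRecord:
    """Treated patient: administrations, observation span, adverse events."""

    patient_id: str
    dl_index: int
    administrations: list[tuple[dt.date, float]]
    observation_days: int = 0
    discontinued_for_dlt_cycle1: bool = False
    aes: list[AdverseEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.administrations:
            raise ValueError("treated patients need at least one administration")
        if any(a <= 0 for _, a in self.administrations):
            raise ValueError("administered activities must be positive")

    @property
    def cycle1_activity_gbq(self) -> float:
        return self.administrations[0][1]

    @property
    def first_administration(self) -> dt.date:
        return min(d for d, _ in self.administrations)

    @property
    def last_administration(self) -> dt.date:
        return max(d for d, _ in self.administrations)


def classify_dlt(
    ae: AdverseEvent,
    window_days: int = DLT_WINDOW_DAYS,
    min_grade: int = 3,
) -> bool:
    """True iff the event qualifies as a dose-limiting toxicity.

    Requires relatedness, non-attribution to disease, onset no more than
    ``window_days`` after the first administration, and grade at or above
    ``min_grade``.
    """
    return (
        ae.related
        and not ae.disease_attributable
        and ae.onset_day <= window_days
        and ae.grade >= min_grade
    )


def dose_determining_membership(
    patient: PatientRecord, planned_cycle1_activity_gbq: float
) -> bool:
    """Membership in the dose-determining (DLT-evaluable) set.

    Either minimum exposure (>= 90% of planned cycle-1 activity and >= 42
    days of observation) or early discontinuation because of a cycle-1
    DLT.
    """
    compliant = (
        patient.cycle1_activity_gbq >= 0.9 * planned_cycle1_activity_gbq
        and patient.observation_days >= DLT_WINDOW_DAYS
    )
    return compliant or patient.discontinued_for_dlt_cycle1


def exposure_duration_weeks(first_date: dt.date, last_date: dt.date) -> float:
    """(last - first + 42 days) / 7, reported to 2 decimals.

    The 42-day term extends exposure through the at-risk window after the
    final administration, so a single-cycle patient contributes 6.00 wk.
    """
    if last_date < first_date:
        raise ValueError("last administration precedes the first")
    weeks = ((last_date - first_date).days + 42) / 7
    return float(Decimal(repr(weeks)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def tabulate_counts(n: int, denominator: int) -> tuple[int, float]:
    """n and percentage (one decimal, half away from zero) of a denominator."""
    if denominator < 1:
        raise ValueError("denominator must be >= 1")
    if n > denominator:
        raise ValueError(f"count {n} exceeds denominator {denominator}")
    pct = 100.0 * n / denominator
    return n, float(Decimal(repr(pct)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _patient_flags(p: PatientRecord, window_days: int, min_grade: int) -> dict:
    related = [ae for ae in p.aes if ae.related]
    dlts = [ae for ae in p.aes if classify_dlt(ae, window_days, min_grade)]
    worst_dlt = max((ae.grade for ae in dlts), default=0)
    return {
        "any_trae": bool(related),
        "grade3plus_trae": any(ae.grade >= 3 for ae in related),
        "serious_trae": any(ae.serious for ae in related),
        "any_dlt": bool(dlts),
        "worst_dlt_grade": worst_dlt,
    }


def safety_summary(
    patients: Sequence[PatientRecord],
    window_days: int = DLT_WINDOW_DAYS,
    min_grade: int = 3,
    dl_labels: Optional[dict[int, str]] = None,
) -> pd.DataFrame:
    """Per-DL and pooled "n (%)" table of TRAE and DLT categories.

    Patient-level counting: each patient contributes at most once per
    category regardless of how many qualifying events they had.  Rows are
    categories; columns are one per dose level plus a pooled column.
    """
    if not patients:
        raise ValueError("need at least one patient")
    rows = []
    for p in patients:
        flags = _patient_flags(p, window_days, min_grade)
        flags["dl_index"] = p.dl_index
        rows.append(flags)
    df = pd.DataFrame(rows)
    categories = ["any_trae", "grade3plus_trae", "serious_trae", "any_dlt"]

    def column(sub: pd.DataFrame) -> dict:
        denom = len(sub)
        out = {"n": denom}
        for cat in categories:
            n, pct = tabulate_counts(int(sub[cat].sum()), denom)
            out[cat] = f"{n} ({pct})"
        return out

    cols = {}
    for dl, sub in df.groupby("dl_index", sort=True):
        label = (dl_labels or {}).get(dl, f"DL{dl}")
        cols[label] = column(sub)
    cols["all"] = column(df)
    return pd.DataFrame(cols)
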