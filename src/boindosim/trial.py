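"""Trial orchestration: dose ladder, ECA gating, escalation simulation.

Glues the BOIN decision engine to a provisional activity ladder, applies
the organ-dosimetry activity cap (maximum allowed cumulative administered
activity) to per-patient schedules, and runs Monte-Carlo trials to obtain
operating characteristics (selection percentages, patients and DLTs per
dose level).

DLT outcomes in simulation are Bernoulli draws at each level's true
probability, independent of simulated dosimetry: the dosimetry gate and
the toxicity process are modelled as separate constraints, reflecting
settings where absorbed organ doses sit far below toxicity thresholds and
carry no detectable dose-toxicity correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .boin import BoinDesign, Decision, DlState, decide, eliminate_check, select_mtd
from .dosimetry import EcaResult

__all__ = [
    "DoseLevel",
    "PatientSchedule",
    "SimScenario",
    "TrialRecord",
    "build_ladder",
    "gate_next_cycle",
    "apply_dose_reduction",
    "run_trial",
    "operating_characteristics",
]


@dataclass(frozen=True)
class DoseLevel:
    """One rung of the provisional activity ladder.

    Cycle 1 may differ from later cycles (an intrapatient step-up ladder
    rung such as 1.85 GBq then 5.55 GBq); the planned cumulative activity
    is cycle1 + later x (cycles - 1).
    """

    dl_index: int
    cycle1_activity_gbq: float
    later_cycle_activity_gbq: float
    planned_cycles: int

    def __post_init__(self) -> None:
        if self.cycle1_activity_gbq <= 0 or self.later_cycle_activity_gbq <= 0:
            raise ValueError("activities must be positive")
        if self.planned_cycles < 1:
            raise ValueError("planned_cycles must be >= 1")

    @property
    def planned_cumulative_activity_gbq(self) -> float:
        return self.cycle1_activity_gbq + self.later_cycle_activity_gbq * (
            self.planned_cycles - 1
        )

    @property
    def planned_schedule(self) -> list[float]:
        return [self.cycle1_activity_gbq] + [self.later_cycle_activity_gbq] * (
            self.planned_cycles - 1
        )


def build_ladder(levels: Sequence[dict]) -> list[DoseLevel]:
    """Build and validate the provisional ladder from config rows.

    Each row needs cycle1_activity_gbq, later_cycle_activity_gbq and
    planned_cycles.  The ladder must be strictly increasing in cycle-1
    activity.
    """
    if not levels:
        raise ValueError("ladder needs at least one dose level")
    ladder = [
        DoseLevel(
            dl_index=i,
            cycle1_activity_gbq=row["cycle1_activity_gbq"],
            later_cycle_activity_gbq=row.get(
                "later_cycle_activity_gbq", row["cycle1_activity_gbq"]
            ),
            planned_cycles=row["planned_cycles"],
        )
        for i, row in enumerate(levels)
    ]
    acts = [dl.cycle1_activity_gbq for dl in ladder]
    if any(b <= a for a, b in zip(acts, acts[1:])):
        raise ValueError("ladder must be strictly increasing in cycle-1 activity")
    return ladder


def gate_next_cycle(
    cumulative_activity_gbq: float,
    proposed_activity_gbq: float,
    eca: Optional[EcaResult],
    floor_gbq: float = 1.85,
) -> tuple[str, float]:
    """Check a proposed administration against the cumulative activity cap.

    Returns (action, activity): 'allow' with the proposed activity when
    cumulative + proposed stays within the cap, 'reduce' with the largest
    permitted activity when that is still at or above ``floor_gbq``, else
    'block' with 0.  A missing EcaResult blocks (the cap must exist before
    dosing beyond the protocol minimum).
    """
    if eca is None:
        return "block", 0.0
    headroom = eca.overall_max_activity_gbq - cumulative_activity_gbq
    if proposed_activity_gbq <= headroom:
        return "allow", proposed_activity_gbq
    if headroom >= floor_gbq:
        return "reduce", headroom
    return "block", 0.0


@dataclass
class PatientSchedule:
    """Per-patient remaining cycle activities and reduction status."""

    patient_id: str
    remaining_activities_gbq: list[float]
    n_reductions: int = 0
    discontinued: bool = False

    MAX_REDUCTIONS = 1


def apply_dose_reduction(
    schedule: PatientSchedule,
    ladder_activities: Sequence[float],
    reason: str = "",
) -> PatientSchedule:
    """Reduce all remaining cycles one ladder step; enforce the 1-reduction cap.

    A second reduction request, or a reduction that would fall below the
    lowest ladder activity, discontinues the patient instead.
    """
    if schedule.discontinued:
        raise ValueError(f"patient {schedule.patient_id} already discontinued")
    floor = min(ladder_activities)
    if schedule.n_reductions >= PatientSchedule.MAX_REDUCTIONS:
        schedule.discontinued = True
        return schedule
    steps = sorted(ladder_activities)
    reduced = []
    for act in schedule.remaining_activities_gbq:
        lower = [s for s in steps if s < act]
        if not lower:
            schedule.discontinued = True
            return schedule
        reduced.append(lower[-1])
    if reduced and min(reduced) < floor:
        schedule.discontinued = True
        return schedule
    schedule.remaining_activities_gbq = reduced
    schedule.n_reductions += 1
    return schedule


@dataclass(frozen=True)
class SimScenario:
    """True state of nature for a simulated trial."""

    true_dlt_probs: tuple[float, ...]
    n_trials: int = 1
    cohort_size: int = 3

    def __post_init__(self) -> None:
        if not all(0.0 <= p <= 1.0 for p in self.true_dlt_probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass
class TrialRecord:
    """Outcome of one simulated trial: per-DL data, decisions, MTD."""

    mtd_index: Optional[int]
    dl_states: list[DlState]
    decision_log: list[dict] = field(default_factory=list)
    n_enrolled: int = 0


def _next_open_lower(dl_states: list[DlState], i: int) -> Optional[int]:
    for j in range(i - 1, -1, -1):
        if not dl_states[j].eliminated:
            return j
    return None


def _next_open_higher(dl_states: list[DlState], i: int) -> Optional[int]:
    if i + 1 < len(dl_states) and not dl_states[i + 1].eliminated:
        return i + 1
    return None


def run_trial(
    scenario: SimScenario,
    design: BoinDesign,
    ladder: Sequence[DoseLevel],
    rng: np.random.Generator,
) -> TrialRecord:
    """Simulate one complete escalation trial.

    Cohorts of ``scenario.cohort_size`` accrue at the current dose level;
    after each cohort the BOIN decision is applied to the level's
    cumulative (n, y).  Elimination removes the level and everything above
    it.  The trial stops when the patient budget is exhausted, all levels
    are eliminated, or a level at its per-DL cap draws a stay decision;
    the MTD is then chosen by isotonic regression over the tried levels.
    """
    if len(scenario.true_dlt_probs) != len(ladder):
        raise ValueError("scenario must give one DLT probability per dose level")
    dl_states = [DlState(dl_index=dl.dl_index) for dl in ladder]
    current = 0
    enrolled = 0
    log: list[dict] = []

    while True:
        st = dl_states[current]
        k = min(scenario.cohort_size, design.max_total - enrolled,
                design.max_per_dl - st.n_evaluable)
        if k <= 0:
            break
        y_new = int(rng.binomial(k, scenario.true_dlt_probs[current]))
        st.n_evaluable += k
        st.n_dlt += y_new
        enrolled += k

        higher = _next_open_higher(dl_states, current)
        lower = _next_open_lower(dl_states, current)
        decision = decide(st, design, higher is not None, lower is not None)
        log.append(
            {
                "dl_index": current,
                "n": st.n_evaluable,
                "y": st.n_dlt,
                "has_higher": higher is not None,
                "has_lower": lower is not None,
                "decision": decision.value,
            }
        )

        # elimination removes the level and everything above; a terminal
        # de-escalation at the lowest level still eliminates when the
        # overdose rule fired, so no MTD can be declared there
        if decision is Decision.DEESCALATE_AND_ELIMINATE or (
            decision is Decision.TERMINATE
            and eliminate_check(
                st.n_evaluable, st.n_dlt, design.phi,
                design.elim_cutoff, design.elim_min_n,
            )
        ):
            for j in range(current, len(dl_states)):
                dl_states[j].eliminated = True
        if decision is Decision.TERMINATE:
            break
        if enrolled >= design.max_total:
            break
        if decision is Decision.ESCALATE and higher is not None:
            current = higher
        elif decision in (Decision.DEESCALATE, Decision.DEESCALATE_AND_ELIMINATE):
            if lower is None:
                break
            current = lower
        else:  # stay (or escalate degraded to stay)
            if st.n_evaluable >= design.max_per_dl:
                break

    if all(s.eliminated for s in dl_states if s.n_evaluable >= 1):
        mtd = None
    else:
        mtd = select_mtd(dl_states, design)
    return TrialRecord(mtd, dl_states, log, enrolled)


def operating_characteristics(
    records: Sequence[TrialRecord], n_dls: int
) -> dict:
    """Summary across simulated trials.

    Returns selection percentage, mean patients and mean DLTs per dose
    level, plus the no-MTD percentage; selection percentages over the
    levels sum to at most 100.
    """
    if not records:
        raise ValueError("need at least one trial record")
    n = len(records)
    sel = np.zeros(n_dls)
    npat = np.zeros(n_dls)
    ndlt = np.zeros(n_dls)
    none_count = 0
    for rec in records:
        if rec.mtd_index is None:
            none_count += 1
        else:
            sel[rec.mtd_index] += 1
        for st in rec.dl_states:
            npat[st.dl_index] += st.n_evaluable
            ndlt[st.dl_index] += st.n_dlt
    return {
        "selection_pct": (100.0 * sel / n).tolist(),
        "no_mtd_pct": 100.0 * none_count / n,
        "mean_patients": (npat / n).tolist(),
        "mean_dlts": (ndlt / n).tolist(),
        "n_trials": n,
    }
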