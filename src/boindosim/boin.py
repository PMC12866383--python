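"""Bayesian optimal interval (BOIN) dose-escalation engine.

The BOIN design compares the observed dose-limiting-toxicity (DLT) rate in
the current cohort against two fixed boundaries, lambda_e and lambda_d,
chosen to minimise the probability of an incorrect escalation decision for
a target DLT rate ``phi``.  An overdose-elimination rule removes dose
levels whose beta-binomial posterior makes excessive toxicity likely, and
the maximum tolerated dose (MTD) is selected at the end of the trial by
isotonic regression of the per-level DLT-rate estimates.

Defaults follow the standard BOIN recommendations: ``phi1 = 0.6 * phi``
(highest DLT probability still considered sub-therapeutic), ``phi2 =
1.4 * phi`` (lowest probability considered over-toxic), elimination when
``Pr(p > phi | data) > 0.95`` with at least 3 patients observed.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

__all__ = [
    "BoinDesign",
    "DlState",
    "Decision",
    "compute_boundaries",
    "decide",
    "eliminate_check",
    "isotonic_estimates",
    "select_mtd",
]


class InvalidDesignError(ValueError):
    """Raised when design parameters violate 0 < phi1 < phi < phi2 < 1."""


def compute_boundaries(phi: float, phi1: float, phi2: float) -> tuple[float, float]:
    """Optimal escalation/de-escalation boundaries for a target DLT rate.

    lambda_e = ln((1-phi1)/(1-phi)) / ln(phi(1-phi1) / (phi1(1-phi)))
    lambda_d = ln((1-phi)/(1-phi2)) / ln(phi2(1-phi) / (phi(1-phi2)))

    These are the thresholds on the observed DLT proportion that equalise
    the posterior odds of the adjacent hypotheses, so that
    lambda_e < phi < lambda_d always holds.

    Parameters
    ----------
    phi : target DLT probability at the MTD.
    phi1 : highest DLT probability deemed sub-therapeutic.
    phi2 : lowest DLT probability deemed over-toxic.
    """
    if not (0.0 < phi1 < phi < phi2 < 1.0):
        raise InvalidDesignError(
            f"require 0 < phi1 < phi < phi2 < 1, got phi1={phi1}, phi={phi}, phi2={phi2}"
        )
    lambda_e = math.log((1 - phi1) / (1 - phi)) / math.log(
        phi * (1 - phi1) / (phi1 * (1 - phi))
    )
    lambda_d = math.log((1 - phi) / (1 - phi2)) / math.log(
        phi2 * (1 - phi) / (phi * (1 - phi2))
    )
    return lambda_e, lambda_d


@dataclass(frozen=True)
class BoinDesign:
    """Design constants driving every escalation decision.

    Parameters
    ----------
    phi : target DLT probability (dimensionless).
    phi1, phi2 : interval end points; default to 0.6*phi and 1.4*phi.
    elim_cutoff : posterior probability above which a dose level is
        eliminated for overdosing.
    elim_min_n : minimum evaluable patients before elimination can fire.
    max_per_dl : cap on patients treated at one dose level.
    max_total : cap on patients treated overall.
    min_cohort : minimum evaluable patients per dose level before a
        decision is made.
    """

    phi: float = 0.25
    phi1: Optional[float] = None
    phi2: Optional[float] = None
    elim_cutoff: float = 0.95
    elim_min_n: int = 3
    max_per_dl: int = 9
    max_total: int = 36
    min_cohort: int = 3

    def __post_init__(self) -> None:
        if self.phi1 is None:
            object.__setattr__(self, "phi1", 0.6 * self.phi)
        if self.phi2 is None:
            object.__setattr__(self, "phi2", 1.4 * self.phi)
        # validates the ordering as a side effect
        compute_boundaries(self.phi, self.phi1, self.phi2)
        if not (self.max_per_dl >= self.min_cohort >= 1):
            raise InvalidDesignError("require max_per_dl >= min_cohort >= 1")
        if self.max_total < self.max_per_dl:
            raise InvalidDesignError("require max_total >= max_per_dl")
        if not (0.0 < self.elim_cutoff < 1.0):
            raise InvalidDesignError("elim_cutoff must lie in (0, 1)")

    @property
    def lambda_e(self) -> float:
        return compute_boundaries(self.phi, self.phi1, self.phi2)[0]

    @property
    def lambda_d(self) -> float:
        return compute_boundaries(self.phi, self.phi1, self.phi2)[1]


@dataclass
class DlState:
    """Evolving record of one dose level: evaluable patients, DLTs, status."""

    dl_index: int
    n_evaluable: int = 0
    n_dlt: int = 0
    eliminated: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n_dlt <= self.n_evaluable):
            raise ValueError(
                f"require 0 <= n_dlt <= n_evaluable, got y={self.n_dlt}, n={self.n_evaluable}"
            )


class Decision(str, enum.Enum):
    ESCALATE = "escalate"
    STAY = "stay"
    DEESCALATE = "deescalate"
    DEESCALATE_AND_ELIMINATE = "deescalate_and_eliminate"
    TERMINATE = "terminate"


def eliminate_check(
    n: int, y: int, phi: float, elim_cutoff: float = 0.95, elim_min_n: int = 3
) -> bool:
    """Beta-binomial overdose-elimination rule.

    With a uniform prior, the posterior of the DLT probability after y
    toxicities in n patients is Beta(1+y, 1+n-y).  The dose level is
    eliminated when at least ``elim_min_n`` patients have been observed and
    Pr(p > phi | data) exceeds ``elim_cutoff``.
    """
    if not (0 <= y <= n):
        raise ValueError(f"require 0 <= y <= n, got y={y}, n={n}")
    if n < elim_min_n:
        return False
    return float(stats.beta.sf(phi, 1 + y, 1 + n - y)) > elim_cutoff


def decide(
    dl_state: DlState,
    design: BoinDesign,
    has_higher_dl: bool,
    has_lower_dl: bool,
) -> Decision:
    """One BOIN interval decision for the current dose level.

    Compares the observed DLT proportion with the design boundaries:
    escalate when p_hat <= lambda_e, de-escalate when p_hat >= lambda_d
    (with elimination appended when the overdose rule fires), otherwise
    stay.  ``has_higher_dl`` means a non-eliminated higher level exists;
    escalation without one degrades to stay.  De-escalation without a
    lower level yields terminate.
    """
    n, y = dl_state.n_evaluable, dl_state.n_dlt
    if n < 1:
        raise ValueError("decision requires at least one evaluable patient")
    p_hat = y / n
    if p_hat <= design.lambda_e:
        return Decision.ESCALATE if has_higher_dl else Decision.STAY
    if p_hat >= design.lambda_d:
        if eliminate_check(n, y, design.phi, design.elim_cutoff, design.elim_min_n):
            if has_lower_dl:
                return Decision.DEESCALATE_AND_ELIMINATE
            return Decision.TERMINATE
        return Decision.DEESCALATE if has_lower_dl else Decision.TERMINATE
    return Decision.STAY


def _pava(values: Sequence[float], weights: Sequence[float]) -> list[float]:
    """Weighted pool-adjacent-violators: non-decreasing least-squares fit."""
    merged: list[list[float]] = []  # [block mean, block weight]
    sizes: list[int] = []
    for v, w in zip(values, weights):
        merged.append([v, w])
        sizes.append(1)
        while len(merged) > 1 and merged[-2][0] > merged[-1][0]:
            v2, w2 = merged.pop()
            s2 = sizes.pop()
            v1, w1 = merged.pop()
            s1 = sizes.pop()
            merged.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2])
            sizes.append(s1 + s2)
    expanded: list[float] = []
    for (v, _w), s in zip(merged, sizes):
        expanded.extend([v] * s)
    return expanded


def isotonic_estimates(
    dl_states: Sequence[DlState], prior_mass: float = 0.05
) -> list[float]:
    """Isotonic (non-decreasing) DLT-rate estimates across tried levels.

    Raw estimates are posterior means of Beta(y + prior_mass, n - y +
    prior_mass) — a weakly-informative smoothing that keeps levels with
    zero events distinguishable — pooled by the pool-adjacent-violators
    algorithm with inverse-posterior-variance weights.
    """
    means, weights = [], []
    for st in dl_states:
        a = st.n_dlt + prior_mass
        b = st.n_evaluable - st.n_dlt + prior_mass
        m = a / (a + b)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        means.append(m)
        weights.append(1.0 / var)
    return _pava(means, weights)


def select_mtd(
    dl_states: Sequence[DlState], design: BoinDesign
) -> Optional[int]:
    """Select the MTD among tried, non-eliminated dose levels.

    The isotonic estimate closest to the target ``phi`` wins.  Ties are
    broken toward the higher level when the tied estimate is below phi and
    toward the lower level otherwise.  Returns ``None`` when no tried
    level survives elimination.
    """
    tried = [st for st in dl_states if st.n_evaluable >= 1]
    if not tried:
        return None
    tried = sorted(tried, key=lambda st: st.dl_index)
    iso = isotonic_estimates(tried)
    candidates = [
        (st, p) for st, p in zip(tried, iso) if not st.eliminated
    ]
    if not candidates:
        return None
    best_dist = min(abs(p - design.phi) for _, p in candidates)
    tied = [(st, p) for st, p in candidates if math.isclose(abs(p - design.phi), best_dist, abs_tol=1e-12)]
    st, p = tied[0]
    if p < design.phi:
        st = max(tied, key=lambda t: t[0].dl_index)[0]
    else:
        st = min(tied, key=lambda t: t[0].dl_index)[0]
    return st.dl_index
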