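"""Diagnostic testing pathways.

Two strategies are compared for a cohort presenting with haematuria:

* ``CYSTOSCOPY_ONLY`` — every patient receives flexible cystoscopy;
  positives go on to TURBT (false positives receive it unnecessarily).
* ``DCRSHP_TRIAGE`` — every patient receives the urine biomarker test;
  only biomarker-positives are referred for cystoscopy, and only patients
  positive on *both* tests proceed to TURBT (series positivity rule,
  conditional independence of the two tests given disease status).

The pathway classifies the cohort into true/false positives/negatives and
attaches the one-off testing-phase costs and QALY decrements incurred at
time zero (undiscounted).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .parameters import ParameterSet, TestAccuracy

__all__ = ["Strategy", "CohortSplit", "TestingOutcome", "classify_cohort",
           "testing_cost", "testing_disutility", "testing_outcome",
           "TURBT_DECREMENT_DAYS"]

TURBT_DECREMENT_DAYS = 7.0
_DAYS_PER_YEAR = 365.25


class Strategy(Enum):
    DCRSHP_TRIAGE = "dcrshp_triage"
    CYSTOSCOPY_ONLY = "cystoscopy_only"


@dataclass(frozen=True)
class CohortSplit:
    """Fractions of the presenting cohort by true status x test outcome."""

    tp: float
    fp: float
    tn: float
    fn: float
    p_dcrshp_positive: float = 0.0  # referred on to cystoscopy (triage arm)

    def __post_init__(self):
        total = self.tp + self.fp + self.tn + self.fn
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"split sums to {total}, not 1")
        for v in (self.tp, self.fp, self.tn, self.fn):
            if not -1e-15 <= v <= 1.0 + 1e-12:
                raise ValueError("split fractions must lie in [0, 1]")


@dataclass(frozen=True)
class TestingOutcome:
    cost_per_patient: float
    qaly_decrement_per_patient: float
    split: CohortSplit


def classify_cohort(prevalence: float, strategy: Strategy,
                    acc_d: TestAccuracy, acc_c: TestAccuracy) -> CohortSplit:
    """TP/FP/TN/FN fractions of the tested cohort for one strategy."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    p = prevalence
    se_c, sp_c = acc_c.sensitivity, acc_c.specificity
    if strategy is Strategy.CYSTOSCOPY_ONLY:
        tp = p * se_c
        fn = p * (1.0 - se_c)
        tn = (1.0 - p) * sp_c
        fp = (1.0 - p) * (1.0 - sp_c)
        return CohortSplit(tp=tp, fp=fp, tn=tn, fn=fn, p_dcrshp_positive=0.0)
    se_d, sp_d = acc_d.sensitivity, acc_d.specificity
    tp = p * se_d * se_c
    fn = p * (1.0 - se_d * se_c)
    fp = (1.0 - p) * (1.0 - sp_d) * (1.0 - sp_c)
    tn = max(0.0, 1.0 - tp - fn - fp)  # clamp float residue at the boundary
    referred = p * se_d + (1.0 - p) * (1.0 - sp_d)
    return CohortSplit(tp=tp, fp=fp, tn=tn, fn=fn, p_dcrshp_positive=referred)


def testing_cost(strategy: Strategy, split: CohortSplit, dcrshp_price: float,
                 cysto_cost: float, turbt_cost: float) -> float:
    """Expected testing-phase cost per presenting patient.

    The diagnostic TURBT for every test-positive (true or false) is charged
    here; the cohort model charges TURBTs only on recurrence or late
    detection.  Cost is affine in the test price with slope exactly 1.
    """
    for c in (dcrshp_price, cysto_cost, turbt_cost):
        if c < 0:
            raise ValueError("costs must be non-negative")
    turbt = (split.tp + split.fp) * turbt_cost
    if strategy is Strategy.CYSTOSCOPY_ONLY:
        return cysto_cost + turbt
    return dcrshp_price + split.p_dcrshp_positive * cysto_cost + turbt


def testing_disutility(strategy: Strategy, split: CohortSplit,
                       cysto_utility_factor: float, turbt_decrement: float) -> float:
    """Expected testing-phase QALY loss per presenting patient.

    A cystoscopy scales that cycle's utility by ``cysto_utility_factor``
    (loss of (1-factor) x 0.5 QALY-years per scoped patient); a TURBT costs
    ``turbt_decrement`` over 7 days.  In the triage arm only the referred
    fraction is scoped.
    """
    if not 0.0 <= cysto_utility_factor <= 1.0:
        raise ValueError("utility factor must lie in [0, 1]")
    scoped = 1.0 if strategy is Strategy.CYSTOSCOPY_ONLY else split.p_dcrshp_positive
    cysto_loss = scoped * (1.0 - cysto_utility_factor) * 0.5
    turbt_loss = (split.tp + split.fp) * turbt_decrement * (
        TURBT_DECREMENT_DAYS / _DAYS_PER_YEAR)
    return cysto_loss + turbt_loss


def testing_outcome(strategy: Strategy, params: ParameterSet) -> TestingOutcome:
    """Classify the cohort and attach testing-phase cost and disutility."""
    split = classify_cohort(params.prevalence, strategy,
                            params.accuracy_dcrshp, params.accuracy_cysto)
    cost = testing_cost(strategy, split, params.dcrshp_price,
                        params.cost_cysto, params.cost_turbt)
    dis = testing_disutility(strategy, split, params.cysto_utility_factor,
                             params.d_turbt)
    return TestingOutcome(cost_per_patient=cost,
                          qaly_decrement_per_patient=dis, split=split)
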