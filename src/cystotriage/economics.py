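"""Comparative cost-effectiveness outputs: ICER, net monetary benefit.

``evaluate_strategy`` composes the testing pathway with the cohort model to
give discounted cost, QALYs and life years per patient for one strategy;
``icer`` and ``nmb`` turn a pair of results into the standard comparative
measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .lifetable import LifeTable, make_life_table
from .markov import (accumulate_rewards, horizon_dynamics,
                     initial_distribution, run_cohort)
from .parameters import ParameterSet
from .pathway import Strategy, testing_outcome

__all__ = ["StrategyResult", "IncrementalResult", "evaluate_strategy",
           "evaluate_both", "icer", "nmb", "table_report"]


@dataclass(frozen=True)
class StrategyResult:
    strategy: Strategy
    cost: float         # discounted GBP per patient
    qalys: float        # discounted QALYs per patient
    life_years: float   # discounted life years per patient


@dataclass(frozen=True)
class IncrementalResult:
    """Alternative vs reference strategy comparison."""

    delta_cost: float
    delta_qalys: float
    delta_ly: float
    icer: float | None          # None when dominance applies
    dominance: str              # "icer", "alt_dominant", "alt_dominated",
                                # "equal", "cost_only"


def evaluate_strategy(strategy: Strategy, params: ParameterSet,
                      life_table: LifeTable | None = None,
                      dynamics=None) -> StrategyResult:
    """Full pipeline for one strategy: decision tree then cohort model."""
    if life_table is None:
        life_table = make_life_table(start_age=params.start_age,
                                     male_fraction=params.male_fraction)
    testing = testing_outcome(strategy, params)
    init = initial_distribution(testing.split, params)
    trace = run_cohort(init, params, life_table, dynamics=dynamics)
    cost, qalys, ly = accumulate_rewards(trace, params)
    return StrategyResult(strategy=strategy,
                          cost=cost + testing.cost_per_patient,
                          qalys=qalys - testing.qaly_decrement_per_patient,
                          life_years=ly)


def evaluate_both(params: ParameterSet,
                  life_table: LifeTable | None = None):
    """(cystoscopy-only, triage) results sharing one life table and one set
    of per-cycle transition dynamics (they depend only on the parameters)."""
    if life_table is None:
        life_table = make_life_table(start_age=params.start_age,
                                     male_fraction=params.male_fraction)
    dyn = horizon_dynamics(params, life_table)
    ref = evaluate_strategy(Strategy.CYSTOSCOPY_ONLY, params, life_table, dyn)
    alt = evaluate_strategy(Strategy.DCRSHP_TRIAGE, params, life_table, dyn)
    return ref, alt


def icer(ref: StrategyResult, alt: StrategyResult) -> IncrementalResult:
    """Incremental result of ``alt`` versus ``ref`` with dominance flags."""
    dc = alt.cost - ref.cost
    dq = alt.qalys - ref.qalys
    dly = alt.life_years - ref.life_years
    if dq == 0.0 and dc == 0.0:
        return IncrementalResult(dc, dq, dly, None, "equal")
    if dq == 0.0:
        return IncrementalResult(dc, dq, dly, None, "cost_only")
    if dc <= 0.0 and dq > 0.0:
        return IncrementalResult(dc, dq, dly, None, "alt_dominant")
    if dc >= 0.0 and dq < 0.0:
        return IncrementalResult(dc, dq, dly, None, "alt_dominated")
    return IncrementalResult(dc, dq, dly, dc / dq, "icer")


def nmb(result: StrategyResult, wtp: float) -> float:
    """Net monetary benefit: QALYs x willingness to pay - cost."""
    if wtp < 0:
        raise ValueError("willingness to pay must be non-negative")
    return result.qalys * wtp - result.cost


def table_report(ref: StrategyResult, alt: StrategyResult) -> pd.DataFrame:
    """Incremental cost-effectiveness table for the two strategies."""
    inc = icer(ref, alt)
    return pd.DataFrame([
        {"strategy": ref.strategy.value, "cost": ref.cost,
         "incremental_cost": None, "qalys": ref.qalys,
         "incremental_qalys": None, "icer": None,
         "life_years": ref.life_years, "incremental_ly": None},
        {"strategy": alt.strategy.value, "cost": alt.cost,
         "incremental_cost": inc.delta_cost, "qalys": alt.qalys,
         "incremental_qalys": inc.delta_qalys,
         "icer": inc.icer if inc.dominance == "icer" else inc.dominance,
         "life_years": alt.life_years, "incremental_ly": inc.delta_ly},
    ])
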