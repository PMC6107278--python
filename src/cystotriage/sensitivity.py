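"""Deterministic and probabilistic sensitivity analyses.

Deterministic: threshold test price (the price at which incremental net
monetary benefit is zero — closed form, since the triage arm's cost is
affine in the price with slope one), prevalence sweep of incremental QALYs,
two-way price x prevalence frontier, and a cystoscopy-disutility sweep.

Probabilistic: joint parameter draws re-evaluated through the full
pipeline, summarised as a cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .economics import evaluate_both, nmb
from .lifetable import make_life_table
from .parameters import (ParameterSet, build_base_case, default_psa_specs,
                         sample_parameter_set)

__all__ = ["threshold_price", "threshold_price_bisection", "prevalence_sweep",
           "qaly_crossover", "two_way_price_prevalence",
           "cysto_disutility_sweep", "run_psa", "ceac", "PSASample",
           "CEACurve"]


def _inmb(params: ParameterSet, wtp: float) -> float:
    """Incremental NMB of triage vs cystoscopy at the given parameters."""
    ref, alt = evaluate_both(params)
    return nmb(alt, wtp) - nmb(ref, wtp)


def threshold_price(params: ParameterSet, wtp: float) -> tuple[float, bool]:
    """Highest test price at which triage stays cost-effective at ``wtp``.

    Closed form: incremental NMB falls by exactly 1 per unit of price, so
    the zero crossing is the incremental NMB evaluated at price 0.  Returns
    ``(price, cost_effective_at_zero)``; the price is floored at 0 when the
    triage arm is not cost-effective even for a free test.
    """
    if wtp <= 0:
        raise ValueError("willingness to pay must be positive")
    at_zero = dataclasses.replace(params, dcrshp_price=0.0)
    inmb0 = _inmb(at_zero, wtp)
    if inmb0 < 0:
        return 0.0, False
    return inmb0, True


def threshold_price_bisection(params: ParameterSet, wtp: float,
                              tol: float = 0.01, hi: float = 50000.0) -> float:
    """Bisection check of :func:`threshold_price` (to ``tol`` pounds)."""
    lo = 0.0
    f_lo = _inmb(dataclasses.replace(params, dcrshp_price=lo), wtp)
    if f_lo < 0:
        return 0.0
    f_hi = _inmb(dataclasses.replace(params, dcrshp_price=hi), wtp)
    if f_hi > 0:
        raise ValueError("bracket upper bound too low")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _inmb(dataclasses.replace(params, dcrshp_price=mid), wtp) >= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def prevalence_sweep(params: ParameterSet, grid, wtp: float = 20000.0) -> pd.DataFrame:
    """Incremental QALYs and NMB of triage across a prevalence grid."""
    rows = []
    for prev in grid:
        p = dataclasses.replace(params, prevalence=float(prev))
        ref, alt = evaluate_both(p)
        rows.append({"prevalence": float(prev),
                     "delta_qalys": alt.qalys - ref.qalys,
                     "delta_cost": alt.cost - ref.cost,
                     "delta_nmb": nmb(alt, wtp) - nmb(ref, wtp)})
    return pd.DataFrame(rows)


def qaly_crossover(sweep: pd.DataFrame) -> float | None:
    """Linearly interpolated prevalence where incremental QALYs change sign."""
    x = sweep["prevalence"].to_numpy()
    y = sweep["delta_qalys"].to_numpy()
    sign = np.sign(y)
    for i in range(len(y) - 1):
        if sign[i] != sign[i + 1] and sign[i] != 0:
            x0, x1, y0, y1 = x[i], x[i + 1], y[i], y[i + 1]
            return float(x0 - y0 * (x1 - x0) / (y1 - y0))
    return None


def two_way_price_prevalence(params: ParameterSet, prevalence_grid,
                             wtp: float = 20000.0) -> pd.DataFrame:
    """Maximum cost-effective price at each prevalence, with QALY flag.

    ``effective`` marks grid points where triage also gains QALYs; points
    that are cost-effective only through cost savings are kept but flagged.
    """
    rows = []
    for prev in prevalence_grid:
        p = dataclasses.replace(params, prevalence=float(prev))
        ref, alt = evaluate_both(dataclasses.replace(p, dcrshp_price=0.0))
        inmb0 = nmb(alt, wtp) - nmb(ref, wtp)
        rows.append({"prevalence": float(prev),
                     "threshold_price": max(0.0, inmb0),
                     "delta_qalys_at_zero_price": alt.qalys - ref.qalys,
                     "effective": alt.qalys > ref.qalys})
    return pd.DataFrame(rows)


def cysto_disutility_sweep(params: ParameterSet, factor_grid) -> pd.DataFrame:
    """Incremental QALYs as the per-cystoscopy utility factor varies."""
    rows = []
    for f in factor_grid:
        p = dataclasses.replace(params, cysto_utility_factor=float(f))
        ref, alt = evaluate_both(p)
        rows.append({"cysto_utility_factor": float(f),
                     "delta_qalys": alt.qalys - ref.qalys})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class PSASample:
    """Joint parameter draws with per-draw outcomes for both strategies."""

    draws: pd.DataFrame     # one named column per sampled parameter
    outcomes: pd.DataFrame  # cost_ref, qalys_ref, cost_alt, qalys_alt
    seed: int
    n: int
    n_redrawn: int = 0      # infeasible extreme draws replaced (logged)

    def inmb(self, wtp: float) -> np.ndarray:
        o = self.outcomes
        return (wtp * (o["qalys_alt"] - o["qalys_ref"])
                - (o["cost_alt"] - o["cost_ref"])).to_numpy()

    def net_benefit(self, wtp: float) -> np.ndarray:
        """(n, 2) net benefit matrix: columns (cystoscopy, triage)."""
        o = self.outcomes
        return np.column_stack([
            wtp * o["qalys_ref"] - o["cost_ref"],
            wtp * o["qalys_alt"] - o["cost_alt"],
        ])


def run_psa(params: ParameterSet, specs=None, n: int = 10000,
            seed: int = 0, price_range: tuple[float, float] | None = (50.0, 620.0),
            ) -> PSASample:
    """``n`` seeded joint draws, each run through the full pipeline.

    The test price is drawn uniformly over ``price_range`` per iteration
    (pass ``None`` to keep the base-case price fixed).  Each draw uses its
    own seed substream, so the outcome matrix is invariant to evaluation
    order and reproducible given ``(seed, n)``.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    specs = specs if specs is not None else default_psa_specs(params)
    life_table = make_life_table(start_age=params.start_age,
                                 male_fraction=params.male_fraction)
    draw_rows, out_rows = [], []
    n_redrawn = 0
    for i in range(n):
        for attempt in range(100):
            rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(i, attempt)))
            drawn = sample_parameter_set(params, specs, rng)
            if price_range is not None:
                price = float(rng.uniform(*price_range))
                drawn = dataclasses.replace(drawn, dcrshp_price=price)
            try:
                ref, alt = evaluate_both(drawn, life_table)
                break
            except ValueError:
                # a rare extreme draw (e.g. huge RR) breaks row feasibility:
                # record and redraw from the next substream
                n_redrawn += 1
        else:
            raise RuntimeError(f"draw {i}: no feasible parameter set in 100 tries")
        row = {k: getattr(drawn, k) for k in specs
               if k not in ("diagnosis_split",)
               and hasattr(drawn, k)}
        row["sens_dcrshp"] = drawn.accuracy_dcrshp.sensitivity
        row["spec_dcrshp"] = drawn.accuracy_dcrshp.specificity
        row["sens_cysto"] = drawn.accuracy_cysto.sensitivity
        row["spec_cysto"] = drawn.accuracy_cysto.specificity
        if "diagnosis_split" in specs:
            for j, frac in enumerate(drawn.diagnosis_split):
                row[f"diagnosis_split_{j}"] = frac
        row["dcrshp_price"] = drawn.dcrshp_price
        draw_rows.append(row)
        out_rows.append({"cost_ref": ref.cost, "qalys_ref": ref.qalys,
                         "cost_alt": alt.cost, "qalys_alt": alt.qalys})
    return PSASample(draws=pd.DataFrame(draw_rows),
                     outcomes=pd.DataFrame(out_rows), seed=seed, n=n,
                     n_redrawn=n_redrawn)


@dataclass
class CEACurve:
    """Probability each strategy is cost-effective along a WTP grid."""

    wtp: np.ndarray
    p_triage: np.ndarray
    p_cysto: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "p_triage": self.p_triage,
                             "p_cystoscopy": self.p_cysto})


def ceac(sample: PSASample, wtp_grid) -> CEACurve:
    """Fraction of draws in which triage has the higher NMB (ties split)."""
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    p_tri = np.empty_like(wtp_grid)
    for i, w in enumerate(wtp_grid):
        d = sample.inmb(w)
        p_tri[i] = np.mean((d > 0) + 0.5 * (d == 0))
    return CEACurve(wtp=wtp_grid, p_triage=p_tri, p_cysto=1.0 - p_tri)
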