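"""Six-month-cycle Markov cohort model of bladder-cancer management.

Diagnosed patients occupy one of five treatment states — low-risk NMIBC,
high-risk NMIBC on BCG, high-risk NMIBC post-cystectomy, MIBC
post-cystectomy, metastasis — with recurrence, progression and
disease-specific mortality at the printed six-month probabilities.
Patients missed by the testing pathway (false negatives) occupy mirrored
*undiagnosed* states in which progression and disease-specific mortality
are inflated by the untreated relative risk, and from which they are
detected (and treated) on a staged schedule: 50% within the first year,
75% cumulatively by the second, all thereafter.

Within a cycle, disease-specific transitions are applied first and
other-cause (all-cause) mortality then removes a fraction of the residual
"stay" probability, so the printed disease probabilities are preserved
exactly.  Rewards are accumulated with half-cycle correction (average of
start- and end-of-cycle occupancy) and mid-cycle discounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import LifeTable
from .parameters import ParameterSet
from .pathway import CohortSplit

__all__ = ["STATES", "S", "detection_schedule", "cycle_dynamics",
           "build_transition_matrix", "initial_distribution", "run_cohort",
           "accumulate_rewards", "CohortTrace", "entry_effects"]

STATES = ["WELL", "LR", "HR_BCG", "HR_CYST", "MIBC", "MET",
          "U_LR", "U_HR_BCG", "U_HR_CYST", "U_MIBC", "U_MET",
          "DEAD_BC", "DEAD_OTHER"]
S = {name: i for i, name in enumerate(STATES)}
N_STATES = len(STATES)
ALIVE = np.arange(N_STATES) < S["DEAD_BC"]
UNDIAGNOSED = [S["U_LR"], S["U_HR_BCG"], S["U_HR_CYST"], S["U_MIBC"], S["U_MET"]]
DIAGNOSED_OF = {S["U_LR"]: S["LR"], S["U_HR_BCG"]: S["HR_BCG"],
                S["U_HR_CYST"]: S["HR_CYST"], S["U_MIBC"]: S["MIBC"],
                S["U_MET"]: S["MET"]}

EVENTS = ["turbt", "cystectomy", "detection", "enter_hrbcg", "enter_mibc",
          "enter_met"]
RECURRING = ["scopes", "bcg_vials", "ct_scans", "chemo_courses_met"]
_DAYS = 365.25


class MassConservationError(RuntimeError):
    pass


def detection_schedule(cycle: int, year1: float = 0.5, year2: float = 0.75) -> float:
    """Per-cycle conditional detection probability for undiagnosed patients.

    Reproduces the cumulative schedule: ``year1`` detected by the end of
    year 1, ``year2`` by the end of year 2, everyone after year 2.
    """
    if cycle < 1:
        raise ValueError("detection is undefined before the first cycle "
                         "(testing happens at time zero)")
    if cycle <= 2:
        return 1.0 - (1.0 - year1) ** 0.5
    if cycle <= 4:
        cond2 = (year2 - year1) / (1.0 - year1)
        return 1.0 - (1.0 - cond2) ** 0.5
    return 1.0


def _postcyst_utility(p: ParameterSet) -> float:
    """Standing post-cystectomy utility, impotence-weighted."""
    return p.u_postcyst * (p.p_impotence * p.u_impotence
                           + (1.0 - p.p_impotence))


def entry_effects(p: ParameterSet) -> dict[str, float]:
    """One-off QALY decrements attached to state-entry events."""
    cyst_dec = (max(0.0, _postcyst_utility(p) - p.u_cystectomy_period)
                * 60.0 / _DAYS
                + p.p_cyst_compl * p.d_cyst_compl * 60.0 / _DAYS)
    return {
        "turbt_dec": p.d_turbt * 7.0 / _DAYS,
        "cystectomy_dec": cyst_dec,
        "hrbcg_dec": (p.d_bcg_induction * 42.0 / _DAYS
                      + p.p_bcg_compl * p.d_bcg_compl * 0.5),
        "chemo_dec": p.d_chemo * 103.0 / _DAYS,
        "scope_dec": (1.0 - p.cysto_utility_factor) * 0.5,
    }


def cycle_dynamics(params: ParameterSet, cycle: int, life_table: LifeTable):
    """Transition matrix and per-occupant event rates for one model cycle.

    ``cycle`` is 1-based (cycle 1 covers months 0-6).  Returns ``(M, E)``
    where ``M`` is the row-stochastic transition matrix and ``E[s, e]`` the
    expected count of event ``e`` per occupant of state ``s``.
    """
    p = params
    # era split: "late" MIBC values bind beyond 5 years from model entry,
    # so they are inert at the default 5-year horizon
    late = (cycle - 1) * p.cycle_length >= 5.0
    prog_mibc_met = p.p_prog_mibc_met_late if late else p.p_prog_mibc_met
    bcdeath_mibc = p.p_bcdeath_mibc_late if late else p.p_bcdeath_mibc

    tm = p.p_turbt_mort
    cm = p.p_cystectomy_mort
    q_conv = p.p_rec_cystectomy
    rr = p.rr_untreated

    age = p.start_age + (cycle - 1) * p.cycle_length
    q_ac = life_table.death_prob(age)

    M = np.zeros((N_STATES, N_STATES))
    E = np.zeros((N_STATES, len(EVENTS)))
    ev = {name: i for i, name in enumerate(EVENTS)}

    def recurrence_branch(s: int, p_rec: float):
        """Recurrence: TURBT for all, a fraction converts to cystectomy."""
        E[s, ev["turbt"]] += p_rec
        died = p_rec * tm
        surv = p_rec * (1.0 - tm)
        conv = surv * q_conv
        E[s, ev["cystectomy"]] += conv
        died += conv * cm
        M[s, S["HR_CYST"]] += conv * (1.0 - cm)
        M[s, S["DEAD_BC"]] += died
        # non-converting recurrences remain in state: only the moved mass counts
        return died + conv * (1.0 - cm)  # probability of leaving the state

    def enter_mibc(s: int, flow: float):
        """Progression to MIBC: TURBT (if from an NMIBC state), cystectomy, chemo."""
        E[s, ev["turbt"]] += flow
        surv = flow * (1.0 - tm)
        E[s, ev["cystectomy"]] += surv
        arrive = surv * (1.0 - cm)
        E[s, ev["enter_mibc"]] += arrive
        M[s, S["MIBC"]] += arrive
        M[s, S["DEAD_BC"]] += flow - arrive
        return flow

    def enter_met_via_turbt(s: int, flow: float):
        E[s, ev["turbt"]] += flow
        arrive = flow * (1.0 - tm)
        E[s, ev["enter_met"]] += arrive
        M[s, S["MET"]] += arrive
        M[s, S["DEAD_BC"]] += flow - arrive
        return flow

    # --- WELL ------------------------------------------------------------
    out = 0.0
    if p.bc_death_in_well:
        M[S["WELL"], S["DEAD_BC"]] += p.p_bcdeath_nmibc
        out += p.p_bcdeath_nmibc
    _finish_row(M, S["WELL"], out, q_ac)

    # --- LR NMIBC --------------------------------------------------------
    s = S["LR"]
    out = p.p_bcdeath_nmibc
    M[s, S["DEAD_BC"]] += p.p_bcdeath_nmibc
    out += recurrence_branch(s, p.p_rec_lr)
    _finish_row(M, s, out, q_ac)

    # --- HR NMIBC on BCG --------------------------------------------------
    s = S["HR_BCG"]
    out = p.p_bcdeath_nmibc
    M[s, S["DEAD_BC"]] += p.p_bcdeath_nmibc
    out += recurrence_branch(s, p.p_rec_hr)
    out += enter_mibc(s, p.p_prog_hrbcg_mibc)
    out += enter_met_via_turbt(s, p.p_prog_hrbcg_met)
    _finish_row(M, s, out, q_ac)

    # --- HR NMIBC post-cystectomy ----------------------------------------
    s = S["HR_CYST"]
    out = p.p_bcdeath_nmibc + p.p_prog_hrcyst_met
    M[s, S["DEAD_BC"]] += p.p_bcdeath_nmibc
    M[s, S["MET"]] += p.p_prog_hrcyst_met
    E[s, ev["enter_met"]] += p.p_prog_hrcyst_met
    _finish_row(M, s, out, q_ac)

    # --- MIBC post-cystectomy --------------------------------------------
    s = S["MIBC"]
    out = bcdeath_mibc + prog_mibc_met
    M[s, S["DEAD_BC"]] += bcdeath_mibc
    M[s, S["MET"]] += prog_mibc_met
    E[s, ev["enter_met"]] += prog_mibc_met
    _finish_row(M, s, out, q_ac)

    # --- Metastasis -------------------------------------------------------
    s = S["MET"]
    M[s, S["DEAD_BC"]] += p.p_bcdeath_met
    _finish_row(M, s, p.p_bcdeath_met, q_ac)

    # --- undiagnosed mirrors ---------------------------------------------
    d = detection_schedule(cycle, p.fn_detect_year1, p.fn_detect_year2)
    rrp = lambda x: min(1.0, rr * x)
    # Untreated NMIBC is not held back by TURBT/BCG/cystectomy, so all
    # undiagnosed NMIBC states share the pooled NMIBC progression rates
    # (to MIBC and to metastasis), inflated by the untreated relative risk.
    nmibc_prog = [(S["U_MIBC"], rrp(p.p_prog_hrbcg_mibc)),
                  (S["U_MET"], rrp(p.p_prog_hrbcg_met))]
    undiag_moves = {
        S["U_LR"]: nmibc_prog,
        S["U_HR_BCG"]: nmibc_prog,
        S["U_HR_CYST"]: nmibc_prog,
        S["U_MIBC"]: [(S["U_MET"], rrp(prog_mibc_met))],
        S["U_MET"]: [],
    }
    undiag_death = {
        S["U_LR"]: rrp(p.p_bcdeath_nmibc),
        S["U_HR_BCG"]: rrp(p.p_bcdeath_nmibc),
        S["U_HR_CYST"]: rrp(p.p_bcdeath_nmibc),
        S["U_MIBC"]: rrp(bcdeath_mibc),
        S["U_MET"]: rrp(p.p_bcdeath_met),
    }
    for s in UNDIAGNOSED:
        target = DIAGNOSED_OF[s]
        out = d
        # detection first: TURBT for every detected patient, then the
        # diagnosed state's entry treatment
        E[s, ev["detection"]] += d
        E[s, ev["turbt"]] += d
        surv = d * (1.0 - tm)
        died = d * tm
        if target in (S["HR_CYST"], S["MIBC"]):
            E[s, ev["cystectomy"]] += surv
            arrive = surv * (1.0 - cm)
            died += surv * cm
            if target == S["MIBC"]:
                E[s, ev["enter_mibc"]] += arrive
        else:
            arrive = surv
        if target == S["HR_BCG"]:
            E[s, ev["enter_hrbcg"]] += arrive
        if target == S["MET"]:
            E[s, ev["enter_met"]] += arrive
        M[s, target] += arrive
        M[s, S["DEAD_BC"]] += died
        # undetected patients progress/die at the inflated rates
        u = 1.0 - d
        dd = u * undiag_death[s]
        M[s, S["DEAD_BC"]] += dd
        out += dd
        for tgt, prob in undiag_moves[s]:
            flow = u * prob
            M[s, tgt] += flow
            out += flow
        _finish_row(M, s, out, q_ac)

    # --- absorbing states -------------------------------------------------
    M[S["DEAD_BC"], S["DEAD_BC"]] = 1.0
    M[S["DEAD_OTHER"], S["DEAD_OTHER"]] = 1.0

    rowsum = M.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=1e-10):
        bad = STATES[int(np.argmax(np.abs(rowsum - 1.0)))]
        raise MassConservationError(f"row {bad} sums to {rowsum.max()}")
    return M, E


def _finish_row(M: np.ndarray, s: int, moved: float, q_ac: float) -> None:
    """Set the stay probability and apply other-cause death to the residual."""
    stay = 1.0 - moved
    if stay < -1e-12:
        raise ValueError(f"negative residual stay probability in state {STATES[s]}")
    stay = max(stay, 0.0)
    M[s, S["DEAD_OTHER"]] += stay * q_ac
    M[s, s] += stay * (1.0 - q_ac)


def build_transition_matrix(params: ParameterSet, cycle: int,
                            life_table: LifeTable) -> np.ndarray:
    """Row-stochastic transition matrix for one (1-based) model cycle."""
    M, _ = cycle_dynamics(params, cycle, life_table)
    return M


def horizon_dynamics(params: ParameterSet, life_table: LifeTable):
    """(M, E) pairs for every cycle; independent of the cohort split, so one
    computation serves both strategy arms."""
    return [cycle_dynamics(params, k + 1, life_table)
            for k in range(params.n_cycles)]


@dataclass
class CohortTrace:
    """Per-cycle state occupancy and event flows of the cohort."""

    occupancy: np.ndarray      # (n_cycles+1, N_STATES)
    events: pd.DataFrame       # one row per cycle, EVENTS + RECURRING columns
    init_cost: float           # time-zero entry treatment costs
    init_qaly_loss: float      # time-zero entry decrements

    def to_frame(self) -> pd.DataFrame:
        occ = pd.DataFrame(self.occupancy, columns=STATES)
        occ.index.name = "cycle_start"
        return occ


def initial_distribution(split: CohortSplit, params: ParameterSet):
    """Start-of-model occupancy vector plus time-zero treatment effects.

    True positives receive a diagnostic TURBT (mortality applied; its cost
    and decrement are charged by the testing pathway) and enter the
    diagnosed states per the case-mix split, incurring entry treatments
    (cystectomy, chemotherapy, BCG induction, palliative care).  False
    positives survive or die of their unnecessary TURBT and enter Well.
    False negatives enter the undiagnosed mirrors untreated.
    """
    p = params
    eff = entry_effects(p)
    occ = np.zeros(N_STATES)
    cost = 0.0
    qloss = 0.0
    tm = p.p_turbt_mort
    cm = p.p_cystectomy_mort
    split_states = [S["LR"], S["HR_BCG"], S["HR_CYST"], S["MIBC"], S["MET"]]
    u_states = [S["U_LR"], S["U_HR_BCG"], S["U_HR_CYST"], S["U_MIBC"], S["U_MET"]]

    occ[S["WELL"]] += split.tn
    occ[S["WELL"]] += split.fp * (1.0 - tm)
    occ[S["DEAD_BC"]] += split.fp * tm + split.tp * tm

    surv_tp = split.tp * (1.0 - tm)
    for frac, s in zip(p.diagnosis_split, split_states):
        m = surv_tp * frac
        if s in (S["HR_CYST"], S["MIBC"]):
            cost += m * p.cost_cystectomy
            qloss += m * eff["cystectomy_dec"]
            occ[S["DEAD_BC"]] += m * cm
            m_alive = m * (1.0 - cm)
            if s == S["MIBC"]:
                cost += m_alive * p.chemo_vials_per_course * p.cost_cisplatin_vial
                qloss += m_alive * eff["chemo_dec"]
            occ[s] += m_alive
        else:
            if s == S["HR_BCG"]:
                qloss += m * eff["hrbcg_dec"]
            if s == S["MET"]:
                cost += m * _palliative_cost(p)
            occ[s] += m

    for frac, s in zip(p.diagnosis_split, u_states):
        occ[s] += split.fn * frac

    total = occ.sum()
    if abs(total - 1.0) > 1e-9:
        raise MassConservationError(f"initial occupancy sums to {total}")
    return occ, cost, qloss


def _palliative_cost(p: ParameterSet) -> float:
    if p.palliative_per_day:
        return p.cost_palliative_day * p.palliative_days
    return p.cost_palliative_day


def _scope_rate(state: int, cycle: int) -> float:
    """Surveillance cystoscopies per occupant per cycle."""
    if state == S["LR"]:
        return 1.0 if cycle == 1 else 0.5
    if state == S["HR_BCG"]:
        if cycle <= 4:
            return 2.0
        if cycle <= 6:
            return 1.5
        return 0.5
    return 0.0


def _ct_rate(state: int, cycle: int) -> float:
    """CT scans per occupant per cycle (urogram or abdomen/pelvis)."""
    if state == S["HR_BCG"]:
        return 0.5  # annual CT urogram
    if state in (S["HR_CYST"], S["MIBC"]):
        if cycle <= 2:
            return 1.5
        if cycle <= 6:
            return 1.0
        return 0.5
    return 0.0


def run_cohort(init, params: ParameterSet, life_table: LifeTable,
               init_cost: float = 0.0, init_qaly_loss: float = 0.0,
               dynamics=None) -> CohortTrace:
    """Propagate the cohort over the horizon, recording occupancy and events.

    ``init`` may be an occupancy vector or the tuple from
    :func:`initial_distribution`.  ``dynamics`` (from
    :func:`horizon_dynamics`) may be supplied to share the per-cycle
    matrices between strategy arms.
    """
    if isinstance(init, tuple):
        init, init_cost, init_qaly_loss = init
    init = np.asarray(init, dtype=float)
    if abs(init.sum() - 1.0) > 1e-9:
        raise MassConservationError("initial occupancy must sum to 1")
    n = params.n_cycles
    if dynamics is None:
        dynamics = horizon_dynamics(params, life_table)
    occ = np.zeros((n + 1, N_STATES))
    occ[0] = init
    ev_rows = []
    for k in range(n):
        cycle = k + 1
        M, E = dynamics[k]
        start = occ[k]
        occ[k + 1] = start @ M
        if abs(occ[k + 1].sum() - 1.0) > 1e-9:
            raise MassConservationError(f"mass not conserved at cycle {cycle}")
        counts = start @ E  # expected event counts this cycle
        row = dict(zip(EVENTS, counts))
        hcc = 0.5 * (start + occ[k + 1])
        row["scopes"] = sum(hcc[s] * _scope_rate(s, cycle)
                            for s in (S["LR"], S["HR_BCG"]))
        row["bcg_vials"] = hcc[S["HR_BCG"]] * (6.0 if cycle <= 6 else 0.0)
        row["ct_scans"] = sum(hcc[s] * _ct_rate(s, cycle)
                              for s in (S["HR_BCG"], S["HR_CYST"], S["MIBC"]))
        row["chemo_courses_met"] = hcc[S["MET"]] * params.p_chemo_response
        ev_rows.append(row)
    events = pd.DataFrame(ev_rows, index=pd.RangeIndex(1, n + 1, name="cycle"))
    return CohortTrace(occupancy=occ, events=events,
                       init_cost=init_cost, init_qaly_loss=init_qaly_loss)


def state_utilities(p: ParameterSet) -> np.ndarray:
    """Standing utility weight for each state."""
    u = np.zeros(N_STATES)
    u[S["WELL"]] = p.u_well
    u[S["LR"]] = u[S["HR_BCG"]] = p.u_cancer
    u[S["HR_CYST"]] = u[S["MIBC"]] = _postcyst_utility(p)
    u[S["MET"]] = (p.p_chemo_response * p.u_met_responsive
                   + (1.0 - p.p_chemo_response) * p.u_met_unresponsive)
    for s in UNDIAGNOSED:
        u[s] = p.u_cancer
    return u


def accumulate_rewards(trace: CohortTrace, params: ParameterSet,
                       discount_rate: float | None = None,
                       half_cycle: bool = True):
    """Discounted (cost, QALYs, life years) per patient over the horizon.

    Per-cycle rewards use half-cycle-corrected occupancy (start/end average)
    and a discount factor evaluated at the cycle midpoint; time-zero entry
    effects recorded on the trace are added undiscounted.
    """
    p = params
    r = p.discount_rate if discount_rate is None else discount_rate
    eff = entry_effects(p)
    u = state_utilities(p)
    chemo_cost = p.chemo_vials_per_course * p.cost_cisplatin_vial
    event_cost = {"turbt": p.cost_turbt, "cystectomy": p.cost_cystectomy,
                  "detection": 0.0, "enter_hrbcg": 0.0,
                  "enter_mibc": chemo_cost, "enter_met": _palliative_cost(p),
                  "scopes": p.cost_cysto, "bcg_vials": p.cost_bcg_vial,
                  "ct_scans": p.cost_ct, "chemo_courses_met": chemo_cost}
    event_dec = {"turbt": eff["turbt_dec"], "cystectomy": eff["cystectomy_dec"],
                 "detection": 0.0, "enter_hrbcg": eff["hrbcg_dec"],
                 "enter_mibc": eff["chemo_dec"], "enter_met": 0.0,
                 "scopes": eff["scope_dec"], "bcg_vials": 0.0,
                 "ct_scans": 0.0, "chemo_courses_met": eff["chemo_dec"]}

    occ = trace.occupancy
    n = occ.shape[0] - 1
    cols = list(trace.events.columns)
    counts = trace.events.to_numpy()                    # (n, n_event_cols)
    cost_vec = np.array([event_cost[c] for c in cols])
    dec_vec = np.array([event_dec[c] for c in cols])
    mid_t = (np.arange(n) + 0.5) * p.cycle_length
    disc = (1.0 + r) ** (-mid_t)
    hcc = 0.5 * (occ[:-1] + occ[1:]) if half_cycle else occ[:-1]
    life_years = float(disc @ hcc[:, ALIVE].sum(axis=1)) * p.cycle_length
    q_cycles = hcc @ u * p.cycle_length - counts @ dec_vec
    c_cycles = counts @ cost_vec
    cost = trace.init_cost + float(disc @ c_cycles)
    qalys = -trace.init_qaly_loss + float(disc @ q_cycles)
    return cost, qalys, life_years
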