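import numpy as np
import pandas as pd
import pytest

import cystotriage.markov as mk
from cystotriage.markov import (S, STATES, CohortTrace, accumulate_rewards,
                                build_transition_matrix, cycle_dynamics,
                                detection_schedule, entry_effects,
                                initial_distribution, run_cohort,
                                state_utilities)
from cystotriage.parameters import build_base_case
from cystotriage.pathway import Strategy, classify_cohort
from conftest import no_death_params


class TestDetectionSchedule:
    def test_first_year_cumulative_half(self):
        d = detection_schedule(1)
        assert (1 - d) ** 2 == pytest.approx(0.5, rel=1e-12)
        assert d == pytest.approx(1 - np.sqrt(0.5), rel=1e-12)

    def test_second_year_cumulative_three_quarters(self):
        surv = 1.0
        for c in range(1, 5):
            surv *= 1 - detection_schedule(c)
        assert 1 - surv == pytest.approx(0.75, rel=1e-12)

    def test_everyone_found_after_second_year(self):
        assert detection_schedule(5) == 1.0
        assert detection_schedule(9) == 1.0

    def test_undefined_before_first_cycle(self):
        with pytest.raises(ValueError):
            detection_schedule(0)


class TestTransitionMatrix:
    def test_rows_sum_to_one_every_cycle(self, base_params, life_table):
        for cycle in range(1, 11):
            M = build_transition_matrix(base_params, cycle, life_table)
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-10)
            assert ((M >= 0) & (M <= 1)).all()

    def test_dead_states_absorbing(self, base_params, life_table):
        M = build_transition_matrix(base_params, 3, life_table)
        for name in ("DEAD_BC", "DEAD_OTHER"):
            row = np.zeros(len(STATES))
            row[S[name]] = 1.0
            assert (M[S[name]] == row).all()

    def test_untreated_progression_inflated_by_rr(self, base_params, life_table):
        # undiagnosed HR(BCG) -> undiagnosed MIBC at (1-d) * min(1, 2.56 x 0.030)
        M = build_transition_matrix(base_params, 1, life_table)
        d = detection_schedule(1)
        assert min(1.0, 2.56 * 0.030) == pytest.approx(0.0768)
        assert M[S["U_HR_BCG"], S["U_MIBC"]] == pytest.approx((1 - d) * 0.0768)

    def test_rr_one_matches_diagnosed_probabilities(self, life_table):
        """With RR = 1, undiagnosed HR(BCG) progression and disease death
        equal the diagnosed state's (up to detection and treatment flows)."""
        p = build_base_case({"rr_untreated": 1.0})
        M = build_transition_matrix(p, 1, life_table)
        d = detection_schedule(1)
        assert M[S["U_HR_BCG"], S["U_MIBC"]] / (1 - d) == pytest.approx(
            p.p_prog_hrbcg_mibc)
        assert M[S["U_MIBC"], S["U_MET"]] / (1 - d) == pytest.approx(
            p.p_prog_mibc_met)
        # undiagnosed MET death = detection-TURBT deaths + untreated deaths
        expected = d * p.p_turbt_mort + (1 - d) * p.p_bcdeath_met
        assert M[S["U_MET"], S["DEAD_BC"]] == pytest.approx(expected)

    def test_null_dynamics_identity_except_detection(self, zero_mortality_life_table):
        p = no_death_params()
        M = build_transition_matrix(p, 1, zero_mortality_life_table)
        d = detection_schedule(1)
        for name in ("WELL", "LR", "HR_BCG", "HR_CYST", "MIBC", "MET"):
            assert M[S[name], S[name]] == pytest.approx(1.0)
        for u_name, d_name in (("U_LR", "LR"), ("U_MIBC", "MIBC")):
            assert M[S[u_name], S[u_name]] == pytest.approx(1 - d)
            assert M[S[u_name], S[d_name]] == pytest.approx(d)

    def test_infeasible_row_raises(self, life_table):
        p = build_base_case({"rr_untreated": 12.0})
        with pytest.raises(ValueError, match="U_MIBC"):
            build_transition_matrix(p, 1, life_table)


class TestInitialDistribution:
    def _split(self, p, strategy=Strategy.CYSTOSCOPY_ONLY):
        return classify_cohort(p.prevalence, strategy, p.accuracy_dcrshp,
                               p.accuracy_cysto)

    def test_pure_tp_cohort(self):
        from cystotriage.pathway import CohortSplit
        p = build_base_case({"prevalence": 1.0,
                             "sens_cysto": 1.0, "spec_cysto": 1.0})
        split = CohortSplit(tp=1.0, fp=0.0, tn=0.0, fn=0.0)
        occ, cost, qloss = initial_distribution(split, p)
        surv = 1 - p.p_turbt_mort
        assert occ[S["LR"]] == pytest.approx(surv * 105 / 192)
        assert occ[S["MET"]] == pytest.approx(surv * 13 / 192)
        # cystectomy-track entrants also face operative mortality
        assert occ[S["MIBC"]] == pytest.approx(
            surv * (14 / 192) * (1 - p.p_cystectomy_mort))
        assert occ.sum() == pytest.approx(1.0, abs=1e-12)
        assert cost > 0 and qloss > 0

    def test_disease_free_perfectly_specific_cohort(self):
        p = build_base_case({"prevalence": 0.0, "spec_cysto": 1.0,
                             "spec_dcrshp": 1.0})
        occ, cost, qloss = initial_distribution(self._split(p), p)
        assert occ[S["WELL"]] == pytest.approx(1.0)
        assert cost == 0.0 and qloss == 0.0

    def test_fn_mass_enters_undiagnosed_mirrors(self, base_params):
        occ, *_ = initial_distribution(self._split(base_params), base_params)
        split = self._split(base_params)
        undiag = sum(occ[S[n]] for n in ("U_LR", "U_HR_BCG", "U_HR_CYST",
                                         "U_MIBC", "U_MET"))
        assert undiag == pytest.approx(split.fn, abs=1e-12)


class TestRunCohort:
    def test_mass_conserved_and_dead_monotone(self, base_params, life_table):
        split = classify_cohort(base_params.prevalence, Strategy.DCRSHP_TRIAGE,
                                base_params.accuracy_dcrshp,
                                base_params.accuracy_cysto)
        trace = run_cohort(initial_distribution(split, base_params),
                           base_params, life_table)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        for name in ("DEAD_BC", "DEAD_OTHER"):
            assert (np.diff(trace.occupancy[:, S[name]]) >= -1e-12).all()

    def test_all_well_cohort_is_static_without_mortality(
            self, zero_mortality_life_table):
        p = no_death_params()
        init = np.zeros(len(STATES))
        init[S["WELL"]] = 1.0
        trace = run_cohort(init, p, zero_mortality_life_table)
        assert np.allclose(trace.occupancy, init, atol=1e-12)

    def test_no_false_negatives_no_undiagnosed_mass(self, base_params, life_table):
        p = build_base_case({"sens_cysto": 1.0})
        split = classify_cohort(p.prevalence, Strategy.CYSTOSCOPY_ONLY,
                                p.accuracy_dcrshp, p.accuracy_cysto)
        trace = run_cohort(initial_distribution(split, p), p, life_table)
        for name in ("U_LR", "U_HR_BCG", "U_HR_CYST", "U_MIBC", "U_MET"):
            assert (trace.occupancy[:, S[name]] == 0).all()

    def test_undiagnosed_mass_halves_within_first_year(
            self, zero_mortality_life_table):
        """With deaths off, detection alone drains half the undiagnosed
        cohort by the end of cycle 2."""
        p = no_death_params()
        init = np.zeros(len(STATES))
        init[S["U_LR"]] = 0.6
        init[S["U_HR_BCG"]] = 0.4
        trace = run_cohort(init, p, zero_mortality_life_table)
        undiag = trace.occupancy[:, [S["U_LR"], S["U_HR_BCG"], S["U_HR_CYST"],
                                     S["U_MIBC"], S["U_MET"]]].sum(axis=1)
        assert undiag[2] == pytest.approx(0.5, rel=1e-10)
        assert undiag[4] == pytest.approx(0.25, rel=1e-10)
        assert undiag[5] == pytest.approx(0.0, abs=1e-12)


class TestRewards:
    def _flat_trace(self, p, n_events=None):
        n = p.n_cycles
        occ = np.zeros((n + 1, len(STATES)))
        occ[:, S["WELL"]] = 1.0
        events = pd.DataFrame(0.0, index=range(1, n + 1),
                              columns=mk.EVENTS + mk.RECURRING)
        if n_events:
            for (cycle, name), v in n_events.items():
                events.loc[cycle, name] = v
        return CohortTrace(occupancy=occ, events=events,
                           init_cost=0.0, init_qaly_loss=0.0)

    def test_full_health_no_discount_limit(self):
        p = build_base_case({"discount_rate": 0.0})
        cost, qalys, ly = accumulate_rewards(self._flat_trace(p), p)
        assert ly == pytest.approx(5.0, rel=1e-12)
        assert qalys == pytest.approx(5.0, rel=1e-12)
        assert cost == 0.0

    def test_discounted_annuity_closed_form(self, base_params):
        """No deaths: life years equal the mid-cycle discounted annuity."""
        _, _, ly = accumulate_rewards(self._flat_trace(base_params), base_params)
        r = base_params.discount_rate
        expected = sum(0.5 * (1 + r) ** (-(k + 0.5) / 2) for k in range(10))
        assert ly == pytest.approx(expected, rel=1e-10)

    def test_single_turbt_event_decrement(self):
        p = build_base_case({"discount_rate": 0.0})
        trace = self._flat_trace(p, {(1, "turbt"): 1.0})
        cost, qalys, _ = accumulate_rewards(trace, p)
        assert cost == pytest.approx(2435.0)
        assert 5.0 - qalys == pytest.approx(0.1 * 7 / 365.25, rel=1e-6)

    def test_discounting_never_increases_qalys(self, base_params, life_table):
        split = classify_cohort(base_params.prevalence, Strategy.CYSTOSCOPY_ONLY,
                                base_params.accuracy_dcrshp,
                                base_params.accuracy_cysto)
        trace = run_cohort(initial_distribution(split, base_params),
                           base_params, life_table)
        _, q_disc, ly_disc = accumulate_rewards(trace, base_params)
        _, q_undisc, ly_undisc = accumulate_rewards(trace, base_params,
                                                    discount_rate=0.0)
        assert q_disc <= q_undisc <= ly_undisc <= base_params.horizon_years
        assert q_disc <= ly_disc


class TestMicrosimulationOracle:
    def test_cohort_engine_matches_seeded_microsimulation(
            self, base_params, life_table, rng):
        """Expectation over simulated individual patients reproduces the
        cohort engine's cost and QALYs within 3 Monte-Carlo SEs."""
        p = base_params
        split = classify_cohort(p.prevalence, Strategy.DCRSHP_TRIAGE,
                                p.accuracy_dcrshp, p.accuracy_cysto)
        init, init_cost, init_qaly = initial_distribution(split, p)
        trace = run_cohort((init, init_cost, init_qaly), p, life_table)
        cost_ref, qaly_ref, _ = accumulate_rewards(trace, p)

        # per-state per-cycle reward rates, rebuilt from first principles
        eff = entry_effects(p)
        u = state_utilities(p)
        chemo = p.chemo_vials_per_course * p.cost_cisplatin_vial
        ev_cost = np.array([p.cost_turbt, p.cost_cystectomy, 0.0, 0.0,
                            chemo, p.cost_palliative_day *
                            (p.palliative_days if p.palliative_per_day else 1.0)])
        ev_dec = np.array([eff["turbt_dec"], eff["cystectomy_dec"], 0.0,
                           eff["hrbcg_dec"], eff["chemo_dec"], 0.0])

        n_pat = 40_000
        states = rng.choice(len(STATES), size=n_pat, p=init)
        cost_tot = np.full(n_pat, init_cost)
        qaly_tot = np.full(n_pat, -init_qaly)
        for k in range(p.n_cycles):
            cycle = k + 1
            M, E = cycle_dynamics(p, cycle, life_table)
            disc = 1.035 ** (-(k + 0.5) * 0.5)
            cum = M.cumsum(axis=1)
            nxt = np.empty_like(states)
            for s in np.unique(states):
                idx = np.flatnonzero(states == s)
                nxt[idx] = np.searchsorted(cum[s], rng.random(idx.size))
            # recurring schedule rates at start/end states (half-cycle style)
            def recurring(st_vec):
                scope = np.array([mk._scope_rate(s, cycle) for s in range(len(STATES))])
                ct = np.array([mk._ct_rate(s, cycle) for s in range(len(STATES))])
                bcg = np.where(np.arange(len(STATES)) == S["HR_BCG"],
                               6.0 if cycle <= 6 else 0.0, 0.0)
                met = np.where(np.arange(len(STATES)) == S["MET"],
                               p.p_chemo_response, 0.0)
                c = (scope * p.cost_cysto + ct * p.cost_ct
                     + bcg * p.cost_bcg_vial + met * chemo)
                q = scope * eff["scope_dec"] + met * eff["chemo_dec"]
                return c[st_vec], q[st_vec]
            c0, q0 = recurring(states)
            c1, q1 = recurring(nxt)
            cost_tot += disc * (E[states] @ ev_cost + 0.5 * (c0 + c1))
            qaly_tot += disc * (0.25 * (u[states] + u[nxt])
                                - E[states] @ ev_dec - 0.5 * (q0 + q1))
            states = nxt
        se_c = cost_tot.std() / np.sqrt(n_pat)
        se_q = qaly_tot.std() / np.sqrt(n_pat)
        assert abs(cost_tot.mean() - cost_ref) < 3 * se_c
        assert abs(qaly_tot.mean() - qaly_ref) < 3 * se_q
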