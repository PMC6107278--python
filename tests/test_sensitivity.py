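import dataclasses

import numpy as np
import pandas as pd
import pytest

from cystotriage.parameters import build_base_case, default_psa_specs
from cystotriage.sensitivity import (PSASample, ceac, cysto_disutility_sweep,
                                     prevalence_sweep, qaly_crossover, run_psa,
                                     threshold_price, threshold_price_bisection,
                                     two_way_price_prevalence)


class TestThresholdPrice:
    def test_closed_form_equals_bisection_base_case(self, base_params):
        price, ok = threshold_price(base_params, 20000.0)
        assert ok
        assert abs(price - threshold_price_bisection(base_params, 20000.0)) < 0.01

    def test_closed_form_equals_bisection_random_draws(self, base_params):
        specs = default_psa_specs(base_params)
        from cystotriage.parameters import sample_parameter_set
        checked = 0
        for seed in range(40):
            try:
                drawn = sample_parameter_set(base_params, specs, seed)
            except ValueError:
                continue
            closed, _ = threshold_price(drawn, 20000.0)
            assert abs(closed - threshold_price_bisection(drawn, 20000.0)) < 0.01
            checked += 1
            if checked >= 20:
                break
        assert checked >= 20

    def test_not_cost_effective_at_zero_flag(self):
        # a triage test that misses every cancer in a high-prevalence cohort
        # is not cost-effective even when free (at a QALY-dominated WTP)
        p = build_base_case({"sens_dcrshp": 0.0, "prevalence": 0.4})
        price, ok = threshold_price(p, 50000.0)
        assert price == 0.0 and not ok

    def test_rejects_nonpositive_wtp(self, base_params):
        with pytest.raises(ValueError):
            threshold_price(base_params, 0.0)


@pytest.fixture(scope="module")
def sweep(base_params):
    return prevalence_sweep(base_params, np.arange(0.0, 0.2001, 0.01))


class TestPrevalenceSweep:

    def test_triage_gains_qalys_in_disease_free_cohort(self, sweep):
        assert sweep.delta_qalys.iloc[0] > 0

    def test_delta_qalys_strictly_decreasing(self, sweep):
        assert (np.diff(sweep.delta_qalys) < 0).all()

    def test_crossover_interpolation(self):
        df = pd.DataFrame({"prevalence": [0.0, 0.1, 0.2],
                           "delta_qalys": [0.002, 0.001, -0.001]})
        assert qaly_crossover(df) == pytest.approx(0.15)
        df_none = pd.DataFrame({"prevalence": [0.0, 0.1],
                                "delta_qalys": [0.002, 0.001]})
        assert qaly_crossover(df_none) is None


class TestTwoWay:
    def test_frontier_consistent_with_threshold_price(self, base_params):
        frontier = two_way_price_prevalence(base_params, [base_params.prevalence])
        direct, _ = threshold_price(base_params, 20000.0)
        assert frontier.threshold_price.iloc[0] == pytest.approx(direct, abs=1e-6)

    def test_effectiveness_flag_tracks_delta_qalys(self, base_params):
        frontier = two_way_price_prevalence(base_params, [0.0, 0.14])
        assert (frontier.effective
                == (frontier.delta_qalys_at_zero_price > 0)).all()


def test_cysto_disutility_sweep_monotone(base_params):
    sweep = cysto_disutility_sweep(base_params, np.linspace(0.95, 1.0, 11))
    # the less harmful the cystoscopy, the smaller the triage advantage
    assert (np.diff(sweep.delta_qalys) < 0).all()
    base_row = sweep[np.isclose(sweep.cysto_utility_factor, 0.997)]
    assert len(base_row) == 0 or base_row.delta_qalys.notna().all()


class TestRunPsa:
    def test_determinism(self, base_params):
        a = run_psa(base_params, n=40, seed=5)
        b = run_psa(base_params, n=40, seed=5)
        pd.testing.assert_frame_equal(a.outcomes, b.outcomes)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_single_fixed_draw_reproduces_base_case(self, base_params):
        from cystotriage.distributions import fixed
        from cystotriage.economics import evaluate_both
        sample = run_psa(base_params, specs={"prevalence": fixed(base_params.prevalence)},
                         n=1, seed=0, price_range=None)
        ref, alt = evaluate_both(base_params)
        assert sample.outcomes.cost_ref[0] == pytest.approx(ref.cost)
        assert sample.outcomes.qalys_alt[0] == pytest.approx(alt.qalys)

    def test_sampled_accuracy_means(self, base_params):
        sample = run_psa(base_params, n=400, seed=3)
        emp = sample.draws["sens_dcrshp"]
        mc_se = emp.std() / np.sqrt(len(emp))
        assert abs(emp.mean() - 57 / 63) < 4 * mc_se

    def test_price_drawn_within_range(self, base_params):
        sample = run_psa(base_params, n=50, seed=9, price_range=(50.0, 620.0))
        assert sample.draws.dcrshp_price.between(50, 620).all()


class TestCeac:
    def _toy_sample(self, d_cost, d_qaly):
        n = len(d_cost)
        outcomes = pd.DataFrame({
            "cost_ref": np.zeros(n), "qalys_ref": np.zeros(n),
            "cost_alt": d_cost, "qalys_alt": d_qaly})
        return PSASample(draws=pd.DataFrame(index=range(n)),
                         outcomes=outcomes, seed=0, n=n)

    def test_single_draw_step_curve(self):
        sample = self._toy_sample(np.array([-10.0]), np.array([0.0]))
        curve = ceac(sample, [0.0, 1000.0])
        assert (curve.p_triage == 1.0).all()

    def test_limits_recover_known_fractions(self, rng):
        d_cost = rng.normal(0, 1, 1000)
        d_qaly = rng.normal(0, 1, 1000)
        sample = self._toy_sample(d_cost, d_qaly)
        assert ceac(sample, [0.0]).p_triage[0] == pytest.approx(
            np.mean(d_cost < 0), abs=1e-12)
        assert ceac(sample, [1e12]).p_triage[0] == pytest.approx(
            np.mean(d_qaly > 0), abs=1e-3)

    def test_curves_sum_to_one_and_ties_split(self):
        sample = self._toy_sample(np.array([0.0, -1.0]), np.array([0.0, 0.0]))
        curve = ceac(sample, [0.0, 20000.0])
        assert np.allclose(curve.p_triage + curve.p_cysto, 1.0)
        assert curve.p_triage[0] == pytest.approx(0.75)  # one tie, one win
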