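"""Markov engine: conversions, matrix construction, trace invariants.

Closed-form expectations are computed inline from the continuous-time
competing-risk model, independently of the engine's cycle iteration.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckdcea import engine, fixtures, outcomes


def closed_form_times(p_onset, p_death_pre, p_death_dial):
    """Continuous-time constant-hazard expectations: mean years pre-dialysis,
    probability of ever reaching dialysis, and mean years in dialysis."""
    r_d = -math.log(1 - p_onset)
    r_m = -math.log(1 - p_death_pre)
    r_dd = -math.log(1 - p_death_dial)
    t_pre = 1.0 / (r_d + r_m)
    reach = r_d / (r_d + r_m)
    return t_pre, reach, reach / r_dd


class TestConversions:
    def test_prob_to_rate_values(self):
        assert engine.annual_prob_to_rate(0.0) == 0.0
        assert engine.annual_prob_to_rate(0.244) == pytest.approx(
            -math.log(0.756), rel=1e-12
        )
        # frozen closed-form evaluation of -ln(0.756)
        assert engine.annual_prob_to_rate(0.244) == pytest.approx(0.279714, abs=5e-7)

    @given(st.floats(min_value=0.0, max_value=0.999))
    @settings(derandomize=True, max_examples=50)
    def test_rate_prob_inverse_pair(self, p):
        assert engine.rate_to_prob(engine.annual_prob_to_rate(p)) == pytest.approx(
            p, abs=1e-12
        )

    def test_prob_out_of_domain(self):
        with pytest.raises(ValueError):
            engine.annual_prob_to_rate(1.0)
        with pytest.raises(ValueError):
            engine.annual_prob_to_rate(-0.1)

    def test_hazard_ratio_identity_and_zero(self):
        assert engine.apply_hazard_ratio(0.244, 1.0) == pytest.approx(0.244)
        assert engine.apply_hazard_ratio(0.244, 0.0) == 0.0

    def test_hazard_ratio_on_hazard_scale(self):
        # 1 - 0.756^0.237, frozen
        assert engine.apply_hazard_ratio(0.244, 0.237) == pytest.approx(
            0.064143, abs=5e-7
        )
        assert engine.apply_hazard_ratio(0.244, 0.237) == pytest.approx(
            1 - 0.756**0.237, rel=1e-12
        )

    @given(
        st.floats(min_value=0.01, max_value=0.9),
        st.floats(min_value=0.1, max_value=3.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_hazard_ratio_multiplies_rate(self, p, hr):
        scaled = engine.apply_hazard_ratio(p, hr)
        assert engine.annual_prob_to_rate(scaled) == pytest.approx(
            hr * engine.annual_prob_to_rate(p), rel=1e-10
        )


class TestExitSplit:
    def test_competing_exit_closed_form(self):
        r_d = engine.annual_prob_to_rate(0.244)
        r_m = engine.annual_prob_to_rate(0.111)
        p_exit, shares = engine.per_cycle_exit_split([r_d, r_m], 1.0)
        assert p_exit == pytest.approx(1 - math.exp(-(r_d + r_m) / 12), rel=1e-12)
        assert p_exit == pytest.approx(0.0325721, abs=5e-7)  # frozen
        assert shares[0] == pytest.approx(r_d / (r_d + r_m), rel=1e-12)
        assert shares[0] == pytest.approx(0.7039095, abs=5e-7)  # frozen

    def test_single_destination(self):
        p_exit, shares = engine.per_cycle_exit_split([0.3, 0.0], 1.0)
        assert shares[0] == 1.0 and shares[1] == 0.0

    def test_symmetric_split(self):
        _, shares = engine.per_cycle_exit_split([0.2, 0.2], 6.0)
        assert shares[0] == shares[1] == 0.5

    def test_all_zero_rates_flagged(self):
        p_exit, shares = engine.per_cycle_exit_split([0.0, 0.0], 1.0)
        assert p_exit == 0.0
        assert np.all(np.isnan(shares))

    def test_shares_sum_to_one(self):
        _, shares = engine.per_cycle_exit_split([0.1, 0.2, 0.3], 1.0)
        assert shares.sum() == pytest.approx(1.0)


class TestCycleMatrix:
    def test_structure(self, default_params):
        m = engine.build_cycle_matrix(
            default_params.transition, "lpd", default_params.settings
        )
        assert m.shape == (3, 3)
        assert np.allclose(m.sum(axis=1), 1.0)
        assert np.all(m >= 0)
        assert np.array_equal(m[2], [0, 0, 1])  # death absorbing
        assert m[1, 0] == 0.0  # no return from dialysis

    def test_lpd_pre_row_matches_exit_split(self, default_params):
        m = engine.build_cycle_matrix(
            default_params.transition, "lpd", default_params.settings
        )
        r_d = engine.annual_prob_to_rate(0.244)
        r_m = engine.annual_prob_to_rate(0.111)
        p_exit, shares = engine.per_cycle_exit_split([r_d, r_m], 1.0)
        assert m[0, 1] == pytest.approx(p_exit * shares[0], rel=1e-12)
        assert m[0, 2] == pytest.approx(p_exit * shares[1], rel=1e-12)

    def test_dialysis_monthly_death_prob(self):
        # 1 - exp(ln(1 - 0.138)/12), frozen
        assert engine.dialysis_monthly_death_prob(0.138) == pytest.approx(
            0.0122987, abs=5e-7
        )

    def test_hr_one_gives_lpd_matrix(self, default_params):
        t = default_params.transition.model_copy(deep=True)
        t.hr_dialysis_svlpd = t.hr_dialysis_svlpd.replace_value(1.0)
        m_sv = engine.build_cycle_matrix(t, "svlpd", default_params.settings)
        m_lpd = engine.build_cycle_matrix(t, "lpd", default_params.settings)
        assert np.allclose(m_sv, m_lpd, atol=1e-14)

    def test_unknown_strategy(self, default_params):
        with pytest.raises(ValueError):
            engine.build_cycle_matrix(
                default_params.transition, "vlpd", default_params.settings
            )


class TestCohortTrace:
    @pytest.mark.parametrize("seed", range(8))
    def test_conservation_and_monotonicity(self, seed):
        params = fixtures.random_valid_parameters(seed, jitter=0.3)
        for strategy in engine.STRATEGIES:
            trace = engine.run_strategy(params.transition, strategy, params.settings)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(trace.occupancy >= -1e-15)
            dead = trace.state_occupancy(engine.DEAD)
            assert np.all(np.diff(dead) >= -1e-15)
            pre = trace.state_occupancy(engine.PRE)
            assert np.all(np.diff(pre) <= 1e-15)

    def test_zero_transitions_hit_horizon_cap(self, default_params):
        settings_ = default_params.settings.model_copy(
            update={"horizon_max_cycles": 50}
        )
        m = np.eye(3)
        trace = engine.run_cohort(m, settings_)
        assert trace.horizon_capped
        assert trace.n_cycles == 50
        assert np.allclose(trace.occupancy, trace.occupancy[0])

    def test_fast_path_matches_generic_iteration(self, default_params):
        m = engine.build_cycle_matrix(
            default_params.transition, "svlpd", default_params.settings
        )
        fast = engine.run_cohort(m, default_params.settings)
        slow = engine.run_cohort(lambda k: m, default_params.settings)
        assert fast.occupancy.shape == slow.occupancy.shape
        assert np.allclose(fast.occupancy, slow.occupancy, atol=1e-12)
        assert np.allclose(
            fast.new_dialysis_entries, slow.new_dialysis_entries, atol=1e-12
        )

    def test_dialysis_entries_accumulate_to_dialysis_inflow(self, default_params):
        trace = engine.run_strategy(
            default_params.transition, "lpd", default_params.settings
        )
        # everyone entering dialysis either is there or has died from there
        p_dd = engine.dialysis_monthly_death_prob(0.138)
        dial = trace.state_occupancy(engine.DIAL)
        expected_next = dial[:-1] * (1 - p_dd) + trace.new_dialysis_entries
        assert np.allclose(dial[1:], expected_next, atol=1e-12)

    def test_unknown_state_raises(self, default_params):
        trace = engine.run_strategy(
            default_params.transition, "lpd", default_params.settings
        )
        with pytest.raises(KeyError):
            trace.state_index("transplant")


class TestOracleEquivalence:
    """Trace-derived mean state times vs continuous-time closed forms."""

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("strategy", engine.STRATEGIES)
    def test_state_times_match_closed_form(self, seed, strategy):
        params = fixtures.random_valid_parameters(seed, jitter=0.3)
        t = params.transition
        p_onset = t.p_dialysis_annual_lpd.value
        if strategy == "svlpd":
            p_onset = engine.apply_hazard_ratio(p_onset, t.hr_dialysis_svlpd.value)
        exp_pre, _, exp_dial = closed_form_times(
            p_onset, t.p_death_pre_annual.value, t.p_death_dialysis_annual.value
        )
        trace = engine.run_strategy(t, strategy, params.settings)
        got_pre = outcomes.accumulate_time(trace, engine.PRE, params.settings)
        got_dial = outcomes.accumulate_time(trace, engine.DIAL, params.settings)
        cycle_years = 1.0 / 12.0
        assert abs(got_pre - exp_pre) < cycle_years
        assert abs(got_dial - exp_dial) < cycle_years

    def test_lower_hr_delays_dialysis(self, default_params):
        pre_times, dial_times = [], []
        for hr in (1.0, 0.5, 0.237, 0.1):
            t = default_params.transition.model_copy(deep=True)
            t.hr_dialysis_svlpd = t.hr_dialysis_svlpd.replace_value(hr)
            trace = engine.run_strategy(t, "svlpd", default_params.settings)
            pre_times.append(
                outcomes.accumulate_time(trace, engine.PRE, default_params.settings)
            )
            dial_times.append(
                outcomes.accumulate_time(trace, engine.DIAL, default_params.settings)
            )
        assert all(a < b for a, b in zip(pre_times, pre_times[1:]))
        assert all(a > b for a, b in zip(dial_times, dial_times[1:]))

    def test_hr_one_traces_identical(self, default_params):
        t = default_params.transition.model_copy(deep=True)
        t.hr_dialysis_svlpd = t.hr_dialysis_svlpd.replace_value(1.0)
        lpd = engine.run_strategy(t, "lpd", default_params.settings)
        svlpd = engine.run_strategy(t, "svlpd", default_params.settings)
        assert np.array_equal(lpd.occupancy, svlpd.occupancy)


def test_trace_export_frame(default_params):
    trace = engine.run_strategy(
        default_params.transition, "lpd", default_params.settings
    )
    df = trace.to_frame()
    assert list(df.columns[:2]) == ["cycle", "month"]
    assert set(engine.BASE_STATES) <= set(df.columns)
    assert df["new_dialysis_entries"].iloc[0] == 0.0
    assert df["cumulative_deaths"].is_monotonic_increasing
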