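"""Markov engine: rate conversion, transitions, trace and reward accrual."""

import numpy as np
import pytest

from slncea import (
    LifeTable,
    Scenario,
    Strategy,
    accumulate_outcomes,
    annualize,
    build_transition_matrix,
    build_tree_result,
    recurrence_case_fatality,
    run_cohort,
)
from slncea.markov import (
    STATES,
    _state_rewards,
    calibrate_recurrence_mortality,
)

REC = STATES.index("recurrence")
DEAD = STATES.index("dead")


def immortal_table(start_age=65, max_age=110):
    q = np.zeros(max_age - start_age + 1)
    q[-1] = 1.0
    return LifeTable(start_age, max_age, q)


def quiet_disease(ps, **extra):
    """No recurrence, no toxicity, no complications: everyone stays well."""
    zeros = {f"r5_rec_{g}": 0.0 for g in ("ebrt", "chemo", "both", "vbt_pos", "vbt_neg")}
    zeros |= {f"r5_vag_{g}": 0.0 for g in ("ebrt", "chemo", "both", "vbt_pos", "vbt_neg")}
    zeros |= {f"m5_{g}": 0.0 for g in ("ebrt", "chemo", "both", "vbt_pos", "vbt_neg")}
    zeros |= {f"p_st_tox_{m}": 0.0 for m in ("ebrt", "chemo", "both", "vbt")}
    zeros |= {f"p_lt_tox_{m}": 0.0 for m in ("ebrt", "chemo", "both", "vbt")}
    zeros |= {
        "p_lymphedema_lnd": 0.0,
        "p_lymphedema_sln": 0.0,
        "p_lymphocele_lnd": 0.0,
        "p_lymphocele_sln": 0.0,
    }
    return ps.with_values(zeros | extra)


class TestAnnualize:
    def test_constant_hazard_closed_form(self):
        assert annualize(0.25) == pytest.approx(1 - 0.75 ** 0.2)
        assert annualize(0.25) == pytest.approx(0.05591, abs=5e-6)

    def test_boundary_values(self):
        assert annualize(0.0) == 0.0
        assert annualize(1.0) == 1.0

    def test_rejects_non_probability(self):
        with pytest.raises(ValueError):
            annualize(1.2)


class TestRecurrenceMortality:
    def test_case_fatality_ratio_without_life_table(self, ps):
        # printed rates read as cancer mortality when no background available
        assert recurrence_case_fatality("ebrt", ps) == pytest.approx(
            annualize(0.315 / 0.416), abs=1e-6
        )

    def test_background_share_subtracted_with_life_table(self, ps, lt):
        with_bg = recurrence_case_fatality("ebrt", ps, lt)
        assert 0 < with_bg < recurrence_case_fatality("ebrt", ps)

    def test_no_cancer_deaths(self, ps):
        none = ps.with_value("m5_ebrt", 0.0)
        assert recurrence_case_fatality("ebrt", none) == 0.0

    def test_all_recurrers_die_within_window(self, ps):
        fatal = ps.with_value("m5_ebrt", ps.r5_rec("ebrt"))
        assert recurrence_case_fatality("ebrt", fatal) == 1.0

    def test_excess_mortality_clips_with_warning(self, ps):
        bad = ps.with_value("m5_ebrt", 0.9)
        with pytest.warns(UserWarning, match="clipped"):
            assert recurrence_case_fatality("ebrt", bad) == 1.0

    def test_calibrated_rate_reproduces_printed_mortality(self, ps, lt):
        # replaying the single-group mini-model with the solved rate must
        # land on the printed 5-year all-cause mortality
        for group in ("ebrt", "chemo", "vbt_neg"):
            d = calibrate_recurrence_mortality(group, ps, lt)
            p_rec = annualize(ps.r5_rec(group))
            post, rec, dead = 1.0, 0.0, 0.0
            for age in range(65, 70):
                q = lt.q_at(age)
                d_rec = 1 - (1 - d) * (1 - q)
                dead += post * q + rec * d_rec
                rec = rec * (1 - d_rec) + post * p_rec
                post *= 1 - p_rec - q
            assert dead == pytest.approx(ps.m5(group), abs=1e-6)

    def test_unreachable_mortality_clips_to_one(self, ps, lt):
        # the missed-metastases group's 70% five-year mortality cannot be
        # reached even with immediate death after recurrence
        with pytest.warns(UserWarning, match="unreachable"):
            assert calibrate_recurrence_mortality("vbt_pos", ps, lt) == 1.0


class TestTransitionMatrix:
    @pytest.mark.parametrize("cycle", [1, 3, 5, 6, 20])
    def test_rows_sum_to_one(self, ps, lt, cycle):
        tree = build_tree_result(Strategy.SLN, Scenario.CHEMO, ps)
        m = build_transition_matrix(tree, Scenario.CHEMO, ps, lt, cycle)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert (m >= 0).all() and (m <= 1).all()

    def test_node_negative_recurrence_rate(self, ps, lt):
        tree = build_tree_result(Strategy.LND, Scenario.EBRT, ps)
        m = build_transition_matrix(tree, Scenario.EBRT, ps, lt, 1)
        assert m[1, REC] == pytest.approx(annualize(0.25), abs=1e-9)

    def test_death_is_absorbing(self, ps, lt):
        tree = build_tree_result(Strategy.LND, Scenario.EBRT, ps)
        m = build_transition_matrix(tree, Scenario.EBRT, ps, lt, 10)
        assert m[DEAD, DEAD] == 1.0

    def test_recurrence_stops_after_five_cycles_by_default(self, ps, lt):
        tree = build_tree_result(Strategy.LND, Scenario.EBRT, ps)
        m5_ = build_transition_matrix(tree, Scenario.EBRT, ps, lt, 5)
        m6 = build_transition_matrix(tree, Scenario.EBRT, ps, lt, 6)
        assert m5_[1, REC] > 0
        assert m6[1, REC] == 0.0

    def test_lifetime_window_keeps_rates_active(self, ps, lt):
        forever = ps.with_value("p_lnm", ps.p_lnm)
        forever.flags["failure_window"] = "lifetime"
        tree = build_tree_result(Strategy.LND, Scenario.EBRT, forever)
        m6 = build_transition_matrix(tree, Scenario.EBRT, forever, lt, 6)
        assert m6[1, REC] == pytest.approx(annualize(0.25), abs=1e-9)

    def test_cycle_out_of_range_rejected(self, ps, lt):
        tree = build_tree_result(Strategy.LND, Scenario.EBRT, ps)
        with pytest.raises(ValueError):
            build_transition_matrix(tree, Scenario.EBRT, ps, lt, 0)


class TestCohortTrace:
    @pytest.mark.parametrize("strategy", list(Strategy))
    def test_mass_conserved_and_dead_monotone(self, ps, lt, strategy):
        tree = build_tree_result(strategy, Scenario.BOTH, ps)
        trace = run_cohort(tree, Scenario.BOTH, ps, lt)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        assert (np.diff(trace.occupancy[:, DEAD]) >= -1e-12).all()

    def test_starts_from_tree_occupancy_with_nobody_dead(self, ps, lt):
        tree = build_tree_result(Strategy.SLN, Scenario.EBRT, ps)
        trace = run_cohort(tree, Scenario.EBRT, ps, lt)
        assert trace.occupancy[0, DEAD] == 0.0
        assert trace.occupancy[0, REC] == 0.0
        assert trace.occupancy[0, 0] == pytest.approx(tree.occupancy["pos_treated"])

    def test_identity_dynamics_freeze_the_trace(self, ps):
        still = quiet_disease(ps)
        tree = build_tree_result(Strategy.LND, Scenario.EBRT, still)
        trace = run_cohort(tree, Scenario.EBRT, still, immortal_table())
        expected = np.broadcast_to(trace.occupancy[0], trace.occupancy.shape)
        np.testing.assert_allclose(trace.occupancy, expected, atol=1e-12)

    def test_trace_export_shape(self, ps, lt):
        tree = build_tree_result(Strategy.LND, Scenario.EBRT, ps)
        df = run_cohort(tree, Scenario.EBRT, ps, lt).to_frame()
        assert set(df.columns) == {"cycle", "state", "occupancy"}
        assert len(df) == 21 * len(STATES)


class TestOutcomeAccrual:
    def test_twenty_undiscounted_perfect_years(self, ps):
        perfect = quiet_disease(ps).with_value("disc_effects", 0.0)
        tree = build_tree_result(Strategy.LND, Scenario.EBRT, perfect)
        trace = run_cohort(tree, Scenario.EBRT, perfect, immortal_table())
        _, qaly = accumulate_outcomes(trace, tree, Scenario.EBRT, perfect)
        assert qaly == pytest.approx(20.0, abs=1e-9)

    def test_discounted_annuity_closed_form(self, ps):
        perfect = quiet_disease(ps)  # disc_effects stays at 1.5%
        tree = build_tree_result(Strategy.LND, Scenario.EBRT, perfect)
        trace = run_cohort(tree, Scenario.EBRT, perfect, immortal_table())
        _, qaly = accumulate_outcomes(trace, tree, Scenario.EBRT, perfect)
        assert qaly == pytest.approx(sum(1.015 ** -t for t in range(1, 21)), abs=1e-9)
        assert qaly == pytest.approx(17.169, abs=1e-3)

    def test_long_term_utility_of_node_negative_state(self, ps):
        # 1 − 0.19·(1−0.925) − 0.26·(1−0.866) = 0.9509, before the vaginal
        # recurrence term
        novag = ps.with_value("r5_vag_vbt_neg", 0.0)
        tree = build_tree_result(Strategy.LND, Scenario.EBRT, novag)
        _, utils = _state_rewards(tree, Scenario.EBRT, novag, cycle=2)
        assert utils[1] == pytest.approx(0.9509, abs=1e-4)

    def test_short_term_toxicity_only_in_first_cycle(self, ps):
        tree = build_tree_result(Strategy.LND, Scenario.CHEMO, ps)
        _, u1 = _state_rewards(tree, Scenario.CHEMO, ps, cycle=1)
        _, u2 = _state_rewards(tree, Scenario.CHEMO, ps, cycle=2)
        # chemo short-term toxicity (90%) far exceeds long-term (35%)
        assert u1[0] < u2[0]

    def test_discounting_never_increases_totals(self, ps, lt):
        tree = build_tree_result(Strategy.LND, Scenario.EBRT, ps)
        trace = run_cohort(tree, Scenario.EBRT, ps, lt)
        cost, qaly = accumulate_outcomes(trace, tree, Scenario.EBRT, ps)
        flat = ps.with_values({"disc_costs": 0.0, "disc_effects": 0.0})
        cost0, qaly0 = accumulate_outcomes(trace, tree, Scenario.EBRT, flat)
        assert cost <= cost0 and qaly <= qaly0

    def test_salvage_chemotherapy_charged_on_recurrence_inflow(self, ps, lt):
        tree = build_tree_result(Strategy.LND, Scenario.EBRT, ps)
        trace = run_cohort(tree, Scenario.EBRT, ps, lt)
        cost, _ = accumulate_outcomes(trace, tree, Scenario.EBRT, ps)
        cheap = ps.with_value("c_chemo", 0.0)
        cost_no_salvage, _ = accumulate_outcomes(trace, tree, Scenario.EBRT, cheap)
        expected_salvage = sum(
            (1.04 ** -t) * trace.rec_inflow[t] * ps.c_chemo for t in range(1, 21)
        )
        assert cost - cost_no_salvage == pytest.approx(expected_salvage)
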