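"""Cost/LY/QALY accrual and incremental cost-effectiveness logic."""

import numpy as np
import pytest

from mscua import (
    CohortTrace,
    CostUtilityAnalysis,
    HealthState as H,
    Strategy,
    StrategyResult,
    compute_icer,
    discount_factor,
    accrue,
)
from mscua.params import ValidationError


def one_state_trace(state: H, n_cycles: int, strategy=Strategy.BSC) -> CohortTrace:
    occ = np.zeros((n_cycles + 1, 7))
    occ[:, state] = 1.0
    return CohortTrace(occ, strategy)


class TestDiscountFactor:
    def test_time_zero(self):
        assert discount_factor(0, 0.03) == 1.0

    def test_zero_rate(self):
        assert discount_factor(240, 0.0) == 1.0

    def test_one_year(self):
        assert discount_factor(12, 0.03) == pytest.approx(1 / 1.03)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError):
            discount_factor(1, -0.01)


class TestAccrue:
    def test_single_cycle_edss0_bsc_undiscounted(self, params):
        p = params.with_settings(discount_cost_annual=0.0, discount_outcome_annual=0.0)
        res = accrue(one_state_trace(H.EDSS0_2, 1), p, Strategy.BSC)
        assert res.total_cost == pytest.approx(1317.70 + 2686.70)
        assert res.total_qaly == pytest.approx(0.600 / 12)
        assert res.total_ly == pytest.approx(1 / 12)

    def test_relapse_cycle_replaces_opd(self, params):
        p = params.with_settings(discount_cost_annual=0.0)
        res = accrue(one_state_trace(H.REL0_2, 1), p, Strategy.BSC)
        assert res.cost_breakdown["relapse"] == pytest.approx(40585.63)
        assert res.cost_breakdown["opd"] == 0.0
        assert res.cost_breakdown["nonmedical"] == pytest.approx(2686.70)

    def test_all_dead_trace_accrues_nothing(self, params):
        res = accrue(one_state_trace(H.DEAD, 24), params, Strategy.BSC)
        assert res.total_cost == res.total_qaly == res.total_ly == 0.0

    def test_full_survival_ly_is_discounted_annuity(self, params):
        # immortal cohort: LY must equal the closed-form monthly annuity
        n = 360
        res = accrue(one_state_trace(H.EDSS0_2, n), params, Strategy.BSC)
        beta = 1.03 ** (-1 / 12)
        annuity = (1 - beta**n) / (1 - beta) / 12
        assert res.total_ly == pytest.approx(annuity, rel=1e-12)

    def test_treated_states_carry_drug_admin_ae(self, params):
        p = params.with_settings(discount_cost_annual=0.0)
        res = accrue(one_state_trace(H.EDSS0_2, 1, Strategy.RITUXIMAB), p, Strategy.RITUXIMAB)
        assert res.cost_breakdown["drug"] == pytest.approx(8236.0)
        assert res.cost_breakdown["administration"] == pytest.approx(506.34)
        expected_ae = (0.1880 * 1465.12 + 0.1690 * 4999.92
                       + 0.0111 * 23952.00 + 0.0065 * 9118.03) / 12
        assert res.cost_breakdown["adverse_events"] == pytest.approx(expected_ae)

    def test_no_drug_cost_after_edss6(self, params):
        res = accrue(one_state_trace(H.EDSS6_7, 12, Strategy.RITUXIMAB), params,
                     Strategy.RITUXIMAB)
        assert res.cost_breakdown["drug"] == 0.0
        assert res.cost_breakdown["administration"] == 0.0

    def test_breakdown_sums_to_total(self, base_case):
        for r in base_case.strategy_results:
            assert sum(r.cost_breakdown.values()) == pytest.approx(r.total_cost, abs=1e-6)

    def test_strategy_mismatch_rejected(self, params):
        with pytest.raises(ValidationError):
            accrue(one_state_trace(H.EDSS0_2, 1, Strategy.BSC), params, Strategy.RITUXIMAB)

    def test_half_cycle_option_shrinks_first_cycle_weight(self, params):
        full = accrue(one_state_trace(H.EDSS0_2, 1), params, Strategy.BSC)
        half = accrue(one_state_trace(H.EDSS0_2, 1),
                      params.with_settings(half_cycle=True), Strategy.BSC)
        # one immortal cycle: trapezoid = ordinary accrual (0.5 + 0.5 weights)
        assert half.total_ly == pytest.approx(
            (0.5 + 0.5 * discount_factor(1, 0.03)) / 12)
        assert half.total_ly < full.total_ly


class TestBaseCaseProperties:
    def test_discount_monotonicity(self, params, base_case):
        undiscounted = CostUtilityAnalysis(
            params, discount_cost_annual=0.0, discount_outcome_annual=0.0
        ).run()
        for r0, r3 in zip(undiscounted.strategy_results, base_case.strategy_results):
            assert r3.total_cost <= r0.total_cost
            assert r3.total_qaly <= r0.total_qaly
            assert r3.total_ly <= r0.total_ly
            for comp in r3.cost_breakdown:
                assert r3.cost_breakdown[comp] <= r0.cost_breakdown[comp] + 1e-9

    def test_qaly_bounded_by_best_utility(self, base_case, params):
        u_max = params["u_edss0"]
        for r in base_case.strategy_results:
            assert 0.0 < r.total_qaly <= u_max * r.total_ly

    def test_cost_monotone_in_unit_costs(self, analysis, base_case):
        bumped = CostUtilityAnalysis(
            analysis.params.with_values({"opd_cost_edss0": 2000.0})
        ).run()
        for r_hi, r in zip(bumped.strategy_results, base_case.strategy_results):
            assert r_hi.total_cost > r.total_cost

    def test_rituximab_and_biosimilar_differ_only_in_drug_cost(self, base_case):
        rtx = base_case.result(Strategy.RITUXIMAB)
        bio = base_case.result(Strategy.BIOSIMILAR)
        assert rtx.total_ly == bio.total_ly
        assert rtx.total_qaly == bio.total_qaly
        for comp in rtx.cost_breakdown:
            if comp == "drug":
                assert rtx.cost_breakdown[comp] > bio.cost_breakdown[comp]
            else:
                assert rtx.cost_breakdown[comp] == pytest.approx(bio.cost_breakdown[comp])


class TestIcer:
    @staticmethod
    def result(strategy, cost, qaly, ly=None):
        return StrategyResult(strategy, cost, qaly if ly is None else ly, qaly, {})

    @pytest.mark.parametrize(
        "d_cost,d_qaly,expected",
        [
            (100.0, 1.0, 100.0),       # NE quadrant: ratio
            (-100.0, 1.0, "Dominant"),  # SE: cheaper and better
            (100.0, -1.0, "Dominated"),  # NW: costlier and worse
            (-100.0, -1.0, 100.0),     # SW quadrant: ratio again
        ],
    )
    def test_dominance_truth_table(self, d_cost, d_qaly, expected):
        ref = self.result(Strategy.BSC, 1000.0, 5.0)
        alt = self.result(Strategy.RITUXIMAB, 1000.0 + d_cost, 5.0 + d_qaly)
        entry = compute_icer([ref, alt])[Strategy.RITUXIMAB]
        assert entry.icer_per_qaly == expected

    def test_identical_results_undefined(self):
        ref = self.result(Strategy.BSC, 1000.0, 5.0)
        alt = self.result(Strategy.BIOSIMILAR, 1000.0, 5.0)
        entry = compute_icer([ref, alt])[Strategy.BIOSIMILAR]
        assert entry.icer_per_qaly == 0.0

    def test_equal_effect_unequal_cost_flagged_nan(self):
        ref = self.result(Strategy.BSC, 1000.0, 5.0)
        alt = self.result(Strategy.RITUXIMAB, 2000.0, 5.0)
        entry = compute_icer([ref, alt])[Strategy.RITUXIMAB]
        assert np.isnan(entry.icer_per_qaly)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError):
            compute_icer([self.result(Strategy.RITUXIMAB, 1.0, 1.0)], Strategy.BSC)

    def test_base_case_biosimilar_dominant(self, base_case):
        entry = base_case.icer_table[Strategy.BIOSIMILAR]
        assert entry.icer_per_qaly == "Dominant"
        assert entry.incremental_cost < 0 < entry.incremental_qaly

    def test_unrounded_icer_consistency(self, base_case):
        e = base_case.icer_table[Strategy.RITUXIMAB]
        assert e.icer_per_qaly == pytest.approx(e.incremental_cost / e.incremental_qaly)
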