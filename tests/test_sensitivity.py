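"""PSA sampling, net monetary benefit, CEAC and tornado analysis."""

import numpy as np
import pytest

from mscua import ParamSpec, ParameterSet, Strategy, ceac, nmb, owsa, run_psa, sample_psa
from mscua.params import PARAM_NAMES, ValidationError
from mscua.sensitivity import PsaResult, ALL_STRATEGIES


class TestNmb:
    def test_zero_wtp_is_negative_cost(self):
        assert nmb(5000.0, 2.0, 0.0) == -5000.0

    def test_threshold_exactness(self):
        assert nmb(160_000.0, 1.0, 160_000.0) == 0.0

    def test_negative_wtp_rejected(self):
        with pytest.raises(ValidationError):
            nmb(1.0, 1.0, -1.0)

    def test_incremental_nmb_changes_sign_at_icer(self, base_case):
        e = base_case.icer_table[Strategy.RITUXIMAB]
        icer = e.incremental_cost / e.incremental_qaly
        below = nmb(e.incremental_cost, e.incremental_qaly, icer * 0.99)
        above = nmb(e.incremental_cost, e.incremental_qaly, icer * 1.01)
        at = nmb(e.incremental_cost, e.incremental_qaly, icer)
        assert below < 0 < above
        assert at == pytest.approx(0.0, abs=1e-6)


class TestSamplePsa:
    def test_seed_reproducibility(self, params):
        a = sample_psa(params, 20, seed=123)
        b = sample_psa(params, 20, seed=123)
        assert all(x.values == y.values for x, y in zip(a, b))

    def test_different_seeds_differ(self, params):
        a = sample_psa(params, 5, seed=1)
        b = sample_psa(params, 5, seed=2)
        assert a[0].values != b[0].values

    def test_all_fixed_degenerates_to_base(self, params):
        specs = {n: ParamSpec(n, "fixed", params.specs[n].mean) for n in PARAM_NAMES}
        fixed = ParameterSet(specs, params.settings)
        draws = sample_psa(fixed, 3, seed=0)
        assert all(d.values == fixed.values for d in draws)

    def test_sampled_probabilities_and_costs_in_support(self, params):
        for d in sample_psa(params, 50, seed=5):
            for name in PARAM_NAMES:
                v = d.values[name]
                if d.specs[name].family == "beta":
                    assert 0.0 <= v <= 1.0
                else:
                    assert v >= 0.0
            assert d.values["u_rel0"] <= d.values["u_edss0"]

    def test_sample_mean_recovers_relapse_probability(self, params):
        rng = np.random.default_rng(99)
        x = params.spec("p_relapse").sample(rng, size=100_000)
        se = 0.0755 / np.sqrt(x.size)
        assert abs(x.mean() - 0.0755) < 3 * se


class TestRunPsa:
    def test_bit_identical_under_fixed_seed(self, params):
        a = run_psa(params, 30, seed=7)
        b = run_psa(params, 30, seed=7)
        np.testing.assert_array_equal(a.costs, b.costs)
        np.testing.assert_array_equal(a.qalys, b.qalys)

    def test_mean_near_base_case_up_to_nonlinearity(self, params, base_case):
        """PSA means approach the deterministic base case.

        The model is convex in several inputs whose SD equals their mean
        (relapse and mortality rows), so the Monte-Carlo mean carries a
        Jensen bias of a few percent; a 10% relative band captures the
        convergence without hiding gross errors.
        """
        psa = run_psa(params, 2000, seed=3)
        for j, s in enumerate(psa.strategies):
            r = base_case.result(s)
            assert psa.costs[:, j].mean() == pytest.approx(r.total_cost, rel=0.10)
            assert psa.qalys[:, j].mean() == pytest.approx(r.total_qaly, rel=0.10)

    def test_treated_arms_share_qalys_per_draw(self, params):
        psa = run_psa(params, 25, seed=4)
        j_rtx = psa.strategies.index(Strategy.RITUXIMAB)
        j_bio = psa.strategies.index(Strategy.BIOSIMILAR)
        np.testing.assert_allclose(psa.qalys[:, j_rtx], psa.qalys[:, j_bio])
        assert np.all(psa.costs[:, j_rtx] > psa.costs[:, j_bio])


class TestCeac:
    def test_single_draw_is_indicator(self):
        psa = PsaResult(ALL_STRATEGIES, np.array([[100.0, 300.0, 200.0]]),
                        np.array([[1.0, 2.0, 2.0]]), seed=0)
        curve = ceac(psa, np.array([0.0, 1000.0]))
        np.testing.assert_array_equal(curve.probabilities[0], [1.0, 0.0, 0.0])
        # at high WTP the extra QALYs win; biosimilar is the cheaper of the tied pair
        np.testing.assert_array_equal(curve.probabilities[1], [0.0, 0.0, 1.0])

    def test_zero_wtp_selects_cheapest(self, params):
        psa = run_psa(params, 40, seed=11)
        curve = ceac(psa, np.array([0.0]))
        cheapest = psa.costs.argmin(axis=1)
        expected = np.bincount(cheapest, minlength=3) / psa.n_draws
        np.testing.assert_allclose(curve.probabilities[0], expected)

    def test_ties_split_equally(self):
        psa = PsaResult(ALL_STRATEGIES, np.array([[100.0, 100.0, 300.0]]),
                        np.array([[1.0, 1.0, 1.0]]), seed=0)
        curve = ceac(psa, np.array([50_000.0]))
        np.testing.assert_allclose(curve.probabilities[0], [0.5, 0.5, 0.0])

    def test_normalization_and_support(self, params):
        curve = ceac(run_psa(params, 200, seed=8))
        assert np.all(curve.probabilities >= 0.0)
        np.testing.assert_allclose(curve.probabilities.sum(axis=1), 1.0, atol=1e-12)

    def test_biosimilar_acceptance_trends_up_with_wtp(self, params):
        curve = ceac(run_psa(params, 500, seed=13))
        p = curve.probabilities[:, curve.strategies.index(Strategy.BIOSIMILAR)]
        # non-decreasing trend within Monte-Carlo wiggle
        assert np.all(np.diff(p) > -0.05)
        assert p[-1] > p[0]

    def test_empty_grid_rejected(self, params):
        psa = run_psa(params, 5, seed=1)
        with pytest.raises(ValidationError):
            ceac(psa, np.array([]))


@pytest.fixture(scope="module")
def tornado(params):
    return owsa(params)


class TestOwsa:
    def test_sorted_by_descending_spread(self, tornado):
        spreads = [e.spread for e in tornado]
        assert spreads == sorted(spreads, reverse=True)

    def test_inert_parameter_has_zero_spread(self, tornado):
        by_name = {e.parameter: e for e in tornado}
        # relapse care beyond EDSS 6 never enters any strategy (relapse stops there)
        assert by_name["relapse_cost_edss8"].spread == 0.0
        assert by_name["relapse_cost_edss6"].spread == 0.0

    def test_drug_cost_uses_twenty_percent_band(self, tornado, params):
        e = next(t for t in tornado if t.parameter == "c_biosimilar_month")
        assert e.low_input == pytest.approx(2967.0 * 0.8)
        assert e.high_input == pytest.approx(2967.0 * 1.2)

    def test_relapse_probability_among_top_drivers(self, tornado):
        top = [e.parameter for e in tornado[:3]]
        assert "p_relapse" in top

    def test_base_outcome_within_bounds_for_monotone_cost(self, params, base_case):
        # a pure cost parameter moves the INMB monotonically
        [entry] = owsa(params, target_params=["c_biosimilar_month"])
        e = base_case.icer_table[Strategy.BIOSIMILAR]
        base_inmb = params.settings.wtp * e.incremental_qaly - e.incremental_cost
        lo, hi = sorted([entry.outcome_low, entry.outcome_high])
        assert lo <= base_inmb <= hi

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(ValidationError):
            owsa(params, target_params=["nonexistent"])
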