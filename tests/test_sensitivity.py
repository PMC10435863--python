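import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from schizocua.economics import compare
from schizocua.markov import run_cohort
from schizocua.parameters import DomainError
from schizocua.sensitivity import (
    ParameterDistribution,
    ceac,
    fit_beta,
    fit_gamma,
    icer_by_cycle,
    run_psa,
    scenario_sweep,
    tornado,
    uncertain_parameters,
)


class TestFitBeta:
    def test_alpha_beta_two(self):
        sd = math.sqrt(0.05)
        dist = fit_beta(0.5, (0.5 - 1.96 * sd, 0.5 + 1.96 * sd))
        assert dist.fitted["alpha"] == pytest.approx(2.0, abs=1e-9)
        assert dist.fitted["beta"] == pytest.approx(2.0, abs=1e-9)

    def test_published_range_sd(self):
        dist = fit_beta(0.0292, (0.0263, 0.0321))
        sd = (0.0321 - 0.0263) / 3.92
        assert round(sd, 7) == 0.0014796
        var = (dist.fitted["alpha"] * dist.fitted["beta"]
               / ((dist.fitted["alpha"] + dist.fitted["beta"]) ** 2
                  * (dist.fitted["alpha"] + dist.fitted["beta"] + 1)))
        assert math.sqrt(var) == pytest.approx(sd, abs=1e-10)

    def test_symmetric_bounds_give_equal_shapes(self):
        dist = fit_beta(0.5, (0.3, 0.7))
        assert dist.fitted["alpha"] == pytest.approx(dist.fitted["beta"], abs=1e-12)

    def test_infeasible_moments_raise(self):
        with pytest.raises(DomainError):
            fit_beta(0.5, (-3.0, 4.0))  # sd too large for a beta

    @pytest.mark.parametrize("mean", [0.0, 1.0, -0.1, 1.1])
    def test_mean_outside_open_interval_raises(self, mean):
        with pytest.raises(DomainError):
            fit_beta(mean, (0.1, 0.2))

    @given(mean=st.floats(0.05, 0.95), half_width=st.floats(1e-4, 0.05))
    @settings(max_examples=100)
    def test_moment_recovery(self, mean, half_width):
        dist = fit_beta(mean, (mean - half_width, mean + half_width))
        a, b = dist.fitted["alpha"], dist.fitted["beta"]
        assert a / (a + b) == pytest.approx(mean, abs=1e-10)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert var == pytest.approx((2 * half_width / 3.92) ** 2, abs=1e-10)


class TestFitGamma:
    def test_shape_scale_example(self):
        dist = fit_gamma(100.0, (100 - 1.96 * 20, 100 + 1.96 * 20))
        assert dist.fitted["shape"] == pytest.approx(25.0, abs=1e-9)
        assert dist.fitted["scale"] == pytest.approx(4.0, abs=1e-9)

    def test_published_hospitalization_sd(self):
        sd = (2398.68 - 1599.12) / 3.92
        assert round(sd, 2) == 203.97

    @given(mean=st.floats(1.0, 1e5), rel_width=st.floats(0.01, 0.5))
    @settings(max_examples=100)
    def test_mean_identity(self, mean, rel_width):
        dist = fit_gamma(mean, (mean * (1 - rel_width), mean * (1 + rel_width)))
        assert dist.fitted["shape"] * dist.fitted["scale"] == pytest.approx(
            mean, rel=1e-12)

    def test_nonpositive_mean_raises(self):
        with pytest.raises(DomainError):
            fit_gamma(0.0, (1.0, 2.0))


class TestUncertainParameters:
    def test_deterministic_order_and_ids(self, reference):
        arms, config = reference
        ids = [p.parameter_id for p in uncertain_parameters(arms, config)]
        assert ids == [p.parameter_id for p in uncertain_parameters(arms, config)]
        assert "cost.PP1M" in ids and "utility.stable" in ids
        assert "discount_rate" not in ids

    def test_discount_included_on_request(self, reference):
        arms, config = reference
        ids = [p.parameter_id
               for p in uncertain_parameters(arms, config, include_discount=True)]
        assert ids[-1] == "discount_rate"

    def test_pp1m_cost_draw_moves_pp3m_nonstable_cost(self, reference):
        arms, config = reference
        param = next(p for p in uncertain_parameters(arms, config)
                     if p.parameter_id == "cost.PP1M")
        new_arms, _ = param.apply(dict(arms), config, 500.0)
        assert new_arms["PP1M"].drug_cost_cycle_stable.mean == 500.0
        assert new_arms["PP1M"].drug_cost_cycle_nonstable.mean == 500.0
        assert new_arms["PP3M"].drug_cost_cycle_nonstable.mean == 500.0
        assert new_arms["PP3M"].drug_cost_cycle_stable.mean == 813.64

    def test_apply_does_not_mutate_input(self, reference):
        arms, config = reference
        param = uncertain_parameters(arms, config)[0]
        param.apply(dict(arms), config, 0.5)
        assert arms["PP1M"].p_disc_nonstable.value == 0.2140


class TestTornado:
    def test_absent_parameter_has_zero_width(self, reference):
        arms, config = reference
        entries = tornado(arms, config, ("PP1M", "ER"))
        by_id = {e.parameter_id: e for e in entries}
        assert by_id["cost.PP3M"].width == 0.0
        for field in ("p_disc_stable", "p_relapse_stable", "p_relapse_nonadherent"):
            assert by_id[f"PP3M.{field}"].width == 0.0

    def test_sorted_by_width_descending(self, reference):
        arms, config = reference
        entries = tornado(arms, config, ("PP3M", "ER"))
        widths = [e.width for e in entries]
        assert widths == sorted(widths, reverse=True)

    def test_drug_costs_outrank_probabilities(self, reference):
        arms, config = reference
        for intervention in ("PP1M", "PP3M"):
            entries = tornado(arms, config, (intervention, "ER"))
            cost_widths = [e.width for e in entries
                           if e.parameter_id in (f"cost.{intervention}", "cost.ER")]
            prob_widths = [e.width for e in entries if ".p_" in e.parameter_id]
            assert min(cost_widths) > max(prob_widths)
            assert entries[0].parameter_id.startswith("cost.")

    def test_widening_a_bound_widens_the_bar(self, reference):
        from dataclasses import replace

        arms, config = reference
        base = {e.parameter_id: e.width
                for e in tornado(arms, config, ("PP1M", "ER"))}
        c = arms["PP1M"].drug_cost_cycle_stable
        stretched = replace(c, low=c.mean - 2 * (c.mean - c.low),
                            high=c.mean + 2 * (c.high - c.mean))
        arms2 = dict(arms)
        arms2["PP1M"] = replace(arms["PP1M"], drug_cost_cycle_stable=stretched,
                                drug_cost_cycle_nonstable=stretched)
        wider = {e.parameter_id: e.width
                 for e in tornado(arms2, config, ("PP1M", "ER"))}
        assert wider["cost.PP1M"] >= base["cost.PP1M"]

    def test_discount_rate_entry_present(self, reference):
        arms, config = reference
        entries = tornado(arms, config, ("PP1M", "ER"))
        assert any(e.parameter_id == "discount_rate" and e.width > 0 for e in entries)


def _all_fixed(arms, config):
    return {p.parameter_id: ParameterDistribution(p.parameter_id, "fixed",
                                                  p.mean, p.low, p.high)
            for p in uncertain_parameters(arms, config)}


class TestPsa:
    def test_all_fixed_reproduces_base_case_exactly(self, reference, reference_results):
        arms, config = reference
        result = run_psa(arms, config, 3, seed=0,
                         distributions=_all_fixed(arms, config))
        for s in result.samples:
            for name, res in reference_results.items():
                assert s.costs[name] == res.total_cost
                assert s.qalys[name] == res.total_qaly

    def test_same_seed_identical(self, reference):
        arms, config = reference
        a = run_psa(arms, config, 5, seed=42)
        b = run_psa(arms, config, 5, seed=42)
        assert a.samples == b.samples

    def test_different_seeds_differ(self, reference):
        arms, config = reference
        a = run_psa(arms, config, 2, seed=1)
        b = run_psa(arms, config, 2, seed=2)
        assert a.samples != b.samples

    def test_draw_means_near_fitted_means(self, reference):
        arms, config = reference
        n = 400
        result = run_psa(arms, config, n, seed=9, record_draws=True)
        params = {p.parameter_id: p for p in uncertain_parameters(arms, config)}
        for pid, param in params.items():
            if param.low == param.high:
                continue
            draws = np.array([d[pid] for d in result.draws])
            se = draws.std(ddof=1) / math.sqrt(n)
            assert abs(draws.mean() - param.mean) < 4 * se, pid

    def test_sample_fields_finite_and_nonnegative(self, reference):
        arms, config = reference
        result = run_psa(arms, config, 10, seed=3)
        for s in result.samples:
            for v in list(s.costs.values()) + list(s.qalys.values()):
                assert np.isfinite(v) and v >= 0

    def test_invalid_inputs_raise(self, reference):
        arms, config = reference
        with pytest.raises(DomainError):
            run_psa(arms, config, 0, seed=1)
        with pytest.raises(DomainError):
            run_psa(arms, config, 1, seed=1, comparator="XXX")


class TestCeac:
    def _samples(self, deltas):
        from schizocua.sensitivity import PsaSample

        return [PsaSample(i, {}, {}, {"A_vs_B": dc}, {"A_vs_B": dq})
                for i, (dc, dq) in enumerate(deltas)]

    def test_zero_wtp_counts_cheaper_iterations(self):
        samples = self._samples([(-10, -1), (5, 1), (-1, 2), (0, 1)])
        points = ceac(samples, [0.0], "A_vs_B")
        assert points[0].probability_cost_effective == 0.5  # ties to comparator

    def test_dominant_in_every_iteration_gives_one(self):
        samples = self._samples([(-10, 1), (-5, 2), (-1, 0.5)])
        for point in ceac(samples, [0.0, 1e4, 1e8], "A_vs_B"):
            assert point.probability_cost_effective == 1.0

    def test_large_wtp_limit_counts_higher_qalys(self):
        samples = self._samples([(100, 1), (100, -1), (100, 2), (100, -0.5)])
        points = ceac(samples, [1e12], "A_vs_B")
        assert points[0].probability_cost_effective == 0.5

    def test_complementary_probabilities(self, reference):
        arms, config = reference
        result = run_psa(arms, config, 20, seed=5)
        grid = [0, 6000, 12756.55, 30000]
        points = ceac(result.samples, grid, "PP1M_vs_ER")
        comp = [1.0 - p.probability_cost_effective for p in points]
        dc = np.array([s.delta_costs["PP1M_vs_ER"] for s in result.samples])
        dq = np.array([s.delta_qalys["PP1M_vs_ER"] for s in result.samples])
        for wtp, expected in zip(grid, comp):
            assert np.mean(wtp * dq - dc <= 0.0) == pytest.approx(expected)

    def test_empty_inputs_raise(self):
        with pytest.raises(DomainError):
            ceac([], [0.0], "A_vs_B")
        with pytest.raises(DomainError):
            ceac(self._samples([(1, 1)]), [], "A_vs_B")


class TestScenarioSweep:
    def test_identity_point_reproduces_base_case(self, reference, reference_results):
        arms, config = reference
        base = compare(reference_results["PP1M"], reference_results["ER"]).icer
        grid = scenario_sweep(arms, config, "price_multiplier", axis_values=[1.0])
        assert grid.icer_series["PP1M_vs_ER"][0] == pytest.approx(base, rel=1e-12)

    def test_price_reduction_lowers_icers(self, reference):
        arms, config = reference
        grid = scenario_sweep(arms, config, "price_multiplier")
        for series in grid.icer_series.values():
            # axis is ordered from 1.0 downward; ICERs must not increase
            assert all(a >= b for a, b in zip(series, series[1:]))

    def test_hospitalization_cost_increase_lowers_icers(self, reference):
        arms, config = reference
        grid = scenario_sweep(arms, config, "hospitalization_multiplier")
        pairs = sorted(zip(grid.axis_values, grid.icer_series["PP1M_vs_ER"]))
        icers = [icer for _, icer in pairs]
        assert all(a >= b for a, b in zip(icers, icers[1:]))

    def test_longer_horizon_lowers_icers(self, reference):
        arms, config = reference
        grid = scenario_sweep(arms, config, "horizon_years")
        for series in grid.icer_series.values():
            assert all(a >= b for a, b in zip(series, series[1:]))

    def test_price_only_arms_leaves_comparator_untouched(self, reference, reference_results):
        arms, config = reference
        grid = scenario_sweep(arms, config, "price_multiplier", axis_values=[0.5],
                              price_only_arms=["PP1M", "PP3M"])
        full = scenario_sweep(arms, config, "price_multiplier", axis_values=[0.5])
        # cutting only the injectables' price lowers their ICER further
        assert (grid.icer_series["PP1M_vs_ER"][0]
                < full.icer_series["PP1M_vs_ER"][0])

    def test_nonpositive_multiplier_raises(self, reference):
        arms, config = reference
        with pytest.raises(DomainError):
            scenario_sweep(arms, config, "price_multiplier", axis_values=[0.0])

    def test_unknown_axis_raises(self, reference):
        arms, config = reference
        with pytest.raises(DomainError):
            scenario_sweep(arms, config, "nonsense_axis")


class TestIcerByCycle:
    def test_full_horizon_matches_base_case(self, reference, reference_results):
        arms, config = reference
        grid = icer_by_cycle(arms, config, config.n_cycles)
        base = compare(reference_results["PP3M"], reference_results["ER"]).icer
        assert grid.icer_series["PP3M_vs_ER"][-1] == pytest.approx(base, rel=1e-9)

    def test_strictly_decreasing_over_first_six_cycles(self, reference):
        arms, config = reference
        grid = icer_by_cycle(arms, config, 6)
        for series in grid.icer_series.values():
            assert all(a > b for a, b in zip(series, series[1:]))

    def test_first_cycle_exceeds_full_horizon(self, reference):
        arms, config = reference
        grid = icer_by_cycle(arms, config, config.n_cycles)
        for series in grid.icer_series.values():
            assert series[0] > series[-1]

    def test_matches_explicit_truncated_run(self, reference):
        arms, config = reference
        grid = icer_by_cycle(arms, config, 12)
        truncated = config.with_horizon_cycles(7)
        results = {n: run_cohort(a, truncated)[1] for n, a in arms.items()}
        explicit = compare(results["PP1M"], results["ER"]).icer
        assert grid.icer_series["PP1M_vs_ER"][6] == pytest.approx(explicit, rel=1e-12)

    def test_invalid_max_cycles_raises(self, reference):
        arms, config = reference
        with pytest.raises(DomainError):
            icer_by_cycle(arms, config, 0)
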