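"""Tornado one-way analysis and the probabilistic sensitivity analysis."""

import numpy as np
import pytest

from migraine_cea.economics import CostItem, discount_factor
from migraine_cea.inputs import default_model
from migraine_cea.sensitivity import (
    OwsaSpec,
    _sample_beta,
    _sample_gamma,
    ceac,
    default_owsa_specs,
    perturb,
    run_owsa,
    run_psa,
    sample_psa_draw,
)


def degenerate_model():
    """Base-case model with every sampling distribution collapsed to a point."""
    m = default_model()
    for s in m.strategies:
        s.utilities.sd[:] = 0.0
        c = s.costs
        for key in ("cm_acute", "cm_prevention", "em_acute", "em_prevention"):
            item = getattr(c, key)
            setattr(c, key, CostItem(item.name, item.mean, 0.0, item.use_prob))
        c.entry_items = tuple(CostItem(i.name, i.mean, 0.0, i.use_prob)
                              for i in c.entry_items)
        c.drug_cost_low = c.drug_cost_high = c.drug_cost_per_dose
        s.transitions.se = np.zeros((6, 6))
    return m


class TestOwsa:
    def test_zero_effect_parameter_leaves_icer_unchanged(self, base_model, base_result):
        # the occipital nerve block is priced near zero; scaling the whole
        # entry bundle cancels between arms anyway, so ICER must not move
        entries = run_owsa(base_model, [OwsaSpec("cost:entry", 0.8, 1.2)])
        assert entries[0].icer_low == pytest.approx(base_result.ce.icer)
        assert entries[0].icer_high == pytest.approx(base_result.ce.icer)

    def test_drug_cost_bound_matches_closed_form(self, base_model, base_result):
        # oracle: +20% drug cost adds 0.2 x discounted drug cost to dC only
        entries = run_owsa(base_model, [OwsaSpec("cost:drug", 0.8, 1.2)])
        ce = base_result.ce
        drug_pv = sum(
            discount_factor(k, base_model.discount) * 1708.0
            for k in range(1, base_model.n_cycles + 1)
        )
        expected_high = (ce.incremental_cost + 0.2 * drug_pv) / ce.incremental_qalys
        assert entries[0].icer_high == pytest.approx(expected_high, rel=1e-9)

    def test_intervention_utility_down_raises_icer(self, base_model, base_result):
        entries = run_owsa(base_model, [OwsaSpec("utility:eptinezumab:4-9", 0.9, 1.1)])
        assert entries[0].icer_low > base_result.ce.icer
        assert entries[0].icer_high < base_result.ce.icer

    def test_placebo_and_intervention_cost_moves_oppose(self):
        # a cost item present in only one arm moves the ICER in opposite
        # directions depending on which arm carries it
        shifts = {}
        for arm in ("eptinezumab", "placebo"):
            m = default_model()
            for s in m.strategies:
                item_mean = 100.0 if s.name == arm else 0.0
                s.costs = s.costs.scaled()  # fresh copy
                s.costs.em_acute = CostItem("em_acute", item_mean, 0.0)
                s.costs.cm_acute = CostItem("cm_acute", item_mean, 0.0)
            base_icer = m.evaluate().ce.icer
            up = perturb(m, "cost:em_acute", 1.2).evaluate().ce.icer
            shifts[arm] = up - base_icer
        assert shifts["eptinezumab"] > 0 > shifts["placebo"]

    def test_entries_sorted_by_bar_width(self, base_model):
        entries = run_owsa(base_model)
        widths = [e.width for e in entries]
        assert widths == sorted(widths, reverse=True)

    def test_transition_perturbation_renormalizes_row(self, base_model):
        m = perturb(base_model, "transition:placebo:4-9->0-3", 1.1)
        p = m.strategy("placebo").transitions.p
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert p[1, 0] > base_model.strategy("placebo").transitions.p[1, 0]

    def test_default_specs_cover_utilities_costs_transitions(self, base_model):
        kinds = {s.parameter.split(":")[0] for s in default_owsa_specs(base_model)}
        assert kinds == {"utility", "transition", "cost"}


class TestPsaDistributions:
    def test_beta_moment_match(self, rng):
        draws = [_sample_beta(0.778, 0.010, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(0.778, abs=0.005)
        assert np.std(draws) == pytest.approx(0.010, abs=0.002)

    def test_gamma_moment_match(self, rng):
        draws = [_sample_gamma(270.0, 135.0, rng) for _ in range(10_000)]
        assert np.mean(draws) == pytest.approx(270.0, abs=5.0)

    def test_oversized_beta_sd_names_no_silent_clip(self, rng):
        with pytest.raises(ValueError, match="SD"):
            _sample_beta(0.99, 0.5, rng)


class TestPsa:
    def test_degenerate_draw_reproduces_base_case_exactly(self):
        m = degenerate_model()
        base = m.evaluate()
        draw = sample_psa_draw(m, np.random.default_rng(0))
        assert draw.delta_cost == base.ce.incremental_cost
        assert draw.delta_qalys == base.ce.incremental_qalys

    def test_degenerate_psa_summary_equals_base_case(self):
        m = degenerate_model()
        base = m.evaluate()
        psa = run_psa(m, n=3, seed=1)
        assert np.all(psa.delta_cost == base.ce.incremental_cost)
        assert np.all(psa.delta_qalys == base.ce.incremental_qalys)

    def test_same_seed_bit_identical(self, base_model):
        a = run_psa(base_model, n=50, seed=123)
        b = run_psa(base_model, n=50, seed=123)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qalys, b.delta_qalys)
        assert a.prob_cost_effective == b.prob_cost_effective

    def test_different_seeds_differ(self, base_model):
        a = run_psa(base_model, n=20, seed=1)
        b = run_psa(base_model, n=20, seed=2)
        assert not np.array_equal(a.delta_cost, b.delta_cost)

    def test_sampled_transition_rows_stay_on_simplex(self, base_model):
        draw_model = base_model.copy()
        rng = np.random.default_rng(99)
        for _ in range(5):
            m = draw_model.copy()
            for s in m.strategies:
                from migraine_cea.sensitivity import _sample_transition_rows

                p = _sample_transition_rows(s.transitions.p, None, 100.0, rng)
                np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
                assert np.all(p >= 0)
                # structural zeros are preserved
                assert np.all(p[s.transitions.p == 0] == 0)


@pytest.fixture(scope="module")
def psa(base_model):
    return run_psa(base_model, n=400, seed=7)


class TestCeac:

    def test_complementarity(self, psa):
        curve = ceac(psa)
        np.testing.assert_allclose(
            curve.prob_intervention + curve.prob_comparator, 1.0, atol=1e-12
        )

    def test_monotone_when_all_qaly_gains_positive(self, psa):
        assert np.all(psa.delta_qalys > 0)
        curve = ceac(psa)
        assert np.all(np.diff(curve.prob_intervention) >= 0)

    def test_zero_threshold_probability_is_fraction_cost_saving(self, psa):
        curve = ceac(psa, thresholds=np.array([0.0]))
        assert curve.prob_intervention[0] == np.mean(psa.delta_cost < 0)

    def test_crosses_half_near_median_draw_icer(self, psa):
        # brute-force oracle over the draw set
        icers = np.sort(psa.delta_cost / psa.delta_qalys)
        median = np.median(icers)
        curve = ceac(psa, thresholds=np.array([median * 0.9, median, median * 1.1]))
        assert curve.prob_intervention[0] < 0.5 <= curve.prob_intervention[2]

    def test_empty_grid_rejected(self, psa):
        with pytest.raises(ValueError):
            ceac(psa, thresholds=np.array([]))

    def test_ties_go_to_comparator(self, psa):
        # at exactly L = dC/dE the draw is not counted as cost-effective
        i = 5
        L = psa.delta_cost[i] / psa.delta_qalys[i]
        curve = ceac(psa, thresholds=np.array([L]))
        wins = L * psa.delta_qalys - psa.delta_cost
        assert curve.prob_intervention[0] == np.mean(wins > 0)
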