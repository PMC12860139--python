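"""Discounting, QALY/cost accrual, ICER quadrants and net monetary benefit."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from migraine_cea.economics import (
    CostItem,
    CostSchedule,
    DiscountSpec,
    UtilitySet,
    accrue_costs,
    accrue_qalys,
    compute_icer,
    discount_factor,
    net_monetary_benefit,
)
from migraine_cea.markov import CohortTrace
from migraine_cea.states import N_BANDS

QUARTER = DiscountSpec(annual_rate=0.03, cycle_length_years=0.25)
NO_DISCOUNT = DiscountSpec(annual_rate=0.0, cycle_length_years=0.25)


def uniform_trace(n_cycles=2, band=0):
    occ = np.tile(np.eye(N_BANDS)[band], (n_cycles + 1, 1))
    return CohortTrace(occ, 0.25)


class TestDiscountFactor:
    def test_first_cycle_undiscounted(self):
        assert discount_factor(1, QUARTER) == 1.0

    def test_zero_rate_never_discounts(self):
        assert discount_factor(7, NO_DISCOUNT) == 1.0

    def test_quarterly_second_cycle_closed_form(self):
        assert discount_factor(2, QUARTER) == pytest.approx(1.03 ** -0.25)
        assert discount_factor(2, QUARTER) == pytest.approx(0.992638, abs=1e-6)

    @given(st.integers(1, 40), st.floats(0.0, 0.2))
    def test_discounted_never_exceeds_undiscounted(self, k, rate):
        assert discount_factor(k, DiscountSpec(rate, 0.25)) <= 1.0


class TestAccrueQalys:
    def test_single_cycle_best_state(self):
        u = UtilitySet("e", [0.778, 0.732, 0.681, 0.635, 0.595, 0.553], np.full(6, 0.01))
        q = accrue_qalys(uniform_trace(1, band=0), u, NO_DISCOUNT)
        assert q == pytest.approx(0.778 * 0.25)

    def test_near_zero_utilities_give_near_zero_qalys(self):
        u = UtilitySet("z", np.full(6, 1e-12), np.zeros(6))
        assert accrue_qalys(uniform_trace(), u, QUARTER) == pytest.approx(0.0, abs=1e-9)

    @given(st.integers(0, 5), st.floats(0.001, 0.2))
    def test_raising_any_band_utility_never_lowers_qalys(self, band, bump):
        rng = np.random.default_rng(band)
        occ = rng.dirichlet(np.ones(N_BANDS), size=3)
        occ[0] = occ[0] / occ[0].sum()
        trace = CohortTrace(occ, 0.25)
        mean = np.linspace(0.7, 0.4, N_BANDS)
        base = accrue_qalys(trace, UtilitySet("u", mean, np.zeros(6)), QUARTER)
        raised = mean.copy()
        raised[band] = min(raised[band] + bump, 0.999)
        up = accrue_qalys(trace, UtilitySet("u", raised, np.zeros(6)), QUARTER)
        assert up >= base - 1e-12


class TestAccrueCosts:
    def test_drug_only_two_cycles_no_discount(self):
        costs = CostSchedule(drug_cost_per_dose=1708.0)
        total, bd = accrue_costs(uniform_trace(2), costs, NO_DISCOUNT, drug_active=True)
        assert total == pytest.approx(2 * 1708.0)
        assert bd["medication"] == 0 and bd["entry"] == 0

    def test_all_zero_schedule_costs_nothing(self):
        total, _ = accrue_costs(uniform_trace(2), CostSchedule(), QUARTER, drug_active=False)
        assert total == 0.0

    def test_chronicity_splits_medication_costs(self):
        costs = CostSchedule(
            cm_acute=CostItem("cm_acute", 270.0, 135.0),
            cm_prevention=CostItem("cm_prevention", 37.0, 18.5),
            em_acute=CostItem("em_acute", 184.0, 92.0),
            em_prevention=CostItem("em_prevention", 27.4, 13.7),
        )
        em_total, _ = accrue_costs(uniform_trace(1, band=2), costs, NO_DISCOUNT, False)
        cm_total, _ = accrue_costs(uniform_trace(1, band=3), costs, NO_DISCOUNT, False)
        assert em_total == pytest.approx(184.0 + 27.4)
        assert cm_total == pytest.approx(270.0 + 37.0)

    def test_entry_items_expected_cost_charged_once(self):
        costs = CostSchedule(entry_items=(
            CostItem("mri", 195.9, 97.95, use_prob=0.5),
            CostItem("ecg", 4.5, 2.25, use_prob=1.0),
        ))
        total, bd = accrue_costs(uniform_trace(3), costs, QUARTER, False)
        assert total == pytest.approx(195.9 * 0.5 + 4.5)
        assert bd["entry"] == total

    def test_discounting_reduces_total(self):
        costs = CostSchedule(drug_cost_per_dose=1000.0)
        discounted, _ = accrue_costs(uniform_trace(4), costs, QUARTER, True)
        undiscounted, _ = accrue_costs(uniform_trace(4), costs, NO_DISCOUNT, True)
        assert discounted < undiscounted

    def test_drug_cost_bounds_must_be_ordered(self):
        with pytest.raises(ValueError):
            CostSchedule(drug_cost_per_dose=100.0, drug_cost_low=200.0, drug_cost_high=50.0)


class TestIcer:
    def test_simple_ratio(self):
        ce = compute_icer("a", "b", 200.0, 100.0, 2.0, 1.0)
        assert ce.icer == pytest.approx(100.0)
        assert ce.dominance is None

    @pytest.mark.parametrize(
        "dc, de, flag",
        [
            (+100.0, +1.0, None),       # NE quadrant: trade-off, ICER defined
            (-100.0, +1.0, "dominant"),  # cheaper and better
            (+100.0, -1.0, "dominated"),  # costlier and worse
            (-100.0, -1.0, None),       # SW quadrant: trade-off
            (-100.0, 0.0, "dominant"),
            (+100.0, 0.0, "dominated"),
            (0.0, +1.0, "dominant"),
            (0.0, -1.0, "dominated"),
        ],
    )
    def test_dominance_flags_cover_all_quadrants(self, dc, de, flag):
        ce = compute_icer("a", "b", 1000.0 + dc, 1000.0, 1.0 + de, 1.0)
        assert ce.dominance == flag

    def test_zero_qaly_difference_yields_undefined_icer_not_exception(self):
        ce = compute_icer("a", "b", 150.0, 100.0, 1.0, 1.0)
        assert ce.icer is None

    def test_icer_uses_unrounded_increments(self):
        ce = compute_icer("a", "b", 4461.234, 1065.111, 0.3541, 0.3082)
        assert ce.icer == pytest.approx((4461.234 - 1065.111) / (0.3541 - 0.3082))


class TestNmb:
    def test_zero_everything_is_zero(self):
        assert net_monetary_benefit(0.0, 0.0, 50_000.0) == 0.0

    def test_arithmetic_on_published_scale(self):
        assert net_monetary_benefit(1065.0, 0.31, 96_981.0) == pytest.approx(
            96_981.0 * 0.31 - 1065.0
        )

    @given(
        st.floats(0.0, 5000.0), st.floats(0.0, 5000.0),
        st.floats(0.01, 1.0), st.floats(0.0, 200_000.0),
    )
    def test_nmb_ordering_matches_icer_threshold_rule(self, c_a, c_b, de, wtp):
        # with dE > 0: NMB_a > NMB_b  <=>  wtp > (C_a - C_b)/dE
        q_b = 0.5
        q_a = q_b + de
        nmb_a = net_monetary_benefit(c_a, q_a, wtp)
        nmb_b = net_monetary_benefit(c_b, q_b, wtp)
        icer = (c_a - c_b) / de
        if wtp > icer + 1e-9:
            assert nmb_a > nmb_b
        elif wtp < icer - 1e-9:
            assert nmb_a < nmb_b
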