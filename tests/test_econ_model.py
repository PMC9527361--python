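"""Unit tests for the closed-form break-even economics."""

import math
from decimal import Decimal

import numpy as np
import pytest

from vtecost.econ_model import (
    CostScenario,
    DrugCourse,
    absolute_risk_reduction,
    break_even_rate,
    is_cost_effective,
    number_needed_to_treat,
    round_half_away,
    sample_size_two_proportions,
    threshold_drug_cost,
    threshold_treatment_cost,
)

CT = Decimal("9407")


class TestAbsoluteRiskReduction:
    @pytest.mark.parametrize(
        ("label", "arr_pct", "dp"),
        [
            ("Aspirin 81", 0.003, 3),
            ("Aspirin 325", 0.02, 2),
            ("Enoxaparin 40", 1.48, 2),
            ("Rivaroxaban 20", 5.36, 2),
            ("Warfarin 5", 0.02, 2),
            ("Warfarin 5 + INR", 0.09, 2),
        ],
    )
    def test_published_arr(self, regimens, label, arr_pct, dp):
        """Required ARR = C_d/C_t matches the published value per regimen."""
        scenario = CostScenario(CT, initial_rate=0.0046)
        arr = absolute_risk_reduction(regimens[label], scenario)
        assert round_half_away(arr * 100.0, dp) == arr_pct

    def test_drug_cost_equal_to_treatment_cost_needs_full_reduction(self):
        drug = DrugCourse("X", Decimal("9407"))
        assert absolute_risk_reduction(drug, CostScenario(CT, 0.5)) == 1.0

    def test_independent_of_volume_and_rate(self, regimens):
        drug = regimens["Enoxaparin 40"]
        values = {
            absolute_risk_reduction(drug, CostScenario(CT, rate, annual_surgeries=s))
            for rate in (0.0046, 0.098)
            for s in (1, 250, 100_000)
        }
        assert len(values) == 1


class TestBreakEvenRate:
    def test_aspirin_low_rate_final(self, regimens):
        res = break_even_rate(regimens["Aspirin 81"], CostScenario(CT, 0.0046))
        assert round_half_away(res.final_rate * 100.0, 3) == 0.457
        assert res.cost_effective

    def test_enoxaparin_low_rate_infeasible(self, regimens):
        res = break_even_rate(regimens["Enoxaparin 40"], CostScenario(CT, 0.0046))
        assert round_half_away(res.final_rate * 100.0, 3) == -1.015
        assert not res.cost_effective

    def test_zero_cost_drug_preserves_initial_rate(self):
        free = DrugCourse("Free", Decimal("0"))
        res = break_even_rate(free, CostScenario(CT, 0.0101))
        assert res.final_rate == 0.0101
        assert math.isinf(res.nnt_exact)

    def test_result_internal_consistency(self, regimens, low_rate_scenario):
        for drug in regimens.values():
            res = break_even_rate(drug, low_rate_scenario)
            assert abs((low_rate_scenario.initial_rate - res.final_rate) - res.arr) < 1e-12
            assert abs(res.nnt_exact * res.arr - 1.0) < 1e-9


class TestNumberNeededToTreat:
    def test_rounds_to_nearest_not_ceiling(self):
        # 50000/138.77 = 360.31 must print 360
        nnt_exact, nnt = number_needed_to_treat(138.77 / 50000)
        assert nnt == 360

    @pytest.mark.parametrize(
        ("arr", "expected"),
        [(1.0, 1), (8.29 / 9407, 1135), (0.30 / 9407, 31357), (504.23 / 110000, 218)],
    )
    def test_published_nnts(self, arr, expected):
        assert number_needed_to_treat(arr)[1] == expected

    @pytest.mark.parametrize("arr", [0.0, -0.1, 1.5])
    def test_domain_errors(self, arr):
        with pytest.raises(ValueError):
            number_needed_to_treat(arr)


class TestCostEffectiveness:
    def test_expensive_drug_only_at_high_rate(self, regimens):
        riva = regimens["Rivaroxaban 20"]
        assert is_cost_effective(riva, CostScenario(CT, 0.098))
        assert not is_cost_effective(riva, CostScenario(CT, 0.0046))

    def test_exact_boundary_counts_as_cost_effective(self):
        # C_d / C_t == VR_i exactly: break-even final rate is zero
        drug = DrugCourse("Boundary", Decimal("9.407"))
        assert is_cost_effective(drug, CostScenario(CT, 9.407 / 9407))


class TestThresholds:
    @pytest.mark.parametrize(
        ("label", "expected"),
        [("Enoxaparin 40", 30167.39), ("Rivaroxaban 20", 109615.22)],
    )
    def test_threshold_treatment_cost_matches_bisection(self, regimens, label, expected):
        """C_t* = C_d/VR_i agrees with a cent-resolution bisection on the
        cost-effectiveness verdict."""
        drug = regimens[label]
        thr = threshold_treatment_cost(drug, 0.0046)
        assert round(thr, 2) == expected

        lo, hi = Decimal("1.00"), Decimal("200000.00")
        while hi - lo > Decimal("0.01"):
            mid = ((lo + hi) / 2).quantize(Decimal("0.01"))
            if is_cost_effective(drug, CostScenario(mid, 0.0046)):
                hi = mid
            else:
                lo = mid
        assert abs(float(hi) - thr) <= 0.02

    def test_threshold_trivial_unit_case(self):
        assert threshold_treatment_cost(DrugCourse("X", Decimal("1")), 1.0) == 1.0

    def test_threshold_zero_rate_rejected(self, regimens):
        with pytest.raises(ValueError):
            threshold_treatment_cost(regimens["Aspirin 81"], 0.0)

    @pytest.mark.parametrize(
        ("rate", "expected_cents"), [(0.0046, 4327), (0.0101, 9501)]
    )
    def test_threshold_drug_cost_matches_cent_scan(self, rate, expected_cents):
        """C_d* = C_t*VR_i agrees with a brute-force scan of the verdict
        over course prices in 1-cent steps."""
        scenario = CostScenario(CT, rate)
        thr = threshold_drug_cost(scenario)
        assert round(thr, 2) == expected_cents / 100

        # scan downward from just above the threshold: first affordable price
        cents = expected_cents + 5
        while not is_cost_effective(DrugCourse("X", Decimal(cents) / 100), scenario):
            cents -= 1
        assert cents == expected_cents

    def test_threshold_drug_cost_zero_rate(self):
        assert threshold_drug_cost(CostScenario(CT, 0.0)) == 0.0


class TestSampleSize:
    def test_known_total_for_textbook_case(self):
        assert sample_size_two_proportions(0.20, 0.10, alpha=0.05, power=0.80) == 398

    def test_simulated_power_meets_nominal(self):
        """Empirical power of the pooled two-proportion z-test at the
        computed n reaches the nominal 80%."""
        n_arm = sample_size_two_proportions(0.20, 0.10) // 2
        rng = np.random.default_rng(2026)
        sims = 4000
        x1 = rng.binomial(n_arm, 0.20, sims)
        x2 = rng.binomial(n_arm, 0.10, sims)
        p1, p2 = x1 / n_arm, x2 / n_arm
        pooled = (x1 + x2) / (2 * n_arm)
        se = np.sqrt(pooled * (1 - pooled) * 2 / n_arm)
        z = np.abs(p1 - p2) / se
        power = np.mean(z > 1.959964)
        assert power >= 0.80

    def test_monotone_in_alpha_and_power(self):
        base = sample_size_two_proportions(0.20, 0.10, alpha=0.05, power=0.80)
        assert sample_size_two_proportions(0.20, 0.10, alpha=0.01, power=0.80) > base
        assert sample_size_two_proportions(0.20, 0.10, alpha=0.05, power=0.90) > base

    def test_tiny_risk_difference_gives_enormous_n(self):
        """At the aspirin-level ARR the equivalent trial is infeasibly
        large; the value is recorded, not compared to anything."""
        n = sample_size_two_proportions(0.0046, 0.0046 - 0.0000319)
        assert n > 10_000_000

    def test_equal_proportions_rejected(self):
        with pytest.raises(ValueError):
            sample_size_two_proportions(0.1, 0.1)


class TestValidation:
    def test_negative_costs_rejected(self):
        with pytest.raises(ValueError):
            DrugCourse("X", Decimal("-1"))
        with pytest.raises(ValueError):
            DrugCourse("X", Decimal("1"), monitoring_cost=Decimal("-0.01"))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"treatment_cost": Decimal("0"), "initial_rate": 0.01},
            {"treatment_cost": Decimal("-5"), "initial_rate": 0.01},
            {"treatment_cost": Decimal("100"), "initial_rate": 1.5},
            {"treatment_cost": Decimal("100"), "initial_rate": -0.1},
            {"treatment_cost": Decimal("100"), "initial_rate": 0.01, "annual_surgeries": 0},
        ],
    )
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CostScenario(**kwargs)

    def test_monitoring_is_additive(self, regimens):
        assert regimens["Warfarin 5 + INR"].effective_cost == Decimal("8.29")
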