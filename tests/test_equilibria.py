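"""Payoff model and equilibrium solvers: closed forms vs grid-search oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thresholdgame import (
    CANONICAL_SCHEDULES,
    GameConfig,
    ThresholdBelief,
    cooperative_equilibrium,
    expected_payoff,
    nash_equilibrium,
    success_probability,
    table2,
    two_stage_expected_contributions,
    verify_equilibrium,
)
from thresholdgame.equilibria import BoundaryCase, Concept, _group_objective


class TestSuccessProbability:
    @pytest.mark.parametrize(
        "total, belief, expected",
        [
            (120, ThresholdBelief.uniform(0, 240), 0.5),
            (156, ThresholdBelief.uniform(84, 156), 1.0),
            (84, ThresholdBelief.uniform(84, 156), 0.0),
            (101.4, ThresholdBelief.uniform(0, 240), 0.4225),
            (130, ThresholdBelief.point(120), 1.0),
            (120, ThresholdBelief.point(120), 1.0),  # inclusive: equal meets
            (119, ThresholdBelief.point(120), 0.0),
            (126, ThresholdBelief.uniform(108, 132), 0.75),
        ],
    )
    def test_known_values(self, total, belief, expected):
        assert success_probability(total, belief) == pytest.approx(expected, abs=1e-12)

    def test_negative_total_rejected(self):
        with pytest.raises(ValueError):
            success_probability(-1.0, ThresholdBelief.uniform(0, 240))

    @given(
        total=st.floats(0, 300),
        lo=st.floats(0, 200),
        width=st.floats(0.5, 200),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounded_and_monotone(self, total, lo, width):
        belief = ThresholdBelief.uniform(lo, lo + width)
        p = success_probability(total, belief)
        assert 0.0 <= p <= 1.0
        assert success_probability(total + 1.0, belief) >= p

    def test_piecewise_linear_breakpoints(self):
        belief = ThresholdBelief.uniform(84, 156)
        # linear in the interior with slope 1/width, flat outside
        mid = np.linspace(85, 155, 20)
        slopes = np.diff([success_probability(t, belief) for t in mid]) / np.diff(mid)
        assert np.allclose(slopes, 1 / 72)
        assert success_probability(83.9, belief) == 0.0
        assert success_probability(156.1, belief) == 1.0


class TestExpectedPayoff:
    def test_certain_success_keeps_remainder(self):
        assert expected_payoff(20, 120, ThresholdBelief.point(120)) == pytest.approx(20.0)

    def test_certain_failure_keeps_fraction(self):
        assert expected_payoff(0, 0, ThresholdBelief.uniform(0, 240)) == pytest.approx(4.0)

    def test_hand_substitution(self):
        value = expected_payoff(20, 106.67, ThresholdBelief.uniform(0, 240))
        assert value == pytest.approx(20 * (0.1 + 0.9 * 106.67 / 240), abs=1e-9)
        assert round(value, 1) == 10.0

    def test_own_exceeding_group_rejected(self):
        with pytest.raises(ValueError):
            expected_payoff(30, 20, ThresholdBelief.uniform(0, 240))


# printed equilibrium predictions (dollar totals and success probabilities);
# warning-narrow Nash is checked against the first-order condition instead
TABLE2_CELLS = [
    ("certainty", Concept.cooperative, 120.00, 1.00),
    ("certainty", Concept.nash, 120.00, 1.00),
    ("uncertainty", Concept.cooperative, 106.67, 0.44),
    ("uncertainty", Concept.nash, 11.42, 0.05),
    ("warning_wide", Concept.cooperative, 156.00, 1.00),
    ("warning_wide", Concept.nash, 99.42, 0.21),
    ("warning_narrow", Concept.cooperative, 132.00, 1.00),
]


class TestEquilibria:
    @pytest.mark.parametrize("treatment, concept, dollars, prob", TABLE2_CELLS)
    def test_printed_cells(self, beliefs, treatment, concept, dollars, prob):
        belief = beliefs[treatment]
        result = (
            cooperative_equilibrium(belief)
            if concept is Concept.cooperative
            else nash_equilibrium(belief)
        )
        assert result.total_contribution == pytest.approx(dollars, abs=0.02)
        assert result.success_probability == pytest.approx(prob, abs=0.005)

    def test_warning_narrow_nash_is_foc_solution(self, beliefs):
        """The symmetric FOC gives 130.8/1.05; it must survive the deviation oracle."""
        result = nash_equilibrium(beliefs["warning_narrow"])
        assert result.total_contribution == pytest.approx(130.8 / 1.05, abs=1e-9)
        ok, gain = verify_equilibrium(
            result.total_contribution, Concept.nash, beliefs["warning_narrow"]
        )
        assert ok, f"unilateral deviation gains {gain}"

    @pytest.mark.parametrize("treatment", list(CANONICAL_SCHEDULES))
    @pytest.mark.parametrize("concept", [Concept.cooperative, Concept.nash])
    def test_all_solutions_pass_grid_oracle(self, beliefs, treatment, concept):
        belief = beliefs[treatment]
        result = (
            cooperative_equilibrium(belief)
            if concept is Concept.cooperative
            else nash_equilibrium(belief)
        )
        ok, gain = verify_equilibrium(
            result.total_contribution, concept, belief, grid_step=0.01, tolerance=1e-3
        )
        assert ok, f"{treatment}/{concept}: improvement of {gain} found"

    def test_interior_foc_residual(self, beliefs, config):
        """Interior stationary points satisfy the first-order condition to 1e-9."""
        kappa = config.keep_fraction_on_failure
        for name in ("uncertainty", "warning_wide", "warning_narrow"):
            b = beliefs[name]
            coop = cooperative_equilibrium(b)
            if coop.boundary_case is BoundaryCase.interior:
                q = coop.total_contribution
                resid = -(kappa + (1 - kappa) * (q - b.lo) / b.width) + (
                    config.max_total - q
                ) * (1 - kappa) / b.width
                assert abs(resid) < 1e-9
            nash = nash_equilibrium(b)
            if nash.boundary_case is BoundaryCase.interior:
                c = nash.total_contribution
                resid = -(kappa + (1 - kappa) * (c - b.lo) / b.width) + (
                    config.endowment - c / config.n_players
                ) * (1 - kappa) / b.width
                assert abs(resid) < 1e-9

    def test_cooperative_matches_discrete_grid_maximizer(self, beliefs, config):
        """Exhaustive $2-grid search lands within one step of the continuous optimum."""
        belief = beliefs["uncertainty"]
        grid = np.arange(0, config.max_total + 1, 2.0)
        values = [_group_objective(q, belief, config) for q in grid]
        best = grid[int(np.argmax(values))]
        assert abs(best - cooperative_equilibrium(belief).total_contribution) <= 2.0

    def test_zero_profile_equilibrium_status(self, beliefs):
        # unilateral deviation from all-zero gains under the wide uniform belief
        assert nash_equilibrium(beliefs["uncertainty"]).zero_is_also_equilibrium is False
        # but not when one player alone cannot reach the lower limit
        assert nash_equilibrium(beliefs["certainty"]).zero_is_also_equilibrium is True
        assert nash_equilibrium(beliefs["warning_narrow"]).zero_is_also_equilibrium is True

    def test_non_equilibrium_rejected_by_oracle(self, beliefs):
        ok, gain = verify_equilibrium(60.0, Concept.nash, beliefs["certainty"])
        assert not ok and gain > 0.5  # deviating to 0 keeps 4.0 instead of 3.0

    def test_cooperative_dominates_nash(self, beliefs):
        for name, belief in beliefs.items():
            coop = cooperative_equilibrium(belief).total_contribution
            nash = nash_equilibrium(belief).total_contribution
            assert coop >= nash - 1e-9


STAGE_SPLITS = [
    ("certainty", Concept.cooperative, 60.00, 60.00),
    ("certainty", Concept.nash, 60.00, 60.00),
    ("uncertainty", Concept.cooperative, 53.34, 53.34),
    ("uncertainty", Concept.nash, 5.71, 5.71),
    ("warning_wide", Concept.cooperative, 53.34, 102.67),
    ("warning_wide", Concept.nash, 5.71, 93.71),
    ("warning_narrow", Concept.cooperative, 53.34, 78.67),
]


class TestStageSplits:
    @pytest.mark.parametrize("treatment, concept, first, second", STAGE_SPLITS)
    def test_printed_splits(self, treatment, concept, first, second):
        split = two_stage_expected_contributions(CANONICAL_SCHEDULES[treatment], concept)
        assert split.first_half == pytest.approx(first, abs=0.02)
        assert split.second_half == pytest.approx(second, abs=0.02)
        assert not split.feasibility_warnings

    @pytest.mark.parametrize("treatment", list(CANONICAL_SCHEDULES))
    @pytest.mark.parametrize("concept", [Concept.cooperative, Concept.nash])
    def test_splits_sum_to_final_equilibrium(self, treatment, concept):
        split = two_stage_expected_contributions(CANONICAL_SCHEDULES[treatment], concept)
        assert split.first_half + split.second_half == pytest.approx(split.total, abs=1e-9)
        assert split.first_half >= 0 and split.second_half >= 0

    def test_infeasible_per_round_amount_flagged(self):
        # a schedule jumping to a huge revised threshold forces > $4/round
        from thresholdgame import TreatmentSchedule

        schedule = TreatmentSchedule(
            "custom",
            ThresholdBelief.uniform(0, 240),
            6,
            ThresholdBelief.uniform(230, 240),
        )
        split = two_stage_expected_contributions(schedule, Concept.cooperative)
        assert split.feasibility_warnings


class TestTable2:
    def test_structure(self):
        df = table2()
        assert set(df.treatment) == set(CANONICAL_SCHEDULES)
        assert len(df) == 4 * 2 * 4  # treatments x concepts x stages

    def test_uncertainty_row(self):
        df = table2()
        unc = df[df.treatment == "uncertainty"].set_index(["concept", "stage"]).dollars
        assert unc["cooperative", "total_final"] == pytest.approx(106.67, abs=0.02)
        assert unc["nash", "total_final"] == pytest.approx(11.42, abs=0.02)

    def test_certainty_stage_cells(self):
        df = table2()
        cert = df[(df.treatment == "certainty") & df.stage.str.endswith("_half")]
        assert np.allclose(cert.dollars, 60.0)
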