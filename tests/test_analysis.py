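"""Group-level analysis pipeline: avoidance probabilities, curves, reports."""

import numpy as np
import pandas as pd
import pytest

from thresholdgame import (
    CANONICAL_SCHEDULES,
    AgentStrategy,
    avoidance_probability_per_group,
    generate_experiment,
    half_split_summary,
    proposals_pledges_contributions,
    run_full_analysis,
    simulate_group,
    success_curve,
    treatment_avoidance_summary,
)
from thresholdgame.analysis import DEFAULT_THRESHOLDS
from thresholdgame.simulate import ExperimentDataset, GroupRecord
from thresholdgame.config import GameConfig


class TestAvoidanceProbability:
    @pytest.mark.parametrize(
        "total, treatment, expected",
        [
            (120, "uncertainty", 0.5),
            (108, "warning_narrow", 0.0),
            (119, "certainty", 0.0),
            (120, "certainty", 1.0),
            (126, "warning_narrow", 0.75),
            (101.4, "uncertainty", 0.4225),
        ],
    )
    def test_final_limits_applied(self, total, treatment, expected):
        schedule = CANONICAL_SCHEDULES[treatment]
        assert avoidance_probability_per_group(total, schedule) == pytest.approx(expected)

    def test_warning_uses_revised_not_initial_limits(self):
        # under the initial [0,240] belief 126 would give 0.525, not 0.75
        schedule = CANONICAL_SCHEDULES["warning_narrow"]
        assert avoidance_probability_per_group(126, schedule) == 0.75


class TestAvoidanceSummary:
    def test_linearity_within_support(self, default_dataset):
        """Under uncertainty, mean p equals mean total / 240 (p linear on [0,240])."""
        per_group, summary = treatment_avoidance_summary(default_dataset)
        unc = per_group[per_group.treatment == "uncertainty"]
        assert (unc.total < 240).all() and (unc.total > 0).all()
        mean_p = summary.set_index("treatment").loc["uncertainty", "mean_p"]
        assert mean_p == pytest.approx(unc.total.mean() / 240.0, abs=1e-12)

    def test_percent_derived_from_mean(self, small_dataset):
        _, summary = treatment_avoidance_summary(small_dataset)
        for _, row in summary.iterrows():
            assert row.percent == round(row.mean_p * 100)
            assert 0.0 <= row.mean_p <= 1.0


class TestSuccessCurve:
    def test_zero_threshold_is_always_cleared(self, small_dataset):
        curve = success_curve(small_dataset, [0, 120])
        assert (curve[curve.threshold == 0].percent == 100.0).all()

    def test_counted_example(self):
        """7 groups at 118 and 3 at 125: 30% clear a threshold of 120."""
        config = GameConfig()
        groups = [
            _group_with_total(total, i)
            for i, total in enumerate([118.0] * 7 + [126.0] * 3)
        ]
        ds = ExperimentDataset(groups, config, dict(CANONICAL_SCHEDULES), seed=None)
        curve = success_curve(ds, [120])
        assert curve.percent.iloc[0] == pytest.approx(30.0)
        assert curve.n_avoiding.iloc[0] == 3

    def test_nonincreasing_in_threshold(self, default_dataset):
        curve = success_curve(default_dataset, list(DEFAULT_THRESHOLDS))
        for treatment, sub in curve.groupby("treatment"):
            values = sub.sort_values("threshold").percent.to_numpy()
            assert (np.diff(values) <= 1e-9).all()

    def test_unsorted_thresholds_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            success_curve(small_dataset, [120, 40])


def _group_with_total(total: float, group_id: int, treatment: str = "uncertainty") -> GroupRecord:
    """A structurally valid group whose contributions sum to ``total``."""
    config = GameConfig()
    contributions = np.zeros((6, 10))
    remaining = total
    for player in range(6):
        for rnd in range(10):
            step = min(4.0, remaining - remaining % 2) if remaining >= 2 else 0.0
            choice = 4.0 if remaining >= 4 else (2.0 if remaining >= 2 else 0.0)
            contributions[player, rnd] = choice
            remaining -= choice
    assert remaining == 0, "total must be a multiple of 2 and at most 240"
    g = GroupRecord(
        treatment=treatment,
        group_id=group_id,
        contributions=contributions,
        communications=[],
        realized_threshold=120,
        total_contribution=float(contributions.sum()),
    )
    g.success = g.total_contribution >= g.realized_threshold
    from thresholdgame import resolve_payoffs

    g.payoffs = resolve_payoffs(g, config)
    return g


class TestHalfSplit:
    def test_fixed_agents_split_evenly(self):
        strategies = [AgentStrategy.fixed_per_round(2.0)] * 6
        g = simulate_group(CANONICAL_SCHEDULES["certainty"], strategies,
                           rng=np.random.default_rng(0))
        ds = ExperimentDataset([g], GameConfig(), dict(CANONICAL_SCHEDULES), seed=None)
        halves, per_round = half_split_summary(ds)
        assert halves.first_half.iloc[0] == 60.0
        assert halves.second_half.iloc[0] == 60.0
        assert np.allclose(per_round.mean_contribution, 12.0)

    def test_halves_sum_to_total(self, default_dataset):
        halves, _ = half_split_summary(default_dataset)
        summary = {
            t: np.mean([g.total_contribution for g in default_dataset.by_treatment(t)])
            for t in default_dataset.treatments
        }
        for _, row in halves.iterrows():
            assert row.first_half + row.second_half == pytest.approx(summary[row.treatment])


class TestProposalsPledgesContributions:
    def test_full_alignment_case(self):
        strategies = [
            AgentStrategy(target_total=20.0, proposal_level=120.0, pledge_gap=0.0)
        ] * 6
        g = simulate_group(CANONICAL_SCHEDULES["certainty"], strategies,
                           rng=np.random.default_rng(0))
        ds = ExperimentDataset([g], GameConfig(), dict(CANONICAL_SCHEDULES), seed=None)
        table = proposals_pledges_contributions(ds)
        row = table.iloc[0]
        assert row.proposals == pytest.approx(120.0)
        assert row.pledges == pytest.approx(120.0)
        assert row.contributions == pytest.approx(120.0)

    def test_pledge_gap_lowers_pledges(self):
        strategies = [
            AgentStrategy(target_total=20.0, proposal_level=120.0, pledge_gap=3.0)
        ] * 6
        g = simulate_group(CANONICAL_SCHEDULES["certainty"], strategies,
                           rng=np.random.default_rng(0))
        ds = ExperimentDataset([g], GameConfig(), dict(CANONICAL_SCHEDULES), seed=None)
        row = proposals_pledges_contributions(ds).iloc[0]
        assert row.pledges < row.proposals

    def test_uncertainty_preset_ordering(self, default_dataset):
        """Proposals >= pledges >= contributions under threshold uncertainty."""
        table = proposals_pledges_contributions(default_dataset).set_index("treatment")
        row = table.loc["uncertainty"]
        assert row.proposals >= row.pledges >= row.contributions


class TestFullAnalysis:
    def test_all_treatments_populated(self, small_dataset):
        report = run_full_analysis(small_dataset)
        assert set(report.treatment_summary.treatment) == set(small_dataset.treatments)
        assert not report.tests_frame().empty

    def test_success_curve_consistent_with_fisher_margins(self, default_dataset):
        """The Fisher table at threshold $120 uses the same counts as the curve."""
        report = run_full_analysis(default_dataset)
        curve = report.success_curve
        at120 = curve[curve.threshold == 120].set_index("treatment")
        for t in default_dataset.treatments:
            n = at120.loc[t, "n_groups"]
            assert at120.loc[t, "percent"] == pytest.approx(
                100.0 * at120.loc[t, "n_avoiding"] / n
            )

    def test_rerun_is_deterministic(self, small_dataset):
        a = run_full_analysis(small_dataset)
        b = run_full_analysis(small_dataset)
        for name in a.tables():
            pd.testing.assert_frame_equal(a.tables()[name], b.tables()[name])
        assert {k: v.p_value for k, v in a.tests.items()} == {
            k: v.p_value for k, v in b.tests.items()
        }

    def test_empty_dataset_rejected(self):
        ds = ExperimentDataset([], GameConfig(), {}, seed=None)
        with pytest.raises(ValueError):
            run_full_analysis(ds)
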