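"""Group-level analysis of catastrophe-avoidance experiments.

Implements the study-style battery with the group as the statistical unit
throughout: per-group avoidance probabilities from the piecewise-linear
ramp (with each treatment's *final* threshold limits), success curves over
hypothetical thresholds, half-game and per-round contribution summaries,
the proposals/pledges/contributions comparison, and the exact
nonparametric tests comparing treatments with each other and with the
equilibrium predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import CANONICAL_SCHEDULES, GameConfig, TreatmentSchedule
from .equilibria import Concept, solve, success_probability
from .simulate import ExperimentDataset, GroupRecord
from .stats import TestResult, fisher_exact_2x2, friedman, kruskal_wallis, rank_sum_test, signed_rank_test

__all__ = [
    "DEFAULT_THRESHOLDS",
    "AnalysisReport",
    "avoidance_probability_per_group",
    "treatment_avoidance_summary",
    "success_curve",
    "half_split_summary",
    "proposals_pledges_contributions",
    "run_full_analysis",
]

#: hypothetical threshold values examined in the success curve: the four
#: even levels up to the expected threshold plus the three upper limits
DEFAULT_THRESHOLDS: tuple[float, ...] = (40, 60, 80, 100, 120, 132, 156, 240)


def avoidance_probability_per_group(
    group_total: float, schedule: TreatmentSchedule
) -> float:
    """Probability a group's total avoids catastrophe under its final belief.

    Warning treatments are judged against the narrowed limits introduced
    mid-game; a known threshold gives the inclusive step function.
    """
    return success_probability(group_total, schedule.final_belief)


def _schedule_for(
    treatment: str, schedules: Optional[Mapping[str, TreatmentSchedule]]
) -> TreatmentSchedule:
    table = schedules if schedules is not None else CANONICAL_SCHEDULES
    return table[treatment]


def treatment_avoidance_summary(
    dataset: ExperimentDataset,
    schedules: Optional[Mapping[str, TreatmentSchedule]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group avoidance probabilities and their per-treatment means.

    Returns ``(per_group, per_treatment)``; the summary carries the mean
    probability both raw and as a rounded percentage.
    """
    sched = dict(schedules if schedules is not None else dataset.schedules or CANONICAL_SCHEDULES)
    rows = []
    for g in dataset.groups:
        p = avoidance_probability_per_group(g.total_contribution, sched[g.treatment])
        rows.append(
            dict(treatment=g.treatment, group_id=g.group_id, total=g.total_contribution, p_avoid=p)
        )
    per_group = pd.DataFrame(rows)
    if per_group.empty:
        warnings.warn("no groups in dataset; avoidance summary is empty")
        return per_group, pd.DataFrame(columns=["treatment", "mean_p", "percent"])
    summary = (
        per_group.groupby("treatment", sort=False)["p_avoid"]
        .mean()
        .rename("mean_p")
        .reset_index()
    )
    summary["percent"] = (summary["mean_p"] * 100).round().astype(int)
    return per_group, summary


def success_curve(
    dataset: ExperimentDataset, thresholds: Sequence[float] = DEFAULT_THRESHOLDS
) -> pd.DataFrame:
    """Percent of groups whose total meets each hypothetical threshold.

    One row per (treatment, threshold); the curve is nonincreasing in the
    threshold for every treatment.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for treatment in dataset.treatments:
        totals = np.array([g.total_contribution for g in dataset.by_treatment(treatment)])
        for thr in thresholds:
            n_avoid = int((totals >= thr).sum())
            rows.append(
                dict(
                    treatment=treatment,
                    threshold=thr,
                    n_groups=len(totals),
                    n_avoiding=n_avoid,
                    percent=100.0 * n_avoid / len(totals),
                )
            )
    return pd.DataFrame(rows)


def _half_sums(group: GroupRecord, config: GameConfig) -> tuple[float, float]:
    half = config.n_rounds // 2
    first = float(group.contributions[:, :half].sum())
    second = float(group.contributions[:, half:].sum())
    return first, second


def half_split_summary(dataset: ExperimentDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean group contributions per half and per round, by treatment.

    Returns ``(halves, per_round)``.  ``halves`` has the per-treatment mean
    first-half and second-half group totals (which sum to the mean total);
    ``per_round`` has the mean group contribution in each round.
    """
    config = dataset.config
    half_rows, round_rows = [], []
    for treatment in dataset.treatments:
        groups = dataset.by_treatment(treatment)
        firsts, seconds = zip(*(_half_sums(g, config) for g in groups))
        half_rows.append(
            dict(
                treatment=treatment,
                first_half=float(np.mean(firsts)),
                second_half=float(np.mean(seconds)),
                total=float(np.mean(firsts) + np.mean(seconds)),
            )
        )
        per_round = np.mean([g.contributions.sum(axis=0) for g in groups], axis=0)
        for rnd, value in enumerate(per_round, start=1):
            round_rows.append(dict(treatment=treatment, round=rnd, mean_contribution=float(value)))
    return pd.DataFrame(half_rows), pd.DataFrame(round_rows)


def proposals_pledges_contributions(dataset: ExperimentDataset) -> pd.DataFrame:
    """Average group proposals, pledges and contributions per treatment.

    Proposals enter as the collective target (mean group proposal) averaged
    over the two communication rounds; pledges are summed within a group
    per round, then averaged over rounds and groups; contributions are the
    realised group totals.  Groups lacking round-6 communications are
    reported from round 1 only and flagged.
    """
    rows = []
    for treatment in dataset.treatments:
        groups = dataset.by_treatment(treatment)
        proposals, pledges, flags = [], [], []
        for g in groups:
            by_round: dict[int, list] = {}
            for c in g.communications:
                by_round.setdefault(c.round, []).append(c)
            if not by_round:
                continue
            expected_rounds = dataset.config.communication_rounds
            if set(by_round) != set(expected_rounds):
                flags.append(g.group_id)
            proposals.append(np.mean([recs[0].collective_target for recs in by_round.values()]))
            pledges.append(np.mean([sum(c.pledge for c in recs) for recs in by_round.values()]))
        if flags:
            warnings.warn(
                f"{treatment}: groups {flags} missing communications for some rounds; "
                "using available rounds only"
            )
        rows.append(
            dict(
                treatment=treatment,
                proposals=float(np.mean(proposals)) if proposals else np.nan,
                pledges=float(np.mean(pledges)) if pledges else np.nan,
                contributions=float(np.mean([g.total_contribution for g in groups])),
                incomplete_groups=len(flags),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class AnalysisReport:
    """All tables and test results of one full analysis run."""

    treatment_summary: pd.DataFrame
    halves: pd.DataFrame
    per_round: pd.DataFrame
    success_curve: pd.DataFrame
    avoidance_per_group: pd.DataFrame
    avoidance_summary: pd.DataFrame
    proposals_pledges: pd.DataFrame
    tests: dict[str, TestResult] = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "treatment_summary": self.treatment_summary,
            "halves": self.halves,
            "per_round": self.per_round,
            "success_curve": self.success_curve,
            "avoidance_per_group": self.avoidance_per_group,
            "avoidance_summary": self.avoidance_summary,
            "proposals_pledges": self.proposals_pledges,
        }

    def tests_frame(self) -> pd.DataFrame:
        rows = [
            dict(
                name=name,
                method=t.method,
                statistic=t.statistic,
                p_value=t.p_value,
                exact=t.exact,
                n_per_sample="x".join(map(str, t.n_per_sample)),
            )
            for name, t in self.tests.items()
        ]
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        """Human-readable digest of the report."""
        lines = ["Catastrophe-avoidance analysis", "=" * 32, ""]
        lines.append("Total group contributions (mean +/- sd):")
        for _, r in self.treatment_summary.iterrows():
            lines.append(f"  {r.treatment:>15}: ${r['mean']:.1f} +/- {r['sd']:.2f}")
        lines.append("")
        lines.append("Mean probability of avoiding catastrophe:")
        for _, r in self.avoidance_summary.iterrows():
            lines.append(f"  {r.treatment:>15}: {r.percent:d}%")
        lines.append("")
        lines.append("Proposals / pledges / contributions:")
        for _, r in self.proposals_pledges.iterrows():
            lines.append(
                f"  {r.treatment:>15}: {r.proposals:.1f} / {r.pledges:.1f} / {r.contributions:.1f}"
            )
        lines.append("")
        lines.append("Tests (two-sided):")
        for name, t in self.tests.items():
            lines.append(f"  {name}: {t.method} = {t.statistic:.2f}, p = {t.p_value:.3f}")
        return "\n".join(lines) + "\n"


def run_full_analysis(
    dataset: ExperimentDataset,
    schedules: Optional[Mapping[str, TreatmentSchedule]] = None,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> AnalysisReport:
    """Run the whole group-level battery on one dataset.

    Deterministic given the dataset (no permutation components are enabled
    by default).  Comparisons against equilibrium predictions use each
    treatment's final-belief equilibria; treatment contrasts compare the
    uncertainty treatment with every other treatment on second-half
    contributions, plus success at the expected threshold via Fisher.
    """
    if not dataset.groups:
        raise ValueError("dataset contains no groups")
    sched = dict(schedules if schedules is not None else dataset.schedules or CANONICAL_SCHEDULES)
    config = dataset.config

    totals = {
        t: np.array([g.total_contribution for g in dataset.by_treatment(t)])
        for t in dataset.treatments
    }
    treatment_summary = pd.DataFrame(
        [
            dict(
                treatment=t,
                n_groups=len(v),
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)) if len(v) > 1 else 0.0,
            )
            for t, v in totals.items()
        ]
    )
    halves, per_round = half_split_summary(dataset)
    curve = success_curve(dataset, thresholds)
    per_group, avoidance = treatment_avoidance_summary(dataset, sched)
    ppc = proposals_pledges_contributions(dataset)

    tests: dict[str, TestResult] = {}
    # totals versus the (final-belief) equilibrium predictions
    for t in dataset.treatments:
        belief = sched[t].final_belief
        for concept in (Concept.cooperative, Concept.nash):
            eq_total = solve(belief, concept, config).total_contribution
            tests[f"{t}_vs_{concept.value}_equilibrium"] = signed_rank_test(totals[t], eq_total)
    # treatment effects on contributions
    second_half = {
        t: np.array([_half_sums(g, config)[1] for g in dataset.by_treatment(t)])
        for t in dataset.treatments
    }
    first_half = {
        t: np.array([_half_sums(g, config)[0] for g in dataset.by_treatment(t)])
        for t in dataset.treatments
    }
    if len(dataset.treatments) >= 2:
        tests["first_half_by_treatment"] = kruskal_wallis(list(first_half.values()))
        tests["second_half_by_treatment"] = kruskal_wallis(list(second_half.values()))
        tests["avoidance_by_treatment"] = kruskal_wallis(
            [per_group.loc[per_group.treatment == t, "p_avoid"].to_numpy() for t in dataset.treatments]
        )
    baseline = "uncertainty" if "uncertainty" in dataset.treatments else dataset.treatments[0]
    for t in dataset.treatments:
        if t == baseline:
            continue
        tests[f"second_half_{t}_vs_{baseline}"] = rank_sum_test(second_half[t], second_half[baseline])
        tests[f"avoidance_{t}_vs_{baseline}"] = rank_sum_test(
            per_group.loc[per_group.treatment == t, "p_avoid"].to_numpy(),
            per_group.loc[per_group.treatment == baseline, "p_avoid"].to_numpy(),
        )
        # success at the expected threshold, as counts
        expected_thr = 120.0
        a = int((totals[t] >= expected_thr).sum())
        b = int((totals[baseline] >= expected_thr).sum())
        table = [[a, len(totals[t]) - a], [b, len(totals[baseline]) - b]]
        tests[f"success_at_120_{t}_vs_{baseline}"] = fisher_exact_2x2(table)
    # contribution dynamics over rounds within each treatment
    for t in dataset.treatments:
        matrix = np.array([g.contributions.sum(axis=0) for g in dataset.by_treatment(t)])
        if matrix.shape[0] >= 2:
            tests[f"rounds_trend_{t}"] = friedman(matrix)

    return AnalysisReport(
        treatment_summary=treatment_summary,
        halves=halves,
        per_round=per_round,
        success_curve=curve,
        avoidance_per_group=per_group,
        avoidance_summary=avoidance,
        proposals_pledges=ppc,
        tests=tests,
    )
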