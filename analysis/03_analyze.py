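#!/usr/bin/env python
"""Group-level analysis of the simulated experiment.

Reads results/experiment/ (run 02_simulate.py first), applies the full
battery — treatment summaries, half-game splits, success curves over
hypothetical thresholds, avoidance probabilities under each treatment's
final threshold limits, proposals/pledges/contributions, and the exact
nonparametric tests — and writes the report tables to results/report/.
"""

from pathlib import Path

from thresholdgame import run_full_analysis
from thresholdgame.io import read_dataset, write_report

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    dataset = read_dataset(ROOT / "experiment")
    report = run_full_analysis(dataset)
    write_report(report, ROOT / "report")
    print(f"wrote report tables to {ROOT / 'report'}\n")
    print(report.summary_text())
    curve = report.success_curve
    at120 = curve[curve.threshold == 120].set_index("treatment")
    print("Groups clearing the expected threshold of $120:")
    for treatment, row in at120.iterrows():
        print(f"  {treatment:>15}: {row.n_avoiding:.0f}/{row.n_groups:.0f}")
    print(
        "\nAs designed into the presets, threshold uncertainty depresses totals\n"
        "and avoidance probability, and only the narrow early-warning signal\n"
        "restores certainty-level contributions."
    )


if __name__ == "__main__":
    main()
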