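#!/usr/bin/env python
"""Generate the synthetic experiment: 10 groups in each of 4 treatments.

Uses the calibration presets, whose agents track the canonical
treatment-level mean totals ($119 certainty, $101.4 uncertainty, $109.4
warning-wide, $124.2 warning-narrow).  Writes the dataset CSVs under
results/experiment/ and prints the per-treatment group totals.
"""

import argparse
from pathlib import Path

import numpy as np

from thresholdgame import generate_experiment
from thresholdgame.io import write_dataset

OUT = Path(__file__).resolve().parent.parent / "results" / "experiment"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=2024)
    args = parser.parse_args()

    dataset = generate_experiment(seed=args.seed)
    write_dataset(dataset, OUT)
    print(f"wrote {len(dataset.groups)} groups "
          f"({len(dataset.groups) * dataset.config.n_players} players) to {OUT}\n")
    for treatment in dataset.treatments:
        totals = np.array([g.total_contribution for g in dataset.by_treatment(treatment)])
        successes = sum(g.success for g in dataset.by_treatment(treatment))
        print(
            f"  {treatment:>15}: totals mean ${totals.mean():6.1f} "
            f"(sd {totals.std(ddof=1):5.2f}), {successes}/{len(totals)} groups "
            "avoided catastrophe at their drawn threshold"
        )
    print(
        "\nGroup totals cluster near each treatment's calibration target;\n"
        "variability across groups is much smaller than between human groups,\n"
        "which matters for interpreting the test battery downstream."
    )


if __name__ == "__main__":
    main()
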