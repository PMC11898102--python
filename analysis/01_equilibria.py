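#!/usr/bin/env python
"""Solve the game's equilibrium predictions for the four treatments.

Writes results/table2.csv (one row per treatment x concept x stage) and
prints the headline solutions: a known $120 threshold supports cooperative
and Nash totals of $120; wide uniform uncertainty on [$0, $240] drops the
cooperative optimum to $106.67 (success probability 0.44) and the symmetric
Nash total to $11.42 (0.05); mid-game narrowing to [$84, $156] or
[$108, $132] pushes the cooperative optimum to the revised upper limit
($156 / $132, certain success) and the Nash total to $99.42 / $124.57.
"""

from pathlib import Path

from thresholdgame import CANONICAL_SCHEDULES, table2
from thresholdgame.equilibria import Concept, solve, verify_equilibrium

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    df = table2()
    df.to_csv(OUT / "table2.csv", index=False, float_format="%.4f")
    print(f"wrote {OUT / 'table2.csv'} ({len(df)} cells)\n")

    print("Equilibrium totals under each treatment's final belief:")
    for name, schedule in CANONICAL_SCHEDULES.items():
        for concept in (Concept.cooperative, Concept.nash):
            r = solve(schedule.final_belief, concept)
            ok, gain = verify_equilibrium(r.total_contribution, concept, schedule.final_belief)
            print(
                f"  {name:>15} {concept.value:>11}: ${r.total_contribution:7.2f} "
                f"(p = {r.success_probability:.2f}, {r.boundary_case.value}, "
                f"oracle {'ok' if ok else f'FAILED gain={gain:.3g}'})"
            )
    print(
        "\nCooperative totals weakly dominate Nash totals in every treatment;\n"
        "the early-warning signal moves both upward, far more so for the\n"
        "narrow signal's Nash prediction ($11.42 -> $124.57)."
    )


if __name__ == "__main__":
    main()
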