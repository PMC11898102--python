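# thresholdgame

Equilibrium analysis, synthetic experiments and group-level statistics for
the iterated **catastrophe-avoidance game** (a threshold public-goods game,
also known as the collective-risk social dilemma) under threshold
uncertainty and mid-game early-warning signals.

The setting models international climate cooperation in the laboratory:
six players each hold a $40 endowment and over 10 rounds choose to put $0,
$2 or $4 into a joint damage-prevention account. If the group total at the
end of the game fails to reach a threshold *Q*, every player loses 90% of
what remains in their personal account. Four treatments vary what groups
know about *Q*: it is known exactly ($120), uniformly uncertain on
[$0, $240], or initially uncertain and then narrowed mid-game by an early
warning signal to [$84, $156] (wide) or [$108, $132] (narrow) — all with
E(*Q*) = $120. Players exchange non-binding proposals and pledges at
rounds 1 and 6.

## The model

With risk-neutral players the iterated game reduces to a one-shot game in
the end-of-game total *Q*<sub>T</sub>. The probability of avoiding
catastrophe under a uniform threshold belief on [*Q*<sub>min</sub>, *Q*<sub>max</sub>] is the
piecewise-linear ramp

```
p(QT) = 0                               QT < Qmin
        (QT − Qmin)/(Qmax − Qmin)       Qmin ≤ QT ≤ Qmax
        1                               QT > Qmax
```

and a player who contributed *q* of her endowment *w* expects
(*w* − *q*)(κ + (1 − κ)*p*(*Q*<sub>T</sub>)) with κ = 0.1 the fraction kept
on failure. The package solves two solution concepts in closed form and
verifies both against exhaustive grid search:

- the **cooperative equilibrium** — the total maximising the group's summed
  expected payoff (*nw* − *Q*)(κ + (1 − κ)*p*(*Q*));
- the **symmetric Nash equilibrium** — the solution of each player's
  first-order condition against the others' symmetric strategies, with
  corner and all-zero-profile handling.

On top of the solvers sit a seeded synthetic-experiment generator
(strategy-driven agents playing the full protocol, including the round-6
warning and whole-dollar threshold draws) and the group-level analysis
battery: avoidance probabilities, success curves over hypothetical
thresholds, half-game splits, proposals/pledges/contributions, and exact
small-sample nonparametric tests (Fisher by the probability-mass rule;
signed-rank and rank-sum by complete enumeration over the observed tie
structure; Kruskal–Wallis and Friedman with chi-square p-values).

## Worked example

```python
>>> from thresholdgame import ThresholdBelief, cooperative_equilibrium, nash_equilibrium
>>> wide = ThresholdBelief.uniform(0, 240)
>>> coop = cooperative_equilibrium(wide)
>>> round(coop.total_contribution, 2), round(coop.success_probability, 2)
(106.67, 0.44)
>>> nash = nash_equilibrium(wide)
>>> round(nash.total_contribution, 2), nash.zero_is_also_equilibrium
(11.43, False)
>>> narrow = ThresholdBelief.uniform(108, 132)
>>> round(nash_equilibrium(narrow).total_contribution, 2)
124.57
```

Uncertainty is devastating in this model: the group optimum falls from
$120 (catastrophe avoided with certainty) to $106.67 with a 44% success
chance, and self-interested play collapses to $11.43. A narrow
early-warning signal restores a Nash total of $124.57 (69% success); a
wide one only reaches $99.43 (21%).

The same numbers are available from the shell:

```bash
thresholdgame reproduce-table2 --out table2.csv
thresholdgame simulate --seed 1 --out-dir data/
thresholdgame analyze --in-dir data/ --out report/
```

The repository also contains the full pipeline as numbered drivers:
`analysis/01_equilibria.py` (prediction table), `analysis/02_simulate.py`
(the 4 × 10-group synthetic experiment) and `analysis/03_analyze.py`
(the statistical battery), writing their tables under `results/`.

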