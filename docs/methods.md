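# Methods

## Game and payoff model

The game is the iterated collective-risk social dilemma with threshold
uncertainty. Structural constants (`GameConfig`): n = 6 players, 10
rounds, endowment w = $40, per-round choices {0, 2, 4} dollars,
keep-fraction on failure κ = 0.1 (players lose 90% of their remaining
endowment if the group total misses the threshold), communication at
rounds 1 and 6. With these defaults the maximum personal contribution
(10 × $4) exactly exhausts the endowment and the maximum group total is
$240.

Because payoffs accrue only once, at the end of the game, and players are
assumed risk-neutral, the equilibrium analysis treats the game as one-shot
in the final total Q. The success probability under a uniform threshold
belief on [Qmin, Qmax] is the piecewise-linear ramp p(Q) =
clip((Q − Qmin)/(Qmax − Qmin), 0, 1); a point belief uses the
inclusive step 1{Q ≥ threshold} ("equal or exceed"). A player with
personal total q expects (w − q)(κ + (1 − κ)p(Q)).

### Continuous vs discrete thresholds

The experiment draws thresholds over whole dollars; the solvers use the
continuous-uniform approximation, which yields the familiar closed forms
(e.g. the cooperative optimum 320/3 ≈ 106.67 under [0, 240]). The
discrete distribution is used only where it belongs: the simulator's
threshold draw (`sample_threshold`, uniform over {Qmin, …, Qmax}).

### Solvers

*Cooperative*: maximise the group objective (nw − Q)(κ + (1 − κ)p(Q)).
On the linear branch the stationary point is
Q\* = (nw + Qmin − κ(Qmax − Qmin)/(1 − κ))/2; the candidate set is
{0, Q\* if interior, Qmax}, ties broken toward higher payoff then higher
success probability. Narrow supports put the optimum at the upper corner
(success certain): [84, 156] → $156, [108, 132] → $132.

*Symmetric Nash*: solve each player's first-order condition at a symmetric
profile C = nc, giving C\* = (w + Qmin − κ(Qmax − Qmin)/(1 − κ))/(1 + 1/n)
on the linear branch. If the interior candidate leaves the support, the
pivotal upper-corner profile (everyone contributes Qmax/n) is examined
instead. Point beliefs use the threshold itself as the focal candidate.
Every candidate must survive a unilateral-deviation scan over a $0.01 grid
of one player's alternatives (tolerance $0.001) before being returned; the
all-zero profile's equilibrium status is computed the same way and
reported as a flag, never assumed. Under [0, 240] a lone deviation from
all-zero pays (marginal success value 0.15 > 0.1 marginal cost at c = 0),
so zero is *not* an equilibrium there, while it is under the certainty,
[84, 156] and [108, 132] beliefs, where no single player can reach Qmin.

The [108, 132] Nash total is C\* = 130.8/1.05 ≈ $124.57 (success 0.69).
Published treatments of this design sometimes quote $124.71 (0.70) for
this cell; that value is not the symmetric first-order-condition solution
of the payoff model above, though it lies within the oracle's tolerance of
one. This package reports the FOC solution and requires it (not the quoted
figure) to pass the best-response oracle.

*Verification*: `verify_equilibrium` is an independent grid-search oracle —
for Nash it scans one player's deviations, for cooperative all grid totals
of the group objective — and is used both in the test suite and at run
time by the acceptance script.

*Stage splits*: players are assumed to spread contributions evenly, so the
first half targets half the initial-belief equilibrium and the second half
makes up the difference to the (revised-belief) equilibrium. Implied
per-player per-round amounts above $4 are flagged, not clamped; no
canonical schedule triggers the flag.

## Synthetic experiment generator

The study's behavioural data cannot be derived from its design, and the
generator does not pretend otherwise: agents are an invention whose only
obligations are (a) the design's structure — choice set, budgets,
communication protocol, warning timing, whole-dollar draws, payoff rule —
and (b) treatment-level mean totals matching the canonical values by
construction.

Each agent (`AgentStrategy`) tracks a personal target: in each round it
intends (remaining target)/(remaining rounds), optionally pulled toward
the lagged group-mean contribution by `reciprocity_weight`, perturbed by
Gaussian noise (`noise_sd`, default $1.50/round in presets), and snapped
to the nearest feasible choice (midpoint ties resolve downward, budgets
clamp). The feedback through the remaining target makes quantization
errors self-correcting, so realised personal totals are approximately
unbiased for the target — the property the calibration rests on.

Communications: each agent proposes a group total (`proposal_level`); the
round's mean proposal is the collective target. The pledge is the agent's
stated fair share of her own proposal minus `pledge_gap` (floored at 0).
"Intent" here is deliberately the *stated* intent, not the behavioural
target: with a positive gap and a behavioural target below the stated fair
share this reproduces the proposals ≥ pledges ≥ contributions ordering
characteristic of uncertain treatments, and with gap 0 and aligned targets
all three coincide. When a warning triggers retargeting, the agent's
proposal moves with its new target.

Warning responses: `retarget_mean` re-aims the personal total at the
revised expected threshold's fair share (E(Q)/6), `retarget_upper` at the
revised upper limit's fair share (Qmax/6), `none` keeps the original
target. Retargeting happens at the start of the revision round, before
that round's communications — matching the protocol — and produces the
punctuated round-6 rise in contributions.

Calibration presets (per-group expected totals in parentheses): certainty —
six agents at $119/6 each ($119); uncertainty — six at $101.4/6, pledge
gap $1.50 ($101.4); warning-wide — uncertainty behaviour with two agents
retargeting to the mean at round 6 (2×$20 + 4×$16.9 = $107.6, tracking
$109.4); warning-narrow — two agents retarget to the upper limit, four to
the mean (2×$22 + 4×$20 = $124, tracking $124.2). Integer mixes cannot hit
the fractional targets exactly; all land inside the ±$3 design band that
the preset contract promises at 1000 groups. Measured means at 1000 groups
per treatment sit within ~$2 of the targets, with a small upward drift
(~+$1.5) in low-target treatments caused by the noise floor at zero intent.

What the generator does **not** emulate: between-group heterogeneity at
human scale (group SDs here are ≈ $4 vs ≈ $11–24 in human play), free
riding and conditional-cooperation dynamics, declining round trajectories
under uncertainty, and any individual-level behavioural theory. Passing
tests on synthetic data therefore validate the *pipeline* — bookkeeping,
statistics, determinism — not behavioural claims about people.

Randomness: one root seed; group g of treatment index t (treatments in
sorted name order) uses `SeedSequence(seed, spawn_key=(t, g))`, so any
subset of the design reproduces the identical groups.

## Statistics

With 10 groups per treatment as the statistical unit, exact tests matter.

- **Fisher exact (2×2)**: two-sided by the probability-mass rule (sum of
  hypergeometric probabilities ≤ the observed table's); zero margins give
  p = 1 by convention. Backed by `scipy.stats.fisher_exact`, whose
  two-sided method is exactly this rule.
- **Signed-rank** (sample vs reference): zeros dropped, mid-ranks on
  |differences|, statistic = sum of positive ranks; for n ≤ 25 the exact
  null over all 2ⁿ sign assignments is computed by dynamic programming on
  doubled (integer) ranks, two-sided p = doubled smaller tail, capped at 1.
  Ten all-positive differences give W = 55, p = 2⁻⁹ ≈ 0.002.
- **Rank-sum** (two independent samples): statistic reported as the larger
  of U and U′ (0..n₁n₂ scale, so 0..100 for ten-group treatments); for
  n₁, n₂ ≤ 12 the exact permutation null of the rank sum over the observed
  mid-rank multiset is computed by subset-sum DP, doubled-tail two-sided.
  Larger samples fall back to tie-corrected normal approximations.
- **Kruskal–Wallis / Friedman**: chi-square-approximate p-values with
  mid-rank tie correction (the convention implied by χ² reporting in this
  literature), with an optional seeded Monte-Carlo permutation p-value
  alongside (add-one estimator). The Friedman statistic is computed
  directly (matching `scipy.stats.friedmanchisquare` where both apply) so
  that the k = 2 case and degenerate inputs are handled.

The exact implementations are cross-checked in the test suite against
brute-force enumeration (with ties) and scipy's exact modes (tie-free).

Display conventions: percentages to integers, dollars to two decimals,
p-values to three; full precision kept internally. Equilibrium tables are
compared to two-decimal reference values with an absolute $0.02 tolerance,
which absorbs the mixed rounding/truncation conventions such values are
printed with.

## Analysis pipeline

Per-group avoidance probabilities apply the ramp with each treatment's
*final* limits (the narrowed ones in warning treatments; the step for
certainty). Because p is linear on the support, the uncertainty
treatment's mean probability equals (mean total)/240 whenever all totals
are interior — the identity the tests exploit. Success curves count groups
with total ≥ threshold at {40, 60, 80, 100, 120, 132, 156, 240} (the even
levels to E(Q) plus the three upper limits) and are nonincreasing by
construction. Proposals are averaged as collective targets over the two
communication rounds; pledges are summed within group, then averaged over
rounds and groups. The full battery compares each treatment against its
cooperative and Nash predictions (signed-rank), contrasts every treatment
with the uncertainty baseline (rank-sum on second-half contributions and
avoidance probabilities, Fisher on success at $120), and tests round
trends (Friedman) — deterministic given the dataset, since no permutation
component is enabled by default.

## Numerical and I/O choices

Money is serialized as two-decimal strings; collective-target validation
tolerates half-cent discrepancies so serialization round-trips cleanly.
Datasets round-trip through three CSVs plus a metadata JSON (seed, config,
package version; timestamps excluded from determinism checks). Malformed
rows are rejected with file, line and column. Missing communications load
as an empty, flagged field rather than failing.

## Problem sizes

Default runs use the study-scale design (4 treatments × 10 groups × 6
players × 10 rounds). Calibration checks use 1000 groups per treatment
(~1 s), chosen so the Monte-Carlo error of a mean total (≈ $0.12) is
negligible against the ±$3 band. Grid oracles use a $0.01 step over one
endowment (Nash) or the full $240 range (cooperative).

## Known limitations

- Only symmetric pure-strategy equilibria; no round-by-round subgame
  analysis, no risk attitudes, no asymmetric profiles.
- The generator's agents are stationary target-trackers; they do not learn
  or punish, and their dispersion is far below human heterogeneity.
- Exact rank tests switch to asymptotics beyond n = 25 (signed-rank) /
  n = 12 per sample (rank-sum).
- Friedman/Kruskal–Wallis p-values are asymptotic; the permutation option
  exists but is off by default to keep analyses deterministic.
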