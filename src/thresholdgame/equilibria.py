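"""Payoff model and equilibrium solvers for the catastrophe-avoidance game.

With risk-neutral players the iterated game collapses to an equivalent
one-shot game: only the end-of-game group total Q matters.  A player who
has contributed q of her endowment w receives

    u(q, Q) = (w - q) * (kappa + (1 - kappa) * p(Q))

where kappa is the fraction kept on failure (0.1: "lose 90%") and p(Q) is
the probability that Q meets or exceeds the threshold.  Under a uniform
threshold belief on [Qmin, Qmax], p is the piecewise-linear ramp

    p(Q) = 0                        for Q < Qmin
         = (Q - Qmin)/(Qmax - Qmin) for Qmin <= Q <= Qmax
         = 1                        for Q > Qmax

and for a known threshold it degenerates to the step 1{Q >= threshold}.

Two solution concepts are solved in closed form and cross-checked by grid
search:

* the *cooperative equilibrium* maximises the group's summed expected
  payoff (n*w - Q) * (kappa + (1-kappa) p(Q));
* the symmetric *Nash equilibrium* solves each player's first-order
  condition against the others' symmetric strategies, with explicit
  handling of the all-zero profile and of upper-corner (pivotal)
  candidates when the interior solution leaves the belief's support.

Equilibrium solving uses the continuous-uniform approximation of the
whole-dollar threshold draw; this is what yields totals like 320/3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

from .config import (
    CANONICAL_SCHEDULES,
    TREATMENT_ORDER,
    BeliefKind,
    GameConfig,
    ThresholdBelief,
    TreatmentSchedule,
)

__all__ = [
    "Concept",
    "BoundaryCase",
    "EquilibriumResult",
    "StageSplit",
    "success_probability",
    "expected_payoff",
    "cooperative_equilibrium",
    "nash_equilibrium",
    "solve",
    "verify_equilibrium",
    "two_stage_expected_contributions",
    "table2",
]


class Concept(str, Enum):
    cooperative = "cooperative"
    nash = "nash"


class BoundaryCase(str, Enum):
    interior = "interior"
    upper_corner = "upper_corner"
    zero = "zero"


@dataclass(frozen=True)
class EquilibriumResult:
    """One solution concept's prediction for total group contributions."""

    concept: Concept
    total_contribution: float
    per_player: float
    success_probability: float
    boundary_case: BoundaryCase
    group_expected_payoff: float
    zero_is_also_equilibrium: Optional[bool] = None  # Nash only


def success_probability(total: float, belief: ThresholdBelief) -> float:
    """Probability that a group total meets or exceeds the threshold.

    Uniform beliefs use the piecewise-linear ramp over the support; point
    beliefs use the inclusive step function (success iff total >= threshold).
    """
    if total < 0:
        raise ValueError(f"total contribution must be nonnegative, got {total}")
    if belief.kind is BeliefKind.point:
        return 1.0 if total >= belief.lo else 0.0
    if total <= belief.lo:
        return 0.0
    if total >= belief.hi:
        return 1.0
    return (total - belief.lo) / belief.width


def expected_payoff(
    own_total: float,
    group_total: float,
    belief: ThresholdBelief,
    config: GameConfig = GameConfig(),
) -> float:
    """A player's expected end-of-game payoff given her own and the group total."""
    if not 0 <= own_total <= config.endowment:
        raise ValueError(f"own_total must lie in [0, {config.endowment}]")
    if own_total > group_total + 1e-12:
        raise ValueError("own_total cannot exceed the group total")
    kappa = config.keep_fraction_on_failure
    p = success_probability(group_total, belief)
    return (config.endowment - own_total) * (kappa + (1.0 - kappa) * p)


def _group_objective(total: float, belief: ThresholdBelief, config: GameConfig) -> float:
    """Summed expected payoff of the whole group at total Q."""
    kappa = config.keep_fraction_on_failure
    p = success_probability(total, belief)
    return (config.max_total - total) * (kappa + (1.0 - kappa) * p)


def cooperative_equilibrium(
    belief: ThresholdBelief, config: GameConfig = GameConfig()
) -> EquilibriumResult:
    """Total contribution maximising the group's summed expected payoff.

    Candidates are the interior stationary point of the group objective on
    the linear branch of p, the upper support limit (success certain), and
    zero; ties break toward higher payoff, then higher success probability.
    """
    kappa = config.keep_fraction_on_failure
    nw = config.max_total
    candidates: list[tuple[float, BoundaryCase]] = [(0.0, BoundaryCase.zero)]
    if belief.kind is BeliefKind.point:
        if belief.lo <= nw:
            candidates.append((belief.lo, BoundaryCase.upper_corner))
    else:
        # stationary point of (nw - Q)(kappa + (1-kappa)(Q-lo)/width)
        q_star = (nw + belief.lo - kappa * belief.width / (1.0 - kappa)) / 2.0
        if belief.lo < q_star < min(belief.hi, nw):
            candidates.append((q_star, BoundaryCase.interior))
        if belief.hi <= nw:
            candidates.append((belief.hi, BoundaryCase.upper_corner))
    best_total, best_case = max(
        candidates,
        key=lambda c: (
            _group_objective(c[0], belief, config),
            success_probability(c[0], belief),
        ),
    )
    return EquilibriumResult(
        concept=Concept.cooperative,
        total_contribution=best_total,
        per_player=best_total / config.n_players,
        success_probability=success_probability(best_total, belief),
        boundary_case=best_case,
        group_expected_payoff=_group_objective(best_total, belief, config),
    )


def _unilateral_gain(
    total: float, belief: ThresholdBelief, config: GameConfig, grid_step: float
) -> float:
    """Largest payoff gain a symmetric player can get by a unilateral grid move."""
    c = total / config.n_players
    others = total - c
    current = expected_payoff(c, total, belief, config)
    dev = np.arange(0.0, config.endowment + grid_step / 2, grid_step)
    # include breakpoints of p and the current choice itself
    extra = [c, belief.lo - others, belief.hi - others]
    dev = np.concatenate([dev, [e for e in extra if 0.0 <= e <= config.endowment]])
    kappa = config.keep_fraction_on_failure
    totals = others + dev
    p = np.clip(
        (totals - belief.lo) / belief.width if belief.width > 0 else np.where(totals >= belief.lo, 1.0, 0.0),
        0.0,
        1.0,
    )
    if belief.kind is BeliefKind.point:
        p = np.where(totals >= belief.lo, 1.0, 0.0)
    payoffs = (config.endowment - dev) * (kappa + (1.0 - kappa) * p)
    return float(payoffs.max() - current)


def _is_symmetric_equilibrium(
    total: float,
    belief: ThresholdBelief,
    config: GameConfig,
    grid_step: float = 0.01,
    tolerance: float = 1e-3,
) -> bool:
    return _unilateral_gain(total, belief, config, grid_step) <= tolerance


def nash_equilibrium(
    belief: ThresholdBelief, config: GameConfig = GameConfig()
) -> EquilibriumResult:
    """Focal symmetric Nash equilibrium under a threshold belief.

    For uniform beliefs the interior candidate solves the symmetric
    first-order condition; if it leaves the support, the pivotal
    upper-corner profile (total = Qmax) is examined instead.  For point
    beliefs the focal candidate is the threshold itself.  Among symmetric
    profiles that survive a unilateral-deviation check, the payoff-superior
    one is returned; the all-zero profile's equilibrium status is always
    computed and reported via ``zero_is_also_equilibrium``.
    """
    kappa = config.keep_fraction_on_failure
    n = config.n_players
    w = config.endowment
    candidates: list[tuple[float, BoundaryCase]] = []
    if belief.kind is BeliefKind.point:
        if belief.lo <= config.max_total and belief.lo / n <= w:
            candidates.append((belief.lo, BoundaryCase.upper_corner))
    else:
        # symmetric FOC on the linear branch:
        #   -(kappa + (1-kappa)(C-lo)/width) + (w - C/n)(1-kappa)/width = 0
        c_star = (w + belief.lo - kappa * belief.width / (1.0 - kappa)) / (1.0 + 1.0 / n)
        if belief.lo <= c_star <= belief.hi and 0.0 <= c_star / n <= w:
            case = BoundaryCase.interior
            if math.isclose(c_star, belief.hi):
                case = BoundaryCase.upper_corner
            candidates.append((c_star, case))
        elif c_star > belief.hi and belief.hi / n <= w:
            # pivotal upper-corner candidate: everyone contributes hi/n
            candidates.append((belief.hi, BoundaryCase.upper_corner))
    surviving = [
        (t, case) for t, case in candidates if t > 0 and _is_symmetric_equilibrium(t, belief, config)
    ]
    zero_eq = _is_symmetric_equilibrium(0.0, belief, config)
    if surviving:
        total, case = max(surviving, key=lambda c: expected_payoff(c[0] / n, c[0], belief, config))
    else:
        total, case = 0.0, BoundaryCase.zero
    return EquilibriumResult(
        concept=Concept.nash,
        total_contribution=total,
        per_player=total / n,
        success_probability=success_probability(total, belief),
        boundary_case=case,
        group_expected_payoff=_group_objective(total, belief, config),
        zero_is_also_equilibrium=zero_eq,
    )


def solve(
    belief: ThresholdBelief, concept: Concept | str, config: GameConfig = GameConfig()
) -> EquilibriumResult:
    """Dispatch to the cooperative or Nash solver."""
    concept = Concept(concept)
    if concept is Concept.cooperative:
        return cooperative_equilibrium(belief, config)
    return nash_equilibrium(belief, config)


def verify_equilibrium(
    total: float,
    concept: Concept | str,
    belief: ThresholdBelief,
    config: GameConfig = GameConfig(),
    grid_step: float = 0.01,
    tolerance: float = 1e-3,
) -> tuple[bool, float]:
    """Grid-search oracle for a claimed equilibrium total.

    Nash: no unilateral deviation on the grid may improve a symmetric
    player's expected payoff by more than ``tolerance``.  Cooperative: no
    grid total may improve the group objective by more than ``tolerance``.
    Returns ``(verdict, max_gain)`` with the largest improvement found.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    concept = Concept(concept)
    if concept is Concept.nash:
        gain = _unilateral_gain(total, belief, config, grid_step)
        return gain <= tolerance, gain
    grid = np.arange(0.0, config.max_total + grid_step / 2, grid_step)
    extra = [q for q in (belief.lo, belief.hi, total) if 0.0 <= q <= config.max_total]
    grid = np.concatenate([grid, extra])
    current = _group_objective(total, belief, config)
    values = np.array([_group_objective(q, belief, config) for q in extra])
    # vectorised objective on the regular part of the grid
    kappa = config.keep_fraction_on_failure
    reg = np.arange(0.0, config.max_total + grid_step / 2, grid_step)
    if belief.kind is BeliefKind.point:
        p = np.where(reg >= belief.lo, 1.0, 0.0)
    else:
        p = np.clip((reg - belief.lo) / belief.width, 0.0, 1.0) if belief.width > 0 else np.where(reg >= belief.lo, 1.0, 0.0)
    obj = (config.max_total - reg) * (kappa + (1.0 - kappa) * p)
    gain = float(max(obj.max(), values.max() if values.size else -np.inf) - current)
    return gain <= tolerance, gain


@dataclass(frozen=True)
class StageSplit:
    """Expected contributions over the two halves of the game for one concept."""

    concept: Concept
    first_half: float
    second_half: float
    total: float
    feasibility_warnings: tuple[str, ...] = ()


def two_stage_expected_contributions(
    schedule: TreatmentSchedule,
    concept: Concept | str,
    config: GameConfig = GameConfig(),
) -> StageSplit:
    """Split the equilibrium path into first- and second-half expected totals.

    Players are assumed to spread contributions evenly: the first half aims
    at half the initial-belief equilibrium; after a mid-game revision the
    second half makes up the difference to the revised-belief equilibrium.
    Implied per-player per-round amounts above the largest round choice are
    flagged, not clamped.
    """
    concept = Concept(concept)
    initial = solve(schedule.initial_belief, concept, config).total_contribution
    final = solve(schedule.final_belief, concept, config).total_contribution
    first = initial / 2.0
    second = final - first
    warnings: list[str] = []
    if second < -1e-9:
        warnings.append(
            f"revised equilibrium {final:.2f} below first-half contributions {first:.2f}"
        )
        second = max(second, 0.0) if abs(second) < 1e-9 else second
    half_rounds = config.n_rounds / 2.0
    max_choice = max(config.round_choices)
    for label, amount in (("first", first), ("second", second)):
        per_round = amount / (config.n_players * half_rounds)
        if per_round > max_choice + 1e-9:
            warnings.append(
                f"{label}-half implied per-player per-round contribution "
                f"{per_round:.2f} exceeds the maximum round choice {max_choice:g}"
            )
    return StageSplit(concept, first, second, final, tuple(warnings))


def table2(config: GameConfig = GameConfig()) -> pd.DataFrame:
    """Equilibrium predictions for the four canonical treatments.

    Returns a long-form table with one row per (treatment, concept, stage):
    stages ``total_initial`` / ``total_final`` carry the equilibrium totals
    under the initial and final threshold beliefs with their success
    probabilities; ``first_half`` / ``second_half`` carry the expected
    stage contributions (no probability attached).
    """
    rows = []
    for name in TREATMENT_ORDER:
        schedule = CANONICAL_SCHEDULES[name]
        for concept in (Concept.cooperative, Concept.nash):
            initial = solve(schedule.initial_belief, concept, config)
            final = solve(schedule.final_belief, concept, config)
            split = two_stage_expected_contributions(schedule, concept, config)
            rows.extend(
                [
                    dict(
                        treatment=name,
                        concept=concept.value,
                        stage="total_initial",
                        dollars=initial.total_contribution,
                        probability=initial.success_probability,
                    ),
                    dict(
                        treatment=name,
                        concept=concept.value,
                        stage="total_final",
                        dollars=final.total_contribution,
                        probability=final.success_probability,
                    ),
                    dict(
                        treatment=name,
                        concept=concept.value,
                        stage="first_half",
                        dollars=split.first_half,
                        probability=np.nan,
                    ),
                    dict(
                        treatment=name,
                        concept=concept.value,
                        stage="second_half",
                        dollars=split.second_half,
                        probability=np.nan,
                    ),
                ]
            )
    return pd.DataFrame(rows)
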