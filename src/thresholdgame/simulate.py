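"""Synthetic experiment generator for the catastrophe-avoidance game.

Produces datasets with the full structure of the 4-treatment x 10-group
design — six strategy-driven agents per group playing ten rounds with
$0/$2/$4 choices, proposals and pledges at rounds 1 and 6, a mid-game
narrowing of the threshold range in the warning treatments, a whole-dollar
threshold draw and end-of-game payoff resolution — so that every analysis
stage can be exercised without human data.

Agents follow a simple target-tracking rule: each holds a personal
contribution target for the whole game and in each round intends to
contribute the remaining target spread evenly over the remaining rounds,
optionally pulled toward the previous round's group-mean contribution
(reciprocity) and perturbed by Gaussian noise, then snapped to the nearest
feasible choice.  The feedback through the remaining target makes the
realised personal total an (approximately) unbiased tracker of the target,
which is what the calibration presets rely on.

Randomness uses one root seed with an explicit stream-splitting scheme:
group ``g`` of treatment index ``t`` draws from
``numpy.random.SeedSequence(seed, spawn_key=(t, g))``, so any subset of
groups is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import (
    CANONICAL_SCHEDULES,
    TREATMENT_ORDER,
    BeliefKind,
    GameConfig,
    ThresholdBelief,
    TreatmentSchedule,
)
from . import equilibria

__all__ = [
    "AgentStrategy",
    "CommunicationRecord",
    "GroupRecord",
    "ExperimentDataset",
    "sample_threshold",
    "quantize_choice",
    "simulate_group",
    "resolve_payoffs",
    "generate_experiment",
    "calibration_presets",
    "DEFAULT_DESIGN",
]


class StrategyFamily(str, Enum):
    fair_share = "fair_share"
    conditional = "conditional"
    nash_player = "nash_player"
    cooperative_player = "cooperative_player"
    fixed = "fixed"


class WarningResponse(str, Enum):
    retarget_mean = "retarget_mean"
    retarget_upper = "retarget_upper"
    none = "none"


@dataclass(frozen=True)
class AgentStrategy:
    """Parameters of one simulated player.

    ``target_total`` is the personal amount the agent tries to contribute
    over the whole game.  ``reciprocity_weight`` pulls the per-round intent
    toward the lagged group-mean contribution.  ``warning_response`` says
    how the target is revised when an early-warning signal arrives:
    retarget to a fair share of the revised expected threshold
    (``retarget_mean``), of the revised upper limit (``retarget_upper``),
    or not at all.  ``proposal_level`` is the group total the agent
    proposes; the pledge is the agent's stated fair share of her own
    proposal minus ``pledge_gap`` (floored at zero).
    """

    family: StrategyFamily = StrategyFamily.fair_share
    target_total: float = 20.0
    reciprocity_weight: float = 0.0
    noise_sd: float = 0.0
    warning_response: WarningResponse = WarningResponse.none
    pledge_gap: float = 0.0
    proposal_level: float = 120.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", StrategyFamily(self.family))
        object.__setattr__(self, "warning_response", WarningResponse(self.warning_response))
        if not 0.0 <= self.reciprocity_weight <= 1.0:
            raise ValueError("reciprocity_weight must be in [0, 1]")
        if self.target_total < 0 or self.noise_sd < 0:
            raise ValueError("target_total and noise_sd must be nonnegative")

    @classmethod
    def fixed_per_round(cls, amount: float, config: GameConfig = GameConfig()) -> "AgentStrategy":
        """An agent contributing a constant amount each round (no noise)."""
        return cls(
            family=StrategyFamily.fixed,
            target_total=amount * config.n_rounds,
            proposal_level=amount * config.n_rounds * config.n_players,
        )

    @classmethod
    def nash_player(
        cls, belief: ThresholdBelief, config: GameConfig = GameConfig(), **kw
    ) -> "AgentStrategy":
        total = equilibria.nash_equilibrium(belief, config).total_contribution
        return cls(
            family=StrategyFamily.nash_player,
            target_total=total / config.n_players,
            proposal_level=total,
            **kw,
        )

    @classmethod
    def cooperative_player(
        cls, belief: ThresholdBelief, config: GameConfig = GameConfig(), **kw
    ) -> "AgentStrategy":
        total = equilibria.cooperative_equilibrium(belief, config).total_contribution
        return cls(
            family=StrategyFamily.cooperative_player,
            target_total=total / config.n_players,
            proposal_level=total,
            **kw,
        )


@dataclass(frozen=True)
class CommunicationRecord:
    """One player's non-binding announcements in one communication round."""

    player: int
    round: int
    proposal: float
    pledge: float
    collective_target: float  # group-mean proposal of that round


@dataclass
class GroupRecord:
    """One group's complete play of the game."""

    treatment: str
    group_id: int
    contributions: np.ndarray  # (n_players, n_rounds)
    communications: list[CommunicationRecord]
    realized_threshold: int
    total_contribution: float = 0.0
    success: bool = False
    payoffs: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def player_totals(self) -> np.ndarray:
        return self.contributions.sum(axis=1)

    def validate(self, config: GameConfig = GameConfig()) -> None:
        """Enforce the structural invariants of a played game."""
        n, r = self.contributions.shape
        if n != config.n_players or r != config.n_rounds:
            raise ValueError(f"contribution matrix must be {config.n_players}x{config.n_rounds}")
        choices = set(config.round_choices)
        if not set(np.unique(self.contributions)) <= choices:
            raise ValueError(f"contributions must lie in {sorted(choices)}")
        totals = self.player_totals()
        if (totals > config.endowment + 1e-9).any():
            raise ValueError("a player's cumulative contribution exceeds the endowment")
        if abs(self.total_contribution - self.contributions.sum()) > 1e-9:
            raise ValueError("total_contribution does not equal the matrix sum")
        if self.success != (self.total_contribution >= self.realized_threshold):
            raise ValueError("success flag inconsistent with threshold comparison")
        expected = resolve_payoffs(self, config)
        if not np.allclose(self.payoffs, expected):
            raise ValueError("payoffs inconsistent with the payoff rule")
        for rec in self.communications:
            same_round = [c.proposal for c in self.communications if c.round == rec.round]
            # tolerance admits two-decimal money serialization round-trips
            if abs(rec.collective_target - float(np.mean(same_round))) > 0.006:
                raise ValueError("collective_target must be the mean group proposal")


@dataclass
class ExperimentDataset:
    """A collection of simulated groups plus the provenance to rebuild it."""

    groups: list[GroupRecord]
    config: GameConfig
    schedules: dict[str, TreatmentSchedule]
    seed: Optional[int]
    metadata: dict = field(default_factory=dict)

    def by_treatment(self, name: str) -> list[GroupRecord]:
        return [g for g in self.groups if g.treatment == name]

    @property
    def treatments(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups:
            if g.treatment not in seen:
                seen.append(g.treatment)
        return seen


def sample_threshold(belief: ThresholdBelief, rng: np.random.Generator) -> int:
    """Draw a whole-dollar threshold: uniform over {lo, lo+1, ..., hi}."""
    if belief.kind is BeliefKind.point:
        return int(round(belief.lo))
    lo = int(np.ceil(belief.lo))
    hi = int(np.floor(belief.hi))
    return int(rng.integers(lo, hi + 1))


def quantize_choice(
    desired_per_round: float, remaining_budget: float, config: GameConfig = GameConfig()
) -> float:
    """Snap a continuous intent onto the feasible per-round choice set.

    Picks the nearest choice not exceeding the remaining budget; exact
    midpoint ties resolve downward ($1.00 -> $0).
    """
    if remaining_budget < 0:
        raise ValueError("remaining_budget must be nonnegative")
    feasible = [c for c in config.round_choices if c <= remaining_budget + 1e-9]
    return min(feasible, key=lambda c: (abs(c - desired_per_round), c))


def resolve_payoffs(group: GroupRecord, config: GameConfig = GameConfig()) -> np.ndarray:
    """End-of-game cash: the remaining endowment, scaled down on failure."""
    remainder = config.endowment - group.player_totals()
    if group.total_contribution >= group.realized_threshold:
        return remainder
    return config.keep_fraction_on_failure * remainder


def _warning_target(
    strategy: AgentStrategy, revised: ThresholdBelief, config: GameConfig
) -> Optional[float]:
    """Personal total an agent retargets to when the warning arrives."""
    if strategy.warning_response is WarningResponse.retarget_mean:
        return revised.mean / config.n_players
    if strategy.warning_response is WarningResponse.retarget_upper:
        return revised.hi / config.n_players
    return None


def simulate_group(
    schedule: TreatmentSchedule,
    strategies: Sequence[AgentStrategy],
    config: GameConfig = GameConfig(),
    rng: Optional[np.random.Generator] = None,
    group_id: int = 0,
) -> GroupRecord:
    """Play one group through the full game.

    Sequencing follows the experimental protocol: an early-warning revision
    (if scheduled) is announced at the start of its round, *before* that
    round's proposals and pledges, which in turn precede the contribution
    decisions.
    """
    if len(strategies) != config.n_players:
        raise ValueError(f"need exactly {config.n_players} strategies, got {len(strategies)}")
    rng = np.random.default_rng(rng)
    n, n_rounds = config.n_players, config.n_rounds
    contributions = np.zeros((n, n_rounds))
    cumulative = np.zeros(n)
    targets = np.array([s.target_total for s in strategies])
    proposals = np.array([s.proposal_level for s in strategies])
    communications: list[CommunicationRecord] = []
    last_round_mean = 0.0

    for rnd in range(1, n_rounds + 1):
        if schedule.revision_round == rnd and schedule.revised_belief is not None:
            for i, s in enumerate(strategies):
                new_target = _warning_target(s, schedule.revised_belief, config)
                if new_target is not None:
                    targets[i] = new_target
                    proposals[i] = new_target * n
        if rnd in config.communication_rounds:
            collective = float(np.mean(proposals))
            for i, s in enumerate(strategies):
                pledge = max(0.0, proposals[i] / n - s.pledge_gap)
                communications.append(
                    CommunicationRecord(i, rnd, float(proposals[i]), pledge, collective)
                )
        rounds_left = n_rounds - rnd + 1
        for i, s in enumerate(strategies):
            base = max(0.0, targets[i] - cumulative[i]) / rounds_left
            intent = base
            if rnd > 1 and s.reciprocity_weight > 0:
                intent = (1 - s.reciprocity_weight) * base + s.reciprocity_weight * last_round_mean
            if s.noise_sd > 0:
                intent += rng.normal(0.0, s.noise_sd)
            choice = quantize_choice(intent, config.endowment - cumulative[i], config)
            contributions[i, rnd - 1] = choice
            cumulative[i] += choice
        last_round_mean = float(contributions[:, rnd - 1].mean())

    threshold = sample_threshold(schedule.final_belief, rng)
    group = GroupRecord(
        treatment=schedule.name,
        group_id=group_id,
        contributions=contributions,
        communications=communications,
        realized_threshold=threshold,
        total_contribution=float(contributions.sum()),
    )
    group.success = group.total_contribution >= threshold
    group.payoffs = resolve_payoffs(group, config)
    return group


#: the study design: 10 groups in each of the four treatments
DEFAULT_DESIGN: dict[str, int] = {name: 10 for name in TREATMENT_ORDER}


def generate_experiment(
    design: Mapping[str, int] | None = None,
    strategy_mix: Mapping[str, Sequence[AgentStrategy]] | None = None,
    seed: int = 0,
    config: GameConfig = GameConfig(),
    schedules: Mapping[str, TreatmentSchedule] | None = None,
) -> ExperimentDataset:
    """Simulate a full experiment: ``design`` maps schedule name -> n_groups.

    ``strategy_mix`` maps schedule name to the six agent strategies used in
    every group of that treatment (defaults to the calibration presets).
    Groups are simulated independently on split random streams, so the same
    seed always reproduces the same dataset.
    """
    design = dict(design if design is not None else DEFAULT_DESIGN)
    schedules = dict(schedules if schedules is not None else CANONICAL_SCHEDULES)
    mix = dict(strategy_mix) if strategy_mix is not None else calibration_presets(config)
    groups: list[GroupRecord] = []
    used: dict[str, TreatmentSchedule] = {}
    for t_index, (name, n_groups) in enumerate(sorted(design.items())):
        if n_groups == 0:
            continue
        schedule = schedules[name]
        used[name] = schedule
        strategies = mix[name]
        for g in range(n_groups):
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(t_index, g)))
            groups.append(simulate_group(schedule, strategies, config, rng, group_id=g))
    return ExperimentDataset(
        groups=groups,
        config=config,
        schedules=used,
        seed=seed,
        metadata={"design": design, "generator": "thresholdgame.simulate"},
    )


# Treatment-level mean group totals the presets are built to track.  These
# are the observed treatment means of the study design the generator
# emulates; per-agent targets are simply the fair share (mean / 6).
PRESET_MEAN_TARGETS: dict[str, float] = {
    "certainty": 119.0,
    "uncertainty": 101.4,
    "warning_wide": 109.4,
    "warning_narrow": 124.2,
}


def calibration_presets(config: GameConfig = GameConfig()) -> dict[str, list[AgentStrategy]]:
    """Named strategy mixes that track the canonical treatment-level means.

    Calibration is by construction: each agent's personal target is the
    fair share of the treatment's target mean, and warning treatments reach
    their post-warning level through fixed integer mixes of retarget
    responses (warning_narrow: two agents aim at the revised upper limit,
    four at the revised mean, i.e. $2x22 + $4x20 = $124 per group;
    warning_wide: two agents retarget to the revised mean, four keep their
    initial uncertainty-level target, ~$107.6 per group).
    """
    n = config.n_players
    noise = 1.5  # dollars per round; mixes the quantizer without drowning the target
    uncertainty_share = PRESET_MEAN_TARGETS["uncertainty"] / n

    def agent(target: float, response: WarningResponse, gap: float,
              family: StrategyFamily = StrategyFamily.fair_share) -> AgentStrategy:
        return AgentStrategy(
            family=family,
            target_total=target,
            noise_sd=noise,
            warning_response=response,
            pledge_gap=gap,
            proposal_level=120.0,
        )

    presets = {
        "certainty": [
            agent(PRESET_MEAN_TARGETS["certainty"] / n, WarningResponse.none, 0.0)
            for _ in range(n)
        ],
        "uncertainty": [
            agent(uncertainty_share, WarningResponse.none, 1.5) for _ in range(n)
        ],
        "warning_wide": [
            agent(
                uncertainty_share,
                WarningResponse.retarget_mean if i < 2 else WarningResponse.none,
                1.5,
            )
            for i in range(n)
        ],
        "warning_narrow": [
            agent(
                uncertainty_share,
                WarningResponse.retarget_upper if i < 2 else WarningResponse.retarget_mean,
                0.5,
            )
            for i in range(n)
        ],
    }
    return presets
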