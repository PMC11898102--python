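"""Structural description of the catastrophe-avoidance game.

The game: groups of ``n_players`` each hold an ``endowment`` and, over
``n_rounds`` rounds, choose a per-round contribution from ``round_choices``
into a joint damage-prevention account.  If the group total at the end of
the game falls short of a (possibly uncertain) threshold, every player keeps
only ``keep_fraction_on_failure`` of what remains in their personal account.
Non-binding proposals and pledges are exchanged in ``communication_rounds``.

Threshold beliefs are either a known point value or a uniform distribution
over a dollar range; early-warning treatments narrow the uniform range
mid-game while preserving its expected value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "GameConfig",
    "ThresholdBelief",
    "TreatmentSchedule",
    "CANONICAL_SCHEDULES",
    "canonical_schedule",
]


@dataclass(frozen=True)
class GameConfig:
    """Structural constants of the game.

    Defaults reproduce the canonical design: six players, ten rounds,
    $40 endowments, per-round choices of $0/$2/$4, a 90% loss on failure
    (``keep_fraction_on_failure = 0.1``) and communication at rounds 1 and 6.
    """

    n_players: int = 6
    n_rounds: int = 10
    endowment: float = 40.0
    round_choices: tuple[float, ...] = (0.0, 2.0, 4.0)
    keep_fraction_on_failure: float = 0.1
    communication_rounds: frozenset[int] = frozenset({1, 6})

    def __post_init__(self) -> None:
        if self.n_players < 1 or self.n_rounds < 1:
            raise ValueError("n_players and n_rounds must be positive")
        if any(c < 0 for c in self.round_choices):
            raise ValueError("round_choices must be nonnegative")
        if self.n_rounds * max(self.round_choices) > self.endowment + 1e-9:
            raise ValueError(
                "maximal contribution path exceeds the endowment: "
                f"{self.n_rounds} x {max(self.round_choices)} > {self.endowment}"
            )
        if not 0.0 <= self.keep_fraction_on_failure <= 1.0:
            raise ValueError("keep_fraction_on_failure must be in [0, 1]")
        if not set(self.communication_rounds) <= set(range(1, self.n_rounds + 1)):
            raise ValueError("communication_rounds must lie in 1..n_rounds")

    @property
    def max_total(self) -> float:
        """Largest feasible group total (= n_players x endowment)."""
        return self.n_players * self.endowment


class BeliefKind(str, Enum):
    point = "point"
    uniform = "uniform"


@dataclass(frozen=True)
class ThresholdBelief:
    """Belief about the catastrophe threshold Q.

    ``point`` beliefs put all mass on ``lo`` (= ``hi``); ``uniform`` beliefs
    spread it evenly over ``[lo, hi]``.  The experiment draws whole-dollar
    thresholds; equilibrium analysis treats the distribution as continuous.
    """

    kind: BeliefKind
    lo: float
    hi: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", BeliefKind(self.kind))
        if self.lo > self.hi:
            raise ValueError(f"belief requires lo <= hi, got [{self.lo}, {self.hi}]")
        if self.kind is BeliefKind.point and self.lo != self.hi:
            raise ValueError("point belief requires lo == hi")
        if self.lo < 0:
            raise ValueError("threshold support must be nonnegative")

    @classmethod
    def point(cls, value: float) -> "ThresholdBelief":
        return cls(BeliefKind.point, value, value)

    @classmethod
    def uniform(cls, lo: float, hi: float) -> "ThresholdBelief":
        return cls(BeliefKind.uniform, lo, hi)

    @property
    def mean(self) -> float:
        return (self.lo + self.hi) / 2.0

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.kind is BeliefKind.point:
            return f"point({self.lo:g})"
        return f"uniform[{self.lo:g},{self.hi:g}]"


@dataclass(frozen=True)
class TreatmentSchedule:
    """A treatment's threshold information over the course of the game.

    ``revision_round``/``revised_belief`` describe an early-warning signal:
    from that round on (before that round's communications) the belief is
    replaced by a narrower one nested inside the initial support.
    """

    name: str
    initial_belief: ThresholdBelief
    revision_round: Optional[int] = None
    revised_belief: Optional[ThresholdBelief] = None

    def __post_init__(self) -> None:
        if (self.revision_round is None) != (self.revised_belief is None):
            raise ValueError("revision_round and revised_belief must come together")
        if self.revised_belief is not None:
            ib, rb = self.initial_belief, self.revised_belief
            if not (ib.lo <= rb.lo and rb.hi <= ib.hi):
                raise ValueError("revised support must nest within the initial support")

    @property
    def final_belief(self) -> ThresholdBelief:
        """The belief in force at the end of the game (revised if any)."""
        return self.revised_belief if self.revised_belief is not None else self.initial_belief

    def belief_at_round(self, round_index: int) -> ThresholdBelief:
        """Belief in force during ``round_index`` (1-based)."""
        if self.revision_round is not None and round_index >= self.revision_round:
            return self.revised_belief  # type: ignore[return-value]
        return self.initial_belief


def _canonical() -> dict[str, TreatmentSchedule]:
    wide_initial = ThresholdBelief.uniform(0.0, 240.0)
    return {
        "certainty": TreatmentSchedule("certainty", ThresholdBelief.point(120.0)),
        "uncertainty": TreatmentSchedule("uncertainty", wide_initial),
        "warning_wide": TreatmentSchedule(
            "warning_wide", wide_initial, 6, ThresholdBelief.uniform(84.0, 156.0)
        ),
        "warning_narrow": TreatmentSchedule(
            "warning_narrow", wide_initial, 6, ThresholdBelief.uniform(108.0, 132.0)
        ),
    }


CANONICAL_SCHEDULES: dict[str, TreatmentSchedule] = _canonical()

#: order treatments are reported in throughout
TREATMENT_ORDER = ("certainty", "uncertainty", "warning_wide", "warning_narrow")


def canonical_schedule(name: str) -> TreatmentSchedule:
    """Look up one of the four canonical treatment schedules by name.

    Accepts both underscore and hyphen spellings (``warning-narrow``).
    """
    key = name.replace("-", "_").lower()
    try:
        return CANONICAL_SCHEDULES[key]
    except KeyError:
        raise KeyError(
            f"unknown schedule {name!r}; choose from {sorted(CANONICAL_SCHEDULES)}"
        ) from None
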