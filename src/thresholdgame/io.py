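"""Dataset and configuration serialization.

Datasets are written as three plain CSV tables per directory —
``contributions.csv`` (one row per player-round), ``communications.csv``
(one row per player-communication-round) and ``groups.csv`` (one row per
group with threshold draw, outcome and payoffs) — plus ``metadata.json``
recording the seed, configuration hash and package version.  Money is
serialized as decimal strings with two fraction digits; probabilities at
full precision.  ``write_dataset`` followed by ``read_dataset`` is the
identity on all analysed fields.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import CANONICAL_SCHEDULES, BeliefKind, GameConfig, ThresholdBelief, TreatmentSchedule
from .simulate import (
    AgentStrategy,
    CommunicationRecord,
    ExperimentDataset,
    GroupRecord,
    resolve_payoffs,
)

__all__ = [
    "RunConfig",
    "DatasetFormatError",
    "write_dataset",
    "read_dataset",
    "write_report",
]


class DatasetFormatError(ValueError):
    """A dataset file violates the expected schema.

    Carries the offending file, line (1-based, header excluded) and column
    where known.
    """

    def __init__(self, file: str, line: Optional[int], column: Optional[str], message: str):
        self.file, self.line, self.column = file, line, column
        where = file + (f":{line}" if line is not None else "")
        if column:
            where += f" (column {column})"
        super().__init__(f"{where}: {message}")


def _money(x: float) -> str:
    return f"{x:.2f}"


# ---------------------------------------------------------------------------
# run configuration


def _belief_to_dict(b: ThresholdBelief) -> dict:
    return {"kind": b.kind.value, "lo": b.lo, "hi": b.hi}


def _belief_from_dict(d: Mapping[str, Any]) -> ThresholdBelief:
    return ThresholdBelief(BeliefKind(d["kind"]), float(d["lo"]), float(d["hi"]))


def _schedule_to_dict(s: TreatmentSchedule) -> dict:
    out: dict[str, Any] = {"name": s.name, "initial_belief": _belief_to_dict(s.initial_belief)}
    if s.revised_belief is not None:
        out["revision_round"] = s.revision_round
        out["revised_belief"] = _belief_to_dict(s.revised_belief)
    return out


def _schedule_from_dict(d: Mapping[str, Any]) -> TreatmentSchedule:
    return TreatmentSchedule(
        name=d["name"],
        initial_belief=_belief_from_dict(d["initial_belief"]),
        revision_round=d.get("revision_round"),
        revised_belief=_belief_from_dict(d["revised_belief"]) if "revised_belief" in d else None,
    )


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulate-and-analyse run."""

    game: GameConfig = field(default_factory=GameConfig)
    schedules: dict[str, TreatmentSchedule] = field(
        default_factory=lambda: dict(CANONICAL_SCHEDULES)
    )
    design: dict[str, int] = field(
        default_factory=lambda: {name: 10 for name in CANONICAL_SCHEDULES}
    )
    preset: str = "calibration"
    seed: int = 0
    out_dir: str = "results"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        game = dataclasses.asdict(self.game)
        game["round_choices"] = list(self.game.round_choices)
        game["communication_rounds"] = sorted(self.game.communication_rounds)
        return {
            "game": game,
            "schedules": [_schedule_to_dict(s) for s in self.schedules.values()],
            "design": dict(self.design),
            "preset": self.preset,
            "seed": self.seed,
            "out_dir": self.out_dir,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "RunConfig":
        game_d = dict(d.get("game", {}))
        if game_d:
            game_d["round_choices"] = tuple(float(c) for c in game_d.get("round_choices", (0, 2, 4)))
            game_d["communication_rounds"] = frozenset(
                int(r) for r in game_d.get("communication_rounds", (1, 6))
            )
            game = GameConfig(**game_d)
        else:
            game = GameConfig()
        schedules = {
            s["name"]: _schedule_from_dict(s) for s in d.get("schedules", [])
        } or dict(CANONICAL_SCHEDULES)
        return cls(
            game=game,
            schedules=schedules,
            design=dict(d.get("design", {name: 10 for name in schedules})),
            preset=d.get("preset", "calibration"),
            seed=int(d.get("seed", 0)),
            out_dir=d.get("out_dir", "results"),
            log_level=d.get("log_level", "INFO"),
        )

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix in {".yaml", ".yml"}:
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yaml", ".yml"} else json.loads(text)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(canon).hexdigest()[:16]


# ---------------------------------------------------------------------------
# dataset writing


def write_dataset(dataset: ExperimentDataset, out_dir: str | Path) -> None:
    """Write a dataset to ``out_dir`` as the three CSV tables plus metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contrib_rows, comm_rows, group_rows = [], [], []
    n_players = dataset.config.n_players
    for g in dataset.groups:
        cumulative = np.cumsum(g.contributions, axis=1)
        for player in range(n_players):
            for rnd in range(dataset.config.n_rounds):
                contrib_rows.append(
                    dict(
                        treatment=g.treatment,
                        group_id=g.group_id,
                        player_id=player,
                        round=rnd + 1,
                        contribution=_money(g.contributions[player, rnd]),
                        cumulative=_money(cumulative[player, rnd]),
                    )
                )
        for c in g.communications:
            comm_rows.append(
                dict(
                    treatment=g.treatment,
                    group_id=g.group_id,
                    player_id=c.player,
                    round=c.round,
                    proposal=_money(c.proposal),
                    pledge=_money(c.pledge),
                    collective_target=_money(c.collective_target),
                )
            )
        row = dict(
            treatment=g.treatment,
            group_id=g.group_id,
            realized_threshold=g.realized_threshold,
            total_contribution=_money(g.total_contribution),
            success=int(g.success),
        )
        for i, payoff in enumerate(g.payoffs, start=1):
            row[f"payoff_{i}"] = _money(payoff)
        group_rows.append(row)
    pd.DataFrame(contrib_rows).to_csv(out / "contributions.csv", index=False)
    pd.DataFrame(comm_rows).to_csv(out / "communications.csv", index=False)
    pd.DataFrame(group_rows).to_csv(out / "groups.csv", index=False)
    game = dataclasses.asdict(dataset.config)
    game["round_choices"] = list(dataset.config.round_choices)
    game["communication_rounds"] = sorted(dataset.config.communication_rounds)
    metadata = {
        "seed": dataset.seed,
        "game": game,
        "schedules": [_schedule_to_dict(s) for s in dataset.schedules.values()],
        "package_version": __version__,
        "written_at": datetime.now(timezone.utc).isoformat(),  # excluded from determinism
        **dataset.metadata,
    }
    (out / "metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# dataset reading


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise DatasetFormatError(str(path), None, None, "file not found")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise DatasetFormatError(str(path), None, None, f"unreadable CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DatasetFormatError(str(path), None, ",".join(missing), "missing required columns")
    return df


def read_dataset(
    in_dir: str | Path, config: Optional[GameConfig] = None
) -> ExperimentDataset:
    """Load a dataset written by :func:`write_dataset`, validating the schema.

    A missing communications file loads the dataset with communications
    absent (flagged in metadata); schema violations raise
    :class:`DatasetFormatError` naming file, line and column.
    """
    in_dir = Path(in_dir)
    meta_path = in_dir / "metadata.json"
    metadata: dict[str, Any] = {}
    schedules: dict[str, TreatmentSchedule] = {}
    seed = None
    if meta_path.exists():
        metadata = json.loads(meta_path.read_text())
        seed = metadata.get("seed")
        schedules = {s["name"]: _schedule_from_dict(s) for s in metadata.get("schedules", [])}
        if config is None and "game" in metadata:
            game_d = dict(metadata["game"])
            game_d["round_choices"] = tuple(float(c) for c in game_d["round_choices"])
            game_d["communication_rounds"] = frozenset(game_d["communication_rounds"])
            config = GameConfig(**game_d)
    config = config or GameConfig()

    contrib = _read_csv(
        in_dir / "contributions.csv",
        ["treatment", "group_id", "player_id", "round", "contribution"],
    )
    groups_df = _read_csv(
        in_dir / "groups.csv",
        ["treatment", "group_id", "realized_threshold", "total_contribution", "success"],
    )
    comm_path = in_dir / "communications.csv"
    comms = None
    if comm_path.exists():
        comms = _read_csv(
            comm_path,
            ["treatment", "group_id", "player_id", "round", "proposal", "pledge", "collective_target"],
        )
    else:
        metadata["communications_missing"] = True

    choices = set(config.round_choices)
    file = str(in_dir / "contributions.csv")
    for idx, value in contrib["contribution"].items():
        if float(value) not in choices:
            raise DatasetFormatError(
                file, int(idx) + 1, "contribution", f"value {value} not in {sorted(choices)}"
            )

    groups: list[GroupRecord] = []
    payoff_cols = [c for c in groups_df.columns if c.startswith("payoff_")]
    for row_idx, row in groups_df.iterrows():
        key = (row["treatment"], row["group_id"])
        sub = contrib[(contrib.treatment == key[0]) & (contrib.group_id == key[1])]
        matrix = np.zeros((config.n_players, config.n_rounds))
        if len(sub) != config.n_players * config.n_rounds:
            raise DatasetFormatError(
                file, None, None,
                f"group {key} has {len(sub)} player-round rows, "
                f"expected {config.n_players * config.n_rounds}",
            )
        for _, r in sub.iterrows():
            matrix[int(r.player_id), int(r["round"]) - 1] = float(r.contribution)
        communications: list[CommunicationRecord] = []
        if comms is not None:
            csub = comms[(comms.treatment == key[0]) & (comms.group_id == key[1])]
            for _, r in csub.iterrows():
                communications.append(
                    CommunicationRecord(
                        int(r.player_id), int(r["round"]), float(r.proposal),
                        float(r.pledge), float(r.collective_target),
                    )
                )
        g = GroupRecord(
            treatment=str(row["treatment"]),
            group_id=int(row["group_id"]),
            contributions=matrix,
            communications=communications,
            realized_threshold=int(row["realized_threshold"]),
            total_contribution=float(row["total_contribution"]),
            success=bool(int(row["success"])),
        )
        if abs(g.total_contribution - matrix.sum()) > 0.005:
            raise DatasetFormatError(
                str(in_dir / "groups.csv"), int(row_idx) + 1, "total_contribution",
                f"total {g.total_contribution} does not match contribution rows ({matrix.sum()})",
            )
        g.payoffs = (
            np.array([float(row[c]) for c in payoff_cols])
            if payoff_cols
            else resolve_payoffs(g, config)
        )
        groups.append(g)
    return ExperimentDataset(
        groups=groups, config=config, schedules=schedules, seed=seed, metadata=metadata
    )


# ---------------------------------------------------------------------------
# reports


def write_report(report, out_dir: str | Path) -> None:
    """Write an :class:`~thresholdgame.analysis.AnalysisReport` as CSVs + summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in report.tables().items():
        table.to_csv(out / f"{name}.csv", index=False, float_format="%.6f")
    report.tests_frame().to_csv(out / "tests.csv", index=False, float_format="%.6f")
    (out / "summary.txt").write_text(report.summary_text())
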