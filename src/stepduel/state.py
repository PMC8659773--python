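"""Game data model and daily update orchestration.

The game is a cumulative-step competition: the one human user accrues their
measured daily steps; rival NPCs are re-placed around the user's score each
day by the gap formulas in :mod:`stepduel.engine`.  One update per calendar
day: effort -> rank fluctuation -> rival scores -> regrouping -> rendering.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import engine
from .config import GameConfig
from .grouping import GroupAssignment, assign_groups, regroup


@dataclass(frozen=True)
class StepRecord:
    """One participant-day pedometer observation."""

    participant_id: str
    date: dt.date
    steps: int

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be non-negative")


def read_step_log(path_or_buffer) -> list[StepRecord]:
    """Read a ``participant_id,date,steps`` CSV into records.

    Dates are ISO-8601.  Duplicate (participant, date) pairs are rejected.
    """
    df = pd.read_csv(path_or_buffer, dtype={"participant_id": str})
    required = {"participant_id", "date", "steps"}
    if not required.issubset(df.columns):
        raise ValueError(f"step log must have columns {sorted(required)}")
    if df.duplicated(subset=["participant_id", "date"]).any():
        raise ValueError("duplicate (participant_id, date) rows in step log")
    return [
        StepRecord(str(r.participant_id), dt.date.fromisoformat(str(r.date)), int(r.steps))
        for r in df.itertuples()
    ]


def compute_baseline(history: Sequence[StepRecord | int], window: int) -> int:
    """Frozen pre-game step baseline: the mean of the last ``window`` days.

    ``history`` may be raw daily counts or :class:`StepRecord` objects (the
    most recent ``window`` of them, by date, are used).  Rounded to the
    nearest whole step.
    """
    if window < 1:
        raise ValueError("window must be at least one day")
    if history and isinstance(history[0], StepRecord):
        counts = [r.steps for r in sorted(history, key=lambda r: r.date)[-window:]]
    else:
        counts = list(history)[-window:]
    if not counts:
        raise ValueError("no pre-game step data inside the baseline window")
    return int(round(float(np.mean(counts))))


@dataclass
class PlayerState:
    player_id: str
    kind: str  # "human" | "npc"
    rank: int
    score: int


@dataclass
class GameState:
    """Per-day snapshot of the whole competition field."""

    config: GameConfig
    day_index: int
    players: list[PlayerState]
    user_baseline: int
    last_effort: int = 0
    prev_user_rank: Optional[int] = None
    rng: np.random.Generator = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def user(self) -> PlayerState:
        return next(p for p in self.players if p.kind == "human")

    def ranking(self) -> list[PlayerState]:
        return sorted(self.players, key=lambda p: p.rank)

    def check_invariants(self) -> None:
        ranks = sorted(p.rank for p in self.players)
        if ranks != list(range(1, self.config.field_size + 1)):
            raise AssertionError("ranks are not a permutation of 1..field_size")
        if sum(p.kind == "human" for p in self.players) != 1:
            raise AssertionError("exactly one human player required")

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "config": self.config.model_dump(),
            "day_index": self.day_index,
            "user_baseline": self.user_baseline,
            "last_effort": self.last_effort,
            "prev_user_rank": self.prev_user_rank,
            "players": [dataclasses.asdict(p) for p in self.players],
            "rng_state": self.rng.bit_generator.state,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, payload: dict) -> "GameState":
        rng = np.random.default_rng(0)
        rng.bit_generator.state = payload["rng_state"]
        return cls(
            config=GameConfig(**payload["config"]),
            day_index=payload["day_index"],
            players=[PlayerState(**p) for p in payload["players"]],
            user_baseline=payload["user_baseline"],
            last_effort=payload["last_effort"],
            prev_user_rank=payload.get("prev_user_rank"),
            rng=rng,
        )

    @classmethod
    def from_json(cls, path) -> "GameState":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


USER_ID = "user"


def init_game(config: GameConfig, user_baseline: int = 0) -> GameState:
    """Day-0 state: user at the configured rank/score, NPCs placed around.

    NPC scores come from the gap formulas evaluated at zero effort, using the
    game's seeded random stream, so the day-0 leaderboard already shows the
    configured basic differences.
    """
    rng = np.random.default_rng(config.rng_seed)
    players = [PlayerState(USER_ID, "human", config.initial_rank, config.initial_score)]
    npc_ranks = [r for r in range(1, config.field_size + 1) if r != config.initial_rank]
    players.extend(PlayerState(f"npc{r:03d}", "npc", r, 0) for r in npc_ranks)
    state = GameState(
        config=config,
        day_index=0,
        players=players,
        user_baseline=user_baseline,
        last_effort=0,
        prev_user_rank=config.initial_rank,
        rng=rng,
    )
    engine.set_rival_scores(state, effort=0, config=config, rng=rng)
    state.check_invariants()
    return state


def daily_update(state: GameState, todays_steps: int, render: bool = True):
    """Advance the game one day on today's measured steps.

    Returns ``(new_state, CompetitionInfo, group_events)``; the input state
    is not modified.  ``render=False`` skips building the presentation
    payload (the returned info is ``None``), for bulk simulation.
    """
    from .presentation import render_info  # deferred: avoids import cycle

    if todays_steps < 0:
        raise ValueError("steps must be non-negative")
    config = state.config
    prev_groups = assign_groups(state.ranking(), config.group_size)
    prev_rank = state.user.rank

    new = GameState(
        config=config,
        day_index=state.day_index + 1,
        players=[dataclasses.replace(p) for p in state.players],
        user_baseline=state.user_baseline,
        prev_user_rank=prev_rank,
        rng=state.rng,
    )
    effort = engine.compute_effort(todays_steps, state.user_baseline)
    k = engine.rank_delta(effort, config.threshold_rank_change)

    ranks = {p.player_id: p.rank for p in new.players}
    ranks = engine.apply_rank_change(ranks, USER_ID, k, config.field_size)
    for p in new.players:
        p.rank = ranks[p.player_id]

    new.user.score = state.user.score + int(todays_steps)
    new.last_effort = effort
    engine.set_rival_scores(new, effort, config, new.rng)
    new.check_invariants()

    groups, events = regroup(prev_groups, new.ranking())
    info = render_info(new, groups, config) if render else None
    return new, info, events


def replay_log(
    config: GameConfig,
    records: Iterable[StepRecord],
    baseline_history: Sequence[StepRecord | int],
    render: bool = True,
):
    """Replay a user's step log through the game, day by day.

    Days missing from the log between the first and last recorded date are
    imputed at the baseline (zero effort) with a warning.  Yields
    ``(date, state, info, events)`` tuples after each update.
    """
    baseline = compute_baseline(baseline_history, config.baseline_window)
    state = init_game(config, user_baseline=baseline)
    by_date = {r.date: r.steps for r in records}
    if not by_date:
        return
    day = min(by_date)
    last = max(by_date)
    while day <= last:
        if day in by_date:
            steps = by_date[day]
        else:
            warnings.warn(f"no step record for {day}; imputing baseline ({baseline})")
            steps = baseline
        state, info, events = daily_update(state, steps, render=render)
        yield day, state, info, events
        day += dt.timedelta(days=1)
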