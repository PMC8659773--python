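"""Rendering of the daily competition information.

The daily message has two parts: a *comment* part summarising the user's
current rank, the rank fluctuation since the previous day and the score gaps
to the adjacent rivals, and a *ranking* part listing rank, display name and
score for every player of each visible view.  Which views a player sees is
fixed by their study condition: a 100-player field under Main 1 additionally
shows the contiguous 10-player group the user currently belongs to, while
under Main 2 only the full field is shown.

NPC display names are fake nicknames generated deterministically from the
game seed, so a replay produces the identical leaderboard text.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

from .grouping import GroupAssignment, group_of

if TYPE_CHECKING:  # pragma: no cover
    from .config import GameConfig
    from .state import GameState

_ADJECTIVES = (
    "Swift", "Brisk", "Steady", "Sunny", "Quiet", "Lucky", "Mighty", "Nimble",
    "Breezy", "Dashing", "Peppy", "Spry", "Zippy", "Chipper", "Rapid", "Merry",
)
_ANIMALS = (
    "Heron", "Otter", "Ibex", "Swallow", "Badger", "Crane", "Fox", "Hare",
    "Plover", "Marten", "Finch", "Stoat", "Wren", "Lynx", "Tern", "Vole",
)


def npc_nicknames(player_ids: Sequence[str], seed: int) -> dict[str, str]:
    """Deterministic fake nicknames, one per NPC id, collision-free."""
    rng = np.random.default_rng(seed)
    names: dict[str, str] = {}
    used = set()
    for pid in sorted(player_ids):
        while True:
            name = f"{rng.choice(_ADJECTIVES)}{rng.choice(_ANIMALS)}{rng.integers(10, 100)}"
            if name not in used:
                used.add(name)
                names[pid] = name
                break
    return names


@dataclass(frozen=True)
class RankingRow:
    rank: int
    display_name: str
    score: int
    is_user: bool = False


@dataclass(frozen=True)
class CompetitionInfo:
    """One day's rendered competition information."""

    day_index: int
    comment_lines: tuple[str, ...]
    views: tuple[str, ...]
    ranking_rows: dict[str, tuple[RankingRow, ...]]  # keyed by view name
    user_rank: int
    rank_change: int                 # + means the rank improved
    gap_above: Optional[int]         # None when the user leads the view
    gap_below: Optional[int]         # None when the user trails the view

    def to_dict(self) -> dict:
        return {
            "day_index": self.day_index,
            "comment_lines": list(self.comment_lines),
            "views": list(self.views),
            "ranking_rows": {
                view: [dataclasses.asdict(r) for r in rows]
                for view, rows in self.ranking_rows.items()
            },
            "user_rank": self.user_rank,
            "rank_change": self.rank_change,
            "gap_above": self.gap_above,
            "gap_below": self.gap_below,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


DEFAULT_TEMPLATES = {
    "rank": "You are in {rank} place today.",
    "up": "Your rank went up by {delta} from yesterday!",
    "down": "Your rank went down by {delta} from yesterday.",
    "same": "No change in rank since yesterday.",
    "gap_above": "The rival just above you leads by {gap} steps.",
    "gap_below": "You lead the rival just below you by {gap} steps.",
    "leader": "You lead the board!",
    "trailer": "Everyone else is ahead - tomorrow is a fresh chance.",
}


def _ordinal(n: int) -> str:
    if 10 <= n % 100 <= 20:
        suffix = "th"
    else:
        suffix = {1: "st", 2: "nd", 3: "rd"}.get(n % 10, "th")
    return f"{n}{suffix}"


def render_info(
    state: "GameState",
    groups: Sequence[GroupAssignment],
    config: "GameConfig",
    templates: Optional[dict[str, str]] = None,
) -> CompetitionInfo:
    """Build the day's comment + ranking payload for the state's condition.

    The comment's gap figures are taken from the *primary* visible view: the
    small group when the condition shows one (attention is being steered to
    the close field), otherwise the overall board.
    """
    tpl = {**DEFAULT_TEMPLATES, **(templates or {})}
    views = config.visible_views()
    user = state.user
    names = npc_nicknames(
        [p.player_id for p in state.players if p.kind == "npc"], config.rng_seed
    )
    names[user.player_id] = "You"

    ranking = state.ranking()
    rows_by_view: dict[str, tuple[RankingRow, ...]] = {}
    for view in views:
        if view == "small_group":
            members = group_of(groups, user.player_id).member_ids
            players = [p for p in ranking if p.player_id in members]
        else:
            players = ranking
        rows_by_view[view] = tuple(
            RankingRow(p.rank, names[p.player_id], p.score, p.kind == "human")
            for p in players
        )

    primary = "small_group" if "small_group" in views else "overall"
    rows = rows_by_view[primary]
    idx = next(i for i, r in enumerate(rows) if r.is_user)
    gap_above = rows[idx - 1].score - rows[idx].score if idx > 0 else None
    gap_below = rows[idx].score - rows[idx + 1].score if idx < len(rows) - 1 else None

    change = (state.prev_user_rank or user.rank) - user.rank
    comment = [tpl["rank"].format(rank=_ordinal(user.rank))]
    if change > 0:
        comment.append(tpl["up"].format(delta=change))
    elif change < 0:
        comment.append(tpl["down"].format(delta=-change))
    else:
        comment.append(tpl["same"])
    comment.append(
        tpl["gap_above"].format(gap=gap_above) if gap_above is not None else tpl["leader"]
    )
    comment.append(
        tpl["gap_below"].format(gap=gap_below) if gap_below is not None else tpl["trailer"]
    )

    return CompetitionInfo(
        day_index=state.day_index,
        comment_lines=tuple(comment),
        views=views,
        ranking_rows=rows_by_view,
        user_rank=user.rank,
        rank_change=change,
        gap_above=gap_above,
        gap_below=gap_below,
    )


def export_notification_payload(info: CompetitionInfo, max_chars: int = 1000) -> str:
    """Flatten the day's info into one plain-text notification digest.

    Deterministic given the info; at most ``max_chars`` characters (the
    ranking table is truncated around the user's position if necessary).
    """
    lines = [f"Day {info.day_index} step competition update", *info.comment_lines, ""]
    view = info.views[0]
    rows = info.ranking_rows[view]
    # keep a window of rows centred on the user so big fields still fit
    idx = next(i for i, r in enumerate(rows) if r.is_user)
    lo, hi = max(0, idx - 4), min(len(rows), idx + 5)
    if lo > 0:
        lines.append("...")
    for r in rows[lo:hi]:
        marker = ">>" if r.is_user else "  "
        lines.append(f"{marker} {r.rank:>3}. {r.display_name:<16} {r.score:>9,}")
    if hi < len(rows):
        lines.append("...")
    text = "\n".join(lines)
    if len(text) > max_chars:
        text = text[: max_chars - 3] + "..."
    return text


def ranking_markdown(info: CompetitionInfo, view: str = "overall") -> str:
    """Optional Markdown table export of one view's ranking."""
    rows = info.ranking_rows[view]
    out = ["| Rank | Player | Score |", "| ---: | :--- | ---: |"]
    out += [f"| {r.rank} | {r.display_name} | {r.score} |" for r in rows]
    return "\n".join(out)
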