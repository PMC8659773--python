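"""Contiguous-rank small groups over a large competition field.

A field of 100 players is partitioned into blocks of 10 by overall rank:
group 1 holds ranks 1-10, group 5 ranks 41-50, and so on (the last group may
be smaller if the field size is not divisible).  The partition is recomputed
at every daily update, so a player whose overall rank crosses a multiple of
the group size is promoted or demoted across the group boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class GroupAssignment:
    group_index: int                 # 1 = top group
    rank_range: tuple[int, int]      # inclusive overall ranks covered
    member_ids: tuple[str, ...]      # ordered by overall rank


@dataclass(frozen=True)
class GroupEvent:
    """A player crossing a group boundary between consecutive updates."""

    player_id: str
    kind: str        # "promotion" | "demotion"
    from_group: int
    to_group: int


def group_index_for_rank(rank: int, group_size: int) -> int:
    return (rank - 1) // group_size + 1


def assign_groups(ranking: Sequence, group_size: int) -> list[GroupAssignment]:
    """Partition players (ordered by rank) into contiguous-rank groups."""
    if group_size < 2:
        raise ValueError("group_size must be at least 2")
    ids = [getattr(p, "player_id", p) for p in ranking]
    groups = []
    for g, start in enumerate(range(0, len(ids), group_size), start=1):
        members = ids[start : start + group_size]
        groups.append(
            GroupAssignment(
                group_index=g,
                rank_range=(start + 1, start + len(members)),
                member_ids=tuple(members),
            )
        )
    return groups


def regroup(
    previous: Sequence[GroupAssignment], new_ranking: Sequence
) -> tuple[list[GroupAssignment], list[GroupEvent]]:
    """Recompute the partition for a new ranking and report boundary crossings.

    Equivalent to :func:`assign_groups` on the new ranking; additionally
    emits a promotion/demotion event for every player whose group index
    changed since ``previous``.
    """
    if not previous:
        raise ValueError("previous assignment must not be empty")
    group_size = len(previous[0].member_ids)
    groups = assign_groups(new_ranking, group_size)
    old_index = {pid: g.group_index for g in previous for pid in g.member_ids}
    events = []
    for g in groups:
        for pid in g.member_ids:
            before = old_index.get(pid)
            if before is not None and before != g.group_index:
                kind = "promotion" if g.group_index < before else "demotion"
                events.append(GroupEvent(pid, kind, before, g.group_index))
    return groups, events


def group_of(groups: Sequence[GroupAssignment], player_id: str) -> GroupAssignment:
    for g in groups:
        if player_id in g.member_ids:
            return g
    raise KeyError(player_id)
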