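"""Game configuration and the four experimental condition presets.

A game is parameterised by a :class:`GameConfig`.  The two *Main*
parameterisations differ only in the rank-fluctuation threshold and the
basic-difference coefficient (1000 steps vs. 8000 steps); the two *Sub*
parameterisations differ in field size and the matching initial rank/score.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

ConditionLabel = Literal["Main1-Sub1", "Main1-Sub2", "Main2-Sub1", "Main2-Sub2"]

#: Which leaderboard views each condition is shown.  Sub 1 plays in a
#: 10-player field whose single "overall" view already is a small field;
#: Sub 2 plays among 100 players and, under Main 1 only, additionally sees
#: the contiguous 10-player group it currently belongs to.
VIEW_MATRIX: dict[str, tuple[str, ...]] = {
    "Main1-Sub1": ("overall",),
    "Main1-Sub2": ("small_group", "overall"),
    "Main2-Sub1": ("overall",),
    "Main2-Sub2": ("overall",),
}


class GameConfig(BaseModel):
    """All tunable parameters of one competition game.

    Parameters
    ----------
    field_size
        Number of players including the (single) human user.
    threshold_rank_change
        Steps of daily effort per unit of rank fluctuation
        (ThresholdRankChange; 1000 in Main 1, 8000 in Main 2).
    bd_coefficient
        Basic-difference coefficient: the score gap to the adjacent rival,
        growing linearly with rank distance (BD_n = coefficient x |n|).
    effort_factor_m
        Fraction of BD_n that sub-threshold effort leaks into the gaps.
    random_factor_l_max
        Upper bound of the uniform random multiplier l in +-(BD_n x l).
    group_size
        Players per contiguous-rank small group.
    baseline_window
        Days of pre-game history averaged into the frozen step baseline.
    initial_rank, initial_score
        The user's placement on day 0.
    rng_seed
        Seed for the game's private random stream (random factor, names).
    condition_label
        Optional study-condition tag; drives view visibility.
    """

    field_size: int = Field(ge=2)
    threshold_rank_change: int = Field(gt=0)
    bd_coefficient: int = Field(gt=0)
    effort_factor_m: float = Field(default=0.3, gt=0.0, lt=1.0)
    random_factor_l_max: float = Field(default=0.2, ge=0.0, lt=1.0)
    group_size: int = Field(default=10, ge=2)
    baseline_window: int = Field(default=7, ge=1)
    initial_rank: int = Field(ge=1)
    initial_score: int = Field(ge=0)
    rng_seed: int = 0
    condition_label: Optional[ConditionLabel] = None

    @model_validator(mode="after")
    def _rank_in_field(self) -> "GameConfig":
        if not 1 <= self.initial_rank <= self.field_size:
            raise ValueError(
                f"initial_rank {self.initial_rank} outside 1..{self.field_size}"
            )
        return self

    def visible_views(self) -> tuple[str, ...]:
        if self.condition_label is None:
            return ("overall",)
        return VIEW_MATRIX[self.condition_label]


_MAIN_PARAMS = {
    "Main1": dict(threshold_rank_change=1000, bd_coefficient=1000),
    "Main2": dict(threshold_rank_change=8000, bd_coefficient=8000),
}
_SUB_PARAMS = {
    "Sub1": dict(field_size=10, initial_rank=6, initial_score=35_000),
    "Sub2": dict(field_size=100, initial_rank=66, initial_score=300_000),
}


def preset_config(condition_label: str, rng_seed: int = 0, **overrides) -> GameConfig:
    """Build the :class:`GameConfig` for one of the four study conditions.

    ``condition_label`` is e.g. ``"Main1-Sub1"``.  Keyword overrides replace
    individual preset fields (useful for e.g. disabling the random factor).
    """
    try:
        main, sub = condition_label.split("-")
        params = {**_MAIN_PARAMS[main], **_SUB_PARAMS[sub]}
    except (ValueError, KeyError):
        raise ValueError(f"unknown condition label {condition_label!r}") from None
    params.update(condition_label=condition_label, rng_seed=rng_seed)
    params.update(overrides)
    return GameConfig(**params)
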