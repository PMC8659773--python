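"""NPC rival mechanics: effort, rank fluctuation and score-gap placement.

Rivals are not autonomous agents.  Every day their cumulative scores are
re-placed around the user's score so that the gap to the rival ``n`` ranks
away equals the sum of three factors:

* **basic difference** — ``BD_n = bd_coefficient * |n|``, a linear spread;
* **effort factor** — ``BD_n * m * frac(|effort| / threshold)`` with sign
  ``-sign(effort) * sign(n)``, so sub-threshold effort visibly shrinks the
  gaps to rivals above (and grows those below) even when the rank does not
  move;
* **random factor** — ``+-(BD_n * l)`` with ``l`` drawn uniformly from
  ``[0, l_max]``, small plausibility noise.

Sign convention: offsets ``n > 0`` denote rivals ranked *above* the user
(better rank number, higher score); ``n < 0`` below.

RNG draw order is fixed for reproducibility: per day, one vector of gap
multipliers ``l`` then one vector of signs, each over rivals in ascending
rank order.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .config import GameConfig
    from .state import GameState


def compute_effort(todays_steps: int, baseline: int) -> int:
    """EffortAmount: today's step count minus the frozen baseline."""
    if todays_steps < 0 or baseline < 0:
        raise ValueError("step counts must be non-negative")
    return int(todays_steps) - int(baseline)


def rank_delta(effort: int, threshold: int) -> int:
    """Signed number of rank units earned by today's effort.

    The integer part of ``effort / threshold``, truncated toward zero, so
    -1500 steps of effort against a 1000-step threshold costs one rank, not
    two.  Positive ``k`` improves the rank (the rank *number* decreases).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return int(effort / threshold)  # int() truncates toward zero


def apply_rank_change(ranks: dict[str, int], user_id: str, k: int, field_size: int) -> dict[str, int]:
    """Move the user ``k`` rank units, shifting displaced rivals by one.

    Each unit of rank-up swaps the user with the rival immediately above;
    each unit of rank-down with the rival immediately below.  Movement is
    clamped to ``[1, field_size]``.  Top-rank rule: a user already at rank 1
    keeps it only while effort clears the rank-up threshold (``k >= 1``);
    otherwise the rank drops so that a rival able to provide rank
    fluctuations is above again.
    """
    old = ranks[user_id]
    new = min(field_size, max(1, old - k))
    if old == 1 and k <= 0:
        # no rival above can yield a rank-up event; demote at least one step
        new = min(field_size, max(2, old - k))
    out = {}
    for pid, r in ranks.items():
        if pid == user_id:
            out[pid] = new
        elif new <= r < old:       # user moved up past these rivals
            out[pid] = r + 1
        elif old < r <= new:       # user moved down past these rivals
            out[pid] = r - 1
        else:
            out[pid] = r
    return out


def basic_difference(n: int, bd_coefficient: int) -> int:
    """BD_|n|: the baseline gap magnitude to the rival ``n`` ranks away."""
    if n == 0:
        raise ValueError("rival offset must be nonzero")
    return int(bd_coefficient) * abs(int(n))


def _effort_fraction(effort: int, threshold: int) -> float:
    frac = abs(effort) / threshold
    return frac - math.floor(frac)


def effort_factor(effort: int, threshold: int, bd_n: int, m: float, n: int) -> int:
    """Signed gap adjustment from sub-threshold effort, for rival offset ``n``.

    Magnitude ``bd_n * m * frac(|effort|/threshold)``; the sign
    ``-sign(effort)*sign(n)`` is applied to the gap *magnitude*, so positive
    effort pulls the user closer to rivals above and away from rivals below.
    """
    if n == 0:
        raise ValueError("rival offset must be nonzero")
    if not 0.0 < m < 1.0:
        raise ValueError("m must lie in (0, 1)")
    magnitude = bd_n * m * _effort_fraction(effort, threshold)
    sign = -np.sign(effort) * np.sign(n)
    return int(round(sign * magnitude))


def random_factor(bd_n: int, l_max: float, rng: np.random.Generator) -> int:
    """Bounded noise ``+-(bd_n * l)``, ``l ~ U[0, l_max]``, uniform sign."""
    if not 0.0 <= l_max < 1.0:
        raise ValueError("l_max must lie in [0, 1)")
    l = rng.uniform(0.0, l_max)
    sign = 1 if rng.integers(0, 2) == 1 else -1
    return int(round(sign * l * bd_n))


def gap_magnitudes(
    offsets: np.ndarray,
    effort: int,
    config: "GameConfig",
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised total gap magnitude for each rival offset.

    ``offsets`` are the signed rank distances (ascending-rank order expected
    by the documented draw order).  Gaps are floored at one step and, per
    side, forced strictly increasing with |offset| so scores can never tie
    or invert relative to ranks, even under extreme factor settings.
    """
    offsets = np.asarray(offsets)
    bd = config.bd_coefficient * np.abs(offsets)
    frac = _effort_fraction(effort, config.threshold_rank_change)
    eff = -np.sign(effort) * np.sign(offsets) * bd * config.effort_factor_m * frac
    l = rng.uniform(0.0, config.random_factor_l_max, size=offsets.size)
    signs = rng.integers(0, 2, size=offsets.size) * 2 - 1
    rand = signs * l * bd
    gaps = np.maximum(1, np.rint(bd + np.rint(eff) + np.rint(rand))).astype(np.int64)

    # enforce strict monotonicity in |offset| independently above and below
    for side in (offsets > 0, offsets < 0):
        idx = np.argsort(np.abs(offsets[side]))
        g = gaps[side][idx]
        for i in range(1, g.size):
            if g[i] <= g[i - 1]:
                g[i] = g[i - 1] + 1
        out = gaps[side]
        out[idx] = g
        gaps[side] = out
    return gaps


def set_rival_scores(state: "GameState", effort: int, config: "GameConfig", rng: np.random.Generator) -> None:
    """Re-place every NPC's cumulative score around the user's (in place).

    Must run after the day's ranks are settled.  The rival at offset ``n``
    ends at ``user_score + g_n`` if above and ``user_score - g_n`` if below,
    where ``g_n`` sums the three gap factors.
    """
    user_rank = state.user.rank
    user_score = state.user.score
    rivals = sorted(
        (p for p in state.players if p.player_id != state.user.player_id),
        key=lambda p: p.rank,
    )
    offsets = np.array([user_rank - p.rank for p in rivals])
    gaps = gap_magnitudes(offsets, effort, config, rng)
    for rival, n, g in zip(rivals, offsets, gaps):
        rival.score = user_score + int(g) if n > 0 else user_score - int(g)
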