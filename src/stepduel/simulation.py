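"""Synthetic participants and the four-period study harness.

The harness emulates the study design end to end: a cohort of low-motivation
walkers with stable personal step baselines, balanced assignment to the four
condition cells (Main 1/2 x Sub 1/2), a two-week pre-intervention period
that fixes each participant's baseline, a two-week intervention in which
each participant plays the competition game daily, and a two-week
post-intervention tail.

The participant response model is deliberately simple plumbing: daily steps
are Normal noise around the personal baseline, plus a linear response to the
previous day's feedback during the intervention only.  The feedback signal
is +1/0/-1 for a rank that rose/held/fell, plus a +1 closeness bonus when
the gap to the rival above is smaller than the basic-difference coefficient.
Nothing in the competition engine depends on this model; it exists so every
engine path is exercised, and the null (``responsiveness = 0``) is the
default.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import GameConfig, preset_config
from .state import compute_baseline, daily_update, init_game

CELLS = ("Main1-Sub1", "Main1-Sub2", "Main2-Sub1", "Main2-Sub2")
PERIODS = ("pre", "intervention", "post")


@dataclass
class ParticipantProfile:
    """One synthetic participant.

    ``responsiveness`` is the steps/day added per unit of positive feedback
    (a synthetic construct; 0 disables the behavioural coupling entirely).
    ``motivation_stage`` is the transtheoretical-model stage 1-5.
    """

    participant_id: str
    baseline_mu: float        # steps/day, personal long-run mean
    baseline_sd: float        # steps/day, day-to-day noise
    motivation_stage: int
    responsiveness: float = 0.0
    condition: Optional[str] = None

    def __post_init__(self):
        if not 1 <= self.motivation_stage <= 5:
            raise ValueError("motivation_stage must be 1..5")
        if self.baseline_mu <= 0:
            raise ValueError("baseline_mu must be positive")


@dataclass(frozen=True)
class PeriodSummary:
    period: str
    condition: str
    n: int
    mean_steps: float
    sem: float


def _stage_probs(stage_mean: float) -> np.ndarray:
    """Geometric-family categorical over stages 1..5 hitting a target mean."""
    stages = np.arange(1, 6)
    if not 1.0 < stage_mean < 5.0:
        raise ValueError("stage_mean must lie strictly between 1 and 5")

    def mean_for(logq):
        w = np.exp(logq * (stages - 1))
        return float((stages * w).sum() / w.sum())

    lo, hi = -20.0, 20.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if mean_for(mid) < stage_mean:
            lo = mid
        else:
            hi = mid
    w = np.exp(lo * (stages - 1))
    return w / w.sum()


def generate_cohort(
    n: int,
    seed: int,
    stage_mean: float = 2.2,
    baseline_median: float = 8000.0,
    baseline_sigma: float = 0.25,
    daily_sd: float = 1500.0,
    responsiveness: float = 0.0,
) -> list[ParticipantProfile]:
    """Draw ``n`` synthetic participants, reproducibly under ``seed``.

    Personal baselines are lognormal with the given median (typical adult
    pedometer averages cluster around 8000 steps/day) and log-scale spread
    ``baseline_sigma``; motivation stages are categorical with the requested
    cohort mean (2.2 matches a low-motivation contemplation-heavy cohort).
    """
    if n < 2:
        raise ValueError("a cohort needs at least two participants")
    rng = np.random.default_rng(seed)
    mus = baseline_median * np.exp(rng.normal(0.0, baseline_sigma, size=n))
    stages = rng.choice(np.arange(1, 6), size=n, p=_stage_probs(stage_mean))
    return [
        ParticipantProfile(
            participant_id=f"p{i:03d}",
            baseline_mu=float(mus[i]),
            baseline_sd=daily_sd,
            motivation_stage=int(stages[i]),
            responsiveness=responsiveness,
        )
        for i in range(n)
    ]


def balance_assign(
    cohort: Sequence[ParticipantProfile],
    cells: Sequence[str] = CELLS,
    seed: int = 0,
    baseline_tolerance: float = 500.0,
    stage_tolerance: float = 0.5,
    max_retries: int = 500,
) -> list[ParticipantProfile]:
    """Randomise participants into cells with matched baseline and motivation.

    Randomised local search: participants are dealt into equal-size cells at
    random, then pairs in different cells are repeatedly swapped whenever the
    swap reduces the tolerance-scaled spread of the cell means (baseline and
    motivation stage jointly).  Restarts until both tolerances hold, so the
    result is still randomised over the many assignments that satisfy them.
    Cell sizes always differ by at most one.
    """
    if len(cohort) < len(cells):
        raise ValueError("cohort smaller than the number of cells")
    rng = np.random.default_rng(seed)
    n, k = len(cohort), len(cells)
    mu = np.array([p.baseline_mu for p in cohort])
    stage = np.array([p.motivation_stage for p in cohort], dtype=float)
    eps = 1e-9

    def cost(mu_sum, stage_sum, counts) -> float:
        worst = 0.0
        for sums, tol in ((mu_sum, baseline_tolerance), (stage_sum, stage_tolerance)):
            means = sums / counts
            worst = max(worst, float(means.max() - means.min()) / max(tol, eps))
        return worst

    for _ in range(max_retries):
        cell_of = np.asarray(rng.permutation(np.arange(n) % k))
        counts = np.bincount(cell_of, minlength=k).astype(float)
        mu_sum = np.bincount(cell_of, weights=mu, minlength=k)
        stage_sum = np.bincount(cell_of, weights=stage, minlength=k)
        current = cost(mu_sum, stage_sum, counts)
        for _ in range(40 * n):
            if current < 1.0:
                break
            i, j = rng.integers(0, n, size=2)
            ci, cj = cell_of[i], cell_of[j]
            if ci == cj:
                continue
            for sums, values in ((mu_sum, mu), (stage_sum, stage)):
                sums[ci] += values[j] - values[i]
                sums[cj] += values[i] - values[j]
            proposed = cost(mu_sum, stage_sum, counts)
            if proposed < current:
                current = proposed
                cell_of[i], cell_of[j] = cj, ci
            else:
                for sums, values in ((mu_sum, mu), (stage_sum, stage)):
                    sums[ci] -= values[j] - values[i]
                    sums[cj] -= values[i] - values[j]
        if current < 1.0:
            return [
                dataclasses.replace(p, condition=cells[cell_of[i]])
                for i, p in enumerate(cohort)
            ]
    raise RuntimeError(
        f"no assignment met tolerances ({baseline_tolerance} steps, "
        f"{stage_tolerance} stages) in {max_retries} tries"
    )


#: Score gap (steps) below which the rival above counts as "close": the
#: slight score difference the close-rival mechanism aims at.  Fixed in
#: absolute steps so that an 8000-step field never reads as close.
CLOSENESS_THRESHOLD = 1000


def _feedback_signal(state, config: GameConfig, closeness: int = CLOSENESS_THRESHOLD) -> int:
    """Previous-day feedback driving the next day's effort response.

    +1/0/-1 for a rank that rose/held/fell, plus a +1 closeness bonus when
    a rival sits within ``closeness`` steps above the user.
    """
    user = state.user
    change = (state.prev_user_rank or user.rank) - user.rank
    signal = int(np.sign(change))
    if user.rank > 1:
        above = next(p for p in state.players if p.rank == user.rank - 1)
        if above.score - user.score < closeness:
            signal += 1
    return signal


def simulate_participant(
    profile: ParticipantProfile,
    config: GameConfig,
    rng: np.random.Generator,
    period_days: int = 14,
    start_date: dt.date = dt.date(2021, 1, 4),
) -> pd.DataFrame:
    """Simulate one participant's three periods; returns their daily log.

    Columns: participant_id, condition, date, day, period, steps,
    feedback_prev (the lagged signal that shifted that day's mean; 0 outside
    the intervention and on its first day).
    """

    def draw(mean: float) -> int:
        return int(round(max(0.0, rng.normal(mean, profile.baseline_sd))))

    rows = []
    day = 0
    pre = []
    for _ in range(period_days):
        steps = draw(profile.baseline_mu)
        pre.append(steps)
        rows.append((day, "pre", steps, 0))
        day += 1

    baseline = compute_baseline(pre, config.baseline_window)
    state = init_game(config, user_baseline=baseline)
    signal = 0
    for _ in range(period_days):
        steps = draw(profile.baseline_mu + profile.responsiveness * signal)
        rows.append((day, "intervention", steps, signal))
        state, _, _ = daily_update(state, steps, render=False)
        signal = _feedback_signal(state, config)
        day += 1

    for _ in range(period_days):
        rows.append((day, "post", draw(profile.baseline_mu), 0))
        day += 1

    df = pd.DataFrame(rows, columns=["day", "period", "steps", "feedback_prev"])
    df.insert(0, "condition", profile.condition or config.condition_label)
    df.insert(0, "participant_id", profile.participant_id)
    df["date"] = [start_date + dt.timedelta(days=int(d)) for d in df["day"]]
    return df


def simulate_study(
    cohort: Sequence[ParticipantProfile],
    seed: int,
    period_days: int = 14,
    configs: Optional[dict[str, GameConfig]] = None,
) -> tuple[pd.DataFrame, list[PeriodSummary]]:
    """Run the full study over an assigned cohort; returns (logs, summaries).

    Every participant must carry a condition assignment.  Each participant
    gets an independent substream of ``seed`` for both their step noise and
    their game's random factor.
    """
    if any(p.condition is None for p in cohort):
        raise ValueError("cohort must be condition-assigned (see balance_assign)")
    master = np.random.default_rng(seed)
    game_seeds = master.integers(0, 2**31 - 1, size=len(cohort))
    logs = []
    for p, gseed in zip(cohort, game_seeds):
        config = (
            configs[p.condition]
            if configs is not None
            else preset_config(p.condition, rng_seed=int(gseed))
        )
        if config.rng_seed != gseed:
            config = config.model_copy(update={"rng_seed": int(gseed)})
        prng = np.random.default_rng(int(gseed) + 1)
        logs.append(simulate_participant(p, config, prng, period_days=period_days))
    log_df = pd.concat(logs, ignore_index=True)
    return log_df, period_summaries(log_df)


def period_summaries(logs: pd.DataFrame) -> list[PeriodSummary]:
    """Per-condition, per-period mean daily steps with standard errors."""
    out = []
    per_participant = (
        logs.groupby(["condition", "period", "participant_id"], observed=True)["steps"]
        .mean()
        .reset_index()
    )
    for (cond, period), grp in per_participant.groupby(["condition", "period"], observed=True):
        vals = grp["steps"].to_numpy()
        sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        out.append(PeriodSummary(period, cond, len(vals), float(vals.mean()), sem))
    order = {p: i for i, p in enumerate(PERIODS)}
    out.sort(key=lambda s: (s.condition, order.get(s.period, 99)))
    return out


def summarize(
    logs: pd.DataFrame, factor: str = "main"
) -> tuple[list[PeriodSummary], pd.DataFrame, pd.DataFrame]:
    """Period summaries plus a two-way mixed ANOVA and Bonferroni pairwise tests.

    ``factor`` chooses the between-subject factor: ``"main"`` collapses the
    four cells to Main 1 vs Main 2 (the study's primary contrast) while
    ``"condition"`` keeps all four.  Period is the repeated (within) factor.
    The ANOVA itself is standard reporting and is delegated to pingouin.
    """
    import pingouin as pg

    required = {"participant_id", "condition", "period", "steps"}
    if not required.issubset(logs.columns):
        raise ValueError(f"logs must have columns {sorted(required)}")
    if logs["period"].nunique() < 2 or logs["condition"].nunique() < 1:
        raise ValueError("logs must cover at least two periods and one condition")

    summaries = period_summaries(logs)
    data = (
        logs.groupby(["participant_id", "condition", "period"], observed=True)["steps"]
        .mean()
        .reset_index()
    )
    expected = logs["condition"].nunique() * logs["period"].nunique()
    if data.groupby(["condition", "period"], observed=True).size().shape[0] != expected:
        raise ValueError("every condition cell must be observed in every period")
    data["main"] = data["condition"].str.split("-").str[0]
    between = factor if factor in ("main", "condition") else "main"

    if np.isclose(data["steps"].var(), 0.0):
        # degenerate no-variance input: report zero F rather than 0/0
        aov = pd.DataFrame(
            {
                "Source": [between, "period", "Interaction"],
                "F": [0.0, 0.0, 0.0],
                "p_unc": [1.0, 1.0, 1.0],
            }
        )
        posthoc = pd.DataFrame()
        return summaries, aov, posthoc

    aov = pg.mixed_anova(
        data=data, dv="steps", within="period", between=between,
        subject="participant_id",
    )
    posthoc = pg.pairwise_tests(
        data=data, dv="steps", within="period", between=between,
        subject="participant_id", padjust="bonf",
    )
    return summaries, aov, posthoc


def estimate_responsiveness(
    logs: pd.DataFrame, cohort: Sequence[ParticipantProfile]
) -> tuple[float, float]:
    """Recover the feedback-response slope from simulated logs.

    Ordinary least squares of intervention-period daily steps, centred on
    each participant's known long-run mean, on the lagged feedback signal.
    Returns ``(estimate, standard error)``.  Used to validate that the
    feedback loop injected into the generator is recoverable at the stated
    strength.
    """
    import statsmodels.api as sm

    mu = {p.participant_id: p.baseline_mu for p in cohort}
    iv = logs[logs["period"] == "intervention"]
    y = iv["steps"].to_numpy(dtype=float) - iv["participant_id"].map(mu).to_numpy()
    x = sm.add_constant(iv["feedback_prev"].to_numpy(dtype=float))
    fit = sm.OLS(y, x).fit()
    return float(fit.params[1]), float(fit.bse[1])
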