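"""Synthetic cohort, balanced assignment and the study harness."""

import numpy as np
import pandas as pd
import pytest

from stepduel import (
    balance_assign,
    estimate_responsiveness,
    generate_cohort,
    preset_config,
    simulate_study,
    summarize,
)
from stepduel.simulation import (
    CELLS,
    ParticipantProfile,
    period_summaries,
    simulate_participant,
)


class TestCohort:
    def test_reproducible_under_seed(self):
        a = generate_cohort(42, seed=1)
        b = generate_cohort(42, seed=1)
        assert a == b
        assert generate_cohort(42, seed=2) != a

    def test_realized_stage_mean_near_target(self):
        cohort = generate_cohort(42, seed=3, stage_mean=2.2)
        mean = np.mean([p.motivation_stage for p in cohort])
        assert abs(mean - 2.2) <= 0.3

    def test_baselines_plausible_pedometer_means(self):
        cohort = generate_cohort(200, seed=4)
        mus = np.array([p.baseline_mu for p in cohort])
        assert 7000 < np.median(mus) < 9000
        assert (mus > 0).all()

    def test_minimal_cohort(self):
        cohort = generate_cohort(2, seed=5)
        assert len(cohort) == 2
        assert all(1 <= p.motivation_stage <= 5 for p in cohort)

    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(1, seed=0)


class TestBalanceAssign:
    def test_cell_sizes_within_one_and_tolerances_met(self):
        cohort = generate_cohort(42, seed=6)
        assigned = balance_assign(cohort, seed=7)
        sizes = pd.Series([p.condition for p in assigned]).value_counts()
        assert sorted(sizes) == [10, 10, 11, 11]
        df = pd.DataFrame(
            {
                "cell": [p.condition for p in assigned],
                "mu": [p.baseline_mu for p in assigned],
                "stage": [p.motivation_stage for p in assigned],
            }
        )
        means = df.groupby("cell").mean()
        assert means["mu"].max() - means["mu"].min() < 500
        assert means["stage"].max() - means["stage"].min() < 0.5

    def test_identical_participants_always_satisfy_tolerance(self):
        cohort = [
            ParticipantProfile(f"p{i}", 8000.0, 1500.0, 2) for i in range(8)
        ]
        assigned = balance_assign(cohort, seed=0)
        assert {p.condition for p in assigned} == set(CELLS)

    def test_infeasible_tolerance_raises(self):
        cohort = generate_cohort(8, seed=8)
        with pytest.raises(RuntimeError):
            balance_assign(
                cohort, seed=0, baseline_tolerance=0.0, stage_tolerance=0.0,
                max_retries=3,
            )

    def test_cohort_smaller_than_cells_rejected(self):
        with pytest.raises(ValueError):
            balance_assign(generate_cohort(2, seed=9), seed=0)


def run_study(seed, resp, n=42, period_days=14, **assign_kw):
    cohort = generate_cohort(n, seed=seed, responsiveness=resp)
    cohort = balance_assign(cohort, seed=seed + 1, **assign_kw)
    logs, summaries = simulate_study(cohort, seed=seed + 2, period_days=period_days)
    return cohort, logs, summaries


def paired_excess(logs, period_a="intervention", period_b="pre"):
    pp = (
        logs.groupby(["participant_id", "condition", "period"], observed=True)["steps"]
        .mean()
        .unstack()
    )
    pp = pp.reset_index()
    pp["main"] = pp["condition"].str.split("-").str[0]
    pp["excess"] = pp[period_a] - pp[period_b]
    return pp


class TestStudyHarness:
    def test_null_responsiveness_means_no_intervention_effect(self):
        _, logs, _ = run_study(seed=21, resp=0.0)
        pp = paired_excess(logs)
        se = pp["excess"].std(ddof=1) / np.sqrt(len(pp))
        assert abs(pp["excess"].mean()) < 3 * se

    def test_null_calibration_rejection_rate_near_alpha(self):
        # permutation-style calibration: with no behavioural coupling the
        # pre/intervention paired t-test should reject at about alpha
        from scipy import stats

        rejections = 0
        reps = 40
        for r in range(reps):
            # tiny cells: widen tolerances (exact balance is not under test)
            _, logs, _ = run_study(
                seed=3100 + r, resp=0.0, n=12, period_days=7,
                baseline_tolerance=2000.0, stage_tolerance=2.0,
            )
            pp = paired_excess(logs)
            p = stats.ttest_1samp(pp["excess"], 0.0).pvalue
            rejections += p < 0.05
        assert rejections / reps <= 0.15

    def test_feedback_drives_main1_but_not_main2(self):
        _, logs, _ = run_study(seed=31, resp=800.0)
        pp = paired_excess(logs)
        by_main = pp.groupby("main")["excess"].mean()
        assert by_main["Main1"] > 0
        assert by_main["Main2"] < by_main["Main1"]
        sig = logs[logs.period == "intervention"].groupby(
            logs["condition"].str.split("-").str[0]
        )["feedback_prev"].mean()
        assert sig["Main1"] > sig["Main2"]

    def test_post_period_returns_toward_baseline(self):
        _, logs, _ = run_study(seed=31, resp=800.0)
        pp = paired_excess(logs)
        main1 = pp[pp["main"] == "Main1"]
        post_excess = (main1["post"] - main1["pre"]).mean()
        intervention_excess = main1["excess"].mean()
        assert abs(post_excess) < intervention_excess

    def test_disabling_feedback_decouples_steps_from_the_game(self):
        # with zero responsiveness the same noise stream yields the same
        # steps under either game parameterisation
        profile = ParticipantProfile("p0", 8000.0, 1500.0, 2, responsiveness=0.0)
        out = {}
        for label in ("Main1-Sub1", "Main2-Sub2"):
            config = preset_config(label, rng_seed=77)
            df = simulate_participant(
                profile, config, np.random.default_rng(123), period_days=7
            )
            out[label] = df["steps"].tolist()
        assert out["Main1-Sub1"] == out["Main2-Sub2"]

    def test_unassigned_cohort_rejected(self):
        cohort = generate_cohort(8, seed=10)
        with pytest.raises(ValueError):
            simulate_study(cohort, seed=0)


def toy_logs():
    rows = []
    data = {
        ("a", "Main1-Sub1"): {"pre": [7000, 9000], "intervention": [8000, 10000], "post": [7000, 7000]},
        ("b", "Main1-Sub1"): {"pre": [6000, 6000], "intervention": [9000, 9000], "post": [6000, 8000]},
        ("c", "Main2-Sub1"): {"pre": [8000, 8000], "intervention": [8000, 8000], "post": [8000, 8000]},
    }
    for (pid, cond), periods in data.items():
        for period, steps in periods.items():
            for s in steps:
                rows.append((pid, cond, period, s))
    return pd.DataFrame(rows, columns=["participant_id", "condition", "period", "steps"])


class TestSummaries:
    def test_period_summaries_match_hand_computed_means(self):
        summaries = {
            (s.condition, s.period): s for s in period_summaries(toy_logs())
        }
        s = summaries[("Main1-Sub1", "pre")]
        # participant means 8000 and 6000 -> mean 7000, SE 1000
        assert s.n == 2 and s.mean_steps == 7000 and s.sem == pytest.approx(1000)
        assert summaries[("Main1-Sub1", "intervention")].mean_steps == 9000
        assert summaries[("Main2-Sub1", "post")].mean_steps == 8000

    def test_constant_logs_give_zero_f(self):
        logs = toy_logs()
        logs["steps"] = 8000
        summaries, aov, posthoc = summarize(logs)
        assert (aov["F"] == 0).all()
        means = {s.mean_steps for s in summaries}
        assert means == {8000}

    def test_missing_period_cell_rejected(self):
        logs = toy_logs()
        broken = logs[~((logs.condition == "Main2-Sub1") & (logs.period == "post"))]
        with pytest.raises(ValueError):
            summarize(broken)

    def test_anova_flags_injected_intervention_shift(self):
        # Monte-Carlo power check: a +1000-step shift in one cell's
        # intervention period should be flagged by the interaction term
        # at alpha = 0.05 with high probability at n = 42
        rng = np.random.default_rng(99)
        cells = np.repeat(CELLS, [11, 11, 10, 10])
        hits = 0
        reps = 200
        for _ in range(reps):
            mus = 8000 * np.exp(rng.normal(0, 0.25, size=42))
            rows = []
            for i, (cell, mu) in enumerate(zip(cells, mus)):
                for period in ("pre", "intervention", "post"):
                    shift = 1000 if (cell == "Main1-Sub1" and period == "intervention") else 0
                    for s in rng.normal(mu + shift, 1500, size=14):
                        rows.append((f"p{i}", cell, period, max(0.0, s)))
            logs = pd.DataFrame(
                rows, columns=["participant_id", "condition", "period", "steps"]
            )
            _, aov, _ = summarize(logs, factor="condition")
            inter = aov.loc[aov["Source"] == "Interaction", "p_unc"]
            hits += float(inter.iloc[0]) < 0.05
        assert hits / reps >= 0.8

    def test_summarize_runs_on_simulated_study(self):
        _, logs, _ = run_study(
            seed=41, resp=0.0, n=16, period_days=7,
            baseline_tolerance=2000.0, stage_tolerance=2.0,
        )
        summaries, aov, posthoc = summarize(logs)
        assert {s.period for s in summaries} == {"pre", "intervention", "post"}
        assert {"main", "period", "Interaction"} <= set(aov["Source"].astype(str))
        assert "p_corr" in posthoc.columns or "p_unc" in posthoc.columns


class TestResponsivenessRecovery:
    def test_injected_slope_recovered_within_two_standard_errors(self):
        cohort, logs, _ = run_study(seed=51, resp=400.0)
        est, se = estimate_responsiveness(logs, cohort)
        assert abs(est - 400.0) <= 2 * se
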