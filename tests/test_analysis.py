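"""Feasibility rates, signed-rank statistics and trajectory summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from exerprog.analysis import (
    DegenerateSampleError,
    FeasibilityCounts,
    FeasibilityThresholds,
    PairedSample,
    UndefinedRateError,
    counts_from_records,
    difficulty_trajectory,
    effect_size_class,
    feasibility_report,
    paired_descriptives,
    wilcoxon_signed_rank,
)
from exerprog.simulate import TrialConfig, sample_patients, simulate_trial

STUDY_COUNTS = FeasibilityCounts(
    screened=23,
    included=13,
    dropouts=3,
    offered_sessions=189,
    attended_sessions=165,
    offered_minutes=4974.0,
    attended_minutes=4915.0,
    mean_motivation=7.67,
    mean_satisfaction=7.44,
)


def enumeration_oracle(diffs):
    """Brute-force signed-rank: all 2^n sign patterns with mid-ranks."""
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    T_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
    count = 0
    for signs in itertools.product([1, -1], repeat=n):
        w_pos = sum(r for r, s in zip(ranks, signs) if s > 0)
        w_neg = ranks.sum() - w_pos
        if min(w_pos, w_neg) <= T_obs + 1e-12:
            count += 1
    return T_obs, count / 2.0**n


class TestFeasibilityRates:
    def test_reproduces_published_protocol_outcomes(self):
        rep = feasibility_report(STUDY_COUNTS)
        expect = {
            "inclusion": (57, True),
            "compliance": (99, True),
            "attrition": (23, False),
            "motivation": (77, True),
            "satisfaction": (74, True),
        }
        for name, (pct, met) in expect.items():
            assert rep[name].pct == pct
            assert rep[name].met is met
        assert not rep.all_met

    def test_adherence_is_attended_over_offered(self):
        # 165/189 = 87.3% -> 87, above the 80% threshold
        adh = feasibility_report(STUDY_COUNTS)["adherence"]
        assert adh.pct == 87 and adh.met

    def test_all_rates_within_0_100(self):
        for r in feasibility_report(STUDY_COUNTS).rates:
            assert 0 <= r.raw_pct <= 100

    def test_half_up_rounding_on_verdict_boundary(self):
        counts = FeasibilityCounts(
            screened=200, included=99, dropouts=0,
            offered_sessions=16, attended_sessions=16,
            offered_minutes=100.0, attended_minutes=100.0,
            mean_motivation=5.95, mean_satisfaction=9.0,
        )
        rep = feasibility_report(counts)
        assert rep["inclusion"].pct == 50 and rep["inclusion"].met  # 49.5 -> 50
        assert rep["motivation"].pct == 60 and rep["motivation"].met  # 59.5 -> 60

    def test_zero_denominator_names_the_metric(self):
        counts = FeasibilityCounts(0, 0, 0, 0, 0, 0.0, 0.0, 5.0, 5.0)
        with pytest.raises(UndefinedRateError, match="inclusion"):
            feasibility_report(counts)

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            FeasibilityCounts(10, 13, 3, 189, 165, 4974.0, 4915.0, 7.0, 7.0)
        with pytest.raises(ValueError):
            FeasibilityThresholds(attrition_max=150.0)

    def test_counts_aggregated_from_simulated_records(self):
        patients = sample_patients(13, seed=2)
        trial = simulate_trial(patients, TrialConfig(), seed=2)
        counts = counts_from_records(trial.records, screened=23)
        assert counts.included == 13 and counts.screened == 23
        assert counts.offered_sessions == 13 * 16
        assert counts.attended_sessions <= counts.offered_sessions
        assert counts.attended_minutes <= counts.offered_minutes
        rep = feasibility_report(counts)
        assert rep["inclusion"].pct == 57


class TestWilcoxon:
    def test_all_positive_distinct_differences(self):
        sample = PairedSample.from_arrays([1, 2, 3, 4, 5], [2, 4, 6, 8, 11])
        res = wilcoxon_signed_rank(sample, method="exact")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.0625)
        asym = wilcoxon_signed_rank(sample, method="asymptotic")
        assert asym.z == pytest.approx(-2.023, abs=5e-4)
        assert asym.r == pytest.approx(0.905, abs=5e-4)

    def test_degenerate_all_zero_differences(self):
        with pytest.raises(DegenerateSampleError):
            wilcoxon_signed_rank(PairedSample.from_arrays([1, 2, 3], [1, 2, 3]))

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_exact_p_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(8):
            pre = rng.integers(0, 6, size=n).astype(float)
            post = pre + rng.integers(-3, 4, size=n)
            if np.all(post == pre):
                post[0] += 1.0
            sample = PairedSample.from_arrays(pre, post)
            res = wilcoxon_signed_rank(sample, method="exact")
            T_oracle, p_oracle = enumeration_oracle(sample.differences)
            assert res.statistic == pytest.approx(T_oracle)
            assert res.p_value == pytest.approx(p_oracle)

    def test_asymptotic_matches_scipy_without_correction(self):
        rng = np.random.default_rng(123)
        for n in (8, 12, 20):
            pre = rng.normal(size=n)
            post = pre + rng.normal(0.4, 1.0, size=n)
            sample = PairedSample.from_arrays(pre, post)
            res = wilcoxon_signed_rank(sample, method="asymptotic")
            ref = stats.wilcoxon(post, pre, correction=False, method="approx")
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_exact_and_asymptotic_agree_for_moderate_n(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            pre = rng.normal(size=12)
            post = pre + rng.normal(0.5, 1.0, size=12)
            sample = PairedSample.from_arrays(pre, post)
            p_exact = wilcoxon_signed_rank(sample, "exact").p_value
            p_asym = wilcoxon_signed_rank(sample, "asymptotic").p_value
            assert abs(p_exact - p_asym) < 0.05

    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(-50, 50, allow_nan=False),
            ),
            min_size=6,
            max_size=15,
        ).filter(lambda ps: sum(a != b for a, b in ps) >= 5)
    )
    def test_antisymmetry_under_pre_post_swap(self, pairs):
        pre = [a for a, _ in pairs]
        post = [b for _, b in pairs]
        fwd = wilcoxon_signed_rank(PairedSample.from_arrays(pre, post))
        rev = wilcoxon_signed_rank(PairedSample.from_arrays(post, pre))
        assert fwd.statistic == rev.statistic
        assert fwd.p_value == pytest.approx(rev.p_value)
        assert fwd.r == pytest.approx(rev.r)

    def test_missing_pairs_removed_and_counted(self):
        sample = PairedSample.from_arrays(
            [1, 2, math.nan, 4, 5, 6], [2, 3, 4, math.nan, 7, 8]
        )
        assert sample.n == 4 and sample.n_missing == 2


class TestEffectSize:
    @pytest.mark.parametrize(
        "r, cls",
        [
            (0.46, "medium"),  # published TUG effect size
            (0.50, "large"),  # boundary: r >= 0.50
            (0.03, "small"),  # published Go-NoGo RT effect size
            (0.30, "medium"),  # boundary: 0.30 <= r
            (0.2999, "small"),
            (0.0, "small"),
            (1.5, "large"),
        ],
    )
    def test_classification_cutoffs(self, r, cls):
        assert effect_size_class(r) == cls

    def test_negative_r_rejected(self):
        with pytest.raises(ValueError):
            effect_size_class(-0.1)

    def test_monotone_total_step_function(self):
        grid = np.linspace(0, 2, 401)
        order = {"small": 0, "medium": 1, "large": 2}
        classes = [order[effect_size_class(r)] for r in grid]
        assert classes == sorted(classes)


class TestDescriptives:
    def test_constant_shift(self):
        d = paired_descriptives(PairedSample.from_arrays([1, 2, 3], [2, 3, 4]))
        assert d.median_diff == 1.0
        assert d.iqr_diff == (1.0, 1.0)

    def test_antisymmetric_differences_interpolated_median(self):
        d = paired_descriptives(
            PairedSample.from_arrays([1, 2, 3, 4], [4, 3, 2, 1])
        )
        # differences (3, 1, -1, -3): median by linear interpolation is 0
        assert d.median_diff == 0.0
        assert d.iqr_diff == (-1.5, 1.5)

    def test_identity_pre_post(self):
        d = paired_descriptives(PairedSample.from_arrays([5, 6, 7], [5, 6, 7]))
        assert d.median_diff == 0.0 and d.iqr_diff == (0.0, 0.0)


class TestDifficultyTrajectory:
    def test_simulated_trial_summary_shape_and_bounds(self):
        patients = sample_patients(13, seed=4)
        trial = simulate_trial(patients, TrialConfig(), seed=4)
        df = difficulty_trajectory(trial.records)
        assert list(df["session_index"]) == list(range(1, 17))
        assert (df["n"] >= 1).all()
        assert df["mean_motor_vas"].between(0, 9).all()
        assert df["frac_target_motor"].between(0, 1).all()

    def test_means_and_fractions_by_hand(self):
        from exerprog.simulate import SessionRecord

        def rec(pid, motor):
            return SessionRecord(
                participant_id=pid, session_index=1, week=1, group="basic",
                anchor_row=0, anchor_col=0, planned_min=15.0, attended_min=15.0,
                motor_vas=motor, cognitive_vas=5.625, motivation=8.0,
                satisfaction=8.0, dropped=False,
            )

        df = difficulty_trajectory([rec("a", 2.0), rec("b", 8.0)])
        row = df.iloc[0]
        assert row["n"] == 2
        assert row["mean_motor_vas"] == pytest.approx(5.0)
        # fraction counts the raw ratings, not their mean: neither 2 nor 8 in target
        assert row["frac_target_motor"] == 0.0
        assert row["frac_target_cognitive"] == 1.0

    def test_dropped_sessions_excluded(self):
        patients = sample_patients(6, seed=8)
        import dataclasses

        patients = [dataclasses.replace(p, dropout_p=0.25) for p in patients]
        trial = simulate_trial(patients, TrialConfig(), seed=8)
        df = difficulty_trajectory(trial.records)
        attended_per_index = {}
        for r in trial.records:
            if not r.dropped:
                attended_per_index[r.session_index] = (
                    attended_per_index.get(r.session_index, 0) + 1
                )
        for _, row in df.iterrows():
            assert row["n"] == attended_per_index[row["session_index"]]
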