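"""Profiles, timepoint summaries, classification and the Welch comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dida import (
    AssayReferences,
    ConfigurationError,
    DisintegrationProfile,
    MGVSeries,
    OutOfRangeError,
    build_profile,
    classify_profile,
    estimate_noise_floor,
    stars_for_p,
    summarize_timepoints,
    value_at,
    welch_t_from_summary,
)
from dida.exceptions import DegenerateVarianceError, InputError

REFS = AssayReferences(mgv_background=20.0, mgv_background_sd=0.0, mgv_tablet_full=160.0)


def _profile(values, dt=1.0, **kwargs):
    values = np.asarray(values, dtype=float)
    return DisintegrationProfile(
        times_s=np.arange(values.size) * dt, percent_remaining=values, **kwargs
    )


def _mgv_for_percent(percents, dt=1.0):
    percents = np.asarray(percents, dtype=float)
    values = REFS.mgv_background + percents / 100.0 * REFS.mgv_tablet_full
    return MGVSeries(times_s=np.arange(percents.size) * dt, values=values)


class TestBuildProfile:
    def test_intact_mgv_gives_flat_100(self):
        profile = build_profile(_mgv_for_percent([100.0] * 5), REFS)
        assert np.allclose(profile.percent_remaining, 100.0)

    def test_background_mgv_gives_flat_0(self):
        profile = build_profile(_mgv_for_percent([0.0] * 5), REFS)
        assert np.allclose(profile.percent_remaining, 0.0)

    def test_smoothing_records_metadata_and_averages(self):
        profile = build_profile(
            _mgv_for_percent([100, 80, 60, 40, 20]), REFS, smoothing_window_s=2.0
        )
        assert profile.smoothed and profile.smoothing_window_s == 2.0
        # centered window of 2 s at t=2 covers samples at 1,2,3 s
        assert profile.percent_remaining[2] == pytest.approx(60.0)

    def test_smoothing_off_by_default(self):
        profile = build_profile(_mgv_for_percent([100, 50]), REFS)
        assert not profile.smoothed and profile.smoothing_window_s is None

    def test_flags_mark_swelling_and_negative(self):
        profile = build_profile(_mgv_for_percent([110.0, 50.0, -3.0]), REFS)
        assert profile.flags == ["swelling", "", "negative"]


class TestValueAt:
    def test_exact_sample_hit(self):
        profile = _profile(np.linspace(100, 40, 61))
        assert value_at(profile, 30.0) == profile.percent_remaining[30]

    def test_midpoint_interpolation(self):
        profile = _profile([100.0, 90.0])
        assert value_at(profile, 0.5) == pytest.approx(95.0)

    def test_out_of_range_rejected(self):
        profile = _profile([100.0, 90.0])
        with pytest.raises(OutOfRangeError):
            value_at(profile, 1.5)


class TestSummarizeTimepoints:
    def test_identical_replicates_have_zero_sd(self):
        profile = _profile(np.linspace(100, 0, 201))
        for s in summarize_timepoints([profile] * 3, [10.0, 30.0, 180.0]):
            assert s.sd_percent == 0.0
            assert s.n == 3

    def test_hand_computed_mean_and_sd(self):
        profiles = [_profile([v] * 31) for v in (20.0, 21.0, 22.0)]
        (summary,) = summarize_timepoints(profiles, [30.0])
        assert summary.mean_percent == pytest.approx(21.0)
        assert summary.sd_percent == pytest.approx(1.0)  # n-1 denominator

    def test_single_replicate_sd_zero(self):
        (summary,) = summarize_timepoints([_profile([50.0] * 11)], [10.0])
        assert summary.sd_percent == 0.0 and summary.n == 1

    def test_short_replicate_named_in_error(self):
        long, short = _profile([50.0] * 200), _profile([50.0] * 20, replicate_id="rep_b")
        with pytest.raises(OutOfRangeError, match="rep_b"):
            summarize_timepoints([long, short], [180.0])


def _decay_profile(k, plateau, duration=250.0, dt=0.1):
    t = np.arange(0, duration + dt / 2, dt)
    return DisintegrationProfile(
        times_s=t, percent_remaining=plateau + (100 - plateau) * np.exp(-k * t)
    )


class TestClassifyProfile:
    def test_instant_reaches_threshold_within_10s(self):
        # pilocarpine-like: ~4% remaining at 10 s
        result = classify_profile(_decay_profile(k=0.33, plateau=0.0))
        assert result.category == "instant"
        assert result.endpoint_time_s <= 10.0

    def test_fast_between_10_and_30s(self):
        result = classify_profile(_decay_profile(k=0.12, plateau=0.0))
        assert result.category == "fast"
        assert 10.0 < result.endpoint_time_s <= 30.0

    def test_prolonged_after_30s(self):
        result = classify_profile(_decay_profile(k=0.03, plateau=0.0))
        assert result.category == "prolonged"
        assert result.endpoint_time_s > 30.0

    def test_plateau_above_threshold_is_partial(self):
        result = classify_profile(_decay_profile(k=0.1, plateau=15.0))
        assert result.category == "partial"
        assert result.endpoint_time_s is None

    def test_plateau_8_threshold_dependence(self):
        # completes under a 10% threshold, partial under 5% (residual material)
        profile = _decay_profile(k=0.1, plateau=8.0)
        assert classify_profile(profile, completion_threshold_pct=10.0).category in (
            "fast",
            "prolonged",
        )
        assert classify_profile(profile, completion_threshold_pct=5.0).category == "partial"

    def test_sustained_swelling_detected(self):
        t = np.arange(0, 200.1, 0.1)
        values = 100 + 25 * (1 - np.exp(-0.05 * t))
        result = classify_profile(DisintegrationProfile(times_s=t, percent_remaining=values))
        assert result.category == "swelling"
        assert result.max_percent >= 105.0

    def test_brief_spike_is_not_swelling(self):
        values = np.full(2001, 50.0)
        values[100:110] = 130.0  # 1 s blip at 10 Hz
        t = np.arange(2001) * 0.1
        result = classify_profile(DisintegrationProfile(times_s=t, percent_remaining=values))
        assert result.category != "swelling"

    def test_endpoint_requires_staying_below(self):
        # dips below threshold then rises again: endpoint is the later crossing
        values = np.concatenate([
            np.linspace(100, 5, 50), np.linspace(5, 40, 50), np.linspace(40, 2, 100),
        ])
        profile = _profile(values, dt=0.5)
        result = classify_profile(profile)
        above = values > 10.0
        expected = profile.times_s[np.nonzero(above)[0][-1] + 1]
        assert result.endpoint_time_s == pytest.approx(expected)

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            classify_profile(_decay_profile(0.1, 0.0), instant_limit_s=30, fast_limit_s=10)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        lo=st.floats(4.0, 12.0),
        hi_delta=st.floats(0.5, 10.0),
        k=st.floats(0.02, 0.3),
    )
    def test_threshold_monotone_endpoint(self, lo, hi_delta, k):
        """Raising the completion threshold never delays the endpoint."""
        profile = _decay_profile(k=k, plateau=0.0)
        e_lo = classify_profile(profile, completion_threshold_pct=lo).endpoint_time_s
        e_hi = classify_profile(profile, completion_threshold_pct=lo + hi_delta).endpoint_time_s
        assert e_hi <= e_lo


class TestNoiseFloor:
    def test_noiseless_background_is_zero(self):
        assert estimate_noise_floor(np.zeros(100)) == 0.0

    def test_matches_sample_sd_of_generator(self, rng):
        values = rng.normal(0.0, 1.7, size=5000)
        assert estimate_noise_floor(values) == pytest.approx(values.std(), abs=1e-12)

    def test_uniform_drift_equals_drift_sd(self):
        drift = np.linspace(0, 2, 100)
        assert estimate_noise_floor(drift) == pytest.approx(drift.std())


class TestWelch:
    def test_identical_groups(self):
        r = welch_t_from_summary(10.0, 2.0, 3, 10.0, 2.0, 3)
        assert r.t_statistic == 0.0
        assert r.p_value == pytest.approx(1.0)
        assert r.significance_stars == ""

    def test_printed_summary_statistics(self):
        # 21±3 vs 8±1, n=3: t = 13/sqrt(10/3), Welch-Satterthwaite df
        r = welch_t_from_summary(21.0, 3.0, 3, 8.0, 1.0, 3)
        assert r.t_statistic == pytest.approx(13.0 / np.sqrt(10.0 / 3.0), abs=1e-9)
        assert r.degrees_freedom == pytest.approx(200.0 / 82.0, abs=1e-9)
        ref = stats.ttest_ind_from_stats(21.0, 3.0, 3, 8.0, 1.0, 3, equal_var=False)
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert r.p_value <= 0.05

    def test_group_order_flips_sign_only(self):
        a = welch_t_from_summary(21.0, 3.0, 3, 8.0, 1.0, 3)
        b = welch_t_from_summary(8.0, 1.0, 3, 21.0, 3.0, 3)
        assert b.t_statistic == pytest.approx(-a.t_statistic)
        assert b.p_value == pytest.approx(a.p_value)
        assert b.significance_stars == a.significance_stars

    def test_agrees_with_full_data_ttest(self, rng):
        for _ in range(10):
            a = rng.normal(20, 3, size=5)
            b = rng.normal(10, 1, size=4)
            r = welch_t_from_summary(
                a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
            )
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert r.t_statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_degenerate_variances(self):
        r = welch_t_from_summary(5.0, 0.0, 3, 5.0, 0.0, 3)
        assert r.p_value == 1.0
        with pytest.raises(DegenerateVarianceError):
            welch_t_from_summary(5.0, 0.0, 3, 6.0, 0.0, 3)

    def test_small_groups_rejected(self):
        with pytest.raises(InputError):
            welch_t_from_summary(5.0, 1.0, 1, 6.0, 1.0, 3)

    @pytest.mark.parametrize(
        ("p", "stars"),
        [
            (0.2, ""), (0.05, "*"), (0.049, "*"), (0.01, "**"),
            (0.0099, "**"), (0.001, "***"), (0.0001, "***"),
        ],
    )
    def test_star_step_function(self, p, stars):
        assert stars_for_p(p) == stars
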