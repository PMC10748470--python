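from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.signal import lombscargle as scipy_lombscargle

from chirpclock import Photoschedule, SingingSeries
from chirpclock.circadian_analysis import (
    angular_variance,
    circular_mean,
    lomb_scargle,
    ls_power,
    ls_significance_threshold,
    period_summary,
    permutation_period_test,
    phase_markers,
    phase_shift,
    summarize_phases,
)
from chirpclock.synthetic_song import SongScheduleParams, simulate_series


def _series(values, mask=None, lights_on=18.0):
    return SingingSeries(
        start=datetime(2022, 6, 1, int(lights_on), 0),
        values=values,
        schedule=Photoschedule("DL", lights_on=lights_on),
        mask=mask,
    )


class TestLombScargle:
    def test_sinusoid_period_recovered(self):
        rng = np.random.default_rng(0)
        t = np.arange(8 * 1440) / 60.0
        y = 0.5 + 0.4 * np.sin(2 * np.pi * t / 24.0) + rng.normal(0, 0.05, t.size)
        pg = lomb_scargle(_series(np.clip(y, 0, 1)))
        assert pg.best_period == pytest.approx(24.0, abs=0.1)
        assert pg.is_rhythmic

    def test_constant_series_is_not_rhythmic(self):
        pg = lomb_scargle(_series(np.full(8 * 1440, 0.5)))
        assert not pg.is_rhythmic
        assert not pg.power.any()

    def test_free_running_simulated_period_recovered(self, dd_schedule):
        p = SongScheduleParams(
            period_h=25.1, onset_zt=13.0, offset_zt=24.0, p_sing=0.8,
            p_noise_sing=0.01, seed=12,
        )
        s = simulate_series(p, dd_schedule, days=8)
        pg = lomb_scargle(s)
        assert pg.best_period == pytest.approx(25.1, abs=0.2)

    def test_masked_minutes_are_ignored(self):
        rng = np.random.default_rng(5)
        t = np.arange(8 * 1440) / 60.0
        y = np.clip(0.5 + 0.4 * np.sin(2 * np.pi * t / 24.0), 0, 1)
        mask = np.zeros(t.size, dtype=bool)
        mask[2000:3440] = True
        corrupted = y.copy()
        corrupted[mask] = rng.random(mask.sum())  # garbage under the mask
        pg = lomb_scargle(_series(corrupted, mask=mask))
        assert pg.best_period == pytest.approx(24.0, abs=0.1)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="3 cycles"):
            lomb_scargle(_series(np.ones(1440)))

    def test_power_matches_least_squares_fit_reduction(self):
        """LS power equals the residual-reduction of a per-frequency sinusoid fit."""
        rng = np.random.default_rng(1)
        for n in (64, 257, 512):
            t = np.sort(rng.uniform(0, 180.0, n))
            y = np.sin(2 * np.pi * t / 23.7) + rng.normal(0, 0.8, n)
            periods = np.linspace(18.0, 30.0, 40)
            ours = ls_power(t, y, periods)
            yc = y - y.mean()
            var = yc.var(ddof=1)
            ss0 = float(yc @ yc)
            brute = []
            for p in periods:
                w = 2 * np.pi / p
                A = np.column_stack([np.cos(w * t), np.sin(w * t)])
                coef, *_ = np.linalg.lstsq(A, yc, rcond=None)
                brute.append((ss0 - float((yc - A @ coef) @ (yc - A @ coef))) / (2 * var))
            assert np.max(np.abs(ours - np.asarray(brute))) < 1e-8

    def test_power_matches_scipy_unnormalized(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 150.0, 300))
        y = np.sin(2 * np.pi * t / 25.0) + rng.normal(0, 0.5, 300)
        periods = np.linspace(18, 30, 30)
        yc = y - y.mean()
        ours = ls_power(t, y, periods) * yc.var(ddof=1)
        ref = scipy_lombscargle(t, yc, 2 * np.pi / periods)
        assert np.allclose(ours, ref, atol=1e-10)


class TestSignificanceThreshold:
    def test_single_frequency_closed_form(self):
        assert ls_significance_threshold(alpha=0.05, M=1) == pytest.approx(
            -np.log(0.05), abs=1e-12
        )

    def test_matches_independent_root_finding_at_m100(self):
        # invert P(max of M iid Exp(1) > z) = alpha numerically
        z_ref = brentq(lambda z: 1 - (1 - np.exp(-z)) ** 100 - 0.05, 1e-9, 50.0)
        assert ls_significance_threshold(alpha=0.05, M=100) == pytest.approx(
            z_ref, abs=1e-9
        )

    def test_monotone_in_alpha(self):
        zs = [ls_significance_threshold(alpha=a, M=10) for a in (0.2, 0.05, 0.01, 1e-4)]
        assert zs == sorted(zs)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ls_significance_threshold(alpha=0.0, M=1)
        with pytest.raises(ValueError):
            ls_significance_threshold(alpha=0.05, M=0)
        with pytest.raises(ValueError):
            ls_significance_threshold(alpha=0.05)


class TestPhaseMarkers:
    def test_triangular_profile_crossings_are_exact(self):
        """Linear 20%-of-peak interpolation on a triangle: onset ZT13.2,
        peak ZT18.0, offset ZT22.8."""
        zt = np.arange(1440) / 60.0
        day = np.where(
            (zt >= 12.0) & (zt <= 18.0),
            (zt - 12.0) / 6.0,
            np.where(zt > 18.0, (24.0 - zt) / 6.0, 0.0),
        )
        s = _series(np.tile(day, 4))
        pm = phase_markers(s, bin_min=1, smooth_window_bins=1, align="left")
        row = pm.table.iloc[0]
        assert row["onset_zt"] == pytest.approx(13.2, abs=1e-9)
        assert row["peak_zt"] == pytest.approx(18.0, abs=1e-9)
        assert row["offset_zt"] == pytest.approx(22.8, abs=1e-9)

    def test_noise_free_boxcar_recovered_within_a_bin(self):
        zt = np.arange(1440) / 60.0
        day = ((zt >= 13.0) & (zt < 24.0)).astype(float)
        s = _series(np.tile(day, 3))
        pm = phase_markers(s, bin_min=30, smooth_window_bins=1)
        row = pm.table.iloc[0]
        assert row["onset_zt"] == pytest.approx(13.0, abs=0.5)
        assert 13.0 <= row["peak_zt"] < 24.0
        assert row["offset_zt"] % 24.0 == pytest.approx(24.0 % 24.0, abs=0.5)

    def test_all_zero_day_has_undefined_markers(self):
        s = _series(np.zeros(2 * 1440))
        pm = phase_markers(s)
        assert pm.table[["onset_zt", "peak_zt", "offset_zt"]].isna().all().all()

    def test_simulated_window_recovered_within_30_minutes(self, dl_schedule):
        p = SongScheduleParams(
            onset_zt=13.5, offset_zt=23.5, p_sing=0.8, p_noise_sing=0.0, seed=8
        )
        s = simulate_series(p, dl_schedule, days=8)
        pm = phase_markers(s, smooth_window_bins=1)
        onset = circular_mean(pm.defined("onset"))
        offset = circular_mean(pm.defined("offset"))
        assert abs(onset - 13.5) <= 0.5
        assert abs(offset - 23.5) <= 0.5


class TestCircularStatistics:
    def test_mean_wraps_midnight(self):
        m = circular_mean([23.0, 1.0])
        assert min(m, 24.0 - m) == pytest.approx(0.0, abs=1e-9)

    def test_identical_values_have_zero_variance(self):
        assert angular_variance([7.5, 7.5, 7.5]) == pytest.approx(0.0, abs=1e-12)

    def test_balanced_angles_have_unit_variance(self):
        assert angular_variance([0.0, 6.0, 12.0, 18.0]) == pytest.approx(1.0, abs=1e-12)

    @given(
        offset=st.floats(min_value=-48.0, max_value=48.0),
        hours=st.lists(
            st.floats(min_value=0.0, max_value=24.0, allow_nan=False), min_size=2, max_size=12
        ),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rotation_equivariance_and_invariance(self, offset, hours):
        base = np.asarray(hours)
        rotated = (base + offset) % 24.0
        expected = (circular_mean(base) + offset) % 24.0
        assert circular_mean(rotated) == pytest.approx(expected, abs=1e-9)
        assert angular_variance(rotated) == pytest.approx(
            angular_variance(base), abs=1e-9
        )

    def test_summary_counts_only_finite(self):
        cs = summarize_phases([13.0, 14.0, np.nan])
        assert cs.n == 2
        assert cs.V_m == pytest.approx(1.0 - cs.R)


class TestPhaseShift:
    def test_advance_between_concentrated_samples(self):
        pre = [13.24 - 0.2, 13.24 + 0.2] * 5
        post = [12.34 - 0.2, 12.34 + 0.2] * 5
        res = phase_shift(pre, post, n_permutations=500, seed=0)
        assert res.shift_h == pytest.approx(0.90, abs=1e-9)
        assert res.p_value < 0.05

    def test_identical_sets_shift_zero(self):
        res = phase_shift([13.0, 14.0, 15.0], [13.0, 14.0, 15.0], n_permutations=200)
        assert res.shift_h == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.5

    def test_wrap_across_midnight_is_shortest_arc_delay(self):
        res = phase_shift([23.5] * 4, [0.5] * 4, n_permutations=100)
        assert res.shift_h == pytest.approx(-1.0, abs=1e-9)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            phase_shift([], [12.0])


class TestPeriodSummaries:
    def test_identical_groups(self):
        table = period_summary({"a": [25.0, 25.0], "b": [25.0, 25.0]})
        assert np.allclose(table["mean_h"], 25.0)
        group_rows = table[table["group"] != "pooled"]
        assert np.allclose(group_rows["se_h"], 0.0)

    def test_singleton_group_has_missing_se(self):
        table = period_summary({"a": [25.0]})
        assert np.isnan(table.loc[table["group"] == "a", "se_h"]).all()

    def test_shared_period_groups_not_rejected(self):
        rng = np.random.default_rng(0)
        groups = {g: 25.1 + rng.normal(0, 0.1, 5) for g in ("22", "25", "28")}
        assert permutation_period_test(groups, n_permutations=500, seed=1) > 0.05

    def test_distinct_periods_rejected(self):
        groups = {"a": [24.0] * 5, "b": [26.0] * 5}
        assert permutation_period_test(groups, n_permutations=500, seed=1) < 0.05

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_period_test({"a": [25.0, 25.1]})
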