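from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from chirpclock import Photoschedule, SingingSeries
from chirpclock.rhythm_series import (
    average_group,
    binarize_scores,
    build_actogram,
    phase_activity_fraction,
    polar_profile,
    singing_effort,
    trim_days,
)
from chirpclock.synthetic_song import SongScheduleParams, simulate_series


def _series(values, sched=None, mask=None, start=None):
    sched = sched or Photoschedule("DL", lights_on=18.0)
    return SingingSeries(
        start=start or datetime(2022, 6, 1, 18, 0),
        values=np.asarray(values, dtype=float),
        schedule=sched,
        id="c01",
        mask=mask,
    )


class TestBinarize:
    def test_predictions_map_one_to_one(self, dl_schedule):
        t0 = datetime(2022, 6, 1, 18, 0)
        preds = pd.DataFrame(
            {
                "t_start": [t0, t0 + timedelta(minutes=1), t0 + timedelta(minutes=2)],
                "prediction": [1, 0, 1],
            }
        )
        s = binarize_scores(preds, dl_schedule)
        assert s.values.tolist() == [1.0, 0.0, 1.0]
        assert not s.mask.any()

    def test_gap_is_masked_and_aggregates_unaffected(self, dl_schedule):
        t0 = datetime(2022, 6, 1, 18, 0)
        rows = [{"t_start": t0 + timedelta(minutes=m), "prediction": 1} for m in range(1440)]
        rows += [
            {"t_start": t0 + timedelta(minutes=m), "prediction": 1}
            for m in range(2880, 4320)
        ]
        s = binarize_scores(pd.DataFrame(rows), dl_schedule)
        assert s.mask.sum() == 1440
        assert singing_effort(s) == pytest.approx(24.0)  # gap day excluded

    def test_empty_predictions_warn(self, dl_schedule):
        with pytest.warns(UserWarning):
            s = binarize_scores(pd.DataFrame(columns=["t_start", "prediction"]), dl_schedule)
        assert s.n_minutes == 0


class TestTrim:
    def test_acclimation_trim_leaves_five_of_eight_days(self):
        s = _series(np.ones(8 * 1440))
        t = trim_days(s)
        days_with_data = np.unique(t.day_index()[t.unmasked()])
        assert days_with_data.tolist() == [3, 4, 5, 6, 7]

    def test_post_reversal_days_masked(self, ld_reversal_schedule):
        s = _series(
            np.ones(17 * 1440),
            sched=ld_reversal_schedule,
            start=datetime(2022, 6, 1, 6, 0),
        )
        t = trim_days(s)
        day = t.day_index()
        for d in (9, 10, 11, 12):
            assert t.mask[day == d].all()
        for d in (3, 8, 13, 16):
            assert not t.mask[day == d].any()

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="acclimation"):
            trim_days(_series(np.ones(1440)))


class TestEffortAndFractions:
    def test_constant_singing_is_24h(self):
        assert singing_effort(_series(np.ones(2 * 1440))) == pytest.approx(24.0)

    def test_660_minutes_per_day_is_11h(self):
        day = np.zeros(1440)
        day[:660] = 1.0
        assert singing_effort(_series(np.tile(day, 3))) == pytest.approx(11.0)

    def test_fully_masked_rejected(self):
        s = _series(np.ones(1440), mask=np.ones(1440, dtype=bool))
        with pytest.raises(ValueError):
            singing_effort(s)

    def test_effort_conserves_total_singing_minutes(self):
        rng = np.random.default_rng(0)
        values = (rng.random(5 * 1440) < 0.4).astype(float)
        mask = rng.random(5 * 1440) < 0.1
        s = _series(values, mask=mask)
        n_days = np.unique(s.day_index()[s.unmasked()]).size
        total = values[~mask].sum()
        assert singing_effort(s) * n_days * 60 == pytest.approx(total)

    def test_dark_only_singing(self, dl_schedule):
        zt = dl_schedule.minute_zt(datetime(2022, 6, 1, 18, 0), 2 * 1440)
        s = _series((zt >= 12.0).astype(float), sched=dl_schedule)
        assert phase_activity_fraction(s) == (1.0, 0.0)

    def test_silent_series(self):
        assert phase_activity_fraction(_series(np.zeros(1440))) == (0.0, 0.0)

    def test_simulated_rate_inside_binomial_band(self, dl_schedule):
        # full-dark window at p_sing = 0.68: the dark-phase fraction is a
        # binomial proportion with n = 5 x 720 dark minutes
        p = SongScheduleParams(
            onset_zt=12.0, offset_zt=24.0, p_sing=0.68, p_noise_sing=0.0, seed=21
        )
        s = simulate_series(p, dl_schedule, days=5)
        dark_frac, light_frac = phase_activity_fraction(s)
        half_width = 1.96 * np.sqrt(0.68 * 0.32 / (5 * 720))
        assert abs(dark_frac - 0.68) < half_width
        assert light_frac == 0.0


class TestGroupAverage:
    def test_minutewise_mean(self):
        avg = average_group([_series([1, 1, 0]), _series([1, 0, 0])])
        assert avg.values.tolist() == [1.0, 0.5, 0.0]

    def test_masked_member_excluded_from_mean(self):
        a = _series([1, 1, 1])
        b = _series([0, 0, 0], mask=np.array([True, True, True]))
        avg = average_group([a, b])
        assert avg.values.tolist() == [1.0, 1.0, 1.0]
        assert not avg.mask.any()

    def test_single_series_is_identity(self):
        s = _series([1, 0, 1])
        avg = average_group([s])
        assert np.array_equal(avg.values, s.values)

    def test_average_bounded_by_members(self):
        rng = np.random.default_rng(2)
        members = [_series((rng.random(1440) < 0.5).astype(float)) for _ in range(3)]
        avg = average_group(members)
        stack = np.stack([m.values for m in members])
        assert np.all(avg.values >= stack.min(axis=0))
        assert np.all(avg.values <= stack.max(axis=0))

    def test_mismatched_time_base_rejected(self):
        with pytest.raises(ValueError):
            average_group([_series([1, 0]), _series([1, 0, 1])])


class TestActogramAndPolar:
    def test_three_days_give_two_rows(self):
        act = build_actogram(_series(np.ones(3 * 1440)))
        assert act.matrix.shape == (2, 2880)

    def test_double_plot_identity_with_random_mask(self):
        rng = np.random.default_rng(4)
        s = _series(
            (rng.random(4 * 1440) < 0.5).astype(float),
            mask=rng.random(4 * 1440) < 0.2,
        )
        assert build_actogram(s).double_plot_identity()

    def test_constant_series_fills_raster_and_polar(self):
        s = _series(np.ones(3 * 1440))
        act = build_actogram(s)
        assert np.all(act.matrix == 1.0)
        _, profile = polar_profile(s)
        assert np.allclose(profile, 1.0)

    def test_boxcar_window_maps_to_polar_bins(self, dl_schedule):
        p = SongScheduleParams(
            onset_zt=13.0, offset_zt=24.0, p_sing=1.0, p_noise_sing=0.0, seed=0
        )
        s = simulate_series(p, dl_schedule, days=3)
        edges, profile = polar_profile(s, bin_min=30)
        assert profile.size == 48
        inside = (edges >= 13.0) & (edges < 24.0)
        assert np.all(profile[inside] == 1.0)
        assert np.all(profile[~inside] == 0.0)
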