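"""Non-wear rule semantics, clipping boundary, imputation and wear accounting."""

import numpy as np
import pandas as pd
import pytest

from actimetry.io import EpochSeries
from actimetry.nonwear import (
    NonwearMask,
    detect_clipping,
    detect_nonwear,
    impute_epochs,
    summarize_wear,
)
from actimetry.sleep import DaySegmentation
from conftest import constant_recording, make_recording


def active_recording(seconds, amp=0.3, fs=30.0, axes=(0, 1, 2)):
    t = np.arange(0, seconds, 1 / fs)
    samples = np.zeros((t.size, 3))
    samples[:, 2] = 1.0
    for ax in axes:
        samples[:, ax] += amp * np.sin(2 * np.pi * (1.3 + 0.2 * ax) * t)
    return make_recording(samples, fs=fs)


class TestDetectNonwear:
    def test_constant_signal_is_all_nonwear(self):
        mask = detect_nonwear(constant_recording((0, 0, 1), 3 * 3600))
        assert mask.block_nonwear.all()
        assert not mask.epoch_wear.any()

    def test_vigorous_signal_is_all_wear(self):
        mask = detect_nonwear(active_recording(3 * 3600, amp=0.3))
        assert not mask.block_nonwear.any()

    def test_one_still_axis_is_still_wear(self):
        # movement on two axes only: just 1 of 3 axes below threshold
        mask = detect_nonwear(active_recording(3 * 3600, amp=0.3, axes=(0, 1)))
        assert not mask.block_nonwear.any()

    def test_two_still_axes_is_nonwear(self):
        mask = detect_nonwear(active_recording(3 * 3600, amp=0.3, axes=(0,)))
        assert mask.block_nonwear.all()

    def test_sd_exactly_at_threshold_counts_as_wear(self):
        # square wave of +/-13 mg has SD exactly 13 mg (strict < rule)
        n = int(3 * 3600 * 30)
        samples = np.zeros((n, 3))
        samples[:, 2] = 1.0
        square = np.where(np.arange(n) % 2 == 0, 0.013, -0.013)
        samples[:, 0] += square
        samples[:, 1] += square
        # ranges are 26 mg < 50 on two axes -> range rule still fires; widen it
        samples[::7, 0] += 0.05
        samples[::11, 1] -= 0.05
        mask = detect_nonwear(make_recording(samples))
        assert not mask.block_nonwear.any()


class TestDetectClipping:
    def test_normal_signal_unflagged(self):
        rec = constant_recording((0, 0, 1.2), 60)
        assert not detect_clipping(rec).any()

    def test_single_spike_flags_only_its_epoch(self):
        samples = np.tile([0.0, 0.0, 1.0], (30 * 60, 1))
        samples[30 * 17] = [0.0, 0.0, 5.9]
        flags = detect_clipping(make_recording(samples))
        assert flags.sum() == 1
        assert flags[3]  # 17 s -> epoch index 3

    def test_exactly_at_limit_is_not_flagged(self):
        rec = constant_recording((0, 0, 5.5), 60)
        assert not detect_clipping(rec, limit=5.5).any()
        rec_above = constant_recording((0, 0, 5.5001), 60)
        assert detect_clipping(rec_above, limit=5.5).all()


def _series(values, start="2019-01-07", pid="P01"):
    return EpochSeries(
        participant_id=pid, site="non_dominant_wrist", metric_name="ENMO",
        start_time=pd.Timestamp(start), values=np.asarray(values, float),
    )


def _mask(n_epochs, nonwear_blocks=(), clipped_epochs=(), start="2019-01-07"):
    n_blocks = int(np.ceil(n_epochs / 180))
    blocks = np.zeros(n_blocks, bool)
    blocks[list(nonwear_blocks)] = True
    clipped = np.zeros(n_epochs, bool)
    clipped[list(clipped_epochs)] = True
    return NonwearMask(pd.Timestamp(start), blocks, clipped)


class TestImputation:
    EPD = 17280  # 5-s epochs per day

    def test_donor_mean_at_same_clock_time(self):
        n = 7 * self.EPD
        values = np.zeros(n)
        slot = 7200  # 10:00:00
        donors = [10, 20, 30, 40, 50, 60]
        di = 0
        for day in range(7):
            if day == 3:
                continue
            values[day * self.EPD + slot] = donors[di]
            di += 1
        bad_block = (3 * self.EPD + slot) // 180
        series = impute_epochs(_series(values), _mask(n, nonwear_blocks=[bad_block]))
        assert series.values[3 * self.EPD + slot] == pytest.approx(35.0)
        assert series.imputed[3 * self.EPD + slot]

    def test_no_donor_stays_missing(self):
        n = 2 * self.EPD
        slot = 2880  # 04:00
        blocks = [slot // 180, (self.EPD + slot) // 180]
        series = impute_epochs(_series(np.ones(n)), _mask(n, nonwear_blocks=blocks))
        # the whole block has no valid donors on the other day
        assert np.isnan(series.values[slot : slot + 1]).all()
        assert not series.imputed[slot]

    def test_clean_series_unchanged(self):
        n = 2 * self.EPD
        values = np.arange(n, dtype=float)
        series = impute_epochs(_series(values), _mask(n))
        np.testing.assert_array_equal(series.values, values)
        assert not series.imputed.any()

    def test_valid_epoch_mean_preserved(self):
        rng = np.random.default_rng(0)
        n = 4 * self.EPD
        values = rng.uniform(0, 100, n)
        mask = _mask(n, nonwear_blocks=[10, 200])
        series = impute_epochs(_series(values), mask)
        valid = mask.epoch_valid
        np.testing.assert_allclose(
            series.values[valid], values[valid], atol=1e-12
        )


class TestWearSummary:
    def _segmentation(self, n_days, pid="P01"):
        nights = [
            (pd.Timestamp("2019-01-07") + pd.Timedelta(days=d, hours=23),
             pd.Timestamp("2019-01-07") + pd.Timedelta(days=d + 1, hours=7))
            for d in range(n_days - 1)
        ]
        return DaySegmentation(pid, pd.Timestamp("2019-01-07"),
                               n_days * 17280, nights)

    def test_fully_worn_week_included(self):
        n = 7 * 17280
        summary = summarize_wear({"hip": _mask(n)}, self._segmentation(7))
        assert summary.included
        assert (summary.per_day["wear_h"] == 24.0).all()

    def test_three_valid_days_excluded(self):
        n = 7 * 17280
        blocks = []
        for day in range(4):  # ruin 4 of 7 days -> only 3 valid
            blocks.extend(range(day * 96, day * 96 + 40))  # 10 h nonwear
        summary = summarize_wear(
            {"hip": _mask(n, nonwear_blocks=blocks)}, self._segmentation(7)
        )
        assert int(summary.valid_days.sum()) == 3
        assert not summary.included

    def test_daily_shower_keeps_days_valid(self):
        n = 7 * 17280
        blocks = []
        for day in range(7):  # 2-h gap each day
            blocks.extend(range(day * 96 + 40, day * 96 + 48))
        summary = summarize_wear(
            {"hip": _mask(n, nonwear_blocks=blocks)}, self._segmentation(7)
        )
        assert (summary.per_day["wear_h"] == 22.0).all()
        assert summary.included
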