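"""Diary-guided separation of waking and sleeping hours.

The detector runs on the *non-dominant wrist* only and is then projected
onto the other sites of the same participant.  It is a posture-angle
heuristic: the arm-to-vertical angle computed from the smoothed tri-axial
signal is nearly constant while asleep, so sustained periods of small
successive angle change inside a diary-guided search window mark the sleep
period.  The constants (5 degree change threshold, 5-min minimum block,
60-min merge gap, +/-2 h diary expansion) are configuration knobs; the
detector is a faithful-in-spirit stand-in for validated wrist sleep
algorithms of this family, not a re-implementation of any specific one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import DEFAULT_EPOCH_S, DiaryNight, EpochSeries, RawRecording, SleepDiary, epoch_align


@dataclass
class AngleSeries:
    """Arm elevation angle (degrees, in [-90, 90]) per 5-s step."""

    participant_id: str
    site: str
    start_time: pd.Timestamp
    values: np.ndarray
    epoch_length: float = DEFAULT_EPOCH_S

    @property
    def n_epochs(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=self.n_epochs,
                             freq=pd.Timedelta(seconds=self.epoch_length))


@dataclass
class DaySegmentation:
    """Detected sleep periods and per-epoch wake/sleep labels.

    The segmentation always originates from the non-dominant wrist and is
    applied verbatim to the co-worn sites.
    """

    participant_id: str
    start_time: pd.Timestamp
    n_epochs: int
    nights: list[tuple[pd.Timestamp, pd.Timestamp]]
    epoch_length: float = DEFAULT_EPOCH_S
    source: str = "non_dominant_wrist"

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        for onset, wake in self.nights:
            if wake <= onset:
                raise ValueError("sleep onset must precede wake time")

    @property
    def labels(self) -> np.ndarray:
        labels = np.full(self.n_epochs, "wake", dtype=object)
        for onset, wake in self.nights:
            i0 = int(np.ceil((onset - self.start_time).total_seconds() / self.epoch_length))
            i1 = int(np.ceil((wake - self.start_time).total_seconds() / self.epoch_length))
            labels[max(i0, 0): max(i1, 0)] = "sleep"
        return labels

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"date": onset.normalize(), "onset": onset, "wake": wake, "source": self.source}
             for onset, wake in self.nights]
        )


def z_angle(rec: RawRecording, smooth: float = DEFAULT_EPOCH_S,
            median_steps: int = 1) -> AngleSeries:
    """Arm elevation angle per 5-s step.

    Axes are smoothed over each ``smooth``-second step (which also rejects
    sample-level noise the way a short rolling median would) before
    computing ``atan(z / sqrt(x^2 + y^2))`` in degrees; an optional
    ``median_steps``-step rolling median adds further smoothing across
    steps.
    """
    t0, epochs, _, _ = epoch_align(rec, smooth)
    means = epochs.mean(axis=1, dtype=np.float64)
    if median_steps > 1:
        means = ndimage.median_filter(means, size=(median_steps, 1), mode="nearest")
    x, y, z = means.T
    angle = np.degrees(np.arctan2(z, np.sqrt(x ** 2 + y ** 2)))
    return AngleSeries(
        participant_id=rec.participant_id,
        site=rec.site,
        start_time=t0,
        values=angle,
        epoch_length=smooth,
    )


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    if flags.size == 0:
        return []
    padded = np.diff(np.concatenate([[0], flags.view(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts, stops))


def detect_sleep_period(
    angles: AngleSeries,
    night: DiaryNight,
    angle_threshold: float = 5.0,
    min_block: float = 5.0,
    merge_gap: float = 60.0,
    search_expand: float = 2.0,
) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Detect (onset, wake) for one diary night.

    Candidate sleep = runs of successive absolute angle change below
    ``angle_threshold`` degrees sustained for at least ``min_block``
    minutes, within the diary interval expanded by ``search_expand`` hours;
    candidates separated by less than ``merge_gap`` minutes are merged and
    the longest merged block wins.  With no candidate the diary times are
    returned unchanged, with a warning.
    """
    dt = angles.epoch_length
    lo_t = night.bed - pd.Timedelta(hours=search_expand)
    hi_t = night.rise + pd.Timedelta(hours=search_expand)
    t0 = angles.start_time
    lo = max(0, int((lo_t - t0).total_seconds() // dt))
    hi = min(angles.n_epochs, int(np.ceil((hi_t - t0).total_seconds() / dt)))
    if hi - lo < 2:
        raise ValueError("angle series does not cover the diary night")
    a = angles.values[lo:hi]
    still = np.abs(np.diff(a)) < angle_threshold  # step i -> i+1

    min_steps = int(round(min_block * 60 / dt))
    candidates = [(s, e) for s, e in _runs(still) if e - s >= min_steps]
    if not candidates:
        warnings.warn(
            f"no sustained still period found for night of {night.date.date()}; "
            "falling back to diary times",
            stacklevel=2,
        )
        return night.bed, night.rise

    gap_steps = int(round(merge_gap * 60 / dt))
    merged = [list(candidates[0])]
    for s, e in candidates[1:]:
        if s - merged[-1][1] < gap_steps:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    s, e = max(merged, key=lambda r: r[1] - r[0])
    onset = t0 + pd.Timedelta(seconds=(lo + s) * dt)
    wake = t0 + pd.Timedelta(seconds=(lo + e + 1) * dt)
    return onset, wake


def segment_days(
    angles: AngleSeries,
    diary: SleepDiary,
    **detect_kwargs,
) -> DaySegmentation:
    """Detect one sleep period per diary night and build epoch labels."""
    nights = []
    for entry in diary:
        onset, wake = detect_sleep_period(angles, entry, **detect_kwargs)
        nights.append((onset, wake))
    return DaySegmentation(
        participant_id=angles.participant_id,
        start_time=angles.start_time,
        n_epochs=angles.n_epochs,
        nights=nights,
        epoch_length=angles.epoch_length,
        source=angles.site,
    )


def apply_segmentation(seg: DaySegmentation, series: EpochSeries) -> EpochSeries:
    """Label a series (any site) with the non-dominant wrist segmentation.

    The series must share the segmentation's epoch grid exactly; a span
    mismatch is an error rather than a silent partial projection.
    """
    if (
        series.n_epochs != seg.n_epochs
        or series.start_time != seg.start_time
        or series.epoch_length != seg.epoch_length
    ):
        raise ValueError(
            f"epoch grid of {series.site} series ({series.n_epochs} epochs from "
            f"{series.start_time}) does not match segmentation span"
        )
    out = series.copy()
    out.labels = seg.labels
    return out
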