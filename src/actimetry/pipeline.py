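"""End-to-end processing convenience layer.

Chains the per-module operations the way a study would run them: raw
signal -> auto-calibration -> epoch metrics -> non-wear detection and
imputation -> diary-guided sleep segmentation on the non-dominant wrist,
projected to every site -> daily intensity minutes -> cut-point
translation grid.  Each stage stays available separately; this module only
wires defaults together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import agreement, calibration, metrics, nonwear, sleep
from .io import EpochSeries, RawRecording, SleepDiary


@dataclass
class ProcessedRecording:
    """Per-recording outputs of the standard processing chain."""

    recording: RawRecording
    series: dict[str, EpochSeries]
    mask: nonwear.NonwearMask
    calibration_params: calibration.CalibrationParams | None = None


def process_recording(
    rec: RawRecording,
    counts: EpochSeries | None = None,
    calibrate: bool = True,
    metric_cfg: metrics.MetricConfig | None = None,
) -> ProcessedRecording:
    """Calibrate, compute epoch metrics, detect non-wear and impute."""
    params = None
    if calibrate and not rec.calibrated:
        rec, params = calibration.calibrate(rec)
    series = metrics.compute_all_metrics(rec, metric_cfg, counts=counts)
    mask = nonwear.detect_nonwear(rec)
    series = {name: nonwear.impute_epochs(s, mask) for name, s in series.items()}
    return ProcessedRecording(recording=rec, series=series, mask=mask,
                              calibration_params=params)


def segment_from_nondominant(
    nondom_rec: RawRecording, diary: SleepDiary
) -> sleep.DaySegmentation:
    """Detect the waking/sleeping split on the non-dominant wrist."""
    angles = sleep.z_angle(nondom_rec)
    return sleep.segment_days(angles, diary)


@dataclass
class TranslationResult:
    """Cut-point translation outputs on one calibration cohort."""

    reports: list[agreement.AgreementReport]
    selected: agreement.CutPointSet
    reference: agreement.CutPointSet
    table: pd.DataFrame = field(repr=False)


def translate_cutpoints(
    ref_series: list[EpochSeries],
    dom_series: list[EpochSeries],
    reference: agreement.CutPointSet = agreement.REFERENCE_CUTPOINTS,
    increments=(0.0, 5.0, 10.0),
    min_wear_hours: float = 16.0,
) -> TranslationResult:
    """Grid-search dominant-wrist thresholds against the reference wrist.

    Both series lists must be labeled ENMO epoch series (one per
    participant) from the same cohort.
    """
    ref_minutes = agreement.cohort_category_minutes(ref_series, reference, min_wear_hours)
    reports = agreement.evaluate_grid(
        ref_minutes, dom_series, reference, increments, min_wear_hours
    )
    selected = agreement.select_cutpoints(reports, reference)
    return TranslationResult(
        reports=reports,
        selected=selected,
        reference=reference,
        table=agreement.reports_to_frame(reports),
    )
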