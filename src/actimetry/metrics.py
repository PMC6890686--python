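"""Epoch-level acceleration signal aggregation metrics.

Three metrics summarise body movement per 5-s epoch of a calibrated
tri-axial signal, all expressed in milli-g:

* **ENMO** — Euclidean norm of each sample minus 1 g, negatives truncated
  to zero *before* averaging over the epoch.
* **LFENMO** — ENMO of the low-pass filtered signal (4th-order Butterworth,
  20 Hz cutoff, applied per axis).
* **MAD** — mean absolute deviation of the vector norm around its epoch
  mean (mean amplitude deviation).

Vendor activity counts are never computed here (the band-pass specifics are
proprietary); they are imported as epoch files and merely carried along so
that all four metrics share the same wear/imputation processing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import DEFAULT_EPOCH_S, EpochSeries, RawRecording, epoch_align


@dataclass
class MetricConfig:
    """Tunable constants of the epoch metrics.

    ``zero_phase`` selects forward-backward (phase-free) Butterworth
    filtering for LFENMO; single-pass filtering is available behind the
    same switch since the phase convention is an open choice.
    """

    epoch_length: float = DEFAULT_EPOCH_S
    lowpass_order: int = 4
    lowpass_cutoff: float = 20.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.epoch_length <= 0 or self.lowpass_cutoff <= 0 or self.lowpass_order < 1:
            raise ValueError("invalid metric configuration")


def _check_calibrated(rec: RawRecording) -> None:
    if not rec.calibrated:
        warnings.warn(
            f"computing epoch metrics on an uncalibrated recording "
            f"({rec.participant_id}/{rec.site})",
            stacklevel=3,
        )


def _epoch_series(rec: RawRecording, name: str, values_mg: np.ndarray,
                  t0, epoch_length: float) -> EpochSeries:
    return EpochSeries(
        participant_id=rec.participant_id,
        site=rec.site,
        metric_name=name,
        start_time=t0,
        values=values_mg,
        epoch_length=epoch_length,
    )


def _enmo_from_epochs(epochs: np.ndarray) -> np.ndarray:
    # epochs: (n, spe, 3) in g -> per-epoch ENMO in mg
    norms = np.linalg.norm(epochs, axis=2)
    return np.maximum(norms - 1.0, 0.0).mean(axis=1, dtype=np.float64) * 1000.0


def enmo(rec: RawRecording, cfg: MetricConfig | None = None) -> EpochSeries:
    """Euclidean norm minus one g, negatives to zero, epoch-averaged (mg)."""
    cfg = cfg or MetricConfig()
    _check_calibrated(rec)
    t0, epochs, _, _ = epoch_align(rec, cfg.epoch_length)
    return _epoch_series(rec, "ENMO", _enmo_from_epochs(epochs), t0, cfg.epoch_length)


def lowpass(samples: np.ndarray, sampling_rate: float, cfg: MetricConfig) -> np.ndarray:
    """Per-axis Butterworth low-pass; returns the input unchanged (with a
    warning) when the cutoff is at or above the Nyquist frequency."""
    if cfg.lowpass_cutoff >= sampling_rate / 2.0:
        warnings.warn(
            f"low-pass cutoff {cfg.lowpass_cutoff} Hz at/above Nyquist for "
            f"{sampling_rate} Hz sampling; filter skipped",
            stacklevel=3,
        )
        return samples
    sos = signal.butter(
        cfg.lowpass_order, cfg.lowpass_cutoff, btype="low", fs=sampling_rate, output="sos"
    )
    if cfg.zero_phase:
        return signal.sosfiltfilt(sos, samples, axis=0)
    return signal.sosfilt(sos, samples, axis=0)


def lfenmo(rec: RawRecording, cfg: MetricConfig | None = None) -> EpochSeries:
    """ENMO of the low-pass filtered signal (mg)."""
    cfg = cfg or MetricConfig()
    _check_calibrated(rec)
    filtered = lowpass(rec.samples, rec.sampling_rate, cfg)
    # re-wrap so grid alignment logic is shared with enmo
    tmp = RawRecording(
        participant_id=rec.participant_id,
        site=rec.site,
        start_time=rec.start_time,
        sampling_rate=rec.sampling_rate,
        samples=np.clip(filtered, -rec.dynamic_range, rec.dynamic_range),
        dynamic_range=rec.dynamic_range,
        calibrated=rec.calibrated,
    )
    t0, epochs, _, _ = epoch_align(tmp, cfg.epoch_length)
    return _epoch_series(rec, "LFENMO", _enmo_from_epochs(epochs), t0, cfg.epoch_length)


def mad(rec: RawRecording, cfg: MetricConfig | None = None) -> EpochSeries:
    """Mean amplitude deviation of the vector norm per epoch (mg)."""
    cfg = cfg or MetricConfig()
    _check_calibrated(rec)
    t0, epochs, _, _ = epoch_align(rec, cfg.epoch_length)
    norms = np.linalg.norm(epochs, axis=2).astype(np.float64)
    dev = np.abs(norms - norms.mean(axis=1, keepdims=True))
    return _epoch_series(rec, "MAD", dev.mean(axis=1) * 1000.0, t0, cfg.epoch_length)


def compute_all_metrics(
    rec: RawRecording,
    cfg: MetricConfig | None = None,
    counts: EpochSeries | None = None,
) -> dict[str, EpochSeries]:
    """Compute ENMO, LFENMO and MAD; attach imported counts unchanged.

    ``counts``, when given, must sit on the identical epoch grid so all
    four metrics can share downstream wear/imputation processing.
    """
    cfg = cfg or MetricConfig()
    out = {
        "ENMO": enmo(rec, cfg),
        "LFENMO": lfenmo(rec, cfg),
        "MAD": mad(rec, cfg),
    }
    if counts is not None:
        ref = out["ENMO"]
        if (
            counts.n_epochs != ref.n_epochs
            or counts.start_time != ref.start_time
            or counts.epoch_length != ref.epoch_length
        ):
            raise ValueError(
                f"counts grid ({counts.n_epochs} epochs from {counts.start_time}) "
                f"misaligned with metric grid ({ref.n_epochs} from {ref.start_time})"
            )
        out["counts"] = counts
    return out
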