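"""Auto-calibration of raw acceleration to local gravity.

During still periods the measured vector should have norm exactly 1 g in
any orientation.  Systematic deviations are modelled as a per-axis gain and
offset, estimated by iteratively regressing still-window mean vectors onto
their closest points on the unit sphere.  The fit requires orientation
diversity (window means beyond +/-300 mg on both sides of every axis);
when coverage fails the identity calibration is returned with a warning so
downstream metrics stay reproducible rather than silently part-corrected.

Temperature covariates used by some devices are deliberately omitted: the
raw exports handled here carry no temperature channel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io import RawRecording

G_TO_MG = 1000.0


@dataclass
class StillWindowSet:
    """Mean vectors (g) and per-axis SDs of detected still windows."""

    means: np.ndarray  # (n, 3) g
    sds: np.ndarray    # (n, 3) g
    window_length: float

    @property
    def n_windows(self) -> int:
        return int(self.means.shape[0])


@dataclass
class CalibrationParams:
    """Per-axis offset (g) and gain mapping raw -> calibrated samples.

    Calibrated = raw * gain + offset.  ``error_before``/``error_after`` are
    the mean absolute deviation of still-window norms from 1 g, in mg.
    """

    offset: np.ndarray
    gain: np.ndarray
    error_before: float
    error_after: float
    n_windows: int
    sphere_coverage_ok: bool

    def __post_init__(self) -> None:
        self.offset = np.asarray(self.offset, dtype=float).reshape(3)
        self.gain = np.asarray(self.gain, dtype=float).reshape(3)
        if (self.gain <= 0).any():
            raise ValueError("gains must be positive")

    @classmethod
    def identity(cls, error: float = float("nan"), n_windows: int = 0,
                 coverage: bool = False) -> "CalibrationParams":
        return cls(np.zeros(3), np.ones(3), error, error, n_windows, coverage)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return bool(np.all(np.abs(self.offset) <= tol) and np.all(np.abs(self.gain - 1) <= tol))

    def to_dict(self) -> dict:
        return {
            "offset_g": self.offset.tolist(),
            "gain": self.gain.tolist(),
            "error_before_mg": self.error_before,
            "error_after_mg": self.error_after,
            "n_windows": self.n_windows,
            "sphere_coverage_ok": self.sphere_coverage_ok,
        }


def find_still_windows(
    rec: RawRecording,
    window: float = 10.0,
    sd_threshold: float = 13.0,
) -> StillWindowSet:
    """Non-overlapping ``window``-second segments still on *all three* axes.

    The stillness criterion (per-axis SD below ``sd_threshold`` mg) is
    stricter than the 2-of-3-axes non-wear rule on purpose: calibration
    needs genuinely static windows.  May return an empty set.
    """
    spw = int(round(window * rec.sampling_rate))
    if rec.n_samples < spw:
        raise ValueError("recording shorter than one still window")
    n = rec.n_samples // spw
    seg = rec.samples[: n * spw].reshape(n, spw, 3)
    means = seg.mean(axis=1, dtype=np.float64)
    sds = seg.std(axis=1, dtype=np.float64)
    keep = (sds < sd_threshold / G_TO_MG).all(axis=1)
    return StillWindowSet(means=means[keep], sds=sds[keep], window_length=window)


def _sphere_error_mg(points: np.ndarray) -> float:
    return float(np.abs(np.linalg.norm(points, axis=1) - 1.0).mean() * G_TO_MG)


def estimate_calibration(
    windows: StillWindowSet,
    max_iter: int = 1000,
    tol: float = 1e-6,
    coverage_mg: float = 300.0,
) -> CalibrationParams:
    """Fit per-axis offset and gain bringing still windows onto the unit sphere.

    Iteratively reweighted least squares: at each pass every window mean is
    projected to its closest point on the unit sphere and each axis is
    regressed (with intercept) onto that target.  Iteration stops when the
    calibration error improves by less than ``tol`` mg or after
    ``max_iter`` passes; the error is non-increasing by construction
    (the best-so-far parameters are kept).

    Sphere coverage requires window means at or beyond +/-``coverage_mg``
    on every axis; without it the identity calibration is returned with
    ``sphere_coverage_ok=False``.
    """
    if windows.n_windows == 0:
        raise ValueError("cannot calibrate from an empty still-window set")
    pts = windows.means
    error_before = _sphere_error_mg(pts)
    cov = coverage_mg / G_TO_MG
    coverage = bool(
        np.all(pts.min(axis=0) <= -cov) and np.all(pts.max(axis=0) >= cov)
    )
    if not coverage:
        warnings.warn(
            "insufficient orientation coverage for auto-calibration; "
            "returning identity parameters",
            stacklevel=2,
        )
        return CalibrationParams.identity(error_before, windows.n_windows, False)

    offset = np.zeros(3)
    gain = np.ones(3)
    best = (error_before, offset.copy(), gain.copy())
    for _ in range(max_iter):
        cal = pts * gain + offset
        norms = np.linalg.norm(cal, axis=1)
        target = cal / norms[:, None]
        # per-axis weighted LSQ of target on raw points; windows closer to
        # the sphere get slightly more weight
        w = 1.0 / np.maximum(np.abs(norms - 1.0), 1e-3)
        sw = np.sqrt(w)
        for ax in range(3):
            A = np.column_stack([pts[:, ax] * sw, sw])
            b = target[:, ax] * sw
            coef, *_ = np.linalg.lstsq(A, b, rcond=None)
            gain[ax], offset[ax] = coef
        err = _sphere_error_mg(pts * gain + offset)
        if err < best[0]:
            improved = best[0] - err
            best = (err, offset.copy(), gain.copy())
            if improved < tol:
                break
        else:
            break
    error_after, offset, gain = best
    return CalibrationParams(
        offset=offset,
        gain=gain,
        error_before=error_before,
        error_after=min(error_after, error_before),
        n_windows=windows.n_windows,
        sphere_coverage_ok=True,
    )


def apply_calibration(rec: RawRecording, params: CalibrationParams) -> RawRecording:
    """Return a calibrated copy (sample -> sample * gain + offset).

    Reapplying to an already-calibrated recording is an error: calibration
    is a one-shot correction, not an idempotent transform.
    """
    if rec.calibrated:
        raise ValueError(
            f"recording {rec.participant_id}/{rec.site} is already calibrated"
        )
    cal = rec.samples * params.gain + params.offset
    cal = np.clip(cal, -rec.dynamic_range, rec.dynamic_range)
    return replace(rec, samples=cal, calibrated=True)


def calibrate(
    rec: RawRecording,
    window: float = 10.0,
    sd_threshold: float = 13.0,
    **estimate_kwargs,
) -> tuple[RawRecording, CalibrationParams]:
    """Convenience wrapper: find still windows, estimate, apply."""
    windows = find_still_windows(rec, window=window, sd_threshold=sd_threshold)
    if windows.n_windows == 0:
        warnings.warn("no still windows found; skipping calibration", stacklevel=2)
        params = CalibrationParams.identity()
    else:
        params = estimate_calibration(windows, **estimate_kwargs)
    return apply_calibration(rec, params), params
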