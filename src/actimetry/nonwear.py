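"""Non-wear detection, clipping detection, imputation and wear summaries.

Non-wear is detected on the raw signal: each 15-min block is classified as
non-wear when, over the surrounding 60-min window (centred on the block,
truncated at the recording edges), at least 2 of the 3 axes have a standard
deviation strictly below 13 mg, or at least 2 of the 3 axes have a value
range strictly below 50 mg.  Sustained abnormal accelerations (any sample
strictly above 5.5 g) flag their epoch as invalid and are routed through
the same imputation path.

Invalid epochs are imputed with the mean of valid epochs at the same clock
time on the other recorded days; epochs with no valid same-time donor stay
missing (NaN) and are excluded from summaries.  Days with >=16 h of wear
are valid; participants with >=4 valid days are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DEFAULT_EPOCH_S, EpochSeries, RawRecording, SECONDS_PER_DAY, epoch_align

MG = 1000.0  # mg per g


@dataclass
class NonwearMask:
    """Block-level wear classification plus per-epoch clipping flags."""

    start_time: pd.Timestamp
    block_nonwear: np.ndarray       # (n_blocks,) bool
    epoch_clipped: np.ndarray       # (n_epochs,) bool
    epoch_length: float = DEFAULT_EPOCH_S
    block_length: float = 900.0

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.block_nonwear = np.asarray(self.block_nonwear, dtype=bool)
        self.epoch_clipped = np.asarray(self.epoch_clipped, dtype=bool)
        epb = self.block_length / self.epoch_length
        if abs(epb - round(epb)) > 1e-9:
            raise ValueError("block grid must align to the epoch grid")

    @property
    def n_epochs(self) -> int:
        return int(self.epoch_clipped.size)

    @property
    def epochs_per_block(self) -> int:
        return int(round(self.block_length / self.epoch_length))

    @property
    def epoch_wear(self) -> np.ndarray:
        """Per-epoch wear flag expanded from the block classification."""
        wear = np.repeat(~self.block_nonwear, self.epochs_per_block)
        return wear[: self.n_epochs]

    @property
    def epoch_valid(self) -> np.ndarray:
        """Worn and not clipped: epochs whose values are trustworthy."""
        return self.epoch_wear & ~self.epoch_clipped

    def to_frame(self) -> pd.DataFrame:
        starts = pd.date_range(
            self.start_time,
            periods=self.block_nonwear.size,
            freq=pd.Timedelta(seconds=self.block_length),
        )
        return pd.DataFrame({"block_start": starts, "nonwear": self.block_nonwear.astype(int)})


def detect_nonwear(
    rec: RawRecording,
    sd_threshold: float = 13.0,
    range_threshold: float = 50.0,
    block: float = 15.0,
    window: float = 60.0,
    clip_limit: float = 5.5,
) -> NonwearMask:
    """Classify 15-min blocks as wear/non-wear from raw-signal variability.

    Parameters are in the units of the rule: mg thresholds, minutes for the
    block and moving-window lengths.  Ties at exactly a threshold count as
    wear (the criteria are strict ``<``).  Clipping flags are computed in
    the same pass (see :func:`detect_clipping`).
    """
    t0, epochs, n_ep, spe = epoch_align(rec)
    epb = int(round(block * 60 / DEFAULT_EPOCH_S))
    wpb = int(round(window * 60 / DEFAULT_EPOCH_S))
    half = wpb // 2
    n_blocks = int(np.ceil(n_ep / epb))

    # per-epoch sufficient statistics, per axis (float64: long cumsums)
    s1 = epochs.sum(axis=1, dtype=np.float64)     # (n_ep, 3)
    s2 = (epochs.astype(np.float64) ** 2).sum(axis=1)
    emin = epochs.min(axis=1)
    emax = epochs.max(axis=1)
    c1 = np.vstack([np.zeros(3), np.cumsum(s1, axis=0)])
    c2 = np.vstack([np.zeros(3), np.cumsum(s2, axis=0)])

    sd_thr = sd_threshold / MG
    rng_thr = range_threshold / MG
    flags = np.zeros(n_blocks, dtype=bool)
    for b in range(n_blocks):
        centre = min(b * epb + epb // 2, n_ep)
        lo = max(0, centre - half)
        hi = min(n_ep, centre + half)
        n = (hi - lo) * spe
        mean = (c1[hi] - c1[lo]) / n
        var = np.maximum((c2[hi] - c2[lo]) / n - mean ** 2, 0.0)
        sd = np.sqrt(var)
        rng = emax[lo:hi].max(axis=0) - emin[lo:hi].min(axis=0)
        flags[b] = (sd < sd_thr).sum() >= 2 or (rng < rng_thr).sum() >= 2

    clipped = detect_clipping(rec, limit=clip_limit)
    return NonwearMask(start_time=t0, block_nonwear=flags, epoch_clipped=clipped)


def detect_clipping(rec: RawRecording, limit: float = 5.5) -> np.ndarray:
    """Per-epoch flags for sustained abnormal accelerations.

    An epoch is flagged when any of its samples has an absolute per-axis
    value or vector norm strictly above ``limit`` g (a sample at exactly
    the limit does not flag).
    """
    _, epochs, _, _ = epoch_align(rec)
    axis_hit = (np.abs(epochs) > limit).any(axis=(1, 2))
    norm_hit = (np.linalg.norm(epochs, axis=2) > limit).any(axis=1)
    return axis_hit | norm_hit


def impute_epochs(series: EpochSeries, mask: NonwearMask) -> EpochSeries:
    """Impute invalid epochs from the same clock time on other days.

    Each non-wear or clipped epoch receives the mean of *valid* epochs at
    the identical time-of-day slot across the rest of the recording; with
    no valid donor the epoch stays NaN.  Valid epochs are untouched, so the
    per-slot cross-day mean of valid data is preserved by construction.
    """
    if series.n_epochs != mask.n_epochs or series.start_time != mask.start_time:
        raise ValueError("epoch series and non-wear mask are misaligned")
    out = series.copy()
    valid = mask.epoch_valid
    out.wear = mask.epoch_wear.copy()
    invalid = ~valid

    epd = int(round(SECONDS_PER_DAY / series.epoch_length))
    midnight = series.start_time.normalize()
    first = int(round((series.start_time - midnight).total_seconds() / series.epoch_length))
    slots = (first + np.arange(series.n_epochs)) % epd

    vals = out.values
    donor_ok = valid & np.isfinite(vals)
    sums = np.bincount(slots[donor_ok], weights=vals[donor_ok], minlength=epd)
    counts = np.bincount(slots[donor_ok], minlength=epd)
    with np.errstate(invalid="ignore"):
        donor_mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    fill = donor_mean[slots[invalid]]
    vals[invalid] = fill
    imputed = np.zeros(series.n_epochs, dtype=bool)
    imputed[invalid] = np.isfinite(fill)
    out.imputed = imputed
    return out


@dataclass
class WearSummary:
    """Per participant-day wear accounting and the inclusion decision.

    ``per_day`` has one row per (site, date) with wear hours over 24 h and
    split by waking/sleeping labels; a calendar day is valid when every
    site recorded >=16 h of wear, and the participant is included with >=4
    valid days.
    """

    per_day: pd.DataFrame
    valid_days: pd.Series  # indexed by date, combined across sites
    included: bool
    min_wear_hours: float = 16.0
    min_valid_days: int = 4


def summarize_wear(
    masks: dict[str, NonwearMask],
    segmentation,
    min_wear_hours: float = 16.0,
    min_valid_days: int = 4,
) -> WearSummary:
    """Aggregate wear hours per day and apply the inclusion rule.

    ``segmentation`` is a :class:`~actimetry.sleep.DaySegmentation` whose
    per-epoch wake/sleep labels are shared by all sites.  Unmatched
    non-wear across sites is deliberately *not* deleted; each site keeps
    its own wear record and only the validity decision is combined.
    """
    rows = []
    for site, mask in masks.items():
        if mask.n_epochs != segmentation.n_epochs or mask.start_time != segmentation.start_time:
            raise ValueError(f"mask for {site} misaligned with segmentation")
        wear = mask.epoch_wear
        sleep = segmentation.labels == "sleep"
        times = pd.DatetimeIndex(
            pd.date_range(mask.start_time, periods=mask.n_epochs,
                          freq=pd.Timedelta(seconds=mask.epoch_length))
        )
        days = times.normalize()
        h = mask.epoch_length / 3600.0
        df = pd.DataFrame({"date": days, "wear": wear, "sleep": sleep})
        grouped = df.groupby("date", sort=True)
        for date, g in grouped:
            w = g["wear"].to_numpy()
            s = g["sleep"].to_numpy()
            rows.append({
                "site": site,
                "date": date,
                "wear_h": w.sum() * h,
                "waking_wear_h": (w & ~s).sum() * h,
                "sleeping_wear_h": (w & s).sum() * h,
            })
    per_day = pd.DataFrame(rows)
    per_day["valid_day"] = per_day["wear_h"] >= min_wear_hours
    valid_days = per_day.groupby("date")["valid_day"].all()
    included = bool(valid_days.sum() >= min_valid_days)
    return WearSummary(
        per_day=per_day,
        valid_days=valid_days,
        included=included,
        min_wear_hours=min_wear_hours,
        min_valid_days=min_valid_days,
    )
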