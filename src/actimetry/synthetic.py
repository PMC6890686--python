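"""Synthetic tri-axial cohorts with known ground truth.

Every downstream stage of the pipeline is tested against recordings whose
truth is known by construction.  The signal model is deliberately simple
but statistically faithful to what the analysis assumes:

* gravity is a slowly wandering unit vector — an angular random walk while
  awake, frozen during sleep apart from sparse posture shifts, and frozen
  completely while the device is off the body;
* body movement is a zero-mean band-limited (0.5–4 Hz) sinusoid mixture
  *along* the gravity direction, rescaled per 5-s epoch so that the epoch
  ENMO of the noiseless signal equals the scheduled bout amplitude exactly
  — the generator's amplitude bookkeeping is the oracle for every
  classification test;
* the dominant wrist carries ``asymmetry_ratio`` times the non-dominant
  dynamic amplitude and the hip ``hip_attenuation`` times it, emulating
  the dominant > non-dominant > hip ordering of waking accelerations;
* white Gaussian sensor noise of ``noise_sd`` mg is added per axis and the
  result is clipped to the +/-6 g dynamic range.

The default *desk-scale profile* (30 Hz, a few days, a dozen participants
at most) keeps tests fast; 100 Hz is supported but not the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    DEFAULT_EPOCH_S,
    DiaryNight,
    RawRecording,
    SECONDS_PER_DAY,
    SITES,
    SleepDiary,
    samples_per_epoch,
    write_raw_csv,
    write_sleep_diary,
)
from .sleep import DaySegmentation

EPOCHS_PER_DAY = int(SECONDS_PER_DAY / DEFAULT_EPOCH_S)  # 17280

#: Reference intensity boundaries (mg) used to label scheduled bouts.
LABEL_CUTS = (45.0, 100.0, 430.0)
INTENSITY_LABELS = ("sedentary", "light", "moderate", "vigorous")


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort.

    Amplitude units are mg; ``asymmetry_ratio`` scales the dominant wrist's
    dynamic acceleration relative to the non-dominant wrist and
    ``hip_attenuation`` scales the hip's.
    """

    n_participants: int = 6
    n_days: int = 4
    sampling_rate: float = 30.0
    epoch_length: float = DEFAULT_EPOCH_S
    asymmetry_ratio: float = 1.1
    hip_attenuation: float = 0.6
    noise_sd: float = 5.0
    seed: int = 0
    sites: tuple[str, ...] = SITES
    start_date: str = "2019-01-07"
    # behavioural structure
    nonwear_rate: float = 0.3               # expected episodes per day
    nonwear_minutes: tuple[float, float] = (45.0, 150.0)
    bout_minutes: tuple[float, float] = (5.0, 40.0)
    amplitude_log_mu: float = float(np.log(20.0))
    amplitude_log_sigma: float = 1.15
    amplitude_range: tuple[float, float] = (3.0, 700.0)
    sleep_onset_h: float = 23.25
    sleep_wake_h: float = 7.25
    sleep_jitter_min: float = 30.0
    wake_drift_deg: float = 4.0             # angular step SD per 5-s step
    sleep_shift_gap_min: tuple[float, float] = (15.0, 40.0)
    sleep_shift_deg: tuple[float, float] = (30.0, 70.0)

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_days < 1:
            raise ValueError("need at least one participant and one day")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.asymmetry_ratio <= 0 or self.hip_attenuation <= 0:
            raise ValueError("site multipliers must be positive")
        if abs(60.0 % self.epoch_length) > 1e-9:
            raise ValueError("epoch_length must divide 60 s")
        samples_per_epoch(self.sampling_rate, self.epoch_length)
        for s in self.sites:
            if s not in SITES:
                raise ValueError(f"unknown site {s!r}")

    @property
    def start_time(self) -> pd.Timestamp:
        return pd.Timestamp(self.start_date)

    def site_multiplier(self, site: str) -> float:
        return {
            "dominant_wrist": self.asymmetry_ratio,
            "non_dominant_wrist": 1.0,
            "hip": self.hip_attenuation,
        }[site]


def intensity_label(amplitude_mg: float) -> str:
    """Ground-truth intensity class of a bout amplitude (non-dominant scale)."""
    return INTENSITY_LABELS[int(np.searchsorted(LABEL_CUTS, amplitude_mg, side="right"))]


@dataclass
class Bout:
    start_ep: int        # absolute 5-s epoch index from recording start
    n_ep: int
    amplitude_mg: float
    label: str


@dataclass
class ActivitySchedule:
    """Ground-truth daily structure for one participant.

    Bouts tile the whole recording (every epoch belongs to exactly one
    bout); non-wear episodes are listed separately and override the bout
    dynamics while they last; sleep windows are [onset, wake) epoch ranges.
    """

    participant_id: str
    seed: int
    n_days: int
    start_time: pd.Timestamp
    bouts: list[Bout]
    nonwear: list[tuple[int, int]]           # (start_ep, n_ep)
    sleep_windows: list[tuple[int, int]]     # (start_ep, end_ep)
    diary: SleepDiary

    @property
    def n_epochs(self) -> int:
        return self.n_days * EPOCHS_PER_DAY

    def validate(self) -> None:
        cursor = 0
        for b in sorted(self.bouts, key=lambda b: b.start_ep):
            if b.start_ep != cursor or b.n_ep < 1:
                raise ValueError("bouts must tile the recording without gaps/overlaps")
            cursor += b.n_ep
        if cursor != self.n_epochs:
            raise ValueError("bouts do not cover the full recording")
        for s, e in self.sleep_windows:
            if not (0 <= s < e <= self.n_epochs):
                raise ValueError("sleep window outside the recording")

    def epoch_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(target_mg, label, nonwear_mask) per epoch, non-dominant scale."""
        n = self.n_epochs
        target = np.zeros(n)
        label = np.empty(n, dtype=object)
        for b in self.bouts:
            sl = slice(b.start_ep, b.start_ep + b.n_ep)
            target[sl] = b.amplitude_mg
            label[sl] = b.label
        nonwear = np.zeros(n, dtype=bool)
        for s, ln in self.nonwear:
            nonwear[s : s + ln] = True
        target[nonwear] = 0.0
        label[nonwear] = "nonwear"
        return target, label, nonwear

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"start_ep": b.start_ep, "n_ep": b.n_ep,
             "amplitude_mg": b.amplitude_mg, "label": b.label}
            for b in self.bouts
        ]
        return pd.DataFrame(rows)


@dataclass
class SyntheticGroundTruth:
    """Everything a test needs to score the pipeline on one participant."""

    schedule: ActivitySchedule
    target_mg: np.ndarray
    epoch_labels: np.ndarray
    nonwear_mask: np.ndarray
    injected_calibration: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def segmentation(self) -> DaySegmentation:
        """True wake/sleep segmentation from the scheduled sleep windows."""
        sch = self.schedule
        nights = [
            (
                sch.start_time + pd.Timedelta(seconds=s * DEFAULT_EPOCH_S),
                sch.start_time + pd.Timedelta(seconds=e * DEFAULT_EPOCH_S),
            )
            for s, e in sch.sleep_windows
        ]
        return DaySegmentation(
            participant_id=sch.participant_id,
            start_time=sch.start_time,
            n_epochs=sch.n_epochs,
            nights=nights,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "participant_id": self.schedule.participant_id,
                "n_days": self.schedule.n_days,
                "sleep_windows_ep": [[int(a), int(b)] for a, b in self.schedule.sleep_windows],
                "nonwear_ep": [[int(a), int(b)] for a, b in self.schedule.nonwear],
                "injected_calibration": {
                    site: {"offset_g": off.tolist(), "gain": gain.tolist()}
                    for site, (off, gain) in self.injected_calibration.items()
                },
            },
            indent=1,
        )


@dataclass
class ParticipantData:
    participant_id: str
    recordings: dict[str, RawRecording]
    truth: SyntheticGroundTruth


# ---------------------------------------------------------------------------
# schedule generation
# ---------------------------------------------------------------------------

def _ep(minutes: float) -> int:
    return max(1, int(round(minutes * 60.0 / DEFAULT_EPOCH_S)))


def generate_schedule(spec: CohortSpec, index: int) -> ActivitySchedule:
    """Randomised but seed-deterministic daily structure for one participant."""
    rng = np.random.default_rng([spec.seed, 11, index])
    pid = f"P{index + 1:02d}"
    n_days, epd = spec.n_days, EPOCHS_PER_DAY
    jitter_ep = _ep(spec.sleep_jitter_min)

    wake_ep = np.clip(
        np.round(spec.sleep_wake_h * 720 + rng.normal(0, jitter_ep, n_days)),
        6.0 * 720, 9.0 * 720,
    ).astype(int)
    bed_ep = np.clip(
        np.round(spec.sleep_onset_h * 720 + rng.normal(0, jitter_ep, n_days)),
        21.5 * 720, epd - 120,
    ).astype(int)

    sleep_windows = [(0, wake_ep[0])]
    for d in range(n_days - 1):
        sleep_windows.append((d * epd + bed_ep[d], (d + 1) * epd + wake_ep[d + 1]))
    sleep_windows.append(((n_days - 1) * epd + bed_ep[n_days - 1], n_days * epd))

    bouts: list[Bout] = []
    for s, e in sleep_windows:
        bouts.append(Bout(s, e - s, float(rng.uniform(2.0, 8.0)), "sleep"))

    nonwear: list[tuple[int, int]] = []
    lo_a, hi_a = spec.amplitude_range
    for d in range(n_days):
        w_start = d * epd + wake_ep[d]
        w_end = d * epd + bed_ep[d]
        cur = w_start
        while cur < w_end:
            n_ep = min(_ep(rng.uniform(*spec.bout_minutes)), w_end - cur)
            amp = float(np.clip(rng.lognormal(spec.amplitude_log_mu,
                                              spec.amplitude_log_sigma), lo_a, hi_a))
            bouts.append(Bout(cur, n_ep, amp, intensity_label(amp)))
            cur += n_ep
        if rng.random() < spec.nonwear_rate:
            dur = _ep(rng.uniform(*spec.nonwear_minutes))
            if w_end - w_start > dur:
                start = int(rng.integers(w_start, w_end - dur))
                nonwear.append((start, dur))

    base = spec.start_time
    nights = []
    for d in range(n_days - 1):
        onset_ts = base + pd.Timedelta(seconds=sleep_windows[d + 1][0] * DEFAULT_EPOCH_S)
        wake_ts = base + pd.Timedelta(seconds=sleep_windows[d + 1][1] * DEFAULT_EPOCH_S)
        bed = (onset_ts - pd.Timedelta(minutes=abs(rng.normal(9, 5)))).round("min")
        rise = (wake_ts + pd.Timedelta(minutes=abs(rng.normal(17, 5)))).round("min")
        nights.append(DiaryNight(date=base + pd.Timedelta(days=d), bed=bed, rise=rise))

    schedule = ActivitySchedule(
        participant_id=pid,
        seed=int(rng.integers(0, 2**31 - 1)),
        n_days=n_days,
        start_time=base,
        bouts=sorted(bouts, key=lambda b: b.start_ep),
        nonwear=nonwear,
        sleep_windows=sleep_windows,
        diary=SleepDiary(nights=nights),
    )
    schedule.validate()
    return schedule


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _orientation_walk(schedule: ActivitySchedule, spec: CohortSpec,
                      state: np.ndarray, site_idx: int) -> np.ndarray:
    """Per-epoch gravity unit vectors: random walk awake, frozen asleep
    (apart from posture shifts) and during non-wear."""
    rng = np.random.default_rng([schedule.seed, 201, site_idx])
    n = schedule.n_epochs
    step = np.radians(spec.wake_drift_deg)
    awake = state == 0
    dtheta = np.where(awake, rng.normal(0, step, n), 0.0)
    dphi = np.where(awake, rng.normal(0, step, n), 0.0)

    lo_g, hi_g = spec.sleep_shift_gap_min
    lo_s, hi_s = spec.sleep_shift_deg
    for s, e in schedule.sleep_windows:
        t = s + _ep(rng.uniform(lo_g, hi_g))
        while t < e:
            mag_t = np.radians(rng.uniform(lo_s, hi_s))
            mag_p = np.radians(rng.uniform(lo_s, hi_s))
            dtheta[t] += rng.choice((-1.0, 1.0)) * mag_t
            dphi[t] += rng.choice((-1.0, 1.0)) * mag_p
            t += _ep(rng.uniform(lo_g, hi_g))

    theta = np.arccos(rng.uniform(-1, 1)) + np.cumsum(dtheta)
    phi = rng.uniform(0, 2 * np.pi) + np.cumsum(dphi)
    st = np.sin(theta)
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def generate_recording(schedule: ActivitySchedule, site: str, spec: CohortSpec) -> RawRecording:
    """Synthesize one device's raw signal from a schedule.

    The noiseless per-epoch ENMO equals the scheduled bout amplitude times
    the site multiplier exactly (the dynamic component is rescaled per
    epoch), which makes the schedule the ground-truth oracle for every
    downstream metric and classification test.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}")
    if site not in spec.sites:
        raise ValueError(f"site {site!r} not part of this cohort spec")
    site_idx = SITES.index(site)
    mult = spec.site_multiplier(site)
    spe = samples_per_epoch(spec.sampling_rate, DEFAULT_EPOCH_S)
    fs = spec.sampling_rate
    n_ep = schedule.n_epochs

    target, _, nonwear = schedule.epoch_arrays()
    state = np.zeros(n_ep, dtype=np.int8)
    for s, e in schedule.sleep_windows:
        state[s:e] = 1
    state[nonwear] = 2

    gvec = _orientation_walk(schedule, spec, state, site_idx)

    target_g = target * mult / 1000.0
    s_signal = np.zeros(n_ep * spe, dtype=np.float32)
    f_hi = min(4.0, 0.4 * fs)
    for bi, b in enumerate(schedule.bouts):
        if b.amplitude_mg <= 0:
            continue
        wrng = np.random.default_rng([schedule.seed, 301, bi])
        n_samp = b.n_ep * spe
        t = (b.start_ep * spe + np.arange(n_samp)) / fs
        wave = np.zeros(n_samp)
        for _ in range(2):
            f = wrng.uniform(0.5, f_hi)
            a = wrng.uniform(0.5, 1.0)
            ph = wrng.uniform(0, 2 * np.pi)
            wave += a * np.sin(2 * np.pi * f * t + ph)
        wave = wave.reshape(b.n_ep, spe)
        pos = np.maximum(wave, 0.0).mean(axis=1)
        tgt = target_g[b.start_ep : b.start_ep + b.n_ep]
        scale = np.where(tgt > 0, tgt / np.maximum(pos, 1e-12), 0.0)
        s_signal[b.start_ep * spe : (b.start_ep + b.n_ep) * spe] = (
            wave * scale[:, None]
        ).ravel()

    # float32 synthesis: the 62 MB/day arrays dominate generation cost and
    # sub-mg precision is ample for every downstream 5-s aggregate
    noise_rng = np.random.default_rng([schedule.seed, 401, site_idx])
    samples = np.repeat(gvec.astype(np.float32), spe, axis=0)
    samples *= (np.float32(1.0) + s_signal)[:, None]
    if spec.noise_sd > 0:
        noise = noise_rng.standard_normal(samples.shape, dtype=np.float32)
        noise *= np.float32(spec.noise_sd / 1000.0)
        samples += noise
    np.clip(samples, -6.0, 6.0, out=samples)

    return RawRecording(
        participant_id=schedule.participant_id,
        site=site,
        start_time=schedule.start_time,
        sampling_rate=fs,
        samples=samples,
        dynamic_range=6.0,
        calibrated=True,
    )


def generate_cohort(spec: CohortSpec) -> list[ParticipantData]:
    """Deterministic cohort: one schedule and one recording per site each."""
    cohort = []
    for i in range(spec.n_participants):
        schedule = generate_schedule(spec, i)
        target, labels, nonwear = schedule.epoch_arrays()
        truth = SyntheticGroundTruth(
            schedule=schedule,
            target_mg=target,
            epoch_labels=labels,
            nonwear_mask=nonwear,
        )
        recs = {site: generate_recording(schedule, site, spec) for site in spec.sites}
        cohort.append(ParticipantData(schedule.participant_id, recs, truth))
    return cohort


def inject_calibration_error(
    rec: RawRecording, offset: np.ndarray, gain: np.ndarray
) -> RawRecording:
    """Distort a recording so that calibration (offset, gain) restores it.

    The inverse of ``calibrated = raw * gain + offset`` is applied, i.e.
    ``raw = (calibrated - offset) / gain``; the distorted copy is marked
    uncalibrated.
    """
    offset = np.asarray(offset, dtype=float).reshape(3)
    gain = np.asarray(gain, dtype=float).reshape(3)
    if (gain <= 0).any():
        raise ValueError("gains must be positive")
    distorted = (rec.samples - offset) / gain
    distorted = np.clip(distorted, -rec.dynamic_range, rec.dynamic_range)
    return replace(rec, samples=distorted, calibrated=False)


# ---------------------------------------------------------------------------
# evaluation helpers and serialization
# ---------------------------------------------------------------------------

def nonwear_block_confusion(
    truth: SyntheticGroundTruth,
    mask,
    window: float = 60.0,
) -> tuple[int, int, int, int]:
    """(tp, fp, fn, tn) of block-level non-wear detection.

    Blocks whose surrounding ``window``-minute span mixes worn and unworn
    ground truth are excluded: the centred-window rule cannot attribute
    them to either state, so only unambiguous blocks are scored.
    """
    epb = mask.epochs_per_block
    half_ep = _ep(window / 2.0)
    nw = truth.nonwear_mask
    n_ep = nw.size
    tp = fp = fn = tn = 0
    for b in range(mask.block_nonwear.size):
        centre = min(b * epb + epb // 2, n_ep)
        lo, hi = max(0, centre - half_ep), min(n_ep, centre + half_ep)
        span = nw[lo:hi]
        if span.all():
            if mask.block_nonwear[b]:
                tp += 1
            else:
                fn += 1
        elif not span.any():
            if mask.block_nonwear[b]:
                fp += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def write_cohort(cohort: list[ParticipantData], out_dir) -> None:
    """Write raw CSVs, diaries, schedule tables and JSON sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for p in cohort:
        for site, rec in p.recordings.items():
            write_raw_csv(rec, out / f"{p.participant_id}_{site}.csv")
        write_sleep_diary(p.truth.schedule.diary, out / f"{p.participant_id}_diary.csv")
        p.truth.schedule.to_frame().to_csv(
            out / f"{p.participant_id}_schedule.csv", index=False
        )
        (out / f"{p.participant_id}_truth.json").write_text(p.truth.to_json())
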