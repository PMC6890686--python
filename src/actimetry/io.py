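"""Containers and file I/O for raw tri-axial acceleration and epoch-level data.

The raw format is a headered CSV in the style of vendor raw exports: a small
key/value (or prose) header declaring participant, wear site, start time and
sampling rate, followed by one ``x,y,z`` sample per row in units of g.
Epoch-level series (ENMO, LFENMO, MAD in mg; imported activity counts per
5 s) live on a common half-open 5-s grid anchored at local midnight.

Timestamps are naive local clock time throughout: the analysis is organised
by the local clock (30-min diurnal bins, sleep diaries, day boundaries at
midnight), so no timezone arithmetic is wanted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Recognised wear sites.
SITES = ("hip", "dominant_wrist", "non_dominant_wrist")

#: Metrics whose epoch values are non-negative by construction.
NONNEGATIVE_METRICS = ("ENMO", "LFENMO", "MAD", "counts")

DEFAULT_EPOCH_S = 5.0
SECONDS_PER_DAY = 86400

_MAGIC = "actimetry-raw"


class FormatError(ValueError):
    """Raised when an input file does not match the expected dialect."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RawRecording:
    """One device's tri-axial acceleration time series.

    Parameters
    ----------
    participant_id : str
        Cohort-unique participant label.
    site : str
        One of :data:`SITES`.
    start_time : pandas.Timestamp
        Naive local wall-clock time of the first sample.
    sampling_rate : float
        Samples per second (Hz).
    samples : numpy.ndarray, shape (n, 3)
        Acceleration in g; row ``i`` was sampled at
        ``start_time + i / sampling_rate``.
    dynamic_range : float
        Sensor clipping range in g (default +/-6 g).
    calibrated : bool
        Whether the samples are already expressed in local-gravity units
        (auto-calibration applied, or synthetic truth).
    """

    participant_id: str
    site: str
    start_time: pd.Timestamp
    sampling_rate: float
    samples: np.ndarray
    dynamic_range: float = 6.0
    calibrated: bool = False

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ValueError(f"unknown wear site {self.site!r}; expected one of {SITES}")
        self.start_time = pd.Timestamp(self.start_time)
        self.samples = np.asarray(self.samples)
        if not np.issubdtype(self.samples.dtype, np.floating):
            self.samples = self.samples.astype(float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must be an (n, 3) array of x,y,z in g")
        if self.samples.shape[0] == 0:
            raise ValueError("recording must contain at least one sample")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if np.abs(self.samples).max() > self.dynamic_range + 1e-9:
            raise ValueError(
                f"samples exceed the +/-{self.dynamic_range} g dynamic range"
            )

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + pd.Timedelta(seconds=self.duration_s)


@dataclass
class EpochSeries:
    """Per-epoch aggregated metric values with wear/imputation flags.

    Epochs are contiguous, half-open ``[t, t + epoch_length)`` intervals.
    ``values`` are mg for ENMO/LFENMO/MAD and counts/epoch for counts;
    missing (un-imputable) epochs are NaN.
    """

    participant_id: str
    site: str
    metric_name: str
    start_time: pd.Timestamp
    values: np.ndarray
    epoch_length: float = DEFAULT_EPOCH_S
    wear: np.ndarray | None = None
    imputed: np.ndarray | None = None
    labels: np.ndarray | None = None  # per-epoch "wake"/"sleep", optional

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        n = self.values.size
        if self.wear is None:
            self.wear = np.ones(n, dtype=bool)
        else:
            self.wear = np.asarray(self.wear, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros(n, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
        for arr, name in ((self.wear, "wear"), (self.imputed, "imputed")):
            if arr.shape != (n,):
                raise ValueError(f"{name} flags must match values length")
        if self.labels is not None and self.labels.shape != (n,):
            raise ValueError("labels must match values length")
        if self.metric_name in NONNEGATIVE_METRICS:
            if np.nanmin(self.values, initial=0.0) < -1e-9:
                raise ValueError(f"{self.metric_name} values must be non-negative")

    @property
    def n_epochs(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(
            self.start_time,
            periods=self.n_epochs,
            freq=pd.Timedelta(seconds=self.epoch_length),
        )

    def copy(self) -> "EpochSeries":
        return EpochSeries(
            participant_id=self.participant_id,
            site=self.site,
            metric_name=self.metric_name,
            start_time=self.start_time,
            values=self.values.copy(),
            epoch_length=self.epoch_length,
            wear=self.wear.copy(),
            imputed=self.imputed.copy(),
            labels=None if self.labels is None else self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "timestamp": self.times,
            "value": self.values,
            "wear": self.wear.astype(int),
            "imputed": self.imputed.astype(int),
        }
        if self.labels is not None:
            data["label"] = self.labels
        return pd.DataFrame(data)


@dataclass
class DiaryNight:
    """One diary entry: the night starting on ``date``."""

    date: pd.Timestamp
    bed: pd.Timestamp
    rise: pd.Timestamp

    def __post_init__(self) -> None:
        self.date = pd.Timestamp(self.date).normalize()
        self.bed = pd.Timestamp(self.bed)
        self.rise = pd.Timestamp(self.rise)
        if self.rise <= self.bed:
            raise ValueError("rise time must fall after bed time")

    @property
    def duration_h(self) -> float:
        return (self.rise - self.bed).total_seconds() / 3600.0


@dataclass
class SleepDiary:
    """Logged bed/rise times, one entry per night."""

    nights: list[DiaryNight] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nights)

    def __iter__(self):
        return iter(self.nights)


# ---------------------------------------------------------------------------
# epoch grid helpers
# ---------------------------------------------------------------------------

def samples_per_epoch(sampling_rate: float, epoch_length: float = DEFAULT_EPOCH_S) -> int:
    spe = sampling_rate * epoch_length
    spe_i = int(round(spe))
    if abs(spe - spe_i) > 1e-9 or spe_i < 1:
        raise ValueError(
            f"epoch_length x sampling_rate must be an integer, got {spe}"
        )
    return spe_i


def epoch_align(rec: RawRecording, epoch_length: float = DEFAULT_EPOCH_S):
    """Align a recording to the midnight-anchored epoch grid.

    The first epoch starts at the recording start time rounded to the next
    grid point that is a whole multiple of ``epoch_length`` from local
    midnight (the recording start itself when already aligned, the typical
    case).  Returns ``(epoch_start_time, samples, n_epochs, spe)`` where
    ``samples`` has leading off-grid samples and the trailing partial epoch
    removed and is reshaped to ``(n_epochs, spe, 3)``.
    """
    spe = samples_per_epoch(rec.sampling_rate, epoch_length)
    midnight = rec.start_time.normalize()
    offset = (rec.start_time - midnight).total_seconds()
    rem = offset % epoch_length
    if rem < 1e-9 or epoch_length - rem < 1e-9:
        skip = 0
        t0 = rec.start_time
    else:
        skip_s = epoch_length - rem
        skip = int(round(skip_s * rec.sampling_rate))
        t0 = rec.start_time + pd.Timedelta(seconds=skip / rec.sampling_rate)
    n_epochs = (rec.n_samples - skip) // spe
    if n_epochs < 1:
        raise ValueError("recording shorter than one epoch after grid alignment")
    body = rec.samples[skip : skip + n_epochs * spe]
    return t0, body.reshape(n_epochs, spe, 3), n_epochs, spe


# ---------------------------------------------------------------------------
# raw CSV
# ---------------------------------------------------------------------------

def write_raw_csv(rec: RawRecording, path) -> None:
    """Write a recording as a headered CSV (6-decimal fixed precision).

    Output is byte-stable for a given recording.
    """
    path = Path(path)
    header = [
        f"{_MAGIC},1",
        f"participant_id,{rec.participant_id}",
        f"site,{rec.site}",
        f"start_time,{rec.start_time.isoformat()}",
        f"sampling_rate_hz,{rec.sampling_rate!r}",
        f"dynamic_range_g,{rec.dynamic_range!r}",
        f"calibrated,{int(rec.calibrated)}",
        "x,y,z",
    ]
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, rec.samples, fmt="%.6f", delimiter=",")


_TIME_RE = re.compile(r"(\d{1,2}:\d{2}(?::\d{2})?)")
_RATE_RE = re.compile(r"(\d+(?:\.\d+)?)\s*Hz", re.IGNORECASE)
_DATE_RE = re.compile(r"(\d{4}-\d{1,2}-\d{1,2}|\d{1,2}/\d{1,2}/\d{4})")


def _parse_date(text: str) -> pd.Timestamp:
    """Accept ISO-8601 (YYYY-MM-DD) and US (M/D/YYYY) date dialects."""
    text = text.strip()
    if "/" in text:
        return pd.Timestamp(pd.to_datetime(text, format="%m/%d/%Y"))
    return pd.Timestamp(text)


def _is_numeric_row(line: str, delim: str) -> bool:
    parts = line.strip().split(delim)
    if len(parts) != 3:
        return False
    try:
        [float(p) for p in parts]
    except ValueError:
        return False
    return True


def read_raw_csv(path, participant_id: str | None = None, site: str | None = None) -> RawRecording:
    """Read a raw tri-axial CSV (native or vendor-style header).

    Header metadata may be given as ``key,value`` lines (the native dialect)
    or as free prose containing ``Start Time``, ``Start Date`` and a
    ``... Hz`` sampling rate, as in vendor raw exports.  Comma and semicolon
    delimiters are accepted.  ``participant_id``/``site`` override or
    supply metadata absent from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # header lives in the first few hundred lines; never slurp the body
    lines = []
    with open(path) as fh:
        for _ in range(500):
            line = fh.readline()
            if not line:
                break
            lines.append(line.rstrip("\n"))
    if not lines:
        raise FormatError(f"{path}: empty file")

    delim = ";" if lines[0].count(";") >= lines[0].count(",") and ";" in lines[0] else ","
    # locate first body row
    body_start = None
    for i, line in enumerate(lines):
        for d in (",", ";"):
            if _is_numeric_row(line, d):
                body_start = i
                delim = d
                break
        if body_start is not None:
            break
    if body_start is None:
        raise FormatError(f"{path}: no numeric x,y,z rows found")

    meta: dict[str, str] = {}
    header_text = []
    for line in lines[:body_start]:
        header_text.append(line)
        parts = [p.strip() for p in re.split("[,;]", line, maxsplit=1)]
        if len(parts) == 2 and parts[0] and parts[1]:
            meta[parts[0].lower()] = parts[1]
    blob = "\n".join(header_text)

    # sampling rate
    if "sampling_rate_hz" in meta:
        rate = float(meta["sampling_rate_hz"])
    else:
        m = _RATE_RE.search(blob)
        if m is None:
            raise FormatError(f"{path}: header missing field 'sampling rate'")
        rate = float(m.group(1))

    # start time
    if "start_time" in meta:
        start = pd.Timestamp(meta["start_time"])
    else:
        mt = re.search(r"start time\D*" + _TIME_RE.pattern, blob, re.IGNORECASE)
        md = re.search(r"start date\D*" + _DATE_RE.pattern, blob, re.IGNORECASE)
        if mt is None or md is None:
            raise FormatError(f"{path}: header missing field 'start time'/'start date'")
        start = _parse_date(md.group(1)) + pd.Timedelta(mt.group(1))

    pid = participant_id or meta.get("participant_id", "unknown")
    the_site = site or meta.get("site")
    if the_site is None:
        raise FormatError(f"{path}: header missing field 'site' (and no site argument)")

    try:
        numeric = pd.read_csv(
            path, skiprows=body_start, header=None, sep=delim,
            names=["x", "y", "z"], dtype=float, na_filter=False,
        )
    except (ValueError, TypeError):
        # slow path only to report which row is bad
        raw = pd.read_csv(path, skiprows=body_start, header=None, sep=delim,
                          names=["x", "y", "z"], dtype=str)
        coerced = raw.apply(pd.to_numeric, errors="coerce")
        bad = coerced.isna().any(axis=1)
        row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else 0
        raise FormatError(f"{path}: non-numeric sample at data row {row + 1}")
    if numeric.isna().any().any():
        bad = numeric.isna().any(axis=1)
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"{path}: non-numeric sample at data row {row + 1}")

    return RawRecording(
        participant_id=pid,
        site=the_site,
        start_time=start,
        sampling_rate=rate,
        samples=numeric.to_numpy(),
        dynamic_range=float(meta.get("dynamic_range_g", 6.0)),
        calibrated=bool(int(meta.get("calibrated", 0))),
    )


# ---------------------------------------------------------------------------
# epoch CSV
# ---------------------------------------------------------------------------

def write_epoch_csv(series: EpochSeries, path) -> None:
    """Write a single epoch series as a headered CSV."""
    path = Path(path)
    df = series.to_frame()
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# participant_id={series.participant_id}\n")
        fh.write(f"# site={series.site}\n")
        fh.write(f"# metric={series.metric_name}\n")
        fh.write(f"# epoch_length_s={series.epoch_length!r}\n")
        df.to_csv(fh, index=False, float_format="%.6f")


def read_epoch_csv(path) -> EpochSeries:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        pos = 0
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val.strip()
            pos += len(line)
    df = pd.read_csv(path, comment="#")
    return EpochSeries(
        participant_id=meta.get("participant_id", "unknown"),
        site=meta.get("site", "non_dominant_wrist"),
        metric_name=meta.get("metric", "ENMO"),
        start_time=pd.Timestamp(df["timestamp"].iloc[0]),
        values=df["value"].to_numpy(float),
        epoch_length=float(meta.get("epoch_length_s", DEFAULT_EPOCH_S)),
        wear=df["wear"].to_numpy(bool),
        imputed=df["imputed"].to_numpy(bool),
        labels=df["label"].to_numpy(object) if "label" in df else None,
    )


def write_epoch_table(series: Sequence[EpochSeries], path) -> None:
    """Write co-registered metric series as one wide CSV.

    Columns: ``timestamp, enmo_mg, lfenmo_mg, mad_mg, counts_5s, wear,
    imputed[, label]`` (only metrics present are written).
    """
    if not series:
        raise ValueError("no series to write")
    first = series[0]
    colname = {"ENMO": "enmo_mg", "LFENMO": "lfenmo_mg", "MAD": "mad_mg", "counts": "counts_5s"}
    df = pd.DataFrame({"timestamp": first.times})
    for s in series:
        if s.n_epochs != first.n_epochs or s.start_time != first.start_time:
            raise ValueError("series do not share one epoch grid")
        df[colname.get(s.metric_name, s.metric_name)] = s.values
    df["wear"] = first.wear.astype(int)
    df["imputed"] = first.imputed.astype(int)
    if first.labels is not None:
        df["label"] = first.labels
    df.to_csv(path, index=False, float_format="%.6f")


def read_epoch_counts(path, participant_id: str = "unknown",
                      site: str = "non_dominant_wrist",
                      epoch_length: float = DEFAULT_EPOCH_S) -> EpochSeries:
    """Read a vendor epoch-counts export onto the 5-s grid.

    The file must contain a timestamp column plus either a vector-magnitude
    column or three per-axis columns (combined as the Euclidean norm).
    Epoch spacing must equal ``epoch_length``.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected timestamp plus counts columns")
    ts = pd.to_datetime(df.iloc[:, 0])
    if len(ts) > 1:
        spacing = np.unique(np.diff(ts.to_numpy()).astype("timedelta64[s]").astype(int))
        if spacing.size != 1 or spacing[0] != int(epoch_length):
            raise FormatError(
                f"{path}: epoch spacing {spacing.tolist()} s != {epoch_length} s"
            )
    lower = {c.lower().replace(" ", "_"): c for c in df.columns}
    vm_col = next((lower[k] for k in ("vm", "vector_magnitude", "vectormagnitude") if k in lower), None)
    if vm_col is not None:
        values = df[vm_col].to_numpy(float)
    else:
        axes = df.iloc[:, 1:4].to_numpy(float)
        if axes.shape[1] != 3:
            raise FormatError(f"{path}: need a vector-magnitude or three axis columns")
        values = np.sqrt((axes ** 2).sum(axis=1))
    if (values < 0).any():
        raise FormatError(f"{path}: negative counts")
    return EpochSeries(
        participant_id=participant_id,
        site=site,
        metric_name="counts",
        start_time=ts.iloc[0],
        values=values,
        epoch_length=epoch_length,
    )


# ---------------------------------------------------------------------------
# sleep diary
# ---------------------------------------------------------------------------

def _clock_delta(text: str) -> pd.Timedelta:
    """Parse ``HH:MM`` or ``HH:MM:SS`` clock text as an offset from midnight."""
    text = str(text).strip()
    if not re.fullmatch(r"\d{1,2}:\d{2}(:\d{2})?", text):
        raise ValueError(f"not a clock time: {text!r}")
    if text.count(":") == 1:
        text += ":00"
    return pd.Timedelta(text)


def read_sleep_diary(path) -> SleepDiary:
    """Read a diary CSV with columns ``date, bed_time, rise_time``.

    Rise times at or before the bed time are resolved to the following
    calendar day (nights crossing midnight).
    """
    df = pd.read_csv(path)
    required = {"date", "bed_time", "rise_time"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    nights = []
    for i, row in df.iterrows():
        try:
            date = pd.Timestamp(row["date"]).normalize()
            bed = date + _clock_delta(row["bed_time"])
            rise = date + _clock_delta(row["rise_time"])
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: unparsable time at row {i + 1}: {exc}") from exc
        if pd.isna(bed) or pd.isna(rise):
            raise FormatError(f"{path}: unparsable time at row {i + 1}")
        if rise <= bed:
            rise += pd.Timedelta(days=1)
        nights.append(DiaryNight(date=date, bed=bed, rise=rise))
    return SleepDiary(nights=nights)


def write_sleep_diary(diary: SleepDiary, path) -> None:
    rows = [
        {
            "date": n.date.date().isoformat(),
            "bed_time": n.bed.strftime("%H:%M:%S"),
            "rise_time": n.rise.strftime("%H:%M:%S"),
        }
        for n in diary
    ]
    pd.DataFrame(rows, columns=["date", "bed_time", "rise_time"]).to_csv(path, index=False)
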