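"""Diurnal profiles, sorted daily acceleration curves and 1D SPM.

Movement patterns over the day are summarised two ways: 30-min clock-time
averages (48 bins, optionally z-scored so different metrics share a plot),
and *sorted curves* — each day's epoch values sorted ascending and
down-averaged onto a fixed number of nodes, so curves start at the quietest
part of the day and end at the most intense regardless of when activity
happened.  Paired curves (e.g. dominant vs non-dominant wrist of the same
participants) are compared with one-dimensional statistical parametric
mapping: a pointwise paired t statistic, field smoothness (FWHM) estimated
from the normalized residuals' temporal gradient, a random-field-theory
critical threshold at the requested family-wise alpha, and cluster-level
p-values for suprathreshold regions.  A permutation (sign-flip) max-t
threshold ships alongside as the validation oracle and small-n fallback.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import EpochSeries, SECONDS_PER_DAY

_SQRT_4LN2 = math.sqrt(4.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# diurnal profile
# ---------------------------------------------------------------------------

@dataclass
class DiurnalProfile:
    """48 half-hour clock bins of cohort-mean metric values (mg)."""

    metric_name: str
    values: np.ndarray           # (48,), NaN where no data
    zscored: np.ndarray | None = None
    n_participants: int = 0

    @property
    def bin_starts_h(self) -> np.ndarray:
        return np.arange(48) * 0.5


def diurnal_profile(series_list, zscore: bool = False, bin_minutes: float = 30.0) -> DiurnalProfile:
    """Clock-binned means: epochs -> bins per day -> days -> participants.

    Empty bins propagate as NaN and are excluded from z-scoring.  The
    z-scored variant standardises the 48 bin means to mean 0 / SD 1 (all
    zeros under a zero-SD guard).
    """
    n_bins = int(round(SECONDS_PER_DAY / 60.0 / bin_minutes))
    per_participant = []
    for s in series_list:
        sec = (
            (s.times - s.times.normalize()).total_seconds().to_numpy()
            if hasattr((s.times - s.times.normalize()), "total_seconds")
            else (s.times - s.times.normalize()).total_seconds()
        )
        bins = (sec // (bin_minutes * 60.0)).astype(int) % n_bins
        days = s.times.normalize()
        df = pd.DataFrame({"day": days, "bin": bins, "value": s.values})
        df = df.dropna(subset=["value"])
        day_bin = df.groupby(["day", "bin"])["value"].mean()
        per_bin = day_bin.groupby("bin").mean()
        vec = np.full(n_bins, np.nan)
        vec[per_bin.index.to_numpy()] = per_bin.to_numpy()
        per_participant.append(vec)
    stack = np.vstack(per_participant)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nanmean(stack, axis=0)
    z = None
    if zscore:
        finite = np.isfinite(values)
        z = np.full_like(values, np.nan)
        if finite.any():
            sd = values[finite].std()
            if sd == 0:
                z[finite] = 0.0
            else:
                z[finite] = (values[finite] - values[finite].mean()) / sd
    name = series_list[0].metric_name if series_list else ""
    return DiurnalProfile(metric_name=name, values=values, zscored=z,
                          n_participants=len(per_participant))


# ---------------------------------------------------------------------------
# sorted curves
# ---------------------------------------------------------------------------

@dataclass
class SortedCurve:
    """Ascending-sorted daily curve, averaged over a participant's days."""

    participant_id: str
    site: str
    values: np.ndarray    # (Q,), non-decreasing
    n_days: int
    q: int


def _downsample_sorted(sorted_vals: np.ndarray, q: int) -> np.ndarray:
    n = sorted_vals.size
    if n == q:
        return sorted_vals
    if n % q == 0:
        return sorted_vals.reshape(q, n // q).mean(axis=1)
    # uneven split: average nearly equal chunks
    edges = np.linspace(0, n, q + 1).round().astype(int)
    return np.add.reduceat(sorted_vals, edges[:-1]) / np.diff(edges)


def sorted_curve(series: EpochSeries, q: int = 1440) -> SortedCurve:
    """Sort each complete day's epoch values and down-average to ``q`` nodes.

    Only complete days — full epoch coverage, every value present after
    imputation — contribute; partial days are excluded with a warning.
    """
    epd = int(round(SECONDS_PER_DAY / series.epoch_length))
    if q > epd:
        raise ValueError(f"q={q} exceeds {epd} epochs per day")
    days = series.times.normalize()
    curves = []
    for day in pd.unique(days):
        vals = series.values[np.asarray(days == day)]
        if vals.size != epd or not np.isfinite(vals).all():
            warnings.warn(
                f"excluding incomplete day {pd.Timestamp(day).date()} for "
                f"{series.participant_id}/{series.site}",
                stacklevel=2,
            )
            continue
        curves.append(_downsample_sorted(np.sort(vals), q))
    if not curves:
        raise ValueError("no complete days to build a sorted curve from")
    return SortedCurve(
        participant_id=series.participant_id,
        site=series.site,
        values=np.vstack(curves).mean(axis=0),
        n_days=len(curves),
        q=q,
    )


def cohort_curve(curves) -> np.ndarray:
    """Pointwise mean across participants' sorted curves."""
    return np.vstack([c.values for c in curves]).mean(axis=0)


# ---------------------------------------------------------------------------
# 1D statistical parametric mapping
# ---------------------------------------------------------------------------

@dataclass
class SPMResult:
    t: np.ndarray                       # (Q,) paired t statistic
    fwhm: float                         # smoothness, in nodes
    threshold: float                    # critical |t| at the requested alpha
    clusters: list[tuple[int, int, float]]  # (start, end inclusive, cluster p)
    alpha: float
    df: int

    @property
    def significant(self) -> bool:
        return bool(self.clusters)


def estimate_fwhm(residuals: np.ndarray) -> float:
    """Field smoothness from the average temporal gradient of the
    normalized residuals; returns +inf for a flat (zero-gradient) field.

    Mean-centred residuals carry n-1 degrees of freedom, which inflates
    the normalized gradient and deflates the raw estimate by about
    (n-1)/n; the estimate is rescaled accordingly.
    """
    r = np.asarray(residuals, float)
    n = r.shape[0]
    ssq = (r ** 2).sum(axis=0)
    grad = np.diff(r, axis=1)
    denom = 0.5 * (ssq[:-1] + ssq[1:])
    ok = denom > 0
    if not ok.any():
        return math.inf
    v = ((grad ** 2).sum(axis=0)[ok] / denom[ok]).mean()
    if v <= 0:
        return math.inf
    correction = n / (n - 1) if n > 1 else 1.0
    return float(_SQRT_4LN2 / math.sqrt(v) * correction)


def _ec_density(u: float, df: int, resels: float) -> float:
    """Expected Euler characteristic of a 1D t field above u."""
    p0 = stats.t.sf(u, df)
    p1 = resels * _SQRT_4LN2 / (2.0 * math.pi) * (1.0 + u ** 2 / df) ** (-(df - 1) / 2.0)
    return p0 + p1


def rft_threshold(df: int, q: int, fwhm: float, alpha: float = 0.05,
                  two_sided: bool = True) -> float:
    """Critical t solving the smooth-field exceedance relation at alpha."""
    tail = alpha / 2.0 if two_sided else alpha
    resels = 0.0 if math.isinf(fwhm) else (q - 1) / fwhm
    f = lambda u: _ec_density(u, df, resels) - tail
    lo, hi = 1e-3, 100.0
    if f(lo) < 0:  # already below alpha everywhere
        return lo
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def _clusters_from(mask: np.ndarray) -> list[tuple[int, int]]:
    out = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return out
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, stops)]


def _cluster_p(extent: int, u: float, df: int, q: int, fwhm: float,
               two_sided: bool) -> float:
    """Cluster-level corrected p for a suprathreshold run of ``extent`` nodes."""
    resels = 0.0 if math.isinf(fwhm) else (q - 1) / fwhm
    em = _ec_density(u, df, resels)           # expected clusters, one tail
    if em <= 0:
        return 0.0
    en = q * stats.t.sf(u, df) / em           # expected cluster extent (nodes)
    if en <= 0:
        return 0.0
    beta = math.pi / (4.0 * en ** 2)
    p_ge = math.exp(-beta * extent ** 2)
    tails = 2.0 if two_sided else 1.0
    return float(1.0 - math.exp(-tails * em * p_ge))


def spm_paired_t(
    curves_a,
    curves_b,
    alpha: float = 0.05,
    two_sided: bool = True,
) -> SPMResult:
    """Node-wise paired t comparison of two sets of per-participant curves.

    ``curves_a``/``curves_b`` are paired (n, Q) arrays or lists of
    :class:`SortedCurve` from the same participants.  Nodes with zero
    residual variance receive a guarded (huge-|t|) statistic and a warning.
    """
    a = np.vstack([c.values if isinstance(c, SortedCurve) else c for c in curves_a])
    b = np.vstack([c.values if isinstance(c, SortedCurve) else c for c in curves_b])
    if a.shape != b.shape:
        raise ValueError("curve sets must be paired with equal node counts")
    n, q = a.shape
    if n < 3:
        raise ValueError("need at least 3 paired participants")
    d = b - a
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any() and (mean[zero_var] != 0).any():
        warnings.warn("zero residual variance at some nodes; t guarded", stacklevel=2)
    se = np.where(zero_var, np.finfo(float).tiny ** 0.5, sd) / math.sqrt(n)
    t = np.where(zero_var & (mean == 0), 0.0, mean / se)

    resid = d - mean
    fwhm = estimate_fwhm(resid)
    df = n - 1
    thr = rft_threshold(df, q, fwhm, alpha, two_sided)
    exceed = np.abs(t) > thr if two_sided else t > thr
    clusters = [
        (s, e, _cluster_p(e - s + 1, thr, df, q, fwhm, two_sided))
        for s, e in _clusters_from(exceed)
    ]
    return SPMResult(t=t, fwhm=fwhm, threshold=thr, clusters=clusters,
                     alpha=alpha, df=df)


def permutation_threshold(
    curves_a,
    curves_b,
    alpha: float = 0.05,
    n_perm: int = 2048,
    seed: int | None = 0,
) -> float:
    """Sign-flip max-|t| critical value (exact enumeration when feasible).

    The non-parametric oracle for :func:`rft_threshold`: under
    exchangeability of the paired differences the distribution of the
    maximum |t| over nodes gives an exact family-wise threshold.
    """
    a = np.vstack([c.values if isinstance(c, SortedCurve) else c for c in curves_a])
    b = np.vstack([c.values if isinstance(c, SortedCurve) else c for c in curves_b])
    d = b - a
    n, q = d.shape
    if 2 ** n <= n_perm:
        signs = np.array(
            [[1 if (i >> k) & 1 else -1 for k in range(n)] for i in range(2 ** n)],
            dtype=float,
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    means = signs @ d / n                     # (P, Q)
    ssq = (d ** 2).sum(axis=0)                # invariant under sign flips
    var = np.maximum((ssq[None, :] - n * means ** 2) / (n - 1), 0.0)
    se = np.sqrt(var / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        tmax = np.nanmax(np.abs(np.where(se > 0, means / se, 0.0)), axis=1)
    return float(np.quantile(tmax, 1.0 - alpha))


def percentile_band_report(result: SPMResult, q: int) -> list[str]:
    """Cluster node ranges expressed as percentile bands of the sorted day."""
    out = []
    for start, end, p in result.clusters:
        lo = round(start / q * 100)
        hi = round((end + 1) / q * 100)
        out.append(f"{lo}th–{hi}th percentile (cluster p = {p:.3g})")
    return out
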