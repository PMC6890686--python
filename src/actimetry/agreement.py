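"""Intensity classification, agreement statistics and cut-point translation.

Waking epochs of the ENMO series are binned into sedentary / light /
moderate / vigorous physical activity by mg thresholds with a
lower-inclusive, upper-exclusive convention (sedentary ``[0, sed)``, light
``[sed, light)``, moderate ``[light, mod)``, vigorous ``[mod, inf)``).
Daily minutes per category are averaged over valid days into per-participant
means, which are the unit of every agreement analysis.

Cut points validated for the non-dominant wrist are translated to the
dominant wrist by a small grid search (each reference threshold
incremented by 0, 5 and 10 mg), scoring every candidate against the
non-dominant reference with Lin's concordance correlation coefficient
(LCCC), the paired mean difference with its 95% CI, and the group-level
mean absolute percent error (MAPE).  A deterministic three-step procedure
then assembles the translated set: closest vigorous estimate first, then
moderate, then light/sedentary, with ties broken by preserving the
reference's inter-threshold distances.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import EpochSeries

CATEGORIES = ("sedentary", "light", "moderate", "vigorous")


@dataclass(frozen=True)
class CutPointSet:
    """Ordered intensity thresholds in mg."""

    sedentary_upper: float
    light_upper: float
    moderate_upper: float

    def __post_init__(self) -> None:
        if not (0 < self.sedentary_upper < self.light_upper < self.moderate_upper):
            raise ValueError("cut points must satisfy 0 < sed < light < moderate")

    @property
    def bounds(self) -> dict[str, tuple[float, float]]:
        return {
            "sedentary": (0.0, self.sedentary_upper),
            "light": (self.sedentary_upper, self.light_upper),
            "moderate": (self.light_upper, self.moderate_upper),
            "vigorous": (self.moderate_upper, math.inf),
        }

    def classify(self, values: np.ndarray) -> np.ndarray:
        """Category index (0..3) per value, half-open intervals."""
        edges = [self.sedentary_upper, self.light_upper, self.moderate_upper]
        return np.searchsorted(edges, np.asarray(values), side="right")


#: Reference thresholds validated for the non-dominant wrist.
REFERENCE_CUTPOINTS = CutPointSet(45.0, 100.0, 430.0)


# ---------------------------------------------------------------------------
# daily minutes
# ---------------------------------------------------------------------------

@dataclass
class DailyIntensitySummary:
    """Waking minutes per intensity category.

    ``per_day`` holds one row per day; ``per_participant`` the mean over
    valid days (the analysis unit).  Category minutes sum to the waking
    wear minutes exactly.
    """

    participant_id: str
    site: str
    cuts: CutPointSet
    per_day: pd.DataFrame
    per_participant: pd.Series


def _waking_day_values(series: EpochSeries):
    """Per-day arrays of usable waking epoch values plus validity flags."""
    if series.labels is None:
        raise ValueError("series must carry wake/sleep labels (apply_segmentation)")
    usable = (series.wear | series.imputed) & np.isfinite(series.values)
    waking = usable & (series.labels == "wake")
    days = series.times.normalize()
    order = pd.unique(days)
    out = []
    for day in order:
        in_day = np.asarray(days == day)
        wear_h = (series.wear[in_day] | series.imputed[in_day]).sum() * series.epoch_length / 3600.0
        out.append((pd.Timestamp(day), series.values[in_day & waking], wear_h))
    return out, series.epoch_length


def classify_minutes(
    series: EpochSeries,
    cuts: CutPointSet,
    min_wear_hours: float = 16.0,
) -> DailyIntensitySummary:
    """Bin waking, worn-or-imputed epochs into daily category minutes.

    Days with fewer than ``min_wear_hours`` of wear-or-imputed time do not
    enter the per-participant mean.
    """
    day_values, epoch_len = _waking_day_values(series)
    min_per_epoch = epoch_len / 60.0
    rows = []
    for day, vals, wear_h in day_values:
        cats = cuts.classify(vals)
        counts = np.bincount(cats, minlength=4)
        rows.append({
            "date": day,
            **{c: counts[i] * min_per_epoch for i, c in enumerate(CATEGORIES)},
            "waking_wear_min": vals.size * min_per_epoch,
            "valid_day": wear_h >= min_wear_hours,
        })
    per_day = pd.DataFrame(rows)
    valid = per_day[per_day["valid_day"]]
    cols = list(CATEGORIES) + ["waking_wear_min"]
    per_participant = valid[cols].mean() if len(valid) else pd.Series(np.nan, index=cols)
    return DailyIntensitySummary(
        participant_id=series.participant_id,
        site=series.site,
        cuts=cuts,
        per_day=per_day,
        per_participant=per_participant,
    )


def cohort_category_minutes(
    series_list: Sequence[EpochSeries],
    cuts: CutPointSet,
    min_wear_hours: float = 16.0,
) -> pd.DataFrame:
    """Per-participant mean daily minutes per category, rows = participants."""
    rows = {}
    for s in series_list:
        rows[s.participant_id] = classify_minutes(s, cuts, min_wear_hours).per_participant
    return pd.DataFrame(rows).T.rename_axis("participant_id")


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def lccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (1/n moment convention).

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2).  Degenerate inputs:
    zero total variance returns 1 for equal means, otherwise the
    denominator is the squared mean shift and the result is 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    vx, vy = x.var(), y.var()
    sxy = ((x - x.mean()) * (y - y.mean())).mean()
    shift = (x.mean() - y.mean()) ** 2
    denom = vx + vy + shift
    if denom == 0:
        return 1.0
    return float(2.0 * sxy / denom)


def mean_diff_ci(
    x: np.ndarray, y: np.ndarray, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Paired mean difference (y - x) with its t-based confidence interval."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need paired vectors of length >= 2")
    d = y - x
    n = d.size
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        return mean, (mean, mean)
    half = stats.t.ppf(0.5 + conf / 2.0, n - 1) * sd / math.sqrt(n)
    return mean, (mean - half, mean + half)


def paired_t_p(x: np.ndarray, y: np.ndarray) -> float:
    """p-value of the paired t-test on (y - x); 1.0 for identical vectors."""
    d = np.asarray(y, float) - np.asarray(x, float)
    if d.std(ddof=1) == 0:
        return 1.0 if d.mean() == 0 else 0.0
    return float(stats.ttest_rel(y, x).pvalue)


def mape_group(ref_mean: float, diff: float) -> float:
    """Group-level MAPE: 100 |mean difference| / reference mean, 2 decimals.

    This is the operational definition consistent with reporting MAPE from
    a group mean difference (e.g. a 25 min/day difference on a 769 min/day
    reference is 3.25%).
    """
    if ref_mean <= 0:
        raise ValueError("reference mean must be positive")
    return round(100.0 * abs(diff) / ref_mean, 2)


def mape_individual(x: np.ndarray, y: np.ndarray) -> float:
    """Mean of per-participant absolute percent errors (not used for
    cut-point selection; provided for completeness)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if (x <= 0).any():
        raise ValueError("reference values must be positive")
    return float(np.mean(np.abs(y - x) / x) * 100.0)


def shared_variance(x: np.ndarray, y: np.ndarray) -> tuple[float, tuple[float, float], float]:
    """OLS shared variance r^2 with a Fisher-z CI and the slope-test p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4:
        raise ValueError("need n >= 4")
    if x.var() == 0 or y.var() == 0:
        raise ValueError("zero variance input")
    res = stats.linregress(x, y)
    r = res.rvalue
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    half = 1.959963984540054 / math.sqrt(x.size - 3)
    lo, hi = np.tanh(z - half), np.tanh(z + half)
    if lo < 0 < hi:
        ci = (0.0, float(max(lo**2, hi**2)))
    else:
        ci = (float(min(lo**2, hi**2)), float(max(lo**2, hi**2)))
    return float(r**2), ci, float(res.pvalue)


# ---------------------------------------------------------------------------
# grid search and selection
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Agreement of one candidate threshold (set) in one category."""

    category: str
    thresholds: tuple[float, ...]   # (sed,) | (sed, light) | (light, mod) | (mod,)
    ref_mean: float
    ref_sd: float
    comp_mean: float
    comp_sd: float
    lccc: float
    mean_diff: float
    ci: tuple[float, float]
    mape: float
    p_value: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _minutes_between(day_values, lower: float, upper: float, min_per_epoch: float,
                     min_wear_hours: float = 16.0) -> float:
    """Mean daily minutes with value in [lower, upper) over valid days."""
    per_day = [
        ((vals >= lower) & (vals < upper)).sum() * min_per_epoch
        for _, vals, wear_h in day_values
        if wear_h >= min_wear_hours
    ]
    return float(np.mean(per_day)) if per_day else float("nan")


def _category_report(category, thresholds, ref, comp) -> AgreementReport:
    diff, ci = mean_diff_ci(ref, comp)
    ref_mean = float(np.mean(ref))
    if ref_mean > 0:
        mape = mape_group(ref_mean, diff)
    else:
        # no reference time in this category (possible in small cohorts):
        # MAPE is undefined; rank such candidates by |diff| alone
        mape = 0.0 if diff == 0 else math.inf
    return AgreementReport(
        category=category,
        thresholds=thresholds,
        ref_mean=float(np.mean(ref)),
        ref_sd=float(np.std(ref, ddof=1)),
        comp_mean=float(np.mean(comp)),
        comp_sd=float(np.std(comp, ddof=1)),
        lccc=lccc(ref, comp),
        mean_diff=diff,
        ci=ci,
        mape=mape,
        p_value=paired_t_p(ref, comp),
    )


def candidate_grid(
    reference: CutPointSet = REFERENCE_CUTPOINTS,
    increments: Iterable[float] = (0.0, 5.0, 10.0),
) -> dict[str, list[tuple[float, ...]]]:
    """Category-specific candidate thresholds of the translation grid."""
    inc = list(increments)
    sed = [reference.sedentary_upper + i for i in inc]
    light = [reference.light_upper + i for i in inc]
    mod = [reference.moderate_upper + i for i in inc]
    return {
        "sedentary": [(s,) for s in sed],
        "light": [(s, l) for s in sed for l in light],
        "moderate": [(l, m) for l in light for m in mod],
        "vigorous": [(m,) for m in mod],
    }


def evaluate_grid(
    ref_minutes: pd.DataFrame,
    dom_series: Sequence[EpochSeries],
    reference: CutPointSet = REFERENCE_CUTPOINTS,
    increments: Iterable[float] = (0.0, 5.0, 10.0),
    min_wear_hours: float = 16.0,
) -> list[AgreementReport]:
    """Score every candidate threshold against the non-dominant reference.

    ``ref_minutes`` is the output of :func:`cohort_category_minutes` on the
    non-dominant wrist with the reference cut points; ``dom_series`` are
    the labeled dominant-wrist ENMO series of the same participants.
    Non-monotone candidates are skipped with a warning.
    """
    grid = candidate_grid(reference, increments)
    dom = {}
    for s in dom_series:
        day_values, epoch_len = _waking_day_values(s)
        dom[s.participant_id] = (day_values, epoch_len / 60.0)
    pids = [p for p in ref_minutes.index if p in dom]
    if len(pids) < 3:
        raise ValueError("need at least 3 participants present on both wrists")
    missing = set(ref_minutes.index) - set(dom)
    if missing:
        warnings.warn(f"participants without dominant-wrist data: {sorted(missing)}")

    def comp_minutes(lower, upper):
        return np.array([
            _minutes_between(dom[p][0], lower, upper, dom[p][1], min_wear_hours)
            for p in pids
        ])

    reports: list[AgreementReport] = []
    for category, cands in grid.items():
        ref_vals = ref_minutes.loc[pids, category].to_numpy(float)
        for thr in cands:
            if len(thr) == 2 and thr[0] >= thr[1]:
                warnings.warn(f"skipping non-monotone candidate {thr} for {category}")
                continue
            if category == "sedentary":
                lower, upper = 0.0, thr[0]
            elif category == "vigorous":
                lower, upper = thr[0], math.inf
            else:
                lower, upper = thr
            reports.append(
                _category_report(category, thr, ref_vals, comp_minutes(lower, upper))
            )
    return reports


def _rank_key(r: AgreementReport) -> tuple[float, float, float]:
    # closest mean estimate first, then MAPE, then highest concordance
    return (round(abs(r.mean_diff), 9), round(r.mape, 9), round(-r.lccc, 9))


def _best(reports: list[AgreementReport]) -> list[AgreementReport]:
    best_key = min(_rank_key(r) for r in reports)
    return [r for r in reports if _rank_key(r) == best_key]


def select_cutpoints(
    reports: Sequence[AgreementReport],
    reference: CutPointSet = REFERENCE_CUTPOINTS,
) -> CutPointSet:
    """Assemble the translated cut-point set by the three-step criteria.

    Step 1 picks the vigorous boundary (smallest |mean diff|, then MAPE,
    then highest LCCC); when *all* vigorous candidates tie, the boundary is
    deferred to step 2.  Step 2 picks the moderate (light, mod) pair under
    the same ordering among candidates consistent with step 1, breaking
    ties by matching the reference inter-threshold distance and then by
    proximity to the reference thresholds.  Step 3 fixes the sedentary
    boundary from the light candidates sharing step 2's light threshold.
    The procedure is deterministic and order-independent.
    """
    by_cat = {c: [r for r in reports if r.category == c] for c in CATEGORIES}
    for c, rs in by_cat.items():
        if not rs:
            raise ValueError(f"no candidate reports for category {c!r}")

    ref_dist_mod = reference.moderate_upper - reference.light_upper
    ref_dist_light = reference.light_upper - reference.sedentary_upper

    # step 1: vigorous
    vig = sorted(by_cat["vigorous"], key=lambda r: r.thresholds)
    best_vig = _best(vig)
    if len(best_vig) == len(vig):
        pinned_mod = None  # all equally comparable; defer to step 2
    else:
        best_vig.sort(key=lambda r: (abs(r.thresholds[0] - reference.moderate_upper),
                                     r.thresholds[0]))
        pinned_mod = best_vig[0].thresholds[0]

    # step 2: moderate (light, mod) pair
    mods = sorted(by_cat["moderate"], key=lambda r: r.thresholds)
    if pinned_mod is not None:
        mods = [r for r in mods if r.thresholds[1] == pinned_mod]
        if not mods:
            raise ValueError("no moderate candidate consistent with the vigorous choice")
    best_mod = _best(mods)
    best_mod.sort(key=lambda r: (
        abs((r.thresholds[1] - r.thresholds[0]) - ref_dist_mod),
        abs(r.thresholds[0] - reference.light_upper) + abs(r.thresholds[1] - reference.moderate_upper),
        r.thresholds,
    ))
    light_upper, moderate_upper = best_mod[0].thresholds

    # step 3: sedentary via the light candidates sharing the light threshold
    lights = sorted(
        (r for r in by_cat["light"] if r.thresholds[1] == light_upper),
        key=lambda r: r.thresholds,
    )
    if not lights:
        raise ValueError("no light candidate consistent with the moderate choice")
    best_light = _best(lights)
    best_light.sort(key=lambda r: (
        abs((r.thresholds[1] - r.thresholds[0]) - ref_dist_light),
        abs(r.thresholds[0] - reference.sedentary_upper),
        r.thresholds,
    ))
    sedentary_upper = best_light[0].thresholds[0]

    return CutPointSet(sedentary_upper, light_upper, moderate_upper)


def cross_validate(
    cuts: CutPointSet,
    ref_series: Sequence[EpochSeries],
    dom_series: Sequence[EpochSeries],
    reference: CutPointSet = REFERENCE_CUTPOINTS,
    calibration_ids: Iterable[str] | None = None,
    min_wear_hours: float = 16.0,
) -> list[AgreementReport]:
    """Validate translated cut points on an independent cohort.

    The non-dominant wrist with the reference set stays the criterion; the
    dominant wrist is classified with ``cuts``.  Overlap with the
    calibration cohort's participant ids is an error.
    """
    pids = {s.participant_id for s in ref_series} | {s.participant_id for s in dom_series}
    if calibration_ids is not None:
        overlap = pids & set(calibration_ids)
        if overlap:
            raise ValueError(
                f"cross-validation cohort overlaps calibration cohort: {sorted(overlap)}"
            )
    ref_minutes = cohort_category_minutes(ref_series, reference, min_wear_hours)
    dom_minutes = cohort_category_minutes(dom_series, cuts, min_wear_hours)
    common = [p for p in ref_minutes.index if p in dom_minutes.index]
    if len(common) < 3:
        raise ValueError("need at least 3 participants present on both wrists")
    thr = {
        "sedentary": (cuts.sedentary_upper,),
        "light": (cuts.sedentary_upper, cuts.light_upper),
        "moderate": (cuts.light_upper, cuts.moderate_upper),
        "vigorous": (cuts.moderate_upper,),
    }
    return [
        _category_report(
            c, thr[c],
            ref_minutes.loc[common, c].to_numpy(float),
            dom_minutes.loc[common, c].to_numpy(float),
        )
        for c in CATEGORIES
    ]


def reports_to_frame(reports: Sequence[AgreementReport]) -> pd.DataFrame:
    """Translation-table-shaped DataFrame (one row per candidate/category)."""
    rows = []
    for r in reports:
        rows.append({
            "category": r.category,
            "thresholds_mg": "-".join(f"{t:g}" for t in r.thresholds),
            "ref_mean_min": r.ref_mean,
            "ref_sd_min": r.ref_sd,
            "comp_mean_min": r.comp_mean,
            "comp_sd_min": r.comp_sd,
            "lccc": r.lccc,
            "mean_diff_min": r.mean_diff,
            "ci95_low": r.ci[0],
            "ci95_high": r.ci[1],
            "mape_pct": r.mape,
            "paired_t_p": r.p_value,
        })
    return pd.DataFrame(rows)
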