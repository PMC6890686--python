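"""Agreement statistics, grid search and the three-step cut-point selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from actimetry.agreement import (
    AgreementReport,
    CutPointSet,
    REFERENCE_CUTPOINTS,
    candidate_grid,
    classify_minutes,
    cohort_category_minutes,
    cross_validate,
    evaluate_grid,
    lccc,
    mape_group,
    mape_individual,
    mean_diff_ci,
    select_cutpoints,
    shared_variance,
)
from actimetry.io import EpochSeries
from actimetry import reference


EPD = 17280


def labeled_series(values_by_day, pid="P01", site="non_dominant_wrist",
                   waking_hours=(7, 23)):
    """Full days of epoch values with a fixed waking window."""
    values = np.concatenate(values_by_day).astype(float)
    n = values.size
    assert n % EPD == 0
    hours = (np.arange(n) % EPD) * 5 / 3600
    labels = np.where((hours >= waking_hours[0]) & (hours < waking_hours[1]),
                      "wake", "sleep").astype(object)
    return EpochSeries(pid, site, "ENMO", pd.Timestamp("2019-01-07"),
                       values, labels=labels)


class TestCutPointSet:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            CutPointSet(100, 50, 430)

    def test_boundary_value_goes_to_upper_category(self):
        cuts = CutPointSet(50, 110, 440)
        assert cuts.classify(np.array([49.999, 50.0, 110.0, 440.0])).tolist() == [0, 1, 2, 3]


class TestClassifyMinutes:
    def test_constant_sedentary_day(self):
        series = labeled_series([np.full(EPD, 30.0)])
        summary = classify_minutes(series, REFERENCE_CUTPOINTS)
        assert summary.per_participant["sedentary"] == pytest.approx(960.0)
        assert summary.per_participant["light"] == 0.0

    def test_category_minutes_sum_to_waking_wear_minutes(self):
        rng = np.random.default_rng(0)
        series = labeled_series([rng.lognormal(3, 1.2, EPD) for _ in range(2)])
        summary = classify_minutes(series, REFERENCE_CUTPOINTS)
        for _, row in summary.per_day.iterrows():
            total = sum(row[c] for c in ("sedentary", "light", "moderate", "vigorous"))
            assert total == pytest.approx(row["waking_wear_min"])

    def test_unlabeled_series_rejected(self):
        series = EpochSeries("P01", "hip", "ENMO", pd.Timestamp("2019-01-07"),
                             np.zeros(EPD))
        with pytest.raises(ValueError, match="label"):
            classify_minutes(series, REFERENCE_CUTPOINTS)


class TestLccc:
    def test_perfect_concordance(self):
        x = np.array([1.0, 2, 3, 4])
        assert lccc(x, x) == pytest.approx(1.0)

    def test_constant_shift_closed_form(self):
        x = np.array([1.0, 2.0, 3.0])
        assert lccc(x, x + 1) == pytest.approx(4 / 7)

    def test_perfect_discordance(self):
        x = np.array([-1.0, 0.0, 1.0])
        assert lccc(x, -x) == pytest.approx(-1.0)

    def test_degenerate_inputs(self):
        c = np.array([5.0, 5.0, 5.0])
        assert lccc(c, c) == 1.0
        assert lccc(c, c + 2) == 0.0

    @given(st.integers(0, 10_000))
    def test_never_exceeds_pearson_magnitude(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = rng.normal(size=8) + 0.5 * x
        r = stats.pearsonr(x, y).statistic
        assert lccc(x, y) <= abs(r) + 1e-12


class TestMeanDiffAndMape:
    def test_identical_vectors(self):
        x = np.array([1.0, 2, 3])
        assert mean_diff_ci(x, x) == (0.0, (0.0, 0.0))

    def test_exact_constant_shift(self):
        x = np.array([1.0, 2, 3])
        d, ci = mean_diff_ci(x, x + 10)
        assert d == 10.0 and ci == (10.0, 10.0)

    def test_matches_direct_t_interval(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=12), rng.normal(size=12)
        d, (lo, hi) = mean_diff_ci(x, y)
        diff = y - x
        half = stats.t.ppf(0.975, 11) * diff.std(ddof=1) / math.sqrt(12)
        assert lo == pytest.approx(diff.mean() - half)
        assert hi == pytest.approx(diff.mean() + half)

    def test_group_mape_rounding(self):
        assert mape_group(769, -25) == 3.25
        assert mape_group(9, 0) == 0.0
        with pytest.raises(ValueError):
            mape_group(0, 5)

    def test_individual_mape_differs_from_group(self):
        x = np.array([100.0, 200.0])
        y = np.array([150.0, 150.0])
        assert mape_group(float(x.mean()), float((y - x).mean())) == 0.0
        assert mape_individual(x, y) == pytest.approx(37.5)


class TestSharedVariance:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r2, ci, p = shared_variance(x, 2 * x + 1)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_normals_rarely_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            _, _, p = shared_variance(rng.normal(size=42), rng.normal(size=42))
            hits += p > 0.05
        assert hits >= 18  # >= 90% of seeds

    def test_matches_bruteforce_correlation(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 1.5, 5.0, 6.0, 6.5])
        r2, _, _ = shared_variance(x, y)
        assert r2 == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)


def _cohort_series(rng, n_participants=4, days=2, ratio=1.0):
    ref, dom = [], []
    for i in range(n_participants):
        day_vals = [rng.lognormal(3.0, 1.15, EPD) for _ in range(days)]
        pid = f"P{i + 1:02d}"
        ref.append(labeled_series(day_vals, pid=pid))
        dom.append(labeled_series([ratio * v for v in day_vals], pid=pid,
                                  site="dominant_wrist"))
    return ref, dom


class TestGridSearch:
    def test_grid_has_table_structure(self):
        grid = candidate_grid()
        assert len(grid["sedentary"]) == 3
        assert len(grid["light"]) == 9
        assert len(grid["moderate"]) == 9
        assert len(grid["vigorous"]) == 3

    def test_identical_wrists_make_unshifted_candidate_perfect(self):
        rng = np.random.default_rng(11)
        ref, dom = _cohort_series(rng, ratio=1.0)
        ref_minutes = cohort_category_minutes(ref, REFERENCE_CUTPOINTS)
        reports = evaluate_grid(ref_minutes, dom)
        assert len(reports) == 24
        for r in reports:
            is_reference = (
                (r.category == "sedentary" and r.thresholds == (45.0,))
                or (r.category == "light" and r.thresholds == (45.0, 100.0))
                or (r.category == "moderate" and r.thresholds == (100.0, 430.0))
                or (r.category == "vigorous" and r.thresholds == (430.0,))
            )
            if is_reference:
                assert r.lccc == pytest.approx(1.0)
                assert r.mean_diff == 0.0
                assert r.mape == 0.0
        assert select_cutpoints(reports) == REFERENCE_CUTPOINTS

    def test_asymmetric_wrists_favour_shifted_candidate(self):
        rng = np.random.default_rng(13)
        ref, dom = _cohort_series(rng, ratio=1.1)
        ref_minutes = cohort_category_minutes(ref, REFERENCE_CUTPOINTS)
        reports = evaluate_grid(ref_minutes, dom)
        sed = {r.thresholds[0]: abs(r.mean_diff) for r in reports
               if r.category == "sedentary"}
        assert sed[50.0] < sed[45.0]


def _tied_reports(diff=0.0, mape=0.0, l=0.9):
    reports = []
    for cat, cands in candidate_grid().items():
        for thr in cands:
            reports.append(AgreementReport(
                category=cat, thresholds=thr, ref_mean=100, ref_sd=10,
                comp_mean=100 + diff, comp_sd=10, lccc=l, mean_diff=diff,
                ci=(diff - 1, diff + 1), mape=mape, p_value=0.5,
            ))
    return reports


class TestSelection:
    def test_published_table_yields_published_set(self):
        reports = reference.published_calibration_reports()
        assert select_cutpoints(reports) == CutPointSet(50.0, 110.0, 440.0)

    def test_full_tie_returns_reference_set(self):
        assert select_cutpoints(_tied_reports()) == REFERENCE_CUTPOINTS

    def test_selection_is_order_independent(self):
        reports = reference.published_calibration_reports()
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = list(reports)
            rng.shuffle(shuffled)
            assert select_cutpoints(shuffled) == CutPointSet(50.0, 110.0, 440.0)

    def test_missing_category_rejected(self):
        reports = [r for r in reference.published_calibration_reports()
                   if r.category != "vigorous"]
        with pytest.raises(ValueError, match="vigorous"):
            select_cutpoints(reports)


class TestCrossValidation:
    def test_identical_wrists_validate_cleanly(self):
        rng = np.random.default_rng(19)
        ref, dom = _cohort_series(rng, ratio=1.0)
        reports = cross_validate(CutPointSet(45, 100, 430), ref, dom)
        assert len(reports) == 4
        for r in reports:
            assert r.mean_diff == pytest.approx(0.0, abs=1e-9)
            assert r.lccc > 0.95

    def test_reference_cuts_on_asymmetric_cohort_undercount_sedentary(self):
        rng = np.random.default_rng(23)
        ref, dom = _cohort_series(rng, ratio=1.1)
        reports = cross_validate(REFERENCE_CUTPOINTS, ref, dom)
        sed = next(r for r in reports if r.category == "sedentary")
        assert sed.mean_diff < 0  # dominant wrist records higher accelerations

    def test_participant_overlap_rejected(self):
        rng = np.random.default_rng(29)
        ref, dom = _cohort_series(rng)
        with pytest.raises(ValueError, match="overlap"):
            cross_validate(REFERENCE_CUTPOINTS, ref, dom,
                           calibration_ids=["P01", "P99"])
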