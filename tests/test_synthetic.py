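"""Generator contracts: determinism, amplitude bookkeeping, site asymmetry."""

import numpy as np
import pytest
from scipy import stats

from actimetry.io import SITES
from actimetry.metrics import enmo
from actimetry.nonwear import detect_nonwear
from actimetry.synthetic import (
    CohortSpec,
    generate_cohort,
    generate_recording,
    generate_schedule,
    inject_calibration_error,
    intensity_label,
)

FAST = dict(sampling_rate=15.0, n_days=1)


class TestDeterminismAndShape:
    def test_identical_specs_give_identical_cohorts(self):
        spec = CohortSpec(n_participants=2, seed=7, **FAST)
        a = generate_cohort(spec)
        b = generate_cohort(CohortSpec(n_participants=2, seed=7, **FAST))
        for pa, pb in zip(a, b):
            for site in spec.sites:
                np.testing.assert_array_equal(
                    pa.recordings[site].samples, pb.recordings[site].samples
                )

    def test_shapes_match_the_spec(self):
        spec = CohortSpec(n_participants=2, seed=1, **FAST)
        cohort = generate_cohort(spec)
        assert len(cohort) == 2
        for p in cohort:
            assert set(p.recordings) == set(SITES)
            for rec in p.recordings.values():
                assert rec.duration_s == spec.n_days * 86400

    def test_schedule_tiles_the_day_exactly(self):
        spec = CohortSpec(n_participants=1, seed=3, **FAST)
        schedule = generate_schedule(spec, 0)
        schedule.validate()
        target, labels, nonwear = schedule.epoch_arrays()
        assert target.size == schedule.n_epochs
        assert all(l is not None for l in labels)

    def test_bout_labels_follow_reference_cuts(self):
        assert intensity_label(30) == "sedentary"
        assert intensity_label(45) == "light"      # lower bound inclusive
        assert intensity_label(200) == "moderate"
        assert intensity_label(440) == "vigorous"


class TestAmplitudeBookkeeping:
    def test_noiseless_enmo_equals_schedule_target(self):
        spec = CohortSpec(n_participants=1, seed=5, noise_sd=0.0,
                          nonwear_rate=0.0, **FAST)
        p = generate_cohort(spec)[0]
        series = enmo(p.recordings["non_dominant_wrist"])
        target = p.truth.target_mg
        active = target > 10
        rel = np.abs(series.values[active] - target[active]) / target[active]
        assert rel.max() < 0.02

    def test_static_schedule_gives_zero_enmo(self):
        spec = CohortSpec(n_participants=1, seed=5, noise_sd=0.0,
                          nonwear_rate=0.0, **FAST)
        schedule = generate_schedule(spec, 0)
        for b in schedule.bouts:
            b.amplitude_mg = 0.0
        rec = generate_recording(schedule, "non_dominant_wrist", spec)
        np.testing.assert_allclose(enmo(rec).values, 0.0, atol=1e-6)


class TestSiteStructure:
    def test_dominant_scales_by_asymmetry_ratio(self):
        spec = CohortSpec(n_participants=1, seed=9, noise_sd=0.0,
                          nonwear_rate=0.0, asymmetry_ratio=1.1, **FAST)
        p = generate_cohort(spec)[0]
        nd = enmo(p.recordings["non_dominant_wrist"]).values
        dom = enmo(p.recordings["dominant_wrist"]).values
        active = p.truth.target_mg > 20
        ratio = dom[active] / nd[active]
        assert np.median(ratio) == pytest.approx(1.1, rel=0.01)

    def test_waking_enmo_ordering_dominant_nondominant_hip(self):
        spec = CohortSpec(n_participants=2, seed=13, nonwear_rate=0.0, **FAST)
        means = {site: [] for site in SITES}
        for p in generate_cohort(spec):
            wake = p.truth.epoch_labels != "sleep"
            for site in SITES:
                means[site].append(enmo(p.recordings[site]).values[wake].mean())
        assert np.mean(means["dominant_wrist"]) > np.mean(means["non_dominant_wrist"])
        assert np.mean(means["non_dominant_wrist"]) > np.mean(means["hip"])

    def test_symmetric_wrists_differ_only_by_noise(self):
        spec = CohortSpec(
            n_participants=6, seed=17, asymmetry_ratio=1.0, nonwear_rate=0.0,
            sites=("dominant_wrist", "non_dominant_wrist"), **FAST,
        )
        dom, nd = [], []
        for p in generate_cohort(spec):
            wake = p.truth.epoch_labels != "sleep"
            dom.append(enmo(p.recordings["dominant_wrist"]).values[wake].mean())
            nd.append(enmo(p.recordings["non_dominant_wrist"]).values[wake].mean())
        assert stats.ttest_rel(dom, nd).pvalue > 0.05


class TestNonwearAndCalibrationInjection:
    def test_nonwear_interior_blocks_satisfy_rule(self):
        spec = CohortSpec(n_participants=1, seed=21, nonwear_rate=1.0,
                          nonwear_minutes=(120.0, 120.0), **FAST)
        p = generate_cohort(spec)[0]
        mask = detect_nonwear(p.recordings["non_dominant_wrist"])
        epb = mask.epochs_per_block
        assert p.truth.schedule.nonwear, "expected an injected episode"
        for start_ep, n_ep in p.truth.schedule.nonwear:
            # blocks whose 60-min centred window is fully inside the episode:
            # centre c = b*epb + epb//2 must satisfy c -+ 360 within bounds
            first = int(np.ceil((start_ep + 360 - epb // 2) / epb))
            last = (start_ep + n_ep - 360 - epb // 2) // epb
            assert last >= first
            assert mask.block_nonwear[first : last + 1].all()

    def test_identity_injection_is_identity(self):
        spec = CohortSpec(n_participants=1, seed=2, **FAST)
        rec = generate_cohort(spec)[0].recordings["hip"]
        out = inject_calibration_error(rec, np.zeros(3), np.ones(3))
        np.testing.assert_array_equal(out.samples, rec.samples)
        assert not out.calibrated

    def test_offset_injection_shifts_still_norms(self):
        from conftest import constant_recording

        rec = constant_recording((1.0, 0, 0), 60)
        out = inject_calibration_error(rec, [0.05, 0, 0], [1, 1, 1])
        norms = np.linalg.norm(out.samples, axis=1)
        assert np.abs(norms.mean() - 0.95) < 1e-9
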