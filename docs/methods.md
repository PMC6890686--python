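# Methods

`actimetry` implements a complete raw-accelerometry analysis chain for
multi-site (hip, dominant wrist, non-dominant wrist) recordings: epoch
metric computation, gravity auto-calibration, non-wear handling, sleep
segmentation, intensity classification with cut-point translation, and
curve-level comparison. This note documents the models, the tunable
constants, the synthetic-data model used to validate every stage, and the
numerical choices that were genuinely open.

## Epoch metrics

All metrics summarise a calibrated tri-axial signal a(t) (units of g) over
half-open 5-s epochs anchored at local midnight, expressed in milli-g:

* **ENMO** = mean over the epoch of max(‖a‖ − 1, 0). Truncation of
  negative deviations happens per sample, *before* averaging; this order
  matters whenever the norm dips below 1 g within an epoch.
* **LFENMO** = ENMO of the signal after a per-axis 4th-order Butterworth
  low-pass at 20 Hz. Filtering is zero-phase (forward–backward) by
  default so features stay aligned with their epochs; a single-pass mode
  exists behind `MetricConfig.zero_phase` because the phase convention is
  not standardised. When the cutoff is at or above Nyquist (sampling
  below 40 Hz) the filter is skipped with a warning and LFENMO equals
  ENMO by construction.
* **MAD** = mean over the epoch of |‖a‖ − m| where m is the epoch mean of
  ‖a‖ (mean amplitude deviation of the resultant norm).

ENMO and MAD depend only on the vector norm and are exactly rotation
invariant; LFENMO is rotation invariant only approximately (the filter is
per-axis), which holds to well under 1 mg for locomotion-band signals.
Activity counts are a proprietary vendor metric; they are imported from
epoch exports and carried through the same wear/imputation processing but
never computed here.

Epoch grid: the first epoch starts at the recording start advanced, if
necessary, to the next whole multiple of 5 s from midnight (partial head
epochs are dropped rather than fabricated); the trailing partial epoch is
dropped. Day boundaries fall at local midnight and all timestamps are
naive local clock time, because every downstream construct (30-min bins,
diaries, "24 h" accounting) is clock-based.

## Auto-calibration

Still periods measure pure gravity, so their mean vectors must lie on the
unit sphere. Still windows are non-overlapping 10-s segments with
per-axis SD below 13 mg on **all three** axes (deliberately stricter than
the 2-of-3 non-wear criterion). A per-axis gain and offset
(calibrated = raw·gain + offset) is fitted by iteratively reweighted least
squares: each window mean is projected to its closest point on the unit
sphere and each axis regressed onto the projection, until the mean
absolute sphere error improves by less than 1e-6 mg (the best-so-far
parameters are kept, so the error is non-increasing). The fit requires
window means at or beyond ±300 mg on every axis; without that sphere
coverage the identity calibration is returned with a flag and warning —
never a silent partial fit. Temperature covariates are omitted (the raw
exports handled here carry no temperature channel). On synthetic
distortions (offsets ≤ 50 mg, gains 0.97–1.03, ≥ 12 orientations) the
median recovery error is well below 3 mg / 0.003.

## Non-wear, clipping and imputation

Each 15-min block is classified non-wear when, over the 60-min window
centred on the block (truncated at recording edges), at least 2 of 3 axes
have SD strictly below 13 mg **or** at least 2 of 3 axes have a value
range strictly below 50 mg; statistics are computed on raw samples. Epochs
containing any sample strictly above 5.5 g (per axis or norm) are flagged
as clipped and treated like non-wear. Invalid epochs are imputed with the
mean of valid epochs at the same clock slot on the other recorded days; a
slot with no valid donor stays missing and is excluded from summaries.
Days with ≥ 16 h wear are valid and participants need ≥ 4 valid days for
inclusion; non-wear unmatched across sites is *not* deleted — each site
keeps its own record and only the validity decision is combined.

The centred-window construction blurs episode boundaries by up to half a
window: a block at the edge of a genuine non-wear episode sees a window
mixing worn and unworn signal and its classification is structurally
ambiguous. Recovery on synthetic cohorts is therefore scored on blocks
whose full 60-min window lies inside a single ground-truth state, where
sensitivity and specificity both exceed 0.95.

## Sleep segmentation

The detector runs on the non-dominant wrist only. The arm elevation angle
atan(z̄/√(x̄²+ȳ²)) is computed per 5-s step from step-averaged axes;
within the diary interval expanded by ±2 h, runs of successive absolute
angle change below 5° sustained ≥ 5 min are sleep candidates, candidates
separated by < 60 min are merged, and the longest merged block gives
(onset, wake). With no candidate the diary times are used, with a
warning. The detected segmentation is projected verbatim onto the hip and
dominant-wrist series of the same participant. The constants (5°, 5 min,
60 min, ±2 h) are configuration knobs; the detector is a
faithful-in-spirit member of the posture-angle family of wrist sleep
algorithms, not a re-implementation of any specific published tool. On
synthetic cohorts the median onset/wake error is ~1 min; isolated large
errors occur when a non-wear episode (frozen orientation) directly abuts
the sleep period and merges with it — a failure mode shared by real
angle-based detectors, and the reason diary guidance bounds the search.

## Intensity classification and cut-point translation

Waking, worn-or-imputed ENMO epochs are binned with a lower-inclusive /
upper-exclusive convention: sedentary [0, 45), light [45, 100), moderate
[100, 430), vigorous [430, ∞) mg for the non-dominant reference set.
Daily minutes are averaged over valid days into per-participant means —
the unit of all agreement analysis, so category minutes sum exactly to
waking wear minutes.

Translation to the dominant wrist evaluates each reference threshold
incremented by 0, 5 and 10 mg, structured by category: 3 sedentary
candidates, 9 light pairs, 9 moderate pairs, 3 vigorous candidates (24
rows). Each candidate is scored against the non-dominant reference with:

* **Lin's CCC** ρc = 2·s_xy / (s_x² + s_y² + (x̄−ȳ)²), with 1/n moment
  estimators; degenerate zero-variance inputs return 1 (equal means) or 0.
* **Paired mean difference** (dominant − reference) with its t-based 95%
  CI, and the paired-t p-value.
* **Group MAPE** = 100·|mean difference| / reference group mean, reported
  to two decimals. The per-participant mean of absolute percent errors is
  a different statistic and is provided separately (`mape_individual`)
  but not used for selection.

Selection proceeds vigorous → moderate → light/sedentary. Within each
step candidates are ordered by smallest |mean difference|, then smallest
MAPE, then largest LCCC; a full tie at one step defers the boundary to
the next; partial ties are broken by preserving the reference's
inter-threshold distance (e.g. moderate span 330 mg) and then by
proximity to the reference thresholds. The ordering of the three tie
metrics is a design choice — the published worked example does not pin a
strict order — and is fixed here with the published outcome (50/110/440
from the printed candidate table) as the regression test. Cross-validation
re-scores the selected set on an independent cohort (participant overlap
with the calibration cohort is an error).

Inter-metric comparability uses OLS shared variance r² with a Fisher-z CI
(endpoints squared, lower bound 0 when the r interval crosses zero) and
the slope-test p.

## Curve analysis and 1D SPM

Diurnal profiles are 30-min clock-bin means (epochs → bins per day → days
→ participants), optionally z-scored across the 48 bins so metrics with
different units share a plot; empty bins propagate as missing. Sorted
curves sort each complete day's 17,280 epoch values ascending and
down-average them onto Q nodes (Q=1440 by default, one per minute;
configurable), then average days within participant; the curve is
non-decreasing and preserves the day mean.

Paired curves are compared with one-dimensional statistical parametric
mapping: (1) a pointwise paired t statistic; (2) field smoothness (FWHM)
from the mean squared temporal gradient of the normalized residuals, with
an n/(n−1) correction for the degrees of freedom lost to mean-centring;
(3) the critical threshold t* solving the expected-Euler-characteristic
relation for a t field with resels (Q−1)/FWHM at the requested
family-wise α (two-sided by default, α/2 per tail); (4) cluster p-values
from the standard expected-cluster-count / cluster-extent approximation.
Zero-residual-variance nodes get a guarded statistic and a warning. A
sign-flip permutation max-|t| threshold (exact enumeration up to 2¹¹
flips) ships alongside as the non-parametric oracle and small-n fallback;
on smooth null fields the two thresholds agree within a few percent and
the empirical family-wise error rate is close to nominal (validated at
n = 15 pairs, Q = 200, FWHM ≈ 35 nodes — a regime where the smooth-field
assumptions genuinely hold; RFT becomes conservative for rougher fields
or fewer subjects, which is the safe direction).

## Synthetic cohort model

The generator exists so that every stage is testable against known truth.
Per participant it draws a daily schedule: nightly sleep windows (~23:15
bed, ~7:15 wake, 30-min jitter), waking bouts of 5–40 min with amplitudes
from a log-normal (median 20 mg, σ_log 1.15, truncated 3–700 mg) — chosen
to give roughly 12–13 h/day sedentary, 2–3 h light, ~1 h moderate and a
few minutes vigorous during 16 waking hours, the profile typical of adult
cohorts — and optional non-wear episodes of 45–150 min (0.3/day).

The signal model is gravity times (1 + s(t)) plus per-axis Gaussian noise
(5 mg default), clipped at ±6 g. Gravity is a unit vector performing an
angular random walk (4°/5-s step) while awake, frozen during sleep except
for posture shifts every 15–40 min (30–70°), and frozen completely during
non-wear. The wake drift makes waking time visibly non-still both to the
non-wear rule and to the 5° sleep detector; the sleep shifts keep sleep
classified as wear while leaving long still runs for the detector. The
dynamic component s(t) is a two-sinusoid mixture in 0.5–4 Hz (the human
locomotion band, transparent to the 20-Hz low-pass) *along* the gravity
direction, rescaled per epoch so that the noiseless epoch ENMO equals the
scheduled amplitude exactly — the amplitude bookkeeping that makes the
schedule the oracle for classification tests. The dominant wrist scales
the dynamic amplitude by `asymmetry_ratio` (1.1 default) and the hip by
`hip_attenuation` (0.6), reproducing the dominant > non-dominant > hip
ordering of waking accelerations; the single-ratio asymmetry is an
assumption (group means constrain no more), flagged as such.

What the generator does **not** emulate: biomechanically realistic gait
spectra, device-specific noise colouring, temperature drift, or movement
orthogonal to gravity. Passing tests therefore demonstrate correctness of
the *processing* under the stated statistical structure, not validity of
the physiological conclusions on real data. Signals are synthesised in
float32 (long accumulations downstream are performed in float64); the
default desk profile is 30 Hz, a few days, ≤ 12 participants — 100 Hz is
supported but slower.

Problem sizes used by the test suite (chosen to keep the default run
fast): metric oracle on 1000 random epochs at 50 Hz; concordance on a
6 × 2-day wrist cohort at 30 Hz plus a 100-Hz day; non-wear recovery on
12 × 1-day participants; calibration recovery over 100 seeded
distortions; cut-point scaling recovery over 20 seeds of 4 × 2-day
two-wrist cohorts; SPM null calibration over 1000 replicates; end-to-end
smoke on a 6 × 4-day three-site cohort. The translation grid tops out at
+10 mg, so with a 1.1 asymmetry the vigorous boundary saturates at 440 mg
(1.1 × 430 = 473 is not expressible); the scaling-recovery check is
asserted on the sedentary and light boundaries.

## Known limitations

* Counts are ingest-only; no attempt is made to reproduce the vendor
  band-pass.
* The sleep detector is a stand-in for the cited family of algorithms and
  is evaluated only on synthetic truth; naps and fragmented sleep are out
  of scope (one sleep period per night).
* Cut points are translated against a between-wrist criterion, not
  against energy expenditure; nothing here validates the thresholds'
  physiological meaning.
* RFT cluster p-values use the classical 1D approximations; for very few
  participants the permutation mode is the safer inference.
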