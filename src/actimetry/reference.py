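"""Published reference values for the dominant-wrist cut-point translation.

The non-dominant-wrist ENMO cut points 45/100/430 mg (Hildebrand et al.'s
thresholds for sedentary/light/moderate/vigorous intensity) are the field's
reference set.  A published translation study reported, for an adult
calibration sample wearing devices on both wrists, the agreement of every
grid candidate (each threshold incremented by 0/5/10 mg on the dominant
wrist) against that reference — group means and SDs of daily minutes,
Lin's CCC, the paired mean difference with its 95% CI and the group MAPE —
and selected 50/110/440 mg for the dominant wrist, cross-validated on an
independent sample.  Those printed statistics are encoded here verbatim:
they are the worked example for :func:`actimetry.agreement.select_cutpoints`
and the regression anchor for the MAPE arithmetic.
"""

from __future__ import annotations

from .agreement import AgreementReport, CutPointSet, REFERENCE_CUTPOINTS

#: The translated dominant-wrist set selected by the published study.
PUBLISHED_SELECTED_CUTPOINTS = CutPointSet(50.0, 110.0, 440.0)

# category, thresholds, ref mean, ref SD, comp mean, comp SD, LCCC,
# mean diff, (CI low, CI high), MAPE %
_CALIBRATION_ROWS = [
    ("sedentary", (45.0,),        769, 69, 744, 71, 0.86, -25, (-55, 6),   3.25),
    ("sedentary", (50.0,),        769, 69, 766, 69, 0.92,  -3, (-33, 27),  0.39),
    ("sedentary", (55.0,),        769, 69, 786, 67, 0.90,  17, (-13, 46),  2.21),
    ("light", (45.0, 100.0),      147, 29, 161, 34, 0.84,  14, (0, 28),    9.52),
    ("light", (45.0, 105.0),      147, 29, 170, 37, 0.73,  23, (9, 37),   15.65),
    ("light", (45.0, 110.0),      147, 29, 179, 38, 0.63,  31, (17, 46),  21.09),
    ("light", (50.0, 100.0),      147, 29, 139, 30, 0.91,  -8, (-21, 5),   5.44),
    ("light", (50.0, 105.0),      147, 29, 148, 33, 0.93,   1, (-12, 15),  0.68),
    ("light", (50.0, 110.0),      147, 29, 157, 34, 0.89,   9, (-4, 23),   6.12),
    ("light", (55.0, 100.0),      147, 29, 120, 27, 0.62, -27, (-40, -15), 18.37),
    ("light", (55.0, 105.0),      147, 29, 129, 29, 0.78, -19, (-31, -6),  12.93),
    ("light", (55.0, 110.0),      147, 29, 137, 31, 0.88, -10, (-23, 3),   6.80),
    ("moderate", (100.0, 430.0),  104, 28, 120, 30, 0.72,  16, (3, 28),   15.38),
    ("moderate", (100.0, 435.0),  104, 28, 120, 30, 0.72,  14, (0, 28),   13.46),
    ("moderate", (100.0, 440.0),  104, 28, 120, 30, 0.72,  16, (4, 29),   15.38),
    ("moderate", (105.0, 430.0),  104, 28, 111, 28, 0.82,   7, (-5, 19),   6.73),
    ("moderate", (105.0, 435.0),  104, 28, 111, 28, 0.81,   7, (-5, 19),   6.73),
    ("moderate", (105.0, 440.0),  104, 28, 111, 28, 0.81,   7, (-5, 19),   6.73),
    ("moderate", (110.0, 430.0),  104, 28, 103, 26, 0.84,  -1, (-13, 10),  0.96),
    ("moderate", (110.0, 435.0),  104, 28, 103, 26, 0.84,  -1, (-13, 11),  0.96),
    ("moderate", (110.0, 440.0),  104, 28, 103, 26, 0.84,  -1, (-13, 11),  0.96),
    ("vigorous", (430.0,),          9,  7,   9,  7, 0.95,   0, (-3, 3),    0.0),
    ("vigorous", (435.0,),          9,  7,   9,  7, 0.95,   0, (-3, 3),    0.0),
    ("vigorous", (440.0,),          9,  7,   9,  7, 0.95,   0, (-3, 3),    0.0),
]

_CROSS_VALIDATION_ROWS = [
    ("sedentary", (50.0,),        750, 78, 755, 94, 0.85,   5, (-36, 45),  0.67),
    ("light", (50.0, 110.0),      134, 34, 133, 36, 0.89,  -2, (-18, 15),  1.49),
    ("moderate", (110.0, 440.0),  103, 44,  97, 44, 0.92,  -6, (-26, 15),  5.82),
    ("vigorous", (440.0,),          7,  7,   7,  7, 0.90,   1, (-2, 4),   14.29),
]


def _to_reports(rows) -> list[AgreementReport]:
    return [
        AgreementReport(
            category=cat,
            thresholds=thr,
            ref_mean=float(rm), ref_sd=float(rs),
            comp_mean=float(cm), comp_sd=float(cs),
            lccc=float(l),
            mean_diff=float(d),
            ci=(float(ci[0]), float(ci[1])),
            mape=float(m),
            p_value=float("nan"),   # not printed in the source table
        )
        for cat, thr, rm, rs, cm, cs, l, d, ci, m in rows
    ]


def published_calibration_reports() -> list[AgreementReport]:
    """The 24 printed grid-candidate agreement rows of the calibration sample."""
    return _to_reports(_CALIBRATION_ROWS)


def published_cross_validation_reports() -> list[AgreementReport]:
    """The printed cross-validation block (reference 45/100/430 vs 50/110/440)."""
    return _to_reports(_CROSS_VALIDATION_ROWS)


__all__ = [
    "REFERENCE_CUTPOINTS",
    "PUBLISHED_SELECTED_CUTPOINTS",
    "published_calibration_reports",
    "published_cross_validation_reports",
]
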