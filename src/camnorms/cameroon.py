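"""Built-in adult Cameroonian norm set (normative sample: 395 healthy
HIV-seronegative adults, age 18-64, tested in French in Yaounde).

The scaled-score conversion tables and T-score regression coefficients below
are transcribed from the published norms for this battery.  Every table is
checked against the structural invariants (contiguous SS levels, gap-free
coverage of the instrument range, direction monotonicity) at import time by
the :class:`~camnorms.norms.ScaledScoreTable` constructor; a row failing
those checks would be a transcription error, not data.
"""

from __future__ import annotations

from .measures import MEASURES
from .norms import NormCoefficients, NormSet, ScaledScoreTable

# (ss, raw_lo, raw_hi), ss ascending.  Timed/error measures (CTT2, HCT, WCST)
# improve as raw falls, so their raw ranges descend with ss; correct/word
# counts ascend.  Action Fluency has no printed SS below 3 and Letter
# Fluency none below 2.
_SS_BINS: dict[str, tuple[tuple[int, int, int], ...]] = {
    "ctt2_time": (
        (1, 429, 450), (2, 396, 428), (3, 329, 395), (4, 269, 328),
        (5, 234, 268), (6, 199, 233), (7, 163, 198), (8, 143, 162),
        (9, 127, 142), (10, 113, 126), (11, 101, 112), (12, 91, 100),
        (13, 80, 90), (14, 72, 79), (15, 65, 71), (16, 55, 64),
        (17, 49, 54), (18, 11, 48), (19, 0, 10),
    ),
    "hct_errors": (
        (1, 163, 208), (2, 152, 162), (3, 143, 151), (4, 133, 142),
        (5, 122, 132), (6, 111, 121), (7, 100, 110), (8, 91, 99),
        (9, 80, 90), (10, 69, 79), (11, 55, 68), (12, 43, 54),
        (13, 34, 42), (14, 25, 33), (15, 22, 24), (16, 19, 21),
        (17, 17, 18), (18, 14, 16), (19, 0, 13),
    ),
    "stroop_correct": (
        (1, 0, 7), (2, 8, 12), (3, 13, 16), (4, 17, 18),
        (5, 19, 20), (6, 21, 23), (7, 24, 25), (8, 26, 29),
        (9, 30, 32), (10, 33, 36), (11, 37, 40), (12, 41, 44),
        (13, 45, 48), (14, 49, 53), (15, 54, 60), (16, 61, 71),
        (17, 72, 82), (18, 83, 122), (19, 123, 133),
    ),
    "wcst_errors": (
        (1, 60, 64), (2, 53, 59), (3, 51, 52), (4, 50, 50),
        (5, 48, 49), (6, 45, 47), (7, 40, 44), (8, 36, 39),
        (9, 30, 35), (10, 26, 29), (11, 21, 25), (12, 17, 20),
        (13, 14, 16), (14, 12, 13), (15, 11, 11), (16, 9, 10),
        (17, 8, 8), (18, 6, 7), (19, 0, 5),
    ),
    "category_fluency": (
        (1, 0, 2), (2, 3, 4), (3, 5, 5), (4, 6, 6),
        (5, 7, 7), (6, 8, 9), (7, 10, 10), (8, 11, 12),
        (9, 13, 14), (10, 15, 15), (11, 16, 17), (12, 18, 19),
        (13, 20, 21), (14, 22, 23), (15, 24, 25), (16, 26, 27),
        (17, 28, 28), (18, 29, 41), (19, 42, 45),
    ),
    "action_fluency": (
        (3, 0, 2), (4, 3, 4), (5, 5, 5), (6, 6, 6),
        (7, 7, 8), (8, 9, 9), (9, 10, 11), (10, 12, 12),
        (11, 13, 14), (12, 15, 16), (13, 17, 18), (14, 19, 20),
        (15, 21, 22), (16, 23, 25), (17, 26, 33), (18, 34, 35),
        (19, 36, 45),
    ),
    "letter_fluency": (
        (2, 0, 0), (3, 1, 1), (4, 2, 8), (5, 9, 11),
        (6, 12, 14), (7, 15, 17), (8, 18, 21), (9, 22, 26),
        (10, 27, 31), (11, 32, 34), (12, 35, 38), (13, 39, 44),
        (14, 45, 47), (15, 48, 50), (16, 51, 56), (17, 57, 71),
        (18, 72, 77), (19, 78, 80),
    ),
}

# T = 50 + 10*(SS - (b0 + b_edu*(edu+1)/10 + b_age*age/100 + b_male*male))/resid_sd
_COEFFICIENTS: dict[str, tuple[float, float, float, float, float]] = {
    #               b0      b_edu   b_age    b_male  resid_sd
    "ctt2_time":        (9.359, 2.690, -8.673, -0.029, 2.485),
    "hct_errors":       (9.640, 1.944, -7.529,  0.999, 2.639),
    "stroop_correct":  (10.556, 1.464, -7.586,  0.064, 2.755),
    "wcst_errors":      (8.230, 1.958, -3.361,  0.816, 2.835),
    "category_fluency": (8.710, 2.454, -6.271,  0.320, 2.665),
    "action_fluency":   (8.144, 2.406, -4.400,  0.475, 2.616),
    "letter_fluency":   (5.736, 3.819, -3.040,  0.519, 2.440),
}

_LABEL = "cameroon_adult"
_PROVENANCE = (
    "Adult Cameroonian norms for executive function and verbal fluency "
    "(normative sample of 395 HIV-seronegative adults, age 18-64); "
    "transcribed from the published conversion and regression tables."
)


def builtin_cameroon_norms() -> NormSet:
    """The built-in adult Cameroonian norm set (all 7 measures)."""
    measures = tuple(MEASURES.values())
    ss_tables = {
        name: ScaledScoreTable(MEASURES[name], bins)
        for name, bins in _SS_BINS.items()
    }
    coefficients = {
        name: NormCoefficients(MEASURES[name], *vals)
        for name, vals in _COEFFICIENTS.items()
    }
    return NormSet(
        label=_LABEL,
        provenance=_PROVENANCE,
        measures=measures,
        ss_tables=ss_tables,
        coefficients=coefficients,
    )
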