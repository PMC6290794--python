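"""End-to-end norm construction: normative sample -> complete norm set.

Per measure: build the raw -> scaled-score lookup from the normative sample,
fit the MFP demographic-correction model on the scaled scores, and emit the
linear T-score coefficients.  The result is a :class:`~camnorms.norms.NormSet`
ready for :func:`camnorms.scoring.score_frame`.
"""

from __future__ import annotations

import pandas as pd

from .measures import MEASURES
from .mfp import MFPModel, MFPResults
from .norms import NormSet
from .scaled import build_ss_table, quantile_scaled_scores


def fit_norm_set(
    normative: pd.DataFrame,
    measures: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    label: str = "refit",
    provenance: str = "",
) -> tuple[NormSet, dict[str, MFPResults]]:
    """Fit a norm set on a normative sample table.

    ``normative`` needs age, education, male and one raw-score column per
    measure (NaN = not administered; per-measure complete case).  Returns the
    norm set and the per-measure MFP fit results (for diagnostics such as
    selected FP shapes and bootstrap stability).
    """
    if measures is None:
        measures = tuple(m for m in MEASURES if m in normative.columns)
    if not measures:
        raise ValueError("no measure columns found in the normative table")
    ss_tables = {}
    coefficients = {}
    fits: dict[str, MFPResults] = {}
    for name in measures:
        measure = MEASURES[name]
        sub = normative.dropna(subset=[name])
        table = build_ss_table(measure, sub[name].to_numpy(dtype=float))
        ss = quantile_scaled_scores(sub[name].to_numpy(dtype=float), measure)
        res = MFPModel(ss, sub[["age", "education", "male"]]).fit(alpha=alpha)
        ss_tables[name] = table
        coefficients[name] = res.to_norm_coefficients(measure)
        fits[name] = res
    norm_set = NormSet(
        label=label,
        provenance=provenance,
        measures=tuple(MEASURES[m] for m in measures),
        ss_tables=ss_tables,
        coefficients=coefficients,
    )
    return norm_set, fits
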