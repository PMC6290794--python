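"""Raw -> scaled-score table construction (quantile normalization).

Scaled scores standardize raw-score quantiles of a normative sample to a
mean-10, SD-3 integer scale (1-19).  Each distinct raw value is oriented so
that higher = better, assigned the mid-rank plotting position
``q = (rank - 0.5) / n`` (ties share their mid-rank), mapped through the
standard normal quantile function ``z = Phi^{-1}(q)`` and scored
``ss = round(10 + 3 z)`` (half away from zero), clamped to [1, 19].  Bins are
the min/max observed raw value per SS level; the extreme bins are widened to
the instrument floor/ceiling and unobserved interior SS levels receive a
share of the raw gap between their observed neighbours, so the resulting
lookup is total on the instrument range.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .measures import TestMeasure
from .norms import SS_MAX, SS_MIN, ScaledScoreTable

MIN_SAMPLE_SIZE = 20


class SampleError(ValueError):
    """The normative sample cannot support a scaled-score table."""


def round_half_away(x):
    """Round to nearest integer, halves away from zero (so 10.5 -> 11, -10.5 -> -11)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def quantile_scaled_scores(values: np.ndarray, measure: TestMeasure) -> np.ndarray:
    """Integer scaled score for each sample value (mid-rank quantile mapping)."""
    oriented = measure.orient(np.asarray(values, dtype=float))
    n = oriented.size
    ranks = stats.rankdata(oriented, method="average")
    q = (ranks - 0.5) / n
    z = stats.norm.ppf(q)
    return np.clip(round_half_away(10.0 + 3.0 * z), SS_MIN, SS_MAX).astype(int)


def build_ss_table(measure: TestMeasure, values) -> ScaledScoreTable:
    """Construct a scaled-score lookup table from a normative raw sample.

    Parameters
    ----------
    measure : TestMeasure
        Measure descriptor (supplies orientation and the instrument range to
        which the extreme bins are widened).
    values : array-like
        Raw scores of the normative sample; at least 20 values, all within
        the instrument range, not all identical.

    Returns
    -------
    ScaledScoreTable

    Raises
    ------
    SampleError
        If the sample is too small, out of range, constant, or too sparse to
        give every interior SS level a non-empty raw range.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise SampleError("sample must be one-dimensional")
    if np.any(~np.isfinite(values)):
        raise SampleError(f"{measure.name}: sample contains non-finite values")
    if values.size < MIN_SAMPLE_SIZE:
        raise SampleError(
            f"{measure.name}: need at least {MIN_SAMPLE_SIZE} values to build a "
            f"scaled-score table, got {values.size}"
        )
    if np.any(values < measure.raw_min) | np.any(values > measure.raw_max):
        raise SampleError(
            f"{measure.name}: sample values outside instrument range "
            f"[{measure.raw_min}, {measure.raw_max}]"
        )
    if np.all(values == values[0]):
        raise SampleError(
            f"{measure.name}: constant sample has no quantile spread"
        )

    ss = quantile_scaled_scores(values, measure)

    # Bins in oriented space (higher oriented value = better = higher ss).
    oriented = measure.orient(values).astype(int)
    levels = np.unique(ss)
    obins: dict[int, list[int]] = {}
    for level in levels:
        sel = oriented[ss == level]
        obins[int(level)] = [int(sel.min()), int(sel.max())]

    # Fill unobserved interior levels by splitting the raw gap between the
    # neighbouring observed bins; split point gaps (no missing level) at the
    # midpoint.
    filled: dict[int, list[int]] = {int(levels[0]): obins[int(levels[0])]}
    for lo_level, hi_level in zip(levels[:-1], levels[1:]):
        lo_level, hi_level = int(lo_level), int(hi_level)
        lo_bin = filled[lo_level]
        hi_bin = obins[hi_level]
        gap = hi_bin[0] - lo_bin[1] - 1
        missing = hi_level - lo_level - 1
        if missing == 0:
            half = gap // 2
            lo_bin[1] += half
            filled[hi_level] = [lo_bin[1] + 1, hi_bin[1]]
        else:
            hi_bin = list(hi_bin)
            deficit = missing - gap
            if deficit > 0:
                # not enough unobserved raw values between the bins: borrow
                # spare width from the neighbouring bins themselves
                spare_lo = lo_bin[1] - lo_bin[0]
                spare_hi = hi_bin[1] - hi_bin[0]
                take_lo = min((deficit + 1) // 2, spare_lo)
                take_hi = min(deficit - take_lo, spare_hi)
                take_lo = min(deficit - take_hi, spare_lo)
                if take_lo + take_hi < deficit:
                    raise SampleError(
                        f"{measure.name}: sample too sparse to assign a raw range "
                        f"to every scaled score between {lo_level} and {hi_level}"
                    )
                lo_bin[1] -= take_lo
                hi_bin[0] += take_hi
            edges = np.linspace(lo_bin[1], hi_bin[0], missing + 2).round().astype(int)
            start = lo_bin[1] + 1
            for k in range(missing):
                end = int(edges[k + 1])
                # keep this fill bin non-empty while leaving >= 1 raw value
                # for each remaining fill bin
                end = min(max(end, start), hi_bin[0] - 1 - (missing - 1 - k))
                filled[lo_level + 1 + k] = [start, end]
                start = end + 1
            filled[hi_level] = [start, hi_bin[1]]
    # Widen extreme bins to the instrument range (oriented bounds).
    o_floor = int(min(measure.orient(measure.raw_min), measure.orient(measure.raw_max)))
    o_ceil = int(max(measure.orient(measure.raw_min), measure.orient(measure.raw_max)))
    filled[int(levels[0])][0] = o_floor
    filled[int(levels[-1])][1] = o_ceil

    # Back to original orientation.
    bins = []
    for level in sorted(filled):
        olo, ohi = filled[level]
        if measure.higher_is_better:
            lo, hi = olo, ohi
        else:
            lo, hi = -ohi, -olo
        bins.append((level, int(lo), int(hi)))
    return ScaledScoreTable(measure, tuple(bins))


def raw_to_ss(table: ScaledScoreTable, raw) -> int:
    """Scaled score for a raw value (clamps with a warning outside the range)."""
    return table.lookup(raw)


def ss_to_raw_midpoint(table: ScaledScoreTable, ss: int) -> int:
    """Floor of the midpoint of the SS bin; inverse of :func:`raw_to_ss` up to binning."""
    return table.midpoint(ss)
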