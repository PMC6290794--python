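"""Apply a norm set to subjects: T-scores, deficit scores, impairment flags.

Pipeline per subject and measure: raw -> scaled score (table lookup) ->
demographically corrected T-score (linear formula) -> deficit score.  The
deficit score grades impairment from 0 (T >= 40, none) to 5 (T < 20,
severe) in 5-point T steps.  Domain composites (executive over CTT2, HCT,
Stroop, WCST; verbal over the three fluency tests) are complete-case: they
are reported only when every member test is present.  A domain is impaired
when its mean deficit score exceeds 0.5 -- i.e. the subject is on average at
least mildly impaired on more than half of the member tests; a single
measure is impaired when its deficit score is >= 1 (T < 40).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .measures import DOMAIN_MEMBERS, MEASURE_NAMES, get_measure
from .mfp import Demographics
from .norms import NormCoefficients, NormSet

AGE_RANGE = (18.0, 64.0)
EDU_RANGE = (0.0, 20.0)

# deficit bin left edges on the T scale: deficit k for T in [edge_k, edge_{k-1})
_DEFICIT_EDGES = (20.0, 25.0, 30.0, 35.0, 40.0)


class ExtrapolationWarning(UserWarning):
    """Demographics outside the normative range; T-score is an extrapolation."""


def t_score(coef: NormCoefficients, ss, demo: Demographics) -> float:
    """Demographically corrected T-score for a scaled score.

    Emits :class:`ExtrapolationWarning` when age falls outside 18-64 or
    education outside 0-20 years (the norm was developed inside those
    ranges); the value is still returned, unrounded.
    """
    if not (AGE_RANGE[0] <= demo.age <= AGE_RANGE[1]) or not (
        EDU_RANGE[0] <= demo.education <= EDU_RANGE[1]
    ):
        warnings.warn(
            f"demographics (age={demo.age}, education={demo.education}) outside "
            f"the normative range; T-score is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    pred = coef.predict_ss(demo.age, demo.education, demo.male)
    return float(50.0 + 10.0 * (ss - pred) / coef.resid_sd)


def t_score_array(coef: NormCoefficients, ss, age, education, male) -> np.ndarray:
    """Vectorized T-score (no warnings; extrapolation handled by the caller)."""
    pred = coef.predict_ss(age, education, male)
    return 50.0 + 10.0 * (np.asarray(ss, dtype=float) - pred) / coef.resid_sd


def deficit_from_t(t) -> int:
    """Deficit score 0-5 from a T-score (0: T >= 40 ... 5: T < 20)."""
    t = float(t)
    if not np.isfinite(t):
        raise ValueError(f"T-score must be finite, got {t}")
    return int(5 - np.searchsorted(_DEFICIT_EDGES, t, side="right"))


def deficit_from_t_array(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return 5 - np.searchsorted(_DEFICIT_EDGES, t, side="right")


@dataclass(frozen=True)
class RawRecord:
    """One subject's raw test results and demographics."""

    subject_id: str
    group: str  # "hiv_neg" | "hiv_pos"
    demographics: Demographics
    raw: dict[str, float]
    covariates: dict[str, object] | None = None

    def __post_init__(self) -> None:
        if self.group not in ("hiv_neg", "hiv_pos"):
            raise ValueError(f"group must be 'hiv_neg' or 'hiv_pos', got {self.group!r}")
        if not self.raw:
            raise ValueError(f"{self.subject_id}: at least one raw score is required")
        for name in self.raw:
            get_measure(name)  # raises with the valid names listed


@dataclass(frozen=True)
class ScoredRecord:
    """Scores derived from one :class:`RawRecord` under a norm set."""

    subject_id: str
    group: str
    ss: dict[str, int]
    t: dict[str, float]
    deficit: dict[str, int]
    measure_impaired: dict[str, bool]
    domain_t: dict[str, float]
    domain_deficit: dict[str, float]
    domain_impaired: dict[str, bool]
    warnings: tuple[str, ...] = field(default=())


def score_record(record: RawRecord, norms: NormSet) -> ScoredRecord:
    """Score one subject: per-measure SS/T/deficit plus domain composites."""
    demo = record.demographics
    notes: list[str] = []
    if not (AGE_RANGE[0] <= demo.age <= AGE_RANGE[1]) or not (
        EDU_RANGE[0] <= demo.education <= EDU_RANGE[1]
    ):
        notes.append("extrapolation: demographics outside the normative range")
    ss: dict[str, int] = {}
    t: dict[str, float] = {}
    deficit: dict[str, int] = {}
    impaired: dict[str, bool] = {}
    for name, raw in record.raw.items():
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            continue
        if name not in norms.ss_tables:
            raise KeyError(
                f"{record.subject_id}: norm set {norms.label!r} has no norms for "
                f"{name!r}; it covers {', '.join(norms.measure_names)}"
            )
        table = norms.ss_tables[name]
        ss_val, clamped = table.lookup_array([raw])
        if clamped[0]:
            notes.append(f"{name}: raw {raw} outside instrument range, clamped")
        ss[name] = int(ss_val[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            t[name] = t_score(norms.coefficients[name], ss[name], demo)
        deficit[name] = deficit_from_t(t[name])
        impaired[name] = deficit[name] >= 1
    domain_t: dict[str, float] = {}
    domain_deficit: dict[str, float] = {}
    domain_impaired: dict[str, bool] = {}
    for domain, members in DOMAIN_MEMBERS.items():
        if all(m in t for m in members):
            domain_t[domain] = float(np.mean([t[m] for m in members]))
            domain_deficit[domain] = float(np.mean([deficit[m] for m in members]))
            domain_impaired[domain] = domain_deficit[domain] > 0.5
    return ScoredRecord(
        subject_id=record.subject_id,
        group=record.group,
        ss=ss,
        t=t,
        deficit=deficit,
        measure_impaired=impaired,
        domain_t=domain_t,
        domain_deficit=domain_deficit,
        domain_impaired=domain_impaired,
        warnings=tuple(notes),
    )


# --- DataFrame (cohort) interface ----------------------------------------

_DEMO_COLS = ("subject_id", "group", "age", "education", "male")


def score_frame(df: pd.DataFrame, norms: NormSet) -> pd.DataFrame:
    """Vectorized scoring of a cohort table.

    ``df`` must carry subject_id, group, age, education, male and one column
    per measure (NaN = not administered).  The returned frame adds ``ss_*``,
    ``t_*``, ``deficit_*`` and ``impaired_*`` columns per measure, domain
    composites (``t_executive`` etc.) and a boolean ``warn_extrapolation``.
    Any extra columns (HIV covariates) pass through untouched.
    """
    missing = [c for c in _DEMO_COLS if c not in df.columns]
    if missing:
        raise KeyError(f"cohort table is missing columns {missing}")
    out = df.reset_index(drop=True).copy()
    age = out["age"].to_numpy(dtype=float)
    edu = out["education"].to_numpy(dtype=float)
    male = out["male"].to_numpy(dtype=float)
    out["warn_extrapolation"] = (
        (age < AGE_RANGE[0]) | (age > AGE_RANGE[1])
        | (edu < EDU_RANGE[0]) | (edu > EDU_RANGE[1])
    )
    present = [m for m in norms.measure_names if m in out.columns]
    if not present:
        raise KeyError(
            f"cohort table has no measure columns; expected some of "
            f"{', '.join(norms.measure_names)}"
        )
    for name in present:
        raw = out[name].to_numpy(dtype=float)
        mask = np.isfinite(raw)
        ss = np.full(len(out), np.nan)
        tcol = np.full(len(out), np.nan)
        dcol = np.full(len(out), np.nan)
        if mask.any():
            ss_vals, clamped = norms.ss_tables[name].lookup_array(raw[mask])
            ss[mask] = ss_vals
            tcol[mask] = t_score_array(
                norms.coefficients[name], ss_vals, age[mask], edu[mask], male[mask]
            )
            dcol[mask] = deficit_from_t_array(tcol[mask])
            if clamped.any():
                warnings.warn(
                    f"{name}: {int(clamped.sum())} raw value(s) outside the "
                    "instrument range were clamped",
                    stacklevel=2,
                )
        out[f"ss_{name}"] = ss
        out[f"t_{name}"] = tcol
        out[f"deficit_{name}"] = dcol
        out[f"impaired_{name}"] = pd.array(
            np.where(np.isfinite(dcol), dcol >= 1, pd.NA), dtype="boolean"
        )
    for domain, members in DOMAIN_MEMBERS.items():
        tcols = [f"t_{m}" for m in members if f"t_{m}" in out.columns]
        dcols = [f"deficit_{m}" for m in members if f"deficit_{m}" in out.columns]
        if len(tcols) != len(members):
            continue
        complete = out[tcols].notna().all(axis=1)
        out[f"t_{domain}"] = out[tcols].mean(axis=1).where(complete)
        out[f"deficit_{domain}"] = out[dcols].mean(axis=1).where(complete)
        out[f"impaired_{domain}"] = pd.array(
            np.where(complete, out[f"deficit_{domain}"] > 0.5, pd.NA), dtype="boolean"
        )
    return out


def cohort_summary(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-group summary in the layout of the published comparison tables.

    One row per (group, measure-or-domain): complete-case n, mean and SD of
    the T-score, impaired count and percentage.  SD is NA for n < 2.
    """
    rows = []
    targets = [c[len("t_"):] for c in scored.columns if c.startswith("t_")]
    for group, sub in scored.groupby("group", sort=True):
        for name in targets:
            t = sub[f"t_{name}"].dropna()
            imp = sub[f"impaired_{name}"].dropna()
            rows.append(
                {
                    "group": group,
                    "measure": name,
                    "n": int(t.size),
                    "t_mean": float(t.mean()) if t.size else np.nan,
                    "t_sd": float(t.std(ddof=1)) if t.size >= 2 else np.nan,
                    "n_impaired": int(imp.sum()) if imp.size else 0,
                    "pct_impaired": float(100.0 * imp.mean()) if imp.size else np.nan,
                }
            )
    return pd.DataFrame(rows)


def score_cohort(records, norms: NormSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a cohort (DataFrame or RawRecord sequence); returns (scored, summary)."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(records)
    if not len(df):
        raise ValueError("cohort is empty")
    scored = score_frame(df, norms)
    return scored, cohort_summary(scored)


def records_to_frame(records) -> pd.DataFrame:
    """Flatten RawRecord objects into the wide cohort-table layout."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.demographics.age,
            "education": r.demographics.education,
            "male": r.demographics.male,
        }
        row.update({m: r.raw.get(m, np.nan) for m in MEASURE_NAMES})
        if r.covariates:
            row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)
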