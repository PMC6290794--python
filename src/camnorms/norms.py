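"""Norm data model: scaled-score lookup tables, T-score coefficients, norm sets.

A :class:`NormSet` bundles, per measure, (a) a raw-score -> scaled-score (SS)
lookup table and (b) the linear coefficients of the demographically corrected
T-score formula

    T = 50 + 10 * (SS - (b0 + b_edu*(edu+1)/10 + b_age*age/100 + b_male*male)) / resid_sd

Norm sets serialize to a small, human-auditable JSON dialect (documented in
:func:`save_norms`).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .measures import Direction, Domain, TestMeasure

SCHEMA_VERSION = 1

SS_MIN, SS_MAX = 1, 19


class NormValidationError(ValueError):
    """A norm component violates its structural invariants."""


class NormParseError(ValueError):
    """A norm file cannot be parsed into the documented schema."""


class ClampWarning(UserWarning):
    """A raw score fell outside the table range and was clamped to the extreme bin."""


@dataclass(frozen=True)
class ScaledScoreTable:
    """Lookup from raw-score ranges to integer scaled scores (1-19).

    ``bins`` is an ordered tuple of ``(ss, raw_lo, raw_hi)`` with ss ascending.
    A measure may lack low SS levels (printed as em-dashes in the source
    table), but present levels must be contiguous, ranges must tile the
    instrument range without gaps or overlap, and ranges must move in the
    direction implied by the measure's orientation.
    """

    measure: TestMeasure
    bins: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        m = self.measure
        if not self.bins:
            raise NormValidationError(f"{m.name}: empty scaled-score table")
        ss_vals = [b[0] for b in self.bins]
        if ss_vals != sorted(ss_vals) or len(set(ss_vals)) != len(ss_vals):
            raise NormValidationError(f"{m.name}: ss levels must be strictly increasing")
        if ss_vals[0] < SS_MIN or ss_vals[-1] > SS_MAX:
            raise NormValidationError(
                f"{m.name}: ss levels must lie in [{SS_MIN}, {SS_MAX}]"
            )
        if ss_vals != list(range(ss_vals[0], ss_vals[-1] + 1)):
            raise NormValidationError(f"{m.name}: ss levels must be contiguous")
        for ss, lo, hi in self.bins:
            if lo > hi:
                raise NormValidationError(
                    f"{m.name} ss={ss}: raw_lo ({lo}) > raw_hi ({hi})"
                )
        # Orientation: with ss ascending, raw ranges increase for
        # higher-is-better measures and decrease for lower-is-better ones.
        ordered = self.bins if m.higher_is_better else self.bins[::-1]
        prev_hi = None
        for ss, lo, hi in ordered:
            if prev_hi is not None and lo != prev_hi + 1:
                raise NormValidationError(
                    f"{m.name} ss={ss}: raw ranges overlap or leave a gap "
                    f"(expected raw_lo {prev_hi + 1}, got {lo})"
                )
            prev_hi = hi
        lo_all = ordered[0][1]
        hi_all = ordered[-1][2]
        if lo_all != m.raw_min or hi_all != m.raw_max:
            raise NormValidationError(
                f"{m.name}: table covers [{lo_all}, {hi_all}] "
                f"but instrument range is [{m.raw_min}, {m.raw_max}]"
            )

    @property
    def ss_min(self) -> int:
        return self.bins[0][0]

    @property
    def ss_max(self) -> int:
        return self.bins[-1][0]

    # --- lookup -----------------------------------------------------------

    def _raw_sorted(self):
        """Bins ordered by raw value ascending: (raw_lo array, ss array)."""
        ordered = self.bins if self.measure.higher_is_better else self.bins[::-1]
        return (
            np.array([b[1] for b in ordered]),
            np.array([b[0] for b in ordered]),
        )

    def lookup(self, raw: float) -> int:
        """Scaled score whose raw range contains ``raw`` (clamped with warning)."""
        ss, clamped = self.lookup_array(np.asarray([raw]))
        if clamped[0]:
            warnings.warn(
                f"{self.measure.name}: raw value {raw} outside instrument range "
                f"[{self.measure.raw_min}, {self.measure.raw_max}]; clamped",
                ClampWarning,
                stacklevel=2,
            )
        return int(ss[0])

    def lookup_array(self, raw) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized lookup.  Returns (ss, clamped_mask); no warning emitted."""
        raw = np.asarray(raw, dtype=float)
        clamped = (raw < self.measure.raw_min) | (raw > self.measure.raw_max)
        lows, ss = self._raw_sorted()
        idx = np.clip(np.searchsorted(lows, raw, side="right") - 1, 0, len(lows) - 1)
        return ss[idx], clamped

    def midpoint(self, ss: int) -> int:
        """Floor of the midpoint of the ``ss`` bin (inverse-lookup representative)."""
        for s, lo, hi in self.bins:
            if s == ss:
                return (lo + hi) // 2
        raise ValueError(
            f"{self.measure.name}: ss={ss} not in table "
            f"(valid range {self.ss_min}..{self.ss_max})"
        )

    def bin_bounds(self, ss: int) -> tuple[int, int]:
        for s, lo, hi in self.bins:
            if s == ss:
                return lo, hi
        raise ValueError(
            f"{self.measure.name}: ss={ss} not in table "
            f"(valid range {self.ss_min}..{self.ss_max})"
        )


@dataclass(frozen=True)
class NormCoefficients:
    """Linear T-score formula coefficients for one measure (scaled-score scale)."""

    measure: TestMeasure
    b0: float
    b_edu: float
    b_age: float
    b_male: float
    resid_sd: float

    def __post_init__(self) -> None:
        if not self.resid_sd > 0:
            raise NormValidationError(
                f"{self.measure.name}: resid_sd must be > 0, got {self.resid_sd}"
            )

    def predict_ss(self, age, education, male):
        """Expected scaled score for the given demographics."""
        age = np.asarray(age, dtype=float)
        education = np.asarray(education, dtype=float)
        male = np.asarray(male, dtype=float)
        return (
            self.b0
            + self.b_edu * (education + 1.0) / 10.0
            + self.b_age * age / 100.0
            + self.b_male * male
        )


@dataclass(frozen=True)
class NormSet:
    """A complete norm set: one SS table and one coefficient row per measure."""

    label: str
    measures: tuple[TestMeasure, ...]
    ss_tables: dict[str, ScaledScoreTable]
    coefficients: dict[str, NormCoefficients]
    provenance: str = ""

    def __post_init__(self) -> None:
        names = {m.name for m in self.measures}
        if len(names) != len(self.measures):
            raise NormValidationError("duplicate measures in norm set")
        for part, mapping in (("ss_tables", self.ss_tables), ("coefficients", self.coefficients)):
            if set(mapping) != names:
                missing = sorted(names - set(mapping))
                extra = sorted(set(mapping) - names)
                raise NormValidationError(
                    f"{part}: entries do not match measures "
                    f"(missing {missing}, unexpected {extra})"
                )
        for name in names:
            if self.ss_tables[name].measure.name != name:
                raise NormValidationError(f"ss_tables[{name}] describes a different measure")
            if self.coefficients[name].measure.name != name:
                raise NormValidationError(f"coefficients[{name}] describes a different measure")

    @property
    def measure_names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.measures)


# --- JSON serialization ----------------------------------------------------


def _norms_to_dict(norms: NormSet) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "label": norms.label,
        "provenance": norms.provenance,
        "measures": [
            {
                "name": m.name,
                "domain": m.domain.value,
                "direction": m.direction.value,
                "raw_min": m.raw_min,
                "raw_max": m.raw_max,
            }
            for m in norms.measures
        ],
        "ss_tables": {
            name: [
                {"ss": ss, "raw_lo": lo, "raw_hi": hi}
                for ss, lo, hi in table.bins
            ]
            for name, table in norms.ss_tables.items()
        },
        "coefficients": {
            name: {
                "b0": c.b0,
                "b_edu": c.b_edu,
                "b_age": c.b_age,
                "b_male": c.b_male,
                "resid_sd": c.resid_sd,
            }
            for name, c in norms.coefficients.items()
        },
    }


def _norms_from_dict(data: dict) -> NormSet:
    try:
        measures = tuple(
            TestMeasure(
                name=m["name"],
                domain=Domain(m["domain"]),
                direction=Direction(m["direction"]),
                raw_min=int(m["raw_min"]),
                raw_max=int(m["raw_max"]),
            )
            for m in data["measures"]
        )
        by_name = {m.name: m for m in measures}
        ss_tables = {}
        for name, rows in data["ss_tables"].items():
            if name not in by_name:
                raise NormParseError(f"ss_tables[{name}]: not a declared measure")
            ss_tables[name] = ScaledScoreTable(
                by_name[name],
                tuple(
                    (int(r["ss"]), int(r["raw_lo"]), int(r["raw_hi"])) for r in rows
                ),
            )
        coefficients = {}
        for name, c in data["coefficients"].items():
            if name not in by_name:
                raise NormParseError(f"coefficients[{name}]: not a declared measure")
            coefficients[name] = NormCoefficients(
                by_name[name],
                b0=float(c["b0"]),
                b_edu=float(c["b_edu"]),
                b_age=float(c["b_age"]),
                b_male=float(c["b_male"]),
                resid_sd=float(c["resid_sd"]),
            )
        return NormSet(
            label=data["label"],
            provenance=data.get("provenance", ""),
            measures=measures,
            ss_tables=ss_tables,
            coefficients=coefficients,
        )
    except KeyError as exc:
        raise NormParseError(f"norm file missing required field {exc.args[0]!r}") from exc
    except (TypeError, ValueError) as exc:
        if isinstance(exc, (NormParseError, NormValidationError)):
            raise
        raise NormParseError(f"malformed norm file: {exc}") from exc


def save_norms(norms: NormSet, path) -> None:
    """Write a norm set as JSON (keys: label, provenance, measures, ss_tables,
    coefficients; see the format note in the package docs)."""
    Path(path).write_text(json.dumps(_norms_to_dict(norms), indent=2) + "\n")


def load_norms(path) -> NormSet:
    """Read and validate a norm-set JSON file (round-trip inverse of save_norms)."""
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise NormParseError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(data, dict):
        raise NormParseError(f"{path}: top level must be a JSON object")
    return _norms_from_dict(data)
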