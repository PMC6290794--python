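"""Descriptors for the seven neuropsychological measures in the battery.

The battery covers two cognitive domains:

* executive function -- Color Trails-II completion time (seconds), Halstead
  Category Test total errors, Stroop Color-Word interference total correct,
  and WCST-64 total errors;
* verbal fluency -- Category (animals), Action (verbs) and Letter (F-A-S)
  fluency word counts.

For timed/error measures a *lower* raw score is better; for correct/word
counts a *higher* raw score is better.  All downstream code handles
orientation through :attr:`TestMeasure.direction` so that scaled scores are
always "higher = better".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Domain(str, enum.Enum):
    EXECUTIVE = "executive"
    VERBAL = "verbal"


class Direction(str, enum.Enum):
    LOWER_RAW_BETTER = "lower_raw_better"
    HIGHER_RAW_BETTER = "higher_raw_better"


@dataclass(frozen=True)
class TestMeasure:
    """One NP measure: identity, domain, score orientation, instrument range."""

    name: str
    domain: Domain
    direction: Direction
    raw_min: int
    raw_max: int

    def __post_init__(self) -> None:
        if self.raw_min >= self.raw_max:
            raise ValueError(
                f"{self.name}: raw_min ({self.raw_min}) must be < raw_max ({self.raw_max})"
            )

    @property
    def higher_is_better(self) -> bool:
        return self.direction is Direction.HIGHER_RAW_BETTER

    def orient(self, raw):
        """Map raw scores so that larger oriented values mean better performance."""
        return raw if self.higher_is_better else -raw


# Instrument floors/ceilings are the extreme bin edges of the published
# conversion table (e.g. CTT2 0-450 s, WCST-64 0-64 errors, Stroop 0-133).
MEASURES: dict[str, TestMeasure] = {
    m.name: m
    for m in (
        TestMeasure("ctt2_time", Domain.EXECUTIVE, Direction.LOWER_RAW_BETTER, 0, 450),
        TestMeasure("hct_errors", Domain.EXECUTIVE, Direction.LOWER_RAW_BETTER, 0, 208),
        TestMeasure("stroop_correct", Domain.EXECUTIVE, Direction.HIGHER_RAW_BETTER, 0, 133),
        TestMeasure("wcst_errors", Domain.EXECUTIVE, Direction.LOWER_RAW_BETTER, 0, 64),
        TestMeasure("category_fluency", Domain.VERBAL, Direction.HIGHER_RAW_BETTER, 0, 45),
        TestMeasure("action_fluency", Domain.VERBAL, Direction.HIGHER_RAW_BETTER, 0, 45),
        TestMeasure("letter_fluency", Domain.VERBAL, Direction.HIGHER_RAW_BETTER, 0, 80),
    )
}

MEASURE_NAMES: tuple[str, ...] = tuple(MEASURES)

EXECUTIVE_MEASURES: tuple[str, ...] = tuple(
    m for m, d in MEASURES.items() if d.domain is Domain.EXECUTIVE
)
VERBAL_MEASURES: tuple[str, ...] = tuple(
    m for m, d in MEASURES.items() if d.domain is Domain.VERBAL
)
DOMAIN_MEMBERS: dict[str, tuple[str, ...]] = {
    Domain.EXECUTIVE.value: EXECUTIVE_MEASURES,
    Domain.VERBAL.value: VERBAL_MEASURES,
}


def get_measure(name: str) -> TestMeasure:
    try:
        return MEASURES[name]
    except KeyError:
        raise KeyError(
            f"unknown measure {name!r}; valid measures are {', '.join(MEASURE_NAMES)}"
        ) from None
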