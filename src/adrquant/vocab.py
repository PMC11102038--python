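"""Controlled vocabularies shared across the pipeline.

Treatment outcomes follow the five clinical end points recorded in
spontaneous-report systems; severity grades follow the five-grade
architecture used by expert grading systems (CTCAE-style).
"""
from __future__ import annotations

from enum import Enum


class Outcome(str, Enum):
    """Clinical end point of treating one adverse reaction.

    Ordered from best (recovered) to worst (fatal); the ordinal index
    drives the penalty/weight vectors of the severity model.
    """

    RECOVERED = "O1"
    RECOVERING = "O2"
    NOT_RECOVERED = "O3"
    SEQUELAE = "O4"  # resolved with sequelae
    FATAL = "O5"

    @property
    def index(self) -> int:
        """0-based position in the canonical O1..O5 ordering."""
        return OUTCOMES.index(self)


OUTCOMES: tuple[Outcome, ...] = (
    Outcome.RECOVERED,
    Outcome.RECOVERING,
    Outcome.NOT_RECOVERED,
    Outcome.SEQUELAE,
    Outcome.FATAL,
)

#: Outcomes treated as "very serious" for reporting-rate stratification
#: (resolved with sequelae, fatal).
SERIOUS_OUTCOMES: frozenset[Outcome] = frozenset(
    {Outcome.SEQUELAE, Outcome.FATAL}
)


class Grade(str, Enum):
    """Severity grade: one of five zones on the severity-score axis."""

    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"
    LIFE_THREATENING = "life_threatening"
    DEATH = "death"

    @property
    def index(self) -> int:
        return GRADES.index(self)


GRADES: tuple[Grade, ...] = (
    Grade.MILD,
    Grade.MODERATE,
    Grade.SEVERE,
    Grade.LIFE_THREATENING,
    Grade.DEATH,
)

#: Grades whose ADRs count as "fatal" for underreporting correction and
#: fatal-risk target screening (life-threatening or death).
FATAL_GRADES: frozenset[Grade] = frozenset(
    {Grade.LIFE_THREATENING, Grade.DEATH}
)

#: System Organ Classes whose events are considered non-drug-induced and
#: excluded during report qualification.
DEFAULT_EXCLUDED_SOCS: frozenset[str] = frozenset(
    {
        "congenital, familial and genetic disorders",
        "surgical and medical procedures",
        "social circumstances",
        "product issues",
        "injury, poisoning and procedural complications",
    }
)
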