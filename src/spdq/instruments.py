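"""Questionnaire data model and deterministic scoring.

The painDETECT questionnaire (PD-Q) is a nine-item neuropathic-pain screen:
seven sensory symptom items graded 0-5 (never .. very strongly), one
pain-course-pattern item (four categories) and one radiating-pain yes/no item.
Three 0-10 numerical rating scales (NRS) for pain intensity are recorded but
never enter any total.

The Spine painDETECT questionnaire (SPDQ) re-weights the same nine items with
integer discriminant coefficients and subtracts a constant of 12; the
short-form SPDQ (SF-SPDQ) keeps only electric shock-like pain (weight -4) and
numbness (weight +9) and subtracts 7.  Both are positive (possible spinal
neuropathic pain) at a total score >= 0.  The PD-Q total ranges from -1 to 38
and is banded unlikely (<=12) / uncertain (13-18) / likely (>=19).

All scoring is exact integer arithmetic; no floats are involved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "SENSORY_ITEMS",
    "COURSE_PATTERNS",
    "COURSE_SCORES",
    "ALL_SCORED_ITEMS",
    "QuestionnaireRecord",
    "Instrument",
    "ScoreResult",
    "SPDQ",
    "SF_SPDQ",
    "BUILTIN_INSTRUMENTS",
    "get_instrument",
    "radiating_score",
    "score_pdq",
    "score_instrument",
    "classify",
    "pdq_band",
    "PDQ_MIN",
    "PDQ_MAX",
]

#: The seven sensory symptom items, in questionnaire order.
SENSORY_ITEMS: tuple[str, ...] = (
    "burning",
    "tingling",
    "light_touch",
    "electric_shock",
    "cold_heat",
    "numbness",
    "slight_pressure",
)

#: Pain-course-pattern response categories.
COURSE_PATTERNS: tuple[str, ...] = (
    "persistent_slight_fluct",
    "persistent_with_attacks",
    "attacks_no_pain_between",
    "attacks_with_pain_between",
)

#: PD-Q score contributed by each course-pattern category.
COURSE_SCORES: dict[str, int] = {
    "persistent_slight_fluct": 0,
    "persistent_with_attacks": -1,
    "attacks_no_pain_between": 1,
    "attacks_with_pain_between": 1,
}

#: All nine scored items (the NRS items are never scored).
ALL_SCORED_ITEMS: tuple[str, ...] = SENSORY_ITEMS + ("course_pattern", "radiating")

GROUP_LABELS = ("NeP-SD", "NocP")

#: Case (screen-target) group label.
CASE_LABEL = "NeP-SD"

PDQ_MIN, PDQ_MAX = -1, 38


def radiating_score(radiating: bool) -> int:
    """PD-Q encoding of the radiating-pain item: yes -> 2, no -> 0."""
    return 2 if radiating else 0


@dataclass(frozen=True)
class QuestionnaireRecord:
    """One respondent's questionnaire answers.

    Any field may be ``None`` (missing).  Sensory grades must be integers in
    [0, 5], NRS values integers in [0, 10]; out-of-range values are rejected
    rather than clamped, so data-entry faults surface immediately.
    """

    burning: int | None = None
    tingling: int | None = None
    light_touch: int | None = None
    electric_shock: int | None = None
    cold_heat: int | None = None
    numbness: int | None = None
    slight_pressure: int | None = None
    course_pattern: str | None = None
    radiating: bool | None = None
    nrs_current: int | None = None
    nrs_worst_4w: int | None = None
    nrs_avg_4w: int | None = None
    group_label: str | None = None

    def __post_init__(self) -> None:
        for item in SENSORY_ITEMS:
            v = getattr(self, item)
            if v is not None and (not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= 5):
                raise ValueError(f"{item}: grade must be an integer in [0, 5], got {v!r}")
        if self.course_pattern is not None and self.course_pattern not in COURSE_PATTERNS:
            raise ValueError(
                f"course_pattern: expected one of {COURSE_PATTERNS}, got {self.course_pattern!r}"
            )
        if self.radiating is not None and not isinstance(self.radiating, bool):
            raise ValueError(f"radiating: expected bool or None, got {self.radiating!r}")
        for item in ("nrs_current", "nrs_worst_4w", "nrs_avg_4w"):
            v = getattr(self, item)
            if v is not None and (not isinstance(v, int) or isinstance(v, bool) or not 0 <= v <= 10):
                raise ValueError(f"{item}: NRS must be an integer in [0, 10], got {v!r}")
        if self.group_label is not None and self.group_label not in GROUP_LABELS:
            raise ValueError(f"group_label: expected one of {GROUP_LABELS}, got {self.group_label!r}")

    def item_score(self, item: str) -> int | None:
        """PD-Q numeric encoding of one scored item (grade, course score, or 2/0)."""
        if item == "course_pattern":
            return None if self.course_pattern is None else COURSE_SCORES[self.course_pattern]
        if item == "radiating":
            return None if self.radiating is None else radiating_score(self.radiating)
        if item in SENSORY_ITEMS:
            return getattr(self, item)
        raise KeyError(item)

    def missing_items(self, items: tuple[str, ...] = ALL_SCORED_ITEMS) -> tuple[str, ...]:
        return tuple(i for i in items if self.item_score(i) is None)

    def is_case(self) -> bool | None:
        if self.group_label is None:
            return None
        return self.group_label == CASE_LABEL


@dataclass(frozen=True)
class Instrument:
    """A named integer scoring rule over the PD-Q item encodings.

    total = sum_i weight_i * grade_i
            + course_weight * course_score
            + radiating_weight * radiating_score
            - constant

    and the screen is positive iff total >= cutoff.  ``uses_course`` /
    ``uses_radiating`` control which items are *required* for a complete
    score; the SPDQ requires the course item even though its weight is zero.
    """

    name: str
    item_weights: Mapping[str, int] = field(default_factory=dict)
    course_weight: int = 0
    radiating_weight: int = 0
    uses_course: bool = False
    uses_radiating: bool = False
    constant: int = 0
    cutoff: int = 0

    def __post_init__(self) -> None:
        for item, w in self.item_weights.items():
            if item not in SENSORY_ITEMS:
                raise ValueError(f"unknown sensory item {item!r}")
            if not isinstance(w, int) or isinstance(w, bool):
                raise ValueError(f"weight for {item!r} must be an integer, got {w!r}")
        for name in ("course_weight", "radiating_weight", "constant", "cutoff"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ValueError(f"{name} must be an integer, got {v!r}")

    @property
    def required_items(self) -> tuple[str, ...]:
        items = [i for i in SENSORY_ITEMS if i in self.item_weights]
        if self.uses_course:
            items.append("course_pattern")
        if self.uses_radiating:
            items.append("radiating")
        return tuple(items)

    def score_range(self) -> tuple[int, int]:
        """Attainable [min, max] total, by extremes of each independent item."""
        lo = hi = -self.constant
        for w in self.item_weights.values():
            lo += min(0, 5 * w)
            hi += max(0, 5 * w)
        if self.uses_course:
            contrib = [self.course_weight * COURSE_SCORES[c] for c in COURSE_PATTERNS]
            lo += min(contrib)
            hi += max(contrib)
        if self.uses_radiating:
            contrib = [self.radiating_weight * s for s in (0, 2)]
            lo += min(contrib)
            hi += max(contrib)
        return lo, hi

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "item_weights": dict(self.item_weights),
            "course_weight": self.course_weight,
            "radiating_weight": self.radiating_weight,
            "uses_course": self.uses_course,
            "uses_radiating": self.uses_radiating,
            "constant": self.constant,
            "cutoff": self.cutoff,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Instrument":
        return cls(
            name=d["name"],
            item_weights={k: int(v) for k, v in d.get("item_weights", {}).items()},
            course_weight=int(d.get("course_weight", 0)),
            radiating_weight=int(d.get("radiating_weight", 0)),
            uses_course=bool(d.get("uses_course", False)),
            uses_radiating=bool(d.get("uses_radiating", False)),
            constant=int(d.get("constant", 0)),
            cutoff=int(d.get("cutoff", 0)),
        )


@dataclass(frozen=True)
class ScoreResult:
    """Outcome of scoring one record with one instrument.

    ``total`` and ``classification`` are ``None`` when the record is missing
    a required item (``complete`` is then False and ``missing`` lists them).
    """

    instrument_name: str
    total: int | None
    classification: str | None
    complete: bool
    missing: tuple[str, ...] = ()


# Published instruments. Integer discriminant weights over the PD-Q item
# encodings; constants chosen so the positivity cutoff is >= 0.
SPDQ = Instrument(
    name="SPDQ",
    item_weights={
        "burning": 1,
        "tingling": 2,
        "light_touch": -2,
        "electric_shock": -4,
        "cold_heat": -3,
        "numbness": 8,
        "slight_pressure": 1,
    },
    course_weight=0,
    radiating_weight=1,
    uses_course=True,
    uses_radiating=True,
    constant=12,
    cutoff=0,
)

SF_SPDQ = Instrument(
    name="SF-SPDQ",
    item_weights={"electric_shock": -4, "numbness": 9},
    constant=7,
    cutoff=0,
)

BUILTIN_INSTRUMENTS: dict[str, Instrument] = {"spdq": SPDQ, "sf-spdq": SF_SPDQ}


def get_instrument(name: str) -> Instrument:
    """Look up a built-in instrument by its (case-insensitive) name."""
    key = name.lower().replace("_", "-")
    try:
        return BUILTIN_INSTRUMENTS[key]
    except KeyError:
        raise KeyError(
            f"unknown instrument {name!r}; built-ins: {sorted(BUILTIN_INSTRUMENTS)}"
        ) from None


def pdq_band(total: int) -> str:
    """PD-Q interpretation band: unlikely (<=12), uncertain (13-18), likely (>=19)."""
    if total <= 12:
        return "unlikely"
    if total <= 18:
        return "uncertain"
    return "likely"


def classify(total: int, instrument: Instrument) -> str:
    """Binary classification at the instrument's cutoff (total >= cutoff -> positive)."""
    return "positive" if total >= instrument.cutoff else "negative"


def score_pdq(record: QuestionnaireRecord) -> ScoreResult:
    """Unweighted PD-Q total (sum of grades + course score + radiating score).

    Requires all nine scored items; the total lies in [-1, 38] and maps to
    the unlikely / uncertain / likely bands.
    """
    missing = record.missing_items(ALL_SCORED_ITEMS)
    if missing:
        return ScoreResult("PD-Q", None, None, False, missing)
    total = sum(record.item_score(i) for i in SENSORY_ITEMS)
    total += record.item_score("course_pattern") + record.item_score("radiating")
    return ScoreResult("PD-Q", total, pdq_band(total), True)


def score_instrument(record: QuestionnaireRecord, instrument: Instrument) -> ScoreResult:
    """Weighted instrument total; complete-case per instrument.

    A record missing any item the instrument requires yields no total (the
    SF-SPDQ can therefore still be scored when SPDQ-only items are missing).
    """
    missing = record.missing_items(instrument.required_items)
    if missing:
        return ScoreResult(instrument.name, None, None, False, missing)
    total = sum(w * record.item_score(i) for i, w in instrument.item_weights.items())
    if instrument.uses_course:
        total += instrument.course_weight * record.item_score("course_pattern")
    if instrument.uses_radiating:
        total += instrument.radiating_weight * record.item_score("radiating")
    total -= instrument.constant
    return ScoreResult(instrument.name, total, classify(total, instrument), True)
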