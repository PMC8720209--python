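"""Ordinal side-effect scales and patient health states.

Four radiation-related side effects define the pre-treatment health state:
erectile function (EPIC: percent of attempts in which an erection was
achieved), urinary incontinence (EPIC: frequency of uncontrolled urine
leakage), nocturia (IPSS: times per night woken to urinate), and bowel
incontinence (EPIC: frequency of uncontrolled stool leakage).

Each side effect is measured on a totally ordered ordinal scale listed best
level first; a later position in the list always means a worse state.  The
scales ship with standard EPIC/IPSS response sets and can be overridden
through a YAML/JSON scale registry for institutions using different item
wordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "SideEffect",
    "SideEffectScale",
    "HealthState",
    "ScaleError",
    "OffScaleError",
    "default_registry",
    "load_registry",
    "parse_health_state",
]


class ScaleError(ValueError):
    """A scale definition or health-state answer set is invalid."""


class OffScaleError(ScaleError):
    """A level label does not belong to the scale it was used with."""


class SideEffect(str, Enum):
    """The four modeled side effects."""

    ERECTILE_FUNCTION = "erectile_function"
    URINARY_INCONTINENCE = "urinary_incontinence"
    NOCTURIA = "nocturia"
    BOWEL_INCONTINENCE = "bowel_incontinence"

    @classmethod
    def coerce(cls, value: "SideEffect | str") -> "SideEffect":
        if isinstance(value, cls):
            return value
        key = str(value).strip().lower()
        alias = _SIDE_EFFECT_ALIASES.get(key)
        if alias is not None:
            return alias
        try:
            return cls(key)
        except ValueError:
            raise ScaleError(f"unknown side effect {value!r}") from None


# Common shorthand used on questionnaires and in cohort tables.
_SIDE_EFFECT_ALIASES: dict[str, SideEffect] = {
    "ed": SideEffect.ERECTILE_FUNCTION,
    "erectile_dysfunction": SideEffect.ERECTILE_FUNCTION,
    "ui": SideEffect.URINARY_INCONTINENCE,
    "bi": SideEffect.BOWEL_INCONTINENCE,
    "urinary_frequency": SideEffect.NOCTURIA,
}


@dataclass(frozen=True)
class SideEffectScale:
    """An ordered ordinal scale for one side effect, best level first.

    Parameters
    ----------
    side_effect
        Which side effect the scale measures.
    levels
        Distinct ordinal labels; position 0 is the best state and the last
        position the worst.
    question
        The questionnaire item wording shown during elicitation.
    """

    side_effect: SideEffect
    levels: tuple[str, ...]
    question: str = ""

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ScaleError(f"{self.side_effect.value}: a scale needs at least two levels")
        if len(set(self.levels)) != len(self.levels):
            raise ScaleError(f"{self.side_effect.value}: scale levels must be distinct")

    def __len__(self) -> int:
        return len(self.levels)

    def index(self, level: str) -> int:
        """Position of ``level`` on the scale (0 = best)."""
        try:
            return self.levels.index(level)
        except ValueError:
            raise OffScaleError(
                f"{level!r} is not a level of the {self.side_effect.value} scale "
                f"{list(self.levels)}"
            ) from None

    def is_worse(self, a: str, b: str) -> bool:
        """Strict ordinal comparison: is state ``a`` worse than state ``b``?"""
        return self.index(a) > self.index(b)

    @property
    def best(self) -> str:
        return self.levels[0]

    @property
    def worst(self) -> str:
        return self.levels[-1]


def default_registry() -> dict[SideEffect, SideEffectScale]:
    """The standard EPIC/IPSS response sets for the four side effects."""
    return {
        SideEffect.ERECTILE_FUNCTION: SideEffectScale(
            SideEffect.ERECTILE_FUNCTION,
            ("100%", "75%", "50%", "25%", "0%"),
            "Over the past 4 weeks, what percentage of the time that you wanted "
            "to have an erection were you able to achieve one?",
        ),
        SideEffect.URINARY_INCONTINENCE: SideEffectScale(
            SideEffect.URINARY_INCONTINENCE,
            (
                "rarely or never",
                "about once a week",
                "more than once a week",
                "about once a day",
                "more than once a day",
            ),
            "Over the past 4 weeks, how often have you had uncontrolled leakage "
            "of urine?",
        ),
        SideEffect.NOCTURIA: SideEffectScale(
            SideEffect.NOCTURIA,
            ("0", "1", "2", "3", "4", "5+"),
            "Over the past 4 weeks, how many times have you typically woken up "
            "to go to the bathroom after you went to bed?",
        ),
        SideEffect.BOWEL_INCONTINENCE: SideEffectScale(
            SideEffect.BOWEL_INCONTINENCE,
            (
                "rarely or never",
                "about once a week",
                "more than once a week",
                "about once a day",
                "more than once a day",
            ),
            "Over the past 4 weeks, how often have you had uncontrolled leakage "
            "of stool or feces?",
        ),
    }


def load_registry(path: str | Path) -> dict[SideEffect, SideEffectScale]:
    """Load a scale registry from a YAML or JSON file.

    The file maps side-effect ids to ``{levels: [...], question: ...}``.
    Side effects absent from the file keep their default scales.
    """
    path = Path(path)
    raw = path.read_text()
    data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    if not isinstance(data, Mapping):
        raise ScaleError(f"scale registry {path} must be a mapping")
    registry = default_registry()
    for key, entry in data.items():
        se = SideEffect.coerce(key)
        registry[se] = SideEffectScale(
            se,
            tuple(str(lv) for lv in entry["levels"]),
            str(entry.get("question", registry[se].question)),
        )
    return registry


@dataclass(frozen=True)
class HealthState:
    """One level per side effect: the patient's state on all four scales."""

    levels: Mapping[SideEffect, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", dict(self.levels))

    def validate(self, registry: Mapping[SideEffect, SideEffectScale]) -> "HealthState":
        missing = [se.value for se in SideEffect if se not in self.levels]
        if missing:
            raise ScaleError(f"health state is missing side effects: {missing}")
        extra = [se for se in self.levels if se not in SideEffect]
        if extra:
            raise ScaleError(f"health state has unknown side effects: {extra}")
        for se, level in self.levels.items():
            registry[se].index(level)  # raises OffScaleError if bad
        return self

    def level(self, side_effect: SideEffect | str) -> str:
        return self.levels[SideEffect.coerce(side_effect)]

    def to_dict(self) -> dict[str, str]:
        return {se.value: lv for se, lv in self.levels.items()}

    @classmethod
    def from_dict(
        cls,
        data: Mapping[str, str],
        registry: Mapping[SideEffect, SideEffectScale] | None = None,
    ) -> "HealthState":
        return parse_health_state(data, registry)


def parse_health_state(
    answers: Mapping[str, object],
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
) -> HealthState:
    """Map raw questionnaire answers onto scale levels.

    ``answers`` maps a side-effect id (or common shorthand such as ``ED``)
    to a raw response.  Responses are matched case-insensitively against the
    scale levels; integers are accepted for the nocturia count.

    Raises
    ------
    ScaleError
        If a side effect is missing or duplicated.
    OffScaleError
        If a response is not a level of its scale.
    """
    registry = registry if registry is not None else default_registry()
    levels: dict[SideEffect, str] = {}
    for key, raw in answers.items():
        se = SideEffect.coerce(key)
        if se in levels:
            raise ScaleError(f"duplicate answer for {se.value}")
        levels[se] = _match_level(registry[se], raw)
    missing = [se.value for se in SideEffect if se not in levels]
    if missing:
        raise ScaleError(f"missing answers for side effects: {missing}")
    return HealthState(levels)


def _match_level(scale: SideEffectScale, raw: object) -> str:
    text = str(raw).strip()
    lowered = {lv.lower(): lv for lv in scale.levels}
    if text.lower() in lowered:
        return lowered[text.lower()]
    raise OffScaleError(
        f"{text!r} is not a valid response for {scale.side_effect.value}; "
        f"expected one of {list(scale.levels)}"
    )
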