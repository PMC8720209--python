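"""Preference thresholds and willingness-to-accept valuations.

A patient states, for each side effect, the worst level they would
tolerate once side effects have stabilized (a year or more after
treatment) — the *preference threshold* — and the dollar amount they would
have to be paid to accept living strictly worse than that threshold for
the rest of their life (*willingness to accept*, WTA).  Dollars are
elicited as willingness to get paid rather than willingness to pay so the
patient's bank balance never caps the answer; the engine treats them
purely as burden magnitudes on a common scale.

The threshold level itself is tolerated: "worse than threshold" is strict.
A patient tolerating waking twice a night is paying to avoid *more than*
two wakings, not two.
"""

from __future__ import annotations

from typing import TYPE_CHECKING, Mapping

from pydantic import BaseModel, Field, field_validator

from .scales import SideEffect, SideEffectScale, default_registry
from .toxicity import ToxicityMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .engine import TreatmentCatalog

__all__ = [
    "PreferenceProfile",
    "PreferenceError",
    "exceedance_probability",
    "validate_profile",
    "mirrored_value_prompt",
]


class PreferenceError(ValueError):
    """A preference profile is inconsistent with the scales or catalog."""


class PreferenceProfile(BaseModel):
    """Per-side-effect thresholds and dollar valuations for one patient.

    Attributes
    ----------
    thresholds
        Maximum tolerated level per side effect (a label from the scale).
    wta_side_effect
        Dollars to accept living above the threshold for life, per side
        effect.
    wta_alternative_burden
        Dollars to endure each alternative's non-medical attributes
        (visits, time at the hospital, ...), per treatment id.
    wta_failure
        Dollars to accept biochemical failure.

    Dollar amounts are unbounded above by design; extreme values are legal
    and simply dominate the ranking.
    """

    thresholds: dict[SideEffect, str]
    wta_side_effect: dict[SideEffect, float]
    wta_alternative_burden: dict[str, float] = Field(default_factory=dict)
    wta_failure: float = 0.0

    @field_validator("wta_failure")
    @classmethod
    def _nonnegative_failure(cls, v: float) -> float:
        if not (v >= 0) or v != v or v in (float("inf"),):
            raise ValueError("wta_failure must be finite and nonnegative")
        return v

    @field_validator("wta_side_effect", "wta_alternative_burden")
    @classmethod
    def _nonnegative_dollars(cls, v: dict) -> dict:
        for key, dollars in v.items():
            if not (dollars >= 0) or dollars == float("inf"):
                raise ValueError(f"dollar value for {key} must be finite and nonnegative")
        return v


def exceedance_probability(
    matrix: ToxicityMatrix, pre_level: str, threshold: str
) -> float:
    """Probability the post-treatment state is strictly worse than ``threshold``.

    Sums ``P(post = j | pre = pre_level)`` over the post levels ``j`` that
    rank strictly worse (later on the scale) than the threshold level.
    Returns a value in [0, 1]; zero when the threshold is the worst level.
    """
    row = matrix.row(pre_level)
    t = matrix.index(threshold)
    return float(row[t + 1 :].sum())


def validate_profile(
    profile: PreferenceProfile,
    catalog: "TreatmentCatalog | None" = None,
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
) -> PreferenceProfile:
    """Check a profile against the scale registry and treatment catalog.

    Verifies every side effect has a threshold (on its scale) and a dollar
    value, that burden entries refer to catalog treatments, and normalizes
    currency to whole dollars.  Returns the normalized profile.
    """
    registry = registry if registry is not None else default_registry()
    for se in SideEffect:
        if se not in profile.thresholds:
            raise PreferenceError(f"missing threshold for {se.value}")
        registry[se].index(profile.thresholds[se])
        if se not in profile.wta_side_effect:
            raise PreferenceError(f"missing willingness-to-accept value for {se.value}")
    unknown = set(profile.thresholds) - set(SideEffect)
    if unknown:
        raise PreferenceError(f"thresholds given for unknown side effects: {sorted(unknown)}")
    if catalog is not None:
        known = set(catalog.treatments)
        bad = set(profile.wta_alternative_burden) - known
        if bad:
            raise PreferenceError(f"burden values for unknown treatments: {sorted(bad)}")
        burdens = {t: round(profile.wta_alternative_burden.get(t, 0.0)) for t in known}
    else:
        burdens = {t: round(v) for t, v in profile.wta_alternative_burden.items()}
    return PreferenceProfile(
        thresholds=dict(profile.thresholds),
        wta_side_effect={se: float(round(v)) for se, v in profile.wta_side_effect.items()},
        wta_alternative_burden={t: float(v) for t, v in burdens.items()},
        wta_failure=float(round(profile.wta_failure)),
    )


def mirrored_value_prompt(
    profile: PreferenceProfile,
    side_effect: SideEffect | str,
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
) -> str:
    """The value-elicitation question, restating the chosen threshold.

    The valuation page mirrors the health state selected on the threshold
    page: the prompt names living *worse than* exactly the level the
    patient declared tolerable.
    """
    registry = registry if registry is not None else default_registry()
    se = SideEffect.coerce(side_effect)
    level = profile.thresholds[se]
    registry[se].index(level)
    return (
        f"How much would we have to pay you to accept a {se.value.replace('_', ' ')} "
        f"state worse than {level!r} for the rest of your life?"
    )
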