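"""NCCN prostate-cancer risk stratification.

Implements the published NCCN rule set over clinical T stage, Grade Group,
PSA, and biopsy-core features, producing one of six risk groups
(very low .. very high), plus the three-way simplification
(LOW / INTERMEDIATE / HIGH) used by the decision aid because most outcome
data are reported at that granularity.

Rules are evaluated from most to least severe (very high -> high ->
unfavorable intermediate -> favorable intermediate -> very low -> low) so
that exclusions such as "no very high risk features" are honored.

Risk-factor definitions:

* intermediate risk factors (IRF): cT2b-cT2c; Grade Group 2 or 3;
  PSA 10-20 ng/mL
* high risk features (HRF): cT3a; Grade Group 4 or 5; PSA > 20 ng/mL
* very high risk features: cT3b-cT4; primary Gleason pattern 5;
  2 or 3 high risk features; > 4 cores with Grade Group 4 or 5
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "TStage",
    "NCCNRiskGroup",
    "BroadRisk",
    "RiskCategory",
    "ClinicalProfile",
    "ClassificationGapError",
    "classify_nccn",
    "to_broad_category",
]


class TStage(str, Enum):
    """Clinical T stages covered by the rule set (needle-biopsy T1c upward)."""

    T1C = "cT1c"
    T2A = "cT2a"
    T2B = "cT2b"
    T2C = "cT2c"
    T3A = "cT3a"
    T3B = "cT3b"
    T4 = "cT4"


class NCCNRiskGroup(str, Enum):
    VERY_LOW = "very_low"
    LOW = "low"
    FAVORABLE_INTERMEDIATE = "favorable_intermediate"
    UNFAVORABLE_INTERMEDIATE = "unfavorable_intermediate"
    HIGH = "high"
    VERY_HIGH = "very_high"


class BroadRisk(str, Enum):
    """Three-way simplification used for eligibility and success tables."""

    LOW = "LOW"
    INTERMEDIATE = "INTERMEDIATE"
    HIGH = "HIGH"


_BROAD_MAP: dict[NCCNRiskGroup, BroadRisk] = {
    NCCNRiskGroup.VERY_LOW: BroadRisk.LOW,
    NCCNRiskGroup.LOW: BroadRisk.LOW,
    NCCNRiskGroup.FAVORABLE_INTERMEDIATE: BroadRisk.INTERMEDIATE,
    NCCNRiskGroup.UNFAVORABLE_INTERMEDIATE: BroadRisk.INTERMEDIATE,
    NCCNRiskGroup.HIGH: BroadRisk.HIGH,
    NCCNRiskGroup.VERY_HIGH: BroadRisk.HIGH,
}


@dataclass(frozen=True)
class RiskCategory:
    """A fine NCCN group together with its broad three-way image."""

    nccn_group: NCCNRiskGroup
    broad: BroadRisk

    def __post_init__(self) -> None:
        if _BROAD_MAP[self.nccn_group] is not self.broad:
            raise ValueError(
                f"{self.nccn_group.value} maps to {_BROAD_MAP[self.nccn_group].value}, "
                f"not {self.broad.value}"
            )

    @classmethod
    def from_group(cls, group: NCCNRiskGroup) -> "RiskCategory":
        return cls(group, _BROAD_MAP[group])


class ClassificationGapError(ValueError):
    """The profile cannot be resolved by the printed rule set.

    Carries the name of the rule that could not be decided, typically
    because an optional biopsy detail needed by exactly one rule is absent.
    """

    def __init__(self, rule: str, detail: str):
        self.rule = rule
        super().__init__(f"cannot resolve rule {rule!r}: {detail}")


class ClinicalProfile(BaseModel):
    """Clinical and pathologic inputs to the risk classifier.

    ``max_single_core_involvement`` (percent tumor in the most involved
    core) is only consulted by the very-low-risk rule; leaving it out is
    legal unless that rule becomes decisive, in which case a
    :class:`ClassificationGapError` is raised rather than guessing.
    """

    t_stage: TStage
    grade_group: int = Field(ge=1, le=5)
    psa: float = Field(gt=0, description="PSA in ng/mL")
    cores_positive: int = Field(ge=0)
    cores_total: int = Field(ge=1)
    primary_gleason_pattern: Optional[int] = Field(default=None, ge=3, le=5)
    max_single_core_involvement: Optional[float] = Field(default=None, ge=0, le=100)
    cores_with_grade_group_4_or_5: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_core_counts(self) -> "ClinicalProfile":
        if self.cores_positive > self.cores_total:
            raise ValueError("cores_positive cannot exceed cores_total")
        if self.cores_with_grade_group_4_or_5 > self.cores_positive:
            raise ValueError("cores_with_grade_group_4_or_5 cannot exceed cores_positive")
        return self

    @property
    def fraction_cores_positive(self) -> float:
        return self.cores_positive / self.cores_total


def _intermediate_risk_factors(p: ClinicalProfile) -> int:
    return sum(
        (
            p.t_stage in (TStage.T2B, TStage.T2C),
            p.grade_group in (2, 3),
            10 <= p.psa <= 20,
        )
    )


def _high_risk_features(p: ClinicalProfile) -> int:
    return sum(
        (
            p.t_stage is TStage.T3A,
            p.grade_group in (4, 5),
            p.psa > 20,
        )
    )


def classify_nccn(profile: ClinicalProfile) -> RiskCategory:
    """Classify a clinical profile into its NCCN risk group.

    Deterministic, evaluated in severity order.  Raises
    :class:`ClassificationGapError` when a rule cannot be decided from the
    data supplied (only the very-low-risk core-involvement criterion can
    trigger this with valid inputs).
    """
    hrf = _high_risk_features(profile)

    # Very high: at least one of the listed features.
    if (
        profile.t_stage in (TStage.T3B, TStage.T4)
        or profile.primary_gleason_pattern == 5
        or hrf >= 2
        or profile.cores_with_grade_group_4_or_5 > 4
    ):
        return RiskCategory.from_group(NCCNRiskGroup.VERY_HIGH)

    # High: no very-high feature (excluded above) and exactly one high risk feature.
    if hrf == 1:
        return RiskCategory.from_group(NCCNRiskGroup.HIGH)

    irf = _intermediate_risk_factors(profile)
    if irf >= 1:
        # Unfavorable: 2-3 IRFs, or Grade Group 3, or >= 50% cores positive.
        if irf >= 2 or profile.grade_group == 3 or profile.fraction_cores_positive >= 0.5:
            return RiskCategory.from_group(NCCNRiskGroup.UNFAVORABLE_INTERMEDIATE)
        # Favorable: exactly one IRF, Grade Group 1 or 2, < 50% cores positive.
        if profile.grade_group in (1, 2):
            return RiskCategory.from_group(NCCNRiskGroup.FAVORABLE_INTERMEDIATE)
        raise ClassificationGapError(  # pragma: no cover - unreachable with valid enums
            "favorable_intermediate",
            f"one intermediate risk factor but Grade Group {profile.grade_group}",
        )

    # No intermediate or high risk factors: low-risk tier.
    # Stage is necessarily cT1c-cT2a, Grade Group 1, PSA < 10 here.
    if _qualifies_very_low(profile):
        return RiskCategory.from_group(NCCNRiskGroup.VERY_LOW)
    return RiskCategory.from_group(NCCNRiskGroup.LOW)


def _qualifies_very_low(p: ClinicalProfile) -> bool:
    if p.t_stage is not TStage.T1C:
        return False
    if p.cores_positive >= 3:
        return False
    # < 50% involvement required in each positive core; only decisive when
    # the other criteria already hold.
    if p.cores_positive > 0 and p.max_single_core_involvement is None:
        raise ClassificationGapError(
            "very_low",
            "max_single_core_involvement is required to separate very low "
            "from low risk (< 50% in each positive core)",
        )
    return p.cores_positive == 0 or p.max_single_core_involvement < 50


def to_broad_category(nccn_group: NCCNRiskGroup) -> BroadRisk:
    """Collapse the six NCCN groups onto LOW / INTERMEDIATE / HIGH."""
    return _BROAD_MAP[NCCNRiskGroup(nccn_group)]
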