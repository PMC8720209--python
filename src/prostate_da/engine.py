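"""Linear additive expected-cost evaluation and ranking of treatment alternatives.

Each eligible alternative is scored by a linear additive value function on
a common dollar scale.  For an alternative *a* with toxicity matrices
``M_{a,s}``, a pre-treatment state ``x``, and a preference profile with
thresholds ``τ_s``, side-effect valuations ``w_s``, alternative burdens
``b_a`` and failure valuation ``w_F``:

    side-effect cost  = Σ_s  P(post worse than τ_s | pre = x_s; M_{a,s}) · w_s
    burden cost       = b_a
    failure cost      = (1 − P(5-year FFBF | a, risk)) · w_F
    total             = side-effect + burden + failure

The engine computes expected *burden* (lower is better); a display layer
may negate it to present "value".  Ranking is a pure function of its
inputs, so re-evaluating after any single preference change gives the
real-time-update semantics of an interactive aid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .preferences import PreferenceError, PreferenceProfile, exceedance_probability, validate_profile
from .risk import BroadRisk, RiskCategory
from .scales import HealthState, SideEffect, SideEffectScale, default_registry
from .toxicity import ToxicityMatrix, identity_matrix

__all__ = [
    "TreatmentCatalog",
    "CatalogError",
    "ComponentCosts",
    "AlternativeEvaluation",
    "EvaluationResult",
    "SearchConfig",
    "default_catalog",
    "load_catalog",
    "eligible_alternatives",
    "component_costs",
    "rank_alternatives",
    "find_supporting_preferences",
]

ACTIVE_SURVEILLANCE = "active_surveillance"


class CatalogError(ValueError):
    """The treatment catalog is missing an entry the evaluation needs."""


class TreatmentCatalog(BaseModel):
    """Treatments, per-risk eligibility, and success probabilities.

    ``treatments`` is ordered least-intensive first; that order is the
    deterministic tie-break when two alternatives have equal total cost.
    ``success[treatment][risk]`` is the probability of 5-year freedom from
    biochemical failure for an eligible (treatment, risk) pair.
    """

    treatments: list[str]
    eligibility: dict[BroadRisk, list[str]]
    success: dict[str, dict[BroadRisk, float]]

    @model_validator(mode="after")
    def _check(self) -> "TreatmentCatalog":
        known = set(self.treatments)
        if len(known) != len(self.treatments):
            raise ValueError("duplicate treatment ids in catalog")
        for risk, subset in self.eligibility.items():
            unknown = set(subset) - known
            if unknown:
                raise ValueError(f"eligibility for {risk.value} names unknown treatments {sorted(unknown)}")
            for t in subset:
                p = self.success.get(t, {}).get(risk)
                if p is None:
                    raise ValueError(f"missing success probability for eligible pair ({t}, {risk.value})")
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"success probability for ({t}, {risk.value}) outside [0, 1]")
        return self

    def success_probability(self, treatment_id: str, risk: BroadRisk) -> float:
        try:
            return self.success[treatment_id][risk]
        except KeyError:
            raise CatalogError(
                f"no success probability for ({treatment_id}, {risk.value})"
            ) from None


def load_catalog(path: str | Path) -> TreatmentCatalog:
    """Load a catalog from a YAML or JSON config file."""
    path = Path(path)
    raw = path.read_text()
    data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    return TreatmentCatalog.model_validate(data)


def default_catalog() -> TreatmentCatalog:
    """The catalog shipped with the package (placeholder success values)."""
    raw = resources.files("prostate_da.data").joinpath("default_catalog.yaml").read_text()
    return TreatmentCatalog.model_validate(yaml.safe_load(raw))


def eligible_alternatives(risk: RiskCategory | BroadRisk, catalog: TreatmentCatalog) -> list[str]:
    """Treatments available for the patient's broad risk category."""
    broad = risk.broad if isinstance(risk, RiskCategory) else BroadRisk(risk)
    try:
        subset = catalog.eligibility[broad]
    except KeyError:
        raise CatalogError(f"catalog has no eligibility entry for {broad.value}") from None
    if not subset:
        raise CatalogError(f"catalog eligibility for {broad.value} is empty")
    return list(subset)


@dataclass(frozen=True)
class ComponentCosts:
    """Additive cost breakdown for one alternative, in dollars."""

    exceedance: Mapping[SideEffect, float]
    side_effect_cost: float
    burden_cost: float
    failure_cost: float

    @property
    def total(self) -> float:
        return self.side_effect_cost + self.burden_cost + self.failure_cost


MatrixMap = Mapping[tuple[str, SideEffect], ToxicityMatrix]


def _matrix_for(
    matrices: MatrixMap,
    treatment_id: str,
    side_effect: SideEffect,
    registry: Mapping[SideEffect, SideEffectScale] | None,
) -> ToxicityMatrix:
    m = matrices.get((treatment_id, side_effect))
    if m is not None:
        return m
    if treatment_id == ACTIVE_SURVEILLANCE:
        # No side effects are attributed to surveillance: state persists.
        return identity_matrix(side_effect, treatment_id, registry)
    raise CatalogError(f"no toxicity matrix for ({treatment_id}, {side_effect.value})")


def component_costs(
    pre_state: HealthState,
    profile: PreferenceProfile,
    alternative: str,
    matrices: MatrixMap,
    catalog: TreatmentCatalog,
    risk: RiskCategory | BroadRisk,
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
) -> ComponentCosts:
    """Evaluate the three additive cost components for one alternative."""
    broad = risk.broad if isinstance(risk, RiskCategory) else BroadRisk(risk)
    exceedance: dict[SideEffect, float] = {}
    se_cost = 0.0
    for se in SideEffect:
        matrix = _matrix_for(matrices, alternative, se, registry)
        p = exceedance_probability(matrix, pre_state.level(se), profile.thresholds[se])
        exceedance[se] = p
        se_cost += p * profile.wta_side_effect[se]
    burden = profile.wta_alternative_burden.get(alternative, 0.0)
    failure = (1.0 - catalog.success_probability(alternative, broad)) * profile.wta_failure
    return ComponentCosts(
        exceedance=exceedance,
        side_effect_cost=se_cost,
        burden_cost=burden,
        failure_cost=failure,
    )


@dataclass(frozen=True)
class AlternativeEvaluation:
    treatment_id: str
    costs: ComponentCosts
    rank: int
    is_best: bool


@dataclass(frozen=True)
class EvaluationResult:
    """Ranked evaluation of all eligible alternatives for one patient."""

    risk: BroadRisk
    alternatives: tuple[AlternativeEvaluation, ...]

    @property
    def best(self) -> AlternativeEvaluation:
        return next(a for a in self.alternatives if a.is_best)

    def to_records(self) -> list[dict]:
        return [
            {
                "treatment_id": a.treatment_id,
                "rank": a.rank,
                "is_best": a.is_best,
                **{f"exceedance_{se.value}": a.costs.exceedance[se] for se in SideEffect},
                "side_effect_cost": a.costs.side_effect_cost,
                "burden_cost": a.costs.burden_cost,
                "failure_cost": a.costs.failure_cost,
                "total_cost": a.costs.total,
            }
            for a in self.alternatives
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.to_records())

    def render_text(self, width: int = 40) -> str:
        """Plain-text bar chart; the best alternative is marked ``*best*``."""
        totals = [a.costs.total for a in self.alternatives]
        top = max(totals) or 1.0
        lines = [f"Expected burden by alternative ({self.risk.value} risk):"]
        for a in self.alternatives:
            bar = "#" * max(1, round(width * a.costs.total / top)) if a.costs.total > 0 else ""
            tag = "  *best*" if a.is_best else ""
            lines.append(f"  {a.treatment_id:<22} ${a.costs.total:>10,.0f} {bar}{tag}")
        return "\n".join(lines)


def rank_alternatives(
    pre_state: HealthState,
    profile: PreferenceProfile,
    matrices: MatrixMap,
    catalog: TreatmentCatalog,
    risk: RiskCategory | BroadRisk,
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
) -> EvaluationResult:
    """Rank eligible alternatives by ascending total expected cost.

    Lower expected burden is better.  Ties are broken by the catalog's
    documented treatment order (least-intensive first), making the result
    deterministic and independent of input iteration order.
    """
    broad = risk.broad if isinstance(risk, RiskCategory) else BroadRisk(risk)
    eligible = eligible_alternatives(broad, catalog)
    order = {t: i for i, t in enumerate(catalog.treatments)}
    costed = [
        (t, component_costs(pre_state, profile, t, matrices, catalog, broad, registry))
        for t in sorted(eligible, key=order.__getitem__)
    ]
    ranked = sorted(costed, key=lambda tc: (tc[1].total, order[tc[0]]))
    alternatives = tuple(
        AlternativeEvaluation(treatment_id=t, costs=c, rank=i + 1, is_best=(i == 0))
        for i, (t, c) in enumerate(ranked)
    )
    return EvaluationResult(risk=broad, alternatives=alternatives)


@dataclass(frozen=True)
class SearchConfig:
    """Grid for the preference-space search behind dominance checks.

    The search sweeps a documented grid: one threshold position applied
    across all four scales (clamped to each scale's length), side-effect
    dollar patterns that are either uniform over the four side effects or
    concentrated on a single one, failure dollars over ``dollar_grid``,
    and — when ``burden_lever`` is on — the option of charging every
    competing alternative ``high_burden`` dollars while the target costs
    nothing.
    """

    dollar_grid: tuple[float, ...] = (0.0, 100.0, 1_000.0, 10_000.0)
    burden_lever: bool = True
    high_burden: float = 10_000.0
    max_threshold_positions: int = 6


def _candidate_profiles(
    alternative: str,
    eligible: Sequence[str],
    config: SearchConfig,
    registry: Mapping[SideEffect, SideEffectScale],
) -> Iterable[PreferenceProfile]:
    nonzero = [v for v in config.dollar_grid if v > 0]
    se_patterns: list[dict[SideEffect, float]] = [
        {se: v for se in SideEffect} for v in config.dollar_grid
    ]
    se_patterns += [
        {se: (v if se is target else 0.0) for se in SideEffect}
        for target in SideEffect
        for v in nonzero
    ]
    burden_options: list[dict[str, float]] = [{t: 0.0 for t in eligible}]
    if config.burden_lever:
        burden_options.append(
            {t: (0.0 if t == alternative else config.high_burden) for t in eligible}
        )
    for pos in range(config.max_threshold_positions):
        thresholds = {
            se: registry[se].levels[min(pos, len(registry[se]) - 1)] for se in SideEffect
        }
        for wta_se, wta_fail, burdens in product(se_patterns, config.dollar_grid, burden_options):
            yield PreferenceProfile(
                thresholds=thresholds,
                wta_side_effect=dict(wta_se),
                wta_alternative_burden=dict(burdens),
                wta_failure=wta_fail,
            )


def find_supporting_preferences(
    alternative: str,
    pre_state: HealthState,
    matrices: MatrixMap,
    catalog: TreatmentCatalog,
    risk: RiskCategory | BroadRisk,
    search_config: SearchConfig | None = None,
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
) -> PreferenceProfile | None:
    """Search preference space for a profile making ``alternative`` the best.

    Exhaustively evaluates the :class:`SearchConfig` grid and returns the
    first profile under which the alternative is the *unique* cost
    minimizer, or ``None`` when no grid point supports it — the honest
    report that the alternative is dominated over the searched space.
    """
    config = search_config or SearchConfig()
    reg = registry if registry is not None else default_registry()
    broad = risk.broad if isinstance(risk, RiskCategory) else BroadRisk(risk)
    eligible = eligible_alternatives(broad, catalog)
    if alternative not in eligible:
        raise CatalogError(f"{alternative} is not eligible for {broad.value} risk")
    for profile in _candidate_profiles(alternative, eligible, config, reg):
        totals = {
            t: component_costs(pre_state, profile, t, matrices, catalog, broad, reg).total
            for t in eligible
        }
        best = min(totals.values())
        winners = [t for t, v in totals.items() if v <= best + 1e-12]
        if winners == [alternative]:
            return profile
    return None
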