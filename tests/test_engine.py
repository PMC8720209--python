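"""Linear additive evaluation, ranking, and preference-space search."""

import numpy as np
import pytest

from prostate_da import (
    ACTIVE_SURVEILLANCE,
    BroadRisk,
    CatalogError,
    PreferenceProfile,
    SearchConfig,
    SideEffect,
    TreatmentCatalog,
    component_costs,
    eligible_alternatives,
    estimate_matrix,
    find_supporting_preferences,
    identity_matrix,
    parse_health_state,
    rank_alternatives,
)

ED = SideEffect.ERECTILE_FUNCTION


@pytest.fixture(scope="module")
def pre_state():
    return parse_health_state(
        {"ED": "100%", "UI": "rarely or never", "nocturia": "0", "BI": "rarely or never"}
    )


def profile_with(registry, thresholds=None, wta_se=None, burdens=None, wta_failure=0.0):
    return PreferenceProfile(
        thresholds=thresholds or {se: registry[se].worst for se in SideEffect},
        wta_side_effect=wta_se or {se: 0.0 for se in SideEffect},
        wta_alternative_burden=burdens or {},
        wta_failure=wta_failure,
    )


class TestEligibility:
    def test_low_risk_includes_surveillance_and_sbrt(self, catalog):
        low = eligible_alternatives(BroadRisk.LOW, catalog)
        assert ACTIVE_SURVEILLANCE in low and "SBRT" in low

    def test_high_risk_excludes_surveillance(self, catalog):
        assert ACTIVE_SURVEILLANCE not in eligible_alternatives(BroadRisk.HIGH, catalog)

    def test_every_broad_category_has_options(self, catalog):
        for risk in BroadRisk:
            assert eligible_alternatives(risk, catalog)

    def test_empty_eligibility_entry_rejected(self):
        catalog = TreatmentCatalog(
            treatments=["SBRT"],
            eligibility={BroadRisk.LOW: [], BroadRisk.HIGH: ["SBRT"]},
            success={"SBRT": {BroadRisk.HIGH: 0.9}},
        )
        with pytest.raises(CatalogError, match="empty"):
            eligible_alternatives(BroadRisk.LOW, catalog)
        with pytest.raises(CatalogError, match="no eligibility"):
            eligible_alternatives(BroadRisk.INTERMEDIATE, catalog)


def single_arm_catalog(success=0.9):
    return TreatmentCatalog(
        treatments=["SBRT"],
        eligibility={BroadRisk.LOW: ["SBRT"]},
        success={"SBRT": {BroadRisk.LOW: success}},
    )


class TestComponentCosts:
    def test_hand_computed_additive_example(self, registry, pre_state):
        """0.5 exceedance x $1,000 + $100 burden + 0.1 x $2,000 failure = $800."""
        counts = np.zeros((5, 5), dtype=int)
        counts[0] = [1, 0, 0, 1, 0]  # pre 100%: half stay, half land below 50%
        counts[np.arange(1, 5), np.arange(1, 5)] = 1
        matrices = {("SBRT", se): identity_matrix(se, "SBRT") for se in SideEffect}
        matrices[("SBRT", ED)] = estimate_matrix(counts, "SBRT", ED, registry)
        profile = profile_with(
            registry,
            thresholds={
                ED: "50%",
                **{se: registry[se].worst for se in SideEffect if se is not ED},
            },
            wta_se={ED: 1000.0, **{se: 0.0 for se in SideEffect if se is not ED}},
            burdens={"SBRT": 100.0},
            wta_failure=2000.0,
        )
        costs = component_costs(
            pre_state, profile, "SBRT", matrices, single_arm_catalog(0.9),
            BroadRisk.LOW, registry,
        )
        assert costs.exceedance[ED] == pytest.approx(0.5)
        assert costs.side_effect_cost == pytest.approx(500.0)
        assert costs.burden_cost == pytest.approx(100.0)
        assert costs.failure_cost == pytest.approx(200.0)
        assert costs.total == pytest.approx(800.0)

    def test_all_zero_dollars_give_zero_components(self, registry, pre_state,
                                                   catalog, default_matrices):
        profile = profile_with(registry)
        costs = component_costs(pre_state, profile, "SBRT", default_matrices,
                                catalog, BroadRisk.LOW, registry)
        assert costs.total == 0.0

    def test_surveillance_within_thresholds_costs_nothing(self, registry,
                                                          pre_state, catalog):
        """Identity matrix: a state inside all thresholds stays there."""
        profile = profile_with(
            registry,
            wta_se={se: 10_000.0 for se in SideEffect},
        )
        costs = component_costs(pre_state, profile, ACTIVE_SURVEILLANCE, {},
                                catalog, BroadRisk.LOW, registry)
        assert costs.side_effect_cost == 0.0

    def test_additivity_on_random_instances(self, rng, registry, pre_state,
                                            catalog, default_matrices):
        """total == side-effect + burden + failure, always."""
        scale_levels = {se: registry[se].levels for se in SideEffect}
        for _ in range(1000):
            profile = PreferenceProfile(
                thresholds={se: lv[rng.integers(len(lv))] for se, lv in scale_levels.items()},
                wta_side_effect={se: float(rng.integers(0, 10_000)) for se in SideEffect},
                wta_alternative_burden={t: float(rng.integers(0, 10_000))
                                        for t in catalog.treatments},
                wta_failure=float(rng.integers(0, 10_000)),
            )
            t = catalog.treatments[rng.integers(len(catalog.treatments))]
            risk = next(r for r in BroadRisk if t in catalog.eligibility[r])
            costs = component_costs(pre_state, profile, t, default_matrices,
                                    catalog, risk, registry)
            assert costs.total == pytest.approx(
                costs.side_effect_cost + costs.burden_cost + costs.failure_cost,
                abs=1e-9,
            )

    def test_missing_matrix_is_an_error(self, registry, pre_state):
        with pytest.raises(CatalogError, match="matrix"):
            component_costs(pre_state, profile_with(registry), "SBRT", {},
                            single_arm_catalog(), BroadRisk.LOW, registry)


class TestRanking:
    def test_orders_by_ascending_total(self, registry, pre_state, catalog,
                                       default_matrices):
        profile = profile_with(
            registry,
            burdens={"SBRT": 300.0, ACTIVE_SURVEILLANCE: 800.0},
        )
        result = rank_alternatives(pre_state, profile, default_matrices,
                                   catalog, BroadRisk.LOW, registry)
        totals = [a.costs.total for a in result.alternatives]
        assert totals == sorted(totals)
        assert result.best.costs.total == min(totals)
        assert [a.rank for a in result.alternatives] == list(range(1, len(totals) + 1))
        assert sum(a.is_best for a in result.alternatives) == 1

    def test_tie_break_is_least_intensive_first(self, registry, pre_state,
                                                catalog, default_matrices):
        """With all dollars zero every total ties at 0; the catalog order
        (surveillance first) decides."""
        result = rank_alternatives(pre_state, profile_with(registry),
                                   default_matrices, catalog, BroadRisk.LOW, registry)
        assert result.best.treatment_id == ACTIVE_SURVEILLANCE

    def test_ranking_invariant_to_catalog_iteration_order(self, registry,
                                                          pre_state, catalog,
                                                          default_matrices):
        profile = profile_with(registry, burdens={"SBRT": 10.0, "EBRT_standard": 20.0})
        shuffled = TreatmentCatalog(
            treatments=catalog.treatments,
            eligibility={r: list(reversed(v)) for r, v in catalog.eligibility.items()},
            success=catalog.success,
        )
        a = rank_alternatives(pre_state, profile, default_matrices, catalog,
                              BroadRisk.LOW, registry)
        b = rank_alternatives(pre_state, profile, default_matrices, shuffled,
                              BroadRisk.LOW, registry)
        assert [x.treatment_id for x in a.alternatives] == [x.treatment_id for x in b.alternatives]

    def test_raising_burden_weakly_lowers_rank(self, registry, pre_state,
                                               catalog, default_matrices):
        base = profile_with(registry, burdens={"SBRT": 0.0})
        bumped = profile_with(registry, burdens={"SBRT": 10_000.0})
        rank = lambda res: next(a.rank for a in res.alternatives if a.treatment_id == "SBRT")
        r0 = rank(rank_alternatives(pre_state, base, default_matrices, catalog,
                                    BroadRisk.LOW, registry))
        r1 = rank(rank_alternatives(pre_state, bumped, default_matrices, catalog,
                                    BroadRisk.LOW, registry))
        assert r1 >= r0

    def test_dominance_soundness(self, rng, registry, pre_state, default_matrices,
                                 catalog):
        """If one alternative is component-wise no worse than another on every
        attribute (with burden equal), it never ranks below it."""
        for _ in range(100):
            profile = PreferenceProfile(
                thresholds={se: registry[se].levels[rng.integers(len(registry[se]))]
                            for se in SideEffect},
                wta_side_effect={se: float(rng.integers(0, 5000)) for se in SideEffect},
                wta_alternative_burden={},
                wta_failure=float(rng.integers(0, 5000)),
            )
            result = rank_alternatives(pre_state, profile, default_matrices,
                                       catalog, BroadRisk.LOW, registry)
            by_id = {a.treatment_id: a for a in result.alternatives}
            for a in by_id.values():
                for b in by_id.values():
                    dominates = (
                        all(a.costs.exceedance[se] <= b.costs.exceedance[se]
                            for se in SideEffect)
                        and a.costs.failure_cost <= b.costs.failure_cost
                        and a.costs.burden_cost <= b.costs.burden_cost
                    )
                    if dominates:
                        assert a.costs.total <= b.costs.total + 1e-9


class TestPreferenceSearch:
    def test_burden_lever_supports_every_alternative(self, registry, pre_state,
                                                     catalog, default_matrices):
        """With per-alternative burden free, every one of the seven
        alternatives has a supporting preference profile."""
        for treatment in catalog.treatments:
            risk = next(r for r in BroadRisk if treatment in catalog.eligibility[r])
            found = find_supporting_preferences(
                treatment, pre_state, default_matrices, catalog, risk,
                registry=registry,
            )
            assert found is not None, treatment

    def test_dominated_alternative_reported_not_found(self, registry, pre_state):
        """Burden lever off: an alternative with strictly worse toxicity and
        the lowest success probability admits no supporting profile."""
        worst = np.zeros((5, 5), dtype=int)
        worst[:, -1] = 1  # every pre-state lands on the worst level
        matrices = {("good", se): identity_matrix(se, "good") for se in SideEffect}
        for se in SideEffect:
            k = len(registry[se])
            counts = np.zeros((k, k), dtype=int)
            counts[:, -1] = 1
            matrices[("bad", se)] = estimate_matrix(counts, "bad", se, registry)
        catalog = TreatmentCatalog(
            treatments=["good", "bad"],
            eligibility={BroadRisk.LOW: ["good", "bad"]},
            success={"good": {BroadRisk.LOW: 0.95}, "bad": {BroadRisk.LOW: 0.5}},
        )
        config = SearchConfig(burden_lever=False)
        assert find_supporting_preferences("bad", pre_state, matrices, catalog,
                                           BroadRisk.LOW, config, registry) is None
        assert find_supporting_preferences("good", pre_state, matrices, catalog,
                                           BroadRisk.LOW, config, registry) is not None

    def test_ineligible_alternative_rejected(self, registry, pre_state, catalog,
                                             default_matrices):
        with pytest.raises(CatalogError, match="eligible"):
            find_supporting_preferences(ACTIVE_SURVEILLANCE, pre_state,
                                        default_matrices, catalog, BroadRisk.HIGH,
                                        registry=registry)
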