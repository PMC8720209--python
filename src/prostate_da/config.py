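"""Run configuration and the evaluation pipeline glue.

`run_evaluate` is the pure pipeline behind the `evaluate` CLI subcommand:
classify the clinical profile, select eligible alternatives, load or
default the toxicity matrices, validate the preference profile, and rank.
Output is a versioned JSON document (currency serialized as integer
dollars so repeated runs are byte-identical) with the inputs echoed for
audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

from . import __version__
from .engine import (
    ACTIVE_SURVEILLANCE,
    EvaluationResult,
    TreatmentCatalog,
    default_catalog,
    load_catalog,
    rank_alternatives,
)
from .preferences import PreferenceProfile, validate_profile
from .risk import ClinicalProfile, RiskCategory, classify_nccn
from .scales import HealthState, SideEffect, SideEffectScale, default_registry, load_registry, parse_health_state
from .toxicity import ToxicityMatrix, read_matrix

__all__ = ["RunConfig", "run_evaluate", "load_matrices_dir", "result_document"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class RunConfig:
    """Paths and run-level options shared by the CLI subcommands."""

    scale_registry_path: Path | None = None
    catalog_path: Path | None = None
    matrix_dir: Path | None = None
    seed: int = 0
    output_format: str = "json"  # json | csv | text
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.output_format not in ("json", "csv", "text"):
            raise ValueError(f"unknown output format {self.output_format!r}")
        for p in (self.scale_registry_path, self.catalog_path, self.matrix_dir):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")

    def registry(self) -> dict[SideEffect, SideEffectScale]:
        if self.scale_registry_path is not None:
            return load_registry(self.scale_registry_path)
        return default_registry()

    def catalog(self) -> TreatmentCatalog:
        if self.catalog_path is not None:
            return load_catalog(self.catalog_path)
        return default_catalog()


def load_matrices_dir(
    matrix_dir: str | Path,
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
) -> dict[tuple[str, SideEffect], ToxicityMatrix]:
    """Load every ``*.json`` toxicity matrix in a directory."""
    matrices = {}
    for path in sorted(Path(matrix_dir).glob("*.json")):
        m = read_matrix(path, registry)
        matrices[(m.treatment_id, m.side_effect)] = m
    return matrices


def _load_structured(path: str | Path) -> dict:
    path = Path(path)
    raw = path.read_text()
    return json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)


def result_document(
    result: EvaluationResult,
    risk: RiskCategory,
    inputs_echo: dict,
) -> dict:
    """Assemble the versioned output document (integer dollars throughout)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "generator": f"prostate-da {__version__}",
        "inputs": inputs_echo,
        "risk": {"nccn_group": risk.nccn_group.value, "broad": risk.broad.value},
        "alternatives": [
            {
                "treatment_id": a.treatment_id,
                "rank": a.rank,
                "is_best": a.is_best,
                "exceedance": {
                    se.value: round(a.costs.exceedance[se], 6) for se in SideEffect
                },
                "side_effect_cost": round(a.costs.side_effect_cost),
                "burden_cost": round(a.costs.burden_cost),
                "failure_cost": round(a.costs.failure_cost),
                "total_cost": round(a.costs.total),
            }
            for a in result.alternatives
        ],
        "best": result.best.treatment_id,
    }


def run_evaluate(
    config: RunConfig,
    clinical_profile_file: str | Path,
    health_state_file: str | Path,
    preference_file: str | Path,
    out_path: str | Path | None = None,
) -> dict:
    """Classify → eligibility → ranking, as a pure pipeline.

    Reads the three patient input files (JSON or YAML), runs the full
    evaluation, and returns (and optionally writes) the output document.
    Re-running with identical inputs produces byte-identical JSON.
    """
    registry = config.registry()
    catalog = config.catalog()
    matrices = (
        load_matrices_dir(config.matrix_dir, registry) if config.matrix_dir is not None else {}
    )

    clinical_raw = _load_structured(clinical_profile_file)
    state_raw = _load_structured(health_state_file)
    pref_raw = _load_structured(preference_file)

    profile = ClinicalProfile.model_validate(clinical_raw)
    risk = classify_nccn(profile)
    pre_state = parse_health_state(state_raw, registry)
    preferences = validate_profile(
        PreferenceProfile.model_validate(pref_raw), catalog, registry
    )

    result = rank_alternatives(pre_state, preferences, matrices, catalog, risk, registry)
    doc = result_document(
        result,
        risk,
        inputs_echo={
            "clinical_profile": json.loads(profile.model_dump_json()),
            "health_state": pre_state.to_dict(),
            "preferences": json.loads(preferences.model_dump_json()),
        },
    )
    if out_path is not None:
        Path(out_path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
    return doc
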