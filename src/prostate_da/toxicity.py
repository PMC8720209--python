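"""Toxicity transition matrices estimated from paired patient-reported outcomes.

A toxicity matrix for one (treatment, side effect) pair gives the
conditional probability of each post-treatment ordinal state given the
pre-treatment state, estimated by a frequentist count over paired pre/post
questionnaire records: ``P(post=j | pre=i) = counts[i, j] / row_totals[i]``.

Active surveillance carries no attributed side effects, so its matrices are
identity matrices (the state persists with probability 1).  Rows with no
observations are, by default, also set to the identity row and flagged,
which keeps matrices usable without inventing transitions; optional add-α
(Laplace) smoothing is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scales import OffScaleError, SideEffect, SideEffectScale, default_registry

__all__ = [
    "PairedPRORecord",
    "ToxicityMatrix",
    "MatrixFormatError",
    "tally_transitions",
    "estimate_matrix",
    "estimate_matrices",
    "identity_matrix",
    "assess_pretreatment_predictiveness",
    "read_matrix",
    "write_matrix",
    "read_cohort_csv",
    "write_cohort_csv",
]

_ROW_SUM_TOL = 1e-9


class MatrixFormatError(ValueError):
    """A matrix file is malformed or inconsistent with its scale."""


@dataclass(frozen=True)
class PairedPRORecord:
    """One patient's pre- and post-treatment answer for one side effect."""

    patient_id: str
    treatment_id: str
    side_effect: SideEffect
    pre_level: str
    post_level: str


@dataclass
class ToxicityMatrix:
    """Row-stochastic pre→post transition matrix with its raw counts.

    Raw counts and row totals are kept alongside the probabilities so that
    uncertainty analyses (e.g. bootstrap resampling of rows) remain
    possible downstream.
    """

    treatment_id: str
    side_effect: SideEffect
    levels: tuple[str, ...]
    counts: np.ndarray
    probabilities: np.ndarray
    row_totals: np.ndarray
    empty_rows: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.row_totals = np.asarray(self.row_totals, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        k = len(self.levels)
        if self.counts.shape != (k, k) or self.probabilities.shape != (k, k):
            raise MatrixFormatError(
                f"matrix shape {self.probabilities.shape} does not match the "
                f"{k}-level {self.side_effect.value} scale"
            )
        if (self.counts < 0).any():
            raise MatrixFormatError("counts must be nonnegative")
        if (self.probabilities < -_ROW_SUM_TOL).any():
            raise MatrixFormatError("probabilities must be nonnegative")
        sums = self.probabilities.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise MatrixFormatError(f"rows must sum to 1, got {sums.tolist()}")

    def index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise OffScaleError(
                f"{level!r} is not a level of this {self.side_effect.value} matrix"
            ) from None

    def row(self, pre_level: str) -> np.ndarray:
        return self.probabilities[self.index(pre_level)]

    def cell(self, pre_level: str, post_level: str) -> float:
        return float(self.probabilities[self.index(pre_level), self.index(post_level)])

    def cell_percent(self, pre_level: str, post_level: str, decimals: int = 2) -> float:
        """Cell probability as a percentage rounded for display (e.g. 17.39)."""
        return round(100.0 * self.cell(pre_level, post_level), decimals)

    def to_frame(self, values: str = "probabilities") -> pd.DataFrame:
        data = getattr(self, values)
        return pd.DataFrame(data, index=list(self.levels), columns=list(self.levels))


def _scale_for(
    side_effect: SideEffect,
    registry: Mapping[SideEffect, SideEffectScale] | None,
) -> SideEffectScale:
    registry = registry if registry is not None else default_registry()
    return registry[SideEffect.coerce(side_effect)]


def tally_transitions(
    records: Iterable[PairedPRORecord],
    treatment_id: str,
    side_effect: SideEffect | str,
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Count pre→post transitions for one treatment and side effect.

    Returns ``(counts, row_totals)`` where ``counts[i, j]`` is the number of
    records with pre level ``i`` and post level ``j`` (scale order, best
    first) and ``row_totals[i] = counts[i, :].sum()``.  Records for other
    treatments or side effects are rejected, as are off-scale levels.
    """
    side_effect = SideEffect.coerce(side_effect)
    scale = _scale_for(side_effect, registry)
    k = len(scale)
    counts = np.zeros((k, k), dtype=np.int64)
    for rec in records:
        if rec.treatment_id != treatment_id or SideEffect.coerce(rec.side_effect) is not side_effect:
            raise ValueError(
                f"record for ({rec.treatment_id}, {rec.side_effect}) passed to the "
                f"({treatment_id}, {side_effect.value}) tally"
            )
        counts[scale.index(rec.pre_level), scale.index(rec.post_level)] += 1
    return counts, counts.sum(axis=1)


def estimate_matrix(
    counts: np.ndarray,
    treatment_id: str,
    side_effect: SideEffect | str,
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
    alpha: float = 0.0,
    empty_row_policy: str = "identity",
) -> ToxicityMatrix:
    """Normalize transition counts into a row-stochastic matrix.

    Parameters
    ----------
    counts
        Square nonnegative integer matrix in scale order.
    alpha
        Add-α (Laplace) smoothing pseudo-count per cell; 0 (the default)
        gives the plain frequentist estimate counts / row total.
    empty_row_policy
        ``"identity"`` (default) assigns unobserved pre-states probability 1
        of persisting and flags the row; ``"error"`` raises instead.
    """
    side_effect = SideEffect.coerce(side_effect)
    scale = _scale_for(side_effect, registry)
    counts = np.asarray(counts)
    if counts.shape != (len(scale), len(scale)):
        raise MatrixFormatError(
            f"counts shape {counts.shape} does not match the {len(scale)}-level scale"
        )
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if alpha < 0:
        raise ValueError("smoothing alpha must be nonnegative")
    counts = counts.astype(np.int64)
    row_totals = counts.sum(axis=1)
    empty = row_totals == 0

    smoothed = counts + alpha
    denom = smoothed.sum(axis=1, dtype=float)
    probs = np.zeros_like(smoothed, dtype=float)
    occupied = denom > 0
    probs[occupied] = smoothed[occupied] / denom[occupied, None]

    if empty.any() and alpha == 0:
        if empty_row_policy == "error":
            labels = [scale.levels[i] for i in np.flatnonzero(empty)]
            raise MatrixFormatError(f"no observations for pre-state rows {labels}")
        if empty_row_policy != "identity":
            raise ValueError(f"unknown empty_row_policy {empty_row_policy!r}")
        probs[empty] = np.eye(len(scale))[empty]

    return ToxicityMatrix(
        treatment_id=treatment_id,
        side_effect=side_effect,
        levels=scale.levels,
        counts=counts,
        probabilities=probs,
        row_totals=row_totals,
        empty_rows=tuple(int(i) for i in np.flatnonzero(empty)),
    )


def estimate_matrices(
    records: Sequence[PairedPRORecord],
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
    alpha: float = 0.0,
) -> dict[tuple[str, SideEffect], ToxicityMatrix]:
    """Tally and estimate one matrix per (treatment, side effect) present."""
    grouped: dict[tuple[str, SideEffect], list[PairedPRORecord]] = {}
    for rec in records:
        key = (rec.treatment_id, SideEffect.coerce(rec.side_effect))
        grouped.setdefault(key, []).append(rec)
    out = {}
    for (treatment_id, side_effect), group in grouped.items():
        counts, _ = tally_transitions(group, treatment_id, side_effect, registry)
        out[(treatment_id, side_effect)] = estimate_matrix(
            counts, treatment_id, side_effect, registry, alpha=alpha
        )
    return out


def identity_matrix(
    side_effect: SideEffect | str,
    treatment_id: str = "active_surveillance",
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
) -> ToxicityMatrix:
    """The state-persists matrix used for untreated (active surveillance) arms."""
    side_effect = SideEffect.coerce(side_effect)
    scale = _scale_for(side_effect, registry)
    k = len(scale)
    eye = np.eye(k, dtype=np.int64)
    return ToxicityMatrix(
        treatment_id=treatment_id,
        side_effect=side_effect,
        levels=scale.levels,
        counts=eye,
        probabilities=eye.astype(float),
        row_totals=np.ones(k, dtype=np.int64),
    )


def assess_pretreatment_predictiveness(
    records: Sequence[PairedPRORecord],
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
) -> pd.DataFrame:
    """Rank association between pre- and post-treatment states per cell.

    For each (treatment, side effect) group, levels are encoded as scale
    ranks and the Spearman rank correlation between pre and post ranks is
    computed.  The statistic is NaN (undefined) when either side is
    constant; it is never coerced to zero.

    Returns a DataFrame with columns ``treatment_id``, ``side_effect_id``,
    ``n``, ``spearman_rho``, ``p_value``.
    """
    registry = registry if registry is not None else default_registry()
    grouped: dict[tuple[str, SideEffect], list[PairedPRORecord]] = {}
    for rec in records:
        key = (rec.treatment_id, SideEffect.coerce(rec.side_effect))
        grouped.setdefault(key, []).append(rec)

    rows = []
    for (treatment_id, side_effect), group in sorted(
        grouped.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        scale = registry[side_effect]
        pre = np.array([scale.index(r.pre_level) for r in group])
        post = np.array([scale.index(r.post_level) for r in group])
        if len(group) < 2 or len(np.unique(pre)) < 2 or len(np.unique(post)) < 2:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = stats.spearmanr(pre, post)
        rows.append(
            {
                "treatment_id": treatment_id,
                "side_effect_id": side_effect.value,
                "n": len(group),
                "spearman_rho": float(rho),
                "p_value": float(p),
            }
        )
    return pd.DataFrame(rows, columns=["treatment_id", "side_effect_id", "n", "spearman_rho", "p_value"])


# ---------------------------------------------------------------------------
# Serialization


def write_matrix(matrix: ToxicityMatrix, path: str | Path) -> None:
    """Write a matrix to JSON (full round-trip) or CSV (probabilities only).

    The JSON document stores counts, probabilities, row totals and level
    labels; the CSV layout is one matrix per file with the header row being
    the post-treatment levels and the index the pre-treatment levels.
    """
    path = Path(path)
    if path.suffix == ".csv":
        matrix.to_frame().to_csv(path, index_label="pre_level")
        return
    doc = {
        "schema_version": 1,
        "treatment_id": matrix.treatment_id,
        "side_effect_id": matrix.side_effect.value,
        "levels": list(matrix.levels),
        "counts": matrix.counts.tolist(),
        "probabilities": matrix.probabilities.tolist(),
        "row_totals": matrix.row_totals.tolist(),
        "empty_rows": list(matrix.empty_rows),
    }
    path.write_text(json.dumps(doc, indent=1) + "\n")


def read_matrix(
    path: str | Path,
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
) -> ToxicityMatrix:
    """Read a JSON matrix file, validating shape, labels and row sums."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise MatrixFormatError(f"{path}: not valid JSON ({exc})") from exc
    for key in ("treatment_id", "side_effect_id", "levels", "counts", "probabilities"):
        if key not in doc:
            raise MatrixFormatError(f"{path}: missing field {key!r}")
    side_effect = SideEffect.coerce(doc["side_effect_id"])
    scale = _scale_for(side_effect, registry)
    levels = tuple(doc["levels"])
    if levels != scale.levels:
        raise MatrixFormatError(
            f"{path}: level labels {list(levels)} do not match the registered "
            f"{side_effect.value} scale {list(scale.levels)}"
        )
    counts = np.asarray(doc["counts"])
    row_totals = np.asarray(doc.get("row_totals", counts.sum(axis=1)))
    return ToxicityMatrix(
        treatment_id=str(doc["treatment_id"]),
        side_effect=side_effect,
        levels=levels,
        counts=counts,
        probabilities=np.asarray(doc["probabilities"], dtype=float),
        row_totals=row_totals,
        empty_rows=tuple(doc.get("empty_rows", ())),
    )


_COHORT_COLUMNS = ["patient_id", "treatment_id", "side_effect_id", "pre_level", "post_level"]


def write_cohort_csv(records: Sequence[PairedPRORecord], path: str | Path) -> None:
    """Write paired PRO records as a delimited cohort table."""
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "treatment_id": r.treatment_id,
                "side_effect_id": SideEffect.coerce(r.side_effect).value,
                "pre_level": r.pre_level,
                "post_level": r.post_level,
            }
            for r in records
        ],
        columns=_COHORT_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_cohort_csv(
    path: str | Path,
    registry: Mapping[SideEffect, SideEffectScale] | None = None,
) -> list[PairedPRORecord]:
    """Read a cohort table, validating levels against the scale registry."""
    registry = registry if registry is not None else default_registry()
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise MatrixFormatError(f"{path}: cohort table is missing columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        se = SideEffect.coerce(row.side_effect_id)
        scale = registry[se]
        scale.index(row.pre_level)
        scale.index(row.post_level)
        records.append(
            PairedPRORecord(
                patient_id=str(row.patient_id),
                treatment_id=str(row.treatment_id),
                side_effect=se,
                pre_level=row.pre_level,
                post_level=row.post_level,
            )
        )
    return records
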