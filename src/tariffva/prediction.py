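"""Cause assignment from a fitted Tariff matrix.

Each record's score for a cause is the sum of that cause's rounded
Tariffs over the symptoms the record endorses; the predicted cause is
the argmax, with ties broken deterministically by cause-list order.
This is the additive-score predictor; the rank-against-resampled-pool
refinement used by full production implementations is a documented
extension point (the validation metrics accept any predictor through
this interface), and no "undetermined" category is emitted, so
predicted cause fractions always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .tariff import TariffMatrix
from .va_data import GSDataset, SymptomSchema, VARecord, dichotomize, dichotomize_dataset


@dataclass
class PredictionResult:
    """Per-record cause scores and the argmax assignment."""

    causes: list[str]
    scores: dict[str, np.ndarray]  # record_id -> per-cause score vector
    predicted: dict[str, str]  # record_id -> cause label

    def predicted_labels(self, record_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.predicted[r] for r in record_ids], dtype=object)


def _check_alignment(tm: TariffMatrix, schema: Sequence[SymptomSchema]) -> None:
    ids = [s.symptom_id for s in schema]
    if ids != tm.symptoms:
        raise ValueError("schema symptoms do not match Tariff matrix symptoms")
    if tm.rounded is None:
        raise ValueError("Tariff matrix has no rounded values; run round_tariffs/fit first")


def score_record(
    r: VARecord, tm: TariffMatrix, schema: Sequence[SymptomSchema]
) -> np.ndarray:
    """Per-cause additive Tariff score: sum of rounded Tariffs over the
    symptoms the record endorses. Unendorsed symptoms contribute nothing."""
    _check_alignment(tm, schema)
    return dichotomize(r, schema) @ tm.rounded


def predict(
    ds: GSDataset,
    tm: TariffMatrix,
    schema: Sequence[SymptomSchema] | None = None,
) -> PredictionResult:
    """Assign every record the cause with the highest Tariff score.

    The dataset and matrix must belong to the same module and share
    causes; ties (including the all-zero-score case) go to the earliest
    cause in the matrix's cause list, making prediction deterministic.
    """
    schema = list(schema) if schema is not None else ds.schema
    _check_alignment(tm, schema)
    if ds.module != tm.module:
        raise ValueError(f"module mismatch: dataset {ds.module!r}, matrix {tm.module!r}")
    if not set(ds.causes) & set(tm.causes):
        raise ValueError("dataset and Tariff matrix have disjoint cause lists")
    bits, _ = dichotomize_dataset(ds, schema)
    score_mat = bits @ tm.rounded  # (n_records, n_causes)
    winners = np.argmax(score_mat, axis=1)  # first max -> cause-list tie rule
    scores: dict[str, np.ndarray] = {}
    predicted: dict[str, str] = {}
    for k, r in enumerate(ds.records):
        scores[r.record_id] = score_mat[k]
        predicted[r.record_id] = tm.causes[winners[k]]
    return PredictionResult(causes=list(tm.causes), scores=scores, predicted=predicted)
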