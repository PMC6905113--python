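"""Shared fixtures: hand-sized schemas/datasets and the synthetic study designs."""

from __future__ import annotations

import numpy as np
import pytest

import tariffva as tv


# ---------------------------------------------------------------------------
# Synthetic study designs
# ---------------------------------------------------------------------------


def make_random_spec(
    n_causes: int,
    n_symptoms: int,
    n_per_cause: int,
    seed: int,
    lo: float = 0.05,
    hi: float = 0.6,
    dont_know_rate: float = 0.05,
) -> tv.SyntheticSpec:
    """Unstructured endorsement profiles: p[i, j] iid uniform on [lo, hi]."""
    rng = np.random.default_rng(seed)
    causes = [f"C{j:02d}" for j in range(n_causes)]
    return tv.SyntheticSpec(
        module="adult",
        causes=causes,
        n_per_cause={c: n_per_cause for c in causes},
        symptoms=[f"s{i:03d}" for i in range(n_symptoms)],
        endorse_prob=rng.uniform(lo, hi, (n_symptoms, n_causes)),
        dont_know_rate=dont_know_rate,
        seed=seed,
    )


def make_null_spec(
    n_causes: int, n_symptoms: int, n_per_cause: int, seed: int, p: float = 0.3
) -> tv.SyntheticSpec:
    """Global null: every cause shares the same endorsement probability."""
    causes = [f"C{j:02d}" for j in range(n_causes)]
    return tv.SyntheticSpec(
        module="adult",
        causes=causes,
        n_per_cause={c: n_per_cause for c in causes},
        symptoms=[f"s{i:03d}" for i in range(n_symptoms)],
        endorse_prob=np.full((n_symptoms, n_causes), p),
        seed=seed,
    )


def make_separable_spec(
    n_causes: int = 20,
    n_per_cause: int = 100,
    seed: int = 7,
    signature_p: float = 0.95,
    off_lo: float = 0.005,
    off_hi: float = 0.03,
    dont_know_rate: float = 0.02,
) -> tv.SyntheticSpec:
    """Separable design: three disjoint hallmark symptoms per cause, each
    highly endorsed by its cause and rare elsewhere."""
    rng = np.random.default_rng(seed)
    causes = [f"C{j:02d}" for j in range(n_causes)]
    n_symptoms = 3 * n_causes
    p = rng.uniform(off_lo, off_hi, (n_symptoms, n_causes))
    for j in range(n_causes):
        p[3 * j : 3 * j + 3, j] = signature_p
    return tv.SyntheticSpec(
        module="adult",
        causes=causes,
        n_per_cause={c: n_per_cause for c in causes},
        symptoms=[f"s{i:03d}" for i in range(n_symptoms)],
        endorse_prob=p,
        dont_know_rate=dont_know_rate,
        seed=seed,
    )


def make_grid_spec(
    n_causes: int = 8,
    n_per_cause: int = 200,
    seed: int = 7,
    signature_p: float = 0.9,
    dont_know_rate: float = 0.05,
    endorse_prob: np.ndarray | None = None,
) -> tv.SyntheticSpec:
    """Well-conditioned design for Tariff-stability experiments: each
    symptom's off-target endorsement rates are an evenly spaced grid
    (permuted across causes), so every symptom has a bounded, stable IQR
    and Tariffs of moderate magnitude; three hallmark symptoms per cause
    sit well above the grid."""
    rng = np.random.default_rng(seed)
    causes = [f"C{j:02d}" for j in range(n_causes)]
    n_symptoms = 3 * n_causes
    if endorse_prob is None:
        grid = np.linspace(0.05, 0.4, n_causes - 1)
        endorse_prob = np.empty((n_symptoms, n_causes))
        for i in range(n_symptoms):
            j = i // 3
            row = np.empty(n_causes)
            row[j] = signature_p
            row[np.arange(n_causes) != j] = rng.permutation(grid)
            endorse_prob[i] = row
    return tv.SyntheticSpec(
        module="adult",
        causes=causes,
        n_per_cause={c: n_per_cause for c in causes},
        symptoms=[f"s{i:03d}" for i in range(n_symptoms)],
        endorse_prob=endorse_prob,
        dont_know_rate=dont_know_rate,
        seed=seed,
    )


def shuffle_labels(ds: tv.GSDataset, seed: int) -> tv.GSDataset:
    """Permute gold-standard causes across records, destroying every
    cause-symptom association while keeping both marginals."""
    rng = np.random.default_rng(seed)
    labels = [r.gs_cause for r in ds.records]
    perm = rng.permutation(len(labels))
    records = [
        tv.VARecord(r.record_id, r.module, r.site, labels[perm[k]], r.gs_level, r.responses)
        for k, r in enumerate(ds.records)
    ]
    return tv.GSDataset(ds.module, list(ds.causes), list(ds.schema), records)


# ---------------------------------------------------------------------------
# Hand-sized fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def mixed_schema() -> list[tv.SymptomSchema]:
    return [
        tv.SymptomSchema("chest_pain", "adult", "binary"),
        tv.SymptomSchema("cough_days", "adult", "duration", duration_cutoff=7.0),
        tv.SymptomSchema(
            "stool_kind", "adult", "categorical", endorsing_values=frozenset({"watery", "bloody"})
        ),
    ]


@pytest.fixture
def tiny_dataset(mixed_schema) -> tv.GSDataset:
    def rec(rid, cause, level, chest, cough, stool):
        return tv.VARecord(
            rid, "adult", "site_1", cause, level,
            {"chest_pain": chest, "cough_days": cough, "stool_kind": stool},
        )

    records = [
        rec("r1", "A", "1", tv.YES, 10.0, "watery"),
        rec("r2", "A", "2A", tv.NO, 3.0, "firm"),
        rec("r3", "A", "3", tv.DONT_KNOW, None, tv.DONT_KNOW),
        rec("r4", "B", "2B", tv.YES, 7.0, "bloody"),
        rec("r5", "B", "1", tv.NO, 7.5, None),
    ]
    return tv.GSDataset("adult", ["A", "B"], mixed_schema, records)
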