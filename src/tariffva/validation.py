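"""Out-of-sample validation with Dirichlet-resampled cause compositions.

Splitting the data at random and testing in-sample cause proportions
flatters population-level metrics, because the test composition then
mirrors the training composition. Following the standard VA validation
design, each replicate therefore (1) splits records train/test
stratified by cause, (2) draws a target cause-specific mortality
fraction (CSMF) vector from a Dirichlet distribution, and (3) resamples
the held-out records with replacement to a test set matching the drawn
composition. Metrics are aggregated across replicates as medians with
2.5/97.5-percentile uncertainty intervals.

Metrics
-------
- CCC (chance-corrected concordance), per cause *j* among *N* causes:
  ``(TP_j / T_j - 1/N) / (1 - 1/N)`` — individual-level sensitivity
  corrected for the 1/N agreement expected by chance.
- CSMF accuracy: ``1 - sum_j |true_j - pred_j| / (2 (1 - min_j true_j))``
  — total absolute CSMF error normalized by its maximum.
- CCCSMF accuracy: ``(CSMFA - 0.632) / (1 - 0.632)`` — CSMF accuracy
  rescaled so random assignment scores ~0 and perfection 1; values
  below 0 mean worse than chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prediction import predict
from .tariff import BootstrapConfig, fit
from .va_data import GSDataset, SymptomSchema, VARecord, logger

#: Expected CSMF accuracy of random cause assignment under Dirichlet
#: test compositions; the anchor of the chance correction.
CHANCE_CSMF_ACCURACY = 0.632


@dataclass
class ValidationConfig:
    n_splits: int = 500
    train_fraction: float = 0.75
    dirichlet_alpha: float = 1.0  # symmetric concentration over causes
    test_size: int | None = None  # default: held-out pool size
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_splits < 1:
            raise ValueError("n_splits must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.test_size is not None and self.test_size < 1:
            raise ValueError("test_size must be positive")


@dataclass
class MetricsReport:
    """Median (95% UI) validation metrics across splits.

    Per-cause and overall CCC are reported in percent (as conventionally
    tabulated); CSMF and CCCSMF accuracy on the unit scale.
    """

    module: str
    causes: list[str]
    n_splits: int
    per_cause_ccc: dict[str, tuple[float, float, float]]  # % (median, lo, hi)
    overall_ccc: tuple[float, float, float]  # % unweighted mean across causes
    csmf_accuracy: tuple[float, float, float]
    cccsmf_accuracy: tuple[float, float, float]
    splits: pd.DataFrame | None = None  # one row per split, for diagnostics

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": f"ccc_{c}", "median": m, "ui_lower": lo, "ui_upper": hi}
            for c, (m, lo, hi) in self.per_cause_ccc.items()
        ]
        for name, (m, lo, hi) in (
            ("ccc_overall", self.overall_ccc),
            ("csmf_accuracy", self.csmf_accuracy),
            ("cccsmf_accuracy", self.cccsmf_accuracy),
        ):
            rows.append({"metric": name, "median": m, "ui_lower": lo, "ui_upper": hi})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Metric closed forms
# ---------------------------------------------------------------------------


def ccc(truth, predicted, cause: str, n_causes: int) -> float:
    """Chance-corrected concordance for one cause; NaN when the cause has
    no true cases in the test set."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted labels have different lengths")
    if n_causes < 2:
        raise ValueError("CCC needs at least 2 causes")
    t_mask = truth == cause
    t_j = int(t_mask.sum())
    if t_j == 0:
        return float("nan")
    tp = int((predicted[t_mask] == cause).sum())
    chance = 1.0 / n_causes
    return (tp / t_j - chance) / (1.0 - chance)


def csmf(labels, causes) -> np.ndarray:
    """Cause fractions over the full cause list (zeros allowed); sums to 1."""
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    return np.array([(labels == c).mean() for c in causes], dtype=np.float64)


def csmf_accuracy(true_csmf, pred_csmf) -> float:
    true_csmf = np.asarray(true_csmf, dtype=np.float64)
    pred_csmf = np.asarray(pred_csmf, dtype=np.float64)
    if true_csmf.shape != pred_csmf.shape:
        raise ValueError("CSMF vectors are not aligned")
    if true_csmf.size < 2:
        raise ValueError("CSMF accuracy needs at least 2 causes")
    for v, name in ((true_csmf, "true"), (pred_csmf, "pred")):
        if abs(v.sum() - 1.0) > 1e-8:
            raise ValueError(f"{name} CSMF must sum to 1")
    denom = 2.0 * (1.0 - true_csmf.min())
    if denom == 0.0:
        raise ValueError("CSMF accuracy undefined when one cause holds all mass")
    return 1.0 - np.abs(true_csmf - pred_csmf).sum() / denom


def cccsmf_accuracy(csmfa: float) -> float:
    return (csmfa - CHANCE_CSMF_ACCURACY) / (1.0 - CHANCE_CSMF_ACCURACY)


# ---------------------------------------------------------------------------
# Dirichlet splits
# ---------------------------------------------------------------------------


def dirichlet_split(
    ds: GSDataset, cfg: ValidationConfig, split_index: int
) -> tuple[GSDataset, GSDataset]:
    """One train/test replicate; deterministic given (cfg.seed, split_index).

    Records are partitioned train/test per cause at ``train_fraction``
    (at least one record on each side), a target CSMF is drawn from a
    symmetric Dirichlet over the retained causes, multinomial counts are
    drawn at ``test_size``, and the test set is resampled with
    replacement from the held-out pools to match. Causes with fewer than
    2 records are dropped with a warning. Resampled test records get a
    ``#draw`` suffix on their id so duplicates stay distinct.
    """
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, split_index])
    by_cause: dict[str, list[VARecord]] = {c: [] for c in ds.causes}
    for r in ds.records:
        by_cause[r.gs_cause].append(r)
    kept = []
    for c in ds.causes:
        if len(by_cause[c]) < 2:
            logger.warning("dirichlet_split: cause %r has <2 records; dropped", c)
        else:
            kept.append(c)
    if len(kept) < 2:
        raise ValueError("need at least 2 causes with >=2 records to split")

    train: list[VARecord] = []
    pools: dict[str, list[VARecord]] = {}
    for c in kept:
        recs = list(by_cause[c])
        order = rng.permutation(len(recs))
        n_train = int(np.clip(round(cfg.train_fraction * len(recs)), 1, len(recs) - 1))
        train.extend(recs[i] for i in order[:n_train])
        pools[c] = [recs[i] for i in order[n_train:]]

    test_size = cfg.test_size or sum(len(p) for p in pools.values())
    weights = rng.dirichlet(np.full(len(kept), cfg.dirichlet_alpha))
    counts = rng.multinomial(test_size, weights)

    test: list[VARecord] = []
    draw = 0
    for c, m in zip(kept, counts):
        pool = pools[c]
        for pick in rng.integers(0, len(pool), m):
            src = pool[pick]
            draw += 1
            test.append(
                VARecord(f"{src.record_id}#{draw}", src.module, src.site,
                         src.gs_cause, src.gs_level, src.responses)
            )
    schema = list(ds.schema)
    return (
        GSDataset(ds.module, kept, schema, train),
        GSDataset(ds.module, kept, schema, test),
    )


# ---------------------------------------------------------------------------
# Full validation loop
# ---------------------------------------------------------------------------


def _summary(values: np.ndarray) -> tuple[float, float, float]:
    vals = values[~np.isnan(values)]
    if vals.size == 0:
        return (float("nan"),) * 3
    return (
        float(np.median(vals)),
        float(np.percentile(vals, 2.5)),
        float(np.percentile(vals, 97.5)),
    )


def run_validation(
    ds: GSDataset,
    schema=None,
    vcfg: ValidationConfig | None = None,
    bcfg: BootstrapConfig | None = None,
) -> MetricsReport:
    """Dirichlet-split validation: per split, train Tariffs on the train
    half, predict the resampled test set, and score CCC / CSMF accuracy /
    CCCSMF accuracy. N in CCC is the size of the dataset's full cause
    list; overall CCC is the unweighted mean of per-cause CCCs. Each
    split derives an independent bootstrap seed from (bcfg.seed, split).
    """
    vcfg = vcfg or ValidationConfig()
    bcfg = bcfg or BootstrapConfig()
    schema = list(schema) if schema is not None else ds.schema
    n_causes = len(ds.causes)

    rows = []
    for split in range(vcfg.n_splits):
        train, test = dirichlet_split(ds, vcfg, split)
        sub_seed = int(
            np.random.SeedSequence([bcfg.seed & 0x7FFFFFFF, split]).generate_state(1)[0]
            % (2**31)
        )
        tm = fit(train, schema, BootstrapConfig(bcfg.n_reps, bcfg.ui_level, sub_seed))
        res = predict(test, tm, schema)
        ids = [r.record_id for r in test.records]
        truth = np.array([r.gs_cause for r in test.records], dtype=object)
        pred = res.predicted_labels(ids)
        row = {"split": split}
        ccc_vals = []
        for c in ds.causes:
            v = ccc(truth, pred, c, n_causes)
            row[f"ccc_{c}"] = v
            ccc_vals.append(v)
        row["ccc_overall"] = float(np.nanmean(ccc_vals))
        acc = csmf_accuracy(csmf(truth, ds.causes), csmf(pred, ds.causes))
        row["csmf_accuracy"] = acc
        row["cccsmf_accuracy"] = cccsmf_accuracy(acc)
        rows.append(row)
    splits = pd.DataFrame(rows)

    per_cause = {
        c: tuple(100.0 * v for v in _summary(splits[f"ccc_{c}"].to_numpy()))
        for c in ds.causes
    }
    return MetricsReport(
        module=ds.module,
        causes=list(ds.causes),
        n_splits=vcfg.n_splits,
        per_cause_ccc=per_cause,
        overall_ccc=tuple(100.0 * v for v in _summary(splits["ccc_overall"].to_numpy())),
        csmf_accuracy=_summary(splits["csmf_accuracy"].to_numpy()),
        cccsmf_accuracy=_summary(splits["cccsmf_accuracy"].to_numpy()),
        splits=splits,
    )
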