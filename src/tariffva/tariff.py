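"""The Tariff scoring matrix: endorsement rates, Tariffs, bootstrap
significance, and rounding.

For symptom *i* and cause *j*, the endorsement rate ``x[i, j]`` is the
fraction of cause-*j* deaths whose interview endorses symptom *i*
(don't-know and missing responses stay in the denominator). The Tariff
is a robust z-like score of how distinctive the symptom is for the
cause::

    Tariff[i, j] = (x[i, j] - median_i) / IQR_i

with the median and interquartile range taken across causes for symptom
*i* (linear-interpolation quantiles). Significance is assessed by a
stratified bootstrap: records are resampled with replacement within each
cause, keeping per-cause totals fixed, Tariffs recomputed per replicate,
and a percentile uncertainty interval formed per pair; a Tariff whose
interval touches or crosses zero is removed (set to zero). Surviving
Tariffs are rounded to the nearest 0.5, which discards spurious
precision and limits over-fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .va_data import GSDataset, SymptomSchema, dichotomize_dataset, logger


@dataclass
class BootstrapConfig:
    """Monte-Carlo significance settings: 500 stratified resamples and a
    99% percentile uncertainty interval by default."""

    n_reps: int = 500
    ui_level: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if not 0.0 < self.ui_level < 1.0:
            raise ValueError("ui_level must be in (0, 1)")


@dataclass
class EndorsementMatrix:
    """x[i, j]: fraction of cause-j deaths endorsing symptom i."""

    x: np.ndarray  # (n_symptoms, n_causes)
    symptoms: list[str]
    causes: list[str]
    n_cases: dict[str, int]
    module: str

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.x.shape != (len(self.symptoms), len(self.causes)):
            raise ValueError("endorsement matrix shape does not match axes")
        if np.any((self.x < 0) | (self.x > 1)):
            raise ValueError("endorsement rates must lie in [0, 1]")
        for c in self.causes:
            if self.n_cases.get(c, 0) < 1:
                raise ValueError(f"cause {c!r} has no cases")


@dataclass
class TariffMatrix:
    """Raw, significance-masked, and rounded Tariffs with bootstrap UIs.

    ``raw`` holds the point-estimate Tariffs; pairs whose symptom has
    zero IQR across causes are undefined and stored as 0 with
    ``defined`` False (they are never significant — a symptom constant
    across causes carries no discriminatory signal). ``rounded`` is on
    the 0.5 grid and is 0 wherever ``significant`` is False. Percentile
    bootstrap intervals need not bracket the point estimate in
    degenerate cases, but ``ui_lower <= ui_upper`` always holds.
    """

    raw: np.ndarray
    median: np.ndarray  # per-symptom median endorsement rate across causes
    iqr: np.ndarray  # per-symptom IQR across causes
    defined: np.ndarray  # bool; False where IQR == 0
    significant: np.ndarray  # bool
    symptoms: list[str]
    causes: list[str]
    module: str
    ui_lower: np.ndarray | None = None
    ui_upper: np.ndarray | None = None
    rounded: np.ndarray | None = None
    n_cases: dict[str, int] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.raw.shape

    def masked_raw(self) -> np.ndarray:
        """Raw Tariffs with insignificant pairs set to zero."""
        return np.where(self.significant, self.raw, 0.0)


# ---------------------------------------------------------------------------
# Endorsement rates
# ---------------------------------------------------------------------------


def endorsement_rates(
    ds: GSDataset, schema: Sequence[SymptomSchema] | None = None
) -> EndorsementMatrix:
    """Per-cause symptom endorsement rates.

    Don't-know and missing responses dichotomize to 0 but remain in the
    denominator. Causes with zero records are dropped with a warning.
    """
    if not ds.records:
        raise ValueError("dataset has no records")
    schema = list(schema) if schema is not None else ds.schema
    bits, labels = dichotomize_dataset(ds, schema)
    kept, x_cols, n_cases = [], [], {}
    for c in ds.causes:
        mask = labels == c
        n = int(mask.sum())
        if n == 0:
            logger.warning("endorsement_rates: cause %r has no records; dropped", c)
            continue
        kept.append(c)
        n_cases[c] = n
        x_cols.append(bits[mask].mean(axis=0))
    x = np.column_stack(x_cols)
    return EndorsementMatrix(
        x=x, symptoms=[s.symptom_id for s in schema], causes=kept,
        n_cases=n_cases, module=ds.module,
    )


# ---------------------------------------------------------------------------
# Tariff computation
# ---------------------------------------------------------------------------


def _tariffs_from_x(x: np.ndarray):
    """Tariffs from an endorsement array (..., n_symptoms, n_causes).

    Returns (raw, median, iqr, defined) with the cause axis last;
    undefined pairs (IQR == 0) are 0 with defined False. Quantiles use
    linear interpolation.
    """
    med = np.median(x, axis=-1, keepdims=True)
    q1, q3 = np.percentile(x, [25.0, 75.0], axis=-1, keepdims=True)
    iqr = q3 - q1
    defined = np.broadcast_to(iqr > 0, x.shape)
    raw = np.where(defined, (x - med) / np.where(iqr > 0, iqr, 1.0), 0.0)
    return raw, med[..., 0], iqr[..., 0], defined


def compute_tariffs(em: EndorsementMatrix) -> TariffMatrix:
    """Point-estimate Tariffs from an endorsement matrix.

    The significance mask is an all-true placeholder on defined pairs
    until :func:`bootstrap_significance` fills it.
    """
    if len(em.causes) < 2:
        raise ValueError("Tariffs need at least 2 causes (median/IQR degenerate)")
    raw, med, iqr, defined = _tariffs_from_x(em.x)
    return TariffMatrix(
        raw=raw, median=med, iqr=iqr, defined=defined.copy(),
        significant=defined.copy(), symptoms=list(em.symptoms),
        causes=list(em.causes), module=em.module, n_cases=dict(em.n_cases),
    )


# ---------------------------------------------------------------------------
# Bootstrap significance
# ---------------------------------------------------------------------------


def bootstrap_significance(
    ds: GSDataset,
    schema: Sequence[SymptomSchema] | None = None,
    cfg: BootstrapConfig | None = None,
) -> TariffMatrix:
    """Stratified bootstrap of the Tariff matrix.

    Whole records are resampled with replacement within each cause, so
    per-cause totals are constant across replicates while the endorsement
    rates vary. Each replicate uses an independent RNG stream spawned
    from the master seed, making results independent of execution order.
    A pair is significant when its percentile interval lies strictly on
    one side of zero; an interval touching zero removes the pair.
    """
    cfg = cfg or BootstrapConfig()
    schema = list(schema) if schema is not None else ds.schema
    em = endorsement_rates(ds, schema)
    point = compute_tariffs(em)

    bits, labels = dichotomize_dataset(ds, schema)
    groups = [np.flatnonzero(labels == c) for c in em.causes]
    n_symp, n_causes = em.x.shape

    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_reps)
    x_reps = np.empty((cfg.n_reps, n_symp, n_causes), dtype=np.float64)
    for r in range(cfg.n_reps):
        rng = np.random.default_rng(streams[r])
        for j, idx in enumerate(groups):
            take = idx[rng.integers(0, idx.size, idx.size)]
            x_reps[r, :, j] = bits[take].mean(axis=0)

    t_reps, _, _, _ = _tariffs_from_x(x_reps)
    tail = 100.0 * (1.0 - cfg.ui_level) / 2.0
    # (B+1)p order-statistic quantiles (Efron percentile rule): clamps to the
    # extreme replicates when n_reps is small for the requested tail, giving
    # conservative rather than anti-conservative intervals at reduced reps.
    lo, hi = np.percentile(t_reps, [tail, 100.0 - tail], axis=0, method="weibull")
    significant = point.defined & ((lo > 0.0) | (hi < 0.0))
    return replace(point, ui_lower=lo, ui_upper=hi, significant=significant)


# ---------------------------------------------------------------------------
# Rounding and the full fit
# ---------------------------------------------------------------------------


def _round_half_grid(x: np.ndarray) -> np.ndarray:
    # nearest multiple of 0.5; exact .25/.75 ties round away from zero
    return np.sign(x) * np.floor(np.abs(x) * 2.0 + 0.5) / 2.0


def round_tariffs(tm: TariffMatrix) -> TariffMatrix:
    """Round significant Tariffs to the nearest 0.5; insignificant pairs
    become exactly 0. Ties round away from zero, preserving sign."""
    rounded = np.where(tm.significant, _round_half_grid(tm.raw), 0.0)
    return replace(tm, rounded=rounded)


def fit(
    ds: GSDataset,
    schema: Sequence[SymptomSchema] | None = None,
    cfg: BootstrapConfig | None = None,
) -> TariffMatrix:
    """Full Tariff training: endorsement rates → Tariffs → bootstrap
    significance → rounding. Deterministic given (ds, cfg.seed)."""
    return round_tariffs(bootstrap_significance(ds, schema, cfg))
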