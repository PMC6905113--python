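"""Dataset-robustness analysis: how Tariffs and predictive performance
change when a second gold-standard dataset is pooled with the first.

The core questions, for training sets A and A∪B: what fraction of
cause-symptom Tariffs is significant before and after; how many
A-significant Tariffs stay significant; whether any jointly significant
Tariff flips sign; which pairs move the most; and how per-cause CCC and
overall CCC / CSMF accuracy / CCCSMF accuracy shift under Dirichlet
out-of-sample validation.

"Changed significantly" is operationalized as disjoint 99% bootstrap
uncertainty intervals of the two estimates (pluggable; an alternative
is a bootstrap interval of the paired difference excluding zero).
Because the right denominator for "proportion changed" is debatable,
both are reported: all compared pairs, and pairs significant in either
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .tariff import BootstrapConfig, TariffMatrix, fit
from .va_data import GSDataset, concat_datasets, logger
from .validation import MetricsReport, ValidationConfig, run_validation


@dataclass
class RobustnessReport:
    """Pairwise comparison of two Tariff fits and two validation reports."""

    # Tariff-matrix comparison
    n_pairs: int | None = None
    n_sig_A: int | None = None
    n_sig_AB: int | None = None
    prop_sig_A: float | None = None
    prop_sig_AB: float | None = None
    n_retained: int | None = None
    prop_retained: float | None = None
    n_direction_flips: int | None = None
    n_changed_sig: int | None = None
    prop_changed_all: float | None = None
    prop_changed_ever_sig: float | None = None
    top_deltas: pd.DataFrame | None = None  # cause, symptom, tariff_A, tariff_AB, difference
    # Validation comparison
    per_cause_ccc_delta: dict[str, tuple[float, float, float]] | None = None  # (A, AB, diff) %
    overall_delta: dict[str, float] | None = None  # ccc (pts %), csmf/cccsmf accuracy (unit)


def _align(tm_A: TariffMatrix, tm_AB: TariffMatrix) -> tuple[TariffMatrix, TariffMatrix]:
    if tm_A.symptoms != tm_AB.symptoms:
        raise ValueError("Tariff matrices have different symptom axes")
    if tm_A.causes == tm_AB.causes:
        return tm_A, tm_AB
    shared = [c for c in tm_A.causes if c in tm_AB.causes]
    if not shared:
        raise ValueError("Tariff matrices share no causes")

    def take(tm: TariffMatrix) -> TariffMatrix:
        idx = [tm.causes.index(c) for c in shared]
        return dc_replace(
            tm,
            raw=tm.raw[:, idx],
            defined=tm.defined[:, idx],
            significant=tm.significant[:, idx],
            ui_lower=None if tm.ui_lower is None else tm.ui_lower[:, idx],
            ui_upper=None if tm.ui_upper is None else tm.ui_upper[:, idx],
            rounded=None if tm.rounded is None else tm.rounded[:, idx],
            causes=list(shared),
            n_cases={c: tm.n_cases[c] for c in shared if c in tm.n_cases},
        )

    logger.info("comparing Tariff matrices on %d shared causes", len(shared))
    return take(tm_A), take(tm_AB)


def compare_tariff_matrices(
    tm_A: TariffMatrix,
    tm_AB: TariffMatrix,
    min_tariff: float = 1.0,
    min_delta: float = 1.0,
) -> RobustnessReport:
    """Pair-level comparison of two fitted Tariff matrices.

    Significance retention and direction flips are counted on the
    significance masks (flips only among pairs significant in both: a
    sign change through zero of an insignificant pair is noise). The
    delta table uses significance-masked raw Tariffs and keeps pairs
    whose |Tariff| reaches ``min_tariff`` in either matrix and whose
    |difference| reaches ``min_delta``, ranked by |difference|.
    """
    tm_A, tm_AB = _align(tm_A, tm_AB)
    sig_A, sig_AB = tm_A.significant, tm_AB.significant
    n_pairs = sig_A.size
    both = sig_A & sig_AB
    flips = both & (np.sign(tm_A.raw) != np.sign(tm_AB.raw))

    changed = None
    if tm_A.ui_lower is not None and tm_AB.ui_lower is not None:
        changed = (tm_A.ui_upper < tm_AB.ui_lower) | (tm_AB.ui_upper < tm_A.ui_lower)
    ever_sig = sig_A | sig_AB

    eff_A, eff_AB = tm_A.masked_raw(), tm_AB.masked_raw()
    diff = eff_AB - eff_A
    keep = ((np.abs(eff_A) >= min_tariff) | (np.abs(eff_AB) >= min_tariff)) & (
        np.abs(diff) >= min_delta
    )
    ii, jj = np.nonzero(keep)
    table = pd.DataFrame(
        {
            "cause": [tm_A.causes[j] for j in jj],
            "symptom": [tm_A.symptoms[i] for i in ii],
            "tariff_A": eff_A[ii, jj],
            "tariff_AB": eff_AB[ii, jj],
            "difference": diff[ii, jj],
        }
    )
    table = table.reindex(
        table["difference"].abs().sort_values(ascending=False, kind="stable").index
    ).reset_index(drop=True)

    n_sig_A = int(sig_A.sum())
    return RobustnessReport(
        n_pairs=n_pairs,
        n_sig_A=n_sig_A,
        n_sig_AB=int(sig_AB.sum()),
        prop_sig_A=sig_A.mean(),
        prop_sig_AB=sig_AB.mean(),
        n_retained=int(both.sum()),
        prop_retained=float(both.sum() / n_sig_A) if n_sig_A else float("nan"),
        n_direction_flips=int(flips.sum()),
        n_changed_sig=None if changed is None else int(changed.sum()),
        prop_changed_all=None if changed is None else changed.mean(),
        prop_changed_ever_sig=(
            None
            if changed is None
            else (float(changed[ever_sig].mean()) if ever_sig.any() else 0.0)
        ),
        top_deltas=table,
    )


def compare_validation(
    rep_A: MetricsReport, rep_AB: MetricsReport, strict: bool = True
) -> RobustnessReport:
    """Metric-level comparison: per-cause CCC medians and overall deltas
    (median_AB − median_A). With ``strict`` the cause lists must match;
    otherwise deltas cover the shared causes only."""
    if rep_A.module != rep_AB.module:
        raise ValueError("validation reports are for different modules")
    if strict and rep_A.causes != rep_AB.causes:
        raise ValueError("validation reports have different cause lists")
    shared = [c for c in rep_A.causes if c in rep_AB.causes]
    per_cause = {}
    for c in shared:
        a = rep_A.per_cause_ccc[c][0]
        b = rep_AB.per_cause_ccc[c][0]
        per_cause[c] = (a, b, b - a)
    return RobustnessReport(
        per_cause_ccc_delta=per_cause,
        overall_delta={
            "ccc": rep_AB.overall_ccc[0] - rep_A.overall_ccc[0],
            "csmf_accuracy": rep_AB.csmf_accuracy[0] - rep_A.csmf_accuracy[0],
            "cccsmf_accuracy": rep_AB.cccsmf_accuracy[0] - rep_A.cccsmf_accuracy[0],
        },
    )


def run_robustness_experiment(
    ds_A: GSDataset,
    ds_B: GSDataset,
    schema=None,
    bcfg: BootstrapConfig | None = None,
    vcfg: ValidationConfig | None = None,
) -> RobustnessReport:
    """Fit and validate on A and on the pooled A∪B, then assemble the full
    comparison. An empty second dataset degenerates to a self-comparison.
    Deterministic given the config seeds."""
    bcfg = bcfg or BootstrapConfig()
    vcfg = vcfg or ValidationConfig()
    schema = list(schema) if schema is not None else ds_A.schema
    ds_AB = concat_datasets(ds_A, ds_B) if ds_B.records else ds_A

    tm_A = fit(ds_A, schema, bcfg)
    tm_AB = fit(ds_AB, schema, bcfg)
    report = compare_tariff_matrices(tm_A, tm_AB)

    rep_A = run_validation(ds_A, schema, vcfg, bcfg)
    rep_AB = run_validation(ds_AB, schema, vcfg, bcfg)
    metrics = compare_validation(rep_A, rep_AB, strict=False)
    return dc_replace(
        report,
        per_cause_ccc_delta=metrics.per_cause_ccc_delta,
        overall_delta=metrics.overall_delta,
    )
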