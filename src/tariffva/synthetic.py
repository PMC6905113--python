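"""Synthetic gold-standard VA data with known cause-symptom structure.

The generator emulates the structure of a gold-standard VA database:
per-module cause lists with highly unbalanced counts, per-cause symptom
endorsement probabilities, don't-know contamination, and duration
symptoms that only matter through their dichotomized over-cutoff bit.
Symptoms are conditionally independent given cause — the minimal
structure the additive Tariff scorer assumes. Because the generative
endorsement probabilities are known, population-level ("true") Tariffs
can be computed exactly and serve as a parameter-recovery oracle for the
whole training pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import cause_counts
from .tariff import EndorsementMatrix, TariffMatrix, compute_tariffs, round_tariffs
from .va_data import DONT_KNOW, NO, YES, GSDataset, SymptomSchema, VARecord


@dataclass
class SyntheticSpec:
    """Generative description of a gold-standard VA dataset.

    ``endorse_prob[i, j]`` is the probability that a cause-*j* death
    endorses symptom *i* before don't-know contamination; for duration
    symptoms it is the probability that the drawn duration exceeds the
    cutoff in ``duration_cutoffs``. Each response is independently
    replaced by don't-know with probability ``dont_know_rate``
    (symmetrically for endorsed and unendorsed responses), so the
    effective endorsement probability is ``endorse_prob * (1 -
    dont_know_rate)``.
    """

    module: str
    causes: list[str]
    n_per_cause: dict[str, int]
    symptoms: list[str]
    endorse_prob: np.ndarray  # (n_symptoms, n_causes)
    dont_know_rate: float = 0.0
    duration_cutoffs: dict[str, float] = field(default_factory=dict)
    sites: list[tuple[str, float]] = field(default_factory=lambda: [("site_1", 1.0)])
    seed: int = 0

    def __post_init__(self) -> None:
        self.endorse_prob = np.asarray(self.endorse_prob, dtype=np.float64)
        if self.endorse_prob.shape != (len(self.symptoms), len(self.causes)):
            raise ValueError("endorse_prob dimensions must match symptoms × causes")
        if np.any((self.endorse_prob < 0) | (self.endorse_prob > 1)):
            raise ValueError("endorsement probabilities must lie in [0, 1]")
        if not 0.0 <= self.dont_know_rate <= 1.0:
            raise ValueError("dont_know_rate must lie in [0, 1]")
        for c in self.causes:
            if self.n_per_cause.get(c, 0) < 1:
                raise ValueError(f"n_per_cause[{c!r}] must be >= 1")
        for sid in self.duration_cutoffs:
            if sid not in self.symptoms:
                raise ValueError(f"duration symptom {sid!r} not in symptom list")
            if self.duration_cutoffs[sid] < 0:
                raise ValueError(f"duration cutoff for {sid!r} must be nonnegative")
        weights = [w for _, w in self.sites]
        if not self.sites or any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ValueError("site weights must be nonnegative with positive sum")

    def schema(self) -> list[SymptomSchema]:
        out = []
        for sid in self.symptoms:
            if sid in self.duration_cutoffs:
                out.append(
                    SymptomSchema(sid, self.module, "duration",
                                  duration_cutoff=float(self.duration_cutoffs[sid]))
                )
            else:
                out.append(SymptomSchema(sid, self.module, "binary"))
        return out


def generate(spec: SyntheticSpec) -> GSDataset:
    """Draw a dataset from the spec; byte-identical for equal seeds.

    Binary symptoms are Bernoulli(endorse_prob). Duration symptoms first
    draw the over-cutoff bit at the spec'd probability, then a value:
    an exponential tail above the cutoff, uniform below it — only the
    dichotomized bit is identified downstream. Don't-know then
    overwrites each response independently at ``dont_know_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    schema = spec.schema()
    site_names = [s for s, _ in spec.sites]
    w = np.array([wt for _, wt in spec.sites], dtype=float)
    w /= w.sum()

    records: list[VARecord] = []
    serial = 0
    for j, cause in enumerate(spec.causes):
        n = spec.n_per_cause[cause]
        p = spec.endorse_prob[:, j]
        endorsed = rng.random((n, len(spec.symptoms))) < p  # bit per (record, symptom)
        dk = rng.random((n, len(spec.symptoms))) < spec.dont_know_rate
        sites = rng.choice(len(site_names), size=n, p=w)
        for k in range(n):
            serial += 1
            responses: dict[str, object] = {}
            for i, s in enumerate(schema):
                if dk[k, i]:
                    responses[s.symptom_id] = DONT_KNOW
                elif s.kind == "duration":
                    cut = s.duration_cutoff
                    if endorsed[k, i]:
                        responses[s.symptom_id] = cut + rng.exponential(max(cut, 1.0))
                    else:
                        responses[s.symptom_id] = rng.uniform(0.0, cut)
                else:
                    responses[s.symptom_id] = YES if endorsed[k, i] else NO
            records.append(
                VARecord(
                    record_id=f"{spec.module[0]}{serial:06d}",
                    module=spec.module,
                    site=site_names[sites[k]],
                    gs_cause=cause,
                    gs_level="1",
                    responses=responses,
                )
            )
    return GSDataset(spec.module, list(spec.causes), schema, records)


def true_tariffs(spec: SyntheticSpec) -> TariffMatrix:
    """Population-level Tariffs implied by the generative probabilities.

    Applies the Tariff formula to the effective endorsement
    probabilities ``endorse_prob * (1 - dont_know_rate)``, with the
    median/IQR taken across the spec's causes. Pairs whose symptom has
    zero IQR across causes are undefined (0, never significant). The
    result is the parameter-recovery oracle for fitted Tariffs.
    """
    p_eff = spec.endorse_prob * (1.0 - spec.dont_know_rate)
    em = EndorsementMatrix(
        x=p_eff, symptoms=list(spec.symptoms), causes=list(spec.causes),
        n_cases={c: spec.n_per_cause[c] for c in spec.causes}, module=spec.module,
    )
    return round_tariffs(compute_tariffs(em))


def phmrc_like_spec(
    module: str,
    scale: float = 1.0,
    signature_per_cause: int = 3,
    dont_know_rate: float = 0.05,
    seed: int = 0,
) -> SyntheticSpec:
    """A default spec mirroring the combined PHMRC+IMMCMC cause mix.

    The cause list and relative counts follow the module's published
    combined composition, scaled by ``scale`` and rounded with a floor
    of one case per cause. Endorsement profiles are drawn once from the
    seed: every symptom has a low baseline rate that varies across
    causes (a symptom exactly constant across causes has zero IQR and
    an undefined Tariff, which real endorsement rates essentially never
    exhibit), and each cause gets ``signature_per_cause`` dedicated
    high-lift symptoms, so the causes are discriminable the way real VA
    causes are through their hallmark symptoms.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    combined = cause_counts.counts(module, "combined")
    causes = list(combined)
    n_per_cause = {c: max(1, round(n * scale)) for c, n in combined.items()}

    rng = np.random.default_rng(seed)
    n_causes = len(causes)
    n_symptoms = signature_per_cause * n_causes
    symptoms = [f"s{i:03d}" for i in range(n_symptoms)]
    baseline = rng.uniform(0.02, 0.25, size=n_symptoms)
    p = baseline[:, None] * rng.uniform(0.5, 1.5, size=(n_symptoms, n_causes))
    for j in range(n_causes):
        rows = slice(j * signature_per_cause, (j + 1) * signature_per_cause)
        p[rows, j] = rng.uniform(0.6, 0.9, size=signature_per_cause)
    return SyntheticSpec(
        module=module, causes=causes, n_per_cause=n_per_cause,
        symptoms=symptoms, endorse_prob=p, dont_know_rate=dont_know_rate,
        sites=[("site_1", 0.6), ("site_2", 0.3), ("site_3", 0.1)], seed=seed,
    )
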