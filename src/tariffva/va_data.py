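"""Domain types and tabular I/O for gold-standard verbal-autopsy data.

A gold-standard (GS) death is one whose underlying cause was established
from medical records under strict ex-ante diagnostic criteria; the
associated verbal-autopsy interview records, for every symptom question,
a yes/no/don't-know answer, a categorical code, or a numeric duration.
This module defines the in-memory containers (:class:`SymptomSchema`,
:class:`VARecord`, :class:`GSDataset`), CSV round-tripping in the
one-row-per-death layout used by the public PHMRC release, gold-standard
level filtering, and the dichotomization rule that turns every response
into a 0/1 endorsement bit.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("tariffva")

#: Age strata of the VA instrument, each with its own cause list and symptoms.
MODULES = ("adult", "child", "neonate")

#: Gold-standard certainty levels, in decreasing order of diagnostic certainty.
GS_LEVELS = ("1", "2A", "2B", "3")

SYMPTOM_KINDS = ("binary", "duration", "categorical")

YES = "yes"
NO = "no"
DONT_KNOW = "dont_know"
#: Missing responses are stored as None; they dichotomize to 0 like dont_know.
MISSING = None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymptomSchema:
    """Definition of one symptom question within an age module.

    Parameters
    ----------
    symptom_id:
        Unique identifier of the question within the module.
    module:
        One of ``adult``, ``child``, ``neonate``.
    kind:
        ``binary`` (yes/no/don't-know), ``duration`` (days), or
        ``categorical`` (coded answer).
    duration_cutoff:
        Days; a duration response is endorsed iff strictly greater than
        this cutoff. Required exactly when ``kind == "duration"``.
    endorsing_values:
        Set of categorical codes that count as endorsement. Required
        exactly when ``kind == "categorical"``.
    """

    symptom_id: str
    module: str
    kind: str
    duration_cutoff: float | None = None
    endorsing_values: frozenset[str] | None = None
    question_text: str | None = None

    def __post_init__(self) -> None:
        if self.module not in MODULES:
            raise ValueError(f"unknown module {self.module!r}")
        if self.kind not in SYMPTOM_KINDS:
            raise ValueError(f"unknown symptom kind {self.kind!r}")
        if (self.kind == "duration") != (self.duration_cutoff is not None):
            raise ValueError(
                f"{self.symptom_id}: duration_cutoff must be present iff kind='duration'"
            )
        if self.duration_cutoff is not None and self.duration_cutoff < 0:
            raise ValueError(f"{self.symptom_id}: duration_cutoff must be nonnegative")
        if (self.kind == "categorical") != (self.endorsing_values is not None):
            raise ValueError(
                f"{self.symptom_id}: endorsing_values must be present iff kind='categorical'"
            )
        if self.endorsing_values is not None:
            object.__setattr__(self, "endorsing_values", frozenset(self.endorsing_values))


@dataclass
class VARecord:
    """One death: identifiers, gold-standard cause/level, and raw responses."""

    record_id: str
    module: str
    site: str
    gs_cause: str
    gs_level: str
    responses: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gs_level = str(self.gs_level)
        if self.gs_level not in GS_LEVELS:
            raise ValueError(f"record {self.record_id}: unknown gs_level {self.gs_level!r}")
        if self.module not in MODULES:
            raise ValueError(f"record {self.record_id}: unknown module {self.module!r}")


@dataclass
class GSDataset:
    """A gold-standard VA dataset: the unit of training and validation."""

    module: str
    causes: list[str]
    schema: list[SymptomSchema]
    records: list[VARecord]

    def __post_init__(self) -> None:
        if not self.causes:
            raise ValueError("cause list must be non-empty")
        if len(set(self.causes)) != len(self.causes):
            raise ValueError("cause list contains duplicates")
        ids = [s.symptom_id for s in self.schema]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate symptom_id in schema")
        cause_set = set(self.causes)
        for r in self.records:
            if r.module != self.module:
                raise ValueError(f"record {r.record_id}: module {r.module!r} != {self.module!r}")
            if r.gs_cause not in cause_set:
                raise ValueError(
                    f"record {r.record_id}: gs_cause {r.gs_cause!r} not in cause list"
                )

    @property
    def symptom_ids(self) -> list[str]:
        return [s.symptom_id for s in self.schema]

    @property
    def n_records(self) -> int:
        return len(self.records)

    def cause_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in self.causes}
        for r in self.records:
            counts[r.gs_cause] += 1
        return counts


# ---------------------------------------------------------------------------
# Dichotomization
# ---------------------------------------------------------------------------


def dichotomize(record: VARecord, schema: Sequence[SymptomSchema]) -> np.ndarray:
    """Map one record's raw responses to a full-length 0/1 endorsement vector.

    A binary symptom is endorsed iff the response is ``yes``; a duration
    symptom iff the numeric response is strictly greater than the
    schema's cutoff; a categorical symptom iff the code is in the
    schema's endorsing set. Every other value — ``no``, ``dont_know``,
    missing, or an out-of-set code — is unendorsed (0). The mapping is
    total: any well-formed record yields a bit for every schema symptom.
    """
    bits = np.zeros(len(schema), dtype=np.float64)
    for i, s in enumerate(schema):
        v = record.responses.get(s.symptom_id, MISSING)
        if v is MISSING or v == DONT_KNOW:
            continue
        if s.kind == "binary":
            bits[i] = 1.0 if v == YES else 0.0
        elif s.kind == "duration":
            if isinstance(v, (int, float)) and not isinstance(v, bool):
                bits[i] = 1.0 if float(v) > s.duration_cutoff else 0.0
        else:  # categorical
            bits[i] = 1.0 if v in s.endorsing_values else 0.0
    return bits


def dichotomize_dataset(
    ds: GSDataset, schema: Sequence[SymptomSchema] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Dichotomize every record; returns (n_records × n_symptoms bits, cause labels)."""
    schema = list(schema) if schema is not None else ds.schema
    bits = np.empty((len(ds.records), len(schema)), dtype=np.float64)
    for k, r in enumerate(ds.records):
        bits[k] = dichotomize(r, schema)
    labels = np.array([r.gs_cause for r in ds.records], dtype=object)
    return bits, labels


def median_duration_cutoffs(ds: GSDataset) -> list[SymptomSchema]:
    """Return a schema whose duration cutoffs are the per-symptom median of
    positive observed durations in ``ds`` (symptoms with no positive
    duration keep their existing cutoff)."""
    out = []
    for s in ds.schema:
        if s.kind != "duration":
            out.append(s)
            continue
        vals = [
            float(r.responses[s.symptom_id])
            for r in ds.records
            if isinstance(r.responses.get(s.symptom_id), (int, float))
            and not isinstance(r.responses.get(s.symptom_id), bool)
            and float(r.responses[s.symptom_id]) > 0
        ]
        cutoff = float(np.median(vals)) if vals else s.duration_cutoff
        out.append(replace(s, duration_cutoff=cutoff))
    return out


# ---------------------------------------------------------------------------
# Filtering and combination
# ---------------------------------------------------------------------------


def filter_gold_standard(ds: GSDataset, levels: Iterable[str | int]) -> GSDataset:
    """Keep only records whose gold-standard level is in ``levels``.

    The cause list is left unchanged even if a cause loses all records;
    downstream training drops (and logs) empty causes itself.
    """
    lev = {str(l) for l in levels}
    if not lev:
        raise ValueError("levels must be non-empty")
    kept = [r for r in ds.records if r.gs_level in lev]
    logger.info(
        "filter_gold_standard: kept %d of %d records at levels %s",
        len(kept), len(ds.records), sorted(lev),
    )
    return GSDataset(ds.module, list(ds.causes), list(ds.schema), kept)


def concat_datasets(a: GSDataset, b: GSDataset) -> GSDataset:
    """Pool two datasets of the same module and schema; causes are unioned
    (order: ``a``'s causes, then causes unique to ``b``)."""
    if a.module != b.module:
        raise ValueError(f"module mismatch: {a.module!r} vs {b.module!r}")
    if a.symptom_ids != b.symptom_ids:
        raise ValueError("symptom schemas differ between datasets")
    causes = list(a.causes) + [c for c in b.causes if c not in a.causes]
    return GSDataset(a.module, causes, list(a.schema), list(a.records) + list(b.records))


# ---------------------------------------------------------------------------
# CSV I/O (one row per death; comma-delimited, UTF-8, header mandatory)
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("record_id", "site", "gs_cause", "gs_level")


def _parse_cell(raw: str, s: SymptomSchema) -> object:
    raw = raw.strip()
    if raw == "":
        return MISSING
    if raw == DONT_KNOW:
        return DONT_KNOW
    if s.kind == "binary":
        return raw if raw in (YES, NO) else MISSING
    if s.kind == "duration":
        try:
            return float(raw)
        except ValueError:
            return MISSING  # unparseable cells become missing, row retained
    return raw  # categorical code


def _format_cell(v: object) -> str:
    if v is MISSING:
        return ""
    if isinstance(v, float):
        return repr(v) if not v.is_integer() else str(int(v))
    return str(v)


def read_gs_dataset(
    path,
    schema: Sequence[SymptomSchema],
    module: str,
    causes: Sequence[str] | None = None,
) -> GSDataset:
    """Read a one-row-per-death CSV into a :class:`GSDataset`.

    Required columns: record_id, site, gs_cause, gs_level; one column per
    schema symptom (absent symptom columns read as missing). If
    ``causes`` is given, an unknown gs_cause raises naming the row;
    otherwise the cause list is inferred in order of first appearance.
    """
    schema = list(schema)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _REQUIRED_COLUMNS:
            if col not in header:
                raise ValueError(f"required column {col!r} missing from {path}")
        by_id = {s.symptom_id: s for s in schema}
        records: list[VARecord] = []
        seen_causes: list[str] = []
        known = set(causes) if causes is not None else None
        for rownum, row in enumerate(reader, start=2):
            cause = row["gs_cause"]
            if known is not None and cause not in known:
                raise ValueError(
                    f"{path} row {rownum} (record_id={row['record_id']!r}): "
                    f"gs_cause {cause!r} not in supplied cause list"
                )
            if cause not in seen_causes:
                seen_causes.append(cause)
            responses = {
                sid: _parse_cell(row.get(sid, ""), s) for sid, s in by_id.items()
            }
            records.append(
                VARecord(
                    record_id=row["record_id"],
                    module=module,
                    site=row["site"],
                    gs_cause=cause,
                    gs_level=row["gs_level"],
                    responses=responses,
                )
            )
    cause_list = list(causes) if causes is not None else seen_causes
    if not cause_list:
        raise ValueError(f"{path}: no records and no cause list supplied")
    return GSDataset(module, cause_list, schema, records)


def write_gs_dataset(ds: GSDataset, path) -> None:
    """Write a dataset in the CSV layout accepted by :func:`read_gs_dataset`."""
    sids = ds.symptom_ids
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_REQUIRED_COLUMNS) + sids)
        for r in ds.records:
            writer.writerow(
                [r.record_id, r.site, r.gs_cause, r.gs_level]
                + [_format_cell(r.responses.get(sid, MISSING)) for sid in sids]
            )


# ---------------------------------------------------------------------------
# Matrix I/O (long format: cause, symptom, value, lower, upper, significant)
# ---------------------------------------------------------------------------


def write_matrix(m, path) -> None:
    """Write an endorsement or Tariff matrix as a long-format CSV.

    Columns: cause, symptom, value, lower, upper, significant (and
    rounded, when the matrix carries rounded Tariffs). Endorsement
    matrices leave lower/upper/significant blank.
    """
    is_tariff = hasattr(m, "raw")
    value = m.raw if is_tariff else m.x
    lower = getattr(m, "ui_lower", None)
    upper = getattr(m, "ui_upper", None)
    significant = getattr(m, "significant", None)
    rounded = getattr(m, "rounded", None)
    rows = []
    for j, cause in enumerate(m.causes):
        for i, sid in enumerate(m.symptoms):
            row = {
                "cause": cause,
                "symptom": sid,
                "value": value[i, j],
                "lower": "" if lower is None else lower[i, j],
                "upper": "" if upper is None else upper[i, j],
                "significant": "" if significant is None else bool(significant[i, j]),
            }
            if is_tariff:
                row["rounded"] = "" if rounded is None else rounded[i, j]
            rows.append(row)
    columns = ["cause", "symptom", "value", "lower", "upper", "significant"]
    if is_tariff:
        columns.append("rounded")
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a long-format matrix CSV back into a DataFrame (one row per
    cause-symptom pair, in file order)."""
    return pd.read_csv(path, keep_default_na=False, na_values=[])


# ---------------------------------------------------------------------------
# Schema config (YAML)
# ---------------------------------------------------------------------------


def read_schema(path) -> list[SymptomSchema]:
    """Load a symptom schema from a YAML config.

    Layout::

        module: adult
        symptoms:
          - id: chest_pain
            kind: binary
          - id: illness_days
            kind: duration
            cutoff: 7
          - id: stool_appearance
            kind: categorical
            endorsing: ["watery", "bloody"]
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    module = doc["module"]
    out = []
    for item in doc["symptoms"]:
        out.append(
            SymptomSchema(
                symptom_id=str(item["id"]),
                module=module,
                kind=item["kind"],
                duration_cutoff=item.get("cutoff"),
                endorsing_values=(
                    frozenset(map(str, item["endorsing"])) if "endorsing" in item else None
                ),
                question_text=item.get("text"),
            )
        )
    return out


def write_schema(schema: Sequence[SymptomSchema], path) -> None:
    if not schema:
        raise ValueError("schema must be non-empty")
    modules = {s.module for s in schema}
    if len(modules) != 1:
        raise ValueError("schema mixes modules")
    doc: dict[str, object] = {"module": schema[0].module, "symptoms": []}
    for s in schema:
        item: dict[str, object] = {"id": s.symptom_id, "kind": s.kind}
        if s.duration_cutoff is not None:
            item["cutoff"] = float(s.duration_cutoff)
        if s.endorsing_values is not None:
            item["endorsing"] = sorted(s.endorsing_values)
        if s.question_text is not None:
            item["text"] = s.question_text
        doc["symptoms"].append(item)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
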