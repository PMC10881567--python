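"""Feature schema registry, patient records, and cohort CSV I/O.

The default schema registers the 68 numerical features used for staging:
demographics (2), vital signs (2), genetics (1), cognitive scores (12),
lab tests (42), MRI volumetrics (7) and PET (2).  Missingness is explicit:
a feature absent from a record's map was simply never measured, and no
stage of the pipeline imputes it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import math

import pandas as pd

from .errors import MissingIdColumn, NonNumericValue

CATEGORIES = ("demographics", "vital_signs", "genetics", "cognitive", "lab", "MRI", "PET")
KINDS = ("fuzzy-numeric", "singleton-ordinal")
DIAGNOSIS_CLASSES = ("CN", "SMC", "EMCI", "LMCI", "AD")

ID_COLUMNS = ("RID", "ID")
LABEL_COLUMNS = ("DX", "LABEL")
SYMPTOM_COLUMN = "symptoms"
COMPLICATION_COLUMN = "complications"
OVERRIDE_COLUMN = "severity_overrides"

_NA_TOKENS = {"", "na", "n/a", "nan", "null", "none", "."}


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    category: str
    domain: tuple[float, float]
    kind: str = "fuzzy-numeric"
    aliases: tuple[str, ...] = ()

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")
        if self.kind not in KINDS:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        lo, hi = float(self.domain[0]), float(self.domain[1])
        if not lo < hi:
            raise ValueError(f"{self.name}: degenerate domain {self.domain}")
        object.__setattr__(self, "domain", (lo, hi))
        object.__setattr__(self, "aliases", tuple(self.aliases))


class FeatureSchema:
    """Ordered feature descriptors with alias-aware name resolution."""

    def __init__(self, features: Sequence[FeatureDescriptor]):
        self.features = tuple(features)
        self._by_name: dict[str, FeatureDescriptor] = {}
        self._index: dict[str, str] = {}
        for feat in self.features:
            if feat.name in self._by_name:
                raise ValueError(f"duplicate feature name {feat.name!r}")
            self._by_name[feat.name] = feat
            for key in (feat.name, *feat.aliases):
                self._index[key.lower()] = feat.name

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, name: str) -> bool:
        return name.lower() in self._index

    def resolve(self, name: str) -> str | None:
        return self._index.get(name.lower())

    def get(self, name: str) -> FeatureDescriptor:
        canonical = self.resolve(name)
        if canonical is None:
            raise KeyError(name)
        return self._by_name[canonical]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in self.features)

    def category_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CATEGORIES}
        for feat in self.features:
            counts[feat.category] += 1
        return counts

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FeatureSchema":
        feats = [
            FeatureDescriptor(
                name=spec["name"],
                category=spec["category"],
                domain=tuple(spec["domain"]),
                kind=spec.get("kind", "fuzzy-numeric"),
                aliases=tuple(spec.get("aliases", ())),
            )
            for spec in payload["features"]
        ]
        return cls(feats)

    @classmethod
    def default(cls) -> "FeatureSchema":
        text = resources.files("fuzzydx.data").joinpath("schema.json").read_text("utf-8")
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class PatientRecord:
    """One subject at baseline: partial numeric features plus free-text lists."""

    id: str
    features: Mapping[str, float] = field(default_factory=dict)
    symptoms: tuple[str, ...] = ()
    complications: tuple[str, ...] = ()
    label: str | None = None
    severity_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        feats = dict(self.features)
        for name, value in feats.items():
            if not math.isfinite(float(value)):
                raise ValueError(f"record {self.id}: non-finite value for {name!r}")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "symptoms", tuple(self.symptoms))
        object.__setattr__(self, "complications", tuple(self.complications))
        object.__setattr__(self, "severity_overrides", dict(self.severity_overrides))
        if self.label is not None and self.label not in DIAGNOSIS_CLASSES:
            raise ValueError(f"record {self.id}: unknown diagnosis label {self.label!r}")

    def with_features(self, extra: Mapping[str, float]) -> "PatientRecord":
        merged = {**self.features, **extra}
        return replace(self, features=merged)


# ---- CSV I/O ---------------------------------------------------------------

def _split_list(cell: str) -> tuple[str, ...]:
    return tuple(part.strip() for part in cell.split(";") if part.strip())


def _parse_overrides(cell: str, row: int) -> dict[str, float]:
    overrides: dict[str, float] = {}
    for chunk in cell.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        term, _, value = chunk.rpartition(":")
        try:
            overrides[term.strip()] = float(value)
        except ValueError as exc:
            raise NonNumericValue(
                f"bad severity override {chunk!r}", row, OVERRIDE_COLUMN
            ) from exc
    return overrides


def read_cohort_csv(path, schema: FeatureSchema | None = None) -> list[PatientRecord]:
    """Read an ADNIMERGE-style cohort table into patient records.

    Empty cells and NA tokens become missing features (no imputation);
    columns that are neither the id, label, symptom/complication lists,
    overrides, nor schema features are ignored with one summary warning.
    """
    schema = schema or FeatureSchema.default()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    id_col = next((c for c in frame.columns if c.upper() in ID_COLUMNS), None)
    if id_col is None:
        raise MissingIdColumn(f"no id column among {ID_COLUMNS} in {path}")
    label_col = next((c for c in frame.columns if c.upper() in LABEL_COLUMNS), None)

    feature_cols: dict[str, str] = {}
    unknown: list[str] = []
    special = {id_col, label_col, SYMPTOM_COLUMN, COMPLICATION_COLUMN, OVERRIDE_COLUMN}
    for col in frame.columns:
        if col in special:
            continue
        canonical = schema.resolve(col)
        if canonical is None:
            unknown.append(col)
        else:
            feature_cols[col] = canonical
    if unknown:
        warnings.warn(
            f"ignoring {len(unknown)} unknown column(s): {', '.join(sorted(unknown))}",
            stacklevel=2,
        )

    records: list[PatientRecord] = []
    for row_idx, row in enumerate(frame.itertuples(index=False), start=1):
        row_map = dict(zip(frame.columns, row))
        features: dict[str, float] = {}
        for col, canonical in feature_cols.items():
            cell = str(row_map[col]).strip()
            if cell.lower() in _NA_TOKENS:
                continue
            try:
                features[canonical] = float(cell)
            except ValueError as exc:
                raise NonNumericValue(f"cannot parse {cell!r}", row_idx, col) from exc
        label = None
        if label_col is not None:
            raw = str(row_map[label_col]).strip()
            if raw.lower() not in _NA_TOKENS:
                label = raw.upper()
        records.append(
            PatientRecord(
                id=str(row_map[id_col]).strip(),
                features=features,
                symptoms=_split_list(str(row_map.get(SYMPTOM_COLUMN, ""))),
                complications=_split_list(str(row_map.get(COMPLICATION_COLUMN, ""))),
                label=label,
                severity_overrides=_parse_overrides(
                    str(row_map.get(OVERRIDE_COLUMN, "")), row_idx
                ),
            )
        )
    return records


def write_cohort_csv(records: Sequence[PatientRecord], path, schema: FeatureSchema | None = None) -> None:
    """Write records in the same dialect `read_cohort_csv` accepts (lossless)."""
    schema = schema or FeatureSchema.default()
    present = [name for name in schema.names if any(name in r.features for r in records)]
    rows = []
    for rec in records:
        row = {"RID": rec.id, "DX": rec.label or ""}
        for name in present:
            value = rec.features.get(name)
            row[name] = "" if value is None else repr(float(value))
        row[SYMPTOM_COLUMN] = "; ".join(rec.symptoms)
        row[COMPLICATION_COLUMN] = "; ".join(rec.complications)
        row[OVERRIDE_COLUMN] = "; ".join(
            f"{term}:{value}" for term, value in rec.severity_overrides.items()
        )
        rows.append(row)
    columns = ["RID", "DX", *present, SYMPTOM_COLUMN, COMPLICATION_COLUMN, OVERRIDE_COLUMN]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def validate_record(record: PatientRecord, schema: FeatureSchema | None = None) -> dict:
    """Report-only validation: out-of-domain values, unknown features, emptiness."""
    schema = schema or FeatureSchema.default()
    report: dict = {"id": record.id, "out_of_domain": [], "unknown_features": [], "empty": False}
    for name, value in record.features.items():
        canonical = schema.resolve(name)
        if canonical is None:
            if name not in ("S_Severity", "C_Severity"):
                report["unknown_features"].append(name)
            continue
        lo, hi = schema.get(canonical).domain
        if not lo <= value <= hi:
            report["out_of_domain"].append({"feature": canonical, "value": value, "domain": [lo, hi]})
    if not record.features and not record.symptoms and not record.complications:
        report["empty"] = True
    report["ok"] = not (report["out_of_domain"] or report["unknown_features"] or report["empty"])
    return report
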