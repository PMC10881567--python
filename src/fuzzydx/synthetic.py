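"""Synthetic cohort generation for download-free, end-to-end testing.

Real staging cohorts are registration-gated, so every stage of the
pipeline is exercised on synthetic subjects instead.  Each diagnosis class
has a prototype — per-feature truncated-normal location/spread plus a
symptom/complication vocabulary pool — encoding the qualitative structure
of real baseline cohorts: functional decline (FAQ, CDRSB) peaks in AD,
cognitive screens (MMSE, MoCA) peak in CN, the amnestic markers
(LDELTOTAL, percent forgetting, ADAS13, ventricular volume, CSF tau) are
elevated in LMCI, and hypometabolism with medial-temporal atrophy (FDG,
MidTemp, Hippocampus) marks EMCI.  The generator makes no claim of
distributional fidelity to any real dataset — the prototypes are design
values stored in ``prototypes.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InvalidSpec
from .patients import DIAGNOSIS_CLASSES, FeatureSchema, PatientRecord
from .taxonomy import SymptomTaxonomy, taxonomy_from_dict

MIN_SYMPTOMS = 2
MIN_COMPLICATIONS = 1


@dataclass(frozen=True)
class ClassPrototype:
    """Per-class generative settings."""

    label: str
    features: Mapping[str, tuple[float, float]]  # name -> (mean, sd)
    symptom_pool: tuple[tuple[str, float], ...]  # (term, draw probability)
    complication_pool: tuple[tuple[str, float], ...]
    severity_band: tuple[float, float]
    apoe4_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)

    def __post_init__(self):
        object.__setattr__(self, "features", dict(self.features))
        for term, p in (*self.symptom_pool, *self.complication_pool):
            if not 0.0 <= p <= 1.0:
                raise InvalidSpec(f"{self.label}: draw probability for {term!r} outside [0, 1]")
        if abs(sum(self.apoe4_probs) - 1.0) > 1e-9:
            raise InvalidSpec(f"{self.label}: APOE4 probabilities must sum to 1")


@dataclass(frozen=True)
class CohortSpec:
    """What to generate: per-class sizes, seed, missingness."""

    n_per_class: Mapping[str, int]
    seed: int = 0
    missingness: float | Mapping[str, float] = 0.0
    prototypes: Mapping[str, ClassPrototype] | None = None

    def __post_init__(self):
        for cls, n in self.n_per_class.items():
            if cls not in DIAGNOSIS_CLASSES:
                raise InvalidSpec(f"unknown class {cls!r}")
            if n < 0:
                raise InvalidSpec(f"negative sample count for {cls}")
        rates = (
            self.missingness.values()
            if isinstance(self.missingness, Mapping)
            else [self.missingness]
        )
        for rate in rates:
            if not 0.0 <= rate < 1.0:
                raise InvalidSpec(f"missingness rate {rate} outside [0, 1)")

    def rate_for(self, category: str) -> float:
        if isinstance(self.missingness, Mapping):
            return float(self.missingness.get(category, 0.0))
        return float(self.missingness)


def default_prototypes() -> dict[str, ClassPrototype]:
    text = resources.files("fuzzydx.data").joinpath("prototypes.json").read_text("utf-8")
    payload = json.loads(text)
    prototypes = {}
    for label, spec in payload["classes"].items():
        prototypes[label] = ClassPrototype(
            label=label,
            features={k: tuple(v) for k, v in spec["features"].items()},
            symptom_pool=tuple((t, p) for t, p in spec["symptom_pool"]),
            complication_pool=tuple((t, p) for t, p in spec["complication_pool"]),
            severity_band=tuple(spec["severity_band"]),
            apoe4_probs=tuple(spec["apoe4_probs"]),
        )
    return prototypes


def _truncnorm_draw(rng, mean, sd, lo, hi, size):
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_terms(rng, pool, minimum):
    chosen = [term for term, p in pool if rng.random() < p]
    if len(chosen) < minimum:
        remaining = [term for term, _ in pool if term not in chosen]
        need = min(minimum - len(chosen), len(remaining))
        if need > 0:
            extra = rng.choice(len(remaining), size=need, replace=False)
            chosen.extend(remaining[i] for i in sorted(extra))
    return tuple(chosen)


def generate_cohort(spec: CohortSpec, schema: FeatureSchema | None = None) -> list[PatientRecord]:
    """Deterministically generate a labelled synthetic cohort.

    Numeric features are truncated-normal draws inside the schema domain
    around the class prototype mean; symptom and complication lists are
    Bernoulli draws from the class pools (at least two symptoms and one
    complication per subject so the semantic stage always has input).
    Missingness then removes each generated feature independently at the
    per-category rate, modelling tests the subject never took.
    """
    schema = schema or FeatureSchema.default()
    prototypes = dict(spec.prototypes or default_prototypes())
    rng = np.random.default_rng(spec.seed)
    records: list[PatientRecord] = []
    next_id = 1
    for cls in DIAGNOSIS_CLASSES:
        n = int(spec.n_per_class.get(cls, 0))
        if n == 0:
            continue
        proto = prototypes.get(cls)
        if proto is None:
            raise InvalidSpec(f"no prototype for class {cls!r}")
        draws = {}
        for name, (mean, sd) in proto.features.items():
            lo, hi = schema.get(name).domain
            draws[name] = _truncnorm_draw(rng, mean, sd, lo, hi, n)
        apoe4 = rng.choice(3, size=n, p=proto.apoe4_probs)
        for i in range(n):
            features = {name: float(values[i]) for name, values in draws.items()}
            features["APOE4"] = float(apoe4[i])
            kept = {}
            for name, value in features.items():
                rate = spec.rate_for(schema.get(name).category)
                if rate <= 0.0 or rng.random() >= rate:
                    kept[name] = value
            records.append(
                PatientRecord(
                    id=str(next_id),
                    features=kept,
                    symptoms=_draw_terms(rng, proto.symptom_pool, MIN_SYMPTOMS),
                    complications=_draw_terms(rng, proto.complication_pool, MIN_COMPLICATIONS),
                    label=cls,
                )
            )
            next_id += 1
    return records


def generate_fixture_taxonomy() -> SymptomTaxonomy:
    """The packaged fixture taxonomy (deterministic: loaded from data)."""
    text = resources.files("fuzzydx.data").joinpath("fixture_taxonomy.json").read_text("utf-8")
    return taxonomy_from_dict(json.loads(text))
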