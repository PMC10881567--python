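"""End-to-end diagnosis: semantic binding -> fuzzification -> rules -> COG.

For each record the pipeline (1) scores symptom/complication severity
through the taxonomy, (2) fuzzifies every present numeric feature that has
a registered partition, (3) evaluates the rulebase with min conjunction,
(4) aggregates fired consequents with max, and (5) defuzzifies the output
set by centre of gravity into the diagnosis value DV(p), which the output
partition maps to a class label.  When no rule fires the record is
reported INCONCLUSIVE rather than forced into a nearest class: clinically
safer, and it surfaces rulebase coverage gaps instead of hiding them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import fuzzy, rules as rules_mod, taxonomy as tax_mod
from .errors import EmptyOutput, NonFiniteInput, UnknownPatientId
from .partitions import PartitionRegistry
from .patients import PatientRecord
from .rules import RuleBase, RuleTrace
from .taxonomy import SemanticTrace, SymptomTaxonomy

INCONCLUSIVE = "INCONCLUSIVE"
DEFAULT_RESOLUTION = 1001


@dataclass(frozen=True)
class DiagnosisResult:
    """Crisp diagnosis value plus the full explanation trace for one patient."""

    patient_id: str
    dv: float | None
    predicted: str
    activations: dict[str, float]
    n_rules_fired: int
    semantic: SemanticTrace
    rule_trace: tuple[RuleTrace, ...]
    fuzzified: dict[str, dict[str, float]]
    resolution: int


def diagnose_record(
    record: PatientRecord,
    rulebase: RuleBase,
    registry: PartitionRegistry,
    taxonomy: SymptomTaxonomy,
    tau: float = tax_mod.DEFAULT_TAU,
    resolution: int = DEFAULT_RESOLUTION,
    aggregator: str = "weighted_mean",
) -> DiagnosisResult:
    bound, semantic = tax_mod.bind_semantic_inputs(
        record, taxonomy, tau=tau, aggregator=aggregator
    )
    fuzzified: dict[str, fuzzy.FuzzifiedValue] = {}
    for name, value in bound.features.items():
        canonical = registry.resolve(name)
        if canonical is None:
            continue
        try:
            fuzzified[canonical] = fuzzy.fuzzify(registry.get(canonical), value)
        except NonFiniteInput:
            warnings.warn(f"{record.id}: non-finite {name}; treated as missing", stacklevel=2)
    activations, trace = rules_mod.evaluate(rulebase, fuzzified)
    out_partition = registry.get(rules_mod.OUTPUT_VARIABLE)
    out_set = fuzzy.aggregate_outputs(activations, out_partition)
    try:
        dv = fuzzy.defuzzify_cog(out_set, resolution=resolution)
        predicted = fuzzy.classify(dv, out_partition)
    except EmptyOutput:
        dv, predicted = None, INCONCLUSIVE
    return DiagnosisResult(
        patient_id=record.id,
        dv=dv,
        predicted=predicted,
        activations=dict(out_set.activations),
        n_rules_fired=sum(1 for t in trace if t.strength > 0.0),
        semantic=semantic,
        rule_trace=tuple(trace),
        fuzzified={k: dict(v.degrees) for k, v in fuzzified.items()},
        resolution=resolution,
    )


def diagnose_cohort(
    records: Sequence[PatientRecord],
    rulebase: RuleBase,
    registry: PartitionRegistry,
    taxonomy: SymptomTaxonomy,
    **kwargs,
) -> list[DiagnosisResult]:
    return [
        diagnose_record(rec, rulebase, registry, taxonomy, **kwargs) for rec in records
    ]


def results_frame(results: Sequence[DiagnosisResult]) -> pd.DataFrame:
    """Results table: id, DV, predicted class, per-class activation, rules fired."""
    classes = rules_mod.DIAGNOSIS_CLASSES
    rows = []
    for res in results:
        row = {
            "RID": res.patient_id,
            "DV": "" if res.dv is None else f"{res.dv:.6f}",
            "predicted": res.predicted,
        }
        for cls in classes:
            row[f"act_{cls}"] = f"{res.activations.get(cls, 0.0):.6f}"
        row["n_rules_fired"] = res.n_rules_fired
        rows.append(row)
    return pd.DataFrame(rows)


def write_results_csv(results: Sequence[DiagnosisResult], path) -> None:
    """Atomic write: the results file never exists half-written."""
    import os
    import tempfile

    frame = results_frame(results)
    directory = os.path.dirname(os.path.abspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            frame.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def format_explanation(result: DiagnosisResult, top_k: int = 10) -> str:
    """Human-readable trace: matches, severities, fired rules, DV, class."""
    lines = [f"Patient {result.patient_id}"]
    lines.append("  Symptom matches:")
    for match in result.semantic.symptom_matches:
        target = match.concept_id or "(unmatched)"
        lines.append(
            f"    {match.query!r} -> {target} [route={match.route}, sim={match.similarity:.3f}]"
        )
    if not result.semantic.symptom_matches:
        lines.append("    (none reported)")
    lines.append("  Complication matches:")
    for match in result.semantic.complication_matches:
        target = match.concept_id or "(unmatched)"
        lines.append(
            f"    {match.query!r} -> {target} [route={match.route}, sim={match.similarity:.3f}]"
        )
    if not result.semantic.complication_matches:
        lines.append("    (none reported)")
    lines.append(f"  S_Severity = {result.semantic.s_severity.value:.3f}")
    lines.append(f"  C_Severity = {result.semantic.c_severity.value:.3f}")

    fired = sorted(
        (t for t in result.rule_trace if t.strength > 0.0),
        key=lambda t: (-t.strength, t.rule_id),
    )
    lines.append(f"  Fired rules ({len(fired)} of {len(result.rule_trace)}):")
    for t in fired[:top_k]:
        lines.append(f"    {t.rule_id}: strength {t.strength:.3f} -> {t.consequent}")
    skipped = [t for t in result.rule_trace if t.skipped_missing]
    if skipped:
        lines.append(f"  Skipped (missing features): {len(skipped)}")
        for t in skipped:
            lines.append(f"    {t.rule_id}: missing {', '.join(t.missing_variables)}")
    if result.dv is None:
        lines.append("  Diagnosis: INCONCLUSIVE (no rule fired)")
    else:
        lines.append(f"  DV(p) = {result.dv:.3f}  (grid resolution {result.resolution})")
        lines.append(f"  Diagnosis: {result.predicted}")
    return "\n".join(lines)
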