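"""Fuzzy diagnostic rules: representation, text dialect, and evaluation.

Rules are pure conjunctions of ``<variable> IS <label>`` atoms with a
diagnosis-class consequent on the output variable ``DR``:

    RULE r1: IF CDRSB IS VeryLow AND FAQ IS VeryLow THEN DR IS CN;

Keywords are case-insensitive; variable names resolve through the
partition registry (so ``Age`` and ``AGE`` are the same atom) and labels
resolve case-insensitively against the variable's partition.

Missing-feature semantics: a rule whose antecedent references ANY feature
absent from the record contributes nothing (firing strength 0, marked
``skipped-missing`` in the trace).  Coverage under missingness comes from
rulebase redundancy, not from silently dropping atoms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ParseError, UnknownLabel, UnknownVariable
from .fuzzy import FuzzifiedValue
from .partitions import PartitionRegistry

DIAGNOSIS_CLASSES = ("CN", "SMC", "EMCI", "LMCI", "AD")
OUTPUT_VARIABLE = "DR"

_KEYWORDS = {"RULE", "IF", "IS", "AND", "THEN"}


@dataclass(frozen=True)
class RuleAtom:
    """One ``variable IS label`` condition."""

    variable: str
    label: str


@dataclass(frozen=True)
class FuzzyRule:
    id: str
    antecedent: tuple[RuleAtom, ...]
    consequent: str

    def __post_init__(self):
        if not self.antecedent:
            raise ValueError(f"rule {self.id}: empty antecedent")
        variables = [a.variable for a in self.antecedent]
        if len(set(variables)) != len(variables):
            raise ValueError(f"rule {self.id}: duplicate variable in antecedent")
        if self.consequent not in DIAGNOSIS_CLASSES:
            raise ValueError(f"rule {self.id}: unknown diagnosis class {self.consequent!r}")
        object.__setattr__(self, "antecedent", tuple(self.antecedent))


@dataclass(frozen=True)
class RuleTrace:
    """Evaluation record for one rule."""

    rule_id: str
    strength: float
    skipped_missing: bool
    missing_variables: tuple[str, ...] = ()
    consequent: str = ""


@dataclass
class RuleBase:
    """Ordered rule list bound to a partition registry."""

    rules: list[FuzzyRule]
    registry: PartitionRegistry

    def __post_init__(self):
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate rule id {dup!r}")
        for rule in self.rules:
            for atom in rule.antecedent:
                var = self.registry.get(atom.variable)  # raises UnknownVariable
                if atom.label not in var.labels:
                    raise UnknownLabel(
                        f"rule {rule.id}: label {atom.label!r} not in partition of {var.name!r}"
                    )

    def __len__(self) -> int:
        return len(self.rules)

    def __eq__(self, other) -> bool:
        return isinstance(other, RuleBase) and self.rules == other.rules

    def extend(self, other: "RuleBase") -> "RuleBase":
        return RuleBase(rules=self.rules + other.rules, registry=self.registry)


# --- parsing ---------------------------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*|[:;]|\S")


def _tokenize(text: str):
    tokens = []  # (value, line, col)
    for lineno, line in enumerate(text.splitlines(), start=1):
        body = line.split("#", 1)[0]
        for m in _TOKEN_RE.finditer(body):
            tokens.append((m.group(0), lineno, m.start() + 1))
    return tokens


class _TokenStream:
    def __init__(self, tokens):
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self, expect: str | None = None):
        tok = self.peek()
        if tok is None:
            last = self.tokens[-1] if self.tokens else ("", 1, 1)
            raise ParseError("unexpected end of input", last[1], last[2])
        value, line, col = tok
        if expect is not None:
            matches = value.upper() == expect if expect in _KEYWORDS or expect in {":", ";"} else value == expect
            if not matches:
                raise ParseError(f"expected {expect!r}, found {value!r}", line, col)
        self.pos += 1
        return value, line, col

    def next_word(self, what: str):
        value, line, col = self.next()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", value):
            raise ParseError(f"expected {what}, found {value!r}", line, col)
        return value, line, col


def _resolve_atom(registry: PartitionRegistry, name: str, label: str, line: int, col: int) -> RuleAtom:
    canonical = registry.resolve(name)
    if canonical is None:
        raise UnknownVariable(f"unknown variable {name!r} (line {line}, column {col})")
    var = registry.get(canonical)
    canonical_label = var.resolve_label(label)
    if canonical_label is None:
        raise UnknownLabel(
            f"unknown label {label!r} for variable {canonical!r} (line {line}, column {col})"
        )
    return RuleAtom(variable=canonical, label=canonical_label)


def parse_rules(text: str, registry: PartitionRegistry) -> RuleBase:
    """Parse an FCL-style rule document into a validated :class:`RuleBase`."""
    stream = _TokenStream(_tokenize(text))
    rules: list[FuzzyRule] = []
    while stream.peek() is not None:
        stream.next("RULE")
        rule_id, id_line, id_col = stream.next_word("rule id")
        stream.next(":")
        stream.next("IF")
        atoms: list[RuleAtom] = []
        while True:
            name, line, col = stream.next_word("variable name")
            stream.next("IS")
            label, lline, lcol = stream.next_word("linguistic label")
            if name.upper() == OUTPUT_VARIABLE:
                raise ParseError("output variable DR cannot appear in an antecedent", line, col)
            atoms.append(_resolve_atom(registry, name, label, lline, lcol))
            nxt = stream.peek()
            if nxt is not None and nxt[0].upper() == "AND":
                stream.next("AND")
                continue
            break
        stream.next("THEN")
        out_name, oline, ocol = stream.next_word("output variable")
        if out_name.upper() != OUTPUT_VARIABLE:
            raise ParseError(f"consequent variable must be DR, found {out_name!r}", oline, ocol)
        stream.next("IS")
        cls, cline, ccol = stream.next_word("diagnosis class")
        cls_up = cls.upper()
        if cls_up not in DIAGNOSIS_CLASSES:
            raise ParseError(f"unknown diagnosis class {cls!r}", cline, ccol)
        stream.next(";")
        try:
            rules.append(FuzzyRule(id=rule_id, antecedent=tuple(atoms), consequent=cls_up))
        except ValueError as exc:
            raise ParseError(str(exc), id_line, id_col) from exc
    return RuleBase(rules=rules, registry=registry)


def serialize_rules(rb: RuleBase) -> str:
    """One rule per line, uppercase keywords; re-parses to an equal rulebase."""
    lines = []
    for rule in rb.rules:
        body = " AND ".join(f"{a.variable} IS {a.label}" for a in rule.antecedent)
        lines.append(f"RULE {rule.id}: IF {body} THEN DR IS {rule.consequent};")
    return "\n".join(lines) + "\n"


# --- evaluation ------------------------------------------------------------

def firing_strength(rule: FuzzyRule, fuzzified: Mapping[str, FuzzifiedValue]) -> float:
    """Min over atom degrees; 0 if any antecedent feature is missing."""
    strength = 1.0
    for atom in rule.antecedent:
        fv = fuzzified.get(atom.variable)
        if fv is None:
            return 0.0
        strength = min(strength, fv.degrees[atom.label])
    return strength


def evaluate(
    rb: RuleBase, fuzzified: Mapping[str, FuzzifiedValue]
) -> tuple[list[tuple[str, float]], list[RuleTrace]]:
    """Evaluate every rule; return fired (class, strength) pairs plus a trace.

    The activation list holds one entry per rule with strength > 0 and
    feeds :func:`fuzzydx.fuzzy.aggregate_outputs`; the trace records every
    rule exactly once, including skip reasons.
    """
    activations: list[tuple[str, float]] = []
    trace: list[RuleTrace] = []
    for rule in rb.rules:
        missing = tuple(a.variable for a in rule.antecedent if a.variable not in fuzzified)
        if missing:
            trace.append(
                RuleTrace(rule.id, 0.0, True, missing, rule.consequent)
            )
            continue
        strength = firing_strength(rule, fuzzified)
        trace.append(RuleTrace(rule.id, strength, False, (), rule.consequent))
        if strength > 0.0:
            activations.append((rule.consequent, strength))
    return activations, trace


# --- validation report -----------------------------------------------------

def validation_report(text: str, registry: PartitionRegistry) -> dict:
    """Lenient rule-file checker: collects problems instead of raising.

    Returns a JSON-serializable report with unknown variables/labels,
    duplicate rule ids, and duplicated antecedent variables.
    """
    report: dict = {
        "n_rules": 0,
        "unknown_variables": [],
        "unknown_labels": [],
        "duplicate_ids": [],
        "duplicate_antecedents": [],
        "parse_errors": [],
        "ok": True,
    }
    seen_ids: set[str] = set()
    for stmt in [s.strip() for s in text.split(";") if s.strip()]:
        m = re.match(
            r"RULE\s+(\w+)\s*:\s*IF\s+(.*)\s+THEN\s+DR\s+IS\s+(\w+)\s*$",
            stmt,
            re.IGNORECASE | re.DOTALL,
        )
        if not m:
            report["parse_errors"].append(stmt[:60])
            continue
        rule_id, body, _cls = m.groups()
        report["n_rules"] += 1
        if rule_id in seen_ids:
            report["duplicate_ids"].append(rule_id)
        seen_ids.add(rule_id)
        seen_vars: set[str] = set()
        for part in re.split(r"\s+AND\s+", body, flags=re.IGNORECASE):
            am = re.match(r"(\w+)\s+IS\s+(\w+)\s*$", part.strip(), re.IGNORECASE)
            if not am:
                report["parse_errors"].append(part.strip()[:60])
                continue
            name, label = am.groups()
            canonical = registry.resolve(name)
            if canonical is None:
                report["unknown_variables"].append({"rule": rule_id, "variable": name})
                continue
            if canonical in seen_vars:
                report["duplicate_antecedents"].append({"rule": rule_id, "variable": canonical})
            seen_vars.add(canonical)
            if registry.get(canonical).resolve_label(label) is None:
                report["unknown_labels"].append(
                    {"rule": rule_id, "variable": canonical, "label": label}
                )
    report["ok"] = not any(
        report[k]
        for k in (
            "unknown_variables",
            "unknown_labels",
            "duplicate_ids",
            "duplicate_antecedents",
            "parse_errors",
        )
    )
    return report


# --- shipped rulebases ------------------------------------------------------

def load_rule_resource(name: str, registry: PartitionRegistry) -> RuleBase:
    from importlib import resources

    text = resources.files("fuzzydx.data").joinpath(name).read_text("utf-8")
    return parse_rules(text, registry)


def core_rulebase(registry: PartitionRegistry | None = None) -> RuleBase:
    """The 18 expert rules covering CN/SMC/EMCI/LMCI/AD."""
    registry = registry or PartitionRegistry.default()
    return load_rule_resource("rules_core.fcl", registry)


def extended_rulebase(registry: PartitionRegistry | None = None) -> RuleBase:
    """Curated coverage extensions (documented in the rule file itself)."""
    registry = registry or PartitionRegistry.default()
    return load_rule_resource("rules_extended.fcl", registry)


def default_rulebase(registry: PartitionRegistry | None = None) -> RuleBase:
    registry = registry or PartitionRegistry.default()
    return core_rulebase(registry).extend(extended_rulebase(registry))
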