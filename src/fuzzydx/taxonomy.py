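"""Symptom/complication taxonomy and semantic severity scoring.

A clinician reports symptoms as free text ("anxious", "can't sleep").  A
static rule keyed on the literal string "confusion" would never fire for a
patient described as "suspicious" or "fearful", even though those concepts
sit next to confusion in the mood-and-personality-change branch of the
taxonomy.  This module closes that gap: free text is matched to taxonomy
concepts through normalized labels, synonyms and fuzzy lexical matching,
concept relatedness is measured with Wu–Palmer similarity on the is-a
hierarchy, and the matched concepts' severity weights are aggregated into
two numeric features — ``S_Severity`` for symptoms and ``C_Severity`` for
complications — that the fuzzy rulebase consumes like any other input.
"""

from __future__ import annotations

import difflib
import json
import re
import string
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .errors import (
    CrossCategoryComparison,
    CycleDetected,
    DuplicateId,
    EmptyTerm,
    OrphanConcept,
    TaxonomyError,
)

CATEGORIES = ("symptom", "complication")

DEFAULT_TAU = 0.5               # structural/overall similarity floor
DEFAULT_LEXICAL_THRESHOLD = 0.85  # normalized string-similarity gate

_PUNCT_TABLE = str.maketrans("", "", string.punctuation)


@dataclass(frozen=True)
class ConceptNode:
    """One concept: preferred label, synonyms, is-a parents, severity weight.

    ``severity`` lives on a 0–10 scale (0 benign, 10 maximal clinical
    concern).  ``part_of`` relations are carried as annotations only; they
    play no role in similarity.
    """

    id: str
    label: str
    category: str
    severity: float
    synonyms: tuple[str, ...] = ()
    parents: tuple[str, ...] = ()
    part_of: tuple[str, ...] = ()

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise TaxonomyError(f"{self.id}: unknown category {self.category!r}")
        if not (0.0 <= self.severity <= 10.0):
            raise TaxonomyError(f"{self.id}: severity {self.severity} outside [0, 10]")
        if not self.label.strip():
            raise TaxonomyError(f"{self.id}: empty label")
        if any(not s.strip() for s in self.synonyms):
            raise TaxonomyError(f"{self.id}: empty synonym")
        object.__setattr__(self, "synonyms", tuple(self.synonyms))
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(self, "part_of", tuple(self.part_of))


def normalize_term(text: str) -> str:
    """Canonical token string: lowercase, punctuation stripped, spaces collapsed."""
    out = re.sub(r"\s+", " ", text.lower().translate(_PUNCT_TABLE)).strip()
    if not out:
        raise EmptyTerm(f"term {text!r} normalizes to nothing")
    return out


class SymptomTaxonomy:
    """Validated rooted is-a hierarchy with one root per category."""

    def __init__(self, nodes: Iterable[ConceptNode]):
        self.nodes: dict[str, ConceptNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise DuplicateId(f"duplicate concept id {node.id!r}")
            self.nodes[node.id] = node
        if not self.nodes:
            raise OrphanConcept("taxonomy has no concepts")
        self._graph = nx.DiGraph()  # edges child -> parent
        for node in self.nodes.values():
            self._graph.add_node(node.id)
            for parent in node.parents:
                if parent not in self.nodes:
                    raise OrphanConcept(
                        f"concept {node.id!r} references missing parent {parent!r}"
                    )
                self._graph.add_edge(node.id, parent)
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise CycleDetected(f"parent cycle through {cycle[0][0]!r}")
        self.roots: dict[str, str] = {}
        for node in self.nodes.values():
            if not node.parents:
                if node.category in self.roots:
                    raise OrphanConcept(
                        f"multiple roots for category {node.category!r}: "
                        f"{self.roots[node.category]!r} and {node.id!r}"
                    )
                self.roots[node.category] = node.id
        for node in self.nodes.values():
            root = self.roots.get(node.category)
            if root is None:
                raise OrphanConcept(f"category {node.category!r} has no root")
            if node.id != root and root not in nx.descendants(self._graph, node.id):
                raise OrphanConcept(f"concept {node.id!r} cannot reach its category root")
        self._match_index = self._build_match_index()
        self._depth_cache: dict[str, int] = {}

    # ---- structure ---------------------------------------------------------

    def depth(self, concept_id: str) -> int:
        """Shortest is-a path length to the category root; the root has depth 1."""
        cached = self._depth_cache.get(concept_id)
        if cached is not None:
            return cached
        node = self.nodes[concept_id]
        root = self.roots[node.category]
        d = nx.shortest_path_length(self._graph, concept_id, root) + 1
        self._depth_cache[concept_id] = d
        return d

    def ancestors(self, concept_id: str) -> set[str]:
        """All is-a ancestors of a concept, including itself."""
        return {concept_id} | nx.descendants(self._graph, concept_id)

    def parent_of(self, concept_id: str) -> tuple[str, ...]:
        return self.nodes[concept_id].parents

    def siblings(self, concept_id: str) -> set[str]:
        sibs: set[str] = set()
        for parent in self.nodes[concept_id].parents:
            sibs |= set(self._graph.predecessors(parent))
        sibs.discard(concept_id)
        return sibs

    def __len__(self) -> int:
        return len(self.nodes)

    # ---- matching ----------------------------------------------------------

    def _build_match_index(self) -> dict[str, str]:
        index: dict[str, str] = {}
        # preferred labels take precedence over synonyms on collision
        for node in self.nodes.values():
            for syn in node.synonyms:
                index.setdefault(normalize_term(syn), node.id)
        for node in self.nodes.values():
            index[normalize_term(node.label)] = node.id
        return index

    @property
    def match_index(self) -> Mapping[str, str]:
        return self._match_index


@dataclass(frozen=True)
class TermMatch:
    query: str
    concept_id: str | None
    similarity: float
    route: str  # exact-label | synonym | lexical+structural | unmatched

    def __post_init__(self):
        if (self.concept_id is None) != (self.route == "unmatched"):
            raise ValueError("unmatched iff no concept id")
        if self.route == "unmatched" and self.similarity != 0.0:
            raise ValueError("unmatched terms carry similarity 0")


@dataclass(frozen=True)
class SeverityScore:
    category: str
    value: float
    contributions: tuple[tuple[str, float, float], ...]  # (concept id, sim, severity)


# ---- loading ---------------------------------------------------------------

def taxonomy_from_dict(payload: Mapping) -> SymptomTaxonomy:
    nodes = []
    for spec in payload.get("nodes", []):
        nodes.append(
            ConceptNode(
                id=spec["id"],
                label=spec["label"],
                category=spec["category"],
                severity=float(spec.get("severity", 0.0)),
                synonyms=tuple(spec.get("synonyms", ())),
                parents=tuple(spec.get("parents", ())),
                part_of=tuple(spec.get("part_of", ())),
            )
        )
    return SymptomTaxonomy(nodes)


def load_taxonomy(path) -> SymptomTaxonomy:
    """Load and validate a taxonomy from JSON (``{"nodes": [...]}``)."""
    with open(path, encoding="utf-8") as fh:
        return taxonomy_from_dict(json.load(fh))


def load_taxonomy_obo(path) -> SymptomTaxonomy:
    """Optional OBO-flavored reader.

    Maps ``[Term]`` stanzas (id / name / synonym / is_a) onto concept
    nodes; severity and category ride in ``property_value`` lines, e.g.
    ``property_value: severity "4" xsd:float``.
    """
    import obonet

    graph = obonet.read_obo(path)
    nodes = []
    for node_id, data in graph.nodes(data=True):
        severity, category = 0.0, "symptom"
        for pv in data.get("property_value", []):
            parts = pv.split()
            if not parts:
                continue
            key = parts[0].split(":")[-1].lower()
            value = parts[1].strip('"') if len(parts) > 1 else ""
            if key == "severity":
                severity = float(value)
            elif key == "category":
                category = value
        synonyms = []
        for syn in data.get("synonym", []):
            m = re.match(r'"([^"]*)"', syn)
            if m:
                synonyms.append(m.group(1))
        nodes.append(
            ConceptNode(
                id=node_id,
                label=data.get("name", node_id),
                category=category,
                severity=severity,
                synonyms=tuple(synonyms),
                parents=tuple(data.get("is_a", ())),
            )
        )
    return SymptomTaxonomy(nodes)


# ---- similarity ------------------------------------------------------------

def structural_similarity(c1: str, c2: str, tax: SymptomTaxonomy) -> float:
    """Wu–Palmer similarity: 2·depth(LCS) / (depth(c1) + depth(c2)).

    The least common subsumer (LCS) is the deepest shared is-a ancestor;
    for multi-parent nodes depth is the shortest root path.  Defined only
    within one category — comparing a symptom with a complication raises
    :class:`CrossCategoryComparison`.
    """
    n1, n2 = tax.nodes[c1], tax.nodes[c2]
    if n1.category != n2.category:
        raise CrossCategoryComparison(
            f"cannot compare {c1!r} ({n1.category}) with {c2!r} ({n2.category})"
        )
    common = tax.ancestors(c1) & tax.ancestors(c2)
    lcs_depth = max(tax.depth(a) for a in common)
    return 2.0 * lcs_depth / (tax.depth(c1) + tax.depth(c2))


def _lexical_similarity(a: str, b: str) -> float:
    return difflib.SequenceMatcher(None, a, b).ratio()


def match_term(
    text: str,
    tax: SymptomTaxonomy,
    tau: float = DEFAULT_TAU,
    lexical_threshold: float = DEFAULT_LEXICAL_THRESHOLD,
) -> TermMatch:
    """Resolve free text to a taxonomy concept.

    Route order: exact normalized preferred-label match, exact synonym
    match (both similarity 1.0), then fuzzy lexical matching against every
    label/synonym.  A fuzzy candidate is accepted when its string
    similarity reaches ``lexical_threshold``; its final similarity is the
    string similarity discounted by the Wu–Palmer similarity between the
    matched entry's concept and the concept chosen from its is-a
    neighborhood (identical here, so the discount is 1 on trees).  Anything
    below ``tau`` is reported unmatched — a value, not an error.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    try:
        query = normalize_term(text)
    except EmptyTerm:
        return TermMatch(query=text, concept_id=None, similarity=0.0, route="unmatched")
    hit = tax.match_index.get(query)
    if hit is not None:
        node = tax.nodes[hit]
        route = "exact-label" if normalize_term(node.label) == query else "synonym"
        return TermMatch(query=query, concept_id=hit, similarity=1.0, route=route)
    best_id, best_sim = None, 0.0
    for key, concept_id in tax.match_index.items():
        sim = _lexical_similarity(query, key)
        if sim > best_sim:
            best_id, best_sim = concept_id, sim
    if best_id is None or best_sim < lexical_threshold:
        return TermMatch(query=query, concept_id=None, similarity=0.0, route="unmatched")
    # anchor the candidate in its own neighborhood; on a tree the best
    # structural anchor is the candidate itself (similarity 1)
    similarity = best_sim * structural_similarity(best_id, best_id, tax)
    if similarity < tau:
        return TermMatch(query=query, concept_id=None, similarity=0.0, route="unmatched")
    return TermMatch(
        query=query, concept_id=best_id, similarity=similarity, route="lexical+structural"
    )


# ---- severity aggregation --------------------------------------------------

def severity_score(
    matches: Sequence[TermMatch],
    tax: SymptomTaxonomy,
    category: str,
    aggregator: str = "weighted_mean",
) -> SeverityScore:
    """Aggregate matched concepts' severities into one 0–10 score.

    ``weighted_mean`` (default) is the similarity-weighted mean
    sum(sim_i * sev_i) / sum(sim_i); ``max`` takes max(sim_i * sev_i).
    Unmatched entries and matches from the other category are ignored;
    with no usable match the score is 0.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if aggregator not in ("weighted_mean", "max"):
        raise ValueError(f"unknown aggregator {aggregator!r}")
    contributions = []
    for match in matches:
        if match.concept_id is None:
            continue
        node = tax.nodes[match.concept_id]
        if node.category != category:
            continue
        contributions.append((match.concept_id, match.similarity, node.severity))
    if not contributions:
        return SeverityScore(category=category, value=0.0, contributions=())
    if aggregator == "weighted_mean":
        num = sum(sim * sev for _, sim, sev in contributions)
        den = sum(sim for _, sim, _ in contributions)
        value = num / den
    else:
        value = max(sim * sev for _, sim, sev in contributions)
    value = min(max(value, 0.0), 10.0)
    return SeverityScore(category=category, value=value, contributions=tuple(contributions))


@dataclass(frozen=True)
class SemanticTrace:
    """Everything the explanation needs about the semantic stage."""

    symptom_matches: tuple[TermMatch, ...]
    complication_matches: tuple[TermMatch, ...]
    s_severity: SeverityScore
    c_severity: SeverityScore
    overrides_applied: tuple[str, ...] = ()


def bind_semantic_inputs(
    record,
    tax: SymptomTaxonomy,
    tau: float = DEFAULT_TAU,
    aggregator: str = "weighted_mean",
):
    """Attach numeric ``S_Severity``/``C_Severity`` features to a record.

    Returns ``(new_record, SemanticTrace)``.  Manual per-term severity
    overrides on the record take precedence over taxonomy weights: an
    overridden term contributes its override at similarity 1 within the
    list (symptoms or complications) it was reported in, whether or not
    the taxonomy knows the term.
    """
    overrides = {normalize_term(k): float(v) for k, v in (record.severity_overrides or {}).items()}
    applied: list[str] = []

    def _score(terms: Sequence[str], category: str) -> tuple[tuple[TermMatch, ...], SeverityScore]:
        matches = tuple(match_term(t, tax, tau=tau) for t in terms)
        contributions: list[tuple[str, float, float]] = []
        for term, match in zip(terms, matches):
            try:
                key = normalize_term(term)
            except EmptyTerm:
                continue
            if key in overrides:
                contributions.append((match.concept_id or key, 1.0, overrides[key]))
                applied.append(key)
            elif match.concept_id is not None and tax.nodes[match.concept_id].category == category:
                contributions.append(
                    (match.concept_id, match.similarity, tax.nodes[match.concept_id].severity)
                )
        if not contributions:
            return matches, SeverityScore(category=category, value=0.0, contributions=())
        if aggregator == "weighted_mean":
            value = sum(s * v for _, s, v in contributions) / sum(s for _, s, _ in contributions)
        else:
            value = max(s * v for _, s, v in contributions)
        value = min(max(value, 0.0), 10.0)
        return matches, SeverityScore(category=category, value=value, contributions=tuple(contributions))

    s_matches, s_score = _score(record.symptoms, "symptom")
    c_matches, c_score = _score(record.complications, "complication")
    new_record = record.with_features(
        {"S_Severity": s_score.value, "C_Severity": c_score.value}
    )
    trace = SemanticTrace(
        symptom_matches=s_matches,
        complication_matches=c_matches,
        s_severity=s_score,
        c_severity=c_score,
        overrides_applied=tuple(applied),
    )
    return new_record, trace
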