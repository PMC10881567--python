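"""Taxonomy loading, term matching, structural similarity, severity scoring."""

import json

import pytest
from hypothesis import given, settings, strategies as st

import fuzzydx as fx
from fuzzydx.taxonomy import taxonomy_from_dict


def _mini_nodes(extra=()):
    nodes = [
        {"id": "s", "label": "symptom", "category": "symptom", "severity": 0, "parents": []},
        {"id": "c", "label": "complication", "category": "complication", "severity": 0, "parents": []},
        {"id": "mood", "label": "mood change", "category": "symptom", "severity": 4, "parents": ["s"]},
        {"id": "anx", "label": "anxiety", "category": "symptom", "severity": 4,
         "synonyms": ["anxious"], "parents": ["mood"]},
        {"id": "dep", "label": "depression", "category": "symptom", "severity": 8,
         "synonyms": ["depressed mood"], "parents": ["mood"]},
        {"id": "htn", "label": "hypertension", "category": "complication", "severity": 4,
         "parents": ["c"]},
    ]
    return nodes + list(extra)


class TestLoad:
    def test_fixture_loads_with_two_roots(self, taxonomy):
        assert set(taxonomy.roots) == {"symptom", "complication"}
        assert len(taxonomy) > 30

    def test_cycle_detected(self):
        nodes = _mini_nodes([
            {"id": "a", "label": "a", "category": "symptom", "severity": 1, "parents": ["b"]},
            {"id": "b", "label": "b", "category": "symptom", "severity": 1, "parents": ["a"]},
        ])
        with pytest.raises(fx.CycleDetected):
            taxonomy_from_dict({"nodes": nodes})

    def test_missing_parent_is_orphan(self):
        nodes = _mini_nodes([
            {"id": "x", "label": "x", "category": "symptom", "severity": 1, "parents": ["ghost"]},
        ])
        with pytest.raises(fx.OrphanConcept, match="ghost"):
            taxonomy_from_dict({"nodes": nodes})

    def test_empty_taxonomy_rejected(self):
        with pytest.raises(fx.OrphanConcept):
            taxonomy_from_dict({"nodes": []})

    def test_duplicate_id_rejected(self):
        nodes = _mini_nodes()
        nodes.append(dict(nodes[2]))
        with pytest.raises(fx.DuplicateId):
            taxonomy_from_dict({"nodes": nodes})

    def test_json_file_round_trip(self, tmp_path):
        path = tmp_path / "tax.json"
        path.write_text(json.dumps({"nodes": _mini_nodes()}), "utf-8")
        tax = fx.load_taxonomy(path)
        assert len(tax) == 6

    def test_obo_reader(self, tmp_path):
        obo = """format-version: 1.2

[Term]
id: s
name: symptom
property_value: category "symptom" xsd:string

[Term]
id: anx
name: anxiety
synonym: "anxious" EXACT []
is_a: s ! symptom
property_value: severity "4" xsd:float
property_value: category "symptom" xsd:string
"""
        path = tmp_path / "tax.obo"
        path.write_text(obo, "utf-8")
        tax = fx.load_taxonomy_obo(path)
        assert tax.nodes["anx"].severity == 4.0
        assert "anxious" in tax.nodes["anx"].synonyms
        assert tax.depth("anx") == 2


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("  Depressed  Mood.", "depressed mood"),
            ("Can't sleep", "cant sleep"),
            ("URINARY   FREQUENCY", "urinary frequency"),
        ],
    )
    def test_examples(self, raw, expected):
        assert fx.normalize_term(raw) == expected

    def test_idempotent(self):
        s = fx.normalize_term("  Blurred,  VISION!! ")
        assert fx.normalize_term(s) == s

    def test_empty_raises(self):
        with pytest.raises(fx.EmptyTerm):
            fx.normalize_term("   ...  ")


class TestStructuralSimilarity:
    def test_self_similarity_is_one(self, taxonomy):
        assert fx.structural_similarity("anxiety", "anxiety", taxonomy) == 1.0

    def test_siblings_under_mood_branch(self, taxonomy):
        # both at depth 3, least common subsumer (their parent) at depth 2
        assert fx.structural_similarity("anxiety", "confusion", taxonomy) == pytest.approx(2 / 3)

    def test_root_vs_depth3_leaf(self, taxonomy):
        assert fx.structural_similarity("symptom-root", "anxiety", taxonomy) == pytest.approx(0.5)

    def test_cross_category_raises(self, taxonomy):
        with pytest.raises(fx.CrossCategoryComparison):
            fx.structural_similarity("anxiety", "pneumonia", taxonomy)

    def test_symmetric_bounded_and_decreasing_toward_root(self, taxonomy):
        ids = ["anxiety", "confusion", "insomnia", "memory-loss", "headache", "falls"]
        for a in ids:
            for b in ids:
                s_ab = fx.structural_similarity(a, b, taxonomy)
                assert 0.0 < s_ab <= 1.0
                assert s_ab == fx.structural_similarity(b, a, taxonomy)
                if a != b:
                    assert s_ab < 1.0
        # siblings share a deeper subsumer than cross-branch pairs
        assert fx.structural_similarity("anxiety", "confusion", taxonomy) > fx.structural_similarity(
            "anxiety", "headache", taxonomy
        )


class TestMatchTerm:
    def test_exact_synonym(self, taxonomy):
        m = fx.match_term("anxious", taxonomy)
        assert (m.concept_id, m.similarity, m.route) == ("anxiety", 1.0, "synonym")

    def test_exact_label_with_noise(self, taxonomy):
        m = fx.match_term("  Depressed  Mood.", taxonomy)
        assert m.concept_id == "depression"
        assert m.similarity == 1.0

    def test_lexical_fuzzy_match(self, taxonomy):
        m = fx.match_term("anxiiety", taxonomy)  # typo
        assert m.concept_id == "anxiety"
        assert m.route == "lexical+structural"
        assert 0.85 <= m.similarity < 1.0

    def test_nonsense_unmatched(self, taxonomy):
        m = fx.match_term("zzqx-nonsense", taxonomy)
        assert m.concept_id is None and m.similarity == 0.0 and m.route == "unmatched"

    def test_adding_synonym_never_reduces_similarity(self, taxonomy):
        query = "feeling low"
        before = fx.match_term(query, taxonomy).similarity
        payload = fx.generate_fixture_taxonomy()  # fresh copy
        nodes = [
            {
                "id": n.id, "label": n.label, "category": n.category,
                "severity": n.severity, "synonyms": list(n.synonyms),
                "parents": list(n.parents),
            }
            for n in payload.nodes.values()
        ]
        for spec in nodes:
            if spec["id"] == "depression":
                spec["synonyms"].append("feeling low")
        after = fx.match_term(query, taxonomy_from_dict({"nodes": nodes})).similarity
        assert after >= before
        assert after == 1.0


class TestSeverityScore:
    def test_empty_is_zero(self, taxonomy):
        score = fx.severity_score([], taxonomy, "symptom")
        assert score.value == 0.0 and score.contributions == ()

    def test_single_match_mean(self, taxonomy):
        m = fx.match_term("memory loss", taxonomy)
        score = fx.severity_score([m], taxonomy, "symptom")
        assert score.value == 8.0

    def test_similarity_weighted_mean(self):
        tax = taxonomy_from_dict({"nodes": _mini_nodes()})
        matches = [
            fx.TermMatch("a", "dep", 1.0, "exact-label"),   # severity 8
            fx.TermMatch("b", "anx", 0.5, "lexical+structural"),  # severity 4
        ]
        score = fx.severity_score(matches, tax, "symptom")
        assert score.value == pytest.approx((8 * 1.0 + 4 * 0.5) / 1.5)  # 6.667

    def test_max_aggregator(self):
        tax = taxonomy_from_dict({"nodes": _mini_nodes()})
        matches = [
            fx.TermMatch("a", "dep", 0.6, "lexical+structural"),
            fx.TermMatch("b", "anx", 1.0, "exact-label"),
        ]
        score = fx.severity_score(matches, tax, "symptom", aggregator="max")
        assert score.value == pytest.approx(4.8)

    @given(
        sims=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=5),
        sevs=st.lists(st.floats(0, 10), min_size=5, max_size=5),
    )
    @settings(max_examples=60, derandomize=True)
    def test_weighted_mean_bounded_by_severities(self, sims, sevs):
        tax = taxonomy_from_dict({"nodes": _mini_nodes()})
        used = sevs[: len(sims)]
        matches = [fx.TermMatch(f"q{i}", "anx", s, "lexical+structural") for i, s in enumerate(sims)]
        # substitute severities through contributions arithmetic directly
        num = sum(s * v for s, v in zip(sims, used))
        den = sum(sims)
        assert min(used) - 1e-9 <= num / den <= max(used) + 1e-9


class TestBindSemanticInputs:
    def test_empty_lists_give_zero_severity(self, taxonomy):
        rec = fx.PatientRecord(id="p", features={"MMSE": 29})
        bound, trace = fx.bind_semantic_inputs(rec, taxonomy)
        assert bound.features["S_Severity"] == 0.0
        assert bound.features["C_Severity"] == 0.0
        assert trace.symptom_matches == ()

    def test_uniform_full_matches_recover_concept_severity(self, taxonomy):
        rec = fx.PatientRecord(id="p", symptoms=("memory loss", "disorientation"))
        bound, _ = fx.bind_semantic_inputs(rec, taxonomy)
        assert bound.features["S_Severity"] == 8.0

    def test_complications_route_to_c_severity(self, taxonomy):
        rec = fx.PatientRecord(
            id="p", symptoms=("anxious",), complications=("pneumonia", "bedsore")
        )
        bound, trace = fx.bind_semantic_inputs(rec, taxonomy)
        assert bound.features["C_Severity"] == 8.0
        assert bound.features["S_Severity"] == 4.0
        assert trace.c_severity.contributions[0][0] == "pneumonia"

    def test_manual_override_takes_precedence(self, taxonomy):
        rec = fx.PatientRecord(
            id="p",
            symptoms=("anxious",),
            severity_overrides={"anxious": 9.0},
        )
        bound, trace = fx.bind_semantic_inputs(rec, taxonomy)
        assert bound.features["S_Severity"] == 9.0
        assert trace.overrides_applied == ("anxious",)

    def test_determinism(self, taxonomy):
        rec = fx.PatientRecord(id="p", symptoms=("anxious", "can't sleep", "wibble"))
        a = fx.bind_semantic_inputs(rec, taxonomy)
        b = fx.bind_semantic_inputs(rec, taxonomy)
        assert a[0].features == b[0].features
        assert a[1] == b[1]
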