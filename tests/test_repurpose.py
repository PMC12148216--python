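import itertools

import networkx as nx
import numpy as np
import pytest

from kgsynergy.kg import KnowledgeGraph
from kgsynergy.prediction import PairPrediction
from kgsynergy.repurpose import (
    NO_CONNECTING_PATHWAYS,
    NO_DISEASE_NODE,
    PATHWAYS_FOUND,
    build_report,
    candidate_partners,
    shared_pathways,
    write_report_tsv,
)
from kgsynergy.synergy import SYNERGY_RELATION


def syn_pred(a, b, score):
    return PairPrediction(
        drug_a=a,
        drug_b=b,
        forward_relation=SYNERGY_RELATION,
        forward_score=score,
        reverse_relation=SYNERGY_RELATION,
        reverse_score=score,
    )


@pytest.fixture
def pathway_kg():
    triples = [
        ("drugA", "decreases", "P1"),
        ("drugB", "decreases", "P1"),
        ("P1", "increases", "disease"),
        ("drugC", "decreases", "P2"),  # P2 has no route to disease
        ("isolatedDisease", "increases", "QQ"),
    ]
    types = {
        "drugA": "Drug",
        "drugB": "Drug",
        "drugC": "Drug",
        "P1": "Protein",
        "P2": "Protein",
        "QQ": "Protein",
        "disease": "Pathology",
        "isolatedDisease": "Pathology",
    }
    return KnowledgeGraph.from_triples(triples, entity_type=types)


class TestCandidatePartners:
    def test_ranking_and_safety_flag(self):
        preds = [syn_pred("anchor", "x", 3.0), syn_pred("anchor", "y", 5.0), syn_pred("z", "anchor", 1.0)]
        out = candidate_partners(preds, ["anchor"], exclusion_list={"x"})
        rows = out["anchor"]
        assert [r.partner for r in rows] == ["y", "x", "z"]
        assert [r.rank for r in rows] == [1, 2, 3]
        assert [r.safety_pass for r in rows] == [True, False, True]

    def test_empty_synergy_set(self):
        assert candidate_partners([], ["anchor"]) == {"anchor": []}

    def test_partner_of_two_anchors_ranked_independently(self):
        preds = [syn_pred("a1", "x", 3.0), syn_pred("a2", "x", 1.0), syn_pred("a2", "y", 2.0)]
        out = candidate_partners(preds, ["a1", "a2"])
        assert out["a1"][0].rank == 1
        assert [r.partner for r in out["a2"]] == ["y", "x"]

    def test_needs_anchor(self):
        with pytest.raises(ValueError):
            candidate_partners([], [])


class TestSharedPathways:
    def test_shared_interior_node_found(self, pathway_kg):
        status, pairings = shared_pathways(pathway_kg, "drugA", "drugB", "disease")
        assert status == PATHWAYS_FOUND
        pa, pb, shared = pairings[0]
        assert shared == {"P1"}
        assert pa.nodes[0] == "drugA" and pa.nodes[-1] == "disease"

    def test_no_path_within_max_len(self, pathway_kg):
        status, pairings = shared_pathways(pathway_kg, "drugA", "drugC", "disease")
        assert status == NO_CONNECTING_PATHWAYS
        assert pairings == []

    def test_missing_disease_node_distinguished(self, pathway_kg):
        status, pairings = shared_pathways(pathway_kg, "drugA", "drugB", "covid")
        assert status == NO_DISEASE_NODE
        assert pairings == []

    def test_disease_present_but_unreachable(self, pathway_kg):
        status, _ = shared_pathways(pathway_kg, "drugA", "drugB", "isolatedDisease")
        assert status == NO_CONNECTING_PATHWAYS

    def test_max_len_validation(self, pathway_kg):
        with pytest.raises(ValueError):
            shared_pathways(pathway_kg, "drugA", "drugB", "disease", max_len=1)

    def test_paths_simple_and_within_cap_vs_exhaustive_enumerator(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            n = int(rng.integers(8, 20))
            nodes = [f"n{i}" for i in range(n)]
            triples = []
            for _ in range(2 * n):
                a, b = rng.choice(n, size=2, replace=False)
                triples.append((nodes[a], "increases", nodes[b]))
            types = {x: "Protein" for x in nodes}
            types[nodes[0]] = types[nodes[1]] = "Drug"
            types[nodes[-1]] = "Pathology"
            kg = KnowledgeGraph.from_triples(triples, entity_type=types)
            max_len = 4
            _, pairings = shared_pathways(kg, nodes[0], nodes[1], nodes[-1], max_len=max_len)

            # independent exhaustive enumerator over the undirected projection
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from((t.head, t.tail) for t in kg.triples)

            def brute_paths(src):
                found = []
                for length in range(1, max_len + 1):
                    for mid in itertools.permutations(set(nodes) - {src, nodes[-1]}, length - 1):
                        seq = (src, *mid, nodes[-1])
                        if all(g.has_edge(u, v) for u, v in zip(seq, seq[1:])):
                            found.append(seq)
                return found

            expected = set()
            for pa in brute_paths(nodes[0]):
                for pb in brute_paths(nodes[1]):
                    if set(pa[1:-1]) & set(pb[1:-1]):
                        expected.add((pa, pb))
            got = {(p[0].nodes, p[1].nodes) for p in pairings}
            assert got == expected
            for pa, pb, _ in pairings:
                for path in (pa, pb):
                    assert len(set(path.nodes)) == len(path.nodes)  # simple
                    assert path.length <= max_len


class TestBuildReport:
    def test_verdict_rules(self, pathway_kg):
        preds = [
            syn_pred("drugA", "drugB", 5.0),  # safe, shared pathway
            syn_pred("drugA", "drugC", 4.0),  # safe, no pathway
            syn_pred("drugA", "bad", 3.0),    # excluded drug (absent from kg too)
        ]
        partners = candidate_partners(preds, ["drugA"], exclusion_list={"bad"})
        reports = build_report(pathway_kg, partners, "disease")
        by_candidate = {r.candidate: r for r in reports}
        assert by_candidate["drugB"].verdict == "pathway_supported"
        assert by_candidate["drugC"].verdict == "synergy_only"
        assert by_candidate["bad"].verdict == "excluded"

    def test_deterministic_and_writable(self, pathway_kg, tmp_path):
        preds = [syn_pred("drugA", "drugB", 5.0), syn_pred("drugA", "drugC", 4.0)]
        partners = candidate_partners(preds, ["drugA"])
        r1 = build_report(pathway_kg, partners, "disease")
        r2 = build_report(pathway_kg, partners, "disease")
        assert [(r.candidate, r.verdict, r.synergy_rank) for r in r1] == [
            (r.candidate, r.verdict, r.synergy_rank) for r in r2
        ]
        out = tmp_path / "report.tsv"
        write_report_tsv(r1, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == 1 + len(r1)
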