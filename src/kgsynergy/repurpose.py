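"""Synergy-driven repurposing nominations with shared-pathway evidence.

The hypothesis: if drug B is predicted to synergize with an anchor drug A
(a drug commonly prescribed for the target disease), and both drugs reach
the disease through graph paths sharing at least one intermediate node,
then B is a candidate for repurposing as a single agent.  Safety is an
explicit, user-supplied exclusion list; excluded partners stay in the
report (rank preserved) but are flagged and can never be nominated.

Path tracing runs on the disease-retained causal graph.  Traversal is
direction-agnostic by default — causal edges are directed, but mechanistic
chains read through both orientations — with each step's orientation
recorded; a strict-direction mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .kg import KnowledgeGraph
from .prediction import PairPrediction

__all__ = [
    "PathEvidence",
    "CandidateReport",
    "candidate_partners",
    "shared_pathways",
    "build_report",
    "write_report_tsv",
]

NO_DISEASE_NODE = "no_disease_node"
NO_CONNECTING_PATHWAYS = "no_connecting_pathways"
PATHWAYS_FOUND = "pathways_found"


@dataclass(frozen=True)
class PathEvidence:
    """One simple path drug -> ... -> disease with per-step relations."""

    nodes: tuple[str, ...]
    relations: tuple[str, ...]  # relation label per step, prefixed "<-" when traversed backwards

    @property
    def length(self) -> int:
        return len(self.nodes) - 1

    @property
    def interior(self) -> frozenset[str]:
        return frozenset(self.nodes[1:-1])

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = [self.nodes[0]]
        for rel, node in zip(self.relations, self.nodes[1:]):
            parts.append(f"-[{rel}]-")
            parts.append(node)
        return " ".join(parts)


@dataclass
class RankedPartner:
    anchor: str
    partner: str
    synergy_score: float
    rank: int
    safety_pass: bool


@dataclass
class CandidateReport:
    """One repurposing nomination for (disease, anchor, candidate)."""

    disease: str
    anchor_drug: str
    candidate: str
    synergy_score: float
    synergy_rank: int
    safety_pass: bool
    evidence: list[tuple[PathEvidence, PathEvidence, frozenset[str]]] = field(
        default_factory=list
    )
    pathway_status: str = NO_CONNECTING_PATHWAYS

    @property
    def verdict(self) -> str:
        if not self.safety_pass:
            return "excluded"
        if self.evidence:
            return "pathway_supported"
        return "synergy_only"


def candidate_partners(
    synergy_set: list[PairPrediction],
    anchors: list[str],
    exclusion_list: set[str] | None = None,
) -> dict[str, list[RankedPartner]]:
    """Per anchor: synergistic partners ranked by score descending.

    Partners on the exclusion list keep their rank but are flagged
    ``safety_pass=False``; an anchor with no predicted partners yields an
    empty list.
    """
    if not anchors:
        raise ValueError("need at least one anchor drug")
    exclusion_list = exclusion_list or set()
    out: dict[str, list[RankedPartner]] = {}
    for anchor in anchors:
        partners = []
        for p in synergy_set:
            if anchor == p.drug_a:
                partners.append((p.drug_b, p.min_score))
            elif anchor == p.drug_b:
                partners.append((p.drug_a, p.min_score))
        partners.sort(key=lambda x: (-x[1], x[0]))
        out[anchor] = [
            RankedPartner(
                anchor=anchor,
                partner=name,
                synergy_score=score,
                rank=i + 1,
                safety_pass=name not in exclusion_list,
            )
            for i, (name, score) in enumerate(partners)
        ]
    return out


def _evidence_from_path(graph: nx.DiGraph, nodes: list[str]) -> PathEvidence:
    rels = []
    for u, v in zip(nodes, nodes[1:]):
        if graph.has_edge(u, v):
            rels.append(graph[u][v]["relation"])
        else:
            rels.append("<-" + graph[v][u]["relation"])
    return PathEvidence(nodes=tuple(nodes), relations=tuple(rels))


def shared_pathways(
    graph: KnowledgeGraph,
    drug_a: str,
    drug_b: str,
    disease: str,
    max_len: int = 4,
    directed: bool = False,
) -> tuple[str, list[tuple[PathEvidence, PathEvidence, frozenset[str]]]]:
    """Paired drug->disease paths sharing at least one interior node.

    Enumerates simple paths of at most ``max_len`` edges from each drug to
    the disease (undirected traversal unless ``directed``), then pairs up
    paths from the two drugs that share an intermediate node, sorted by
    combined length.  Returns ``(status, pairings)`` where status
    distinguishes a missing disease node from an unreachable one.
    """
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    if disease not in graph.entity_type:
        return NO_DISEASE_NODE, []
    for drug in (drug_a, drug_b):
        if drug not in graph.entity_type:
            raise KeyError(f"drug {drug!r} absent from the graph")

    dg = nx.DiGraph()
    dg.add_nodes_from(graph.entity_type)
    for t in graph.triples:
        dg.add_edge(t.head, t.tail, relation=t.relation)
    search = dg if directed else dg.to_undirected(as_view=True)

    def paths_from(drug: str) -> list[PathEvidence]:
        try:
            raw = nx.all_simple_paths(search, drug, disease, cutoff=max_len)
            return [_evidence_from_path(dg, p) for p in raw]
        except nx.NodeNotFound:  # pragma: no cover - guarded above
            return []

    paths_a = paths_from(drug_a)
    paths_b = paths_from(drug_b)
    pairings = []
    for pa in paths_a:
        for pb in paths_b:
            shared = pa.interior & pb.interior
            if shared:
                pairings.append((pa, pb, frozenset(shared)))
    pairings.sort(key=lambda x: (x[0].length + x[1].length, x[0].nodes, x[1].nodes))
    status = PATHWAYS_FOUND if pairings else NO_CONNECTING_PATHWAYS
    return status, pairings


def build_report(
    graph: KnowledgeGraph,
    partners: dict[str, list[RankedPartner]],
    disease: str,
    max_len: int = 4,
    directed: bool = False,
) -> list[CandidateReport]:
    """Join synergy ranks with path evidence into candidate reports.

    Verdicts: ``excluded`` (failed safety), ``pathway_supported`` (safe,
    shared pathway found) or ``synergy_only`` (safe, no pathway).
    Deterministic for fixed inputs.
    """
    reports: list[CandidateReport] = []
    for anchor in sorted(partners):
        for rp in partners[anchor]:
            report = CandidateReport(
                disease=disease,
                anchor_drug=anchor,
                candidate=rp.partner,
                synergy_score=rp.synergy_score,
                synergy_rank=rp.rank,
                safety_pass=rp.safety_pass,
            )
            if rp.partner in graph.entity_type and anchor in graph.entity_type:
                status, pairings = shared_pathways(
                    graph, anchor, rp.partner, disease, max_len=max_len, directed=directed
                )
                report.pathway_status = status
                report.evidence = pairings
            else:
                report.pathway_status = NO_CONNECTING_PATHWAYS
            reports.append(report)
    return reports


def write_report_tsv(reports: list[CandidateReport], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "disease\tanchor_drug\tcandidate\tsynergy_rank\tsynergy_score\t"
            "safety_pass\tpathway_status\tn_shared_pathways\tverdict\tbest_shared_nodes\n"
        )
        for r in reports:
            best_shared = ";".join(sorted(r.evidence[0][2])) if r.evidence else ""
            fh.write(
                f"{r.disease}\t{r.anchor_drug}\t{r.candidate}\t{r.synergy_rank}\t"
                f"{r.synergy_score:.6g}\t{int(r.safety_pass)}\t{r.pathway_status}\t"
                f"{len(r.evidence)}\t{r.verdict}\t{best_shared}\n"
            )
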