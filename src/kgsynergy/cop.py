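"""Causal-only graph pruning.

Broad biomedical KGs mix causal edges (``increases``, ``decreases``,
``causes_no_change``) with non-causal ones (``association``,
``in_complex_with`` ...), and contain extreme-degree hub nodes — chiefly
disease (Pathology) nodes — that distort embedding quality.  The
causal-only pharmacome (COP) is derived by a fixed pipeline:

    filter_causal -> drop_isolated -> remove_hubs -> drop_isolated

A companion copy with the hub/disease nodes retained is produced in the
same run; it serves pathway tracing, where disease nodes are the anchors.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .kg import KnowledgeGraph

__all__ = [
    "DEFAULT_CAUSAL_WHITELIST",
    "PruneConfig",
    "filter_causal",
    "drop_isolated",
    "remove_hubs",
    "build_cop",
]

DEFAULT_CAUSAL_WHITELIST = frozenset({"increases", "decreases", "causes_no_change"})


@dataclass
class PruneConfig:
    causal_whitelist: frozenset[str] = DEFAULT_CAUSAL_WHITELIST
    hub_types: frozenset[str] = frozenset({"Pathology"})
    hub_degree_threshold: int | None = None
    keep_disease_copy: bool = True

    def __post_init__(self):
        if not self.causal_whitelist:
            raise ValueError("causal whitelist must be non-empty")
        if self.hub_degree_threshold is not None and self.hub_degree_threshold <= 0:
            raise ValueError("hub degree threshold must be positive")


def filter_causal(kg: KnowledgeGraph, whitelist=DEFAULT_CAUSAL_WHITELIST) -> KnowledgeGraph:
    """Remove triples whose relation is not whitelisted (entity registry
    untouched at this step; isolated entities are swept separately)."""
    whitelist = frozenset(whitelist)
    unknown = whitelist - set(kg.relations)
    if unknown:
        warnings.warn(f"whitelist labels absent from the graph: {sorted(unknown)}", stacklevel=2)
    kept = [t for t in kg.triples if t.relation in whitelist]
    if not kept:
        raise ValueError("causal filter removed every triple; whitelist too aggressive")
    out = KnowledgeGraph.from_triples(kept)
    out.entity_type = dict(kg.entity_type)
    return out


def drop_isolated(kg: KnowledgeGraph) -> KnowledgeGraph:
    """Remove entities incident to no triple (idempotent)."""
    connected = {e for t in kg.triples for e in (t.head, t.tail)}
    out = kg.copy()
    out.entity_type = {e: ty for e, ty in kg.entity_type.items() if e in connected}
    return out


def remove_hubs(
    kg: KnowledgeGraph,
    hub_types: frozenset[str] = frozenset({"Pathology"}),
    degree_threshold: int | None = None,
) -> tuple[KnowledgeGraph, list[tuple[str, str, int]]]:
    """Remove hub nodes (by node type and/or degree) with incident triples,
    then sweep newly isolated nodes.

    Returns the pruned graph and a removal log of (node, reason, degree).
    """
    degree = Counter()
    for t in kg.triples:
        degree[t.head] += 1
        degree[t.tail] += 1
    log: list[tuple[str, str, int]] = []
    hubs: set[str] = set()
    for ent, ty in kg.entity_type.items():
        if ty in hub_types:
            hubs.add(ent)
            log.append((ent, f"type:{ty}", degree[ent]))
        elif degree_threshold is not None and degree[ent] > degree_threshold:
            hubs.add(ent)
            log.append((ent, f"degree>{degree_threshold}", degree[ent]))
    if not hubs:
        return kg.copy(), log
    kept = [t for t in kg.triples if t.head not in hubs and t.tail not in hubs]
    if not kept:
        raise ValueError("hub removal emptied the graph")
    out = KnowledgeGraph.from_triples(kept)
    out.entity_type = {
        e: ty for e, ty in kg.entity_type.items() if e not in hubs
    }
    return drop_isolated(out), log


def build_cop(
    kg: KnowledgeGraph, config: PruneConfig | None = None
) -> tuple[KnowledgeGraph, KnowledgeGraph | None, list[tuple[str, str, int]]]:
    """Run the full pruning pipeline.

    Returns ``(cop, disease_retained_copy, removal_log)``; the companion
    copy differs from COP only by the hub-removal step and is ``None``
    when disabled in the config.
    """
    config = config or PruneConfig()
    causal = drop_isolated(filter_causal(kg, config.causal_whitelist))
    disease_copy = causal.copy() if config.keep_disease_copy else None
    cop, log = remove_hubs(causal, config.hub_types, config.hub_degree_threshold)
    return cop, disease_copy, log
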