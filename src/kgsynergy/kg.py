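"""Knowledge-graph container and edge-list TSV I/O.

The on-disk dialect is a plain tab-separated edge list with three mandatory
columns ``source``, ``relation``, ``target`` (header optional), accompanied
by an optional two-column node-label table (``node`` \\t ``type``) assigning
each entity a single node-type label such as ``Drug``, ``Protein``, ``Gene``
or ``Pathology``.  Entity identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Triple",
    "KnowledgeGraph",
    "KGParseError",
    "read_kg_tsv",
    "write_kg_tsv",
    "read_labels_tsv",
    "write_labels_tsv",
]

UNKNOWN_TYPE = "Unknown"


@dataclass(frozen=True, order=True)
class Triple:
    """One directed, labelled edge ``(head, relation, tail)``."""

    head: str
    relation: str
    tail: str

    def reversed(self) -> "Triple":
        return Triple(self.tail, self.relation, self.head)


class KGParseError(ValueError):
    """Raised for malformed edge-list or label rows (carries the line number)."""


@dataclass
class KnowledgeGraph:
    """A typed multigraph of ``(head, relation, tail)`` triples.

    Duplicate triples are collapsed into :attr:`triple_counts` so repeated
    statements can still act as weights downstream while entity / edge
    reporting stays faithful to the deduplicated structure.
    """

    triples: list[Triple] = field(default_factory=list)
    entity_type: dict[str, str] = field(default_factory=dict)
    relations: list[str] = field(default_factory=list)
    triple_counts: Counter = field(default_factory=Counter)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_triples(
        cls,
        triples: Iterable[Triple | tuple[str, str, str]],
        entity_type: Mapping[str, str] | None = None,
        dedup: bool = True,
    ) -> "KnowledgeGraph":
        kg = cls()
        for t in triples:
            if not isinstance(t, Triple):
                t = Triple(*t)
            kg.add_triple(t, dedup=dedup)
        if entity_type:
            kg.assign_types(entity_type)
        return kg

    def add_triple(self, triple: Triple, dedup: bool = True) -> None:
        seen = triple in self.triple_counts
        self.triple_counts[triple] += 1
        if not seen:
            self.triples.append(triple)
        elif not dedup:
            self.triples.append(triple)
        for ent in (triple.head, triple.tail):
            self.entity_type.setdefault(ent, UNKNOWN_TYPE)
        if triple.relation not in self._relation_set:
            self._relation_set.add(triple.relation)
            self.relations.append(triple.relation)

    def __post_init__(self) -> None:
        self._relation_set = set(self.relations)
        for t in self.triples:
            self._relation_set.add(t.relation)
            if t.relation not in self.relations:
                self.relations.append(t.relation)
            self.triple_counts.setdefault(t, 1)
            for ent in (t.head, t.tail):
                self.entity_type.setdefault(ent, UNKNOWN_TYPE)

    def assign_types(self, mapping: Mapping[str, str]) -> int:
        """Assign node types from a mapping; returns the number of mapped
        entities that were unknown to the graph (reported, types kept)."""
        unknown = 0
        for ent, typ in mapping.items():
            if ent not in self.entity_type:
                unknown += 1
            self.entity_type[ent] = typ
        return unknown

    # -- queries -----------------------------------------------------------

    @property
    def entities(self) -> set[str]:
        return set(self.entity_type)

    @property
    def n_entities(self) -> int:
        return len(self.entity_type)

    @property
    def n_triples(self) -> int:
        return len(self.triples)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    def entities_of_type(self, node_type: str) -> set[str]:
        return {e for e, t in self.entity_type.items() if t == node_type}

    def drugs(self, drug_type: str = "Drug") -> set[str]:
        return self.entities_of_type(drug_type)

    def copy(self) -> "KnowledgeGraph":
        kg = KnowledgeGraph(
            triples=list(self.triples),
            entity_type=dict(self.entity_type),
            relations=list(self.relations),
            triple_counts=Counter(self.triple_counts),
        )
        return kg

    def stats(self) -> dict[str, int]:
        return {
            "n_entities": self.n_entities,
            "n_triples": self.n_triples,
            "n_relations": self.n_relations,
            "n_node_types": len(set(self.entity_type.values())),
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        s = self.stats()
        return (
            f"KnowledgeGraph({s['n_entities']} entities, "
            f"{s['n_triples']} triples, {s['n_relations']} relations)"
        )


# -- TSV I/O ---------------------------------------------------------------


def _looks_like_header(fields: list[str]) -> bool:
    lowered = [f.strip().lower() for f in fields[:3]]
    return lowered[:1] == ["source"] or lowered == ["source", "relation", "target"]


def read_kg_tsv(
    path: str | Path,
    has_header: bool | None = None,
    labels_path: str | Path | None = None,
    dedup: bool = True,
) -> KnowledgeGraph:
    """Read an edge-list TSV into a :class:`KnowledgeGraph`.

    Parameters
    ----------
    path:
        Edge-list file; each data row needs at least three tab-separated
        columns ``source``, ``relation``, ``target`` (extra columns ignored).
    has_header:
        ``True``/``False`` to force, ``None`` to sniff the first row.
    labels_path:
        Optional companion node-type table (``node`` \\t ``type``).
    dedup:
        Collapse repeated identical triples (multiplicity kept in
        ``triple_counts``).
    """
    path = Path(path)
    kg = KnowledgeGraph()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1:
                if has_header is True or (has_header is None and _looks_like_header(fields)):
                    continue
            if len(fields) < 3:
                raise KGParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns, got {len(fields)}"
                )
            head, relation, tail = (f.strip() for f in fields[:3])
            if not head or not relation or not tail:
                raise KGParseError(f"{path}:{lineno}: empty source/relation/target field")
            kg.add_triple(Triple(head, relation, tail), dedup=dedup)
    if labels_path is not None:
        labels = read_labels_tsv(labels_path)
        n_unknown = kg.assign_types(labels)
        if n_unknown:
            warnings.warn(
                f"{n_unknown} labelled nodes absent from the edge list", stacklevel=2
            )
    return kg


def read_labels_tsv(path: str | Path, has_header: bool | None = None) -> dict[str, str]:
    """Read the two-column node-type table; unknown rows keep their label."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if lineno == 1:
                lowered = [f.strip().lower() for f in fields[:2]]
                if has_header is True or (
                    has_header is None and lowered and lowered[0] in ("node", "name", "entity")
                ):
                    continue
            if len(fields) < 2:
                raise KGParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                )
            mapping[fields[0].strip()] = fields[1].strip()
    return mapping


def write_kg_tsv(kg: KnowledgeGraph, path: str | Path, header: bool = True) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if header:
            fh.write("source\trelation\ttarget\n")
        for t in kg.triples:
            fh.write(f"{t.head}\t{t.relation}\t{t.tail}\n")


def write_labels_tsv(kg: KnowledgeGraph, path: str | Path, header: bool = True) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        if header:
            fh.write("node\ttype\n")
        for ent in sorted(kg.entity_type):
            fh.write(f"{ent}\t{kg.entity_type[ent]}\n")
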