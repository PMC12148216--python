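"""Drug-combination harmonization and knowledge-graph enrichment.

Raw combination-screen exports report one row per (drug pair, cell line,
assay), with synergy quantified by the zero-interaction-potency (ZIP)
score; positive ZIP means synergy, negative antagonism, near-zero an
additive (non-interacting) combination.  The pipeline here:

1. ``harmonize``    – canonicalize pair orientation and average replicate
                      ZIP scores per (pair, cell line);
2. ``label_from_zip`` – classify a ZIP score with a symmetric dead band;
3. ``consistency_filter`` – keep only pairs whose per-cell-line classes
                      are unanimous and not additive (removes cell-type
                      dependent combinations);
4. ``enrich_kg``    – write the surviving pairs into the graph as
                      reciprocal ``has_synergism_with`` /
                      ``has_antagonism_with`` edges.
"""

from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .kg import KnowledgeGraph, Triple

__all__ = [
    "SynergyRecord",
    "PairLabel",
    "SYNERGISM",
    "ANTAGONISM",
    "ADDITIVE",
    "SYNERGY_RELATION",
    "ANTAGONISM_RELATION",
    "harmonize",
    "label_from_zip",
    "consistency_filter",
    "enrich_kg",
    "read_combinations_csv",
]

SYNERGISM = "synergism"
ANTAGONISM = "antagonism"
ADDITIVE = "additive"

SYNERGY_RELATION = "has_synergism_with"
ANTAGONISM_RELATION = "has_antagonism_with"

#: default ZIP dead band: |zip| < 10 is treated as additive
DEFAULT_THRESHOLDS = (10.0, -10.0)


@dataclass(frozen=True)
class SynergyRecord:
    """One drug-pair x cell-line synergy measurement."""

    drug_a: str
    drug_b: str
    cell_line: str
    zip: float
    hsa: float | None = None
    bliss: float | None = None
    loewe: float | None = None

    def canonical(self) -> "SynergyRecord":
        if self.drug_a <= self.drug_b:
            return self
        return SynergyRecord(
            self.drug_b, self.drug_a, self.cell_line, self.zip, self.hsa, self.bliss, self.loewe
        )


@dataclass(frozen=True)
class PairLabel:
    """Consolidated per-pair combination class after filtering."""

    drug_a: str
    drug_b: str
    label: str
    mean_zip: float
    n_cell_lines: int

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)


def read_combinations_csv(path: str | Path) -> list[SynergyRecord]:
    """Read a combinations CSV with columns drug_a, drug_b, cell_line, zip
    (optionally hsa, bliss, loewe); extra columns are ignored."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    required = ["drug_a", "drug_b", "cell_line", "zip"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for row in df.itertuples(index=False):
        d = dict(zip(df.columns, row))
        records.append(
            SynergyRecord(
                drug_a=str(d[cols["drug_a"]]),
                drug_b=str(d[cols["drug_b"]]),
                cell_line=str(d[cols["cell_line"]]),
                zip=float(d[cols["zip"]]),
                hsa=float(d[cols["hsa"]]) if "hsa" in cols and pd.notna(d[cols["hsa"]]) else None,
                bliss=float(d[cols["bliss"]])
                if "bliss" in cols and pd.notna(d[cols["bliss"]])
                else None,
                loewe=float(d[cols["loewe"]])
                if "loewe" in cols and pd.notna(d[cols["loewe"]])
                else None,
            )
        )
    return records


def harmonize(records: list[SynergyRecord]) -> list[SynergyRecord]:
    """Deduplicate to one record per (unordered pair, cell line).

    Pair orientation is canonicalized lexicographically and replicate ZIP
    scores for the same key are arithmetically averaged (secondary scores
    averaged over the replicates that report them).  Records with a
    missing/non-finite ZIP are dropped with a warning.  Idempotent.
    """
    groups: dict[tuple[str, str, str], list[SynergyRecord]] = defaultdict(list)
    n_dropped = 0
    for rec in records:
        if rec.zip is None or not math.isfinite(rec.zip):
            n_dropped += 1
            continue
        if rec.drug_a == rec.drug_b:
            n_dropped += 1
            continue
        rec = rec.canonical()
        groups[(rec.drug_a, rec.drug_b, rec.cell_line)].append(rec)
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} records with missing ZIP or self-pairs", stacklevel=2)

    def _mean_opt(values: list[float | None]) -> float | None:
        present = [v for v in values if v is not None]
        return sum(present) / len(present) if present else None

    out = []
    for (a, b, cl) in sorted(groups):
        grp = groups[(a, b, cl)]
        out.append(
            SynergyRecord(
                drug_a=a,
                drug_b=b,
                cell_line=cl,
                zip=sum(r.zip for r in grp) / len(grp),
                hsa=_mean_opt([r.hsa for r in grp]),
                bliss=_mean_opt([r.bliss for r in grp]),
                loewe=_mean_opt([r.loewe for r in grp]),
            )
        )
    return out


def label_from_zip(
    zip_score: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Classify a ZIP score: >= t_syn synergism, <= t_ant antagonism, else
    additive.  Boundaries are inclusive."""
    t_syn, t_ant = thresholds
    if not t_ant < t_syn:
        raise ValueError(f"thresholds must satisfy t_ant < t_syn, got {thresholds}")
    if not math.isfinite(zip_score):
        raise ValueError(f"non-finite ZIP score: {zip_score}")
    if zip_score >= t_syn:
        return SYNERGISM
    if zip_score <= t_ant:
        return ANTAGONISM
    return ADDITIVE


def consistency_filter(
    records: list[SynergyRecord],
    thresholds: tuple[float, float] = DEFAULT_THRESHOLDS,
    return_dropped: bool = False,
):
    """Consolidate harmonized records into per-pair labels.

    Each cell line is labelled independently (on its replicate-averaged
    ZIP); a pair is emitted only when all its cell-line labels agree AND
    the shared label is not additive.  Pairs with mixed labels model a
    cell-type dependent interaction and are removed; all-additive pairs
    carry no interaction signal.

    Returns the list of :class:`PairLabel` (and, when ``return_dropped``,
    a dict with ``mixed`` and ``additive`` drop counts).
    """
    by_pair: dict[tuple[str, str], list[SynergyRecord]] = defaultdict(list)
    for rec in records:
        rec = rec.canonical()
        by_pair[(rec.drug_a, rec.drug_b)].append(rec)

    labels: list[PairLabel] = []
    dropped = {"mixed": 0, "additive": 0}
    for pair in sorted(by_pair):
        recs = by_pair[pair]
        cell_labels = {label_from_zip(r.zip, thresholds) for r in recs}
        if len(cell_labels) > 1:
            dropped["mixed"] += 1
            continue
        (label,) = cell_labels
        if label == ADDITIVE:
            dropped["additive"] += 1
            continue
        labels.append(
            PairLabel(
                drug_a=pair[0],
                drug_b=pair[1],
                label=label,
                mean_zip=sum(r.zip for r in recs) / len(recs),
                n_cell_lines=len(recs),
            )
        )
    if return_dropped:
        return labels, dropped
    return labels


def enrich_kg(
    kg: KnowledgeGraph,
    labels: list[PairLabel],
    include_additive: bool = False,
    synonym_table: dict[str, str] | None = None,
) -> tuple[KnowledgeGraph, int]:
    """Add reciprocal drug-drug combination edges to a copy of the graph.

    Each retained pair whose two drugs resolve to graph entities adds two
    triples (A->B and B->A) labelled ``has_synergism_with`` or
    ``has_antagonism_with``.  Unresolvable pairs are skipped and counted;
    no fuzzy matching is attempted (supply ``synonym_table`` to map
    external drug names onto graph identifiers).

    Returns ``(enriched graph, number of skipped pairs)``.
    """
    enriched = kg.copy()
    relation_for = {SYNERGISM: SYNERGY_RELATION, ANTAGONISM: ANTAGONISM_RELATION}
    if include_additive:
        relation_for[ADDITIVE] = "has_additive_effect_with"
    skipped = 0
    for lab in labels:
        if lab.label not in relation_for:
            skipped += 1
            continue
        a, b = lab.drug_a, lab.drug_b
        if synonym_table:
            a = synonym_table.get(a, a)
            b = synonym_table.get(b, b)
        if a not in kg.entity_type or b not in kg.entity_type:
            skipped += 1
            continue
        rel = relation_for[lab.label]
        enriched.add_triple(Triple(a, rel, b))
        enriched.add_triple(Triple(b, rel, a))
    if skipped:
        warnings.warn(f"skipped {skipped} pairs not resolvable in the graph", stacklevel=2)
    return enriched, skipped
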