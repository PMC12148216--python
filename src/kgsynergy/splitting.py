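"""Stratified triple splitting with relation-coverage guarantees.

Embedding models cannot score a relation label they never saw during
training, so every relation occurring anywhere in the graph must occur at
least once in the training partition.  Splitting is therefore stratified
per relation label: within each stratum the triples are shuffled, test and
validation receive their floored share, and the remainder (plus any
singleton stratum) goes to train.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kg import KnowledgeGraph, Triple

__all__ = ["SplitBundle", "split_triples", "drug_drug_subset", "holdout_sizes"]


@dataclass
class SplitBundle:
    """Disjoint train/validation/test triple partitions of one graph."""

    train: list[Triple]
    validation: list[Triple]
    test: list[Triple]
    seed: int
    drug_drug_test: list[Triple] = field(default_factory=list)

    def sizes(self) -> dict[str, int]:
        return {
            "train": len(self.train),
            "validation": len(self.validation),
            "test": len(self.test),
            "drug_drug_test": len(self.drug_drug_test),
        }


def holdout_sizes(n: int, holdout_fraction: float) -> tuple[int, int]:
    """Sizes ``(kept, held_out)`` of a single hold-out split of ``n`` items.

    The held-out side gets ``ceil(n * holdout_fraction)`` items, the
    convention used throughout scikit-learn's splitters, so a 90/10 split
    of 20 840 pairs yields exactly (18 756, 2 084).
    """
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must be in (0, 1)")
    held = math.ceil(n * holdout_fraction)
    if held in (0, n):
        raise ValueError(f"degenerate split: n={n}, fraction={holdout_fraction}")
    return n - held, held


def _stratified_two_way(
    triples: list[Triple], holdout_fraction: float, rng: np.random.Generator
) -> tuple[list[Triple], list[Triple]]:
    """Split per relation stratum; singletons and remainders stay on the
    kept (training) side so relation coverage holds by construction."""
    by_relation: dict[str, list[Triple]] = {}
    for t in triples:
        by_relation.setdefault(t.relation, []).append(t)
    kept: list[Triple] = []
    held: list[Triple] = []
    for rel in sorted(by_relation):
        stratum = by_relation[rel]
        if len(stratum) == 1:
            kept.extend(stratum)
            continue
        idx = rng.permutation(len(stratum))
        n_held = int(math.floor(len(stratum) * holdout_fraction))
        n_held = min(n_held, len(stratum) - 1)  # never empty the train side
        held.extend(stratum[i] for i in idx[:n_held])
        kept.extend(stratum[i] for i in idx[n_held:])
    return kept, held


def split_triples(
    kg: KnowledgeGraph,
    test_fraction: float = 0.2,
    validation_fraction: float = 0.2,
    seed: int = 0,
) -> SplitBundle:
    """Two-level stratified split: first train/test, then the train side is
    split again into train/validation (both fractions apply to their own
    level, e.g. 0.2 and 0.2 yield 64/16/20 overall).
    """
    if kg.n_triples == 0:
        raise ValueError("cannot split an empty graph")
    for frac in (test_fraction, validation_fraction):
        if not 0.0 < frac < 1.0:
            raise ValueError("fractions must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_pool, test = _stratified_two_way(kg.triples, test_fraction, rng)
    train, validation = _stratified_two_way(train_pool, validation_fraction, rng)

    vocab = set(kg.relations)
    train_vocab = {t.relation for t in train}
    if train_vocab != vocab:  # pragma: no cover - guarded by construction
        missing = vocab - train_vocab
        raise RuntimeError(f"relations missing from train split: {sorted(missing)}")

    bundle = SplitBundle(train=train, validation=validation, test=test, seed=seed)
    bundle.drug_drug_test = drug_drug_subset(bundle, kg)
    return bundle


def drug_drug_subset(
    split: SplitBundle, kg: KnowledgeGraph, drug_type: str = "Drug"
) -> list[Triple]:
    """Test triples whose head and tail are both drug-typed entities."""
    drugs = kg.drugs(drug_type)
    return [t for t in split.test if t.head in drugs and t.tail in drugs]
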