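"""Synthetic fixtures: planted-embedding KGs, synergy tables, drug tables.

Everything downstream is testable without any external download:

* ``generate_planted_kg`` builds a knowledge graph from *ground-truth*
  embeddings with cluster structure — entities sit near one of a few
  cluster centres and each relation connects one ordered centre pair — and
  emits the ``triple_budget`` highest-scoring (h, r, t) candidates under
  the chosen generator model.  Because the relation between two entities
  is determined by their cluster memberships, a competent embedding model
  can recover it, which is what the planted-recovery tests measure.
* ``generate_synergy_table`` draws drug pairs with a latent combination
  class and per-cell-line ZIP scores at class means +15 / -15 / 0 plus
  Gaussian noise; a configurable fraction of pairs get a deliberately
  sign-flipped cell line to exercise the cross-cell-line consistency
  filter.  With the default dead band of +/-10 and noise_sd 2 the class
  means sit 2.5 standard deviations from the thresholds, so per-cell-line
  label flips are rare (~0.6%) and filter behaviour is predictable.
* ``generate_drug_properties`` emits plausible-range physicochemical
  descriptors and random 1024-bit fingerprints, with optional planted
  high-Tanimoto pairs.

Ground truth is always returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .embedding.models import get_model
from .kg import KnowledgeGraph, Triple
from .synergy import ADDITIVE, ANTAGONISM, SYNERGISM, SynergyRecord

__all__ = [
    "SyntheticSpec",
    "CLASS_MEANS",
    "generate_planted_kg",
    "generate_synergy_table",
    "generate_drug_properties",
    "generate_labeled_pair_features",
]

#: latent ZIP class means for synergism / antagonism / additive pairs
CLASS_MEANS = {SYNERGISM: 15.0, ANTAGONISM: -15.0, ADDITIVE: 0.0}

NODE_TYPES = ("Protein", "Gene", "BiologicalProcess", "Pathology")

#: relation vocabulary emulating a pharmacome schema: causal labels first,
#: then common non-causal ones; overflow falls back to generic names
RELATION_POOL = (
    "increases",
    "decreases",
    "causes_no_change",
    "association",
    "in_complex_with",
    "targets",
    "has_variant",
    "equivalent_to",
    "regulates",
    "binds_to",
)


@dataclass
class SyntheticSpec:
    """Study conditions for all synthetic generators."""

    n_entities: int = 500
    n_relations: int = 8
    n_drugs: int = 60
    embedding_dim: int = 16
    generator_model: str = "TransE"
    triple_budget: int = 5000
    n_pairs: int = 500
    inconsistency_rate: float = 0.1
    additive_rate: float = 0.1
    n_cell_lines: int = 3
    noise_sd: float = 2.0
    cluster_noise: float = 0.08
    seed: int = 0

    def __post_init__(self):
        for rate in (self.inconsistency_rate, self.additive_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if min(self.n_entities, self.n_relations, self.triple_budget, self.embedding_dim) < 1:
            raise ValueError("entity/relation/budget/dim counts must be positive")
        if self.generator_model not in ("TransE", "RotatE", "HolE"):
            raise ValueError(f"unsupported generator model {self.generator_model!r}")


@dataclass
class PlantedTruth:
    """Ground truth accompanying a planted KG."""

    params: dict[str, np.ndarray]
    entity_cluster: np.ndarray
    relation_cluster_pairs: list[tuple[int, int]]
    entity_index: dict[str, int]
    relation_index: dict[str, int]
    scores: np.ndarray = field(repr=False, default=None)


def _n_clusters(n_relations: int) -> int:
    c = 2
    while c * (c - 1) < n_relations:
        c += 1
    return max(c, 3)


def _planted_params(spec: SyntheticSpec, rng: np.random.Generator):
    """Ground-truth parameter arrays with cluster structure, per model."""
    d, n_ent, n_rel = spec.embedding_dim, spec.n_entities, spec.n_relations
    n_c = _n_clusters(n_rel)
    cluster_of = rng.integers(0, n_c, size=n_ent)
    # ordered centre pairs, one per relation, all distinct
    all_pairs = [(i, j) for i in range(n_c) for j in range(n_c) if i != j]
    pair_idx = rng.choice(len(all_pairs), size=n_rel, replace=False)
    rel_pairs = [all_pairs[i] for i in pair_idx]

    if spec.generator_model == "TransE":
        centres = rng.normal(0.0, 1.0, size=(n_c, d))
        ent = centres[cluster_of] + rng.normal(0.0, spec.cluster_noise, size=(n_ent, d))
        rel = np.array([centres[j] - centres[i] for i, j in rel_pairs])
        params = {"ent": ent, "rel": rel}
    elif spec.generator_model == "RotatE":
        centre_phase = rng.uniform(0.0, 2.0 * np.pi, size=(n_c, d))
        ent_phase = centre_phase[cluster_of] + rng.normal(
            0.0, spec.cluster_noise, size=(n_ent, d)
        )
        params = {
            "ent_re": np.cos(ent_phase),
            "ent_im": np.sin(ent_phase),
            "phase": np.array(
                [np.mod(centre_phase[j] - centre_phase[i], 2 * np.pi) for i, j in rel_pairs]
            ),
        }
    else:  # HolE: relation vector = correlation of its two cluster centres
        centres = rng.normal(0.0, 1.0 / np.sqrt(d), size=(n_c, d))
        ent = centres[cluster_of] + rng.normal(0.0, spec.cluster_noise, size=(n_ent, d))
        corr = lambda a, b: np.fft.ifft(np.conj(np.fft.fft(a)) * np.fft.fft(b)).real
        rel = np.array([corr(centres[i], centres[j]) for i, j in rel_pairs])
        rel /= np.linalg.norm(rel, axis=1, keepdims=True)
        params = {"ent": ent, "rel": rel}
    return params, cluster_of, rel_pairs


def generate_planted_kg(spec: SyntheticSpec) -> tuple[KnowledgeGraph, PlantedTruth]:
    """Sample ground-truth embeddings and emit the ``triple_budget``
    highest-scoring candidate triples as the planted graph.

    Every emitted triple scores at least as high, under the ground-truth
    model, as every non-emitted candidate (self-loops excluded).  A
    ``n_drugs``-sized subset of entities is typed ``Drug``; the remainder
    cycles through protein/gene/process/pathology types.
    """
    rng = np.random.default_rng(spec.seed)
    model = get_model(spec.generator_model)
    params, cluster_of, rel_pairs = _planted_params(spec, rng)
    n_ent, n_rel = spec.n_entities, spec.n_relations

    n_candidates = n_ent * n_ent * n_rel
    if spec.triple_budget > n_ent * (n_ent - 1) * n_rel:
        raise ValueError("triple_budget exceeds the candidate space")

    # exhaustive scoring, chunked by relation
    scores = np.empty((n_rel, n_ent, n_ent), dtype=np.float32)
    h_grid, t_grid = np.meshgrid(np.arange(n_ent), np.arange(n_ent), indexing="ij")
    h_flat, t_flat = h_grid.ravel(), t_grid.ravel()
    for r in range(n_rel):
        r_flat = np.full(n_ent * n_ent, r)
        scores[r] = model.score(params, h_flat, r_flat, t_flat).reshape(n_ent, n_ent)
        np.fill_diagonal(scores[r], -np.inf)  # no self-loops

    flat = scores.ravel()
    top = np.argpartition(flat, -spec.triple_budget)[-spec.triple_budget :]
    top = top[np.argsort(flat[top])[::-1]]
    r_idx, h_idx, t_idx = np.unravel_index(top, scores.shape)

    entities = [f"E{i:05d}" for i in range(n_ent)]
    relations = [
        RELATION_POOL[i] if i < len(RELATION_POOL) else f"rel_{i}" for i in range(n_rel)
    ]
    drug_ids = rng.choice(n_ent, size=min(spec.n_drugs, n_ent), replace=False)
    entity_type = {}
    for i, name in enumerate(entities):
        entity_type[name] = NODE_TYPES[i % len(NODE_TYPES)]
    for i in drug_ids:
        entity_type[entities[i]] = "Drug"

    triples = [
        Triple(entities[h], relations[r], entities[t])
        for r, h, t in zip(r_idx, h_idx, t_idx)
    ]
    kg = KnowledgeGraph.from_triples(triples)
    # keep all entities registered even if they appear in no top triple
    for name in entities:
        kg.entity_type.setdefault(name, entity_type[name])
    kg.assign_types(entity_type)

    truth = PlantedTruth(
        params=params,
        entity_cluster=cluster_of,
        relation_cluster_pairs=rel_pairs,
        entity_index={e: i for i, e in enumerate(entities)},
        relation_index={r: i for i, r in enumerate(relations)},
        scores=scores,
    )
    return kg, truth


def generate_synergy_table(
    spec: SyntheticSpec, drugs: list[str]
) -> tuple[list[SynergyRecord], dict[tuple[str, str], str], set[tuple[str, str]]]:
    """Synergy records with planted classes and controlled inconsistency.

    Returns ``(records, true_label_per_pair, inconsistent_pairs)``.  Each
    sampled pair draws a latent class (additive with ``additive_rate``,
    the rest split evenly between synergism and antagonism), then one ZIP
    score per cell line at the class mean plus Gaussian noise.  An
    ``inconsistency_rate`` fraction of non-additive pairs get one cell
    line's class mean sign-flipped, so their labels can never be unanimous.
    """
    if len(drugs) < 2:
        raise ValueError("need at least two drugs")
    rng = np.random.default_rng(spec.seed + 1)
    drugs = sorted(drugs)
    all_pairs = [(a, b) for i, a in enumerate(drugs) for b in drugs[i + 1 :]]
    n_pairs = min(spec.n_pairs, len(all_pairs))
    chosen = [all_pairs[i] for i in rng.choice(len(all_pairs), size=n_pairs, replace=False)]

    records: list[SynergyRecord] = []
    truth: dict[tuple[str, str], str] = {}
    inconsistent: set[tuple[str, str]] = set()
    for a, b in chosen:
        u = rng.random()
        if u < spec.additive_rate:
            label = ADDITIVE
        elif u < spec.additive_rate + (1 - spec.additive_rate) / 2:
            label = SYNERGISM
        else:
            label = ANTAGONISM
        truth[(a, b)] = label
        flip_one = (
            label != ADDITIVE
            and spec.n_cell_lines > 1
            and rng.random() < spec.inconsistency_rate
        )
        flip_idx = rng.integers(0, spec.n_cell_lines) if flip_one else -1
        if flip_one:
            inconsistent.add((a, b))
        for cl in range(spec.n_cell_lines):
            mean = CLASS_MEANS[label]
            if cl == flip_idx:
                mean = -mean
            records.append(
                SynergyRecord(
                    drug_a=a,
                    drug_b=b,
                    cell_line=f"CL{cl:03d}",
                    zip=float(mean + rng.normal(0.0, spec.noise_sd)),
                )
            )
    return records, truth, inconsistent


def generate_drug_properties(
    drugs: list[str],
    seed: int = 0,
    n_bits: int = 1024,
    similar_pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Physicochemical descriptor table and random bit fingerprints.

    Descriptors are drawn uniformly from drug-like ranges (MW 100-900,
    logP -2..7, TPSA 0-200, HBD 0-10, HBA 0-12, rotatable bonds 0-15).
    Fingerprints set ~64 of ``n_bits`` bits at random; pairs listed in
    ``similar_pairs`` share most on-bits so their Tanimoto exceeds 0.6 by
    construction.
    """
    rng = np.random.default_rng(seed)
    drugs = list(drugs)
    table = pd.DataFrame(
        {
            "mol_weight": rng.uniform(100, 900, len(drugs)),
            "logp": rng.uniform(-2, 7, len(drugs)),
            "tpsa": rng.uniform(0, 200, len(drugs)),
            "hbd": rng.integers(0, 11, len(drugs)).astype(float),
            "hba": rng.integers(0, 13, len(drugs)).astype(float),
            "rotatable_bonds": rng.integers(0, 16, len(drugs)).astype(float),
        },
        index=pd.Index(drugs, name="drug"),
    )
    n_on = min(64, n_bits)
    fingerprints: dict[str, np.ndarray] = {}
    for drug in drugs:
        fp = np.zeros(n_bits, dtype=bool)
        fp[rng.choice(n_bits, size=n_on, replace=False)] = True
        fingerprints[drug] = fp
    for a, b in similar_pairs or ():
        shared = np.flatnonzero(fingerprints[a])
        fp = np.zeros(n_bits, dtype=bool)
        keep = shared[: int(0.9 * len(shared))]
        fp[keep] = True
        extra = rng.choice(n_bits, size=max(1, n_on - len(keep)), replace=False)
        fp[extra] = True
        fingerprints[b] = fp
    return table, fingerprints


def generate_labeled_pair_features(
    n_pairs: int = 400,
    n_features: int = 20,
    separation: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian class-conditional pair features for classifier sanity
    checks: two balanced classes whose means differ by ``separation`` in
    every feature (labels ``synergism`` / ``antagonism``)."""
    rng = np.random.default_rng(seed)
    y = np.array([SYNERGISM, ANTAGONISM] * (n_pairs // 2) + [SYNERGISM] * (n_pairs % 2))
    shift = np.where(y == SYNERGISM, separation / 2.0, -separation / 2.0)
    X = rng.normal(0.0, 1.0, size=(n_pairs, n_features)) + shift[:, None]
    return X, y
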