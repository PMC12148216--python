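"""Order-invariant drug-pair feature vectors.

A drug pair is described by three blocks:

* topology  – per-drug node degree, local clustering coefficient and
  PageRank on the undirected simple projection of the KG, plus pairwise
  shortest-path length and the cosine similarity of the two drugs'
  adjacency indicator vectors;
* physicochemical – molecular weight, logP, TPSA, H-bond donors/acceptors
  and rotatable-bond count per drug (mean-imputed when missing, with an
  imputation mask recorded);
* fingerprints – Morgan-style bit vectors entering as the elementwise OR
  and AND of the two drugs plus their Tanimoto coefficient, which keeps
  the block symmetric in the pair with bounded dimensionality.

Per-drug blocks are ordered by the lexicographically smaller drug first,
so the vector for (A, B) and (B, A) is identical by construction.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .kg import KnowledgeGraph

__all__ = [
    "PHYSCHEM_COLUMNS",
    "KGTopology",
    "topology_features",
    "tanimoto",
    "build_pair_features",
]

PHYSCHEM_COLUMNS = ["mol_weight", "logp", "tpsa", "hbd", "hba", "rotatable_bonds"]


class KGTopology:
    """Undirected simple-graph projection of a KG with cached centralities.

    PageRank (damping 0.85) and clustering coefficients are computed once
    at construction; per-pair quantities (shortest path, adjacency cosine)
    are computed on demand.
    """

    def __init__(self, kg: KnowledgeGraph, pagerank_damping: float = 0.85):
        g = nx.Graph()
        g.add_nodes_from(kg.entity_type)
        g.add_edges_from(
            (t.head, t.tail) for t in kg.triples if t.head != t.tail
        )
        self.graph = g
        self.pagerank = nx.pagerank(g, alpha=pagerank_damping)
        self.clustering = nx.clustering(g)

    def node_features(self, node: str) -> dict[str, float]:
        if node not in self.graph:
            raise KeyError(f"drug {node!r} absent from the knowledge graph")
        return {
            "degree": float(self.graph.degree[node]),
            "clustering": float(self.clustering[node]),
            "pagerank": float(self.pagerank[node]),
        }

    def shortest_path_length(self, a: str, b: str) -> float:
        """Unweighted shortest-path length; inf when disconnected (callers
        replace inf by a finite sentinel consistently across their pair set)."""
        try:
            return float(nx.shortest_path_length(self.graph, a, b))
        except nx.NetworkXNoPath:
            return float("inf")

    def adjacency_cosine(self, a: str, b: str) -> float:
        """Cosine similarity of the two nodes' adjacency indicator vectors:
        |N(a) & N(b)| / sqrt(|N(a)| |N(b)|)."""
        na, nb = set(self.graph[a]), set(self.graph[b])
        if not na or not nb:
            return 0.0
        return len(na & nb) / np.sqrt(len(na) * len(nb))


def topology_features(
    topology: KGTopology | KnowledgeGraph, drug_a: str, drug_b: str
) -> dict[str, float]:
    """Topology block for one pair (build a :class:`KGTopology` once when
    featurizing many pairs)."""
    if isinstance(topology, KnowledgeGraph):
        topology = KGTopology(topology)
    fa = topology.node_features(drug_a)
    fb = topology.node_features(drug_b)
    return {
        **{f"a_{k}": v for k, v in fa.items()},
        **{f"b_{k}": v for k, v in fb.items()},
        "shortest_path": topology.shortest_path_length(drug_a, drug_b),
        "adjacency_cosine": topology.adjacency_cosine(drug_a, drug_b),
    }


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto (Jaccard) coefficient |A & B| / |A | B| of two bit sets
    (sets of on-bit indices or boolean arrays)."""
    a = set(np.flatnonzero(fp_a)) if isinstance(fp_a, np.ndarray) else set(fp_a)
    b = set(np.flatnonzero(fp_b)) if isinstance(fp_b, np.ndarray) else set(fp_b)
    union = a | b
    if not union:
        warnings.warn("both fingerprints empty; Tanimoto defined as 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


def _canonical(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def build_pair_features(
    pairs: list[tuple[str, str]],
    mode: str = "handcrafted",
    topology: KGTopology | None = None,
    physchem: pd.DataFrame | None = None,
    fingerprints: dict[str, np.ndarray] | None = None,
    embeddings=None,
) -> pd.DataFrame:
    """Feature matrix for a list of drug pairs (one row per pair).

    Parameters
    ----------
    mode:
        ``"handcrafted"`` (topology + physicochemical + fingerprint
        blocks), ``"embedding"`` (the two entity embedding vectors in
        canonical order) or ``"both"``.
    physchem:
        DataFrame indexed by drug id with :data:`PHYSCHEM_COLUMNS`
        (missing values mean-imputed; ``*_imputed`` mask columns added).
    embeddings:
        A trained :class:`~kgsynergy.embedding.ModelState` (required for
        the embedding modes).
    """
    if mode not in ("handcrafted", "embedding", "both"):
        raise ValueError(f"unknown feature mode {mode!r}")
    canonical = [_canonical(a, b) for a, b in pairs]
    blocks: list[pd.DataFrame] = []

    if mode in ("handcrafted", "both"):
        if topology is None or physchem is None or fingerprints is None:
            raise ValueError("handcrafted mode needs topology, physchem and fingerprints")
        missing = {d for p in canonical for d in p if d not in physchem.index}
        if missing:
            raise KeyError(f"drugs missing from the property table: {sorted(missing)}")

        topo_rows = [topology_features(topology, a, b) for a, b in canonical]
        topo = pd.DataFrame(topo_rows)
        finite = topo["shortest_path"].replace(np.inf, np.nan)
        sentinel = (finite.max() + 1.0) if finite.notna().any() else float(
            topology.graph.number_of_nodes()
        )
        topo["shortest_path"] = topo["shortest_path"].replace(np.inf, sentinel)
        blocks.append(topo)

        phys = physchem[PHYSCHEM_COLUMNS].astype(float)
        mask = phys.isna()
        phys = phys.fillna(phys.mean())
        if phys.isna().any().any():
            raise ValueError("a physicochemical column is entirely missing")
        rows = []
        for a, b in canonical:
            row = {}
            for tag, drug in (("a", a), ("b", b)):
                for col in PHYSCHEM_COLUMNS:
                    row[f"{tag}_{col}"] = phys.loc[drug, col]
                    row[f"{tag}_{col}_imputed"] = float(mask.loc[drug, col])
            rows.append(row)
        blocks.append(pd.DataFrame(rows))

        fp_rows = []
        for a, b in canonical:
            fa = np.asarray(fingerprints[a], dtype=bool)
            fb = np.asarray(fingerprints[b], dtype=bool)
            row = {"tanimoto": tanimoto(fa, fb)}
            row.update({f"fp_or_{i}": v for i, v in enumerate((fa | fb).astype(float))})
            row.update({f"fp_and_{i}": v for i, v in enumerate((fa & fb).astype(float))})
            fp_rows.append(row)
        blocks.append(pd.DataFrame(fp_rows))

    if mode in ("embedding", "both"):
        if embeddings is None:
            raise ValueError("embedding mode needs a trained ModelState")
        rows = []
        for a, b in canonical:
            vec = np.concatenate([embeddings.entity_embedding(a), embeddings.entity_embedding(b)])
            rows.append(vec)
        emb = pd.DataFrame(np.asarray(rows))
        emb.columns = [f"emb_{i}" for i in range(emb.shape[1])]
        blocks.append(emb)

    out = pd.concat(blocks, axis=1)
    out.index = pd.MultiIndex.from_tuples(canonical, names=["drug_a", "drug_b"])
    return out
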