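"""SLCWA training loop: negative sampling, losses, Adam, relation ranking.

Training follows the stochastic local closed-world assumption: observed
triples are positives, and negatives are produced on the fly by corrupting
the head or the tail (coin flip) of each positive with a uniformly sampled
entity.  A corruption that happens to reproduce an observed triple is kept
by default (the SLCWA convention); set ``filter_observed_negatives`` to
resample such collisions.

Losses: margin ranking max(0, margin - s_pos + s_neg) for the
distance-based models (TransE, TransR, RotatE) and pointwise softplus
log(1 + exp(-y s)) for the bilinear models (ComplEx, HolE).  Optimization
is plain Adam with dense moment buffers; parameter constraints are
re-applied after every step.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ..kg import KnowledgeGraph, Triple
from .models import MODEL_REGISTRY, get_model

__all__ = [
    "TrainConfig",
    "ModelState",
    "RelationRanking",
    "sample_negatives",
    "train_embeddings",
]


@dataclass
class TrainConfig:
    model: str = "HolE"
    dim: int = 64
    epochs: int = 100
    batch_size: int = 256
    negatives_per_positive: int = 4
    learning_rate: float = 1e-2
    loss: str | None = None  # None = the model's conventional default
    margin: float = 1.0
    l2: float = 1e-4
    seed: int = 0
    filter_observed_negatives: bool = False

    def __post_init__(self):
        if self.model not in MODEL_REGISTRY:
            raise ValueError(f"unknown model {self.model!r}")
        if min(self.epochs, self.batch_size, self.negatives_per_positive, self.dim) < 1:
            raise ValueError("epochs, batch_size, negatives_per_positive, dim must be >= 1")
        if self.learning_rate <= 0 or self.margin <= 0:
            raise ValueError("learning_rate and margin must be positive")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")
        if self.loss is not None and self.loss not in ("margin_ranking", "softplus"):
            raise ValueError(f"unknown loss {self.loss!r}")

    def resolved_loss(self) -> str:
        return self.loss or get_model(self.model).default_loss


@dataclass
class RelationRanking:
    """Full relation ranking for one (head, tail) pair, best first.

    Ties are broken by relation-vocabulary order, deterministically.
    """

    head: str
    tail: str
    ranked: list[tuple[str, float]]

    @property
    def rank_of(self) -> dict[str, int]:
        return {rel: i + 1 for i, (rel, _) in enumerate(self.ranked)}

    def relation_at(self, rank: int) -> str:
        return self.ranked[rank - 1][0]

    @property
    def top(self) -> tuple[str, float]:
        return self.ranked[0]


@dataclass
class ModelState:
    """Trained embedding model: indices, parameter arrays, provenance."""

    model_name: str
    dim: int
    entity_index: dict[str, int]
    relation_index: dict[str, int]
    params: dict[str, np.ndarray]
    config: TrainConfig | None = None
    loss_trajectory: list[float] = field(default_factory=list)

    def __post_init__(self):
        self._model = get_model(self.model_name)
        self._relations = sorted(self.relation_index, key=self.relation_index.get)

    @property
    def relations(self) -> list[str]:
        return list(self._relations)

    def _check_finite(self) -> None:
        for name, arr in self.params.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite parameters in {name!r}; model unusable")

    def _idx(self, mapping: dict[str, int], key: str, kind: str) -> int:
        try:
            return mapping[key]
        except KeyError:
            raise KeyError(f"unknown {kind}: {key!r}") from None

    def score_triple(self, head: str, relation: str, tail: str) -> float:
        h = np.array([self._idx(self.entity_index, head, "entity")])
        r = np.array([self._idx(self.relation_index, relation, "relation")])
        t = np.array([self._idx(self.entity_index, tail, "entity")])
        return float(self._model.score(self.params, h, r, t)[0])

    def score_batch(self, h_idx: np.ndarray, r_idx: np.ndarray, t_idx: np.ndarray) -> np.ndarray:
        return self._model.score(self.params, h_idx, r_idx, t_idx)

    def rank_relations(self, head: str, tail: str) -> RelationRanking:
        """Score every relation for a fixed (head, tail) and sort
        descending; equal scores fall back to vocabulary order."""
        self._check_finite()
        n_rel = len(self.relation_index)
        h = np.full(n_rel, self._idx(self.entity_index, head, "entity"))
        t = np.full(n_rel, self._idx(self.entity_index, tail, "entity"))
        r = np.arange(n_rel)
        scores = self._model.score(self.params, h, r, t)
        order = sorted(range(n_rel), key=lambda i: (-scores[i], i))
        ranked = [(self._relations[i], float(scores[i])) for i in order]
        return RelationRanking(head=head, tail=tail, ranked=ranked)

    def entity_embedding(self, entity: str) -> np.ndarray:
        """Real-valued embedding vector of one entity."""
        vecs = self._model.entity_vectors(self.params)
        return vecs[self._idx(self.entity_index, entity, "entity")].copy()

    # -- checkpointing -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = {
            "format": "kgsynergy-checkpoint-v1",
            "model_name": self.model_name,
            "dim": self.dim,
            "entities": sorted(self.entity_index, key=self.entity_index.get),
            "relations": self._relations,
            "config": asdict(self.config) if self.config else None,
            "loss_trajectory": self.loss_trajectory,
        }
        arrays = {f"param_{k}": v for k, v in self.params.items()}
        np.savez(path, header=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ModelState":
        with np.load(Path(path), allow_pickle=False) as data:
            header = json.loads(str(data["header"]))
            if header.get("format") != "kgsynergy-checkpoint-v1":
                raise ValueError(f"unrecognized checkpoint format in {path}")
            params = {
                k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")
            }
        cfg = TrainConfig(**header["config"]) if header.get("config") else None
        return cls(
            model_name=header["model_name"],
            dim=header["dim"],
            entity_index={e: i for i, e in enumerate(header["entities"])},
            relation_index={r: i for i, r in enumerate(header["relations"])},
            params=params,
            config=cfg,
            loss_trajectory=list(header.get("loss_trajectory") or []),
        )


def sample_negatives(
    positives: np.ndarray,
    n_entities: int,
    k: int,
    rng: np.random.Generator,
    observed: set[tuple[int, int, int]] | None = None,
) -> np.ndarray:
    """Corrupt each positive ``k`` times by replacing head or tail.

    ``positives`` is an integer array of shape (B, 3).  When ``observed``
    is given, corruptions colliding with observed triples are resampled
    (bounded retries); otherwise collisions are permitted, as under the
    stochastic local closed-world assumption.
    """
    if k < 1:
        raise ValueError("need at least one negative per positive")
    if n_entities < 2:
        raise ValueError("need at least two entities to corrupt triples")
    neg = np.repeat(positives, k, axis=0)
    corrupt_head = rng.random(len(neg)) < 0.5
    replacements = rng.integers(0, n_entities, size=len(neg))
    neg[corrupt_head, 0] = replacements[corrupt_head]
    neg[~corrupt_head, 2] = replacements[~corrupt_head]
    # ensure the corrupted slot actually changed
    same = (neg == np.repeat(positives, k, axis=0)).all(axis=1)
    while same.any():
        idx = np.flatnonzero(same)
        repl = rng.integers(0, n_entities, size=len(idx))
        slot = np.where(corrupt_head[idx], 0, 2)
        neg[idx, slot] = repl
        same = (neg == np.repeat(positives, k, axis=0)).all(axis=1)
    if observed is not None:
        for _ in range(20):
            collide = np.fromiter(
                (tuple(row) in observed for row in neg), dtype=bool, count=len(neg)
            )
            if not collide.any():
                break
            idx = np.flatnonzero(collide)
            repl = rng.integers(0, n_entities, size=len(idx))
            slot = np.where(corrupt_head[idx], 0, 2)
            neg[idx, slot] = repl
    return neg


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / bc1) / (np.sqrt(self.v[k] / bc2) + self.eps)


def train_embeddings(
    kg_or_triples: KnowledgeGraph | list[Triple],
    config: TrainConfig,
    entity_index: dict[str, int] | None = None,
    relation_index: dict[str, int] | None = None,
) -> ModelState:
    """Train an embedding model under the SLCWA and return its state.

    When splitting beforehand, pass the *full* graph's indices via
    ``entity_index`` / ``relation_index`` so held-out entities still get
    (randomly initialized) vectors and evaluation never fails on lookup.
    """
    if isinstance(kg_or_triples, KnowledgeGraph):
        triples = kg_or_triples.triples
    else:
        triples = list(kg_or_triples)
    if not triples:
        raise ValueError("no training triples")

    if entity_index is None:
        entities = sorted({e for t in triples for e in (t.head, t.tail)})
        entity_index = {e: i for i, e in enumerate(entities)}
    if relation_index is None:
        rels = sorted({t.relation for t in triples})
        relation_index = {r: i for i, r in enumerate(rels)}

    pos = np.array(
        [
            (entity_index[t.head], relation_index[t.relation], entity_index[t.tail])
            for t in triples
        ],
        dtype=np.int64,
    )
    n_ent, n_rel = len(entity_index), len(relation_index)

    model = get_model(config.model)
    rng = np.random.default_rng(config.seed)
    params = model.init_params(n_ent, n_rel, config.dim, rng)
    opt = _Adam(params, config.learning_rate)
    loss_name = config.resolved_loss()
    margin = config.margin
    k = config.negatives_per_positive
    observed = {tuple(row) for row in pos} if config.filter_observed_negatives else None

    trajectory: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(pos))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(pos), config.batch_size):
            batch = pos[order[start : start + config.batch_size]]
            neg = sample_negatives(batch, n_ent, k, rng, observed)
            grads = {key: np.zeros_like(val) for key, val in params.items()}
            s_pos = model.score(params, batch[:, 0], batch[:, 1], batch[:, 2])
            s_neg = model.score(params, neg[:, 0], neg[:, 1], neg[:, 2])
            if loss_name == "margin_ranking":
                viol = margin - np.repeat(s_pos, k) + s_neg
                active = viol > 0
                loss = float(np.mean(np.maximum(viol, 0.0)))
                d_neg = active.astype(float) / len(s_neg)
                d_pos = -np.add.reduceat(d_neg, np.arange(0, len(d_neg), k))
            else:  # softplus: positives y=+1, negatives y=-1
                loss = float(
                    (np.sum(_softplus(-s_pos)) + np.sum(_softplus(s_neg)))
                    / (len(s_pos) + len(s_neg))
                )
                denom = len(s_pos) + len(s_neg)
                d_pos = -_sigmoid(-s_pos) / denom
                d_neg = _sigmoid(s_neg) / denom
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "NaN/inf loss during training; lower the learning rate"
                )
            model.backward(params, batch[:, 0], batch[:, 1], batch[:, 2], d_pos, grads)
            model.backward(params, neg[:, 0], neg[:, 1], neg[:, 2], d_neg, grads)
            if config.l2 > 0:  # weight decay on the parameters touched this batch
                for key in grads:
                    touched = np.abs(grads[key]).sum(axis=tuple(range(1, grads[key].ndim))) > 0
                    grads[key][touched] += config.l2 * params[key][touched]
            opt.step(params, grads)
            model.apply_constraints(params)
            epoch_loss += loss
            n_batches += 1
        trajectory.append(epoch_loss / n_batches)

    state = ModelState(
        model_name=config.model,
        dim=config.dim,
        entity_index=entity_index,
        relation_index=relation_index,
        params=params,
        config=config,
        loss_trajectory=trajectory,
    )
    state._check_finite()
    return state
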