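"""Declarative pipeline orchestration with run manifests.

A single config (YAML or dict) carries every stage's parameters; stages
execute in workflow order

    enrich -> embed -> evaluate -> ml -> predict -> cop -> repurpose

writing per-stage outputs under ``out_dir`` plus a ``manifest.json``
recording the config hash, input-file hashes, package versions, the stages
run and their wall times.  Re-running with unchanged config and inputs
reproduces identical outputs (all randomness is seeded from the config).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cop import PruneConfig, build_cop
from .embedding.training import TrainConfig, train_embeddings
from .features import build_pair_features
from .kg import read_kg_tsv, write_kg_tsv, write_labels_tsv
from .metrics import rank_table
from .ml import nested_cv
from .prediction import mutual_filter, predict_all_pairs, segregate, write_predictions_tsv
from .repurpose import build_report, candidate_partners, write_report_tsv
from .splitting import split_triples
from .synergy import consistency_filter, enrich_kg, harmonize, read_combinations_csv

__all__ = ["STAGES", "RunConfig", "run_pipeline", "ConfigError"]

STAGES = ("enrich", "embed", "evaluate", "ml", "predict", "cop", "repurpose")

_KNOWN_KEYS = {
    "kg_tsv",
    "labels_tsv",
    "combinations_csv",
    "out_dir",
    "seed",
    "thresholds",
    "embedding",
    "ml",
    "prune",
    "repurposing",
}


class ConfigError(ValueError):
    pass


class RunConfig:
    """Validated pipeline configuration (unknown top-level keys rejected)."""

    def __init__(self, data: dict):
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("kg_tsv", "out_dir"):
            if key not in data:
                raise ConfigError(f"missing required config key: {key}")
        self.data = data
        self.kg_tsv = Path(data["kg_tsv"])
        self.labels_tsv = Path(data["labels_tsv"]) if data.get("labels_tsv") else None
        self.combinations_csv = (
            Path(data["combinations_csv"]) if data.get("combinations_csv") else None
        )
        self.out_dir = Path(data["out_dir"])
        self.seed = int(data.get("seed", 0))
        thr = data.get("thresholds", {})
        self.thresholds = (float(thr.get("synergism", 10.0)), float(thr.get("antagonism", -10.0)))
        emb = dict(data.get("embedding", {}))
        emb.setdefault("seed", self.seed)
        self.train_config = TrainConfig(**emb)
        self.ml = dict(data.get("ml", {}))
        prune = dict(data.get("prune", {}))
        if "causal_whitelist" in prune:
            prune["causal_whitelist"] = frozenset(prune["causal_whitelist"])
        if "hub_types" in prune:
            prune["hub_types"] = frozenset(prune["hub_types"])
        self.prune_config = PruneConfig(**prune)
        self.repurposing = dict(data.get("repurposing", {}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open("r", encoding="utf-8") as fh:
            return cls(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.data, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in workflow order; returns the manifest."""
    stages = list(stages) if stages else list(STAGES)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    stages = [s for s in STAGES if s in stages]

    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "package_version": __version__,
        "seed": config.seed,
        "inputs": {},
        "stages": {},
        "outputs": [],
    }
    for name, path in (
        ("kg_tsv", config.kg_tsv),
        ("labels_tsv", config.labels_tsv),
        ("combinations_csv", config.combinations_csv),
    ):
        if path is not None:
            if not path.exists():
                raise ConfigError(f"input file missing: {path}")
            manifest["inputs"][name] = _file_hash(path)

    def record(stage: str, t0: float, outputs: list[str]) -> None:
        manifest["stages"][stage] = {"wall_s": round(time.perf_counter() - t0, 3)}
        manifest["outputs"].extend(outputs)

    kg = read_kg_tsv(config.kg_tsv, labels_path=config.labels_tsv)
    enriched_path = out / "enriched.tsv"
    state = None
    split = None

    if "enrich" in stages:
        t0 = time.perf_counter()
        if config.combinations_csv is None:
            raise ConfigError("enrich stage requires combinations_csv")
        records = harmonize(read_combinations_csv(config.combinations_csv))
        labels = consistency_filter(records, config.thresholds)
        kg, _ = enrich_kg(kg, labels)
        write_kg_tsv(kg, enriched_path)
        write_labels_tsv(kg, out / "enriched_labels.tsv")
        record("enrich", t0, ["enriched.tsv", "enriched_labels.tsv"])
    elif enriched_path.exists():
        kg = read_kg_tsv(enriched_path, labels_path=out / "enriched_labels.tsv")

    checkpoint = out / "model.npz"
    if "embed" in stages:
        t0 = time.perf_counter()
        split = split_triples(kg, seed=config.seed)
        entity_index = {e: i for i, e in enumerate(sorted(kg.entities))}
        relation_index = {r: i for i, r in enumerate(kg.relations)}
        state = train_embeddings(
            split.train, config.train_config, entity_index, relation_index
        )
        state.save(checkpoint)
        record("embed", t0, ["model.npz"])
    elif checkpoint.exists():
        from .embedding.training import ModelState

        state = ModelState.load(checkpoint)

    if "evaluate" in stages:
        t0 = time.perf_counter()
        if state is None:
            raise ConfigError("evaluate stage needs the embed stage (or its checkpoint)")
        if split is None:
            split = split_triples(kg, seed=config.seed)
        eval_pairs = {}
        for t in split.test:
            eval_pairs.setdefault((t.head, t.tail), t.relation)
        rankings = [state.rank_relations(h, t) for (h, t) in eval_pairs]
        table = rank_table(rankings, eval_pairs, max_rank=3)
        with (out / "evaluation.tsv").open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("rank\tn_true\tn_total\tpercentage\n")
            for row in table:
                fh.write(f"{row.rank}\t{row.n_true}\t{row.n_total}\t{row.percentage:.4f}\n")
        record("evaluate", t0, ["evaluation.tsv"])

    if "ml" in stages:
        t0 = time.perf_counter()
        if config.combinations_csv is None:
            raise ConfigError("ml stage requires combinations_csv")
        if state is None:
            raise ConfigError("ml stage (embedding features) needs a trained model")
        records = harmonize(read_combinations_csv(config.combinations_csv))
        labels = consistency_filter(records, config.thresholds)
        usable = [
            lab
            for lab in labels
            if lab.drug_a in state.entity_index and lab.drug_b in state.entity_index
        ]
        pairs = [lab.pair for lab in usable]
        y = [lab.label for lab in usable]
        X = build_pair_features(pairs, mode="embedding", embeddings=state)
        reports = nested_cv(X, y, seed=config.seed, **config.ml)
        summary = {
            name: {
                "mean_holdout_auc": rep.mean_holdout_auc,
                "holdout_auc": rep.holdout_auc,
                "best_params": [str(p) for p in rep.best_params],
            }
            for name, rep in reports.items()
        }
        (out / "ml_report.json").write_text(json.dumps(summary, indent=2))
        record("ml", t0, ["ml_report.json"])

    preds_path = out / "predictions.tsv"
    if "predict" in stages:
        t0 = time.perf_counter()
        if state is None:
            raise ConfigError("predict stage needs the embed stage (or its checkpoint)")
        drugs = sorted(kg.drugs() & set(state.entity_index))
        known = {
            (t.head, t.tail)
            for t in kg.triples
            if t.head in drugs and t.tail in drugs
        }
        preds = predict_all_pairs(state, drugs, known_pairs=known)
        retained = mutual_filter(preds)
        write_predictions_tsv(retained, preds_path)
        record("predict", t0, ["predictions.tsv"])

    cop_graph = None
    disease_copy = None
    if "cop" in stages:
        t0 = time.perf_counter()
        cop_graph, disease_copy, log = build_cop(kg, config.prune_config)
        write_kg_tsv(cop_graph, out / "cop.tsv")
        outputs = ["cop.tsv", "prune_log.tsv"]
        if disease_copy is not None:
            write_kg_tsv(disease_copy, out / "cop_with_disease.tsv")
            outputs.append("cop_with_disease.tsv")
        with (out / "prune_log.tsv").open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("node\treason\tdegree\n")
            for node, reason, deg in log:
                fh.write(f"{node}\t{reason}\t{deg}\n")
        record("cop", t0, outputs)

    if "repurpose" in stages:
        t0 = time.perf_counter()
        rep_cfg = config.repurposing
        disease = rep_cfg.get("disease")
        anchors = rep_cfg.get("anchors", [])
        if not disease or not anchors:
            raise ConfigError("repurpose stage needs repurposing.disease and .anchors")
        if not preds_path.exists():
            raise ConfigError("repurpose stage needs predictions.tsv; run predict first")
        import pandas as pd

        from .prediction import PairPrediction

        df = pd.read_csv(preds_path, sep="\t")
        retained = [
            PairPrediction(
                drug_a=row.drug_a,
                drug_b=row.drug_b,
                forward_relation=row.forward_relation,
                forward_score=row.forward_score,
                reverse_relation=row.reverse_relation,
                reverse_score=row.reverse_score,
            )
            for row in df.itertuples()
        ]
        syn, _ant = segregate(retained)
        partners = candidate_partners(
            syn, anchors, set(rep_cfg.get("exclude", []))
        )
        if disease_copy is None and (out / "cop_with_disease.tsv").exists():
            disease_copy = read_kg_tsv(out / "cop_with_disease.tsv")
            disease_copy.assign_types(
                {e: kg.entity_type[e] for e in disease_copy.entities if e in kg.entity_type}
            )
        graph = disease_copy if disease_copy is not None else kg
        reports = build_report(
            graph, partners, disease, max_len=int(rep_cfg.get("max_len", 4))
        )
        write_report_tsv(reports, out / "repurposing.tsv")
        record("repurpose", t0, ["repurposing.tsv"])

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
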