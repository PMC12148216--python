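"""Exhaustive drug-pair relation prediction and mutual-consistency filtering.

For every unordered drug pair the trained embedding model ranks all
relations twice — forward (A as head, B as tail) and reverse — and the
rank-1 relation of each orientation is extracted.  A pair is called only
when both orientations agree on the same drug-combination relation
(``has_synergism_with`` or ``has_antagonism_with``); non-mutual or
out-of-class rank-1 predictions are dropped with a reason code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .embedding.training import ModelState
from .synergy import ANTAGONISM, ANTAGONISM_RELATION, SYNERGISM, SYNERGY_RELATION

__all__ = [
    "PairPrediction",
    "COMBINATION_RELATIONS",
    "predict_all_pairs",
    "mutual_filter",
    "segregate",
    "write_predictions_tsv",
]

COMBINATION_RELATIONS = {
    SYNERGY_RELATION: SYNERGISM,
    ANTAGONISM_RELATION: ANTAGONISM,
}


@dataclass
class PairPrediction:
    """Rank-1 relation calls for both orientations of one drug pair."""

    drug_a: str
    drug_b: str
    forward_relation: str
    forward_score: float
    reverse_relation: str
    reverse_score: float

    @property
    def consistent(self) -> bool:
        return (
            self.forward_relation == self.reverse_relation
            and self.forward_relation in COMBINATION_RELATIONS
        )

    @property
    def final_label(self) -> str | None:
        if not self.consistent:
            return None
        return COMBINATION_RELATIONS[self.forward_relation]

    @property
    def drop_reason(self) -> str | None:
        if self.consistent:
            return None
        if self.forward_relation != self.reverse_relation:
            return "nonmutual"
        return "no_combination_call"

    @property
    def min_score(self) -> float:
        return min(self.forward_score, self.reverse_score)


def predict_all_pairs(
    state: ModelState,
    drugs: list[str],
    known_pairs: set[tuple[str, str]] | None = None,
) -> list[PairPrediction]:
    """Rank-1 forward/reverse relation call for every unordered drug pair.

    ``known_pairs`` (canonicalized or not) are excluded, supporting the
    common setup where pairs already linked in the graph are not
    re-predicted.
    """
    if len(drugs) < 2:
        raise ValueError("need at least two drugs")
    known = set()
    for a, b in known_pairs or ():
        known.add((a, b) if a <= b else (b, a))
    drugs = sorted(set(drugs))
    out: list[PairPrediction] = []
    for i, a in enumerate(drugs):
        for b in drugs[i + 1 :]:
            if (a, b) in known:
                continue
            fwd = state.rank_relations(a, b).top
            rev = state.rank_relations(b, a).top
            out.append(
                PairPrediction(
                    drug_a=a,
                    drug_b=b,
                    forward_relation=fwd[0],
                    forward_score=fwd[1],
                    reverse_relation=rev[0],
                    reverse_score=rev[1],
                )
            )
    return out


def mutual_filter(
    preds: list[PairPrediction], return_dropped: bool = False
):
    """Keep only pairs whose two orientations agree on one combination
    relation; everything else is dropped with a reason code."""
    retained = [p for p in preds if p.consistent]
    if return_dropped:
        dropped: dict[str, int] = {}
        for p in preds:
            reason = p.drop_reason
            if reason:
                dropped[reason] = dropped.get(reason, 0) + 1
        return retained, dropped
    return retained


def segregate(
    retained: list[PairPrediction],
) -> tuple[list[PairPrediction], list[PairPrediction]]:
    """Partition consistent calls into (synergism, antagonism) lists, each
    sorted by min(forward, reverse) score descending, then by pair id."""
    for p in retained:
        if not p.consistent:
            raise ValueError(f"inconsistent prediction passed to segregate: {p}")
    key = lambda p: (-p.min_score, p.drug_a, p.drug_b)
    syn = sorted((p for p in retained if p.final_label == SYNERGISM), key=key)
    ant = sorted((p for p in retained if p.final_label == ANTAGONISM), key=key)
    return syn, ant


def read_predictions_tsv(path: str | Path) -> list[PairPrediction]:
    preds = []
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            preds.append(
                PairPrediction(
                    drug_a=row["drug_a"],
                    drug_b=row["drug_b"],
                    forward_relation=row["forward_relation"],
                    forward_score=float(row["forward_score"]),
                    reverse_relation=row["reverse_relation"],
                    reverse_score=float(row["reverse_score"]),
                )
            )
    return preds


def write_predictions_tsv(preds: list[PairPrediction], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(
            "drug_a\tdrug_b\tforward_relation\tforward_score\t"
            "reverse_relation\treverse_score\tfinal_label\n"
        )
        for p in preds:
            fh.write(
                f"{p.drug_a}\t{p.drug_b}\t{p.forward_relation}\t{p.forward_score:.6g}\t"
                f"{p.reverse_relation}\t{p.reverse_score:.6g}\t{p.final_label or ''}\n"
            )
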