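"""Nested cross-validation benchmark of classical pair classifiers.

The protocol: the labelled pairs are first split into a stratified 90%
training portion and a 10% hold-out test set.  Hyperparameters are then
optimized by grid search over ten inner loops, each splitting the training
portion 90/10 into inner-train and validation.  After optimization, ten
model instances — one per inner loop, each carrying that loop's best
parameters — are refit on the full training portion and evaluated on the
hold-out set by ROC-AUC, giving a distribution of hold-out AUCs per model.

The same report schema serves both feature modes (handcrafted KG +
physicochemical features, or embedding vectors), so the embedding-hybrid
path reuses this module unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import binary_roc_auc
from .splitting import holdout_sizes

__all__ = ["MODEL_GRIDS", "CVReport", "nested_cv", "make_classifier"]

#: small fixed default grids per model
MODEL_GRIDS: dict[str, dict[str, list]] = {
    "logistic_regression": {"clf__C": [0.1, 1.0, 10.0]},
    "elastic_net": {"clf__C": [0.1, 1.0], "clf__l1_ratio": [0.2, 0.5, 0.8]},
    "gradient_boosting": {"clf__n_estimators": [100], "clf__max_depth": [2, 3]},
    "random_forest": {"clf__n_estimators": [200], "clf__max_depth": [None, 8]},
    "svm": {"clf__C": [0.1, 1.0, 10.0]},
}


def make_classifier(name: str, seed: int = 0, **params) -> Pipeline:
    """A standardized pipeline for one of the five benchmark classifiers."""
    if name == "logistic_regression":
        clf = LogisticRegression(max_iter=2000, random_state=seed)
    elif name == "elastic_net":
        clf = LogisticRegression(
            solver="saga", l1_ratio=0.5, max_iter=5000, random_state=seed
        )
    elif name == "gradient_boosting":
        clf = GradientBoostingClassifier(random_state=seed)
    elif name == "random_forest":
        clf = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    elif name == "svm":
        clf = SVC(random_state=seed)  # ranking via decision_function
    else:
        raise ValueError(f"unknown model {name!r}; choose from {sorted(MODEL_GRIDS)}")
    pipe = Pipeline([("scale", StandardScaler()), ("clf", clf)])
    if params:
        pipe.set_params(**params)
    return pipe


def _scores(pipe: Pipeline, X) -> np.ndarray:
    if hasattr(pipe, "predict_proba"):
        try:
            return pipe.predict_proba(X)[:, 1]
        except AttributeError:  # pragma: no cover
            pass
    return pipe.decision_function(X)


@dataclass
class CVReport:
    """Nested-CV results for one classifier."""

    model: str
    inner_val_auc: list[float] = field(default_factory=list)
    best_params: list[dict] = field(default_factory=list)
    holdout_auc: list[float] = field(default_factory=list)
    n_train: int = 0
    n_holdout: int = 0

    @property
    def mean_holdout_auc(self) -> float:
        return float(np.mean(self.holdout_auc))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "loop": range(1, len(self.holdout_auc) + 1),
                "inner_val_auc": self.inner_val_auc,
                "holdout_auc": self.holdout_auc,
                "best_params": [str(p) for p in self.best_params],
            }
        )


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def nested_cv(
    features: pd.DataFrame | np.ndarray,
    labels,
    models: list[str] | None = None,
    grids: dict[str, dict[str, list]] | None = None,
    n_loops: int = 10,
    holdout_fraction: float = 0.1,
    inner_fraction: float = 0.1,
    seed: int = 0,
) -> dict[str, CVReport]:
    """Run the nested-CV benchmark and return one report per classifier.

    ``labels`` may be any binary labelling (e.g. ``"synergism"`` vs
    ``"antagonism"``); the lexicographically larger value is the positive
    class.  All splits are stratified and derived from ``seed``.
    """
    X = np.asarray(features, dtype=float)
    y_raw = np.asarray(labels)
    classes = sorted(set(y_raw.tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    y = (y_raw == classes[1]).astype(int)
    if len(y) < 20:
        raise ValueError("need at least 20 labelled pairs")
    models = models or list(MODEL_GRIDS)
    grids = grids or MODEL_GRIDS
    for m in models:
        if m not in grids or not grids[m] or not _grid_points(grids[m]):
            raise ValueError(f"empty or missing hyperparameter grid for {m!r}")

    n_keep, n_hold = holdout_sizes(len(y), holdout_fraction)
    outer = StratifiedShuffleSplit(n_splits=1, test_size=holdout_fraction, random_state=seed)
    (train_idx, hold_idx), = outer.split(X, y)
    assert len(train_idx) == n_keep and len(hold_idx) == n_hold
    X_tr, y_tr = X[train_idx], y[train_idx]
    X_ho, y_ho = X[hold_idx], y[hold_idx]

    inner = StratifiedShuffleSplit(
        n_splits=n_loops, test_size=inner_fraction, random_state=seed + 1
    )
    inner_splits = list(inner.split(X_tr, y_tr))

    reports: dict[str, CVReport] = {}
    for model_name in models:
        report = CVReport(model=model_name, n_train=len(y_tr), n_holdout=len(y_ho))
        for loop, (in_idx, val_idx) in enumerate(inner_splits):
            best_auc, best_params = -np.inf, None
            for point in _grid_points(grids[model_name]):
                pipe = make_classifier(model_name, seed=seed, **point)
                pipe.fit(X_tr[in_idx], y_tr[in_idx])
                auc = binary_roc_auc(y_tr[val_idx], _scores(pipe, X_tr[val_idx]))
                if auc > best_auc:
                    best_auc, best_params = auc, point
            report.inner_val_auc.append(best_auc)
            report.best_params.append(best_params)
            final = make_classifier(model_name, seed=seed + loop, **best_params)
            final.fit(X_tr, y_tr)
            report.holdout_auc.append(binary_roc_auc(y_ho, _scores(final, X_ho)))
        reports[model_name] = report
    return reports
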