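"""Feature-based identification: class separability and ensemble classifiers.

Separability of a labelled feature table is summarized by
``psi = tr(Sigma_inter) - tr(Sigma_intra)``, where ``Sigma_inter`` is the
scatter of per-class mean vectors about the grand mean of class means and
``Sigma_intra`` accumulates the per-class scatter of rows about their class
mean (scaled by 1/n_classes). A larger psi means classes sit further apart
relative to their internal spread. Features mix degrees, length ratios and
frame counts, so they are z-scored before the traces by default; pass
``standardize=False`` for the raw-scale statistic.

Three ensemble classifiers are provided with fixed, reproducible
configurations: a random forest (750 trees, 6 candidate features per
split, 70/30 train/test), XGBoost (depth-3 trees, 300 boosting rounds,
75/25) and LightGBM (multiclass objective, 200 iterations, 75/25). Each
reports held-out accuracy, macro F1, and its native feature-importance
ranking.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import LabelEncoder

from .features import FEATURE_NAMES, FeatureTable

__all__ = [
    "SeparabilityReport",
    "ClassifierReport",
    "METHODS",
    "separability",
    "train_ensemble",
    "evaluate_repeated",
]

METHODS = ("random_forest", "xgboost", "lightgbm")

#: Held-out fraction per method (random forest splits 70/30, boosters 75/25).
_TEST_FRACTION = {"random_forest": 0.30, "xgboost": 0.25, "lightgbm": 0.25}

_DEFAULT_CONFIG: dict[str, dict[str, Any]] = {
    "random_forest": {"n_estimators": 750, "max_features": 6},
    "xgboost": {"max_depth": 3, "n_estimators": 300},
    # min_child_samples lowered from lightgbm's 20: gait tables carry only
    # on the order of ten cycles per subject
    "lightgbm": {"n_estimators": 200, "objective": "multiclass", "min_child_samples": 5},
}


@dataclass
class SeparabilityReport:
    """Between/within scatter matrices and the trace separability psi."""

    sigma_inter: np.ndarray
    sigma_intra: np.ndarray
    psi: float
    standardized: bool = True

    def __post_init__(self) -> None:
        for m in (self.sigma_inter, self.sigma_intra):
            if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-8):
                raise ValueError("scatter matrices must be square and symmetric")


@dataclass
class ClassifierReport:
    """Held-out evaluation of one ensemble method on a feature table."""

    method: str
    accuracy: float
    f1: float
    importance_ranking: list[str]
    config: dict[str, Any]
    seed: int
    accuracy_sd: float | None = None
    f1_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.accuracy <= 1.0 or not 0.0 <= self.f1 <= 1.0:
            raise ValueError("accuracy and f1 must lie in [0, 1]")

    def to_json(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        return json.dumps(d, indent=2, default=float)

    def importance_csv(self, path, top: int | None = 10) -> None:
        names = self.importance_ranking if top is None else self.importance_ranking[:top]
        pd.DataFrame({"rank": np.arange(1, len(names) + 1), "feature": names}).to_csv(
            path, index=False
        )


def _class_blocks(table: FeatureTable, standardize: bool) -> tuple[list[np.ndarray], np.ndarray]:
    X = table.matrix
    y = table.labels
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    classes = pd.unique(y)
    if len(classes) < 2:
        raise ValueError("separability requires at least 2 classes")
    blocks = [X[y == c] for c in classes]
    if any(len(b) == 0 for b in blocks):
        raise ValueError("every class needs at least one row")
    return blocks, classes


def separability(table: FeatureTable, standardize: bool = True) -> SeparabilityReport:
    """Scatter-matrix class separability of a labelled feature table.

    ``Sigma_inter = sum_c (mu_c - mu)(mu_c - mu)^T`` with ``mu`` the mean of
    the class means (not the pooled row mean — they differ for unbalanced
    classes); ``Sigma_intra = sum_c Sigma_c`` where
    ``Sigma_c = (1/n_classes) * sum_i (x_i - mu_c)(x_i - mu_c)^T`` over the
    rows of class c. ``psi = tr(Sigma_inter) - tr(Sigma_intra)``.
    """
    blocks, _ = _class_blocks(table, standardize)
    n_classes = len(blocks)
    mus = np.stack([b.mean(axis=0) for b in blocks])
    grand = mus.mean(axis=0)

    centered = mus - grand
    sigma_inter = centered.T @ centered

    d = mus.shape[1]
    sigma_intra = np.zeros((d, d))
    for b, mu_c in zip(blocks, mus):
        r = b - mu_c
        sigma_intra += (r.T @ r) / n_classes

    psi = float(np.trace(sigma_inter) - np.trace(sigma_intra))
    return SeparabilityReport(
        sigma_inter=sigma_inter, sigma_intra=sigma_intra, psi=psi, standardized=standardize
    )


def _make_model(method: str, config: dict[str, Any], seed: int):
    if method == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **config)
    if method == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            booster="gbtree",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
            tree_method="hist",
            **config,
        )
    if method == "lightgbm":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **config)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def train_ensemble(
    table: FeatureTable,
    method: str = "random_forest",
    config: dict[str, Any] | None = None,
    seed: int = 0,
) -> ClassifierReport:
    """Train one ensemble classifier on a feature table and evaluate held out.

    The split is stratified by subject label (70/30 for the random forest,
    75/25 for the boosting methods). Fully seeded: identical inputs and seed
    reproduce the report bit-for-bit.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    cfg = dict(_DEFAULT_CONFIG[method])
    if config:
        cfg.update(config)

    X = table.matrix
    enc = LabelEncoder()
    y = enc.fit_transform(table.labels)
    counts = np.bincount(y)
    if len(counts) < 2:
        raise ValueError("need at least 2 subjects")
    if counts.min() < 2:
        bad = enc.classes_[int(np.argmin(counts))]
        raise ValueError(f"subject {bad!r} has a single cycle; cannot stratify a split")

    if method == "random_forest":
        cfg["max_features"] = min(cfg.get("max_features", 6), X.shape[1])
    if method == "lightgbm" and cfg.get("objective") == "multiclass" and len(counts) == 2:
        cfg["objective"] = "binary"  # lightgbm rejects multiclass with 2 labels

    X = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=_TEST_FRACTION[method], stratify=y, random_state=seed
    )
    model = _make_model(method, cfg, seed)
    model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    acc = float(accuracy_score(y_te, pred))
    f1 = float(f1_score(y_te, pred, average="macro"))

    importances = np.asarray(model.feature_importances_, dtype=float)
    order = np.argsort(-importances, kind="stable")
    ranking = [FEATURE_NAMES[i] for i in order]

    return ClassifierReport(
        method=method, accuracy=acc, f1=f1, importance_ranking=ranking, config=cfg, seed=seed
    )


def evaluate_repeated(
    table: FeatureTable,
    method: str = "random_forest",
    repeats: int = 100,
    config: dict[str, Any] | None = None,
    seed: int = 0,
) -> ClassifierReport:
    """Repeat train/evaluate over independent resplits; report means and SDs.

    The importance ranking reported is the one from the first repeat.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    accs: list[float] = []
    f1s: list[float] = []
    first: ClassifierReport | None = None
    for r in range(repeats):
        rep = train_ensemble(table, method=method, config=config, seed=(seed + r) % (2**31 - 1))
        if first is None:
            first = rep
        accs.append(rep.accuracy)
        f1s.append(rep.f1)
    assert first is not None
    return ClassifierReport(
        method=method,
        accuracy=float(np.mean(accs)),
        f1=float(np.mean(f1s)),
        importance_ranking=first.importance_ranking,
        config=first.config,
        seed=seed,
        accuracy_sd=float(np.std(accs)),
        f1_sd=float(np.std(f1s)),
    )
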