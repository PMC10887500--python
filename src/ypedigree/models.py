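"""Meiotic-distance classifiers trained on simulated pair data.

The number of meioses separating two men is treated as a class label and
predicted from their per-marker mutation-count vector.  Models are built by
double cross-validation: an outer stratified K-fold split reserves each
fold in turn for unbiased evaluation, while a randomized search over each
family's pre-defined hyper-parameter space (J draws, scored by inner
cross-validation) selects the fold-best configuration on the training
folds only.  Per-fold F1, accuracy, precision, recall and Matthews
correlation are tabulated together with a pooled confusion matrix; the
best-scoring configuration is refit on all data as the deployable model.

At prediction time the class-probability vector over the configured
meiotic-distance range is reduced to nested 85/95/99% confidence ranges by
growing a contiguous interval outward from the modal distance, at each
step absorbing the neighbouring distance with the higher probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint
from sklearn.base import clone
from sklearn.ensemble import HistGradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    matthews_corrcoef,
    precision_score,
    recall_score,
)
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_FAMILIES",
    "ModelBundle",
    "PredictionResult",
    "build_models",
    "evaluate_metrics",
    "predict",
    "confidence_ranges",
    "save_bundle",
    "load_bundle",
    "plot_probabilities",
]

DEFAULT_LEVELS = (0.85, 0.95, 0.99)

# Family registry: estimator factory + pre-defined randomized-search space.
# Spaces are deliberately broad; users may register additional entries.
MODEL_FAMILIES: dict[str, tuple] = {
    "logistic": (
        lambda: LogisticRegression(max_iter=2000),
        {"C": loguniform(1e-3, 1e3)},
    ),
    "svm_linear": (
        lambda: SVC(kernel="linear", probability=True),
        {"C": loguniform(1e-3, 1e2)},
    ),
    "svm_rbf": (
        lambda: SVC(kernel="rbf", probability=True),
        {"C": loguniform(1e-2, 1e3), "gamma": loguniform(1e-4, 1e1)},
    ),
    "random_forest": (
        lambda: RandomForestClassifier(),
        {
            "n_estimators": randint(50, 301),
            "max_depth": [None, 5, 10, 20],
            "min_samples_leaf": randint(1, 10),
            "max_features": ["sqrt", "log2", None],
        },
    ),
    "gradient_boosting": (
        lambda: HistGradientBoostingClassifier(),
        {
            "learning_rate": loguniform(0.01, 0.5),
            "max_iter": randint(50, 301),
            "max_depth": [None, 3, 6, 10],
        },
    ),
    "knn": (
        lambda: KNeighborsClassifier(),
        {"n_neighbors": randint(1, 31), "weights": ["uniform", "distance"]},
    ),
    "mlp": (
        lambda: MLPClassifier(max_iter=600),
        {
            "hidden_layer_sizes": [(32,), (64,), (32, 32)],
            "alpha": loguniform(1e-5, 1e-1),
        },
    ),
}


@dataclass
class ModelBundle:
    """Fitted classifiers plus the bookkeeping needed to apply them."""

    final_model: object
    final_family: str
    final_params: dict
    families: list[str]
    markers: list[str]
    classes: list[int]  # meiotic distances, ascending
    seed: int
    k_folds: int
    n_iter: int
    fold_models: list = field(default_factory=list)  # fold-best fitted models
    metrics: pd.DataFrame | None = None  # one row per outer fold
    confusion: np.ndarray | None = None  # pooled held-out confusion matrix
    fold_indices: list | None = None  # (train_idx, test_idx) per fold


@dataclass
class PredictionResult:
    """Per-pair class probabilities with nested confidence ranges."""

    classes: list[int]
    probabilities: np.ndarray  # (n_pairs, n_classes), rows sum to 1
    ranges: list[dict[float, tuple[int, int]]]  # per pair: level -> (lo, hi)

    def frame(self, pair_ids: list[str] | None = None) -> pd.DataFrame:
        cols = {f"p_{c}": self.probabilities[:, i] for i, c in enumerate(self.classes)}
        df = pd.DataFrame(cols)
        for level in sorted(self.ranges[0]) if self.ranges else []:
            pct = int(round(level * 100))
            df[f"{pct}_min"] = [r[level][0] for r in self.ranges]
            df[f"{pct}_max"] = [r[level][1] for r in self.ranges]
        if pair_ids is not None:
            df.insert(0, "pair", pair_ids)
        return df


def evaluate_metrics(y_true, y_pred, labels=None) -> dict:
    """Accuracy, macro precision/recall/F1 and multi-class Matthews
    correlation, plus the confusion-matrix counts."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot score empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    return {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(
            y_true, y_pred, average="macro", zero_division=0
        ),
        "recall": recall_score(y_true, y_pred, average="macro", zero_division=0),
        "f1": f1_score(y_true, y_pred, average="macro", zero_division=0),
        "mcc": matthews_corrcoef(y_true, y_pred),
        "confusion": confusion_matrix(y_true, y_pred, labels=labels),
    }


def build_models(
    training: pd.DataFrame,
    families: list[str] | None = None,
    k_folds: int = 5,
    n_iter: int = 50,
    seed: int = 0,
    inner_folds: int = 3,
    label_column: str = "generation",
) -> ModelBundle:
    """Double cross-validation model building on a simulated training set.

    ``training`` holds the class label column plus one count column per
    marker.  Per outer fold, each requested family undergoes a randomized
    search of ``n_iter`` draws scored by inner cross-validated macro-F1 on
    the training folds; the fold-best model is then evaluated once on the
    held-out fold.  The configuration with the highest held-out macro-F1 is
    refit on all data as the final model.
    """
    families = families or ["random_forest"]
    unknown = [f for f in families if f not in MODEL_FAMILIES]
    if unknown:
        raise KeyError(f"unknown model families {unknown}; choose from "
                       f"{sorted(MODEL_FAMILIES)}")
    markers = [c for c in training.columns if c != label_column]
    X = training[markers].to_numpy(dtype=float)
    y = training[label_column].to_numpy(dtype=int)
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    _, counts = np.unique(y, return_counts=True)
    if k_folds > counts.min():
        raise ValueError(
            f"k_folds={k_folds} exceeds the smallest class size ({counts.min()})"
        )

    outer = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_rows = []
    fold_models = []
    fold_indices = []
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(outer.split(X, y)):
        fold_indices.append((train_idx, test_idx))
        best = None  # (inner score, family, search)
        for family in families:
            factory, space = MODEL_FAMILIES[family]
            search = RandomizedSearchCV(
                factory(),
                space,
                n_iter=n_iter,
                cv=StratifiedKFold(
                    n_splits=inner_folds, shuffle=True, random_state=seed + 1
                ),
                scoring="f1_macro",
                random_state=seed + fold,
                n_jobs=1,
            )
            _seed_estimator(search.estimator, seed + fold)
            search.fit(X[train_idx], y[train_idx])
            if best is None or search.best_score_ > best[0]:
                best = (search.best_score_, family, search)
        inner_score, family, search = best
        model = search.best_estimator_
        y_pred = model.predict(X[test_idx])
        scores = evaluate_metrics(y[test_idx], y_pred, labels=classes)
        confusion += scores.pop("confusion")
        fold_rows.append(
            {
                "fold": fold,
                "family": family,
                "params": _printable(search.best_params_),
                "inner_f1": inner_score,
                **scores,
            }
        )
        fold_models.append(model)
        logger.info("fold %d: %s f1=%.3f", fold, family, scores["f1"])

    metrics = pd.DataFrame(fold_rows)
    best_fold = int(metrics["f1"].idxmax())
    family = metrics.loc[best_fold, "family"]
    final = clone(fold_models[best_fold])
    _seed_estimator(final, seed)
    final.fit(X, y)
    return ModelBundle(
        final_model=final,
        final_family=family,
        final_params=_printable(
            {k: v for k, v in final.get_params().items() if not callable(v)}
        ),
        families=list(families),
        markers=markers,
        classes=classes,
        seed=seed,
        k_folds=k_folds,
        n_iter=n_iter,
        fold_models=fold_models,
        metrics=metrics,
        confusion=confusion,
        fold_indices=fold_indices,
    )


def _seed_estimator(estimator, seed: int) -> None:
    if "random_state" in estimator.get_params():
        estimator.set_params(random_state=seed)


def _printable(params: dict) -> dict:
    return {k: (v if isinstance(v, (int, float, str, bool, type(None))) else str(v))
            for k, v in params.items()}


def confidence_ranges(
    probabilities: np.ndarray,
    classes: list[int],
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> dict[float, tuple[int, int]]:
    """Nested confidence ranges for one normalized probability vector.

    Starting from the modal meiotic distance, the interval is grown one
    class at a time toward the neighbour with the higher probability until
    its cumulative mass reaches each level.  Larger levels always contain
    smaller ones, so the 85% range lies inside the 95% inside the 99%.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1 or len(p) != len(classes):
        raise ValueError("probability vector does not match the class list")
    if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise ValueError("probabilities must be non-negative and sum to 1")
    lo = hi = int(np.argmax(p))
    mass = p[lo]
    out = {}
    for level in sorted(levels):
        while mass < level - 1e-12 and (lo > 0 or hi < len(p) - 1):
            left = p[lo - 1] if lo > 0 else -1.0
            right = p[hi + 1] if hi < len(p) - 1 else -1.0
            if left >= right:
                lo -= 1
                mass += p[lo]
            else:
                hi += 1
                mass += p[hi]
        out[level] = (classes[lo], classes[hi])
    return out


def predict(
    bundle: ModelBundle,
    features: pd.DataFrame,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> PredictionResult:
    """Class probabilities and confidence ranges for observed pairs.

    Feature columns are matched to the bundle's marker order by name;
    extra metadata columns are ignored, a missing marker is an error.
    """
    missing = [m for m in bundle.markers if m not in features.columns]
    if missing:
        raise KeyError(f"feature table lacks marker column(s) {missing}")
    X = features[bundle.markers].to_numpy(dtype=float)
    raw = bundle.final_model.predict_proba(X)
    # align model class order to the bundle's ascending distances
    order = {c: i for i, c in enumerate(bundle.final_model.classes_)}
    probs = np.column_stack([raw[:, order[c]] for c in bundle.classes])
    probs = probs / probs.sum(axis=1, keepdims=True)
    ranges = [confidence_ranges(row, bundle.classes, levels) for row in probs]
    return PredictionResult(classes=bundle.classes, probabilities=probs, ranges=ranges)


def save_bundle(bundle: ModelBundle, path: str | Path) -> None:
    """Serialize a bundle to one file (fitted models + JSON-able metadata)."""
    payload = {
        "metadata": {
            "families": bundle.families,
            "final_family": bundle.final_family,
            "final_params": bundle.final_params,
            "markers": bundle.markers,
            "classes": bundle.classes,
            "seed": bundle.seed,
            "k_folds": bundle.k_folds,
            "n_iter": bundle.n_iter,
        },
        "final_model": bundle.final_model,
        "fold_models": bundle.fold_models,
        "metrics": bundle.metrics,
        "confusion": bundle.confusion,
    }
    joblib.dump(payload, path)


def load_bundle(path: str | Path) -> ModelBundle:
    payload = joblib.load(path)
    meta = payload["metadata"]
    return ModelBundle(
        final_model=payload["final_model"],
        final_family=meta["final_family"],
        final_params=meta["final_params"],
        families=meta["families"],
        markers=meta["markers"],
        classes=meta["classes"],
        seed=meta["seed"],
        k_folds=meta["k_folds"],
        n_iter=meta["n_iter"],
        fold_models=payload.get("fold_models", []),
        metrics=payload.get("metrics"),
        confusion=payload.get("confusion"),
    )


def plot_probabilities(
    result: PredictionResult, index: int, path: str | Path
) -> None:
    """Bar plot of one pair's probability over meiotic distances, with the
    85/95/99% ranges drawn as horizontal brackets."""
    p = result.probabilities[index]
    ranges = result.ranges[index]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(result.classes, p, color="#4878a8")
    top = float(p.max())
    for i, level in enumerate(sorted(ranges)):
        lo, hi = ranges[level]
        y = top * (1.06 + 0.08 * i)
        ax.plot([lo - 0.4, hi + 0.4], [y, y], lw=2)
        ax.text(hi + 0.6, y, f"{int(round(level * 100))}%", va="center", fontsize=8)
    ax.set_xlabel("meiotic distance")
    ax.set_ylabel("probability")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
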