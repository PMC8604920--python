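"""Model evaluation: confusion counts, support-weighted metrics, baselines.

Metrics follow the two-class *support-weighted* convention: precision,
recall and F1 are computed per class and averaged with weights proportional
to each class's true count.  Under this convention the weighted recall of a
binary classifier is algebraically identical to its accuracy.  All metrics
are reported as percentages.

The classification threshold is 0.5 with ties classified positive
(risk >= 0.5 -> predicted case).  A class that receives no predicted
members has its precision set to 0 with a warning.

Baselines are logistic regression, an RBF support-vector machine, a random
forest and a small fully connected neural network (scikit-learn), each tuned
over a small hyperparameter grid on the validation split and scored on the
test split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.manifold import TSNE
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, DataError
from .gnn import SplitMasks

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "metrics_from_confusion",
    "run_baselines",
    "export_embeddings_tsne",
    "reports_to_frame",
]

BASELINE_NAMES = ["LR", "SVM", "RF", "ANN"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts (positive = case, label 1)."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Support-weighted classification metrics (percent) plus raw counts."""

    model: str
    feature_set: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts

    def as_row(self) -> dict:
        return {
            "method": self.model,
            "feature_set": self.feature_set,
            "accuracy": round(self.accuracy, 2),
            "precision": round(self.precision, 2),
            "recall": round(self.recall, 2),
            "f1": round(self.f1, 2),
            "TP": self.counts.tp,
            "TN": self.counts.tn,
            "FP": self.counts.fp,
            "FN": self.counts.fn,
        }


def confusion(labels, predictions, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/TN/FP/FN at the given risk threshold (ties -> positive)."""
    y = np.asarray(labels)
    p = np.asarray(predictions, dtype=float)
    if y.shape != p.shape:
        raise DataError(f"labels {y.shape} and predictions {p.shape} differ in length")
    if np.any(p < 0) or np.any(p > 1):
        raise DataError("predictions must lie in [0, 1]")
    pred = p >= threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"undefined {what} (zero denominator); using 0", stacklevel=3)
        return 0.0
    return num / den


def metrics_from_confusion(
    c: ConfusionCounts, model: str = "", feature_set: str = ""
) -> MetricsReport:
    """Support-weighted accuracy/precision/recall/F1 (percent) from counts."""
    total = c.total
    if total <= 0:
        raise DataError("confusion counts sum to zero")
    support_pos = c.tp + c.fn
    support_neg = c.tn + c.fp

    prec_pos = _safe_div(c.tp, c.tp + c.fp, "positive-class precision")
    prec_neg = _safe_div(c.tn, c.tn + c.fn, "negative-class precision")
    rec_pos = _safe_div(c.tp, support_pos, "positive-class recall")
    rec_neg = _safe_div(c.tn, support_neg, "negative-class recall")
    f1_pos = _safe_div(2 * prec_pos * rec_pos, prec_pos + rec_pos, "positive-class F1")
    f1_neg = _safe_div(2 * prec_neg * rec_neg, prec_neg + rec_neg, "negative-class F1")

    def weighted(a: float, b: float) -> float:
        return (a * support_pos + b * support_neg) / total

    return MetricsReport(
        model=model,
        feature_set=feature_set,
        accuracy=100.0 * (c.tp + c.tn) / total,
        precision=100.0 * weighted(prec_pos, prec_neg),
        recall=100.0 * weighted(rec_pos, rec_neg),
        f1=100.0 * weighted(f1_pos, f1_neg),
        counts=c,
    )


def _baseline_models(seed: int):
    """(name, constructor, parameter grid) for the four baselines."""
    return [
        (
            "LR",
            lambda C: LogisticRegression(C=C, max_iter=2000, random_state=seed),
            [{"C": c} for c in (0.1, 1.0, 10.0)],
        ),
        (
            "SVM",
            lambda C: SVC(C=C, kernel="rbf", random_state=seed),
            [{"C": c} for c in (0.1, 1.0, 10.0)],
        ),
        (
            "RF",
            lambda n_estimators, max_depth: RandomForestClassifier(
                n_estimators=n_estimators, max_depth=max_depth, random_state=seed
            ),
            [
                {"n_estimators": n, "max_depth": d}
                for n in (100, 300)
                for d in (None, 5)
            ],
        ),
        (
            "ANN",
            lambda hidden_layer_sizes: MLPClassifier(
                hidden_layer_sizes=hidden_layer_sizes,
                max_iter=1000,
                random_state=seed,
            ),
            [{"hidden_layer_sizes": h} for h in ((32, 16), (64, 32))],
        ),
    ]


def run_baselines(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    masks: SplitMasks,
    feature_set: str = "patient_only",
    seed: int = 0,
) -> list[MetricsReport]:
    """Fit LR/SVM/RF/ANN on the train split and report test-split metrics.

    For each model the hyperparameter grid entry with the best
    validation-split accuracy is selected.  Features are standardised with
    statistics fitted on the training split only.  Zero-variance feature
    columns trigger a warning but are retained.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    masks.validate()
    if x.shape[0] != y.shape[0]:
        raise DataError("features and labels are not row-aligned")
    if np.any(x.std(axis=0) == 0):
        warnings.warn("zero-variance feature column(s) present; retained", stacklevel=2)

    scaler = StandardScaler()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns scale to 0
        x_train = scaler.fit_transform(x[masks.train])
        x_val = scaler.transform(x[masks.val])
        x_test = scaler.transform(x[masks.test])
    y_train, y_val, y_test = y[masks.train], y[masks.val], y[masks.test]

    reports = []
    for name, make, grid in _baseline_models(seed):
        best_model, best_acc = None, -1.0
        for params in grid:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = make(**params).fit(x_train, y_train)
            acc = float(np.mean(model.predict(x_val) == y_val))
            if acc > best_acc:
                best_model, best_acc = model, acc
        c = confusion(y_test, best_model.predict(x_test).astype(float))
        reports.append(metrics_from_confusion(c, model=name, feature_set=feature_set))
    return reports


def reports_to_frame(reports: list[MetricsReport]) -> pd.DataFrame:
    """Metrics table in the standard column layout (one row per model)."""
    return pd.DataFrame([r.as_row() for r in reports])


def export_embeddings_tsne(
    embeddings: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    perplexity: float = 30.0,
    n_iter: int = 1000,
) -> pd.DataFrame:
    """Project node embeddings to 2-D with t-SNE for scatter plotting.

    Returns a DataFrame with columns x, y, label (one row per node),
    deterministic under ``seed``.
    """
    emb = np.asarray(embeddings, dtype=float)
    y = np.asarray(labels)
    if emb.ndim != 2 or emb.shape[0] != y.shape[0]:
        raise DataError("embeddings must be 2-D and row-aligned with labels")
    n = emb.shape[0]
    if n < 5:
        raise ConfigurationError("t-SNE export requires at least 5 points")
    if perplexity >= n:
        raise ConfigurationError(
            f"perplexity ({perplexity}) must be smaller than the number of "
            f"points ({n}); pass a smaller perplexity"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=n_iter,
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(emb)
    return pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "label": y})


def plot_embeddings(points: pd.DataFrame, path) -> None:
    """Optional 2-D scatter of t-SNE points coloured by label (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    for lab, sub in points.groupby("label"):
        ax.scatter(sub["x"], sub["y"], s=8, alpha=0.7, label=f"label {lab}")
    ax.legend()
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
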