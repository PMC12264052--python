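"""Metric suite, calibration, confusion matrices and feature attribution.

Conventions (documented rather than left to library defaults):

* Positive class for binary tasks is the adverse outcome, encoded 1.
* F1/precision/recall are 0 when their denominator is empty.
* Binary Brier score is the mean squared error of the adverse-class
  probability; the multiclass Brier sums squared errors over the three
  probability components per sample ("sum" convention) with a halved
  variant ("half") available, since both circulate in the literature.
* Brier skill = 1 - Brier(model)/Brier(reference dummy); undefined (None)
  for a perfect reference.
* ROC AUC is the tie-corrected rank statistic; undefined (None) when only
  one class is present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvaluationBundle",
    "binary_metrics",
    "multiclass_metrics",
    "brier_skill",
    "calibration_table",
    "confusion",
    "importance_ranking",
]


@dataclass
class EvaluationBundle:
    """All evaluation artefacts for one trained model on one test set."""

    task_type: str  # "binary" | "multiclass"
    metrics: dict = field(default_factory=dict)
    calibration: pd.DataFrame | None = None
    confusion_raw: pd.DataFrame | None = None
    confusion_row: pd.DataFrame | None = None
    confusion_col: pd.DataFrame | None = None
    importance: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {"task_type": self.task_type, "metrics": dict(self.metrics)}
        if self.calibration is not None:
            out["calibration"] = self.calibration.to_dict(orient="records")
        for name in ("confusion_raw", "confusion_row", "confusion_col"):
            m = getattr(self, name)
            if m is not None:
                out[name] = m.to_dict(orient="split")
        if self.importance is not None:
            out["importance"] = self.importance.to_dict(orient="records")
        return out


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def confusion(labels, predictions, normalize: str = "none",
              classes=None) -> pd.DataFrame:
    """Confusion matrix with rows = true class, columns = predicted.

    ``normalize="row"`` divides by true-class totals, ``"column"`` by
    predicted-class totals; rows/columns with zero total become None (never
    NaN propagation into downstream sums).
    """
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([labels, predictions]))
    classes = list(classes)
    mat = np.zeros((len(classes), len(classes)), dtype=float)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(labels, predictions):
        mat[index[t], index[p]] += 1
    out = pd.DataFrame(mat, index=classes, columns=classes)
    if normalize == "none":
        return out
    if normalize == "row":
        totals = out.sum(axis=1)
        norm = out.div(totals.replace(0, np.nan), axis=0)
    elif normalize == "column":
        totals = out.sum(axis=0)
        norm = out.div(totals.replace(0, np.nan), axis=1)
    else:
        raise ValueError("normalize must be one of none/row/column")
    return norm.astype(object).where(norm.notna(), None)


def binary_metrics(labels, predictions, probabilities) -> dict:
    """Standard binary metrics on the adverse-positive convention.

    ``probabilities`` is the adverse-class (label 1) probability per row.
    """
    y = np.asarray(labels).astype(int)
    yhat = np.asarray(predictions).astype(int)
    p = np.asarray(probabilities, dtype=float)
    tp = int(((y == 1) & (yhat == 1)).sum())
    fp = int(((y == 0) & (yhat == 1)).sum())
    fn = int(((y == 1) & (yhat == 0)).sum())
    tn = int(((y == 0) & (yhat == 0)).sum())
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    npv = _safe_div(tn, tn + fn)
    brier = float(np.mean((p - y) ** 2))
    if len(np.unique(y)) < 2:
        warnings.warn("single-class labels: ROC AUC undefined", stacklevel=2)
        auc = None
    else:
        auc = float(roc_auc_score(y, p))
    return {
        "accuracy": _safe_div(tp + tn, len(y)),
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "npv": npv,
        "brier": brier,
        "roc_auc": auc,
    }


def multiclass_metrics(labels, predictions, probabilities,
                       classes=(1, 2, 3),
                       brier_convention: str = "sum") -> dict:
    """Per-class one-vs-rest F1, macro F1, accuracy and multiclass Brier.

    ``probabilities`` has one column per entry of ``classes``. A class
    absent from the labels scores F1 = 0 by convention (with a warning).
    """
    y = np.asarray(labels)
    yhat = np.asarray(predictions)
    proba = np.asarray(probabilities, dtype=float)
    classes = list(classes)
    if proba.shape != (len(y), len(classes)):
        raise ValueError("probabilities must be (n_samples, n_classes)")
    class_f1 = []
    for c in classes:
        if not (y == c).any():
            warnings.warn(f"class {c} absent from labels; F1 set to 0",
                          stacklevel=2)
            class_f1.append(0.0)
            continue
        tp = int(((y == c) & (yhat == c)).sum())
        fp = int(((y != c) & (yhat == c)).sum())
        fn = int(((y == c) & (yhat != c)).sum())
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        class_f1.append(_safe_div(2 * prec * rec, prec + rec))
    onehot = (y[:, None] == np.asarray(classes)[None, :]).astype(float)
    brier = float(np.mean(np.sum((proba - onehot) ** 2, axis=1)))
    if brier_convention == "half":
        brier /= 2.0
    elif brier_convention != "sum":
        raise ValueError("brier_convention must be 'sum' or 'half'")
    return {
        "accuracy": float(np.mean(y == yhat)),
        "class_f1": class_f1,
        "f1_macro": float(np.mean(class_f1)),
        "brier": brier,
        "brier_convention": brier_convention,
    }


def brier_skill(brier_model: float, brier_reference: float) -> float | None:
    """Skill relative to the dummy reference: 1 - model/reference."""
    if brier_model < 0 or brier_reference < 0:
        raise ValueError("Brier scores are non-negative")
    if brier_reference == 0:
        return None
    return 1.0 - brier_model / brier_reference


def calibration_table(labels, probabilities, n_bins: int = 10) -> pd.DataFrame:
    """Reliability table on equal-width bins of [0, 1].

    Bins are half-open ``[lo, hi)`` except the last, which includes 1.0.
    Empty bins are reported with count 0 and None frequency/mean.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    y = np.asarray(labels).astype(float)
    p = np.asarray(probabilities, dtype=float)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1], right=False), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        rows.append({
            "bin_low": edges[b],
            "bin_high": edges[b + 1],
            "count": n,
            "mean_predicted": float(p[mask].mean()) if n else None,
            "observed_frequency": float(y[mask].mean()) if n else None,
        })
    return pd.DataFrame(rows)


def importance_ranking(
    model,
    rows: pd.DataFrame,
    n_samples: int = 60,
    n_permutations: int = 8,
    background_size: int = 40,
    seed: int = 0,
    batch_rows: int = 20000,
) -> pd.DataFrame:
    """Per-feature mean absolute attribution by Monte-Carlo Shapley sampling.

    Attribution is computed on the raw predictor columns against the
    model's ``predict_proba`` — a one-hot block therefore aggregates
    automatically to its source predictor. For each evaluated row, feature
    orderings are sampled and marginal contributions measured by swapping
    features one at a time from a background row into the explained row;
    the per-class contributions are combined by mean absolute value and
    averaged over rows. The ranking (descending) is the stable contract;
    raw values depend on the background sample.
    """
    rng = np.random.default_rng(seed)
    features = list(rows.columns)
    n_feat = len(features)
    eval_idx = rng.choice(len(rows), size=min(n_samples, len(rows)), replace=False)
    bg_idx = rng.choice(len(rows), size=min(background_size, len(rows)), replace=True)
    eval_rows = rows.iloc[eval_idx].reset_index(drop=True)
    background = rows.iloc[bg_idx].reset_index(drop=True)

    contrib = np.zeros((len(eval_rows), n_feat))
    states: list[pd.DataFrame] = []
    bookkeeping: list[tuple[int, np.ndarray]] = []
    for i in range(len(eval_rows)):
        for _ in range(n_permutations):
            order = rng.permutation(n_feat)
            base = background.iloc[int(rng.integers(len(background)))].copy()
            chain = [base.copy()]
            for f in order:
                base[features[f]] = eval_rows.iloc[i][features[f]]
                chain.append(base.copy())
            states.append(pd.DataFrame(chain).reset_index(drop=True))
            bookkeeping.append((i, order))

    big = pd.concat(states, ignore_index=True)
    for col in rows.columns:  # restore dtypes lost in row-wise assembly
        big[col] = big[col].astype(rows[col].dtype)
    preds = []
    for start in range(0, len(big), batch_rows):
        preds.append(np.asarray(model.predict_proba(big.iloc[start:start + batch_rows])))
    proba = np.vstack(preds)

    step = n_feat + 1
    counts = np.zeros((len(eval_rows), n_feat))
    for k, (i, order) in enumerate(bookkeeping):
        block = proba[k * step:(k + 1) * step]
        deltas = np.abs(np.diff(block, axis=0)).mean(axis=1)  # mean |d| over classes
        contrib[i, order] += deltas
        counts[i, order] += 1
    per_row = contrib / np.maximum(counts, 1)
    mean_abs = per_row.mean(axis=0)
    out = pd.DataFrame({"feature": features, "mean_abs_attribution": mean_abs})
    return out.sort_values("mean_abs_attribution", ascending=False,
                           kind="stable").reset_index(drop=True)
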