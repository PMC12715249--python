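"""Imbalance-aware multiclass evaluation for the CN / MCI / AD problem.

Conventions that matter and are easy to get wrong:

* Label coding is ordinal — CN = 0, MCI = 1, AD = 2 — so that the squared
  label difference ("ordinal MSE") penalizes CN<->AD confusions four
  times as much as adjacent-stage confusions.
* Balanced accuracy is the mean of macro-averaged sensitivity and
  macro-averaged specificity (not the plain mean of sensitivities): a
  single-class ("degenerate") predictor then scores exactly 50%.
* Precision and F1 use the 0/0 -> 0 convention, so a never-predicted
  class reports 0%, not NaN.
* Table-style percentages are rounded half-away-from-zero to integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

CLASSES = ("CN", "MCI", "AD")
LABEL_CODING = {"CN": 0, "MCI": 1, "AD": 2}


def round_half_away(x: float) -> int:
    """Round half away from zero (table convention), e.g. 0.5 -> 1."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


def _as_codes(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        try:
            return np.asarray([LABEL_CODING[str(v)] for v in arr])
        except KeyError as e:
            raise ValueError(f"unknown label {e.args[0]!r}") from None
    codes = arr.astype(int)
    if codes.size and not np.isin(codes, (0, 1, 2)).all():
        raise ValueError("integer labels must be 0 (CN), 1 (MCI) or 2 (AD)")
    return codes


def confusion_matrix(true_labels, predicted_labels) -> np.ndarray:
    """3x3 counts; rows = true class (CN, MCI, AD), columns = predicted."""
    t = _as_codes(true_labels)
    p = _as_codes(predicted_labels)
    if len(t) != len(p):
        raise ValueError("label vectors must have equal length")
    if len(t) == 0:
        raise ValueError("empty input")
    cm = np.zeros((3, 3), dtype=int)
    np.add.at(cm, (t, p), 1)
    return cm


def _ovr(cm: np.ndarray, k: int) -> tuple[int, int, int, int]:
    tp = cm[k, k]
    fn = cm[k].sum() - tp
    fp = cm[:, k].sum() - tp
    tn = cm.sum() - tp - fn - fp
    return int(tp), int(fp), int(fn), int(tn)


def _safe_div(a: float, b: float) -> float:
    return a / b if b else 0.0


def per_class_metrics(cm: np.ndarray) -> pd.DataFrame:
    """One-vs-rest precision / sensitivity / specificity / F1 / support."""
    rows = []
    for k, cls in enumerate(CLASSES):
        tp, fp, fn, tn = _ovr(cm, k)
        prec = _safe_div(tp, tp + fp)
        sens = _safe_div(tp, tp + fn)
        spec = _safe_div(tn, tn + fp)
        f1 = _safe_div(2 * prec * sens, prec + sens)
        rows.append({"class": cls, "precision": prec, "sensitivity": sens,
                     "specificity": spec, "f1": f1, "support": int(cm[k].sum())})
    return pd.DataFrame(rows).set_index("class")


def aggregate_metrics(cm: np.ndarray) -> dict:
    """Accuracy plus macro (unweighted) and weighted (support-proportional)
    averages of the per-class metrics."""
    per = per_class_metrics(cm)
    n = cm.sum()
    support = per["support"].to_numpy()
    out = {"accuracy": _safe_div(np.trace(cm), n), "n": int(n)}
    for metric in ("precision", "sensitivity", "specificity", "f1"):
        vals = per[metric].to_numpy()
        out[f"macro_{metric}"] = float(vals.mean())
        out[f"weighted_{metric}"] = float((vals * support).sum() / n)
    return out


def balanced_accuracy(cm: np.ndarray) -> float:
    """(macro sensitivity + macro specificity) / 2.

    This sensitivity-specificity form (rather than mean sensitivity
    alone) is the table convention here; it pins every degenerate
    one-class predictor at exactly 0.5.
    """
    agg = aggregate_metrics(cm)
    return (agg["macro_sensitivity"] + agg["macro_specificity"]) / 2.0


def ordinal_mse(true_labels, predicted_labels) -> float:
    """Mean squared difference of ordinal label codes, as a percentage."""
    t = _as_codes(true_labels)
    p = _as_codes(predicted_labels)
    return float(np.mean((t - p) ** 2) * 100.0)


def auc_metrics(scores: np.ndarray, true_labels) -> dict:
    """ROC AUC (micro over flattened one-vs-rest pairs; macro = mean of
    per-class AUCs with ties counted 1/2), macro AUC-PR, and multiclass MCC.

    Degenerate single-class truth makes a per-class AUC undefined; it is
    reported as 0.5.
    """
    S = np.asarray(scores, float)
    t = _as_codes(true_labels)
    if S.ndim != 2 or S.shape[1] != 3 or len(S) != len(t):
        raise ValueError("scores must be (n, 3) aligned with labels")
    if not np.all(np.isfinite(S)):
        raise ValueError("scores must be finite")
    onehot = np.eye(3)[t]
    # micro ROC expects row-normalized scores; normalize defensively
    row_sum = S.sum(axis=1, keepdims=True)
    Sn = np.divide(S, row_sum, out=np.full_like(S, 1 / 3), where=row_sum > 0)
    per_auc, per_ap = [], []
    for k in range(3):
        yk = onehot[:, k]
        if yk.min() == yk.max():
            per_auc.append(0.5)
            per_ap.append(float(yk.mean()) if yk.max() else 0.0)
            continue
        per_auc.append(float(roc_auc_score(yk, S[:, k])))
        per_ap.append(float(average_precision_score(yk, S[:, k])))
    micro = float(roc_auc_score(onehot.ravel(), Sn.ravel()))
    cm = confusion_matrix(t, S.argmax(axis=1))
    return {
        "roc_auc_micro": micro,
        "roc_auc_macro": float(np.mean(per_auc)),
        "auc_pr_macro": float(np.mean(per_ap)),
        "per_class_roc_auc": per_auc,
        "mcc": mcc(cm),
    }


def mcc(cm: np.ndarray) -> float:
    """Generalized (multiclass) Matthews correlation from the confusion matrix."""
    cm = np.asarray(cm, float)
    t_k = cm.sum(axis=1)
    p_k = cm.sum(axis=0)
    n = cm.sum()
    cov_tp = np.trace(cm) * n - t_k @ p_k
    denom = np.sqrt(n**2 - p_k @ p_k) * np.sqrt(n**2 - t_k @ t_k)
    return float(cov_tp / denom) if denom else 0.0


def _tv(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.abs(a - b).sum() / 2.0)


def bias_index(
    predicted_dist,
    true_dist,
    formula: Callable[[np.ndarray, np.ndarray], float] | None = None,
) -> float:
    """[0, 1] score of prediction-distribution collapse.

    Default formula: total-variation distance between the predicted and
    true class distributions, normalized by the distance a point mass on
    the predictor's modal class would attain — so any single-class
    predictor scores exactly 1.0 and a distribution-matched predictor
    scores 0. A different formula can be supplied as a callable.
    """
    p_hat = np.asarray(predicted_dist, float)
    p = np.asarray(true_dist, float)
    p_hat = p_hat / p_hat.sum()
    p = p / p.sum()
    if formula is not None:
        return float(formula(p_hat, p))
    modal = int(np.argmax(p_hat))
    point = np.zeros(3)
    point[modal] = 1.0
    denom = _tv(point, p)
    return float(np.clip(_safe_div(_tv(p_hat, p), denom), 0.0, 1.0))


def degenerate_predictions(test_counts: dict[str, int], target_class: str
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixture vectors for a predictor that outputs one fixed class.

    Returns (true labels, predicted labels, one-hot scores) for a test
    set with the given per-class counts.
    """
    if any(v < 0 for v in test_counts.values()) or sum(test_counts.values()) == 0:
        raise ValueError("counts must be nonnegative with positive total")
    if target_class not in CLASSES:
        raise ValueError(f"unknown target class {target_class!r}")
    true = np.concatenate([
        np.full(test_counts.get(c, 0), LABEL_CODING[c], dtype=int) for c in CLASSES
    ])
    pred = np.full(len(true), LABEL_CODING[target_class], dtype=int)
    scores = np.zeros((len(true), 3))
    scores[:, LABEL_CODING[target_class]] = 1.0
    return true, pred, scores


@dataclass
class MetricReport:
    confusion: np.ndarray
    per_class: pd.DataFrame
    aggregates: dict
    balanced_accuracy: float
    ordinal_mse_percent: float
    auc: dict
    bias_index: float

    def summary_percent(self) -> dict:
        """Table-style integer-percent summary (half-away-from-zero)."""
        a = self.aggregates
        return {
            "accuracy": round_half_away(100 * a["accuracy"]),
            "macro_precision": round_half_away(100 * a["macro_precision"]),
            "macro_sensitivity": round_half_away(100 * a["macro_sensitivity"]),
            "macro_specificity": round_half_away(100 * a["macro_specificity"]),
            "macro_f1": round_half_away(100 * a["macro_f1"]),
            "balanced_accuracy": round_half_away(100 * self.balanced_accuracy),
            "mse_percent": round_half_away(self.ordinal_mse_percent),
            "roc_auc_micro": round_half_away(100 * self.auc["roc_auc_micro"]),
            "roc_auc_macro": round_half_away(100 * self.auc["roc_auc_macro"]),
        }


def evaluate(true_labels, predicted_labels, scores: np.ndarray | None = None
             ) -> MetricReport:
    """Full metric report from labels (and optionally scores for AUCs)."""
    t = _as_codes(true_labels)
    p = _as_codes(predicted_labels)
    cm = confusion_matrix(t, p)
    if scores is None:
        scores = np.eye(3)[p]
    auc = auc_metrics(scores, t)
    pred_dist = np.bincount(p, minlength=3) / len(p)
    true_dist = np.bincount(t, minlength=3) / len(t)
    return MetricReport(
        confusion=cm,
        per_class=per_class_metrics(cm),
        aggregates=aggregate_metrics(cm),
        balanced_accuracy=balanced_accuracy(cm),
        ordinal_mse_percent=ordinal_mse(t, p),
        auc=auc,
        bias_index=bias_index(pred_dist, true_dist),
    )


def rank_models(table: pd.DataFrame) -> pd.DataFrame:
    """Rank a model-metadata table by performance score.

    Each numeric criterion is min-max normalized to [0, 1] (constant
    columns map to 0); rows are sorted by performance score descending,
    ties broken by top5 descending then param_count ascending.
    """
    if table.empty:
        raise ValueError("empty table")
    required = {"top1", "top5", "param_count", "performance_score"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = table.copy()
    for col in ("top1", "top5", "param_count", "performance_score"):
        v = out[col].astype(float)
        span = v.max() - v.min()
        out[f"{col}_norm"] = (v - v.min()) / span if span > 0 else 0.0
    out = out.sort_values(
        by=["performance_score", "top5", "param_count"],
        ascending=[False, False, True],
        kind="stable",
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out
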