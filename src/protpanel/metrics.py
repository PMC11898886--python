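"""Confusion-matrix arithmetic and macro one-vs-rest metrics.

Class order is fixed to (healthy, localized, metastatic); rows are true
classes, columns predicted.  Accuracy is reported as a percentage to two
decimals.  Sensitivity/specificity are macro-averaged one-vs-rest: per-class
recall and true-negative rate, unweighted mean over the three classes —
a documented convention, since several reasonable conventions exist.
"""

from __future__ import annotations

import warnings

import numpy as np

from .panel import GROUPS


def confusion_matrix(y_true, y_pred, classes: tuple[str, ...] = GROUPS) -> np.ndarray:
    """3x3 count matrix, rows = true class, columns = predicted class."""
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred, strict=True):
        cm[idx[t], idx[p]] += 1
    return cm


def _check_cm(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("negative confusion-matrix entry")
    if cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    return cm


def accuracy(cm: np.ndarray) -> float:
    """Overall accuracy in percent, truncated to 2 decimals.

    The two-decimal figure truncates rather than rounds (137/146 ->
    93.83%, not 93.84%), matching the reporting convention of the
    confusion-matrix literature this layout follows.
    """
    cm = _check_cm(cm)
    pct = 100.0 * np.trace(cm) / cm.sum()
    return float(np.floor(pct * 100.0 + 1e-9) / 100.0)


def macro_metrics(cm: np.ndarray, classes: tuple[str, ...] = GROUPS) -> dict:
    """Per-class recall/specificity and their unweighted (macro) means.

    Classes with an all-zero row (no true samples) are excluded from the
    macro mean with a warning.
    """
    cm = _check_cm(cm)
    total = cm.sum()
    recalls, specs = {}, {}
    included = []
    for i, cls in enumerate(classes):
        row = cm[i].sum()
        if row == 0:
            warnings.warn(f"class {cls!r} has no true samples; excluded "
                          "from macro averages", stacklevel=2)
            continue
        tp = cm[i, i]
        fn = row - tp
        fp = cm[:, i].sum() - tp
        tn = total - tp - fn - fp
        recalls[cls] = tp / row
        specs[cls] = tn / (tn + fp) if (tn + fp) > 0 else np.nan
        included.append(cls)
    return {
        "per_class_recall": recalls,
        "per_class_specificity": specs,
        "macro_sensitivity": float(np.mean([recalls[c] for c in included])),
        "macro_specificity": float(np.mean([specs[c] for c in included])),
    }
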