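"""AAMI-style per-class metrics and the 4x4 confusion matrix.

Per class c, one-vs-rest counts are derived from the confusion matrix:
TP = cm[c,c]; FN = row sum - TP; FP = column sum - TP; TN = the rest.
Sensitivity Sen = TP/(TP+FN), positive predictive value PPV = TP/(TP+FP)
and per-class accuracy Acc = (TP+TN)/total are reported alongside the
overall accuracy trace/total.  Per-class Acc is one-vs-rest, which is
why it can exceed the overall accuracy for rare classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import AAMI_CLASSES


@dataclass
class ConfusionMatrix:
    counts: np.ndarray                       # (k, k) ints, rows = true class
    classes: tuple[str, ...] = AAMI_CLASSES

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClassMetrics:
    classes: tuple[str, ...]
    sen: np.ndarray        # per class; NaN when the class has no true beats
    ppv: np.ndarray        # NaN when the class was never predicted
    acc: np.ndarray        # one-vs-rest accuracy per class
    overall_acc: float
    macro_sen: float       # macro means over defined classes
    macro_ppv: float
    macro_acc: float


def confusion(true_labels, predicted_labels,
              classes: tuple[str, ...] = AAMI_CLASSES) -> ConfusionMatrix:
    """Count matrix: counts[i, j] = beats of true class i predicted as j."""
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors differ in length")
    index = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"label outside alphabet {classes}: ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class Sen/PPV/one-vs-rest Acc plus overall and macro averages."""
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts).astype(float)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = total - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sen = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        ppv = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
    acc = (tp + tn) / total
    overall = float(tp.sum() / total)
    return ClassMetrics(
        classes=cm.classes,
        sen=sen, ppv=ppv, acc=acc,
        overall_acc=overall,
        macro_sen=float(np.nanmean(sen)),
        macro_ppv=float(np.nanmean(ppv)),
        macro_acc=float(np.mean(acc)),
    )


def report(cm: ConfusionMatrix) -> str:
    """Plain-text table: Sen/PPV/Acc per class plus a macro-average row."""
    m = metrics(cm)
    lines = [f"{'Type':<8}{'Sen (%)':>10}{'PPV (%)':>10}{'Acc (%)':>10}"]
    def fmt(v):
        return "   --" if np.isnan(v) else f"{100 * v:9.1f}"
    for i, c in enumerate(m.classes):
        lines.append(f"{c:<8}{fmt(m.sen[i]):>10}{fmt(m.ppv[i]):>10}{fmt(m.acc[i]):>10}")
    lines.append(
        f"{'Average':<8}{fmt(m.macro_sen):>10}{fmt(m.macro_ppv):>10}{fmt(m.macro_acc):>10}"
    )
    lines.append(f"Overall accuracy: {100 * m.overall_acc:.1f}%")
    return "\n".join(lines)
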