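"""Evaluation surfaces: leaf- and root-level confusion matrices and metrics.

Predictions are scored twice: over the six fine posture labels (leaf level)
and over their three branch categories — straight / forward / backward
posture (root level).  Collapsing to the root merges confusions between
sibling leaves into diagonal cells, so root-level accuracy can never fall
below leaf-level accuracy on tree-decoded predictions.

Sensitivity, specificity and F-score are one-vs-rest per class and
macro-averaged (stated explicitly in all outputs); Cohen's kappa uses the
marginal-product expected agreement.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .hierarchy import PostureTree, root_label

__all__ = ["ConfusionMatrix", "MetricsReport", "confusion", "collapse_to_root",
           "metrics"]


@dataclass
class ConfusionMatrix:
    """Counts with rows = truth, columns = prediction, in a fixed label order."""

    labels: list[str]
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_percent(self) -> np.ndarray:
        """Row-normalized percentages; zero rows stay zero."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums > 0, 100.0 * self.counts / sums, 0.0)
        return pct

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["truth\\prediction"] + self.labels)
            for lbl, row in zip(self.labels, self.counts):
                w.writerow([lbl] + [int(v) for v in row])
            w.writerow([])
            w.writerow(["row %"] + self.labels)
            for lbl, row in zip(self.labels, self.row_percent):
                w.writerow([lbl] + [f"{v:.2f}" for v in row])


@dataclass
class MetricsReport:
    """Macro-averaged one-vs-rest metric set plus per-class detail."""

    accuracy: float
    sensitivity: float
    specificity: float
    f_score: float
    kappa: float
    per_class: dict[str, dict[str, float]]
    averaging: str = "macro"

    def summary(self) -> str:
        lines = [
            f"accuracy    {self.accuracy:.4f}",
            f"sensitivity {self.sensitivity:.4f}  ({self.averaging})",
            f"specificity {self.specificity:.4f}  ({self.averaging})",
            f"f-score     {self.f_score:.4f}  ({self.averaging})",
            f"kappa       {self.kappa:.4f}",
        ]
        for lbl, d in self.per_class.items():
            lines.append(
                f"  {lbl:20s} sens {d['sensitivity']:.4f}  "
                f"spec {d['specificity']:.4f}  prec {d['precision']:.4f}"
            )
        return "\n".join(lines)


def _validate(truths, preds, labels):
    if len(truths) != len(preds):
        raise ValueError(f"{len(truths)} truths vs {len(preds)} predictions")
    if len(truths) == 0:
        raise ValueError("empty evaluation set")
    known = set(labels)
    for name, seq in (("truth", truths), ("prediction", preds)):
        bad = sorted({x for x in seq if x not in known})
        if bad:
            raise ValueError(f"unknown {name} label(s): {bad}")


def confusion(truths, preds, labels) -> ConfusionMatrix:
    """Exact tallies of truth/prediction pairs in the given label order."""
    _validate(truths, preds, labels)
    counts = _sk_confusion(truths, preds, labels=list(labels))
    return ConfusionMatrix(labels=list(labels), counts=counts.astype(np.int64))


def collapse_to_root(
    arg1=None, arg2=None, *, tree: PostureTree, cm: ConfusionMatrix | None = None
) -> ConfusionMatrix:
    """Root-level (3-class) confusion, from label lists or from a leaf matrix.

    ``collapse_to_root(truths, preds, tree=tree)`` maps every leaf through
    its root branch before tallying; ``collapse_to_root(cm=leaf_cm,
    tree=tree)`` aggregates an existing matrix.  Total count is preserved.
    """
    root_order = [r.branch_label for r in tree.roots]
    if cm is not None:
        idx = {lbl: root_order.index(root_label(tree, lbl)) for lbl in cm.labels}
        counts = np.zeros((len(root_order), len(root_order)), dtype=np.int64)
        for i, ti in enumerate(cm.labels):
            for j, pj in enumerate(cm.labels):
                counts[idx[ti], idx[pj]] += cm.counts[i, j]
        return ConfusionMatrix(labels=root_order, counts=counts)
    truths, preds = arg1, arg2
    _validate(truths, preds, tree.leaf_names)
    rt = [root_label(tree, x) for x in truths]
    rp = [root_label(tree, x) for x in preds]
    return confusion(rt, rp, root_order)


def metrics(truths, preds, labels) -> MetricsReport:
    """Accuracy, macro sensitivity/specificity/F-score and Cohen's kappa.

    The F-score is the harmonic mean of macro precision and macro
    sensitivity; kappa is (p_o - p_e) / (1 - p_e) with marginal-product
    expected agreement p_e.
    """
    cm = confusion(truths, preds, labels)
    counts = cm.counts.astype(np.float64)
    total = counts.sum()
    accuracy = np.trace(counts) / total

    per_class = {}
    sens_list, spec_list, prec_list = [], [], []
    for i, lbl in enumerate(cm.labels):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn > 0 else 0.0
        spec = tn / (tn + fp) if tn + fp > 0 else 0.0
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        per_class[lbl] = {
            "sensitivity": sens, "specificity": spec, "precision": prec,
        }
        sens_list.append(sens)
        spec_list.append(spec)
        prec_list.append(prec)

    macro_sens = float(np.mean(sens_list))
    macro_spec = float(np.mean(spec_list))
    macro_prec = float(np.mean(prec_list))
    f_score = (
        2 * macro_prec * macro_sens / (macro_prec + macro_sens)
        if macro_prec + macro_sens > 0
        else 0.0
    )
    p_o = accuracy
    p_e = float((counts.sum(axis=1) * counts.sum(axis=0)).sum() / total**2)
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0

    return MetricsReport(
        accuracy=float(accuracy),
        sensitivity=macro_sens,
        specificity=macro_spec,
        f_score=float(f_score),
        kappa=float(kappa),
        per_class=per_class,
    )
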