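"""Evaluation protocol for the calibrated classifier.

The central question is open-set: does the classifier assign in-scope
(sinonasal-spectrum) tumors to a methylation class while rejecting
out-of-scope tumors as Unknown?  All in-scope class predictions are
retrospectively collapsed into a single outcome, giving a binary
contingency table against the Unknown outcome, from which

* outlier-detection **sensitivity** — fraction of in-scope samples given
  any in-scope class,
* outlier-detection **specificity** — fraction of out-of-scope samples
  assigned Unknown,
* **per-category specificity** — the same fraction within each coarse
  out-of-scope category,
* **conditional accuracy** — class accuracy over in-scope samples *not*
  rejected as Unknown, and
* the ROC curve / AUC of the continuous outlier score
  ``1 - P(Unknown)``

are derived.  Reported proportions are rounded half-up to three
decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .classify import UNKNOWN
from .data import SampleSheet

__all__ = [
    "round3",
    "collapse_binary",
    "outlier_metrics",
    "per_category_specificity",
    "conditional_accuracy",
    "roc_auc",
    "EvaluationReport",
    "evaluate_predictions",
]


def round3(x: float) -> float:
    """Round half-up to three decimals (report formatting)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"),
                                                  rounding=ROUND_HALF_UP))


def collapse_binary(predictions, truth) -> pd.DataFrame:
    """Collapse class predictions into the binary outlier problem.

    `truth` holds "in_scope" / "out_of_scope" per sample (any in-scope
    class label is also accepted and mapped to "in_scope");
    `predictions` are trained-class labels including Unknown, collapsed
    to "in_scope" (any class) vs "Unknown".  Returns the 2x2 table with
    truth rows [in_scope, out_of_scope] and prediction columns
    [in_scope, Unknown].
    """
    predictions = np.asarray(predictions, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(predictions) == 0:
        raise ValueError("empty input")
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must align")
    truth_bin = np.where(truth == "out_of_scope", "out_of_scope", "in_scope")
    pred_bin = np.where(predictions == UNKNOWN, UNKNOWN, "in_scope")
    table = pd.DataFrame(0, index=["in_scope", "out_of_scope"],
                         columns=["in_scope", UNKNOWN])
    for t, p in zip(truth_bin, pred_bin):
        table.loc[t, p] += 1
    return table


def outlier_metrics(table: pd.DataFrame) -> tuple[float, float]:
    """(sensitivity, specificity) of the binary outlier problem.

    Sensitivity: in-scope samples assigned any in-scope class.
    Specificity: out-of-scope samples assigned Unknown.
    Both rounded half-up to three decimals.
    """
    t = table.to_numpy(dtype=float)
    n_in, n_out = t[0].sum(), t[1].sum()
    if n_in == 0 or n_out == 0:
        raise ValueError("degenerate contingency table (empty margin)")
    return round3(t[0, 0] / n_in), round3(t[1, 1] / n_out)


def per_category_specificity(predictions, sheet: SampleSheet | pd.Series) -> dict:
    """Fraction of out-of-scope samples predicted Unknown, per category."""
    cats = sheet.table["category"] if isinstance(sheet, SampleSheet) else sheet
    predictions = np.asarray(predictions, dtype=object)
    if len(predictions) != len(cats):
        raise ValueError("predictions and categories must align")
    if cats.isna().any():
        raise ValueError("every sample must carry a category")
    out = {}
    for cat in sorted(cats.unique()):
        mask = (cats == cat).to_numpy()
        out[cat] = round3((predictions[mask] == UNKNOWN).mean())
    return out


def conditional_accuracy(predictions, truth_labels) -> float:
    """Accuracy over in-scope test samples not rejected as Unknown."""
    predictions = np.asarray(predictions, dtype=object)
    truth_labels = np.asarray(truth_labels, dtype=object)
    keep = predictions != UNKNOWN
    if not keep.any():
        raise ValueError("all samples predicted Unknown; "
                         "conditional accuracy undefined")
    return round3((predictions[keep] == truth_labels[keep]).mean())


def roc_auc(binary_truth, scores):
    """ROC curve and AUC for the binary outlier problem.

    `binary_truth`: 1/True for in-scope samples; `scores`: the outlier
    score per sample, 1 - P(Unknown).  The curve is a threshold sweep
    over the unique scores, AUC by trapezoid; with the half-tie
    convention this equals the Mann-Whitney concordance probability.
    """
    y = np.asarray(binary_truth).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required for a ROC curve")
    fpr, tpr, _ = roc_curve(y, s)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


@dataclass
class EvaluationReport:
    """Full test-set evaluation."""

    confusion: pd.DataFrame          # true category x predicted class counts
    outlier_sensitivity: float
    outlier_specificity: float
    per_category_specificity: dict
    conditional_accuracy: float
    roc_points: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        props = [self.outlier_sensitivity, self.outlier_specificity,
                 self.conditional_accuracy, self.auc,
                 *self.per_category_specificity.values()]
        if any(not (0 <= p <= 1) for p in props):
            raise ValueError("proportions must lie in [0, 1]")
        if len(self.roc_points):
            if not (np.allclose(self.roc_points[0], [0, 0])
                    and np.allclose(self.roc_points[-1], [1, 1])):
                raise ValueError("ROC must start at (0,0) and end at (1,1)")

    def summary(self) -> str:
        lines = [
            "Evaluation report",
            f"  outlier sensitivity : {self.outlier_sensitivity:.3f}",
            f"  outlier specificity : {self.outlier_specificity:.3f}",
            f"  conditional accuracy: {self.conditional_accuracy:.3f}",
            f"  outlier-detection AUC: {self.auc:.4f}",
            "  per-category specificity:",
        ]
        for cat, v in self.per_category_specificity.items():
            lines.append(f"    {cat}: {v:.3f}")
        return "\n".join(lines)

    def write(self, directory) -> None:
        from pathlib import Path
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        (d / "summary.txt").write_text(self.summary() + "\n")
        self.confusion.to_csv(d / "confusion.tsv", sep="\t",
                              index_label="true_category")
        pd.DataFrame(self.roc_points, columns=["fpr", "tpr"]).to_csv(
            d / "roc.tsv", sep="\t", index=False, float_format="%.10g")


def evaluate_predictions(predictions, probabilities: pd.DataFrame,
                         sheet: SampleSheet, in_scope_category: str = "sinonasal",
                         truth_labels=None) -> EvaluationReport:
    """Assemble the full report for a test cohort.

    `sheet` supplies per-sample category (``in_scope_category`` marks the
    in-scope samples) and, via its label column (or `truth_labels`), the
    true class of in-scope samples.  `probabilities` must contain an
    Unknown column for the ROC score.
    """
    predictions = np.asarray(predictions, dtype=object)
    cats = sheet.table["category"]
    in_scope = (cats == in_scope_category).to_numpy()
    truth_bin = np.where(in_scope, "in_scope", "out_of_scope")
    table = collapse_binary(predictions, truth_bin)
    sens, spec = outlier_metrics(table)

    cat_spec = per_category_specificity(predictions[~in_scope], cats[~in_scope])

    truth_labels = (np.asarray(truth_labels, dtype=object) if truth_labels is not None
                    else sheet.table["label"].to_numpy(dtype=object))
    cond_acc = conditional_accuracy(predictions[in_scope], truth_labels[in_scope])

    score = 1.0 - probabilities[UNKNOWN].to_numpy(dtype=float)
    roc_points, auc_value = roc_auc(in_scope.astype(int), score)

    confusion = pd.crosstab(pd.Series(cats.to_numpy(), name="true_category"),
                            pd.Series(predictions, name="predicted_class"))
    return EvaluationReport(
        confusion=confusion,
        outlier_sensitivity=sens,
        outlier_specificity=spec,
        per_category_specificity=cat_spec,
        conditional_accuracy=cond_acc,
        roc_points=roc_points,
        auc=auc_value,
    )
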