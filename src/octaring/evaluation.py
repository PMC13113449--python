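"""Patient-level data splitting and classification metrics.

Scans from one patient are correlated (1-2 eyes/maps per person), so all
partitioning here is grouped by ``patient_id``: a patient's images are
never divided across train and test, nor across cross-validation folds.
Metrics are the standard one-vs-rest precision, recall, F1 and overall
accuracy, macro-averaged over the three grades by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CLASS_LABELS

__all__ = [
    "SplitPlan",
    "EvaluationReport",
    "patient_level_split",
    "kfold_plan",
    "compute_metrics",
]


@dataclass(frozen=True)
class SplitPlan:
    """Image-level partition assignments derived from a patient-level draw.

    ``assignments`` maps manifest row position to ``"train"``/``"test"``
    (holdout mode) or to an integer fold id (kfold mode).
    """

    mode: str  # "holdout" | "kfold"
    assignments: tuple = field(repr=False)
    seed: int = 0
    n_folds: int | None = None

    def train_indices(self) -> np.ndarray:
        if self.mode != "holdout":
            raise ValueError("train_indices is only defined for holdout plans")
        a = np.asarray(self.assignments)
        return np.flatnonzero(a == "train")

    def test_indices(self) -> np.ndarray:
        if self.mode != "holdout":
            raise ValueError("test_indices is only defined for holdout plans")
        a = np.asarray(self.assignments)
        return np.flatnonzero(a == "test")

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, test) row positions for one cross-validation fold."""
        if self.mode != "kfold":
            raise ValueError("fold_indices is only defined for kfold plans")
        a = np.asarray(self.assignments)
        return np.flatnonzero(a != fold), np.flatnonzero(a == fold)


def _patient_labels(manifest: pd.DataFrame) -> pd.Series:
    """Majority label per patient (ties broken by fixed class order)."""

    def majority(labels: pd.Series) -> str:
        counts = labels.value_counts()
        top = counts[counts == counts.max()].index
        for c in CLASS_LABELS:
            if c in top:
                return c
        return top[0]

    return manifest.groupby("patient_id")["label"].agg(majority)


def patient_level_split(
    manifest: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> SplitPlan:
    """Stratified patient-level holdout split.

    Patients (not images) are sampled into the test set at
    ``test_fraction``, stratified by each patient's majority label with
    largest-remainder apportionment so the total test patient count equals
    ``round(test_fraction * n_patients)``.

    Raises if any class would be absent from either partition.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    if "patient_id" not in manifest.columns:
        raise ValueError("manifest has no patient_id column")
    pat_label = _patient_labels(manifest)
    rng = np.random.default_rng(seed)

    classes = [c for c in CLASS_LABELS if c in set(pat_label)]
    per_class = {c: pat_label.index[pat_label == c].to_numpy() for c in classes}
    n_total = len(pat_label)
    n_test_total = int(round(test_fraction * n_total))

    # largest-remainder apportionment of the test quota across classes;
    # every class keeps at least one training patient, and the total test
    # patient count is exactly round(test_fraction * n_patients)
    exact = {c: test_fraction * len(per_class[c]) for c in classes}
    quota = {c: min(int(np.floor(exact[c])), len(per_class[c]) - 1) for c in classes}
    remainders = sorted(classes, key=lambda c: exact[c] - quota[c], reverse=True)
    i = 0
    while sum(quota.values()) < n_test_total and i < 10 * len(classes):
        c = remainders[i % len(classes)]
        if quota[c] < len(per_class[c]) - 1:
            quota[c] += 1
        i += 1
    while sum(quota.values()) > n_test_total:
        c = max(classes, key=lambda c: quota[c])
        quota[c] -= 1

    test_patients: set = set()
    for c in classes:
        pats = np.sort(per_class[c])
        rng.shuffle(pats)
        test_patients.update(pats[: quota[c]])

    assignments = tuple(
        "test" if p in test_patients else "train" for p in manifest["patient_id"]
    )
    plan = SplitPlan(mode="holdout", assignments=assignments, seed=seed)
    # class presence is only enforceable when the quota has room for every
    # class (tiny cohorts may not admit a fully stratified test set)
    stratifiable = n_test_total >= len(classes)
    for part, idx in (("train", plan.train_indices()), ("test", plan.test_indices())):
        if part == "test" and not stratifiable:
            continue
        present = set(manifest["label"].iloc[idx])
        absent = [c for c in classes if c not in present]
        if absent:
            raise ValueError(
                f"class(es) {absent} absent from the {part} partition; "
                "try a different seed or test_fraction"
            )
    return plan


def kfold_plan(manifest: pd.DataFrame, k: int = 5, seed: int = 0) -> SplitPlan:
    """Patient-grouped, class-stratified k-fold assignment.

    Within each class, shuffled patients are dealt round-robin to folds,
    so folds are near-equal in patient count and every image lands in
    exactly one fold.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    pat_label = _patient_labels(manifest)
    if k > len(pat_label):
        raise ValueError(f"k={k} exceeds the {len(pat_label)} available patients")
    rng = np.random.default_rng(seed)

    fold_of: dict = {}
    # rotate the starting fold between classes so fold sizes stay balanced
    offset = 0
    for c in CLASS_LABELS:
        pats = np.sort(pat_label.index[pat_label == c].to_numpy())
        if len(pats) == 0:
            continue
        rng.shuffle(pats)
        for j, p in enumerate(pats):
            fold_of[p] = (j + offset) % k
        offset += len(pats)
    assignments = tuple(fold_of[p] for p in manifest["patient_id"])
    return SplitPlan(mode="kfold", assignments=assignments, seed=seed, n_folds=k)


@dataclass(frozen=True)
class EvaluationReport:
    """Three-class metrics and the confusion matrix they derive from.

    ``confusion[i, j]`` counts images of true class ``class_order[i]``
    predicted as ``class_order[j]``.  Precision, recall and F1 are
    one-vs-rest per class, then averaged (macro by default).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: tuple  # nested tuples, row = true class
    n_test: int
    class_order: tuple = CLASS_LABELS
    averaging: str = "macro"

    def confusion_matrix(self) -> np.ndarray:
        return np.asarray(self.confusion, dtype=int)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion_matrix": [list(r) for r in self.confusion],
            "n_test": self.n_test,
            "class_order": list(self.class_order),
            "averaging": self.averaging,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def plot_confusion(self, path: str) -> None:
        """Render the confusion matrix as a PNG heatmap."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        cm = self.confusion_matrix()
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(cm, cmap="Blues")
        ax.set_xticks(range(len(self.class_order)), self.class_order)
        ax.set_yticks(range(len(self.class_order)), self.class_order)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(cm.shape[0]):
            for j in range(cm.shape[1]):
                ax.text(j, i, cm[i, j], ha="center", va="center")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def compute_metrics(
    y_true, y_pred, averaging: str = "macro"
) -> EvaluationReport:
    """Accuracy, one-vs-rest precision/recall/F1 and the confusion matrix.

    Per class ``c``: TP = correctly predicted c, FP = predicted c but not c,
    FN = true c missed; precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R) (0 where undefined).  ``averaging`` is ``"macro"``
    (unweighted class mean) or ``"weighted"`` (by class support).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape} true vs {y_pred.shape} predicted"
        )
    unknown = (set(y_true) | set(y_pred)) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown label(s) {sorted(unknown)}")
    if averaging not in ("macro", "weighted"):
        raise ValueError(f"averaging must be macro or weighted, got {averaging!r}")

    k = len(CLASS_LABELS)
    idx = {c: i for i, c in enumerate(CLASS_LABELS)}
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1

    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    if averaging == "macro":
        weights = np.full(k, 1.0 / k)
    else:
        support = cm.sum(axis=1)
        weights = support / support.sum()
    return EvaluationReport(
        accuracy=float(tp.sum() / cm.sum()),
        precision=float(prec @ weights),
        recall=float(rec @ weights),
        f1=float(f1 @ weights),
        confusion=tuple(tuple(int(v) for v in row) for row in cm),
        n_test=int(cm.sum()),
        averaging=averaging,
    )
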