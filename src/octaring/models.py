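"""Regional classifier bank: ten algorithms, one winner per annulus.

Each concentric region yields its own 9-feature dataset, and every
algorithm in the bank is trained on every regional dataset.  The bank
spans diverse model families (linear, instance-based, kernel, single
trees, bagging and boosting ensembles) with fixed tuned hyperparameters;
the accuracy-maximizing algorithm is then assigned to each region.

Scale-sensitive models (LR, SVM, KNN) are standardized with statistics
fit on training rows only.  KNN's neighborhood size is chosen between 3
and 7 per region on an inner validation split.  All randomness is
controlled by each bank member's ``random_seed``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvaluationReport, SplitPlan, compute_metrics
from .features import CLASS_LABELS, PercentileConfig, n_regions_of_table, region_columns

__all__ = [
    "ALGORITHM_ORDER",
    "ClassifierSpec",
    "FittedModel",
    "RegionalModelReport",
    "default_bank",
    "train_classifier",
    "evaluate_bank_per_region",
    "select_best_per_region",
    "save_regional_models",
    "load_regional_models",
]

#: Fixed bank order, used as the final tie-break in winner selection.
ALGORITHM_ORDER = (
    "KNN", "LR", "SVM", "RF", "DT", "ET", "XGB", "AdaBoost", "LGBM", "Bagging",
)

_SCALED = frozenset({"LR", "SVM", "KNN"})


@dataclass(frozen=True)
class ClassifierSpec:
    """One bank member: algorithm id, tuned hyperparameters, seed."""

    algorithm_id: str
    hyperparameters: dict = field(default_factory=dict)
    random_seed: int = 42

    def __post_init__(self) -> None:
        if self.algorithm_id not in ALGORITHM_ORDER:
            raise ValueError(
                f"unknown algorithm {self.algorithm_id!r}; "
                f"expected one of {ALGORITHM_ORDER}"
            )

    def to_dict(self) -> dict:
        return {
            "algorithm_id": self.algorithm_id,
            "hyperparameters": dict(self.hyperparameters),
            "random_seed": self.random_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassifierSpec":
        return cls(
            algorithm_id=d["algorithm_id"],
            hyperparameters=dict(d["hyperparameters"]),
            random_seed=int(d["random_seed"]),
        )


def default_bank(random_seed: int = 42) -> list[ClassifierSpec]:
    """The ten-member bank with its tuned hyperparameters.

    KNN lists both admissible neighborhood sizes (3 and 7); the choice is
    made per region on an inner validation split at training time.
    """
    hp = {
        "KNN": {"n_neighbors": [3, 7], "p": 2},
        "LR": {"C": 1.0, "penalty": "l2", "max_iter": 100},
        "SVM": {"C": 1.0, "gamma": "scale", "kernel": "rbf"},
        "RF": {"n_estimators": 100},
        "DT": {"max_depth": 80, "criterion": "entropy"},
        "ET": {"n_estimators": 100, "max_depth": 10},
        "XGB": {"n_estimators": 80, "max_depth": 8, "learning_rate": 0.05},
        "AdaBoost": {"base_estimator": "decision_tree", "n_estimators": 100},
        "LGBM": {"num_leaves": 31, "n_estimators": 100, "max_depth": 1},
        "Bagging": {
            "base_estimator": "decision_tree",
            "n_estimators": 50,
            "bootstrap": True,
        },
    }
    return [
        ClassifierSpec(a, hyperparameters=hp[a], random_seed=random_seed)
        for a in ALGORITHM_ORDER
    ]


def _build_estimator(spec: ClassifierSpec, n_neighbors: int | None = None):
    from sklearn.ensemble import (
        AdaBoostClassifier,
        BaggingClassifier,
        ExtraTreesClassifier,
        RandomForestClassifier,
    )
    from sklearn.linear_model import LogisticRegression
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import Pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    hp = spec.hyperparameters
    seed = spec.random_seed
    a = spec.algorithm_id
    if a == "KNN":
        k = n_neighbors if n_neighbors is not None else 3
        est = KNeighborsClassifier(n_neighbors=k, p=hp.get("p", 2))
    elif a == "LR":
        # penalty "l2" is sklearn's default and explicit penalty= is
        # deprecated in 1.8, so it stays in the hyperparameter record only
        est = LogisticRegression(
            C=hp["C"], max_iter=hp["max_iter"], random_state=seed
        )
    elif a == "SVM":
        # probability calibration enabled so the voter exposes a smooth
        # per-class score for the surrogate explainer
        est = SVC(
            C=hp["C"], gamma=hp["gamma"], kernel=hp["kernel"],
            probability=True, random_state=seed,
        )
    elif a == "RF":
        est = RandomForestClassifier(
            n_estimators=hp["n_estimators"], random_state=seed
        )
    elif a == "DT":
        est = DecisionTreeClassifier(
            max_depth=hp["max_depth"], criterion=hp["criterion"], random_state=seed
        )
    elif a == "ET":
        est = ExtraTreesClassifier(
            n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
            random_state=seed,
        )
    elif a == "XGB":
        from xgboost import XGBClassifier

        est = XGBClassifier(
            n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
            learning_rate=hp["learning_rate"], random_state=seed,
            verbosity=0, n_jobs=1,
        )
    elif a == "AdaBoost":
        # weak-learner depth-3 trees; full-depth trees leave boosting no
        # residual to reweight
        est = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=3, random_state=seed),
            n_estimators=hp["n_estimators"], random_state=seed,
        )
    elif a == "LGBM":
        from lightgbm import LGBMClassifier

        est = LGBMClassifier(
            num_leaves=hp["num_leaves"], n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"], random_state=seed, verbose=-1, n_jobs=1,
        )
    elif a == "Bagging":
        est = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=seed),
            n_estimators=hp["n_estimators"], bootstrap=hp["bootstrap"],
            random_state=seed,
        )
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(a)
    if a in _SCALED:
        est = Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


@dataclass
class FittedModel:
    """A trained bank member with its fixed label ordering."""

    spec: ClassifierSpec
    estimator: object
    class_order: tuple = CLASS_LABELS
    classes_seen: tuple = CLASS_LABELS  # training classes, fixed order

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        with warnings.catch_warnings():
            # LightGBM records auto-generated column names at fit time and
            # sklearn then warns on unnamed ndarray input; benign here
            warnings.filterwarnings(
                "ignore", message=".*does not have valid feature names.*"
            )
            codes = self.estimator.predict(X)
        lut = np.asarray(self.classes_seen, dtype=object)
        return lut[np.asarray(codes, dtype=int)]


def _encode(y, classes_seen) -> np.ndarray:
    idx = {c: i for i, c in enumerate(classes_seen)}
    return np.asarray([idx[v] for v in y], dtype=int)


def train_classifier(
    spec: ClassifierSpec, features, labels, n_neighbors: int | None = None
) -> FittedModel:
    """Fit one bank member.

    Requires at least two classes and finite features.  For KNN with the
    two-valued neighborhood size, the caller passes the chosen
    ``n_neighbors`` (see :func:`evaluate_bank_per_region`); left unset it
    defaults to 3.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("features must be 2-D with one row per label")
    if np.isnan(X).any():
        raise ValueError("features contain NaN")
    classes_seen = tuple(c for c in CLASS_LABELS if c in set(y))
    if len(classes_seen) < 2:
        raise ValueError("training set contains a single class")
    est = _build_estimator(spec, n_neighbors=n_neighbors)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*lbfgs failed to converge.*")
        warnings.filterwarnings(
            "ignore", message=".*`probability` parameter was deprecated.*"
        )
        est.fit(X, _encode(y, classes_seen))
    return FittedModel(spec=spec, estimator=est, classes_seen=classes_seen)


def _choose_knn_k(spec: ClassifierSpec, X, y) -> int:
    """Pick K in {3, 7} by accuracy on a seeded inner 75/25 split."""
    from sklearn.model_selection import train_test_split

    ks = spec.hyperparameters.get("n_neighbors", [3, 7])
    if isinstance(ks, int):
        return ks
    counts = pd.Series(y).value_counts()
    if counts.min() < 4 or len(y) < 8:
        return int(ks[0])
    Xi, Xv, yi, yv = train_test_split(
        X, y, test_size=0.25, random_state=spec.random_seed, stratify=y
    )
    best_k, best_acc = int(ks[0]), -1.0
    for k in ks:
        if k >= len(yi):
            continue
        m = train_classifier(spec, Xi, yi, n_neighbors=int(k))
        acc = float(np.mean(m.predict(Xv) == yv))
        if acc > best_acc:
            best_k, best_acc = int(k), acc
    return best_k


@dataclass
class RegionalModelReport:
    """Bank evaluation for one region.

    ``test_metrics`` holds each algorithm's held-out metrics;
    ``selection_scores`` holds the accuracy/F1 pairs the winner is chosen
    on (inner-validation by default, so the test set never guides
    selection).
    """

    region_index: int
    test_metrics: dict  # algorithm_id -> EvaluationReport
    selection_scores: dict  # algorithm_id -> {"accuracy","f1"}
    selection_basis: str
    selected_algorithm_id: str | None = None
    knn_k: int = 3


def _inner_split(y_train, seed: int):
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(y_train))
    counts = pd.Series(y_train).value_counts()
    strat = y_train if counts.min() >= 2 else None
    tr, va = train_test_split(idx, test_size=0.25, random_state=seed, stratify=strat)
    return tr, va


def evaluate_bank_per_region(
    table: pd.DataFrame,
    split: SplitPlan,
    bank: list[ClassifierSpec] | None = None,
    config: PercentileConfig = PercentileConfig(),
    selection: str = "validation",
) -> list[RegionalModelReport]:
    """Train and score every bank member on every region's feature block.

    Parameters
    ----------
    selection : "validation" or "test"
        Basis for the winner's accuracy: an inner 75/25 split of the
        training rows (default; keeps the test set untouched) or the
        held-out test metrics themselves.
    """
    if bank is None:
        bank = default_bank()
    if selection not in ("validation", "test"):
        raise ValueError("selection must be 'validation' or 'test'")
    n_regions = n_regions_of_table(table, config)
    tr, te = split.train_indices(), split.test_indices()
    y_tr = table["label"].to_numpy()[tr]
    y_te = table["label"].to_numpy()[te]

    reports = []
    for r in range(1, n_regions + 1):
        cols = region_columns(r, n_regions, config)
        X = table[cols].to_numpy(dtype=float)
        X_tr, X_te = X[tr], X[te]
        if np.all(np.std(X_tr, axis=0) == 0):
            warnings.warn(
                f"region {r}: zero variance in every feature column",
                stacklevel=2,
            )
        test_metrics: dict[str, EvaluationReport] = {}
        sel_scores: dict[str, dict[str, float]] = {}
        knn_k = 3
        for spec in bank:
            k = None
            if spec.algorithm_id == "KNN":
                k = _choose_knn_k(spec, X_tr, y_tr)
                knn_k = k
            model = train_classifier(spec, X_tr, y_tr, n_neighbors=k)
            rep = compute_metrics(y_te, model.predict(X_te))
            test_metrics[spec.algorithm_id] = rep
            if selection == "test":
                sel_scores[spec.algorithm_id] = {
                    "accuracy": rep.accuracy, "f1": rep.f1,
                }
            else:
                itr, iva = _inner_split(y_tr, spec.random_seed + r)
                inner = train_classifier(spec, X_tr[itr], y_tr[itr], n_neighbors=k)
                vrep = compute_metrics(y_tr[iva], inner.predict(X_tr[iva]))
                sel_scores[spec.algorithm_id] = {
                    "accuracy": vrep.accuracy, "f1": vrep.f1,
                }
        reports.append(
            RegionalModelReport(
                region_index=r,
                test_metrics=test_metrics,
                selection_scores=sel_scores,
                selection_basis=selection,
                knn_k=knn_k,
            )
        )
    select_best_per_region(reports, bank)
    return reports


def select_best_per_region(
    reports: list[RegionalModelReport],
    bank: list[ClassifierSpec] | None = None,
) -> dict[int, ClassifierSpec]:
    """Assign each region its accuracy-maximizing algorithm.

    Ties break by higher F1, then by fixed bank order.  Fills
    ``selected_algorithm_id`` on each report and returns the
    region -> spec mapping.
    """
    if not reports:
        raise ValueError("no regional reports to select from")
    if bank is None:
        bank = default_bank()
    by_id = {s.algorithm_id: s for s in bank}
    chosen: dict[int, ClassifierSpec] = {}
    for rep in reports:
        best = None
        for rank, alg in enumerate(ALGORITHM_ORDER):
            if alg not in rep.selection_scores:
                continue
            s = rep.selection_scores[alg]
            key = (s["accuracy"], s["f1"], -rank)
            if best is None or key > best[0]:
                best = (key, alg)
        rep.selected_algorithm_id = best[1]
        spec = by_id[best[1]]
        if best[1] == "KNN":
            spec = replace(
                spec,
                hyperparameters={**spec.hyperparameters, "n_neighbors": rep.knn_k},
            )
        chosen[rep.region_index] = spec
    return chosen


def save_regional_models(
    models: dict[int, FittedModel], directory: str | Path
) -> None:
    """Persist fitted regional winners: one joblib file per region plus a
    JSON manifest of specs, seeds and class order."""
    import joblib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"format_version": 1, "regions": {}}
    for r, model in models.items():
        fname = f"region_{r}.joblib"
        joblib.dump(model.estimator, directory / fname)
        manifest["regions"][str(r)] = {
            "file": fname,
            "spec": model.spec.to_dict(),
            "class_order": list(model.class_order),
            "classes_seen": list(model.classes_seen),
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_regional_models(directory: str | Path) -> dict[int, FittedModel]:
    import joblib

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    models = {}
    for r, entry in manifest["regions"].items():
        models[int(r)] = FittedModel(
            spec=ClassifierSpec.from_dict(entry["spec"]),
            estimator=joblib.load(directory / entry["file"]),
            class_order=tuple(entry["class_order"]),
            classes_seen=tuple(entry["classes_seen"]),
        )
    return models
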