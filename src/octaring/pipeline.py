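"""End-to-end orchestration: features -> regional winners -> voting ensemble.

This module chains the stages the way the diagnostic workflow runs them:
extract the per-region percentile table, train and score the classifier
bank per region, keep each region's winner, fuse the winners by majority
vote, evaluate on held-out patients, and aggregate surrogate
explanations into regional attribution.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ensemble import EnsembleModel
from .evaluation import EvaluationReport, SplitPlan, compute_metrics, kfold_plan
from .explain import (
    AttributionReport,
    InstanceExplanation,
    aggregate_region_attribution,
    explain_instance,
)
from .features import PercentileConfig, n_regions_of_table, region_columns
from .models import (
    ClassifierSpec,
    RegionalModelReport,
    evaluate_bank_per_region,
    train_classifier,
)

__all__ = [
    "fit_ensemble",
    "evaluate_ensemble",
    "cross_validate",
    "explain_ensemble",
    "save_ensemble",
    "load_ensemble",
]


def fit_ensemble(
    table: pd.DataFrame,
    split: SplitPlan,
    bank: list[ClassifierSpec] | None = None,
    config: PercentileConfig = PercentileConfig(),
    selection: str = "validation",
    tie_policy: str = "accuracy",
) -> tuple[EnsembleModel, list[RegionalModelReport]]:
    """Train the bank per region, keep each winner, assemble the voter.

    The winner of each region is refit on all training rows; its
    selection accuracy is recorded for vote tie-breaking.  Feature
    means/stds over the training rows are stored on the ensemble for the
    perturbation explainer.
    """
    reports = evaluate_bank_per_region(
        table, split, bank=bank, config=config, selection=selection
    )
    n_regions = n_regions_of_table(table, config)
    tr = split.train_indices()
    y_tr = table["label"].to_numpy()[tr]

    from .models import default_bank, select_best_per_region

    chosen = select_best_per_region(reports, bank or default_bank())
    regional_models = {}
    region_accuracy = {}
    for rep in reports:
        r = rep.region_index
        cols = region_columns(r, n_regions, config)
        X_tr = table[cols].to_numpy(dtype=float)[tr]
        spec = chosen[r]
        k = rep.knn_k if spec.algorithm_id == "KNN" else None
        regional_models[r] = train_classifier(spec, X_tr, y_tr, n_neighbors=k)
        region_accuracy[r] = rep.selection_scores[spec.algorithm_id]["accuracy"]

    all_cols = []
    for r in range(1, n_regions + 1):
        all_cols.extend(region_columns(r, n_regions, config))
    X_all_tr = table[all_cols].to_numpy(dtype=float)[tr]
    ensemble = EnsembleModel(
        regional_models=regional_models,
        config=config,
        tie_policy=tie_policy,
        region_accuracy=region_accuracy,
        feature_means=X_all_tr.mean(axis=0),
        feature_stds=X_all_tr.std(axis=0),
    )
    return ensemble, reports


def evaluate_ensemble(
    ensemble: EnsembleModel, table: pd.DataFrame, indices=None
) -> EvaluationReport:
    """Score the voting ensemble on the given rows (default: all)."""
    if indices is None:
        indices = np.arange(len(table))
    rows = table.iloc[indices]
    y_pred = ensemble.predict(rows)
    return compute_metrics(rows["label"].to_numpy(), y_pred)


def cross_validate(
    table: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    bank: list[ClassifierSpec] | None = None,
    config: PercentileConfig = PercentileConfig(),
) -> dict:
    """Patient-grouped k-fold evaluation of regional winners and ensemble.

    Returns per-region winner accuracy for every fold plus its mean
    ("average accuracy"), and the ensemble's per-fold and mean accuracy.
    """
    plan = kfold_plan(table, k=k, seed=seed)
    n_regions = n_regions_of_table(table, config)
    region_acc = {r: [] for r in range(1, n_regions + 1)}
    ensemble_acc = []
    for fold in range(k):
        tr, te = plan.fold_indices(fold)
        te_set = set(int(i) for i in te)
        fold_split = SplitPlan(
            mode="holdout",
            assignments=tuple(
                "test" if i in te_set else "train" for i in range(len(table))
            ),
            seed=seed,
        )
        ensemble, reports = fit_ensemble(table, fold_split, bank=bank, config=config)
        for rep in reports:
            win = rep.selected_algorithm_id
            region_acc[rep.region_index].append(
                rep.test_metrics[win].accuracy
            )
        ensemble_acc.append(evaluate_ensemble(ensemble, table, te).accuracy)
    return {
        "k": k,
        "region_fold_accuracy": {
            r: list(map(float, accs)) for r, accs in region_acc.items()
        },
        "region_average_accuracy": {
            r: float(np.mean(accs)) for r, accs in region_acc.items()
        },
        "ensemble_fold_accuracy": list(map(float, ensemble_acc)),
        "ensemble_average_accuracy": float(np.mean(ensemble_acc)),
    }


def explain_ensemble(
    ensemble: EnsembleModel,
    table: pd.DataFrame,
    indices=None,
    n_samples: int = 5000,
    seed: int = 0,
    max_images: int | None = None,
) -> tuple[list[InstanceExplanation], AttributionReport]:
    """Explain each selected image and aggregate regional attribution.

    Explanations use per-image seeds derived from ``seed``; true labels
    drive the class-conditional profiles.  ``max_images`` caps the
    subject count (evenly down-sampled, deterministic).
    """
    if indices is None:
        indices = np.arange(len(table))
    indices = np.asarray(indices)
    if max_images is not None and len(indices) > max_images:
        keep = np.linspace(0, len(indices) - 1, max_images).round().astype(int)
        indices = indices[keep]
    explanations = []
    for j, i in enumerate(indices):
        row = table.iloc[int(i)]
        explanations.append(
            explain_instance(
                ensemble,
                row,
                n_samples=n_samples,
                seed=seed + j,
                image_id=str(row.get("image_path", i)),
            )
        )
    labels = table["label"].to_numpy()[indices]
    return explanations, aggregate_region_attribution(explanations, labels)


def save_ensemble(ensemble: EnsembleModel, directory) -> None:
    """Persist the fitted ensemble: regional model bundle + voting policy
    and training feature statistics."""
    import json
    from pathlib import Path

    from .models import save_regional_models

    directory = Path(directory)
    save_regional_models(ensemble.regional_models, directory)
    extras = {
        "tie_policy": ensemble.tie_policy,
        "region_accuracy": {
            str(r): v for r, v in ensemble.region_accuracy.items()
        },
        "ranks": list(ensemble.config.ranks),
        "feature_means": (
            None
            if ensemble.feature_means is None
            else np.asarray(ensemble.feature_means).tolist()
        ),
        "feature_stds": (
            None
            if ensemble.feature_stds is None
            else np.asarray(ensemble.feature_stds).tolist()
        ),
    }
    (directory / "ensemble.json").write_text(json.dumps(extras, indent=2))


def load_ensemble(directory) -> EnsembleModel:
    import json
    from pathlib import Path

    from .models import load_regional_models

    directory = Path(directory)
    extras = json.loads((directory / "ensemble.json").read_text())
    return EnsembleModel(
        regional_models=load_regional_models(directory),
        config=PercentileConfig(ranks=tuple(extras["ranks"])),
        tie_policy=extras["tie_policy"],
        region_accuracy={
            int(r): v for r, v in extras["region_accuracy"].items()
        },
        feature_means=(
            None
            if extras["feature_means"] is None
            else np.asarray(extras["feature_means"], dtype=float)
        ),
        feature_stds=(
            None
            if extras["feature_stds"] is None
            else np.asarray(extras["feature_stds"], dtype=float)
        ),
    )
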