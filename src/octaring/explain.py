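"""Local linear surrogate explanation of the voting ensemble.

The ensemble's hard vote is piecewise constant, so explanation targets a
continuous surface over it: by default the *soft voting* surface (mean
of the regional voters' predicted-grade probabilities), with the hard
vote share (fraction of voters endorsing the grade) available as an
alternative.  For one image: standardized perturbation rows are sampled
from the training feature distribution (unit Gaussian on the
standardized scale, as in reference perturbation explainers), each row
is scored by the ensemble surface for the predicted grade, and a
proximity-weighted linear model (exponential kernel on standardized
distance to the instance) is fit; its coefficients are the per-feature
weights.  Drawing the sample from the data distribution rather than
tightly around the instance keeps the surrogate informative for
high-margin voters, whose response is locally flat.

Region-level attribution sums the absolute weights of each region's nine
features per subject, averages over subjects (globally and per grade),
and normalizes to percentages over the seven regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import EnsembleModel
from .features import CLASS_LABELS

__all__ = [
    "InstanceExplanation",
    "AttributionReport",
    "explain_instance",
    "aggregate_region_attribution",
]


@dataclass(frozen=True)
class InstanceExplanation:
    """Signed per-feature weights of the local surrogate for one image."""

    image_id: str
    weights: np.ndarray = field(repr=False)
    predicted_label: str
    seed: int
    n_regions: int
    n_ranks: int

    def region_weight(self, region_index: int) -> float:
        """Sum of absolute weights of one region's feature block."""
        k = self.n_ranks
        block = self.weights[(region_index - 1) * k : region_index * k]
        return float(np.abs(block).sum())


def explain_instance(
    ensemble: EnsembleModel,
    feature_row,
    n_samples: int = 5000,
    seed: int = 0,
    kernel_width: float | None = None,
    target: str = "probability",
    image_id: str = "",
) -> InstanceExplanation:
    """Fit the weighted linear surrogate for one image's feature vector.

    Parameters
    ----------
    n_samples : int
        Perturbation rows drawn on the standardized scale; fewer rows
        than features leaves the surrogate ill-posed (a warning is
        issued).
    kernel_width : float, optional
        Width of the exponential proximity kernel on standardized
        distance; defaults to ``0.75 * sqrt(n_features)``.
    target : "probability" or "vote_share"
        Continuous surface the surrogate regresses on: the soft voting
        surface (default) or the hard vote share of the predicted grade.
    """
    if ensemble.feature_means is None or ensemble.feature_stds is None:
        raise ValueError(
            "ensemble carries no training feature statistics; fit it via "
            "the pipeline (or set feature_means/feature_stds) before "
            "explaining"
        )
    if target not in ("probability", "vote_share"):
        raise ValueError(f"unknown surrogate target {target!r}")
    x = ensemble._as_matrix(feature_row)[0]
    d = x.size
    if n_samples < d:
        warnings.warn(
            f"n_samples={n_samples} < {d} features: surrogate is ill-posed",
            stacklevel=2,
        )
    mu = np.asarray(ensemble.feature_means, dtype=float)
    sd = np.asarray(ensemble.feature_stds, dtype=float)
    sd = np.where(sd > 0, sd, 1.0)
    if kernel_width is None:
        kernel_width = 0.75 * np.sqrt(d)

    rng = np.random.default_rng(seed)
    z0 = (x - mu) / sd
    Z = rng.standard_normal((n_samples, d))
    Z[0] = z0  # keep the instance itself in the sample
    X_pert = Z * sd + mu

    label = str(ensemble.predict(x)[0])
    cls = CLASS_LABELS.index(label)
    if target == "probability":
        y = ensemble.predict_proba(X_pert)[:, cls]
    else:
        y = ensemble.predict_shares(X_pert)[:, cls]

    dist = np.sqrt(((Z - z0) ** 2).sum(axis=1))
    w = np.exp(-(dist**2) / kernel_width**2)

    from sklearn.linear_model import Ridge

    surrogate = Ridge(alpha=1.0)
    surrogate.fit(Z, y, sample_weight=w)
    return InstanceExplanation(
        image_id=image_id,
        weights=np.asarray(surrogate.coef_, dtype=float),
        predicted_label=label,
        seed=seed,
        n_regions=ensemble.n_regions,
        n_ranks=ensemble.config.n_ranks,
    )


@dataclass(frozen=True)
class AttributionReport:
    """Region-wise contribution percentages, global and per grade.

    ``global_avg[r]`` is the mean over subjects of region r's summed
    absolute surrogate weights; each percentage vector is that profile
    normalized to 100 over the regions.
    """

    regions: tuple
    global_avg: dict
    global_pct: dict
    class_pct: dict  # label -> {region -> pct}
    classes: tuple = CLASS_LABELS

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.regions:
            row = {
                "region": f"R{r}",
                "global_avg": self.global_avg[r],
                "global_pct": self.global_pct[r],
            }
            for c in self.classes:
                row[f"{c}_pct"] = self.class_pct[c].get(r, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path: str, kind: str = "bar") -> None:
        """Grouped-bar or line plot of regional contributions per grade."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        frame = self.to_frame()
        x = np.arange(len(self.regions))
        fig, ax = plt.subplots(figsize=(6, 3.5))
        if kind == "bar":
            width = 0.25
            for i, c in enumerate(self.classes):
                ax.bar(x + (i - 1) * width, frame[f"{c}_pct"], width, label=c)
        else:
            for c in self.classes:
                ax.plot(x, frame[f"{c}_pct"], marker="o", label=c)
        ax.set_xticks(x, frame["region"])
        ax.set_ylabel("contribution (%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _normalize_pct(profile: dict) -> dict:
    total = sum(profile.values())
    if total <= 0:
        n = len(profile)
        return {r: 100.0 / n for r in profile}
    return {r: 100.0 * v / total for r, v in profile.items()}


def aggregate_region_attribution(
    explanations: list[InstanceExplanation], labels=None
) -> AttributionReport:
    """Average per-region absolute weights over subjects and normalize.

    ``labels`` (true or predicted grades, one per explanation) drive the
    class-conditional profiles; omitted, each explanation's predicted
    label is used.
    """
    if not explanations:
        raise ValueError("no explanations to aggregate")
    if labels is None:
        labels = [e.predicted_label for e in explanations]
    if len(labels) != len(explanations):
        raise ValueError(
            f"{len(labels)} labels for {len(explanations)} explanations"
        )
    n_regions = explanations[0].n_regions
    regions = tuple(range(1, n_regions + 1))

    per_subject = np.array(
        [[e.region_weight(r) for r in regions] for e in explanations]
    )
    global_avg = {r: float(per_subject[:, i].mean()) for i, r in enumerate(regions)}
    global_pct = _normalize_pct(global_avg)

    class_pct = {}
    labels = np.asarray(labels)
    for c in CLASS_LABELS:
        sel = labels == c
        if not sel.any():
            class_pct[c] = {r: float("nan") for r in regions}
            continue
        avg = {
            r: float(per_subject[sel, i].mean()) for i, r in enumerate(regions)
        }
        class_pct[c] = _normalize_pct(avg)
    return AttributionReport(
        regions=regions,
        global_avg=global_avg,
        global_pct=global_pct,
        class_pct=class_pct,
    )
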