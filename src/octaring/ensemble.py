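"""Majority-vote fusion of the per-region classifiers.

Each of the seven regional winners votes a grade from its own 9-feature
block; the image-level label is the modal vote.  With seven voters over
three grades ties are possible (e.g. 3-3-1): the tie defers to the tied
label endorsed by the region with the highest recorded validation
accuracy, falling back to the fixed grade order.  ``vote_shares`` exposes
the per-grade vote fraction — the natural continuous surface over the
otherwise piecewise-constant mode, used by the explainer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CLASS_LABELS, PercentileConfig, region_columns
from .models import FittedModel

__all__ = ["EnsembleModel", "majority_vote", "vote_shares"]


def majority_vote(
    votes,
    tie_policy: str = "accuracy",
    region_accuracy: dict[int, float] | None = None,
) -> str:
    """Modal label of the regional votes.

    ``votes`` is ordered by region (1-based voter index = position + 1).
    On a tie, policy ``"accuracy"`` picks the tied label voted for by the
    highest-accuracy region (requires ``region_accuracy``); policy
    ``"fixed_order"`` — also the fallback — picks the tied label earliest
    in the fixed grade order.
    """
    votes = list(votes)
    if not votes:
        raise ValueError("cannot vote with zero voters")
    unknown = set(votes) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown vote label(s) {sorted(unknown)}")
    counts = {c: votes.count(c) for c in CLASS_LABELS if c in votes}
    top = max(counts.values())
    tied = [c for c in CLASS_LABELS if counts.get(c, 0) == top]
    if len(tied) == 1:
        return tied[0]
    if tie_policy == "accuracy" and region_accuracy:
        best_label, best_acc = None, -np.inf
        for pos, v in enumerate(votes):
            if v in tied:
                acc = region_accuracy.get(pos + 1, -np.inf)
                if acc > best_acc:
                    best_label, best_acc = v, acc
        if best_label is not None and np.isfinite(best_acc):
            return best_label
    return tied[0]  # fixed grade order


def vote_shares(votes) -> np.ndarray:
    """Per-grade vote fraction, ordered (normal, mild, moderate); sums to 1."""
    votes = list(votes)
    if not votes:
        raise ValueError("cannot compute shares of zero votes")
    return np.array(
        [votes.count(c) / len(votes) for c in CLASS_LABELS], dtype=float
    )


@dataclass
class EnsembleModel:
    """The fitted regional winners plus the voting policy.

    ``region_accuracy`` records each winner's validation accuracy for
    tie-breaking.  ``feature_means``/``feature_stds`` are training-set
    statistics over the 63 columns, stored for the perturbation explainer.
    """

    regional_models: dict[int, FittedModel]
    config: PercentileConfig = PercentileConfig()
    tie_policy: str = "accuracy"
    region_accuracy: dict[int, float] = field(default_factory=dict)
    feature_means: np.ndarray | None = None
    feature_stds: np.ndarray | None = None

    def __post_init__(self) -> None:
        regions = sorted(self.regional_models)
        if regions != list(range(1, len(regions) + 1)):
            raise ValueError("regional_models must cover regions 1..N")

    @property
    def n_regions(self) -> int:
        return len(self.regional_models)

    @property
    def n_features(self) -> int:
        return self.n_regions * self.config.n_ranks

    @property
    def feature_names(self) -> list[str]:
        cols = []
        for r in range(1, self.n_regions + 1):
            cols.extend(region_columns(r, self.n_regions, self.config))
        return cols

    def _as_matrix(self, feature_rows) -> np.ndarray:
        if isinstance(feature_rows, pd.DataFrame):
            feature_rows = feature_rows[self.feature_names].to_numpy(dtype=float)
        elif isinstance(feature_rows, pd.Series):
            feature_rows = feature_rows[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(feature_rows, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} feature columns, got {X.shape[1]}"
            )
        return X

    def predict_regions(self, feature_rows) -> np.ndarray:
        """Votes of all regional models; shape (n_rows, n_regions).

        Voter j sees only its own 9-column block, so a vote is invariant
        to every other region's features.
        """
        X = self._as_matrix(feature_rows)
        k = self.config.n_ranks
        votes = np.empty((X.shape[0], self.n_regions), dtype=object)
        for r in range(1, self.n_regions + 1):
            block = X[:, (r - 1) * k : r * k]
            votes[:, r - 1] = self.regional_models[r].predict(block)
        return votes

    def predict(self, feature_rows) -> np.ndarray:
        """Image-level labels by majority vote."""
        votes = self.predict_regions(feature_rows)
        return np.array(
            [
                majority_vote(row, self.tie_policy, self.region_accuracy)
                for row in votes
            ],
            dtype=object,
        )

    def predict_shares(self, feature_rows) -> np.ndarray:
        """Vote-share matrix, shape (n_rows, 3), rows sum to 1."""
        votes = self.predict_regions(feature_rows)
        return np.vstack([vote_shares(row) for row in votes])

    def predict_proba(self, feature_rows) -> np.ndarray:
        """Soft voting surface: mean of the regional voters' class
        probabilities, shape (n_rows, 3).

        The image-level decision remains the hard majority vote; this
        smooth surface exists for diagnostics and for the surrogate
        explainer.  A voter without probability output contributes its
        hard vote as a one-hot row.
        """
        import warnings

        X = self._as_matrix(feature_rows)
        k = self.config.n_ranks
        out = np.zeros((X.shape[0], len(CLASS_LABELS)))
        for r in range(1, self.n_regions + 1):
            m = self.regional_models[r]
            block = X[:, (r - 1) * k : r * k]
            full = np.zeros((X.shape[0], len(CLASS_LABELS)))
            with warnings.catch_warnings():
                warnings.filterwarnings(
                    "ignore", message=".*does not have valid feature names.*"
                )
                try:
                    proba = m.estimator.predict_proba(block)
                except AttributeError:
                    codes = np.asarray(m.estimator.predict(block), dtype=int)
                    proba = np.eye(len(m.classes_seen))[codes]
            for j, c in enumerate(m.classes_seen):
                full[:, CLASS_LABELS.index(c)] = proba[:, j]
            out += full
        return out / self.n_regions

    def explain_record(self, feature_row) -> dict:
        """Machine-readable per-image prediction: regional votes, shares,
        final label."""
        votes = self.predict_regions(feature_row)[0]
        shares = vote_shares(votes)
        return {
            "regional_votes": {r + 1: v for r, v in enumerate(votes)},
            "vote_shares": dict(zip(CLASS_LABELS, shares.tolist())),
            "label": majority_vote(votes, self.tie_policy, self.region_accuracy),
        }
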