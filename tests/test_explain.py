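import numpy as np
import pytest

from octaring.ensemble import EnsembleModel
from octaring.explain import (
    InstanceExplanation,
    aggregate_region_attribution,
    explain_instance,
)
from octaring.features import PercentileConfig
from octaring.models import ClassifierSpec, FittedModel


class _Stub:
    def predict(self, X):
        return np.zeros(len(X), dtype=int)


def _base_ensemble(**kw):
    models = {
        r: FittedModel(spec=ClassifierSpec("LR"), estimator=_Stub())
        for r in range(1, 8)
    }
    return EnsembleModel(
        regional_models=models,
        config=PercentileConfig(),
        feature_means=np.zeros(63),
        feature_stds=np.ones(63),
        **kw,
    )


class _LinearSurface(EnsembleModel):
    """Ensemble stand-in whose continuous surface is a known linear map."""

    def set_coef(self, w):
        self._w = np.asarray(w, dtype=float)

    def predict(self, rows):
        X = self._as_matrix(rows)
        return np.array(["normal"] * len(X), dtype=object)

    def _surface(self, rows):
        Z = (self._as_matrix(rows) - self.feature_means) / self.feature_stds
        return 1 / (1 + np.exp(-Z @ self._w / 4))

    def predict_proba(self, rows):
        y = self._surface(rows)
        return np.column_stack([y, 1 - y, np.zeros_like(y)])

    predict_shares = predict_proba


class _FirstFeatureVoter(EnsembleModel):
    """Votes (hence vote shares) depend only on feature 0."""

    def predict(self, rows):
        X = self._as_matrix(rows)
        return np.where(X[:, 0] > 0, "mild", "normal").astype(object)

    def predict_shares(self, rows):
        X = self._as_matrix(rows)
        mild = (X[:, 0] > 0).astype(float)
        return np.column_stack([1 - mild, mild, np.zeros_like(mild)])

    predict_proba = predict_shares


def linear_ensemble(w):
    models = {
        r: FittedModel(spec=ClassifierSpec("LR"), estimator=_Stub())
        for r in range(1, 8)
    }
    ens = _LinearSurface(
        regional_models=models,
        config=PercentileConfig(),
        feature_means=np.zeros(63),
        feature_stds=np.ones(63),
    )
    ens.set_coef(w)
    return ens


class TestExplainInstance:
    def test_surrogate_recovers_linear_surface(self, rng):
        w = rng.normal(size=63)
        ens = linear_ensemble(w)
        expl = explain_instance(ens, np.zeros(63), n_samples=4000, seed=0)
        r = np.corrcoef(expl.weights, w)[0, 1]
        assert r > 0.9

    def test_ignored_feature_gets_negligible_weight(self):
        models = {
            r: FittedModel(spec=ClassifierSpec("LR"), estimator=_Stub())
            for r in range(1, 8)
        }
        ens = _FirstFeatureVoter(
            regional_models=models,
            config=PercentileConfig(),
            feature_means=np.zeros(63),
            feature_stds=np.ones(63),
        )
        expl = explain_instance(
            ens, np.zeros(63), n_samples=5000, seed=1, target="vote_share"
        )
        w = np.abs(expl.weights)
        assert w[0] == w.max()
        assert np.all(w[1:] < 0.05 * w[0])

    def test_same_seed_reproduces_weights(self, small_fit):
        table, split, ensemble, _ = small_fit
        row = table.iloc[int(split.test_indices()[0])]
        a = explain_instance(ensemble, row, n_samples=400, seed=3)
        b = explain_instance(ensemble, row, n_samples=400, seed=3)
        assert np.array_equal(a.weights, b.weights)
        assert a.predicted_label == b.predicted_label

    def test_missing_feature_stats_rejected(self):
        ens = _base_ensemble()
        ens.feature_means = None
        with pytest.raises(ValueError, match="statistics"):
            explain_instance(ens, np.zeros(63))

    def test_undersampled_surrogate_warns(self):
        ens = linear_ensemble(np.ones(63))
        with pytest.warns(UserWarning, match="ill-posed"):
            explain_instance(ens, np.zeros(63), n_samples=30, seed=0)

    def test_unknown_target_rejected(self):
        ens = linear_ensemble(np.ones(63))
        with pytest.raises(ValueError, match="target"):
            explain_instance(ens, np.zeros(63), target="shapley")


def _expl(weights, label="normal"):
    return InstanceExplanation(
        image_id="x",
        weights=np.asarray(weights, dtype=float),
        predicted_label=label,
        seed=0,
        n_regions=7,
        n_ranks=9,
    )


class TestAggregation:
    def test_concentration_in_one_region(self):
        w = np.zeros(63)
        w[18:27] = 2.0  # region 3 block
        report = aggregate_region_attribution([_expl(w)])
        assert report.global_pct[3] == pytest.approx(100.0)
        assert all(report.global_pct[r] == 0 for r in (1, 2, 4, 5, 6, 7))

    def test_uniform_weights_give_equal_shares(self):
        report = aggregate_region_attribution([_expl(np.ones(63))])
        for r in range(1, 8):
            assert report.global_pct[r] == pytest.approx(100 / 7)

    def test_percentages_sum_to_100_globally_and_per_class(self, rng):
        expls = [
            _expl(rng.normal(size=63), label)
            for label in ("normal", "normal", "mild", "moderate")
        ]
        report = aggregate_region_attribution(expls)
        assert sum(report.global_pct.values()) == pytest.approx(100, abs=1e-6)
        for c in ("normal", "mild", "moderate"):
            assert sum(report.class_pct[c].values()) == pytest.approx(
                100, abs=1e-6
            )
        assert all(v >= 0 for v in report.global_pct.values())

    def test_subject_order_invariance(self, rng):
        expls = [_expl(rng.normal(size=63)) for _ in range(6)]
        a = aggregate_region_attribution(expls)
        b = aggregate_region_attribution(expls[::-1])
        for r in range(1, 8):
            assert a.global_pct[r] == pytest.approx(b.global_pct[r])

    def test_duplicated_subjects_leave_percentages_unchanged(self, rng):
        expls = [_expl(rng.normal(size=63)) for _ in range(4)]
        a = aggregate_region_attribution(expls)
        b = aggregate_region_attribution(expls + expls)
        for r in range(1, 8):
            assert a.global_pct[r] == pytest.approx(b.global_pct[r])

    def test_label_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            aggregate_region_attribution([_expl(np.ones(63))], labels=["a", "b"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_region_attribution([])

    def test_csv_and_plots(self, tmp_path, rng):
        expls = [
            _expl(np.abs(rng.normal(size=63)), label)
            for label in ("normal", "mild", "moderate")
        ]
        report = aggregate_region_attribution(expls)
        report.to_csv(tmp_path / "attr.csv")
        import pandas as pd

        frame = pd.read_csv(tmp_path / "attr.csv")
        assert list(frame["region"]) == [f"R{r}" for r in range(1, 8)]
        assert {"global_avg", "global_pct", "normal_pct"} <= set(frame.columns)
        report.plot(str(tmp_path / "bar.png"), kind="bar")
        report.plot(str(tmp_path / "line.png"), kind="line")
        assert (tmp_path / "bar.png").stat().st_size > 0
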