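import numpy as np
import pandas as pd
import pytest

from octaring.evaluation import SplitPlan
from octaring.features import CLASS_LABELS, feature_columns
from octaring.models import (
    ALGORITHM_ORDER,
    ClassifierSpec,
    RegionalModelReport,
    default_bank,
    evaluate_bank_per_region,
    load_regional_models,
    save_regional_models,
    select_best_per_region,
    train_classifier,
)


def make_table(X, labels, patients=None):
    """Wrap a (n, 63) matrix into the canonical feature-table layout."""
    cols = feature_columns(7)
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "label", labels)
    df.insert(0, "patient_id", patients or [f"P{i}" for i in range(len(df))])
    df.insert(0, "image_path", [f"img{i}.png" for i in range(len(df))])
    return df


def holdout_plan(n, n_test):
    return SplitPlan(
        mode="holdout",
        assignments=tuple(["train"] * (n - n_test) + ["test"] * n_test),
    )


class TestBank:
    def test_ten_members_in_fixed_order(self):
        bank = default_bank()
        assert [s.algorithm_id for s in bank] == list(ALGORITHM_ORDER)
        assert len(bank) == 10

    def test_tuned_hyperparameters(self):
        by_id = {s.algorithm_id: s for s in default_bank()}
        assert by_id["XGB"].hyperparameters == {
            "n_estimators": 80, "max_depth": 8, "learning_rate": 0.05,
        }
        assert by_id["LGBM"].hyperparameters["max_depth"] == 1
        assert by_id["LGBM"].hyperparameters["num_leaves"] == 31
        assert by_id["RF"].hyperparameters["n_estimators"] == 100
        assert by_id["DT"].hyperparameters == {"max_depth": 80, "criterion": "entropy"}
        assert by_id["ET"].hyperparameters == {"n_estimators": 100, "max_depth": 10}
        assert by_id["KNN"].hyperparameters["n_neighbors"] == [3, 7]
        assert by_id["SVM"].hyperparameters == {
            "C": 1.0, "gamma": "scale", "kernel": "rbf",
        }
        assert by_id["Bagging"].hyperparameters["n_estimators"] == 50
        assert by_id["AdaBoost"].hyperparameters["n_estimators"] == 100

    def test_spec_round_trips_through_serialization(self):
        for spec in default_bank():
            assert ClassifierSpec.from_dict(spec.to_dict()) == spec

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(algorithm_id="MLP")


class TestTrainClassifier:
    def test_lr_separates_linearly_separable_classes(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 2)), rng.normal(3, 0.1, (20, 2))])
        y = np.array(["normal"] * 20 + ["mild"] * 20)
        spec = next(s for s in default_bank() if s.algorithm_id == "LR")
        model = train_classifier(spec, X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_knn_votes_with_stored_neighbors(self):
        X = np.array([[0.0, 0], [0.1, 0], [-0.1, 0], [5, 5], [5.1, 5], [4.9, 5]])
        y = np.array(["normal"] * 3 + ["moderate"] * 3)
        spec = next(s for s in default_bank() if s.algorithm_id == "KNN")
        model = train_classifier(spec, X, y, n_neighbors=3)
        assert model.predict([[0.0, 0.0]])[0] == "normal"
        assert model.predict([[5.0, 5.0]])[0] == "moderate"

    @pytest.mark.parametrize("alg", ALGORITHM_ORDER)
    def test_same_seed_same_predictions(self, alg, rng):
        X = rng.normal(size=(60, 9))
        y = np.array((["normal", "mild", "moderate"] * 20))
        spec = next(s for s in default_bank() if s.algorithm_id == alg)
        probe = rng.normal(size=(20, 9))
        k = 3 if alg == "KNN" else None
        p1 = train_classifier(spec, X, y, n_neighbors=k).predict(probe)
        p2 = train_classifier(spec, X, y, n_neighbors=k).predict(probe)
        assert np.array_equal(p1, p2)

    def test_single_class_and_nan_rejected(self):
        spec = default_bank()[0]
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="single class"):
            train_classifier(spec, X, ["normal"] * 10)
        Xn = X.copy()
        Xn[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            train_classifier(spec, Xn, ["normal"] * 5 + ["mild"] * 5)


class TestRegionalEvaluation:
    def test_planted_oracle_column_gives_perfect_region(self, rng):
        # region 1's first feature encodes the label exactly
        n = 120
        X = rng.normal(size=(n, 63))
        labels = np.array([CLASS_LABELS[i % 3] for i in range(n)])
        X[:, 0] = [CLASS_LABELS.index(c) * 10.0 for c in labels]
        table = make_table(X, labels)
        reports = evaluate_bank_per_region(
            table, holdout_plan(n, 30), selection="test"
        )
        best_r1 = max(m.accuracy for m in reports[0].test_metrics.values())
        assert best_r1 == 1.0

    def test_signal_region_outscores_noise_regions(self, study_scale_run):
        # default effects plant the strongest deficits in regions 2-3
        _, _, _, reports = study_scale_run
        best = {
            r.region_index: max(m.accuracy for m in r.test_metrics.values())
            for r in reports
        }
        planted_best = max(best[2], best[3])
        assert planted_best > max(best[r] for r in (1, 4, 6, 7))

    def test_no_leakage_from_test_rows(self, rng):
        n = 90
        X = rng.normal(size=(n, 63))
        labels = np.array([CLASS_LABELS[i % 3] for i in range(n)])
        X[:, 9] = [CLASS_LABELS.index(c) for c in labels]  # signal in R2
        plan = holdout_plan(n, 20)
        t1 = make_table(X, labels)
        X2 = X.copy()
        X2[-20:] = rng.normal(size=(20, 63)) * 100  # perturb test rows only
        t2 = make_table(X2, labels)
        bank = [s for s in default_bank() if s.algorithm_id in ("LR", "RF")]
        r1 = evaluate_bank_per_region(t1, plan, bank=bank)
        r2 = evaluate_bank_per_region(t2, plan, bank=bank)
        # selection is based on training rows only, so winners agree
        for a, b in zip(r1, r2):
            assert a.selection_scores == b.selection_scores
            assert a.selected_algorithm_id == b.selected_algorithm_id


class TestSelection:
    def _report(self, region, scores):
        return RegionalModelReport(
            region_index=region,
            test_metrics={},
            selection_scores=scores,
            selection_basis="validation",
        )

    def test_accuracy_maximizer_wins(self):
        rep = self._report(1, {
            "LR": {"accuracy": 0.95, "f1": 0.95},
            "KNN": {"accuracy": 0.92, "f1": 0.92},
            "RF": {"accuracy": 0.79, "f1": 0.79},
            "ET": {"accuracy": 0.87, "f1": 0.87},
        })
        chosen = select_best_per_region([rep])
        assert chosen[1].algorithm_id == "LR"

    def test_tie_breaks_by_f1_then_bank_order(self):
        rep = self._report(2, {
            "KNN": {"accuracy": 0.9, "f1": 0.88},
            "RF": {"accuracy": 0.9, "f1": 0.91},
        })
        assert select_best_per_region([rep])[2].algorithm_id == "RF"
        rep2 = self._report(3, {
            "KNN": {"accuracy": 0.9, "f1": 0.9},
            "RF": {"accuracy": 0.9, "f1": 0.9},
        })
        assert select_best_per_region([rep2])[3].algorithm_id == "KNN"

    def test_all_tied_gives_first_bank_member(self):
        rep = self._report(1, {
            a: {"accuracy": 0.5, "f1": 0.5} for a in ALGORITHM_ORDER
        })
        assert select_best_per_region([rep])[1].algorithm_id == ALGORITHM_ORDER[0]

    def test_selection_is_idempotent(self):
        rep = self._report(1, {
            "LR": {"accuracy": 0.7, "f1": 0.7},
            "XGB": {"accuracy": 0.8, "f1": 0.8},
        })
        first = select_best_per_region([rep])
        second = select_best_per_region([rep])
        assert first[1] == second[1]

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            select_best_per_region([])


def test_model_bundle_round_trip(tmp_path, rng):
    X = rng.normal(size=(30, 9))
    y = np.array(["normal", "mild", "moderate"] * 10)
    models = {
        r: train_classifier(default_bank()[1], X, y) for r in (1, 2)
    }
    save_regional_models(models, tmp_path / "bundle")
    back = load_regional_models(tmp_path / "bundle")
    probe = rng.normal(size=(10, 9))
    for r in (1, 2):
        assert np.array_equal(models[r].predict(probe), back[r].predict(probe))
        assert back[r].spec == models[r].spec
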