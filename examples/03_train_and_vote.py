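"""Regional classifier selection and majority-vote grading.

Runs the full training pipeline on a 150-image synthetic cohort: trains
the ten-algorithm bank on each region's 9-feature dataset, keeps each
region's winner, fuses the seven regional votes per image, and scores
the result on held-out patients.  Prints the per-region winners and the
ensemble metrics — the voting ensemble should match or beat its best
single region.
"""

from octaring import build_feature_table, build_region_scheme, patient_level_split
from octaring.pipeline import evaluate_ensemble, fit_ensemble
from octaring.simulate import SyntheticConfig, generate_dataset

cfg = SyntheticConfig(n_per_class=50, seed=0)
manifest, images = generate_dataset(cfg)
scheme = build_region_scheme(cfg.image_size, cfg.radial_step)
table = build_feature_table(manifest, scheme, images=images)
split = patient_level_split(table, test_fraction=0.2, seed=0)

ensemble, reports = fit_ensemble(table, split)
print(f"{'region':>6} {'winner':>10} {'test acc':>9}")
for rep in reports:
    acc = rep.test_metrics[rep.selected_algorithm_id].accuracy
    print(f"{rep.region_index:>6} {rep.selected_algorithm_id:>10} {acc:>9.2f}")

report = evaluate_ensemble(ensemble, table, split.test_indices())
print(
    f"\nmajority-vote ensemble (n_test={report.n_test}): "
    f"accuracy {report.accuracy:.2f}, precision {report.precision:.2f}, "
    f"recall {report.recall:.2f}, F1 {report.f1:.2f}"
)
print("confusion matrix (rows = true grade):")
print(report.confusion_matrix())
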