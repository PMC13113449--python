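"""Regional attribution of ensemble decisions via a local surrogate.

Fits the pipeline on a synthetic cohort with disease planted in annuli
2-3 (mild and moderate) plus annulus 5 (moderate only), then explains
the test images with the perturbation surrogate and aggregates absolute
weights into per-region percentage contributions.  The planted annuli
should dominate, and region 5's contribution should rise for moderate
disease relative to normal.
"""

from octaring import build_feature_table, build_region_scheme, patient_level_split
from octaring.pipeline import explain_ensemble, fit_ensemble
from octaring.simulate import SyntheticConfig, generate_dataset

cfg = SyntheticConfig(n_per_class=60, seed=0)
manifest, images = generate_dataset(cfg)
scheme = build_region_scheme(cfg.image_size, cfg.radial_step)
table = build_feature_table(manifest, scheme, images=images)
split = patient_level_split(table, 0.2, seed=0)
ensemble, _ = fit_ensemble(table, split)

explanations, attribution = explain_ensemble(
    ensemble, table, indices=split.test_indices(), n_samples=3000, seed=0
)
print(attribution.to_frame().round(2).to_string(index=False))
print(
    "\nglobal_pct: each annulus's share of the mean absolute surrogate "
    "weight; the class columns condition on the true grade."
)
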