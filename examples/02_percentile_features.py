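"""Percentile vessel-density features from a synthetic cohort.

Generates a small synthetic OCTA-like cohort (6 images per grade),
extracts the 7-region x 9-decile feature table, and prints region-3
features for one image of each grade.  Lower percentile intensities in
the diseased grades reflect the planted parafoveal capillary dropout.
"""

from octaring import build_feature_table, build_region_scheme, region_columns
from octaring.simulate import SyntheticConfig, generate_dataset

cfg = SyntheticConfig(n_per_class=6, seed=0)
manifest, images = generate_dataset(cfg)
scheme = build_region_scheme(cfg.image_size, cfg.radial_step)
table = build_feature_table(manifest, scheme, images=images)

print(f"feature table: {len(table)} images x {table.shape[1] - 3} features")
cols = region_columns(3, scheme.n_regions)
print(f"\nregion-3 deciles ({', '.join(c.split('_')[1] for c in cols)}):")
for grade in ("normal", "mild", "moderate"):
    row = table[table["label"] == grade].iloc[0]
    vals = " ".join(f"{row[c]:5.0f}" for c in cols)
    print(f"  {grade:>8}: {vals}")
print(
    "\nDiseased grades shift the region-3 intensity distribution downward: "
    "mid deciles drop toward the dark background as capillaries vanish."
)
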