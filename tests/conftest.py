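import numpy as np
import pytest

from octaring import build_feature_table, build_region_scheme, patient_level_split
from octaring.pipeline import fit_ensemble
from octaring.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_cohort():
    """90-image synthetic cohort (30/class) with default planted effects."""
    cfg = SyntheticConfig(n_per_class=30, seed=0)
    manifest, images = generate_dataset(cfg)
    scheme = build_region_scheme(cfg.image_size, cfg.radial_step)
    table = build_feature_table(manifest, scheme, images=images)
    return cfg, manifest, images, scheme, table


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Fitted ensemble + regional reports on the 90-image cohort."""
    _, _, _, _, table = small_cohort
    split = patient_level_split(table, 0.2, seed=0)
    ensemble, reports = fit_ensemble(table, split)
    return table, split, ensemble, reports


@pytest.fixture(scope="session")
def study_scale_run():
    """Full pipeline at study scale: 300 images (100/class), seed 0.

    Shared by the end-to-end recovery checks so the expensive fit runs
    once per session.
    """
    cfg = SyntheticConfig(n_per_class=100, seed=0)
    manifest, images = generate_dataset(cfg)
    scheme = build_region_scheme(cfg.image_size, cfg.radial_step)
    table = build_feature_table(manifest, scheme, images=images)
    split = patient_level_split(table, 0.2, seed=0)
    ensemble, reports = fit_ensemble(table, split)
    return table, split, ensemble, reports


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
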