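import pytest

import mitedamage as md
from mitedamage import synthetic as syn


@pytest.fixture(scope="session")
def small_spec():
    return syn.PhenotypeSpec(genotype_label="col", rosette_radius=8.0,
                             damage_fraction=0.05)


@pytest.fixture(scope="session")
def small_scan(small_spec):
    return syn.generate_rosette(small_spec, seed=3, dpi=150, background="white")


@pytest.fixture(scope="session")
def small_control(small_spec):
    import dataclasses
    spec = dataclasses.replace(small_spec, damage_fraction=0.0)
    return syn.generate_rosette(spec, seed=4, dpi=150, background="white")


@pytest.fixture(scope="session")
def tiny_model(small_scan, small_control):
    """A quick random forest trained on one infested + one control scan."""
    labels = [syn.sample_labels(small_scan, 150, seed=11),
              syn.sample_labels(small_control, 150, seed=12)]
    return md.train_pixel_classifier(
        [small_scan.image, small_control.image], labels, seed=0, n_trees=30
    )


ML_RUN_SEED = 20
ML_RUN_KWARGS = dict(n_replicates=8, seed=ML_RUN_SEED, dpi=150.0,
                     background="black")


@pytest.fixture(scope="session")
def ml_run():
    """The reference machine-learning pipeline run on the default cohort.

    Three genotypes spanning the susceptibility spectrum (damage fractions
    0.01 / 0.015 / 0.05), eight treated and eight control replicates each,
    trained on six scans, cluster threshold auto-calibrated on controls,
    per-genotype control correction.
    """
    return md.run_ml_pipeline(**ML_RUN_KWARGS)
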