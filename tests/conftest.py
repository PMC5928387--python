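import numpy as np
import pytest

from factpipe.synthetic_imaging import ConditionSpec, SimulationConfig, generate_plate


@pytest.fixture(scope="session")
def small_plate():
    """One noisy well per condition at reduced scale, with ground truth."""
    config = SimulationConfig(
        conditions={"WT": ConditionSpec(1.0), "MT": ConditionSpec(3.0)},
        image_size=(384, 384),
        cells_per_well=80,
        wells_per_condition=1,
        seed=11,
    )
    images, truth = generate_plate(config)
    return config, images, truth


@pytest.fixture(scope="session")
def clean_sparse_plate():
    """Non-touching cells, no noise or blur: geometry-only ground truth."""
    config = SimulationConfig(
        conditions={"C": ConditionSpec(2.5, ncr_sigma=0.2)},
        image_size=(512, 512),
        cells_per_well=50,
        wells_per_condition=1,
        min_separation_factor=3.0,
        noise_sd=0.0,
        blur_sigma=0.0,
        transfection_fraction=1.0,
        seed=5,
    )
    images, truth = generate_plate(config)
    return config, images, truth
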