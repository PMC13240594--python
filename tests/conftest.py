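import dataclasses

import numpy as np
import pytest

from cryofsl import (PostprocessConfig, SyntheticSpec, generate_fewshot_dataset,
                     generate_micrograph)
from cryofsl.training import TrainConfig, build_desk_model, train_fewshot

# study conditions for desk-scale end-to-end runs: 128 px field, 16 px
# particles at SNR 4, 12 particles per image (near-maximal packing at
# 1.5-diameter separation on a 128 px field)
DESK_SPEC = SyntheticSpec(image_shape=(128, 128), n_particles=12,
                          diameter_px=16.0, snr=4.0, min_separation=24.0,
                          seed=100)
DESK_DIAMETER = 16.0


@pytest.fixture(scope="session")
def desk_spec() -> SyntheticSpec:
    return DESK_SPEC


@pytest.fixture(scope="session")
def postprocess_config() -> PostprocessConfig:
    return PostprocessConfig(expected_diameter_px=DESK_DIAMETER)


@pytest.fixture(scope="session")
def trained_desk_model():
    """One 5-shot training run shared by the end-to-end tests."""
    dataset = generate_fewshot_dataset(DESK_SPEC, K=5)
    model = build_desk_model(seed=0)
    config = TrainConfig(input_size=128, batch_size=2, learning_rate=3e-3,
                         max_epochs=80, seed=0)
    return train_fewshot(dataset, model, config)


@pytest.fixture(scope="session")
def heldout_micrographs():
    """Ten held-out synthetic micrographs under the desk conditions."""
    return [generate_micrograph(dataclasses.replace(DESK_SPEC, seed=500 + k))
            for k in range(10)]
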