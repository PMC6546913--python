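import dataclasses

import numpy as np
import pytest

from her2fish.synthetic import GeneratorConfig, render, sample_spec


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Desk-scale generator: smaller canvas and fewer nuclei for fast tests."""
    return dataclasses.replace(
        GeneratorConfig(), image_size=(800, 600), n_nuclei=(4, 7)
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    """One rendered clean scene shared by read-only tests."""
    spec = sample_spec(small_config, seed=1234)
    image, nuclei_ann, signal_sets = render(spec)
    return spec, image, nuclei_ann, signal_sets


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
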