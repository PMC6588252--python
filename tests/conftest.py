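import numpy as np
import pytest

from octexture import (
    ClassTextureParams,
    CohortConfig,
    LayerTextureParams,
    example_class_params,
)
from octexture.synth import LAYERS


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_config():
    """Small grid that still covers the ETDRS 3000 µm radius."""
    return CohortConfig(
        n_subjects_per_class=2,
        grid=(256, 128, 64),
        voxel_scale=(23.4, 47.0, 7.8),
        seed=99,
    )


@pytest.fixture
def tiny_params():
    return example_class_params(1.0)


@pytest.fixture
def flat_params():
    """One identical layer-texture parameter set for all classes."""
    lp = LayerTextureParams(base_intensity=80.0, noise_sd=10.0,
                            correlation_length_x=4.0, correlation_length_y=2.0)
    return {
        c: ClassTextureParams(c, {lyr: lp for lyr in LAYERS})
        for c in ("HC", "AD", "PD")
    }
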