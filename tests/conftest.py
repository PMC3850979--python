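import numpy as np
import pytest

from brightcell.config import PipelineConfig
from brightcell.synthetic import SceneSpec, generate_frame


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_frame():
    """One moderately populated 256x256 frame plus its ground truth."""
    spec = SceneSpec(image_shape=(256, 256), n_cells=20, seed=11)
    return generate_frame(spec)


@pytest.fixture(scope="session")
def clean_frame():
    """Debris-free flat-illumination frame, convenient for exact checks."""
    spec = SceneSpec(image_shape=(256, 256), n_cells=15, debris_count=0,
                     illumination="flat", seed=12)
    return generate_frame(spec)


def disk_mask(shape, center, radius):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
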