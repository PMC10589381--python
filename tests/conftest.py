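import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from wormspan.blob_world import SimConfig
from wormspan.survival_sim import GridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sim_config():
    """64x64 frames, 10-day sequences: the CPU-scale simulator setup."""
    return SimConfig(image_size=64, seq_length=10, plate_margin=5)


@pytest.fixture
def clean_sim_config():
    """Tiny setup with every nuisance disabled: no occlusion, no blanks,
    no frame perturbation — renders are exact."""
    return SimConfig(image_size=64, seq_length=10, plate_margin=5,
                     occlusion_prob=0.0, blank_day_schedule=frozenset(),
                     max_rotation=0.0, max_translation=0.0,
                     perturb_magnitude=0.0)


@pytest.fixture
def tiny_grid():
    return GridSpec((12, 12), (6, 6), (5, 5))


def count_components(frame, background=255):
    """Connected foreground components of a rendered blob frame."""
    from skimage import measure
    fg = frame < (background // 2 + 1) if background > 127 else frame > 127
    return int(measure.label(fg, connectivity=2).max())
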