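import numpy as np
import pytest

from actinf.visual_world import FovealSampler, HypothesisSet, TemplateImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_sampler():
    """A small foveal sampler (5x5 lattice in the disc) for fast tests."""
    return FovealSampler(sigma_fov=0.25, grid_side=5, max_precision=8.0)


@pytest.fixture
def dot_hypotheses():
    """Two 9x9 templates differing in one bright dot; truth is the dot."""
    blank = np.zeros((9, 9))
    dot = blank.copy()
    dot[2, 6] = 1.0
    return HypothesisSet(
        templates=[TemplateImage(blank, "blank"), TemplateImage(dot, "dot")],
        true_index=1,
    )
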