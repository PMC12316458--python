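import numpy as np
import pytest

from kvflow.core import Track
from kvflow.synthetic_data import RenderConfig, render_image_stack


@pytest.fixture(scope="session")
def separated_bead_scene():
    """Ten static, well-separated beads rendered at SNR 10, with ground truth."""
    xs = [8, 24, 40, 56, 8, 24, 40, 56, 16, 48]
    ys = [8, 8, 8, 8, 40, 40, 40, 40, 24, 56]
    frames = np.arange(5)
    tracks = [
        Track(i, frames, frames * 0.25, np.full(5, float(x)), np.full(5, float(y)))
        for i, (x, y) in enumerate(zip(xs, ys))
    ]
    stack, truth = render_image_stack(tracks, RenderConfig(seed=11))
    return stack, truth, tracks
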