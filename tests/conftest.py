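import numpy as np
import pytest

from napscope import Landmark, PoseFrame
from napscope.synthetic_session import CONTROLLED_ANGLES, place_frame


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_frame(
    angles=None,
    frame_index=0,
    time_s=0.0,
    width=640,
    height=480,
    drop=(),
    visibility=None,
):
    """A complete, geometrically valid pose frame realizing the given
    shoulder/elbow/hip/knee angles (default: all limbs at 90 deg)."""
    if angles is None:
        angles = {a: 90.0 for a in CONTROLLED_ANGLES}
    points = place_frame(angles, width, height)
    for lm in drop:
        points.pop(Landmark.parse(lm) if isinstance(lm, str) else lm)
    vis = {}
    if visibility:
        vis = {
            (Landmark.parse(k) if isinstance(k, str) else k): v
            for k, v in visibility.items()
        }
    return PoseFrame(
        frame_index=frame_index,
        time_s=time_s,
        width_px=width,
        height_px=height,
        points=points,
        visibility=vis,
    )


@pytest.fixture
def complete_frame():
    return make_frame()
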