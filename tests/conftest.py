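import numpy as np
import pytest

import chromatex as cx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_roi():
    """Axis-aligned 1000 x 1000 nm square."""
    return cx.RoiPolygon([[0, 0], [1000, 0], [1000, 1000], [0, 1000]])


@pytest.fixture
def c_shape_roi():
    """Concave C-shaped polygon (nm): a square with a rectangular bite."""
    return cx.RoiPolygon([
        [0, 0], [1000, 0], [1000, 250], [300, 250], [300, 750],
        [1000, 750], [1000, 1000], [0, 1000],
    ])


@pytest.fixture
def circle_roi():
    """64-gon approximation of a 5 um-radius circle centred at (6, 6) um."""
    return cx.circle_polygon(5000.0, (6000.0, 6000.0))


@pytest.fixture
def star_blob():
    """Factory for random star-shaped blob contours (hand-drawn-nucleus-like)."""
    def make(seed: int, radius_nm: float = 5000.0):
        return cx.blob_polygon(radius_nm, (1.5 * radius_nm, 1.5 * radius_nm),
                               rng=np.random.default_rng(seed))
    return make


def make_table(xy, frame=None):
    xy = np.asarray(xy, dtype=float)
    if frame is None:
        frame = np.arange(1, len(xy) + 1)
    return cx.LocalisationTable(frame=frame, x_nm=xy[:, 0], y_nm=xy[:, 1])
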