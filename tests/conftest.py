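import numpy as np
import pytest

from larvamorph import OutlineContour

from shapes import make_polygon


@pytest.fixture
def unit_square() -> OutlineContour:
    return OutlineContour(
        points=np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    )


@pytest.fixture
def circle():
    """Radius-2 circle, 360 vertices, CCW from (2, 0)."""
    t = np.linspace(0.0, 2.0 * np.pi, 360, endpoint=False)
    return OutlineContour(points=np.column_stack([2 * np.cos(t), 2 * np.sin(t)]))


@pytest.fixture
def random_polygon():
    """Factory fixture: irregular star polygon (see shapes.make_polygon)."""
    return make_polygon
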