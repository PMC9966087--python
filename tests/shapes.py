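"""Shared synthetic test shapes."""

import numpy as np

from larvamorph import OutlineContour, resample_contour


def make_polygon(seed: int = 7, n_vertices: int = 11, resample: int | None = 240):
    """Irregular star polygon with no special symmetry."""
    rng = np.random.default_rng(seed)
    th = np.sort(rng.uniform(0.0, 2.0 * np.pi, n_vertices))
    th = th + np.linspace(0.0, 1e-6, n_vertices)
    r = rng.uniform(0.5, 2.0, n_vertices)
    c = OutlineContour(points=np.column_stack([r * np.cos(th), r * np.sin(th)]))
    return resample_contour(c, resample) if resample else c


def make_wavy_circle(amplitude: float = 0.05, lobes: int = 3, n: int = 720):
    """Near-circular smooth contour: r = 2 + amplitude * cos(lobes * t).

    Traversal speed is nearly uniform, so elliptic-Fourier round trips
    through reconstruction are close to exact.
    """
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    r = 2.0 + amplitude * np.cos(lobes * t)
    return OutlineContour(points=np.column_stack([r * np.cos(t), r * np.sin(t)]))
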