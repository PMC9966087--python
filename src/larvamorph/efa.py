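"""Elliptic Fourier analysis (EFA) of closed outlines.

A closed outline traversed at constant speed defines two periodic signals
x(t), y(t) with period T equal to the perimeter.  EFA expands both as
truncated Fourier series,

    x(t) = A0 + sum_n  a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = C0 + sum_n  c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T),

so each harmonic n contributes an ellipse with coefficient matrix
[[a_n, b_n], [c_n, d_n]].  For a polygonal outline x(t) and y(t) are
piecewise linear, and the coefficient integrals have exact closed forms
over the segments (the classic Kuhl-Giardina sums) — no FFT and no
sampling error beyond the polygon itself.

Normalization follows the first-harmonic-ellipse method used by the SHAPE
software family: size is divided out by the first ellipse's semi-major
axis, orientation rotated so that axis lies along +x, and the starting
point shifted to the axis end, leaving a_1 = 1 and b_1 = c_1 = 0.  The
removed similarity transform is returned so it can be exactly inverted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .outlines import OutlineContour, DegenerateContourError

__all__ = [
    "EFACoefficients",
    "NormalizationParams",
    "efa_decompose",
    "efa_normalize",
    "efa_denormalize",
    "efa_reconstruct",
    "coeffs_to_vector",
    "vector_to_coeffs",
    "feature_vector",
    "feature_vector_to_coeffs",
]


@dataclass(frozen=True)
class EFACoefficients:
    """Harmonic coefficient set for one outline.

    ``harmonics`` is an ``(n_harmonics, 4)`` array with columns
    ``a_n, b_n, c_n, d_n``; ``A0, C0`` are the outline's Fourier-mean
    (DC) point.  ``normalized`` records whether the SHAPE-style
    normalization has been applied (then ``a_1 = 1``, ``b_1 = c_1 = 0``
    and ``A0 = C0 = 0``).
    """

    harmonics: np.ndarray
    A0: float = 0.0
    C0: float = 0.0
    normalized: bool = False

    def __post_init__(self) -> None:
        h = np.asarray(self.harmonics, dtype=float)
        if h.ndim != 2 or h.shape[1] != 4 or h.shape[0] < 1:
            raise ValueError(f"harmonics must be (n>=1, 4), got {h.shape}")
        object.__setattr__(self, "harmonics", h)

    @property
    def n_harmonics(self) -> int:
        return len(self.harmonics)

    def coeff(self, name: str, n: int) -> float:
        """Coefficient by name ('a'..'d') and 1-based harmonic index."""
        return float(self.harmonics[n - 1, "abcd".index(name)])


@dataclass(frozen=True)
class NormalizationParams:
    """The similarity transform removed by :func:`efa_normalize`.

    ``scale`` is the first-harmonic semi-major axis length; ``rotation``
    the spatial rotation removed (radians); ``phase`` the starting-point
    parameter shift (radians of the first-harmonic period); ``reflected``
    whether the y-axis was flipped by reflection standardization.
    """

    scale: float
    rotation: float
    phase: float
    reflected: bool = False

    def __post_init__(self) -> None:
        if not self.scale > 0.0:
            raise ValueError("scale must be positive")


def efa_decompose(contour: OutlineContour, n_harmonics: int = 20) -> EFACoefficients:
    """Exact Kuhl-Giardina decomposition of a polygonal outline.

    Integrates the piecewise-linear x(t), y(t) segment by segment, which
    is exact for polygons (unlike FFT estimation, which assumes samples
    equally spaced in arc length).
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    pts = np.vstack([contour.points, contour.points[:1]])
    d = np.diff(pts, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    if not np.all(dt > 0):
        raise DegenerateContourError("zero-length segment in contour")
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise DegenerateContourError("zero perimeter")
    # DC terms: exact mean of the piecewise-linear parametrisation
    mid = (pts[:-1] + pts[1:]) / 2.0
    A0, C0 = (mid * dt[:, None]).sum(axis=0) / T

    n = np.arange(1, n_harmonics + 1)[:, None]  # (N, 1)
    omega_t0 = 2.0 * np.pi * n * t[:-1][None, :] / T
    omega_t1 = 2.0 * np.pi * n * t[1:][None, :] / T
    dcos = np.cos(omega_t1) - np.cos(omega_t0)
    dsin = np.sin(omega_t1) - np.sin(omega_t0)
    slope = d / dt[:, None]  # (K, 2): dx/dt, dy/dt per segment
    const = T / (2.0 * np.pi**2 * n[:, 0] ** 2)
    a = const * (dcos @ slope[:, 0])
    b = const * (dsin @ slope[:, 0])
    c = const * (dcos @ slope[:, 1])
    dd = const * (dsin @ slope[:, 1])
    return EFACoefficients(
        harmonics=np.column_stack([a, b, c, dd]), A0=float(A0), C0=float(C0)
    )


def _rotate_start(h: np.ndarray, theta: float) -> np.ndarray:
    """Shift the starting point by phase ``theta`` (harmonic n by n*theta)."""
    n = np.arange(1, len(h) + 1)
    cn, sn = np.cos(n * theta), np.sin(n * theta)
    a, b, c, d = h.T
    return np.column_stack(
        [a * cn + b * sn, -a * sn + b * cn, c * cn + d * sn, -c * sn + d * cn]
    )


def _rotate_space(h: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the outline by ``-psi`` (premultiply by R(-psi))."""
    cp, sp = np.cos(psi), np.sin(psi)
    a, b, c, d = h.T
    return np.column_stack(
        [cp * a + sp * c, cp * b + sp * d, -sp * a + cp * c, -sp * b + cp * d]
    )


def _normalize_with_phase(h: np.ndarray, theta: float) -> tuple[np.ndarray, float, float]:
    hs = _rotate_start(h, theta)
    psi = float(np.arctan2(hs[0, 2], hs[0, 0]))
    hr = _rotate_space(hs, psi)
    scale = hr[0, 0]  # = +semi-major axis length by construction
    return hr / scale, psi, scale


def efa_normalize(
    coeffs: EFACoefficients, *, standardize_reflection: bool = False
) -> tuple[EFACoefficients, NormalizationParams]:
    """First-harmonic-ellipse normalization (size/rotation/starting point).

    Returns the normalized coefficients and the parameters that exactly
    invert the transform.  With ``standardize_reflection`` chirality is
    removed: the outline is replaced by its mirror image when needed so
    that a fixed-sign convention holds, making an outline and its mirror
    (e.g. the same head seen dorsally vs ventrally) map to the same
    coefficients.  Off by default so mirror images remain distinct
    shapes.  (Because ingestion orients every contour counter-clockwise,
    chirality lives in the signs of the b/c coefficients rather than in
    d_1; the convention forces the largest-magnitude b/c coefficient
    positive, and is therefore stable under digitisation noise.)
    """
    h = coeffs.harmonics.copy()
    a1, b1, c1, d1 = h[0]
    if np.hypot(np.hypot(a1, b1), np.hypot(c1, d1)) < 1e-300:
        raise DegenerateContourError("degenerate first harmonic")
    theta = 0.5 * np.arctan2(
        2.0 * (a1 * b1 + c1 * d1), a1**2 + c1**2 - b1**2 - d1**2
    )
    reflected = False
    cand = []
    for th in (theta, theta + np.pi):
        hn, psi, scale = _normalize_with_phase(h, th)
        if scale <= 0:
            raise DegenerateContourError("degenerate first-harmonic ellipse")
        cand.append((hn, psi, th, scale))
    hn, psi, theta, scale = _canonical_candidate(cand)
    if standardize_reflection:
        # chirality sign read from odd-harmonic b/c coefficients (n >= 3):
        # these are invariant under the start-candidate flip, so the
        # convention is independent of the orientation convention
        bc = hn[2::2, 1:3].ravel()
        if not len(bc) or np.abs(bc).max() <= 1e-12:
            bc = hn[1:, 1:3].ravel()
        if len(bc) and np.abs(bc).max() > 1e-12 and bc[np.argmax(np.abs(bc))] < 0:
            # mirror across the x-axis with traversal re-orientation:
            # (a, b, c, d) -> (a, -b, -c, d) per harmonic
            hn = hn * np.array([1.0, -1.0, -1.0, 1.0])
            reflected = True
            # the mirror may violate the orientation convention; re-pick
            # between the start candidates of the mirrored shape
            cand_m = [
                (hn, psi, theta, scale),
                (hn * _even_flip(len(hn)), psi + np.pi, theta + np.pi, scale),
            ]
            hn, psi, theta, scale = _canonical_candidate(cand_m)
    norm = EFACoefficients(harmonics=hn, A0=0.0, C0=0.0, normalized=True)
    params = NormalizationParams(
        scale=float(scale),
        rotation=float(_wrap_angle(psi)),
        phase=float(_wrap_angle(theta)),
        reflected=reflected,
    )
    return norm, params


def _even_flip(n_harmonics: int) -> np.ndarray:
    """Column mask multiplying even harmonics by -1 (a half-period start
    shift combined with a half-turn rotation)."""
    n = np.arange(1, n_harmonics + 1)
    return np.where(n % 2 == 0, -1.0, 1.0)[:, None]


def _canonical_candidate(candidates):
    """Pick between the two half-period starting points deterministically.

    The two candidates differ by a half-turn of the outline plus a
    half-period start shift (equivalently: a sign flip of all even
    harmonics), so normalization alone leaves a two-fold ambiguity.  The
    canonical choice orients the outline's asymmetric mass: the candidate
    whose reconstructed x-coordinates have positive skewness (the
    pointier/heavier end of the shape lies towards +x) is taken.  This is
    stable under digitisation noise because it depends on the gross shape,
    not on any single near-zero coefficient.  For skew-free shapes the
    largest-magnitude differing coefficient is required to be positive
    instead.  Either way the result is exactly invariant to the
    digitisation starting point.
    """
    t = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
    hn = candidates[0][0]
    n = np.arange(1, len(hn) + 1)[:, None]
    cos_nt, sin_nt = np.cos(n * t), np.sin(n * t)
    x = hn[:, 0] @ cos_nt + hn[:, 1] @ sin_nt
    y = hn[:, 2] @ cos_nt + hn[:, 3] @ sin_nt
    sx = float(np.mean((x - x.mean()) ** 3))
    sy = float(np.mean((y - y.mean()) ** 3))
    skew = sx if abs(sx) >= abs(sy) else sy
    if abs(skew) > 1e-9:
        return candidates[0] if skew > 0 else candidates[1]
    h0, h1 = candidates[0][0].ravel(), candidates[1][0].ravel()
    diff = np.abs(h0 - h1)
    if diff.max() <= 1e-12:
        return candidates[0]
    idx = int(np.argmax(diff))
    return candidates[0] if h0[idx] > 0 else candidates[1]


def _wrap_angle(x: float) -> float:
    """Wrap to (-pi, pi]."""
    w = float(np.arctan2(np.sin(x), np.cos(x)))
    return np.pi if np.isclose(w, -np.pi) else w


def efa_denormalize(
    coeffs: EFACoefficients,
    params: NormalizationParams,
    *,
    A0: float = 0.0,
    C0: float = 0.0,
) -> EFACoefficients:
    """Exactly invert :func:`efa_normalize` given its returned params."""
    h = coeffs.harmonics.copy()
    if params.reflected:
        h = h * np.array([1.0, -1.0, -1.0, 1.0])
    h = h * params.scale
    h = _rotate_space(h, -params.rotation)
    h = _rotate_start(h, -params.phase)
    return EFACoefficients(harmonics=h, A0=A0, C0=C0, normalized=False)


def efa_reconstruct(
    coeffs: EFACoefficients, n_points: int = 256, **contour_kwargs
) -> OutlineContour:
    """Evaluate the truncated series at equally spaced parameter values."""
    if n_points < 8:
        raise ValueError(f"n_points must be >= 8, got {n_points}")
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    n = np.arange(1, coeffs.n_harmonics + 1)[:, None]
    cos_nt = np.cos(n * t[None, :])
    sin_nt = np.sin(n * t[None, :])
    a, b, c, d = coeffs.harmonics.T
    x = coeffs.A0 + a @ cos_nt + b @ sin_nt
    y = coeffs.C0 + c @ cos_nt + d @ sin_nt
    return OutlineContour(points=np.column_stack([x, y]), **contour_kwargs)


# ---------------------------------------------------------------------------
# flat-vector views (for tables and PCA)


def coeffs_to_vector(coeffs: EFACoefficients) -> np.ndarray:
    """Flatten to ``[a1, b1, c1, d1, a2, ...]`` (no DC terms)."""
    return coeffs.harmonics.ravel().copy()


def vector_to_coeffs(vec: np.ndarray, *, normalized: bool = False) -> EFACoefficients:
    v = np.asarray(vec, dtype=float)
    if v.size % 4:
        raise ValueError("coefficient vector length must be a multiple of 4")
    return EFACoefficients(harmonics=v.reshape(-1, 4), normalized=normalized)


def feature_vector(coeffs: EFACoefficients) -> np.ndarray:
    """PCA feature vector of a normalized coefficient set.

    Drops the constant columns a1 (=1), b1 and c1 (=0), keeping
    ``[d1, a2, b2, c2, d2, ...]``.
    """
    if not coeffs.normalized:
        raise ValueError("feature_vector requires normalized coefficients")
    return coeffs_to_vector(coeffs)[3:]


def feature_vector_to_coeffs(vec: np.ndarray) -> EFACoefficients:
    """Inverse of :func:`feature_vector`: reinsert a1=1, b1=c1=0."""
    v = np.concatenate([[1.0, 0.0, 0.0], np.asarray(vec, dtype=float)])
    return vector_to_coeffs(v, normalized=True)
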