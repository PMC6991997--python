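"""Direct least-squares ellipse fitting and rasterization.

The selected disc component has a ragged boundary after vessel removal and
morphology; fitting an ellipse to its outer contour and rasterizing the fit
gives the final smooth disc mask.  The fit is the direct conic
least-squares method with the ellipse-specific constraint ``4ac - b^2 = 1``
(Fitzgibbon), in the numerically stabilized block form of Halir & Flusser,
with the points centered and scaled beforehand for conditioning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import ellipse_interior
from .errors import EllipseFitError


@dataclass
class EllipseParams:
    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (a, b), a >= b > 0
    angle: float  # major-axis orientation, radians in [0, pi)


def fit_ellipse(points: np.ndarray) -> EllipseParams:
    """Fit an ellipse to ``points`` (N x 2, (row, col)) by direct least
    squares with the ellipse constraint.

    Exact samples of an ellipse are recovered to ~1e-6 relative accuracy.
    Raises :class:`EllipseFitError` for < 6 points or degenerate input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise EllipseFitError("need at least 6 (row, col) points")
    # math coordinates: x = col, y = row; normalize for conditioning
    x = pts[:, 1]
    y = pts[:, 0]
    mx, my = x.mean(), y.mean()
    s = np.sqrt(((x - mx) ** 2 + (y - my) ** 2).mean())
    if s == 0:
        raise EllipseFitError("degenerate (coincident) points")
    xn = (x - mx) / s
    yn = (y - my) / s

    d1 = np.column_stack([xn**2, xn * yn, yn**2])
    d2 = np.column_stack([xn, yn, np.ones_like(xn)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("degenerate point configuration") from exc
    m = s1 + s2 @ t
    # inverse of the constraint matrix C1 = [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    w, v = np.linalg.eig(m)
    cond = 4.0 * v[0] * v[2] - v[1] ** 2
    ok = np.nonzero((cond > 0) & np.isfinite(w))[0]
    if ok.size == 0:
        raise EllipseFitError("no elliptical solution (points may be degenerate)")
    a1 = v[:, ok[0]]
    coeffs = np.concatenate([a1, t @ a1])  # a, b, c, d, e, f in normalized frame
    params = _conic_to_geometric(coeffs)
    (cx, cy), (ax_a, ax_b), angle_xy = params
    # denormalize (isotropic scale + shift leaves the angle unchanged)
    cx = cx * s + mx
    cy = cy * s + my
    ax_a *= s
    ax_b *= s
    # convert math-plane angle (x right, y down since y = row) to the
    # (row, col) convention: major-axis direction (drow, dcol) = (sin, cos)
    angle = float(np.mod(angle_xy, np.pi))
    return EllipseParams(center=(float(cy), float(cx)), semi_axes=(float(ax_a), float(ax_b)), angle=angle)


def _conic_to_geometric(coeffs: np.ndarray):
    """Convert conic ``ax^2 + bxy + cy^2 + dx + ey + f = 0`` to center,
    semi-axes (major first) and major-axis angle in the (x, y) plane."""
    a, b, c, d, e, f = coeffs
    den = 4.0 * a * c - b * b
    if den <= 0:
        raise EllipseFitError("conic is not an ellipse")
    cx = (b * e - 2.0 * c * d) / den
    cy = (b * d - 2.0 * a * e) / den
    mu = a * cx**2 + b * cx * cy + c * cy**2 + d * cx + e * cy + f
    q = np.array([[a, b / 2.0], [b / 2.0, c]])
    evals, evecs = np.linalg.eigh(q)
    axes2 = -mu / evals
    if np.any(axes2 <= 0):
        raise EllipseFitError("conic is not a real ellipse")
    axes = np.sqrt(axes2)
    order = np.argsort(axes)[::-1]  # major first
    major_vec = evecs[:, order[0]]
    angle = np.arctan2(major_vec[1], major_vec[0])
    return (cx, cy), (float(axes[order[0]]), float(axes[order[1]])), float(angle)


def rasterize_ellipse(params: EllipseParams, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixel centers inside the ellipse, clipped to shape."""
    return ellipse_interior(shape, params.center, params.semi_axes, params.angle)


def boundary_points(mask: np.ndarray) -> np.ndarray:
    """Sub-pixel outer contour of the largest component of ``mask`` as
    (row, col) points (marching squares at level 0.5).

    A sub-pixel contour sits halfway between inside and outside pixels, so
    a fit to it is unbiased with respect to the rasterization.
    """
    from skimage.measure import find_contours

    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise EllipseFitError("mask has no boundary")
    contour = max(contours, key=len)
    return contour - 1.0  # undo padding offset


def fit_region_ellipse(mask: np.ndarray) -> EllipseParams:
    """Fit an ellipse to the outer contour of a binary region."""
    return fit_ellipse(boundary_points(mask))
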