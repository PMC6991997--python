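"""Shared raster helpers: structuring elements, ellipse rasterization, FOV handling."""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi


def disc_footprint(diameter: int) -> np.ndarray:
    """Boolean disc structuring element of the given pixel diameter.

    Odd diameters match the usual radius-(d-1)/2 disc on an odd grid; even
    diameters use a half-integer center so the support really spans
    ``diameter`` pixels.
    """
    if diameter < 1:
        raise ValueError(f"diameter must be >= 1, got {diameter}")
    c = (diameter - 1) / 2.0
    yy, xx = np.mgrid[0:diameter, 0:diameter]
    return (yy - c) ** 2 + (xx - c) ** 2 <= (diameter / 2.0 - 0.5 + 1e-9) ** 2 + 1e-9


def line_footprint(length: int, angle_deg: float) -> np.ndarray:
    """Boolean line structuring element: nearest-pixel rasterization of a
    centered segment of ``length`` samples at ``angle_deg`` (0 = horizontal,
    measured counterclockwise with rows growing downward)."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    offs = line_offsets(length, angle_deg)
    r = int(np.abs(offs[:, 0]).max())
    c = int(np.abs(offs[:, 1]).max())
    fp = np.zeros((2 * r + 1, 2 * c + 1), dtype=bool)
    fp[offs[:, 0] + r, offs[:, 1] + c] = True
    return fp


def line_offsets(length: int, angle_deg: float) -> np.ndarray:
    """Integer (drow, dcol) offsets of the rasterized centered segment.

    Duplicates from rounding are kept: the segment is defined as ``length``
    equally spaced samples, so means along it weight repeated pixels.
    """
    theta = np.deg2rad(angle_deg)
    d = np.arange(length, dtype=float) - (length - 1) / 2.0
    dr = np.rint(-d * np.sin(theta)).astype(int)
    dc = np.rint(d * np.cos(theta)).astype(int)
    return np.stack([dr, dc], axis=1)


def ellipse_interior(
    shape: tuple[int, int],
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    """Boolean mask of pixel centers inside the ellipse.

    ``angle`` is the major-axis orientation in radians, measured from the
    column axis toward the row axis (i.e. atan2(drow, dcol) of the major-axis
    direction).
    """
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ct, st = np.cos(angle), np.sin(angle)
    along = dc * ct + dr * st
    perp = -dc * st + dr * ct
    return (along / a) ** 2 + (perp / b) ** 2 <= 1.0


def circle_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def compute_fov_mask(image: np.ndarray, threshold: float = 0.02) -> np.ndarray:
    """Estimate the circular field of view: non-black pixels, hole-filled,
    largest connected component."""
    gray = image.mean(axis=2) if image.ndim == 3 else image
    raw = gray > threshold
    if not raw.any():
        return raw
    filled = ndi.binary_fill_holes(raw)
    labels, n = ndi.label(filled)
    if n > 1:
        sizes = ndi.sum_labels(filled, labels, index=np.arange(1, n + 1))
        filled = labels == (1 + int(np.argmax(sizes)))
    return filled


def as_float_rgb(image: np.ndarray) -> np.ndarray:
    """Coerce an RGB raster to float64 in [0, 1]."""
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    img = np.asarray(image[..., :3])
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    if img.dtype == np.uint16:
        return img.astype(np.float64) / 65535.0
    img = img.astype(np.float64)
    if img.max() > 1.0 + 1e-6:
        img = img / 255.0
    return np.clip(img, 0.0, 1.0)
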