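"""Optic-disc localization on the de-hazed image and ROI cropping.

The green channel is used because vessels are most prominent there.  Vessels
are suppressed by the maximum over angular dilations with a short line
structuring element; remaining bright distractors smaller than the disc are
removed by a grey-scale opening (erosion with a disc, then dilation with a
larger disc).  Otsu thresholding of the in-FOV result yields bright
candidate regions; the centroid of the least eccentric one is taken as the
disc center, around which a square working crop and a circular region of
interest of radius ``R = R_a * (1 + roi_factor)`` are laid out (``R_a`` is
the dataset's average disc radius).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import disk

from ._util import circle_mask, line_footprint
from .errors import LocalizationError, ParameterError
from .segment import compute_region_props


@dataclass
class LocalizationConfig:
    line_se_length: int = 12
    n_angles: int = 15
    erosion_disc: int = 15  # radius, px
    dilation_disc: int = 20  # radius, px
    crop_size: int = 300
    avg_radius: float = 40.0  # dataset prior R_a, px at working scale
    roi_factor: float = 0.3

    def validate(self) -> None:
        if self.n_angles < 1:
            raise ParameterError("n_angles must be >= 1")
        if self.line_se_length < 1:
            raise ParameterError("line_se_length must be >= 1")
        if self.crop_size <= 2 * self.avg_radius * (1 + self.roi_factor):
            raise ParameterError(
                "crop_size must exceed the ROI diameter 2*R_a*(1+roi_factor)"
            )


@dataclass
class LocalizationResult:
    od_center: tuple[float, float]  # full-image coordinates
    crop_origin: tuple[int, int]
    roi_mask: np.ndarray = field(repr=False)


def angular_dilation_max(green: np.ndarray, length: int = 12, n_angles: int = 15) -> np.ndarray:
    """Pixelwise max over grey dilations with line SEs at n_angles uniform
    orientations in [0, 180)."""
    if length < 1:
        raise ParameterError("length must be >= 1")
    out = None
    for k in range(n_angles):
        fp = line_footprint(length, 180.0 * k / n_angles)
        d = ndi.grey_dilation(green, footprint=fp, mode="reflect")
        out = d if out is None else np.maximum(out, d)
    return out


def suppress_distractors(
    image: np.ndarray, erosion_disc: int = 15, dilation_disc: int = 20
) -> np.ndarray:
    """Grey erosion with a disc then dilation with a (larger) disc.

    Removes bright features smaller than the erosion disc — light artifacts,
    exudates — while the disc-sized OD survives.
    """
    if erosion_disc < 1 or dilation_disc < 1:
        raise ParameterError("disc sizes must be >= 1")
    er = ndi.grey_erosion(image, footprint=disk(erosion_disc), mode="reflect")
    return ndi.grey_dilation(er, footprint=disk(dilation_disc), mode="reflect")


def otsu_threshold(image: np.ndarray) -> tuple[float, np.ndarray]:
    """Otsu's threshold (max between-class variance over a 256-bin histogram)
    and the mask ``image > threshold``.

    A constant image has no between-class structure: returns an all-false
    mask with a warning instead of failing.
    """
    vals = np.asarray(image)
    if np.all(vals == vals.flat[0]):
        warnings.warn("constant image: Otsu threshold undefined, returning empty mask")
        return float(vals.flat[0]), np.zeros(vals.shape, dtype=bool)
    uniq, counts = np.unique(vals, return_counts=True)
    if uniq.size <= 4096:
        # exact histogram over the occupied levels: the between-class
        # variance search then sees the true discrete distribution
        level = float(threshold_otsu(hist=(counts, uniq)))
        # report the class boundary as the midpoint to the next occupied
        # level; the mask (vals > thr) is identical either way
        above = uniq[uniq > level]
        thr = float((level + above[0]) / 2.0) if above.size else level
    else:
        thr = float(threshold_otsu(vals, nbins=256))
    return thr, vals > thr


def pick_od_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Centroid of the connected component with minimum eccentricity.

    Ties broken by larger area, then by top-left (row, col) centroid order.
    """
    props = compute_region_props(mask)
    if not props:
        raise LocalizationError("no candidate component for OD localization")
    best = min(props, key=lambda p: (p.eccentricity, -p.area, p.centroid[0], p.centroid[1]))
    return best.centroid


def crop_roi(
    image: np.ndarray, center: tuple[float, float], cfg: LocalizationConfig
) -> tuple[np.ndarray, LocalizationResult]:
    """Cut a ``crop_size`` square window around ``center`` (shifted inward at
    borders) and build the circular ROI mask about the detected center."""
    h, w = image.shape[:2]
    size = cfg.crop_size
    if h < size or w < size:
        warnings.warn("image smaller than crop_size; cropping the full image")
        size_r, size_c = min(size, h), min(size, w)
    else:
        size_r = size_c = size
    r0 = int(round(center[0] - size_r / 2))
    c0 = int(round(center[1] - size_c / 2))
    r0 = min(max(r0, 0), h - size_r)
    c0 = min(max(c0, 0), w - size_c)
    crop = image[r0 : r0 + size_r, c0 : c0 + size_c].copy()
    center_in_crop = (center[0] - r0, center[1] - c0)
    radius = cfg.avg_radius * (1.0 + cfg.roi_factor)
    roi = circle_mask((size_r, size_c), center_in_crop, radius)
    return crop, LocalizationResult(
        od_center=(float(center[0]), float(center[1])),
        crop_origin=(r0, c0),
        roi_mask=roi,
    )


def localize_od(
    image: np.ndarray, fov: np.ndarray, cfg: LocalizationConfig | None = None
) -> tuple[np.ndarray, LocalizationResult]:
    """Run the full localization chain on a (de-hazed) RGB image.

    Returns the cropped working image and the localization result.
    """
    cfg = cfg or LocalizationConfig()
    cfg.validate()
    if not fov.any():
        raise LocalizationError("empty field of view")
    green = image[..., 1]
    vessel_free = angular_dilation_max(green, cfg.line_se_length, cfg.n_angles)
    cleaned = suppress_distractors(vessel_free, cfg.erosion_disc, cfg.dilation_disc)
    # Otsu statistics over in-FOV pixels only: the black surround would
    # otherwise dominate the histogram.
    vals = cleaned[fov]
    if np.all(vals == vals[0]):
        raise LocalizationError("no contrast inside the field of view")
    thr, _ = otsu_threshold(vals)
    mask = (cleaned > thr) & fov
    if not mask.any():
        raise LocalizationError("Otsu mask empty inside the field of view")
    center = pick_od_centroid(mask)
    return crop_roi(image, center, cfg)
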