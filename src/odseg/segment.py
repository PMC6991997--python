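"""Binarization of the vessel-free V channel and optic-disc candidate selection.

Two independent binarizations are produced: (1) adaptive thresholding — the
sign of the difference between the channel and its Gaussian-blurred local
background (sigma = 7 px), cleaned by a binary erosion (disc diameter 13)
then dilation (disc diameter 12); and (2) seeded region growing from the
localized disc center, admitting at each step the 8-connected frontier
pixel whose intensity is closest to the running region mean, until that
closest difference exceeds a tolerance (0.05 on the [0, 1] V scale).

Candidates from both routes are pooled; the component whose area lies in
``A_a * (1 ∓ 0.35)`` (``A_a`` the dataset's average disc area) with the
smallest eccentricity ``E = sqrt(Mj^2 - Mn^2) / Mj`` is selected as the
optic disc.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as sk_label, regionprops as sk_regionprops

from ._util import disc_footprint
from .errors import InputError, ParameterError, SegmentationError


@dataclass
class RegionProps:
    """Shape descriptors of one 8-connected component."""

    label: int
    area: int
    centroid: tuple[float, float]
    major_axis: float  # M_j
    minor_axis: float  # M_n
    eccentricity: float  # E = sqrt(Mj^2 - Mn^2)/Mj
    mask: np.ndarray = field(repr=False)  # full-size boolean component mask


@dataclass
class SelectionConfig:
    avg_area: float = 5027.0  # A_a, px^2 at working scale (pi * 40^2)
    area_tolerance: float = 0.35
    grow_tolerance: float = 0.05
    erosion_diameter: int = 13
    dilation_diameter: int = 12
    sigma: float = 7.0
    similarity: str = "mean"  # running region mean, or "seed" for seed value

    def validate(self) -> None:
        if self.avg_area <= 0:
            raise ParameterError("avg_area must be > 0")
        if not (0 < self.area_tolerance < 1):
            raise ParameterError("area_tolerance must be in (0, 1)")
        if self.grow_tolerance <= 0:
            raise ParameterError("grow_tolerance must be > 0")
        if self.sigma <= 0:
            raise ParameterError("sigma must be > 0")
        if self.similarity not in ("mean", "seed"):
            raise ParameterError("similarity must be 'mean' or 'seed'")

    @property
    def area_range(self) -> tuple[float, float]:
        return (
            self.avg_area * (1.0 - self.area_tolerance),
            self.avg_area * (1.0 + self.area_tolerance),
        )


def adaptive_threshold(v: np.ndarray, roi: np.ndarray, sigma: float = 7.0) -> np.ndarray:
    """Sign of the background-subtracted channel, restricted to the ROI.

    The local background is a Gaussian blur (sigma much smaller than the
    disc radius); the mask is ``(v - blur) > 0`` — structures brighter than
    their neighborhood.
    """
    if sigma <= 0:
        raise ParameterError("sigma must be > 0")
    diff = v - ndi.gaussian_filter(v, sigma, mode="reflect")
    return (diff > 0) & roi


def morph_clean(
    mask: np.ndarray, erosion_diameter: int = 13, dilation_diameter: int = 12
) -> np.ndarray:
    """Binary erosion with a disc of diameter 13 px then dilation with a disc
    of diameter 12 px, removing speckle smaller than the erosion disc."""
    er = ndi.binary_erosion(mask, structure=disc_footprint(erosion_diameter))
    return ndi.binary_dilation(er, structure=disc_footprint(dilation_diameter))


_NBRS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def region_grow(
    v: np.ndarray,
    seed: tuple[int, int],
    tolerance: float = 0.05,
    mask: np.ndarray | None = None,
    similarity: str = "mean",
) -> np.ndarray:
    """Seeded region growing with a greedy best-first frontier.

    At each step the unallocated 8-connected frontier pixel with the
    smallest ``|intensity - reference|`` is admitted (reference = running
    region mean, or the seed value when ``similarity='seed'``); growth stops
    when that smallest difference exceeds ``tolerance``.  Ties are broken by
    lowest (row, col).  Returns the single connected component containing
    the seed; growth never leaves ``mask`` when one is given.
    """
    h, w = v.shape
    sr, sc = int(seed[0]), int(seed[1])
    if not (0 <= sr < h and 0 <= sc < w):
        raise InputError("seed outside the raster")
    allowed = np.ones((h, w), dtype=bool) if mask is None else mask.astype(bool)
    if not allowed[sr, sc]:
        raise InputError("seed outside the allowed region")
    if similarity not in ("mean", "seed"):
        raise ParameterError("similarity must be 'mean' or 'seed'")

    region = np.zeros((h, w), dtype=bool)
    in_frontier = np.zeros((h, w), dtype=bool)
    region[sr, sc] = True
    total = float(v[sr, sc])
    count = 1
    seed_val = float(v[sr, sc])

    cap = 1024
    fr = np.empty(cap, dtype=np.int64)  # flat frontier indices
    n_f = 0
    flat_v = v.ravel()

    def push(r, c):
        nonlocal n_f, cap, fr
        if n_f == cap:
            cap *= 2
            fr = np.resize(fr, cap)
        fr[n_f] = r * w + c
        n_f += 1
        in_frontier[r, c] = True

    for dr, dc in _NBRS:
        r, c = sr + dr, sc + dc
        if 0 <= r < h and 0 <= c < w and allowed[r, c]:
            push(r, c)

    while n_f > 0:
        ref = total / count if similarity == "mean" else seed_val
        f = fr[:n_f]
        d = np.abs(flat_v[f] - ref)
        dmin = d.min()
        if dmin > tolerance:
            break
        ties = f[d == dmin]
        pick = int(ties.min())  # lowest (row, col) in flat order
        pos = int(np.nonzero(f == pick)[0][0])
        n_f -= 1
        fr[pos] = fr[n_f]
        r, c = divmod(pick, w)
        in_frontier[r, c] = False
        region[r, c] = True
        total += float(v[r, c])
        count += 1
        for dr, dc in _NBRS:
            rr, cc = r + dr, c + dc
            if (
                0 <= rr < h
                and 0 <= cc < w
                and allowed[rr, cc]
                and not region[rr, cc]
                and not in_frontier[rr, cc]
            ):
                push(rr, cc)
    return region


def eccentricity_from_axes(major: float, minor: float) -> float:
    """``E = sqrt(Mj^2 - Mn^2) / Mj`` for moment-ellipse axis lengths.

    0 for a circle, approaching 1 for a line; degenerate axes give 0.
    """
    if major < minor:
        raise ParameterError("major axis must be >= minor axis")
    if major <= 0:
        return 0.0
    return float(np.sqrt(max(major**2 - minor**2, 0.0)) / major)


def compute_region_props(mask: np.ndarray) -> list[RegionProps]:
    """Per 8-connected component: area, centroid, moment-ellipse axis lengths
    and eccentricity, sorted by label.  Empty mask -> empty list."""
    if not mask.any():
        return []
    labels = sk_label(mask, connectivity=2)
    out = []
    for p in sk_regionprops(labels):
        mj = float(p.axis_major_length)
        mn = float(p.axis_minor_length)
        e = eccentricity_from_axes(mj, mn)
        out.append(
            RegionProps(
                label=int(p.label),
                area=int(p.area),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                major_axis=mj,
                minor_axis=mn,
                eccentricity=e,
                mask=labels == p.label,
            )
        )
    return out


def select_od_region(
    candidates_adaptive: list[RegionProps],
    candidates_grown: list[RegionProps],
    cfg: SelectionConfig,
) -> tuple[RegionProps, bool]:
    """Pool both candidate lists, keep those with area in the configured
    range, return the one with smallest eccentricity (ties: larger area).

    If no candidate falls in the area range, fall back to the candidate
    minimizing ``|area - A_a|`` among those with E < 0.95 and flag the
    result as low-confidence.  Returns ``(chosen, low_confidence)``.
    """
    cfg.validate()
    pool = list(candidates_adaptive) + list(candidates_grown)
    if not pool:
        raise SegmentationError("no candidate regions from either binarization")
    lo, hi = cfg.area_range
    in_range = [p for p in pool if lo <= p.area <= hi]
    if in_range:
        best = min(in_range, key=lambda p: (p.eccentricity, -p.area))
        return best, False
    fallback = [p for p in pool if p.eccentricity < 0.95]
    if not fallback:
        raise SegmentationError(
            "no candidate within the area range and none sufficiently compact"
        )
    best = min(fallback, key=lambda p: abs(p.area - cfg.avg_area))
    return best, True
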