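"""Multi-scale line detector for vessel extraction on the green channel.

A basic line detector of scale ``L`` responds, at each pixel, with the
difference between the best mean intensity along a length-``L`` line through
the pixel (over a set of orientations) and the mean intensity of the
surrounding ``W x W`` window.  On the inverted green channel vessels are
bright ridges, so responses are large on vessels at scales matching their
width.  The multi-scale detector standardizes each scale's response and
averages them together with the standardized inverted green channel itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

from ._util import line_offsets
from .errors import ParameterError


@dataclass
class LineDetectorConfig:
    window: int = 15  # W, odd
    line_lengths: tuple[int, ...] = field(default_factory=lambda: tuple(range(1, 16, 2)))
    n_orientations: int = 12
    vessel_threshold: float = 0.5  # on the standardized combined response

    def validate(self) -> None:
        if self.window % 2 == 0 or self.window < 1:
            raise ParameterError("window must be odd and >= 1")
        if any(l > self.window or l < 1 or l % 2 == 0 for l in self.line_lengths):
            raise ParameterError("line lengths must be odd and <= window")
        if self.n_orientations < 1:
            raise ParameterError("n_orientations must be >= 1")


def _line_kernel(length: int, angle_deg: float) -> np.ndarray:
    """Averaging kernel over the rasterized centered segment (duplicate
    samples from rounding keep their weight)."""
    offs = line_offsets(length, angle_deg)
    r = int(np.abs(offs[:, 0]).max()) if length > 1 else 0
    c = int(np.abs(offs[:, 1]).max()) if length > 1 else 0
    k = np.zeros((2 * r + 1, 2 * c + 1))
    for dr, dc in offs:
        k[dr + r, dc + c] += 1.0 / length
    return k


def basic_line_response(
    igc: np.ndarray,
    window: int = 15,
    length: int = 15,
    n_orientations: int = 12,
    return_orientation: bool = False,
):
    """Line response R_L = max over orientations(line mean) - window mean.

    ``igc`` is the inverted green channel (vessels bright).  Orientations are
    k*180/n_orientations degrees; image borders are reflected.
    """
    if length > window:
        raise ParameterError("line length must not exceed the window size")
    win_mean = ndi.uniform_filter(igc, size=window, mode="reflect")
    best = None
    best_ori = None
    for k in range(n_orientations):
        ang = 180.0 * k / n_orientations
        line_mean = ndi.correlate(igc, _line_kernel(length, ang), mode="reflect")
        if best is None:
            best = line_mean
            best_ori = np.zeros(igc.shape, dtype=np.int32)
        else:
            upd = line_mean > best
            best = np.where(upd, line_mean, best)
            best_ori[upd] = k
    resp = best - win_mean
    if return_orientation:
        return resp, best_ori
    return resp


def multiscale_line_response(
    igc: np.ndarray, cfg: LineDetectorConfig | None = None, fov: np.ndarray | None = None
) -> np.ndarray:
    """Combined multi-scale response: each scale standardized (zero mean,
    unit variance within the FOV) then averaged with the standardized image:
    ``(sum_L R_L' + igc') / (n_L + 1)``."""
    cfg = cfg or LineDetectorConfig()
    cfg.validate()
    sel = fov if fov is not None else np.ones(igc.shape, dtype=bool)

    def standardize(x: np.ndarray) -> np.ndarray:
        mu = x[sel].mean()
        sd = x[sel].std()
        if sd == 0:
            return np.zeros_like(x)
        return (x - mu) / sd

    total = standardize(igc)
    for length in cfg.line_lengths:
        r = basic_line_response(igc, cfg.window, length, cfg.n_orientations)
        total = total + standardize(r)
    return total / (len(cfg.line_lengths) + 1)


def vessel_mask(
    response: np.ndarray, threshold: float, fov: np.ndarray | None = None
) -> np.ndarray:
    """Threshold the combined response and dilate by 1 px so the mask covers
    vessel borders before inpainting."""
    mask = response > threshold
    mask = ndi.binary_dilation(mask, structure=disk(1))
    if fov is not None:
        mask &= fov
    return mask


def detect_vessels(
    green: np.ndarray, cfg: LineDetectorConfig | None = None, fov: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Convenience chain on the (non-inverted) green channel: invert,
    multi-scale response, threshold.  Returns (mask, response)."""
    cfg = cfg or LineDetectorConfig()
    igc = 1.0 - green
    resp = multiscale_line_response(igc, cfg, fov=fov)
    return vessel_mask(resp, cfg.vessel_threshold, fov=fov), resp
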