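"""Haze-line de-hazing for contrast enhancement of fundus images.

Non-uniform illumination over the retina behaves like haze: each true scene
color, attenuated by a spatially varying transmission ``t`` and mixed with a
global airlight ``A``, traces a straight line in RGB space (a *haze-line*)
through ``A``.  Grouping pixels by the direction of ``color - A`` and taking
the per-line maximum radius as the haze-free radius yields a per-pixel
transmission estimate ``t = r / r_max``, which, after edge-aware smoothing,
inverts the forward model ``I = t*J + (1-t)*A``.

This is a compact variant of non-local haze-line de-hazing: airlight from the
brightest in-FOV pixels, directions from a Fibonacci sphere, transmission
regularized by a weighted least-squares smoother guided by image gradients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .errors import InputError, ParameterError


@dataclass
class HazeEstimate:
    airlight: np.ndarray  # RGB triple in [0,1]
    transmission: np.ndarray  # raster in [t_floor, 1]
    n_directions: int


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` approximately uniform unit vectors on the sphere (golden spiral)."""
    if n < 2:
        raise ParameterError("need at least 2 directions")
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    golden = np.pi * (1.0 + np.sqrt(5.0))
    theta = golden * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def estimate_airlight(image: np.ndarray, fov: np.ndarray, top_fraction: float = 0.001) -> np.ndarray:
    """Airlight = mean color of the brightest ``top_fraction`` of in-FOV pixels.

    Brightness is the channel mean; in a fundus image the haze is an additive
    illumination error, so the brightest pixels are the most airlight-like.
    """
    if not fov.any():
        raise InputError("empty field-of-view mask")
    colors = image[fov]
    gray = colors.mean(axis=1)
    k = max(1, int(round(top_fraction * gray.size)))
    idx = np.argpartition(gray, -k)[-k:]
    return colors[idx].mean(axis=0)


def assign_haze_lines(image: np.ndarray, airlight: np.ndarray, n_directions: int = 500) -> np.ndarray:
    """Label each pixel by the sampled unit direction nearest (by angle) to
    ``pixel_color - airlight``.  Pixels exactly at the airlight get label 0."""
    if n_directions < 2:
        raise ParameterError("n_directions must be >= 2")
    dirs = fibonacci_sphere(n_directions)
    diff = (image.reshape(-1, 3) - np.asarray(airlight)[None, :]).astype(np.float32)
    r = np.linalg.norm(diff, axis=1)
    labels = np.zeros(diff.shape[0], dtype=np.int32)
    nz = r > 0
    unit = diff[nz] / r[nz, None]
    dirs32 = dirs.astype(np.float32).T
    # chunked exhaustive nearest-direction search (max dot product)
    out = np.empty(unit.shape[0], dtype=np.int32)
    step = 1 << 16
    for s in range(0, unit.shape[0], step):
        out[s : s + step] = np.argmax(unit[s : s + step] @ dirs32, axis=1)
    labels[nz] = out
    return labels.reshape(image.shape[:2])


def estimate_transmission(
    image: np.ndarray,
    airlight: np.ndarray,
    line_labels: np.ndarray,
    fov: np.ndarray | None = None,
    t_floor: float = 0.1,
) -> np.ndarray:
    """Per-pixel transmission ``t = r / r_max(line)`` clamped to [t_floor, 1].

    ``r`` is the RGB distance to the airlight; ``r_max`` is the largest radius
    observed on the pixel's haze-line (within the FOV when one is given) and
    stands in for the haze-free radius.  A pixel at the airlight itself
    (r = 0) is maximally hazed and clamps to ``t_floor``; its transmission is
    moot for the inversion since ``I - A = 0`` there.  Nonzero-radius pixels
    on a line whose in-FOV maximum is zero get t = 1 (no evidence of haze).
    """
    if not (0.0 < t_floor <= 1.0):
        raise ParameterError("t_floor must be in (0, 1]")
    r = np.linalg.norm(image - np.asarray(airlight)[None, None, :], axis=2)
    n = int(line_labels.max()) + 1
    flat_lab = line_labels.ravel()
    flat_r = r.ravel()
    if fov is not None:
        sel = fov.ravel()
        lab_sel, r_sel = flat_lab[sel], flat_r[sel]
    else:
        lab_sel, r_sel = flat_lab, flat_r
    r_max = np.zeros(n)
    np.maximum.at(r_max, lab_sel, r_sel)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(r_max[flat_lab] > 0, flat_r / r_max[flat_lab], 1.0)
    t = np.where(flat_r == 0, 0.0, t)  # airlight-colored pixels: fully hazed
    return np.clip(t.reshape(r.shape), t_floor, 1.0)


def smooth_transmission(
    t_raw: np.ndarray,
    guide: np.ndarray,
    lam: float = 0.1,
    t_floor: float = 0.1,
    weight: np.ndarray | None = None,
) -> np.ndarray:
    """Reliability-weighted smoothing (regularization) of the transmission map.

    The raw per-pixel estimate ``t = r / r_max`` is meaningless where the
    radius ``r`` is small — pixels whose color sits near the airlight (in a
    fundus image, the bright disc itself) carry no transmission signal, and
    inverting with their raw estimate would blow up their noise.  Since the
    haze/illumination field varies slowly across the retina, the regularized
    map is a normalized convolution: a Gaussian average of ``t_raw`` with
    per-pixel reliability weights (default ``t_raw**2``), at spatial scale
    ``sigma = lam * min(shape)``.  Unreliable pixels thus inherit the
    transmission of their reliable surroundings.

    ``lam = 0`` returns ``t_raw`` unchanged; a constant map is a fixed point
    for any ``lam``.
    """
    if lam < 0:
        raise ParameterError("lambda must be >= 0")
    if t_raw.shape != guide.shape[:2]:
        raise InputError("transmission and guide shapes do not match")
    if lam == 0:
        return t_raw.copy()
    w = t_raw**2 if weight is None else np.asarray(weight, dtype=float)
    if w.shape != t_raw.shape or np.any(w < 0):
        raise ParameterError("weight must be a non-negative raster matching t_raw")
    sigma = lam * min(t_raw.shape)
    num = ndi.gaussian_filter(w * t_raw, sigma, mode="constant", cval=0.0)
    den = ndi.gaussian_filter(w, sigma, mode="constant", cval=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(den > 0, num / den, t_raw)
    return np.clip(t, t_floor, 1.0)


def dehaze(image: np.ndarray, est: HazeEstimate, t_floor: float = 0.1) -> np.ndarray:
    """Invert the haze model: ``J = (I - (1-t)*A) / t``, clipped to [0, 1]."""
    t = np.clip(est.transmission, t_floor, 1.0)[..., None]
    a = np.asarray(est.airlight)[None, None, :]
    return np.clip((image - (1.0 - t) * a) / t, 0.0, 1.0)


def dehaze_image(
    image: np.ndarray,
    fov: np.ndarray,
    n_directions: int = 500,
    lam: float = 0.1,
    t_floor: float = 0.1,
) -> tuple[np.ndarray, HazeEstimate]:
    """Full de-hazing chain: airlight -> haze lines -> transmission ->
    smoothing -> inversion.  Returns the de-hazed image and the estimate."""
    airlight = estimate_airlight(image, fov)
    labels = assign_haze_lines(image, airlight, n_directions)
    t_raw = estimate_transmission(image, airlight, labels, fov=fov, t_floor=t_floor)
    t = smooth_transmission(t_raw, image, lam=lam, t_floor=t_floor)
    est = HazeEstimate(airlight=airlight, transmission=t, n_directions=n_directions)
    out = dehaze(image, est, t_floor=t_floor)
    out[~fov] = image[~fov]
    return out, est
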