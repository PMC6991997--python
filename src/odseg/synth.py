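"""Synthetic fundus scenes with exact ground truth.

Generates color fundus photographs with the structures the segmentation
pipeline cares about: a circular field of view on a black background, a
reddish textured retina with mild vignetting, a bright near-circular optic
disc (OD) with a gentle radial pallor gradient, dark curvilinear vessels
radiating from the disc, optional bright lesions, optional additive haze
(airlight + transmission), and additive Gaussian photon noise.  Every scene
comes with exact rasterized ground-truth masks for the OD and the vessel
tree, so each pipeline stage can be scored without any external dataset.

The forward haze model is ``hazy = t * J + (1 - t) * A`` for scene radiance
``J``, airlight ``A`` and per-pixel transmission ``t``; the de-hazing stage
inverts exactly this model.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from ._util import circle_mask, disc_footprint, ellipse_interior
from .errors import ParameterError

# Default scene geometry: a 512 px square frame with a 240 px FOV puts the
# optic disc (semi-axes ~36-46 px) in the 30-50 px radius range typical of
# fundus photographs at this working scale.
DEFAULT_OD_COLOR = np.array([1.00, 0.92, 0.62])
DEFAULT_VESSEL_COLOR = np.array([0.38, 0.10, 0.08])
DEFAULT_LESION_COLOR = np.array([0.92, 0.88, 0.60])


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic fundus scene."""

    image_size: tuple[int, int] = (512, 512)
    fov_radius: float = 240.0
    od_center: tuple[float, float] = (220.0, 300.0)
    od_axes: tuple[float, float] = (42.0, 38.0)  # (semi-major, semi-minor)
    od_angle: float = 0.0
    od_brightness: float = 0.85
    background_rgb: tuple[float, float, float] = (0.55, 0.28, 0.12)
    vessel_count: int = 8
    vessel_width: int = 3
    haze_airlight: tuple[float, float, float] | None = None
    haze_transmission_range: tuple[float, float] = (0.5, 0.9)
    lesion_count: int = 0
    noise_sigma: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        rows, cols = self.image_size
        if rows < 32 or cols < 32:
            raise ParameterError("image_size must be at least 32x32")
        a, b = self.od_axes
        if not (a > 0 and b > 0):
            raise ParameterError("od_axes must both be > 0")
        fr, fc = (rows - 1) / 2.0, (cols - 1) / 2.0
        d = np.hypot(self.od_center[0] - fr, self.od_center[1] - fc)
        if d + max(a, b) > self.fov_radius:
            raise ParameterError(
                "od ellipse must lie fully inside the field of view "
                f"(center offset {d:.1f} + semi-major {max(a, b):.1f} > "
                f"fov_radius {self.fov_radius:.1f})"
            )
        if not (0.0 <= self.od_brightness <= 1.0):
            raise ParameterError("od_brightness must be in [0, 1]")
        if self.haze_airlight is not None:
            t_min, t_max = self.haze_transmission_range
            if not (0.0 < t_min <= t_max <= 1.0):
                raise ParameterError(
                    "haze_transmission_range must satisfy 0 < t_min <= t_max <= 1"
                )
            if not all(0.0 <= c <= 1.0 for c in self.haze_airlight):
                raise ParameterError("haze_airlight components must be in [0, 1]")
        if self.vessel_count < 0 or self.lesion_count < 0:
            raise ParameterError("vessel_count and lesion_count must be >= 0")
        if self.vessel_width < 1:
            raise ParameterError("vessel_width must be >= 1")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Exact rasterized geometry of a generated scene."""

    od_mask: np.ndarray
    vessel_mask: np.ndarray
    od_center: tuple[float, float]
    od_area: int
    vessel_centerline: np.ndarray | None = None


def apply_haze(
    image: np.ndarray,
    airlight: tuple[float, float, float],
    transmission: float | np.ndarray,
) -> np.ndarray:
    """Forward haze model ``hazy = t*J + (1-t)*A``, clipped to [0, 1]."""
    t = np.asarray(transmission, dtype=float)
    if np.any(t <= 0) or np.any(t > 1):
        raise ParameterError("transmission must be in (0, 1]")
    a = np.asarray(airlight, dtype=float)
    if a.shape != (3,) or np.any(a < 0) or np.any(a > 1):
        raise ParameterError("airlight must be an RGB triple in [0, 1]^3")
    if t.ndim == 2:
        t = t[..., None]
    return np.clip(t * image + (1.0 - t) * a, 0.0, 1.0)


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Low-frequency random field standardized to zero mean, unit max-abs."""
    f = ndi.gaussian_filter(rng.standard_normal(shape), sigma)
    m = np.abs(f).max()
    return f / m if m > 0 else f


def _draw_vessels(
    spec: SceneSpec, rng: np.random.Generator, fov: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize quadratic Bezier vessels radiating from near the OD center.

    Returns ``(full-width mask, 1 px centerline mask)``.
    """
    rows, cols = spec.image_size
    center = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    root = np.array(spec.od_center) + rng.normal(0.0, 2.0, size=2)
    canvas = np.zeros(spec.image_size, dtype=bool)
    angles = np.sort(rng.uniform(0.0, 2.0 * np.pi, size=spec.vessel_count))
    ts = np.linspace(0.0, 1.0, 600)[:, None]
    for ang in angles:
        tip = center + 0.96 * spec.fov_radius * np.array([np.sin(ang), np.cos(ang)])
        mid = 0.5 * (root + tip)
        normal = np.array([np.cos(ang), -np.sin(ang)])
        ctrl = mid + normal * rng.uniform(-0.25, 0.25) * np.linalg.norm(tip - root)
        pts = (1 - ts) ** 2 * root + 2 * ts * (1 - ts) * ctrl + ts**2 * tip
        pr = np.clip(np.rint(pts[:, 0]).astype(int), 0, rows - 1)
        pc = np.clip(np.rint(pts[:, 1]).astype(int), 0, cols - 1)
        canvas[pr, pc] = True
    full = canvas
    if spec.vessel_width > 1:
        full = ndi.binary_dilation(canvas, structure=disc_footprint(spec.vessel_width))
    return full & fov, canvas & fov


def generate_fundus(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the scene and return ``(rgb image in [0,1], GroundTruth)``.

    Deterministic for a fixed ``spec`` (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size
    fc = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    fov = circle_mask(spec.image_size, fc, spec.fov_radius)

    # Retina background: base color, correlated low-frequency texture, mild
    # radial vignetting toward the FOV rim.
    rr, cc = np.mgrid[0:rows, 0:cols]
    rho = np.hypot(rr - fc[0], cc - fc[1]) / spec.fov_radius
    texture = _smooth_field(rng, spec.image_size, 25.0)
    vignette = 1.0 - 0.18 * np.clip(rho, 0.0, 1.0) ** 2
    image = np.empty((rows, cols, 3), dtype=float)
    for ch, base in enumerate(spec.background_rgb):
        image[..., ch] = base * vignette * (1.0 + 0.10 * texture)

    # Optic disc: exact ellipse mask; rendered as a bright plateau with a
    # gentle radial pallor gradient and a ~2 px soft rim so the photometric
    # edge is sharp but not aliased.
    od_mask = ellipse_interior(spec.image_size, spec.od_center, spec.od_axes, spec.od_angle)
    a, b = spec.od_axes
    ct, st = np.cos(spec.od_angle), np.sin(spec.od_angle)
    dr = rr - spec.od_center[0]
    dc = cc - spec.od_center[1]
    along = dc * ct + dr * st
    perp = -dc * st + dr * ct
    rho_e = np.sqrt((along / a) ** 2 + (perp / b) ** 2)
    edge_w = 2.0 / min(a, b)  # ~2 px blend at the rim
    w = np.clip((1.0 - rho_e) / edge_w, 0.0, 1.0)
    od_color = spec.od_brightness * DEFAULT_OD_COLOR
    # 5% radial pallor gradient: the disc is a near-uniform bright plateau
    # in the V channel, which is what makes simple V-channel thresholding
    # viable on real fundus images.
    grad = 1.0 - 0.05 * np.clip(rho_e, 0.0, 1.0) ** 2
    image = image * (1.0 - w[..., None]) + (od_color[None, None, :] * grad[..., None]) * w[..., None]

    # Vessels: dark curvilinear structures, most prominent in green.
    if spec.vessel_count > 0:
        vessel_mask, centerline = _draw_vessels(spec, rng, fov)
    else:
        vessel_mask = np.zeros_like(fov)
        centerline = np.zeros_like(fov)
    if vessel_mask.any():
        vm = vessel_mask[..., None]
        image = np.where(vm, 0.25 * image + 0.75 * DEFAULT_VESSEL_COLOR[None, None, :], image)

    # Bright lesions (exudate-like blobs) outside the OD.
    placed = 0
    attempts = 0
    while placed < spec.lesion_count and attempts < 50 * max(1, spec.lesion_count):
        attempts += 1
        ang = rng.uniform(0.0, 2.0 * np.pi)
        rad = rng.uniform(0.15, 0.85) * spec.fov_radius
        pos = np.array(fc) + rad * np.array([np.sin(ang), np.cos(ang)])
        if np.hypot(pos[0] - spec.od_center[0], pos[1] - spec.od_center[1]) < max(a, b) + 30.0:
            continue
        # exudate-scale blobs: visible diameter ~12-25 px, well under the
        # ~80 px disc diameter at this working scale
        size = rng.uniform(2.5, 5.0)
        blob = np.exp(-((rr - pos[0]) ** 2 + (cc - pos[1]) ** 2) / (2.0 * size**2))
        blob = np.where(blob > 0.05, blob, 0.0)
        image = image * (1.0 - blob[..., None]) + DEFAULT_LESION_COLOR[None, None, :] * blob[..., None]
        placed += 1

    if spec.haze_airlight is not None:
        t_min, t_max = spec.haze_transmission_range
        field = _smooth_field(rng, spec.image_size, 60.0)
        t = t_min + (t_max - t_min) * (field + 1.0) / 2.0
        image = apply_haze(image, spec.haze_airlight, np.clip(t, t_min, t_max))

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)

    image = np.clip(image, 0.0, 1.0)
    image[~fov] = 0.0

    gt = GroundTruth(
        od_mask=od_mask & fov,
        vessel_mask=vessel_mask,
        od_center=spec.od_center,
        od_area=int((od_mask & fov).sum()),
        vessel_centerline=centerline,
    )
    return image, gt


def random_scene(rng: np.random.Generator, difficulty: str = "easy") -> SceneSpec:
    """Draw a randomized SceneSpec under the study conditions.

    ``easy``: no haze, at most 2 lesions.  ``hard``: haze plus 5 lesions.
    """
    if difficulty not in ("easy", "hard"):
        raise ParameterError(f"unknown difficulty {difficulty!r}")
    rows = cols = 512
    fov_radius = 240.0
    fc = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    ang = rng.uniform(0.0, 2.0 * np.pi)
    dist = rng.uniform(0.2, 0.5) * fov_radius
    center = fc + dist * np.array([np.sin(ang), np.cos(ang)])
    major = rng.uniform(36.0, 46.0)
    minor = major * rng.uniform(0.85, 1.0)
    return SceneSpec(
        image_size=(rows, cols),
        fov_radius=fov_radius,
        od_center=(float(center[0]), float(center[1])),
        od_axes=(float(major), float(minor)),
        od_angle=float(rng.uniform(0.0, np.pi)),
        od_brightness=float(rng.uniform(0.78, 0.92)),
        background_rgb=(
            float(rng.uniform(0.48, 0.62)),
            float(rng.uniform(0.24, 0.32)),
            float(rng.uniform(0.08, 0.16)),
        ),
        vessel_count=int(rng.integers(6, 11)),
        vessel_width=3,
        haze_airlight=None if difficulty == "easy" else (0.9, 0.85, 0.8),
        haze_transmission_range=(0.5, 0.9),
        lesion_count=int(rng.integers(0, 3)) if difficulty == "easy" else 5,
        noise_sigma=0.01,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def write_scene(out_dir: str | Path, name: str, spec: SceneSpec) -> dict[str, Path]:
    """Render a scene and write image, masks and a JSON sidecar to disk."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    image, gt = generate_fundus(spec)
    paths = {
        "image": out / f"{name}.png",
        "od_mask": out / f"{name}_od_mask.png",
        "vessel_mask": out / f"{name}_vessel_mask.png",
        "meta": out / f"{name}.json",
    }
    iio.imwrite(paths["image"], (image * 255).round().astype(np.uint8))
    iio.imwrite(paths["od_mask"], gt.od_mask.astype(np.uint8) * 255)
    iio.imwrite(paths["vessel_mask"], gt.vessel_mask.astype(np.uint8) * 255)
    meta = dataclasses.asdict(spec)
    meta["ground_truth"] = {
        "od_center": list(gt.od_center),
        "od_area": gt.od_area,
    }
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths
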