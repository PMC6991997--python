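"""End-to-end optic-disc segmentation pipeline.

Stage order: de-hazing on the whole image, morphological localization and
300 px crop, multi-scale line detection of vessels on the green channel of
the crop, HSV conversion and harmonic inpainting of the V and S channels
under the vessel mask, adaptive thresholding plus seeded region growing of
the vessel-free V channel, eccentricity/area candidate selection, and
least-squares ellipse fitting rasterized back into full-image coordinates.
Deterministic for a fixed image and configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import rgb2hsv
from skimage.transform import rescale as sk_rescale, resize as sk_resize

from ._util import as_float_rgb, compute_fov_mask
from .config import WORKING_SCALE, PipelineConfig
from .dehaze import dehaze_image
from .ellipse import EllipseParams, fit_region_ellipse, rasterize_ellipse
from .errors import EllipseFitError, LocalizationError, OdsegError
from .inpaint import inpaint_channels
from .localize import LocalizationResult, localize_od
from .metrics import evaluate_pairs, write_report
from .segment import (
    adaptive_threshold,
    compute_region_props,
    morph_clean,
    region_grow,
    select_od_region,
)
from .vessels import detect_vessels

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    od_mask: np.ndarray = field(repr=False)  # full-image boolean mask
    ellipse: EllipseParams
    localization: LocalizationResult
    low_confidence: bool
    stage_timings: dict[str, float]


def _maybe_rescale(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale very large images so the short side maps to the working
    scale; returns (image, scale factor applied)."""
    short = min(image.shape[:2])
    if short > 1.5 * WORKING_SCALE:
        factor = WORKING_SCALE / short
        out = sk_rescale(image, factor, channel_axis=2, anti_aliasing=True)
        return np.clip(out, 0.0, 1.0), factor
    return image, 1.0


def run_pipeline(image: np.ndarray, cfg: PipelineConfig | None = None) -> PipelineResult:
    """Segment the optic disc in one RGB fundus image."""
    cfg = cfg or PipelineConfig()
    cfg.validate()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(name: str) -> None:
        nonlocal t0
        now = time.perf_counter()
        timings[name] = now - t0
        t0 = now

    full = as_float_rgb(image)
    work, scale = _maybe_rescale(full)
    fov = compute_fov_mask(work)
    if not fov.any():
        raise LocalizationError("image has no visible field of view")
    tick("preprocess")

    if cfg.dehaze.enabled:
        work, _ = dehaze_image(
            work,
            fov,
            n_directions=cfg.dehaze.n_directions,
            lam=cfg.dehaze.lam,
            t_floor=cfg.dehaze.t_floor,
        )
    tick("dehaze")

    crop, loc = localize_od(work, fov, cfg.localize)
    roi = loc.roi_mask
    origin = loc.crop_origin
    tick("localize")

    crop_fov = fov[
        origin[0] : origin[0] + crop.shape[0], origin[1] : origin[1] + crop.shape[1]
    ]
    v_mask, _resp = detect_vessels(crop[..., 1], cfg.vessels, fov=crop_fov)
    tick("vessels")

    hsv = rgb2hsv(crop)
    v_ch, s_ch = hsv[..., 2], hsv[..., 1]
    v_fill, s_fill = inpaint_channels(v_ch, s_ch, v_mask & crop_fov)
    tick("inpaint")

    adaptive = morph_clean(
        adaptive_threshold(v_fill, roi, cfg.segment.sigma),
        cfg.segment.erosion_diameter,
        cfg.segment.dilation_diameter,
    )
    cand_adaptive = compute_region_props(adaptive)

    seed = (
        int(round(loc.od_center[0] - origin[0])),
        int(round(loc.od_center[1] - origin[1])),
    )
    seed = (
        min(max(seed[0], 0), crop.shape[0] - 1),
        min(max(seed[1], 0), crop.shape[1] - 1),
    )
    grown = region_grow(
        v_fill,
        seed,
        tolerance=cfg.segment.grow_tolerance,
        mask=roi,
        similarity=cfg.segment.similarity,
    )
    cand_grown = compute_region_props(grown)
    chosen, low_confidence = select_od_region(cand_adaptive, cand_grown, cfg.segment)
    tick("segment")

    try:
        params = fit_region_ellipse(chosen.mask)
    except EllipseFitError:
        # degenerate boundary: fall back to the moment-equivalent circle
        radius = max(float(np.sqrt(chosen.area / np.pi)), 0.5)
        params = EllipseParams(center=chosen.centroid, semi_axes=(radius, radius), angle=0.0)
        low_confidence = True
    crop_mask = rasterize_ellipse(params, crop.shape[:2])
    tick("ellipse")

    od_mask_work = np.zeros(work.shape[:2], dtype=bool)
    od_mask_work[
        origin[0] : origin[0] + crop.shape[0], origin[1] : origin[1] + crop.shape[1]
    ] = crop_mask
    center_full = (params.center[0] + origin[0], params.center[1] + origin[1])
    if scale != 1.0:
        od_mask = (
            sk_resize(od_mask_work.astype(float), full.shape[:2], order=0) > 0.5
        )
        params = EllipseParams(
            center=(center_full[0] / scale, center_full[1] / scale),
            semi_axes=(params.semi_axes[0] / scale, params.semi_axes[1] / scale),
            angle=params.angle,
        )
        loc = LocalizationResult(
            od_center=(loc.od_center[0] / scale, loc.od_center[1] / scale),
            crop_origin=(
                int(round(loc.crop_origin[0] / scale)),
                int(round(loc.crop_origin[1] / scale)),
            ),
            roi_mask=loc.roi_mask,
        )
    else:
        od_mask = od_mask_work
        params = EllipseParams(
            center=center_full, semi_axes=params.semi_axes, angle=params.angle
        )
    tick("assemble")
    return PipelineResult(
        od_mask=od_mask,
        ellipse=params,
        localization=loc,
        low_confidence=low_confidence,
        stage_timings=timings,
    )


def run_batch(
    input_dir: str | Path,
    cfg: PipelineConfig | None = None,
    truth_dir: str | Path | None = None,
    out_dir: str | Path | None = None,
) -> list[dict]:
    """Run the pipeline over a directory of images.

    Truth masks are matched by filename stem (``<stem>*.png`` in
    ``truth_dir``).  Writes per-image masks/JSON and a CSV report when
    ``out_dir`` is given; returns the report rows.
    """
    import imageio.v3 as iio

    cfg = cfg or PipelineConfig()
    input_dir = Path(input_dir)
    images = sorted(
        p
        for p in input_dir.iterdir()
        if p.suffix.lower() in (".png", ".jpg", ".jpeg", ".tif", ".tiff")
        and "mask" not in p.stem
    )
    if not images:
        log.warning("no images found in %s", input_dir)
    pairs = []
    rows = []
    failures = 0
    for path in images:
        try:
            img = iio.imread(path)
            result = run_pipeline(img, cfg)
        except (OSError, OdsegError) as exc:
            log.warning("skipping %s: %s", path.name, exc)
            failures += 1
            rows.append({"name": path.stem, "sn": None, "sp": None, "acc": None, "aol": None})
            continue
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            iio.imwrite(out / f"{path.stem}_od_mask.png", result.od_mask.astype(np.uint8) * 255)
            meta = {
                "ellipse": {
                    "center": list(result.ellipse.center),
                    "semi_axes": list(result.ellipse.semi_axes),
                    "angle": result.ellipse.angle,
                },
                "od_center": list(result.localization.od_center),
                "low_confidence": result.low_confidence,
            }
            (out / f"{path.stem}.json").write_text(json.dumps(meta, indent=2))
        truth = _find_truth(truth_dir, path.stem) if truth_dir else None
        if truth is not None and truth.shape == result.od_mask.shape:
            pairs.append((path.stem, result.od_mask, truth))
        else:
            rows.append({"name": path.stem, "sn": None, "sp": None, "acc": None, "aol": None})
    scored = evaluate_pairs(pairs) if pairs else []
    report = [r for r in scored if r["name"] != "mean"] + rows
    report += [r for r in scored if r["name"] == "mean"]
    if out_dir is not None:
        write_report(report, Path(out_dir) / "report.csv")
    if failures:
        log.warning("%d image(s) failed", failures)
    return report


def _find_truth(truth_dir: str | Path, stem: str):
    import imageio.v3 as iio

    truth_dir = Path(truth_dir)
    for cand in (truth_dir / f"{stem}_od_mask.png", truth_dir / f"{stem}.png"):
        if cand.exists():
            return np.asarray(iio.imread(cand)) > 127
    return None
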