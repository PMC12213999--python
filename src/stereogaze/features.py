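"""Pupil and glint detection in infrared eye images.

The detection pipeline mirrors the tracker's image-processing stage:

* pupil — binarize below a dark threshold, find connected components,
  filter by area, take the largest candidate, fit an ellipse to its
  contour; the ellipse centre and area describe the pupil.
* glints — binarize above a bright threshold, filter components by area,
  drop candidates above the pupil image centre (the light sources sit
  below the eyes, so real glints project at or below it), keep the two
  candidates closest to the pupil and sort them by x (glint 1 is the
  left one, matching light source 1).

A frame where no pupil or fewer than two glints survive yields NaN
features — failures are recorded, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import exposure, measure

from .simulator import FEATURE_COLUMNS, fit_ellipse


@dataclass
class EyeImage:
    """8-bit grayscale eye region of interest (default 200x200 px)."""

    pixels: np.ndarray
    roi_origin: tuple[float, float] = (0.0, 0.0)  # (x, y) in the parent frame
    timestamp: float = 0.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("EyeImage expects a 2-D grayscale array")


@dataclass
class DetectionParams:
    """Operator-tunable detection settings.

    The thresholds and area bounds are rig- and illumination-dependent and
    are normally tuned on live imagery; these defaults suit the synthetic
    renderer's contrast.
    """

    pupil_threshold: int = 55  # binarize below (pupil is dark)
    pupil_area_min: float = 200.0  # px^2
    pupil_area_max: float = 30000.0
    glint_threshold: int = 190  # binarize above (glints are bright)
    glint_area_min: float = 1.0
    glint_area_max: float = 400.0
    equalize_histogram: bool = False

    def __post_init__(self):
        for lo, hi in ((self.pupil_area_min, self.pupil_area_max),
                       (self.glint_area_min, self.glint_area_max)):
            if not lo < hi:
                raise ValueError("area bounds must satisfy min < max")
        for t in (self.pupil_threshold, self.glint_threshold):
            if not 0 <= t <= 255:
                raise ValueError("thresholds must lie in [0, 255]")


@dataclass
class FeatureFrame:
    """Per-camera per-eye observation; NaN-able throughout."""

    pupil_center: tuple[float, float] = (np.nan, np.nan)  # px
    pupil_area: float = np.nan  # px^2
    glint1: tuple[float, float] = (np.nan, np.nan)
    glint2: tuple[float, float] = (np.nan, np.nan)
    timestamp: float = 0.0
    cam: int = 1
    eye: str = ""


def _prepare(img: EyeImage, params: DetectionParams) -> np.ndarray:
    px = img.pixels
    if params.equalize_histogram:
        px = (exposure.equalize_hist(px) * 255).astype(np.uint8)
    return px


def detect_pupil(img: EyeImage, params: DetectionParams):
    """Pupil centre (x, y in px, ROI frame) and ellipse area (px^2), or
    ``((nan, nan), nan)`` when no candidate survives."""
    px = _prepare(img, params)
    mask = px < params.pupil_threshold
    labels = measure.label(mask, connectivity=2)
    candidates = [
        r
        for r in measure.regionprops(labels)
        if params.pupil_area_min <= r.area <= params.pupil_area_max
    ]
    if not candidates:
        return (np.nan, np.nan), np.nan
    # largest area; ties broken by distance to the ROI centre
    h, w = px.shape
    roi_c = np.array([h / 2, w / 2])
    candidates.sort(
        key=lambda r: (-r.area, np.linalg.norm(np.asarray(r.centroid) - roi_c))
    )
    best = candidates[0]
    comp = labels == best.label
    contours = measure.find_contours(comp.astype(float), 0.5)
    if contours:
        contour = max(contours, key=len)  # (row, col)
        fit = fit_ellipse(contour[:, ::-1])  # (x, y)
        if fit is not None:
            xc, yc, a, b, _ = fit
            if 0 <= xc < w and 0 <= yc < h:
                return (float(xc), float(yc)), float(np.pi * a * b)
    # degenerate contour: fall back to the component centroid and pixel area
    cy, cx = best.centroid
    return (float(cx), float(cy)), float(best.area)


def detect_glints(img: EyeImage, pupil_center, params: DetectionParams):
    """The two glints as ((x1, y1), (x2, y2)) with x1 <= x2, or NaNs when
    fewer than two candidates survive the area and position filters."""
    nanpair = ((np.nan, np.nan), (np.nan, np.nan))
    if np.any(np.isnan(pupil_center)):
        return nanpair
    px = _prepare(img, params)
    mask = px > params.glint_threshold
    labels = measure.label(mask, connectivity=2)
    cands = []
    for r in measure.regionprops(labels):
        if not params.glint_area_min <= r.area <= params.glint_area_max:
            continue
        cy, cx = r.centroid
        if cy < pupil_center[1]:  # above the pupil image centre: not a glint
            continue
        cands.append((cx, cy))
    if len(cands) < 2:
        return nanpair
    cands.sort(key=lambda g: np.hypot(g[0] - pupil_center[0], g[1] - pupil_center[1]))
    two = sorted(cands[:2], key=lambda g: g[0])
    return (
        (float(two[0][0]), float(two[0][1])),
        (float(two[1][0]), float(two[1][1])),
    )


def detect_features(img: EyeImage, params: DetectionParams, cam: int = 1, eye: str = "") -> FeatureFrame:
    """Full single-frame detection; coordinates reported in the parent
    frame (ROI origin added)."""
    center, area = detect_pupil(img, params)
    g1, g2 = detect_glints(img, center, params)
    ox, oy = img.roi_origin

    def shift(p):
        return (p[0] + ox, p[1] + oy) if not np.any(np.isnan(p)) else (np.nan, np.nan)

    return FeatureFrame(
        pupil_center=shift(center),
        pupil_area=area,
        glint1=shift(g1),
        glint2=shift(g2),
        timestamp=img.timestamp,
        cam=cam,
        eye=eye,
    )


def process_stream(
    images: list[EyeImage],
    params: DetectionParams,
    cam: int = 1,
    eye: str = "",
) -> pd.DataFrame:
    """Detect features in an image sequence; one row per input frame in the
    feature-CSV dialect (NaN-preserving, no dropped rows)."""
    ts = [im.timestamp for im in images]
    if any(b < a for a, b in zip(ts, ts[1:])):
        raise ValueError("image timestamps must be monotonically increasing")
    rows = []
    for im in images:
        f = detect_features(im, params, cam=cam, eye=eye)
        rows.append(
            {
                "timestamp_s": f.timestamp,
                "cam": f.cam,
                "eye": f.eye,
                "pupil_x_px": f.pupil_center[0],
                "pupil_y_px": f.pupil_center[1],
                "pupil_area_px2": f.pupil_area,
                "glint1_x_px": f.glint1[0],
                "glint1_y_px": f.glint1[1],
                "glint2_x_px": f.glint2[0],
                "glint2_y_px": f.glint2[1],
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def load_image(path, roi_origin=(0.0, 0.0), timestamp: float = 0.0) -> EyeImage:
    """Read an 8-bit grayscale PNG as an EyeImage."""
    import imageio.v3 as iio

    px = iio.imread(Path(path))
    if px.ndim == 3:
        px = px[..., 0]
    return EyeImage(pixels=px, roi_origin=roi_origin, timestamp=timestamp)
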