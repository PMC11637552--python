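"""Lesion masks for both measurement arms.

The manual arm rasterizes observer-drawn boundary polygons; the automated
arm is a fully specified classical segmenter: mask out the fiducial dot,
move to L*a*b*, take the per-channel median of the remaining image as the
skin reference colour, threshold the per-pixel ΔE-to-skin map with Otsu's
method, clean up with a morphological opening whose radius is 0.2 mm at the
image's calibrated scale, and keep the largest connected component. When
the best component is too faint (max ΔE below a floor) or too small
(below a minimum physical area) the segmenter reports *no detection* —
which downstream stages treat as missing data, never as area zero. The
interface is pluggable so a learned segmenter can be dropped in.

Polygon rasterization uses the half-open convention: vertex coordinates lie
on the pixel-corner lattice (x right, y down, 0-based) and a pixel belongs
to the mask when its centre (col + 0.5, row + 0.5) falls inside the
polygon, so an axis-aligned 10×10 square covers exactly 100 pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from matplotlib.path import Path as _MplPath
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk, opening as _grey_opening

from ._colour import delta_e, srgb_to_lab
from .calibration import FiducialCalibration, ImageRecord

__all__ = [
    "LesionBoundary",
    "LesionMask",
    "AutoSegmentationParams",
    "rasterize_boundary",
    "segment_auto",
    "skin_reference_lab",
    "dot_exclusion_mask",
]


@dataclass
class LesionBoundary:
    """A closed observer-drawn polygon in pixel coordinates."""

    lesion_id: str
    image_id: str
    vertices: np.ndarray  # (n, 2) as (x, y)
    arm: str = "manual"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise ValueError("a boundary needs at least 3 vertices")

    def shoelace_area_px(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))

    def perimeter_px(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class LesionMask:
    """Binary lesion raster for one image and arm.

    ``detected=False`` means no mask exists: ``area_px`` is 0 by convention
    but no area may be reported for the image (missing, not zero).
    """

    raster: Optional[np.ndarray] = field(repr=False, default=None)
    arm: str = "manual"
    detected: bool = True

    @property
    def area_px(self) -> int:
        return int(self.raster.sum()) if self.detected and self.raster is not None else 0


@dataclass
class AutoSegmentationParams:
    delta_e_floor: float = 10.0
    min_area_mm2: float = 0.5
    opening_radius_mm: float = 0.2
    dot_mask_scale: float = 1.4  # dot exclusion region, multiple of fitted semi-axes


def rasterize_boundary(boundary: LesionBoundary, image_shape: tuple[int, int]) -> LesionMask:
    """Fill a simple polygon on the image grid (half-open, even-odd rule).

    The resulting pixel count agrees with the polygon's shoelace area to
    within one boundary-pixel band (± perimeter in px).

    Raises
    ------
    ValueError
        For self-intersecting polygons or fewer than 3 vertices.
    """
    if not _ShapelyPolygon(boundary.vertices).is_valid:
        raise ValueError("boundary polygon is self-intersecting")
    h, w = image_shape[:2]
    path = _MplPath(np.vstack([boundary.vertices, boundary.vertices[:1]]),
                    closed=True)
    xs, ys = np.meshgrid(np.arange(w) + 0.5, np.arange(h) + 0.5)
    inside = path.contains_points(np.column_stack([xs.ravel(), ys.ravel()]))
    return LesionMask(raster=inside.reshape(h, w), arm=boundary.arm, detected=True)


def dot_exclusion_mask(cal: FiducialCalibration, image_shape: tuple[int, int],
                       scale: float = 1.4) -> np.ndarray:
    """Boolean mask covering the fitted fiducial ellipse, slightly dilated."""
    h, w = image_shape[:2]
    out = np.zeros((h, w), dtype=bool)
    if not cal.detected:
        return out
    cx, cy = cal.centre
    a = cal.major_semi_axis * scale
    b = cal.minor_semi_axis * scale
    theta = np.radians(cal.orientation_deg or 0.0)
    ys, xs = np.mgrid[0:h, 0:w]
    dx, dy = xs - cx, ys - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    out[(u / a) ** 2 + (v / b) ** 2 <= 1.0] = True
    return out


def skin_reference_lab(image: ImageRecord | np.ndarray,
                       cal: Optional[FiducialCalibration] = None,
                       dot_mask_scale: float = 1.4) -> np.ndarray:
    """Per-channel median L*a*b* over the non-dot image: the skin reference."""
    rgb = image.rgb if isinstance(image, ImageRecord) else np.asarray(image)
    lab = srgb_to_lab(rgb)
    if cal is not None and cal.detected:
        keep = ~dot_exclusion_mask(cal, rgb.shape[:2], dot_mask_scale)
        lab = lab[keep]
    else:
        lab = lab.reshape(-1, 3)
    return np.median(lab, axis=0)


def segment_auto(
    image: ImageRecord | np.ndarray,
    cal: FiducialCalibration,
    params: Optional[AutoSegmentationParams] = None,
) -> LesionMask:
    """Automated lesion segmentation by colour distance to skin.

    Requires a detected fiducial (the opening radius and minimum area are
    physical quantities). Returns ``detected=False`` when no credible
    lesion is present — typically very small lesions or lesions whose
    colour cannot be distinguished from normal skin.
    """
    if not cal.detected:
        raise ValueError("automated segmentation requires a detected fiducial")
    params = params or AutoSegmentationParams()
    rgb = image.rgb if isinstance(image, ImageRecord) else np.asarray(image)
    h, w = rgb.shape[:2]

    dot = dot_exclusion_mask(cal, (h, w), params.dot_mask_scale)
    lab = srgb_to_lab(rgb)
    skin = np.median(lab[~dot].reshape(-1, 3), axis=0)
    de = delta_e(lab, skin)
    de[dot] = 0.0

    if float(de.max()) < params.delta_e_floor:
        return LesionMask(raster=None, arm="automated", detected=False)

    thresh = threshold_otsu(de[~dot])
    cand = (de > max(thresh, params.delta_e_floor / 2.0)) & ~dot

    radius = max(1, round(params.opening_radius_mm / cal.mm_per_px))
    cand = _grey_opening(cand, disk(radius))
    if not cand.any():
        return LesionMask(raster=None, arm="automated", detected=False)

    labels = label(cand)
    regions = regionprops(labels)
    best = max(regions, key=lambda r: r.area)
    mask = labels == best.label

    area_mm2 = best.area * cal.mm_per_px ** 2
    if area_mm2 < params.min_area_mm2 or float(de[mask].max()) < params.delta_e_floor:
        return LesionMask(raster=None, arm="automated", detected=False)
    return LesionMask(raster=mask, arm="automated", detected=True)
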