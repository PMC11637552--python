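"""Fiducial-dot detection and pixel-to-millimetre scale calibration.

Every study photograph includes a 6 mm adhesive dot placed beside the lesion.
Its known physical diameter anchors the image scale: once the dot is found
and an ellipse fitted to it, ``mm_per_px = 6.0 / (2 * major_semi_axis)``.
The major axis is used deliberately — a circle photographed obliquely remains
a circle of true diameter along the major axis of its elliptical projection,
so the in-plane scale survives camera tilt. The minor/major axis ratio then
measures that tilt and drives the "wrong angle" triage rule downstream.

A single circular fiducial constrains translation and scale but not rotation;
no stage of this package ever infers rotation from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.color import rgb2hsv
from skimage.measure import label, regionprops

__all__ = [
    "ImageRecord",
    "FiducialCalibration",
    "detect_fiducial",
    "scale_from_dot",
    "DEFAULT_DOT_RGB",
    "DOT_DIAMETER_MM",
]

#: Physical diameter of the adhesive reference dot (mm).
DOT_DIAMETER_MM = 6.0

#: Reference sRGB colour of the dot: a saturated blue far from skin and
#: lesion hues, as a real adhesive marker would be chosen.
DEFAULT_DOT_RGB = (40, 70, 200)


@dataclass
class ImageRecord:
    """One photograph of a lesion with its episode/lesion/day identity.

    ``rgb`` is an 8-bit raster indexed (row, col, channel), origin top-left.
    """

    image_id: str
    episode_id: str
    lesion_id: str
    day: int
    timestamp: str
    rgb: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3 or self.rgb.size == 0:
            raise ValueError("rgb raster must be a non-empty (H, W, 3) array")
        if self.day < 1:
            raise ValueError(f"study day must be >= 1, got {self.day}")


@dataclass
class FiducialCalibration:
    """Detected dot geometry and the mm-per-pixel scale it implies.

    When ``detected`` is False all geometric fields are None: scale for that
    image is unknown and triage must label it "no dot".
    """

    detected: bool
    centre: Optional[tuple[float, float]] = None  # (x, y) px
    major_semi_axis: Optional[float] = None  # px
    minor_semi_axis: Optional[float] = None  # px
    orientation_deg: Optional[float] = None
    axis_ratio: Optional[float] = None  # minor/major, in (0, 1]
    confidence: float = 0.0
    mm_per_px: Optional[float] = None


def _hue_distance(h1: np.ndarray, h2: float) -> np.ndarray:
    """Circular distance on the [0, 1) hue wheel."""
    d = np.abs(h1 - h2)
    return np.minimum(d, 1.0 - d)


def detect_fiducial(
    image: ImageRecord | np.ndarray,
    dot_hue_reference: Sequence[int] = DEFAULT_DOT_RGB,
    *,
    confidence_threshold: float = 0.5,
    hue_tolerance: float = 0.10,
    min_saturation: float = 0.25,
    min_area_px: int = 30,
    dot_diameter_mm: float = DOT_DIAMETER_MM,
) -> FiducialCalibration:
    """Locate the reference dot and fit an ellipse to it.

    The detector gates pixels by hue/saturation proximity to the reference
    dot colour, labels connected components, and scores each component by
    the product of its mean colour-match score and its fill ratio against
    the moment-matched ellipse. The best component wins; if its confidence
    falls below ``confidence_threshold`` the dot is declared absent —
    absence is a result, not an error.
    """
    rgb = image.rgb if isinstance(image, ImageRecord) else np.asarray(image)
    hsv = rgb2hsv(rgb.astype(np.float64) / 255.0)
    ref_hsv = rgb2hsv(np.asarray(dot_hue_reference, dtype=np.float64).reshape(1, 1, 3) / 255.0)[0, 0]

    hue_d = _hue_distance(hsv[..., 0], ref_hsv[0])
    colour_score = np.clip(1.0 - hue_d / hue_tolerance, 0.0, 1.0)
    gate = (hue_d < hue_tolerance) & (hsv[..., 1] > min_saturation)

    labels = label(gate)
    best = None
    best_conf = 0.0
    for region in regionprops(labels, intensity_image=colour_score):
        if region.area < min_area_px:
            continue
        major = region.axis_major_length / 2.0
        minor = region.axis_minor_length / 2.0
        if major <= 0 or minor <= 0:
            continue
        ellipse_area = math.pi * major * minor
        fill_ratio = min(region.area / ellipse_area, ellipse_area / region.area)
        conf = float(region.intensity_mean) * fill_ratio
        if conf > best_conf:
            best_conf = conf
            best = region

    if best is None or best_conf < confidence_threshold:
        return FiducialCalibration(detected=False, confidence=best_conf)

    major = best.axis_major_length / 2.0
    minor = best.axis_minor_length / 2.0
    cy, cx = best.centroid
    # regionprops orientation: angle between row axis and major axis, rad.
    orient = math.degrees(-best.orientation) % 180.0
    return FiducialCalibration(
        detected=True,
        centre=(float(cx), float(cy)),
        major_semi_axis=float(major),
        minor_semi_axis=float(minor),
        orientation_deg=float(orient),
        axis_ratio=float(min(minor / major, 1.0)),
        confidence=float(best_conf),
        mm_per_px=dot_diameter_mm / (2.0 * major),
    )


def scale_from_dot(cal: FiducialCalibration, dot_diameter_mm: float = DOT_DIAMETER_MM) -> float:
    """mm-per-pixel scale from the fitted dot, using the major axis.

    Raises
    ------
    ValueError
        If the fiducial was not detected: no scale exists for that image.
    """
    if not cal.detected or cal.major_semi_axis is None:
        raise ValueError("cannot derive a scale from an undetected fiducial")
    return dot_diameter_mm / (2.0 * cal.major_semi_axis)
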