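"""Calibrated area measurement and fixed-boundary colour tracking.

Areas are pixel counts scaled by the square of the fiducial-derived
mm-per-pixel factor. Colour is summarized in CIE L*a*b* inside a *fixed*
boundary: the border drawn on the first (earliest) image of a series is
kept geometrically constant — anchored to the fiducial dot in millimetre
coordinates — and re-projected into every later image using only that
image's dot centre and scale. Had the boundary shrunk with the lesion, no
colour change toward healed skin would ever be measured; keeping it fixed
lets the enclosed region's mean colour converge to the skin reference as
healing proceeds. The colour summary therefore never depends on which
segmentation arm produced the daily area.

A single circular fiducial cannot constrain rotation, so re-projection is
translation + scale only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import binary_erosion

from ._colour import delta_e, srgb_to_lab
from .calibration import FiducialCalibration, ImageRecord
from .segmentation import LesionBoundary, LesionMask, rasterize_boundary, skin_reference_lab

__all__ = [
    "ColourSummary",
    "LesionMeasurement",
    "FixedBoundaryTrack",
    "srgb_to_lab",
    "delta_e",
    "area_mm2",
    "colour_track",
]


@dataclass
class ColourSummary:
    """Mean L*, a*, b* within the tracked boundary and ΔE to skin."""

    image_id: str
    day: int
    l_mean: float
    a_mean: float
    b_mean: float
    delta_e_to_skin: float


@dataclass
class LesionMeasurement:
    """One calibrated per-image, per-arm measurement."""

    image_id: str
    lesion_id: str
    day: int
    arm: str
    area_mm2: Optional[float]  # None when the arm made no detection
    colour: Optional[ColourSummary] = None


def area_mm2(mask: LesionMask, cal: FiducialCalibration) -> float:
    """Calibrated area: pixel count × mm_per_px².

    Raises
    ------
    ValueError
        If the mask reports no detection or the fiducial is undetected —
        missing measurements stay missing, they are never zero.
    """
    if not mask.detected:
        raise ValueError("no lesion detected: area is missing, not zero")
    if not cal.detected or cal.mm_per_px is None:
        raise ValueError("no fiducial: image has no scale")
    return mask.area_px * cal.mm_per_px ** 2


@dataclass
class FixedBoundaryTrack:
    """First-image boundary in fiducial-anchored millimetre coordinates.

    Vertices are stored relative to the dot centre in mm; projecting into a
    later image applies that image's dot centre and scale (translation +
    scale only, no rotation).
    """

    lesion_id: str
    vertices_mm: np.ndarray  # (n, 2)

    @classmethod
    def from_first_image(cls, boundary: LesionBoundary,
                         cal: FiducialCalibration) -> "FixedBoundaryTrack":
        if not cal.detected:
            raise ValueError("cannot anchor a boundary without a detected fiducial")
        centre = np.asarray(cal.centre, dtype=np.float64)
        verts_mm = (boundary.vertices - centre) * cal.mm_per_px
        return cls(lesion_id=boundary.lesion_id, vertices_mm=verts_mm)

    def project(self, cal: FiducialCalibration, image_id: str = "") -> LesionBoundary:
        """Boundary in the pixel frame of an image with the given calibration."""
        if not cal.detected:
            raise ValueError("cannot project into an image without a fiducial")
        centre = np.asarray(cal.centre, dtype=np.float64)
        verts = centre + self.vertices_mm / cal.mm_per_px
        return LesionBoundary(lesion_id=self.lesion_id, image_id=image_id,
                              vertices=verts, arm="manual")


def colour_track(
    images: Sequence[ImageRecord],
    calibrations: Sequence[FiducialCalibration],
    first_boundary: LesionBoundary,
) -> list[ColourSummary]:
    """Fixed-boundary colour trajectory across a day-ordered image series.

    The first image/calibration pair anchors the boundary; each usable
    image contributes the mean L*a*b* within the re-projected boundary and
    its CIE76 ΔE to that image's skin reference colour. A one-pixel band at
    the boundary is excluded from the mean (those pixels mix lesion and
    skin, and sub-pixel re-projection error would otherwise leak skin
    colour into the summary). Images whose fiducial was not detected are
    skipped (a gap, not a zero).
    """
    if len(images) != len(calibrations):
        raise ValueError("images and calibrations must pair up")
    usable = [(im, c) for im, c in zip(images, calibrations) if c.detected]
    if not usable:
        return []
    first_cal = next(c for im, c in zip(images, calibrations)
                     if c.detected and im.image_id == first_boundary.image_id)
    track = FixedBoundaryTrack.from_first_image(first_boundary, first_cal)

    out: list[ColourSummary] = []
    for img, cal in usable:
        boundary = track.project(cal, image_id=img.image_id)
        mask = rasterize_boundary(boundary, img.rgb.shape[:2]).raster
        interior = binary_erosion(mask)
        if interior.any():
            mask = interior
        if not mask.any():
            continue
        lab = srgb_to_lab(img.rgb)
        mean_lab = lab[mask].mean(axis=0)
        skin = skin_reference_lab(img, cal)
        out.append(ColourSummary(
            image_id=img.image_id, day=img.day,
            l_mean=float(mean_lab[0]), a_mean=float(mean_lab[1]),
            b_mean=float(mean_lab[2]),
            delta_e_to_skin=float(delta_e(mean_lab, skin))))
    return out
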