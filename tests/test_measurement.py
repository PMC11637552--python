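"""Colour conversion, calibrated areas, and fixed-boundary colour tracking."""

import numpy as np
import pytest

from lesiontrack.calibration import FiducialCalibration, detect_fiducial
from lesiontrack.measurement import (FixedBoundaryTrack, area_mm2, colour_track,
                                     delta_e, srgb_to_lab)
from lesiontrack.segmentation import (LesionBoundary, LesionMask,
                                      rasterize_boundary)
from lesiontrack.synthesis import (SimulationConfig, manual_boundary,
                                   render_series)

from conftest import clean_kwargs


def _reference_lab(rgb8):
    """Independent sRGB -> L*a*b* conversion written from the standard:
    sRGB gamma expansion, D65 linear transform, CIE f() cube-root form."""
    c = np.asarray(rgb8, float) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    m = np.array([[0.4124564, 0.3575761, 0.1804375],
                  [0.2126729, 0.7151522, 0.0721750],
                  [0.0193339, 0.1191920, 0.9503041]])
    xyz = m @ lin
    wn = np.array([0.95047, 1.0, 1.08883])
    t = xyz / wn
    f = np.where(t > (6 / 29) ** 3, np.cbrt(t), t / (3 * (6 / 29) ** 2) + 4 / 29)
    return np.array([116 * f[1] - 16, 500 * (f[0] - f[1]), 200 * (f[1] - f[2])])


@pytest.mark.parametrize("rgb,expect_exact", [
    ((255, 255, 255), (100.0, 0.0, 0.0)),
    ((0, 0, 0), (0.0, 0.0, 0.0)),
])
def test_lab_extremes(rgb, expect_exact):
    lab = srgb_to_lab(np.array(rgb))
    assert lab[0] == pytest.approx(expect_exact[0], abs=0.01)
    assert abs(lab[1]) < 0.01 and abs(lab[2]) < 0.01


def test_lab_matches_independent_conversion_for_primaries():
    for rgb in ((255, 0, 0), (0, 255, 0), (0, 0, 255), (201, 161, 140)):
        got = srgb_to_lab(np.array(rgb))
        ref = _reference_lab(rgb)
        assert np.allclose(got, ref, atol=0.01)


def test_area_examples_and_scale_law():
    mask = LesionMask(raster=np.ones((10, 10), bool), arm="manual")
    cal = FiducialCalibration(detected=True, major_semi_axis=30.0, mm_per_px=0.1)
    assert area_mm2(mask, cal) == pytest.approx(1.0)
    cal2 = FiducialCalibration(detected=True, major_semi_axis=15.0, mm_per_px=0.2)
    assert area_mm2(mask, cal2) == pytest.approx(4.0)  # scale doubled -> area x4
    with pytest.raises(ValueError):
        area_mm2(LesionMask(raster=None, detected=False), cal)
    with pytest.raises(ValueError):
        area_mm2(mask, FiducialCalibration(detected=False))


def _series(seed=13, **overrides):
    kw = clean_kwargs()
    kw.update(overrides)
    cfg = SimulationConfig(n_lesions=1, n_days=8, rng_seed=seed,
                           baseline_area_mean=10.0, baseline_area_sd=0.0, **kw)
    return cfg, render_series(cfg)


def test_constant_series_has_constant_colour():
    _, (images, truths, _) = _series(healing_gradient_mean=0.0,
                                     healing_gradient_sd=0.0)
    cals = [detect_fiducial(im) for im in images]
    verts = manual_boundary(truths[0])
    fb = LesionBoundary("L001", images[0].image_id, verts)
    track = colour_track(images, cals, fb)
    assert len(track) == len(images)
    for ch in ("l_mean", "a_mean", "b_mean"):
        vals = [getattr(c, ch) for c in track]
        assert max(vals) - min(vals) < 0.5


def test_healing_series_delta_e_strictly_decreasing():
    _, (images, truths, _) = _series(healing_gradient_mean=-1.0,
                                     healing_gradient_sd=0.0)
    cals = [detect_fiducial(im) for im in images]
    fb = LesionBoundary("L001", images[0].image_id, manual_boundary(truths[0]))
    de = [c.delta_e_to_skin for c in colour_track(images, cals, fb)]
    assert all(a > b for a, b in zip(de, de[1:]))


def test_boundary_reprojection_covers_same_mm_region():
    # scale changes between days move the dot and rescale the scene; the
    # re-projected boundary must still cover the truth lesion placement
    _, (images, truths, _) = _series(seed=5, healing_gradient_mean=0.0,
                                     healing_gradient_sd=0.0)
    cals = [detect_fiducial(im) for im in images]
    scales = [t.mm_per_px for t in truths]
    assert max(scales) / min(scales) > 1.2  # the nuisance actually varied
    fb = LesionBoundary("L001", images[0].image_id, manual_boundary(truths[0]))
    track = FixedBoundaryTrack.from_first_image(fb, cals[0])
    for img, cal, truth in zip(images[1:], cals[1:], truths[1:]):
        proj = track.project(cal, image_id=img.image_id)
        mask = rasterize_boundary(proj, img.rgb.shape[:2]).raster
        overlap = np.logical_and(mask, truth.mask).sum() / truth.mask.sum()
        assert overlap >= 0.95


def test_area_invariant_to_resolution_preserving_physical_scale():
    # identical scene rendered at two pixel scales; only the resolution
    # differs, so the measured area must agree within 2%
    areas = []
    for scale in (0.10, 0.05):
        _, (images, truths, _) = _series(seed=3, mm_per_px_range=(scale, scale),
                                         healing_gradient_sd=0.0)
        cal = detect_fiducial(images[0])
        verts = manual_boundary(truths[0])
        mask = rasterize_boundary(
            LesionBoundary("L001", images[0].image_id, verts),
            images[0].rgb.shape[:2])
        areas.append(area_mm2(mask, cal))
    assert areas[1] == pytest.approx(areas[0], rel=0.02)


def test_delta_e_zero_for_identical_colours():
    lab = srgb_to_lab(np.array([120, 80, 60]))
    assert delta_e(lab, lab) == 0.0
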