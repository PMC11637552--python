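"""Generator contracts: counts, determinism, healing schedule, truth oracle."""

import numpy as np
import pytest

from lesiontrack.calibration import detect_fiducial
from lesiontrack.synthesis import (GroundTruthRecord, SimulationConfig,
                                   render_series, truth_area_oracle)

from conftest import clean_kwargs


def test_defect_free_single_lesion_yields_one_image_per_day():
    cfg = SimulationConfig(n_lesions=1, n_days=30, rng_seed=5, **clean_kwargs())
    images, truths, _ = render_series(cfg)
    assert len(images) == 30
    assert [t.day for t in truths] == list(range(1, 31))


def test_linear_healing_schedule_day30_area():
    # baseline 12 mm², -0.08 mm²/day, days 1..30 -> 12 + 29*(-0.08) = 9.68
    cfg = SimulationConfig(n_lesions=1, n_days=30, rng_seed=1,
                           baseline_area_mean=12.0, baseline_area_sd=0.0,
                           healing_gradient_mean=-0.08, healing_gradient_sd=0.0,
                           **clean_kwargs())
    _, truths, _ = render_series(cfg)
    assert truths[0].area_mm2 == pytest.approx(12.0)
    assert truths[-1].area_mm2 == pytest.approx(9.68)


def test_same_seed_gives_byte_identical_outputs():
    cfg = SimulationConfig(n_lesions=2, n_days=5, rng_seed=99)
    ia, ta, pa = render_series(cfg)
    ib, tb, pb = render_series(cfg)
    assert len(ia) == len(ib)
    for a, b in zip(ia, ib):
        assert a.image_id == b.image_id
        assert a.rgb.tobytes() == b.rgb.tobytes()
    for a, b in zip(ta, tb):
        assert a.to_jsonable() == b.to_jsonable()
        assert np.array_equal(a.mask, b.mask)
    assert pa.records.equals(pb.records)


def test_truth_area_oracle_examples():
    mask = np.zeros((20, 20), bool)
    mask[:10, :10] = True  # 100 px at 0.1 mm/px -> 1.0 mm²
    rec = GroundTruthRecord("i", "e", "l", 1, mask=mask, mm_per_px=0.1)
    assert truth_area_oracle(rec) == pytest.approx(1.0)

    # rasterized disc, radius 30 px at 0.1 mm/px: oracle vs brute-force pixel
    # count of the same disc, and within 2% of the continuous pi*r² area
    ys, xs = np.mgrid[0:80, 0:80]
    disc = (xs - 40.0) ** 2 + (ys - 40.0) ** 2 <= 30.0 ** 2
    rec = GroundTruthRecord("i", "e", "l", 1, mask=disc, mm_per_px=0.1)
    brute = sum((x - 40.0) ** 2 + (y - 40.0) ** 2 <= 900.0
                for x in range(80) for y in range(80)) * 0.01
    assert truth_area_oracle(rec) == pytest.approx(brute)
    assert truth_area_oracle(rec) == pytest.approx(np.pi * 9.0, rel=0.02)

    empty = GroundTruthRecord("i", "e", "l", 1, mask=np.zeros((5, 5), bool),
                              mm_per_px=0.1)
    assert truth_area_oracle(empty) == 0.0


def test_mask_area_consistent_with_analytic_schedule(clean_series):
    # pixel count × scale² matches the analytic in-plane area to within a
    # boundary-pixel band (mask boundary length × one pixel area)
    _, (_, truths, _) = clean_series
    for t in truths:
        if t.area_mm2 <= 0:
            continue
        oracle = truth_area_oracle(t)
        perim_px = 2 * np.sqrt(np.pi * t.mask.sum())  # circle-equivalent bound
        band = perim_px * t.mm_per_px ** 2
        assert abs(oracle - t.area_mm2) <= band


def test_dot_scale_consistency(clean_series):
    # rendered dot major axis (detected) × true mm_per_px = 6 mm within 1 px·scale
    _, (images, truths, _) = clean_series
    for img, t in zip(images[:10], truths[:10]):
        cal = detect_fiducial(img)
        assert cal.detected
        assert 2 * cal.major_semi_axis * t.mm_per_px == pytest.approx(
            6.0, abs=t.mm_per_px)


def test_healing_monotone_and_colour_converges():
    cfg = SimulationConfig(n_lesions=2, n_days=20, rng_seed=3, **clean_kwargs())
    _, truths, _ = render_series(cfg)
    for lid in {t.lesion_id for t in truths}:
        ts = sorted((t for t in truths if t.lesion_id == lid), key=lambda t: t.day)
        areas = [t.area_mm2 for t in ts]
        assert all(a >= b for a, b in zip(areas, areas[1:]))
        de = [np.linalg.norm(np.subtract(t.lesion_lab, t.skin_lab)) for t in ts]
        assert all(a >= b - 1e-9 for a, b in zip(de, de[1:]))


def test_no_dot_flag_matches_rendered_scene():
    cfg = SimulationConfig(n_lesions=1, n_days=12, rng_seed=8,
                           **clean_kwargs(p_no_dot=0.5))
    _, truths, _ = render_series(cfg)
    flags = {t.no_dot for t in truths}
    assert flags == {True, False}  # both branches realized at p=0.5, n=12
    for t in truths:
        assert (t.dot_centre is None) == t.no_dot


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_days=0).validate()
    with pytest.raises(ValueError):
        SimulationConfig(n_lesions=0).validate()
    with pytest.raises(ValueError):
        SimulationConfig(p_no_dot=1.5).validate()
    with pytest.raises(ValueError):
        SimulationConfig(dot_diameter_mm=0.0).validate()


def test_prom_values_in_range(clean_series):
    _, (_, _, proms) = clean_series
    r = proms.records
    pain = r[r["instrument"] == "PAIN"]["value"]
    assert pain.between(0, 10).all()
    for inst in ("RAYNAUD_VAS", "LESION_VAS", "SEVERITY_VAS"):
        assert r[r["instrument"] == inst]["value"].between(0, 100).all()
    hd = r[r["instrument"] == "HDISS_DU"]
    assert hd["value"].between(0, 7).all()
    assert (hd.groupby(["episode_id", "day"]).size() == 24).all()
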