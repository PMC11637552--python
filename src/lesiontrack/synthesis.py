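"""Synthetic lesion-photograph generator with full ground truth.

No image dataset was deposited with the study this package operationalizes,
so every downstream stage is exercised against rendered scenes with known
truth. Each lesion is a fixed irregular shape (an ellipse with a low-order
radial sinusoid perturbation — star-shaped, hence always a simple boundary)
placed at a fixed millimetre offset from a 6 mm blue adhesive dot. Day by
day the lesion's in-plane area follows a linear healing schedule, its colour
interpolates in L*a*b* from lesion colour to skin colour in proportion to
remaining area, and the camera nuisances change: mm-per-pixel scale,
lighting gain, colour cast, sensor noise, and a small out-of-plane tilt that
projects the dot as an ellipse with axis ratio cos(tilt).

Defect processes emulate real participant behaviour: missing days, images
with no dot, duplicate (blurred re-take) images, and wrong-angle images shot
at a large tilt.

Coordinate conventions: rasters are sampled at integer pixel indices
(x = column, y = row, origin top-left); polygon annotations returned by
:func:`manual_boundary` live on the half-open corner lattice used by
``segmentation.rasterize_boundary`` (vertex coordinate = index + 0.5).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.measure import find_contours

from ._colour import lab_to_srgb, srgb_to_lab
from .calibration import DEFAULT_DOT_RGB, DOT_DIAMETER_MM, ImageRecord

__all__ = [
    "SimulationConfig",
    "GroundTruthRecord",
    "SyntheticPROMSet",
    "render_series",
    "truth_area_oracle",
    "manual_boundary",
]

VAS_INSTRUMENTS = ("RAYNAUD_VAS", "LESION_VAS", "SEVERITY_VAS")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the source study's design: 27 lesions photographed
    daily for 30 days, baseline areas log-normal with mean 11.6 mm² and
    s.d. 16.0 mm² (the printed s.d. exceeds the mean, so a normal draw
    would go negative), mean healing gradient -0.08 mm²/day, a 6 mm
    fiducial dot, and defect rates consistent with the study's image
    accounting (10% duplicates, 5% no-dot, ~1.5% wrong-angle).
    """

    n_lesions: int = 27
    n_days: int = 30
    baseline_area_mean: float = 11.6
    baseline_area_sd: float = 16.0
    healing_gradient_mean: float = -0.08
    healing_gradient_sd: float = 0.06
    area_noise_sd: float = 0.0
    dot_diameter_mm: float = DOT_DIAMETER_MM
    mm_per_px_range: tuple[float, float] = (0.05, 0.15)
    tilt_max_deg: float = 10.0
    wrong_angle_tilt_range: tuple[float, float] = (48.0, 65.0)
    p_missing_day: float = 0.07
    p_no_dot: float = 0.05
    p_duplicate: float = 0.10
    p_wrong_angle: float = 0.015
    lighting_gain_range: tuple[float, float] = (0.85, 1.15)
    colour_cast_sd: float = 4.0
    noise_sd: float = 3.0
    annotation_jitter_px: float = 1.0
    skin_rgb: tuple[int, int, int] = (201, 161, 140)
    lesion_rgb: tuple[int, int, int] = (128, 32, 38)
    dot_rgb: tuple[int, int, int] = DEFAULT_DOT_RGB
    lesion_dot_separation_mm: float = 8.0
    margin_mm: float = 3.0
    # PROM generation (Table-1-style distributions)
    pain_mean: float = 5.7
    pain_sd_between: float = 1.5
    pain_sd_within: float = 1.8
    pain_slope_mean: float = -0.02
    pain_slope_sd: float = 0.04
    vas_means: tuple[float, float, float] = (70.7, 72.4, 66.0)
    vas_sd_between: float = 18.0
    vas_sd_within: float = 12.0
    hdiss_mean: float = 2.2
    hdiss_sd: float = 0.9
    hdiss_item_sd: float = 1.2
    hdiss_day30_shift: float = -0.3
    p_hdiss_special: float = 0.05
    p_missing_pain: float = 0.30
    p_missing_vas: float = 0.15
    p_missing_hdiss: float = 0.20
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.dot_diameter_mm <= 0:
            raise ValueError("dot_diameter_mm must be positive")
        for name in ("p_missing_day", "p_no_dot", "p_duplicate", "p_wrong_angle",
                     "p_hdiss_special", "p_missing_pain", "p_missing_vas",
                     "p_missing_hdiss"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        lo, hi = self.mm_per_px_range
        if not 0 < lo <= hi:
            raise ValueError("mm_per_px_range must be a positive interval")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = tuple(v) if isinstance(v, list) else v
        return cls(**kwargs)


@dataclass
class GroundTruthRecord:
    """Everything the generator knows about one rendered image.

    ``area_mm2`` is the analytic in-plane lesion area from the healing
    schedule; ``mask`` is its rasterized projection (pixel count × scale²
    agrees with ``area_mm2 × cos(tilt)`` up to a boundary-pixel band).
    """

    image_id: str
    episode_id: str
    lesion_id: str
    day: int
    mask: np.ndarray = field(repr=False)
    area_mm2: float = 0.0
    mm_per_px: float = 0.0
    dot_centre: Optional[tuple[float, float]] = None  # (x, y) px
    dot_axes: Optional[tuple[float, float]] = None  # (major, minor) semi-axes px
    dot_angle_deg: float = 0.0
    tilt_deg: float = 0.0
    lesion_lab: tuple[float, float, float] = (0.0, 0.0, 0.0)
    skin_lab: tuple[float, float, float] = (0.0, 0.0, 0.0)
    no_dot: bool = False
    wrong_angle: bool = False
    duplicate_of: Optional[str] = None

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("mask")
        for k in ("dot_centre", "dot_axes", "lesion_lab", "skin_lab"):
            if d[k] is not None:
                d[k] = [float(v) for v in d[k]]
        return d


@dataclass
class SyntheticPROMSet:
    """Generated patient-reported outcomes in long form.

    ``records`` has columns (episode_id, lesion_id, day, instrument, item,
    value); submitted rows only. ``expected`` counts per instrument include
    the rows removed by the missingness process, so completeness equals
    1 − realized missingness by construction. ``truth`` holds the per-episode
    generating parameters (e.g. the true pain slope) for association tests.
    """

    records: pd.DataFrame
    expected: dict[str, int]
    truth: dict[str, dict[str, float]]

    def completeness(self, instrument: str) -> float:
        n = int((self.records["instrument"] == instrument).sum())
        if instrument == "HDISS_DU":
            n = len(self.records[self.records["instrument"] == instrument]
                    .groupby(["episode_id", "day"]))
        return n / self.expected[instrument] if self.expected[instrument] else float("nan")


class _LesionShape:
    """Fixed per-lesion star-shaped boundary: perturbed ellipse in mm."""

    _PHI = np.linspace(0.0, 2.0 * np.pi, 2048, endpoint=False)

    def __init__(self, rng: np.random.Generator):
        self.aspect = rng.uniform(0.6, 1.0)
        self.beta = rng.uniform(0.0, np.pi)
        ks = np.array([2, 3, 4])
        self.amps = rng.uniform(0.0, 0.18) / ks * rng.uniform(0.5, 1.0, size=3)
        self.phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
        r = self._unit_radius(self._PHI)
        # area of r(phi): (1/2) ∫ r² dphi
        self.unit_area = 0.5 * float(np.sum(r ** 2)) * (2.0 * np.pi / len(self._PHI))
        self.unit_rmax = float(r.max())

    def _unit_radius(self, phi: np.ndarray) -> np.ndarray:
        p = phi - self.beta
        q = self.aspect
        ell = q / np.sqrt((q * np.cos(p)) ** 2 + np.sin(p) ** 2)
        pert = 1.0 + sum(a * np.cos(k * p + ph)
                         for a, k, ph in zip(self.amps, (2, 3, 4), self.phases))
        return ell * pert

    def radius_mm(self, phi: np.ndarray, area_mm2: float) -> np.ndarray:
        s = np.sqrt(area_mm2 / self.unit_area)
        return s * self._unit_radius(phi)

    def rmax_mm(self, area_mm2: float) -> float:
        return float(np.sqrt(area_mm2 / self.unit_area) * self.unit_rmax)


def _projection(scale: float, tilt_deg: float, omega_deg: float) -> np.ndarray:
    """Linear map from scene mm to image px: rotation-conjugated axis squash."""
    c, s = np.cos(np.radians(omega_deg)), np.sin(np.radians(omega_deg))
    rot = np.array([[c, -s], [s, c]])
    squash = np.diag([1.0, np.cos(np.radians(tilt_deg))])
    return rot @ squash @ rot.T / scale


def _render_one(
    cfg: SimulationConfig,
    shape: _LesionShape,
    lesion_centre_mm: np.ndarray,
    area_mm2: float,
    lesion_lab: np.ndarray,
    skin_lab: np.ndarray,
    scale: float,
    tilt_deg: float,
    omega_deg: float,
    no_dot: bool,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float], tuple[float, float]]:
    """Render one scene; returns (rgb, lesion mask, dot centre px, dot axes px)."""
    m = _projection(scale, tilt_deg, omega_deg)
    minv = np.linalg.inv(m)
    dot_r = cfg.dot_diameter_mm / 2.0
    rmax = shape.rmax_mm(area_mm2) if area_mm2 > 0 else 0.0
    pts = [(-dot_r, -dot_r), (-dot_r, dot_r), (dot_r, -dot_r), (dot_r, dot_r)]
    lx, ly = lesion_centre_mm
    for dx in (-rmax, rmax):
        for dy in (-rmax, rmax):
            pts.append((lx + dx, ly + dy))
    mm_pts = np.array(pts)
    px_pts = mm_pts @ m.T
    pad = cfg.margin_mm / scale
    lo = px_pts.min(axis=0) - pad
    hi = px_pts.max(axis=0) + pad
    origin = -lo  # px position of the dot centre (scene mm origin)
    w = int(np.ceil(hi[0] - lo[0])) + 1
    h = int(np.ceil(hi[1] - lo[1])) + 1

    xs = np.arange(w) - origin[0]
    ys = np.arange(h) - origin[1]
    px = np.stack(np.meshgrid(xs, ys), axis=-1)  # (h, w, 2) as (x, y)
    mm = px @ minv.T

    # lesion membership via the radial boundary function
    rel = mm - lesion_centre_mm
    if area_mm2 > 0:
        rho = np.hypot(rel[..., 0], rel[..., 1])
        phi = np.arctan2(rel[..., 1], rel[..., 0])
        lesion_mask = rho <= shape.radius_mm(phi, area_mm2)
    else:
        lesion_mask = np.zeros((h, w), dtype=bool)

    img = np.empty((h, w, 3), dtype=np.float64)
    img[...] = lab_to_srgb(skin_lab).astype(np.float64)
    if lesion_mask.any():
        img[lesion_mask] = lab_to_srgb(lesion_lab).astype(np.float64)
    if not no_dot:
        dot_mask = np.hypot(mm[..., 0], mm[..., 1]) <= dot_r
        img[dot_mask] = np.asarray(cfg.dot_rgb, dtype=np.float64)

    gain = rng.uniform(*cfg.lighting_gain_range)
    cast = rng.normal(0.0, cfg.colour_cast_sd, size=3)
    img = img * gain + cast
    img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    cos_t = np.cos(np.radians(tilt_deg))
    axes = (dot_r / scale, dot_r * cos_t / scale)
    return img, lesion_mask, (float(origin[0]), float(origin[1])), axes


def render_series(
    config: SimulationConfig,
) -> tuple[list[ImageRecord], list[GroundTruthRecord], SyntheticPROMSet]:
    """Generate the full synthetic cohort: images, ground truth and PROMs.

    One or more images per non-missing lesion-day; deterministic under
    ``config.rng_seed`` (identical seed ⇒ byte-identical rasters and
    records). One episode per lesion.
    """
    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    lesion_seeds = ss.spawn(config.n_lesions)
    prom_seed = ss.spawn(1)[0]

    skin_lab = srgb_to_lab(np.asarray(config.skin_rgb, dtype=float))
    lesion_lab0 = srgb_to_lab(np.asarray(config.lesion_rgb, dtype=float))

    images: list[ImageRecord] = []
    truths: list[GroundTruthRecord] = []
    lesion_truth: dict[str, dict[str, float]] = {}

    for li in range(config.n_lesions):
        rng = np.random.default_rng(lesion_seeds[li])
        lesion_id = f"L{li + 1:03d}"
        episode_id = f"E{li + 1:03d}"
        shape = _LesionShape(rng)
        mu_ln = np.log(config.baseline_area_mean) - 0.5 * np.log(
            1.0 + (config.baseline_area_sd / config.baseline_area_mean) ** 2)
        sd_ln = np.sqrt(np.log(1.0 + (config.baseline_area_sd / config.baseline_area_mean) ** 2))
        a1 = float(rng.lognormal(mu_ln, sd_ln))
        grad = float(rng.normal(config.healing_gradient_mean, config.healing_gradient_sd))
        angle = rng.uniform(0.0, 2.0 * np.pi)
        centre_mm = config.lesion_dot_separation_mm * np.array([np.cos(angle), np.sin(angle)])
        lesion_truth[episode_id] = {"baseline_area_mm2": a1, "area_slope": grad}

        for day in range(1, config.n_days + 1):
            if rng.random() < config.p_missing_day:
                continue
            area = a1 + grad * (day - 1)
            if config.area_noise_sd > 0:
                area += rng.normal(0.0, config.area_noise_sd)
            area = max(area, 0.0)
            w = min(area / a1, 1.0) if a1 > 0 else 0.0
            lesion_lab = skin_lab + w * (lesion_lab0 - skin_lab)

            no_dot = rng.random() < config.p_no_dot
            wrong_angle = rng.random() < config.p_wrong_angle
            tilt = (rng.uniform(*config.wrong_angle_tilt_range) if wrong_angle
                    else rng.uniform(0.0, config.tilt_max_deg))
            omega = rng.uniform(0.0, 180.0)
            scale = rng.uniform(*config.mm_per_px_range)

            rgb, mask, dot_centre, dot_axes = _render_one(
                config, shape, centre_mm, area, lesion_lab, skin_lab,
                scale, tilt, omega, no_dot, rng)

            image_id = f"{lesion_id}-d{day:02d}-1"
            ts = f"2026-03-{day:02d}T10:00:00"
            images.append(ImageRecord(image_id, episode_id, lesion_id, day, ts, rgb))
            truths.append(GroundTruthRecord(
                image_id=image_id, episode_id=episode_id, lesion_id=lesion_id,
                day=day, mask=mask, area_mm2=area, mm_per_px=scale,
                dot_centre=None if no_dot else dot_centre,
                dot_axes=None if no_dot else dot_axes,
                dot_angle_deg=omega, tilt_deg=tilt,
                lesion_lab=tuple(float(v) for v in lesion_lab),
                skin_lab=tuple(float(v) for v in skin_lab),
                no_dot=no_dot, wrong_angle=wrong_angle))

            if rng.random() < config.p_duplicate:
                # a blurred re-take of the same scene, submitted minutes later
                blurred = gaussian_filter(rgb.astype(np.float64), sigma=(1.5, 1.5, 0))
                blurred = blurred + rng.normal(0.0, config.noise_sd, size=rgb.shape)
                blurred = np.clip(np.round(blurred), 0, 255).astype(np.uint8)
                dup_id = f"{lesion_id}-d{day:02d}-2"
                ts2 = f"2026-03-{day:02d}T10:05:00"
                images.append(ImageRecord(dup_id, episode_id, lesion_id, day, ts2, blurred))
                truths.append(dataclasses.replace(
                    truths[-1], image_id=dup_id, duplicate_of=image_id))

    proms = _render_proms(config, prom_seed, lesion_truth)
    return images, truths, proms


def _render_proms(config: SimulationConfig, seed: np.random.SeedSequence,
                  lesion_truth: dict[str, dict[str, float]]) -> SyntheticPROMSet:
    rng = np.random.default_rng(seed)
    rows = []
    expected = {"PAIN": 0, "HDISS_DU": 0}
    for v in VAS_INSTRUMENTS:
        expected[v] = 0
    truth: dict[str, dict[str, float]] = {}

    vas_days = [d for d in (1, 8, 15, 22, 29) if d <= config.n_days]
    hdiss_days = [d for d in (1, config.n_days) if d >= 1]

    for li in range(config.n_lesions):
        episode_id = f"E{li + 1:03d}"
        lesion_id = f"L{li + 1:03d}"
        pain_mu = rng.normal(config.pain_mean, config.pain_sd_between)
        pain_slope = rng.normal(config.pain_slope_mean, config.pain_slope_sd)
        truth[episode_id] = dict(lesion_truth.get(episode_id, {}))
        truth[episode_id].update({"pain_baseline": pain_mu, "pain_slope": pain_slope})

        for day in range(1, config.n_days + 1):
            expected["PAIN"] += 1
            if rng.random() < config.p_missing_pain:
                continue
            val = pain_mu + pain_slope * (day - 1) + rng.normal(0.0, config.pain_sd_within)
            rows.append((episode_id, lesion_id, day, "PAIN", 0,
                         int(np.clip(round(val), 0, 10))))

        for inst, mean in zip(VAS_INSTRUMENTS, config.vas_means):
            base = rng.normal(mean, config.vas_sd_between)
            for day in vas_days:
                expected[inst] += 1
                if rng.random() < config.p_missing_vas:
                    continue
                val = base + rng.normal(0.0, config.vas_sd_within)
                rows.append((episode_id, lesion_id, day, inst, 0,
                             int(np.clip(round(val), 0, 100))))

        h_mu = float(np.clip(rng.normal(config.hdiss_mean, config.hdiss_sd), 0.0, 5.0))
        for day in sorted(set(hdiss_days)):
            expected["HDISS_DU"] += 1
            if rng.random() < config.p_missing_hdiss:
                continue
            mu = h_mu + (config.hdiss_day30_shift if day > 1 else 0.0)
            for item in range(1, 25):
                if rng.random() < config.p_hdiss_special:
                    v = int(rng.integers(6, 8))
                else:
                    v = int(np.clip(round(mu + rng.normal(0.0, config.hdiss_item_sd)), 0, 5))
                rows.append((episode_id, lesion_id, day, "HDISS_DU", item, v))

    records = pd.DataFrame(
        rows, columns=["episode_id", "lesion_id", "day", "instrument", "item", "value"])
    return SyntheticPROMSet(records=records, expected=expected, truth=truth)


def truth_area_oracle(truth: GroundTruthRecord) -> float:
    """Mask-based area: pixel count × mm_per_px² — the oracle for measurement tests."""
    return float(truth.mask.sum()) * truth.mm_per_px ** 2


def manual_boundary(
    truth: GroundTruthRecord,
    jitter_px: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    n_vertices: int = 72,
) -> Optional[np.ndarray]:
    """Emulate a human tracing the lesion border on one image.

    Extracts the truth mask's outer contour, subsamples it to roughly
    ``n_vertices`` points, and perturbs vertices with Gaussian jitter of
    ``jitter_px`` (annotation imprecision). Jitter is rejected and retried
    if it makes the polygon self-intersecting. Returns an (n, 2) array of
    (x, y) vertices on the half-open corner lattice, or None when the
    lesion has healed (empty mask).
    """
    if not truth.mask.any():
        return None
    contours = find_contours(truth.mask.astype(float), 0.5)
    contour = max(contours, key=len)
    step = max(1, len(contour) // n_vertices)
    pts = contour[::step]
    # (row, col) index coords -> (x, y) corner-lattice coords
    verts = np.column_stack([pts[:, 1], pts[:, 0]]) + 0.5
    if jitter_px > 0 and rng is not None:
        for _ in range(5):
            cand = verts + rng.normal(0.0, jitter_px, size=verts.shape)
            if _ShapelyPolygon(cand).is_valid:
                return cand
        return verts
    return verts
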