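"""End-to-end pipeline: simulate → calibrate → triage → segment → measure → analyze → report.

Each stage communicates with the next only through declared files under a
single run directory:

``images/``   8-bit RGB PNGs plus ``tables/images.csv`` (the ingest index)
``truth/``    generator ground truth (JSON), manual annotations (JSON), config
``masks/``    per-arm single-channel PNG lesion masks for used images
``tables/``   calibration, triage ledger, segmentation, measurement CSVs, PROMs
``report/``   flow accounting (JSON + text), agreement JSON, plots, summary

Re-running a stage on unchanged inputs reproduces its outputs byte for
byte; all randomness flows from the single seed in the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import calibration as cal_mod
from . import measurement as meas_mod
from . import segmentation as seg_mod
from . import synthesis as syn_mod
from . import triage as tri_mod
from .longitudinal import HealingTrajectoryModel
from .proms import pain_gradients, prom_summary

log = logging.getLogger("lesiontrack")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "stage_simulate", "stage_calibrate", "stage_triage", "stage_segment",
           "stage_measure", "stage_analyze", "stage_report"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run configuration; everything random flows from ``seed``."""

    seed: int = 0
    simulate: bool = True
    simulation: syn_mod.SimulationConfig = field(default_factory=syn_mod.SimulationConfig)
    angle_ratio_min: float = 0.75
    window_days: int = 30
    pooling: str = "mean_slopes"
    write_masks: bool = True
    segmentation: seg_mod.AutoSegmentationParams = field(
        default_factory=seg_mod.AutoSegmentationParams)

    def __post_init__(self) -> None:
        self.simulation.rng_seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = syn_mod.SimulationConfig.from_dict(raw.pop("simulation", {}) or {})
        seg = seg_mod.AutoSegmentationParams(**(raw.pop("segmentation", {}) or {}))
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(raw) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(simulation=sim, segmentation=seg, **raw)

    def to_yaml(self) -> str:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj
        return yaml.safe_dump(plain(dataclasses.asdict(self)), sort_keys=True)


def _dirs(out: Path) -> dict[str, Path]:
    d = {name: out / name for name in ("images", "truth", "masks", "tables", "report")}
    for p in d.values():
        p.mkdir(parents=True, exist_ok=True)
    return d


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    d = _dirs(out)
    images, truths, proms = syn_mod.render_series(cfg.simulation)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xA11]))

    index_rows = []
    ann: dict[str, list[list[float]]] = {}
    for img, truth in zip(images, truths):
        Image.fromarray(img.rgb).save(d["images"] / f"{img.image_id}.png")
        index_rows.append({"image_id": img.image_id, "episode_id": img.episode_id,
                           "lesion_id": img.lesion_id, "day": img.day,
                           "timestamp": img.timestamp,
                           "filename": f"{img.image_id}.png"})
        if truth.duplicate_of is None:
            verts = syn_mod.manual_boundary(truth, cfg.simulation.annotation_jitter_px, rng)
            if verts is not None:
                ann[img.image_id] = np.round(verts, 3).tolist()

    pd.DataFrame(index_rows).to_csv(d["tables"] / "images.csv", index=False)
    _write_json(d["truth"] / "truth.json", [t.to_jsonable() for t in truths])
    _write_json(d["truth"] / "annotations.json", ann)
    proms.records.to_csv(d["tables"] / "proms.csv", index=False)
    _write_json(d["truth"] / "prom_expected.json", proms.expected)
    _write_json(d["truth"] / "prom_truth.json", proms.truth)
    (d["truth"] / "config.yaml").write_text(cfg.to_yaml())
    log.info("simulate: %d images, %d lesions", len(images), cfg.simulation.n_lesions)


def _load_images(out: Path, ids: Optional[set[str]] = None) -> list[cal_mod.ImageRecord]:
    d = _dirs(out)
    index_path = d["tables"] / "images.csv"
    if not index_path.exists():
        raise PipelineError("ingest", f"no image index at {index_path}")
    index = pd.read_csv(index_path)
    if index.empty:
        raise PipelineError("ingest", "image index is empty: nothing to process")
    records = []
    for _, row in index.iterrows():
        if ids is not None and row["image_id"] not in ids:
            continue
        rgb = np.asarray(Image.open(d["images"] / row["filename"]).convert("RGB"))
        records.append(cal_mod.ImageRecord(
            image_id=row["image_id"], episode_id=row["episode_id"],
            lesion_id=row["lesion_id"], day=int(row["day"]),
            timestamp=row["timestamp"], rgb=rgb))
    return records


def stage_calibrate(cfg: PipelineConfig, out: Path) -> None:
    d = _dirs(out)
    images = _load_images(out)
    rows = []
    for img in images:
        c = cal_mod.detect_fiducial(img)
        rows.append({
            "image_id": img.image_id, "detected": c.detected,
            "centre_x": c.centre[0] if c.detected else "",
            "centre_y": c.centre[1] if c.detected else "",
            "major_px": c.major_semi_axis if c.detected else "",
            "minor_px": c.minor_semi_axis if c.detected else "",
            "axis_ratio": c.axis_ratio if c.detected else "",
            "confidence": c.confidence,
            "mm_per_px": c.mm_per_px if c.detected else ""})
    pd.DataFrame(rows).to_csv(d["tables"] / "calibration.csv", index=False,
                              float_format="%.6f")
    log.info("calibrate: %d images, %d detected", len(rows),
             sum(r["detected"] for r in rows))


def _load_calibrations(out: Path) -> dict[str, cal_mod.FiducialCalibration]:
    d = _dirs(out)
    path = d["tables"] / "calibration.csv"
    if not path.exists():
        raise PipelineError("triage", f"no calibration table at {path}")
    df = pd.read_csv(path)
    cals = {}
    for _, r in df.iterrows():
        if bool(r["detected"]):
            major = float(r["major_px"])
            cals[r["image_id"]] = cal_mod.FiducialCalibration(
                detected=True, centre=(float(r["centre_x"]), float(r["centre_y"])),
                major_semi_axis=major, minor_semi_axis=float(r["minor_px"]),
                orientation_deg=0.0, axis_ratio=float(r["axis_ratio"]),
                confidence=float(r["confidence"]), mm_per_px=float(r["mm_per_px"]))
        else:
            cals[r["image_id"]] = cal_mod.FiducialCalibration(
                detected=False, confidence=float(r["confidence"]))
    return cals


def stage_triage(cfg: PipelineConfig, out: Path) -> None:
    d = _dirs(out)
    images = _load_images(out)
    cals = _load_calibrations(out)
    expected = {lid: cfg.simulation.n_days
                for lid in sorted({im.lesion_id for im in images})}
    ledger = tri_mod.build_ledger(images, cals, expected, cfg.angle_ratio_min)
    ledger.to_csv(d["tables"] / "ledger.csv", index=False)

    prom_path = d["tables"] / "proms.csv"
    prom_table = None
    if prom_path.exists():
        records = pd.read_csv(prom_path)
        exp_path = d["truth"] / "prom_expected.json"
        if exp_path.exists():
            prom_table = tri_mod.prom_completeness(
                records, json.loads(exp_path.read_text()))
    report = tri_mod.completeness(ledger, expected, prom_table)
    _write_json(d["report"] / "consort.json", report.to_dict())
    (d["report"] / "consort.txt").write_text(report.text_table() + "\n")
    log.info("triage: %s", dict(report.category_counts))


def _used_ledger(out: Path) -> pd.DataFrame:
    path = _dirs(out)["tables"] / "ledger.csv"
    if not path.exists():
        raise PipelineError("segment", f"no triage ledger at {path}")
    ledger = pd.read_csv(path)
    return ledger[ledger["category"] == "USED"]


def stage_segment(cfg: PipelineConfig, out: Path, arm: str = "both") -> None:
    d = _dirs(out)
    used = _used_ledger(out)
    used_ids = set(used["image_id"])
    images = {im.image_id: im for im in _load_images(out, used_ids)}
    cals = _load_calibrations(out)
    arms = ("manual", "automated") if arm == "both" else (arm,)

    ann = {}
    ann_path = d["truth"] / "annotations.json"
    if ann_path.exists():
        ann = json.loads(ann_path.read_text())

    rows = []
    for image_id in sorted(used_ids):
        img = images[image_id]
        cal = cals[image_id]
        for a in arms:
            if a == "manual":
                verts = ann.get(image_id)
                if verts is None:
                    # annotator saw healed skin: record an explicit zero-area mask
                    mask = seg_mod.LesionMask(
                        raster=np.zeros(img.rgb.shape[:2], bool), arm="manual")
                else:
                    boundary = seg_mod.LesionBoundary(
                        lesion_id=img.lesion_id, image_id=image_id,
                        vertices=np.asarray(verts), arm="manual")
                    mask = seg_mod.rasterize_boundary(boundary, img.rgb.shape[:2])
            else:
                mask = seg_mod.segment_auto(img, cal, cfg.segmentation)
            rows.append({"image_id": image_id, "arm": a,
                         "detected": mask.detected, "area_px": mask.area_px})
            if cfg.write_masks and mask.detected and mask.raster is not None:
                Image.fromarray((mask.raster * np.uint8(255))).save(
                    d["masks"] / f"{image_id}_{a}.png")
    pd.DataFrame(rows).to_csv(d["tables"] / "segmentation.csv", index=False)
    log.info("segment: %d mask rows", len(rows))


def stage_measure(cfg: PipelineConfig, out: Path) -> None:
    d = _dirs(out)
    used = _used_ledger(out)
    seg_path = d["tables"] / "segmentation.csv"
    if not seg_path.exists():
        raise PipelineError("measure", f"no segmentation table at {seg_path}")
    seg = pd.read_csv(seg_path)
    cals = _load_calibrations(out)
    images = {im.image_id: im for im in _load_images(out, set(used["image_id"]))}
    ann = json.loads((d["truth"] / "annotations.json").read_text()) \
        if (d["truth"] / "annotations.json").exists() else {}

    # per-image calibrated areas
    area_rows = []
    for _, r in seg.iterrows():
        img = images[r["image_id"]]
        cal = cals[r["image_id"]]
        area = (float(r["area_px"]) * cal.mm_per_px ** 2
                if bool(r["detected"]) and cal.detected else np.nan)
        area_rows.append({"image_id": r["image_id"], "lesion_id": img.lesion_id,
                          "day": img.day, "arm": r["arm"], "area_mm2": area})
    areas = pd.DataFrame(area_rows)

    # fixed-boundary colour trajectories, one per lesion
    colour_rows = []
    for lesion_id, g in used.groupby("lesion_id"):
        series = sorted((images[i] for i in g["image_id"]), key=lambda im: im.day)
        series_cals = [cals[im.image_id] for im in series]
        first = next((im for im, c in zip(series, series_cals)
                      if c.detected and im.image_id in ann), None)
        if first is None:
            log.warning("measure: lesion %s has no usable first annotation", lesion_id)
            continue
        boundary = seg_mod.LesionBoundary(
            lesion_id=lesion_id, image_id=first.image_id,
            vertices=np.asarray(ann[first.image_id]), arm="manual")
        for cs in meas_mod.colour_track(series, series_cals, boundary):
            colour_rows.append({"image_id": cs.image_id, "L_mean": cs.l_mean,
                                "a_mean": cs.a_mean, "b_mean": cs.b_mean,
                                "delta_e": cs.delta_e_to_skin})
    colour = pd.DataFrame(colour_rows)

    table = areas.merge(colour, on="image_id", how="left") if not colour.empty else areas
    table = table.sort_values(["lesion_id", "day", "arm", "image_id"]).reset_index(drop=True)
    table.to_csv(d["tables"] / "measurements.csv", index=False, float_format="%.6f")
    log.info("measure: %d measurement rows", len(table))


def stage_analyze(cfg: PipelineConfig, out: Path) -> "HealingTrajectoryModel":
    d = _dirs(out)
    meas_path = d["tables"] / "measurements.csv"
    if not meas_path.exists():
        raise PipelineError("analyze", f"no measurement table at {meas_path}")
    meas = pd.read_csv(meas_path)

    pain = None
    prom_path = d["tables"] / "proms.csv"
    if prom_path.exists():
        proms = pd.read_csv(prom_path)
        pain = proms[proms["instrument"] == "PAIN"][["lesion_id", "day", "value"]]
        prom_summary(proms).to_csv(d["tables"] / "prom_summary.csv",
                                   index=False, float_format="%.4f")

    model = HealingTrajectoryModel(meas, pain=pain, window_days=cfg.window_days,
                                   pooling=cfg.pooling)
    res = model.fit()
    res.gradients_frame().to_csv(d["tables"] / "gradients.csv", index=False,
                                 float_format="%.6f")

    agreement: dict = {}
    for name, fn in (("area_pearson", res.area_correlation),
                     ("area_ratio_bland_altman", res.area_ratio_agreement),
                     ("gradient_pearson", res.gradient_correlation)):
        try:
            a = fn()
            agreement[name] = {k: v for k, v in dataclasses.asdict(a).items()
                               if v is not None}
        except (ValueError, KeyError) as exc:
            agreement[name] = {"error": str(exc)}
    for arm in ("manual", "automated"):
        mean, se, n = res.mean_gradient(f"{arm}_area")
        agreement[f"{arm}_mean_gradient"] = {
            "slope": mean, "se": se, "n": n,
            "total_change": res.total_change(f"{arm}_area")}
    try:
        agreement["associations"] = res.associations().to_dict(orient="records")
    except ValueError as exc:
        agreement["associations"] = {"error": str(exc)}
    _write_json(d["report"] / "agreement.json", agreement)
    _plots(res, d["report"])
    (d["report"] / "analysis_summary.txt").write_text(res.summary() + "\n")
    log.info("analyze: fitted %d channels", len(res.fits))
    return model


def _plots(res, report_dir: Path) -> None:
    wide = res._paired_areas()
    if not wide.empty:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(wide["automated"], wide["manual"], s=12, alpha=0.6)
        lim = float(max(wide.max())) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=1, label="line of equality")
        ax.set_xlabel("automated area (mm²)")
        ax.set_ylabel("manual area (mm²)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(report_dir / "area_scatter.png", dpi=100)
        plt.close(fig)

        pos = wide[(wide["manual"] > 0) & (wide["automated"] > 0)]
        if len(pos) > 1:
            ratio = np.log(pos["manual"] / pos["automated"])
            mean = ratio.mean()
            sd = ratio.std(ddof=1)
            gm = np.sqrt(pos["manual"] * pos["automated"])
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.scatter(gm, ratio, s=12, alpha=0.6)
            for y, style in ((mean, "-"), (mean - 1.96 * sd, "--"), (mean + 1.96 * sd, "--")):
                ax.axhline(y, color="r", ls=style, lw=1)
            ax.set_xlabel("geometric mean area (mm²)")
            ax.set_ylabel("ln(manual / automated)")
            fig.tight_layout()
            fig.savefig(report_dir / "bland_altman.png", dpi=100)
            plt.close(fig)

    grads = res.gradients_frame()
    if not grads.empty:
        piv = grads.pivot_table(index="lesion_id", columns="channel", values="slope")
        if {"manual_area", "automated_area"}.issubset(piv.columns):
            sub = piv[["manual_area", "automated_area"]].dropna()
            fig, ax = plt.subplots(figsize=(4.5, 4.5))
            ax.scatter(sub["automated_area"], sub["manual_area"], s=18)
            ax.axhline(0, color="grey", lw=0.5)
            ax.axvline(0, color="grey", lw=0.5)
            ax.set_xlabel("automated gradient (mm²/day)")
            ax.set_ylabel("manual gradient (mm²/day)")
            fig.tight_layout()
            fig.savefig(report_dir / "gradient_scatter.png", dpi=100)
            plt.close(fig)


def stage_report(cfg: PipelineConfig, out: Path) -> str:
    d = _dirs(out)
    parts = []
    consort = d["report"] / "consort.txt"
    summary = d["report"] / "analysis_summary.txt"
    if not consort.exists() or not summary.exists():
        raise PipelineError("report", "run triage and analyze before report")
    parts.append(consort.read_text())
    parts.append(summary.read_text())
    text = "\n".join(parts)
    (d["report"] / "report.txt").write_text(text)
    return text


def _manifest(cfg: PipelineConfig, out: Path) -> None:
    d = _dirs(out)
    cfg_text = cfg.to_yaml()
    counts = {}
    for name in ("images.csv", "calibration.csv", "ledger.csv",
                 "segmentation.csv", "measurements.csv", "gradients.csv"):
        p = d["tables"] / name
        if p.exists():
            counts[name] = int(len(pd.read_csv(p)))
    _write_json(out / "manifest.json", {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": cfg.seed,
        "record_counts": counts,
        "package": "lesiontrack 0.1.0"})


def run_pipeline(config: PipelineConfig | str | Path, out: str | Path) -> Path:
    """Execute every stage in order; returns the run directory."""
    cfg = (config if isinstance(config, PipelineConfig)
           else PipelineConfig.from_yaml(config))
    out = Path(out)
    stages = [("simulate", stage_simulate)] if cfg.simulate else []
    stages += [("calibrate", stage_calibrate), ("triage", stage_triage),
               ("segment", stage_segment), ("measure", stage_measure),
               ("analyze", stage_analyze), ("report", stage_report)]
    for name, fn in stages:
        log.info("stage %s", name)
        try:
            fn(cfg, out)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc
    _manifest(cfg, out)
    return out
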