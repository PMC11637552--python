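"""Image usability triage and completeness accounting.

Every submitted image is classified into the flow-ledger categories used in
wound-imaging feasibility reporting: USED, BETTER_IMAGE_CHOSEN (a superior
image from the same day exists), NO_DOT (no fiducial, so no scale), or
WRONG_ANGLE (fiducial too eccentric, implying an oblique view). Days with
no submission are ledgered NOT_SUBMITTED. Wrong-angle is operationalized
from the fiducial's minor/major axis ratio — the dot is the only object of
known shape in the scene — with a default floor of 0.75 (≈ 41° tilt).

Completeness is the fraction of expected lesion-days with a USED image,
reported as integer percentages (rounded half-up, matching the usual
printed style), per lesion and pooled; the same machinery scores PROM
completeness against each instrument's schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import laplace

from .calibration import FiducialCalibration, ImageRecord

__all__ = [
    "UsabilityCategory",
    "CompletenessReport",
    "classify_image",
    "select_daily_image",
    "sharpness",
    "build_ledger",
    "completeness",
    "prom_completeness",
    "percent",
]


class UsabilityCategory(str, Enum):
    USED = "USED"
    BETTER_IMAGE_CHOSEN = "BETTER_IMAGE_CHOSEN"
    NO_DOT = "NO_DOT"
    WRONG_ANGLE = "WRONG_ANGLE"
    NOT_SUBMITTED = "NOT_SUBMITTED"


def percent(numerator: float, denominator: float) -> int:
    """Integer percentage, rounded half-up (printed-style rounding)."""
    if denominator == 0:
        return 0
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def classify_image(
    image: ImageRecord,
    cal: FiducialCalibration,
    angle_ratio_min: float = 0.75,
) -> UsabilityCategory:
    """Usability category for one image given its fiducial calibration.

    NO_DOT when the fiducial was not detected; WRONG_ANGLE when its axis
    ratio falls below ``angle_ratio_min``; otherwise the image is a USED
    candidate (daily selection may later demote it to BETTER_IMAGE_CHOSEN).
    """
    if not cal.detected:
        return UsabilityCategory.NO_DOT
    if cal.axis_ratio is not None and cal.axis_ratio < angle_ratio_min:
        return UsabilityCategory.WRONG_ANGLE
    return UsabilityCategory.USED


def sharpness(image: ImageRecord | np.ndarray) -> float:
    """Variance of a Laplacian high-pass response on the grey image."""
    rgb = image.rgb if isinstance(image, ImageRecord) else np.asarray(image)
    grey = rgb.astype(np.float64).mean(axis=2)
    return float(laplace(grey).var())


def select_daily_image(
    candidates: Sequence[tuple[ImageRecord, FiducialCalibration]],
) -> tuple[ImageRecord, list[ImageRecord]]:
    """Pick the single image to use for a lesion-day.

    Ranking: highest fiducial confidence (rounded to 2 decimals so that
    near-ties fall through), then highest sharpness, then the earliest
    timestamp as the final tie-break. Everything else is demoted to
    BETTER_IMAGE_CHOSEN by the caller.
    """
    if not candidates:
        raise ValueError("select_daily_image needs at least one candidate")
    scored = [(-round(cal.confidence, 2), -sharpness(img), img.timestamp, i, img)
              for i, (img, cal) in enumerate(candidates)]
    scored.sort(key=lambda t: t[:4])
    used = scored[0][4]
    demoted = [t[4] for t in scored[1:]]
    return used, demoted


def build_ledger(
    images: Sequence[ImageRecord],
    calibrations: Mapping[str, FiducialCalibration],
    expected_days_per_lesion: Mapping[str, int],
    angle_ratio_min: float = 0.75,
) -> pd.DataFrame:
    """Classify a batch, run daily selection, and ledger every lesion-day.

    Returns a DataFrame with columns (image_id, lesion_id, day, category);
    NOT_SUBMITTED rows have an empty image_id. Exactly one USED image per
    submitted lesion-day.
    """
    rows = []
    by_day: dict[tuple[str, int], list[tuple[ImageRecord, FiducialCalibration]]] = {}
    for img in images:
        cal = calibrations[img.image_id]
        cat = classify_image(img, cal, angle_ratio_min)
        if cat is UsabilityCategory.USED:
            by_day.setdefault((img.lesion_id, img.day), []).append((img, cal))
        else:
            rows.append((img.image_id, img.lesion_id, img.day, cat.value))

    for (lesion_id, day), cands in by_day.items():
        used, demoted = select_daily_image(cands)
        rows.append((used.image_id, lesion_id, day, UsabilityCategory.USED.value))
        for img in demoted:
            rows.append((img.image_id, lesion_id, day,
                         UsabilityCategory.BETTER_IMAGE_CHOSEN.value))

    submitted_days = {(r[1], r[2]) for r in rows}
    for lesion_id, n_days in expected_days_per_lesion.items():
        for day in range(1, n_days + 1):
            if (lesion_id, day) not in submitted_days:
                rows.append(("", lesion_id, day, UsabilityCategory.NOT_SUBMITTED.value))

    df = pd.DataFrame(rows, columns=["image_id", "lesion_id", "day", "category"])
    return df.sort_values(["lesion_id", "day", "image_id"]).reset_index(drop=True)


@dataclass
class CompletenessReport:
    """Expected / returned / used counts and integer percentages."""

    per_lesion: pd.DataFrame
    expected: int
    returned: int
    used: int
    used_pct: int
    category_counts: dict[str, int]
    prom: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        d = {
            "expected": self.expected,
            "returned": self.returned,
            "used": self.used,
            "used_pct": self.used_pct,
            "categories": self.category_counts,
            "per_lesion": self.per_lesion.to_dict(orient="records"),
        }
        if self.prom is not None:
            d["prom"] = self.prom.to_dict(orient="records")
        return d

    def text_table(self) -> str:
        lines = ["Image accounting",
                 f"  expected {self.expected}  returned {self.returned}  "
                 f"used {self.used} ({self.used_pct}%)"]
        for cat, n in sorted(self.category_counts.items()):
            lines.append(f"  {cat:<22s} {n}")
        if self.prom is not None:
            lines.append("PROM completeness")
            for _, r in self.prom.iterrows():
                lines.append(f"  {r['instrument']:<14s} {r['returned']}/{r['expected']}"
                             f" ({r['pct']}%)")
        return "\n".join(lines)


def completeness(
    ledger: pd.DataFrame,
    expected_days_per_lesion: Mapping[str, int],
    prom_table: Optional[pd.DataFrame] = None,
) -> CompletenessReport:
    """Completeness statistics from a triage ledger.

    Raises on an inconsistent ledger (more than one USED image for a
    lesion-day).
    """
    used_rows = ledger[ledger["category"] == UsabilityCategory.USED.value]
    dup = used_rows.groupby(["lesion_id", "day"]).size()
    if (dup > 1).any():
        bad = dup[dup > 1].index.tolist()
        raise ValueError(f"ledger has multiple USED images for lesion-days: {bad}")

    per_rows = []
    for lesion_id, n_days in sorted(expected_days_per_lesion.items()):
        sub = ledger[ledger["lesion_id"] == lesion_id]
        returned = int((sub["category"] != UsabilityCategory.NOT_SUBMITTED.value).sum())
        used = int((sub["category"] == UsabilityCategory.USED.value).sum())
        per_rows.append({
            "lesion_id": lesion_id, "expected": n_days, "returned": returned,
            "used": used, "used_pct": percent(used, n_days)})
    per_lesion = pd.DataFrame(per_rows)

    expected = int(sum(expected_days_per_lesion.values()))
    returned = int((ledger["category"] != UsabilityCategory.NOT_SUBMITTED.value).sum())
    used = int((ledger["category"] == UsabilityCategory.USED.value).sum())
    cats = ledger["category"].value_counts().to_dict()
    return CompletenessReport(
        per_lesion=per_lesion, expected=expected, returned=returned, used=used,
        used_pct=percent(used, expected),
        category_counts={k: int(v) for k, v in cats.items()},
        prom=prom_table)


def prom_completeness(records: pd.DataFrame, expected: Mapping[str, int]) -> pd.DataFrame:
    """Per-instrument returned/expected counts and integer percentages.

    HDISS-DU is counted per administration (one 24-item questionnaire),
    single-value instruments per record.
    """
    rows = []
    for inst, exp in expected.items():
        sub = records[records["instrument"] == inst]
        if inst == "HDISS_DU":
            n = int(sub.groupby(["episode_id", "day"]).ngroups)
        else:
            n = len(sub)
        rows.append({"instrument": inst, "expected": int(exp), "returned": n,
                     "pct": percent(n, exp)})
    return pd.DataFrame(rows)
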