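"""Validation, scoring and summary of patient-reported outcomes.

Instruments collected by the companion app:

* PAIN — daily pain, integer Likert 0–10 (10 = worst possible pain);
* RAYNAUD_VAS / LESION_VAS / SEVERITY_VAS — weekly 0–100 visual analogue
  scales (interference by Raynaud's, by finger lesions, overall severity);
* HDISS_DU — Hand Disability in Systemic Sclerosis–Digital Ulcers: 24 items
  each scored 0–5 (0 = yes without difficulty, 5 = impossible), with
  special codes 6 ("did not do this activity") and 7 ("used unaffected
  hand only").

HDISS-DU scoring here takes the mean over items scored 0–5; codes 6 and 7
are treated as non-scorable, excluded from the mean and counted
separately, and a score is valid only when at least half the items (12 of
24) are scorable. The instrument's official manual may treat codes 6/7
differently; the rule is declared and configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .longitudinal import GradientFit, fit_gradient

__all__ = [
    "PROMRecord",
    "HDISSDUScore",
    "INSTRUMENT_RANGES",
    "validate_prom",
    "score_hdiss_du",
    "prom_summary",
    "pain_gradients",
]

INSTRUMENT_RANGES = {
    "PAIN": (0, 10),
    "RAYNAUD_VAS": (0, 100),
    "LESION_VAS": (0, 100),
    "SEVERITY_VAS": (0, 100),
    "HDISS_DU": (0, 7),
}

#: Scheduled collection days within a 30-day episode.
SCHEDULES = {
    "PAIN": set(range(1, 31)),
    "RAYNAUD_VAS": {1, 8, 15, 22, 29},
    "LESION_VAS": {1, 8, 15, 22, 29},
    "SEVERITY_VAS": {1, 8, 15, 22, 29},
    "HDISS_DU": {1, 30},
}


@dataclass
class PROMRecord:
    episode_id: str
    day: int
    instrument: str
    value: float
    item: int = 0  # HDISS-DU item number (1-24); 0 for single-value instruments
    valid: bool = True
    reason: str = ""


def validate_prom(record: PROMRecord, check_schedule: bool = False) -> PROMRecord:
    """Range- (and optionally schedule-) check one record.

    Out-of-range values are flagged, not raised, so a batch can continue;
    fractional VAS values (the app used a slider) are rounded and noted.
    """
    inst = record.instrument
    if inst not in INSTRUMENT_RANGES:
        record.valid = False
        record.reason = f"unknown instrument {inst!r}"
        return record
    lo, hi = INSTRUMENT_RANGES[inst]
    v = record.value
    if inst.endswith("VAS") and float(v) != int(v):
        record.value = v = float(round(v))
        record.reason = "fractional VAS rounded"
    if not lo <= v <= hi:
        record.valid = False
        record.reason = f"value {v} outside [{lo}, {hi}]"
        return record
    if inst != "HDISS_DU" and float(v) != int(v) and inst == "PAIN":
        record.valid = False
        record.reason = "pain score must be an integer"
        return record
    if inst == "HDISS_DU" and not 1 <= record.item <= 24:
        record.valid = False
        record.reason = f"HDISS-DU item {record.item} outside 1-24"
        return record
    if check_schedule and record.day not in SCHEDULES[inst]:
        record.valid = False
        record.reason = f"day {record.day} not on the {inst} schedule"
    return record


@dataclass
class HDISSDUScore:
    """Mean item score (0–5) with the non-scorable codes accounted for."""

    score: Optional[float]
    n_valid: int
    n_code6: int
    n_code7: int
    valid: bool


def score_hdiss_du(items: Sequence[float], min_valid_items: int = 12) -> HDISSDUScore:
    """Score one HDISS-DU administration (24 items).

    Items coded 6 ("did not do") and 7 ("unaffected hand only") are
    excluded from the mean and counted separately; the score is invalid
    when fewer than ``min_valid_items`` items are scorable. Item order is
    irrelevant.
    """
    arr = np.asarray(items, dtype=np.float64)
    if arr.shape != (24,):
        raise ValueError(f"HDISS-DU has exactly 24 items, got {arr.shape}")
    if ((arr < 0) | (arr > 7)).any():
        raise ValueError("HDISS-DU items must lie in 0..7")
    scorable = arr <= 5
    n_valid = int(scorable.sum())
    n6 = int((arr == 6).sum())
    n7 = int((arr == 7).sum())
    valid = n_valid >= min_valid_items
    score = float(arr[scorable].mean()) if valid and n_valid else None
    return HDISSDUScore(score=score, n_valid=n_valid, n_code6=n6, n_code7=n7, valid=valid)


def prom_summary(records: pd.DataFrame, days: Sequence[int] = (1, 8, 15, 29)) -> pd.DataFrame:
    """Mean (s.d.) with n per instrument at the reporting days.

    Mirrors the usual baseline/week-1/week-2/end-of-study table: one row
    per instrument, HDISS-DU summarized by its 0–5 administration score
    (nearest scheduled day within ±1). A single observation reports its
    mean with the s.d. absent; instruments with no data yield n = 0 rows.
    """
    rows = []
    for inst in INSTRUMENT_RANGES:
        sub = records[records["instrument"] == inst]
        for day in days:
            if inst == "HDISS_DU":
                day_lo, day_hi = day - 1, day + 1
                day_sub = sub[(sub["day"] >= day_lo) & (sub["day"] <= day_hi)]
                vals = []
                for (_, _d), g in day_sub.groupby(["episode_id", "day"]):
                    g24 = g.sort_values("item")
                    if len(g24) == 24:
                        s = score_hdiss_du(g24["value"].to_numpy())
                        if s.valid:
                            vals.append(s.score)
                vals = np.asarray(vals, dtype=float)
            else:
                vals = sub[sub["day"] == day]["value"].to_numpy(dtype=float)
            n = len(vals)
            mean = float(vals.mean()) if n else float("nan")
            sd = float(vals.std(ddof=1)) if n > 1 else float("nan")
            rows.append({"instrument": inst, "day": day, "n": n,
                         "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def pain_gradients(records: pd.DataFrame, min_points: int = 3) -> dict[str, GradientFit]:
    """Per-episode OLS slope of daily pain vs day.

    Uses the same regression implementation as every other channel, so the
    pain-change scalar entering the association analysis is defined
    identically to the area and colour gradients.
    """
    out: dict[str, GradientFit] = {}
    sub = records[records["instrument"] == "PAIN"]
    for eid, g in sub.groupby("episode_id"):
        arr = g[["day", "value"]].to_numpy(dtype=float)
        if len(arr) < min_points:
            continue
        out[str(eid)] = fit_gradient(arr, lesion_id=str(eid), channel="pain")
    return out
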