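"""Per-lesion healing gradients and between-arm agreement statistics.

The core analysis fits an ordinary least-squares line to each lesion's
day-ordered measurements — area (mm²) for the manual and automated arms,
ΔE-to-skin for colour, and daily pain score — and summarizes the cohort by
the unweighted mean of per-lesion slopes ("the average gradient"). A slope
of g mm²/day over a 30-day window corresponds to a total change of
|g| × 30 mm². Agreement between arms is assessed two ways:

* Pearson correlation, both of paired per-image areas and of per-lesion
  gradients;
* ratio-scale Bland–Altman: with d_i = ln(manual_i / automated_i), the
  geometric mean ratio is exp(mean d) and the 95% limits of agreement are
  exp(mean d ± 1.96 sd d). A geometric mean ratio of 0.6 reads "manual
  measurements are on average 40% lower than automated".

Missing measurements (undetected lesions, missing days) are simply absent:
pairs with a missing member are dropped, never imputed or zero-filled.

`HealingTrajectoryModel` / `HealingTrajectoryResults` wrap the whole
analysis for a cohort measurement table, statsmodels-style.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GradientFit",
    "AgreementResult",
    "fit_gradient",
    "total_change",
    "pearson",
    "bland_altman_ratio",
    "pain_gradient_association",
    "HealingTrajectoryModel",
    "HealingTrajectoryResults",
]


@dataclass
class GradientFit:
    """OLS line for one lesion's series in one channel."""

    lesion_id: str
    channel: str  # manual_area | automated_area | colour | pain
    slope: float  # per day
    intercept: float
    slope_se: float
    n: int
    r2: float


@dataclass
class AgreementResult:
    """Pearson and/or ratio-Bland–Altman agreement between two sets."""

    r: Optional[float] = None
    p_value: Optional[float] = None
    n: int = 0
    valid: bool = True
    note: str = ""
    geometric_mean_ratio: Optional[float] = None
    loa_lower: Optional[float] = None
    loa_upper: Optional[float] = None
    percent_lower: Optional[float] = None  # 100 × (1 − geometric mean ratio)


def fit_gradient(series: Sequence[tuple[float, float]] | np.ndarray,
                 lesion_id: str = "", channel: str = "") -> GradientFit:
    """Ordinary least-squares slope over (day, value) pairs.

    Requires at least 3 non-missing points; missing days are simply absent.
    For a perfectly constant series the slope and its standard error are 0
    and R² is reported as 1 (the flat line is an exact fit).
    """
    arr = np.asarray(series, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("series must be (n, 2) day-value pairs")
    arr = arr[~np.isnan(arr).any(axis=1)]
    n = len(arr)
    if n < 3:
        raise ValueError(f"gradient fit needs >= 3 points, got {n}")
    x, y = arr[:, 0], arr[:, 1]
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0.0:
        raise ValueError("gradient fit needs at least two distinct days")
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    se = math.sqrt(ss_res / (n - 2) / sxx) if n > 2 else float("nan")
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return GradientFit(lesion_id=lesion_id, channel=channel, slope=slope,
                       intercept=intercept, slope_se=se, n=n, r2=r2)


def total_change(fit: GradientFit, window_days: int = 30) -> float:
    """|slope| × window, the total change over the study window.

    Reported as a total *decrease* when the slope is negative (e.g. a slope
    of -0.08 mm²/day over 30 days is a 2.4 mm² decrease).
    """
    return abs(fit.slope) * window_days


def pearson(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Product-moment correlation on pairwise-complete pairs.

    Pairs with a missing (NaN) member are dropped. Fewer than 3 complete
    pairs is an error; zero variance in either vector makes r undefined and
    is flagged rather than raised.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = len(xa)
    if n < 3:
        raise ValueError(f"Pearson correlation needs >= 3 complete pairs, got {n}")
    if np.ptp(xa) == 0.0 or np.ptp(ya) == 0.0:
        return AgreementResult(r=float("nan"), p_value=float("nan"), n=n,
                               valid=False, note="zero variance: r undefined")
    res = sps.pearsonr(xa, ya)
    return AgreementResult(r=float(res.statistic), p_value=float(res.pvalue), n=n)


def bland_altman_ratio(manual: Sequence[float], automated: Sequence[float],
                       loa_multiplier: float = 1.96) -> AgreementResult:
    """Ratio-scale Bland–Altman agreement on the log scale.

    Pairs with a missing member are dropped (matching the handling of
    undetected automated measurements); non-positive values are rejected
    since the ratio analysis lives on the log scale.
    """
    ma = np.asarray(manual, dtype=np.float64)
    au = np.asarray(automated, dtype=np.float64)
    if ma.shape != au.shape:
        raise ValueError("manual and automated must have equal length")
    keep = ~(np.isnan(ma) | np.isnan(au))
    ma, au = ma[keep], au[keep]
    if len(ma) == 0:
        raise ValueError("no complete pairs")
    if (ma <= 0).any() or (au <= 0).any():
        raise ValueError("ratio Bland-Altman requires strictly positive values")
    d = np.log(ma / au)
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1)) if len(d) > 1 else 0.0
    gmr = math.exp(mean_d)
    return AgreementResult(
        n=len(d),
        geometric_mean_ratio=gmr,
        loa_lower=math.exp(mean_d - loa_multiplier * sd_d),
        loa_upper=math.exp(mean_d + loa_multiplier * sd_d),
        percent_lower=100.0 * (1.0 - gmr))


def pain_gradient_association(
    area_fits: Mapping[str, Mapping[str, GradientFit]],
    colour_fits: Mapping[str, GradientFit],
    pain_fits: Mapping[str, GradientFit],
) -> pd.DataFrame:
    """Pairwise Pearson correlations between per-lesion gradient vectors.

    ``area_fits`` maps arm -> {lesion_id -> fit}; colour and pain map
    lesion_id -> fit. Each pair is computed over the lesions present in
    both vectors. Raises (via :func:`pearson`) when fewer than 3 lesions
    overlap.
    """
    vectors: dict[str, dict[str, float]] = {}
    for arm, fits in area_fits.items():
        vectors[f"{arm}_area"] = {k: f.slope for k, f in fits.items()}
    vectors["colour"] = {k: f.slope for k, f in colour_fits.items()}
    vectors["pain"] = {k: f.slope for k, f in pain_fits.items()}

    pairs = [(a, "colour") for a in vectors if a.endswith("_area")]
    pairs += [(a, "pain") for a in vectors if a.endswith("_area")]
    pairs.append(("colour", "pain"))

    rows = []
    for a, b in pairs:
        common = sorted(set(vectors[a]) & set(vectors[b]))
        res = pearson([vectors[a][k] for k in common],
                      [vectors[b][k] for k in common])
        rows.append({"x": a, "y": b, "r": res.r, "p": res.p_value,
                     "n": res.n, "valid": res.valid})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results objects


class HealingTrajectoryModel:
    """Cohort healing-trajectory model over a long-form measurement table.

    Parameters
    ----------
    measurements : DataFrame
        Columns (lesion_id, day, arm, area_mm2) with one row per image and
        arm; missing areas as NaN. Optional column ``delta_e`` (the
        fixed-boundary colour distance to skin; arm-independent, read from
        the manual rows).
    pain : DataFrame, optional
        Columns (lesion_id, day, value) of daily pain scores.
    window_days : int
        Study window for total-change summaries.
    pooling : {"mean_slopes", "mixed"}
        Cohort gradient: unweighted mean of per-lesion OLS slopes
        (default), or the fixed slope of a mixed-effects model with random
        intercept and slope per lesion.
    """

    def __init__(self, measurements: pd.DataFrame, pain: Optional[pd.DataFrame] = None,
                 window_days: int = 30, pooling: str = "mean_slopes",
                 min_points: int = 3):
        required = {"lesion_id", "day", "arm", "area_mm2"}
        if not required.issubset(measurements.columns):
            raise ValueError(f"measurements needs columns {sorted(required)}")
        if pooling not in ("mean_slopes", "mixed"):
            raise ValueError("pooling must be 'mean_slopes' or 'mixed'")
        self.measurements = measurements.copy()
        self.pain = pain.copy() if pain is not None else None
        self.window_days = window_days
        self.pooling = pooling
        self.min_points = min_points

    @classmethod
    def from_measurements(cls, measurements: pd.DataFrame, **kwargs) -> "HealingTrajectoryModel":
        return cls(measurements, **kwargs)

    def _channel_series(self) -> dict[str, dict[str, np.ndarray]]:
        out: dict[str, dict[str, np.ndarray]] = {}
        df = self.measurements
        for arm in sorted(df["arm"].unique()):
            sub = df[(df["arm"] == arm) & df["area_mm2"].notna()]
            out[f"{arm}_area"] = {
                lid: g[["day", "area_mm2"]].to_numpy(dtype=float)
                for lid, g in sub.groupby("lesion_id")}
        if "delta_e" in df.columns:
            sub = df[(df["arm"] == "manual") & df["delta_e"].notna()]
            if sub.empty:  # colour is arm-independent; fall back to any arm
                sub = df[df["delta_e"].notna()].drop_duplicates(["lesion_id", "day"])
            out["colour"] = {
                lid: g[["day", "delta_e"]].to_numpy(dtype=float)
                for lid, g in sub.groupby("lesion_id")}
        if self.pain is not None:
            out["pain"] = {
                lid: g[["day", "value"]].to_numpy(dtype=float)
                for lid, g in self.pain.groupby("lesion_id")}
        return out

    def fit(self) -> "HealingTrajectoryResults":
        fits: dict[str, dict[str, GradientFit]] = {}
        skipped: list[tuple[str, str, int]] = []
        for channel, series in self._channel_series().items():
            fits[channel] = {}
            for lid, arr in series.items():
                if len(arr) < self.min_points:
                    skipped.append((channel, lid, len(arr)))
                    continue
                fits[channel][lid] = fit_gradient(arr, lesion_id=lid, channel=channel)

        mixed = None
        if self.pooling == "mixed":
            mixed = self._fit_mixed()
        return HealingTrajectoryResults(self, fits, skipped, mixed)

    def _fit_mixed(self) -> dict[str, float]:
        import statsmodels.formula.api as smf
        out = {}
        df = self.measurements
        for arm in sorted(df["arm"].unique()):
            sub = df[(df["arm"] == arm) & df["area_mm2"].notna()]
            if sub["lesion_id"].nunique() < 3:
                continue
            md = smf.mixedlm("area_mm2 ~ day", sub, groups=sub["lesion_id"],
                             re_formula="~day")
            try:
                res = md.fit(reml=True, method="lbfgs")
                out[f"{arm}_area"] = float(res.params["day"])
            except Exception:  # singular fits on tiny cohorts
                continue
        return out


@dataclass
class HealingTrajectoryResults:
    """Fitted gradients, cohort summaries and agreement statistics."""

    model: HealingTrajectoryModel
    fits: dict[str, dict[str, GradientFit]]
    skipped: list[tuple[str, str, int]] = field(default_factory=list)
    mixed_slopes: Optional[dict[str, float]] = None

    # -- cohort gradient summaries ------------------------------------

    def mean_gradient(self, channel: str) -> tuple[float, float, int]:
        """Unweighted mean of per-lesion slopes, its SE, and n lesions."""
        slopes = np.array([f.slope for f in self.fits.get(channel, {}).values()])
        if slopes.size == 0:
            return float("nan"), float("nan"), 0
        se = float(slopes.std(ddof=1) / math.sqrt(len(slopes))) if len(slopes) > 1 else float("nan")
        return float(slopes.mean()), se, int(len(slopes))

    def total_change(self, channel: str) -> float:
        mean, _, _ = self.mean_gradient(channel)
        return abs(mean) * self.model.window_days

    def gradients_frame(self) -> pd.DataFrame:
        rows = [{"lesion_id": f.lesion_id, "channel": ch, "slope": f.slope,
                 "intercept": f.intercept, "se": f.slope_se, "n": f.n, "r2": f.r2}
                for ch, d in self.fits.items() for f in d.values()]
        return pd.DataFrame(rows).sort_values(["channel", "lesion_id"]).reset_index(drop=True)

    # -- agreement -----------------------------------------------------

    def _paired_areas(self) -> pd.DataFrame:
        df = self.model.measurements
        wide = df.pivot_table(index=["lesion_id", "day"], columns="arm",
                              values="area_mm2", aggfunc="first")
        return wide.dropna()

    def area_correlation(self) -> AgreementResult:
        wide = self._paired_areas()
        return pearson(wide["manual"], wide["automated"])

    def area_ratio_agreement(self) -> AgreementResult:
        wide = self._paired_areas()
        pos = wide[(wide["manual"] > 0) & (wide["automated"] > 0)]
        return bland_altman_ratio(pos["manual"], pos["automated"])

    def gradient_correlation(self, arm_a: str = "manual", arm_b: str = "automated") -> AgreementResult:
        fa = self.fits.get(f"{arm_a}_area", {})
        fb = self.fits.get(f"{arm_b}_area", {})
        common = sorted(set(fa) & set(fb))
        return pearson([fa[k].slope for k in common], [fb[k].slope for k in common])

    def associations(self) -> pd.DataFrame:
        area = {arm: self.fits[f"{arm}_area"]
                for arm in ("manual", "automated") if f"{arm}_area" in self.fits}
        return pain_gradient_association(
            area, self.fits.get("colour", {}), self.fits.get("pain", {}))

    # -- reporting -----------------------------------------------------

    def baseline_mean_area(self, arm: str) -> tuple[float, float, int]:
        """Mean (sd, n) of day-1 areas for one arm."""
        df = self.model.measurements
        sub = df[(df["arm"] == arm) & (df["day"] == 1) & df["area_mm2"].notna()]
        vals = sub.groupby("lesion_id")["area_mm2"].first()
        if vals.empty:
            return float("nan"), float("nan"), 0
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        return float(vals.mean()), sd, int(len(vals))

    def summary(self) -> str:
        w = self.model.window_days
        lines = ["Healing trajectory summary",
                 "=" * 60]
        for arm in ("manual", "automated"):
            ch = f"{arm}_area"
            if ch not in self.fits:
                continue
            mean, se, n = self.mean_gradient(ch)
            m0, sd0, n0 = self.baseline_mean_area(arm)
            lines.append(f"{arm:>9s} arm: day-1 area {m0:.1f} (s.d. {sd0:.1f}) mm², n={n0}")
            lines.append(f"{'':>9s}      gradient {mean:+.3f} mm²/day (SE {se:.3f}, n={n}); "
                         f"{w}-day change {self.total_change(ch):.1f} mm²")
            if self.mixed_slopes and ch in self.mixed_slopes:
                lines.append(f"{'':>9s}      mixed-model gradient {self.mixed_slopes[ch]:+.3f} mm²/day")
        for ch, label in (("colour", "ΔE/day"), ("pain", "points/day")):
            if ch in self.fits and self.fits[ch]:
                mean, se, n = self.mean_gradient(ch)
                lines.append(f"{ch:>9s}     : gradient {mean:+.4f} {label} (SE {se:.4f}, n={n})")
        try:
            ac = self.area_correlation()
            lines.append(f"paired-area Pearson r = {ac.r:.2f} (n={ac.n}, p={ac.p_value:.2g})")
        except ValueError:
            pass
        try:
            ba = self.area_ratio_agreement()
            lines.append(
                f"ratio Bland–Altman: geometric mean ratio {ba.geometric_mean_ratio:.2f} "
                f"(manual {ba.percent_lower:+.0f}% lower), 95% LoA "
                f"{ba.loa_lower:.3f}–{ba.loa_upper:.2f} (n={ba.n})")
        except ValueError:
            pass
        try:
            gc = self.gradient_correlation()
            lines.append(f"gradient correlation (manual vs automated) r = {gc.r:.2f} (n={gc.n})")
        except (ValueError, KeyError):
            pass
        if self.skipped:
            lines.append(f"{len(self.skipped)} series skipped (<{self.model.min_points} points)")
        return "\n".join(lines)
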