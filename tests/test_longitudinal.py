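"""Gradient fitting, agreement statistics and the trajectory model object."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lesiontrack.longitudinal import (HealingTrajectoryModel, bland_altman_ratio,
                                      fit_gradient, pain_gradient_association,
                                      pearson, total_change)


def _line(days, slope, intercept):
    return [(d, intercept + slope * d) for d in days]


def test_exact_line_recovered():
    fit = fit_gradient(_line(range(1, 31), -0.08, 12.0))
    assert fit.slope == pytest.approx(-0.08)
    assert fit.intercept == pytest.approx(12.0)
    assert fit.r2 == pytest.approx(1.0)
    assert fit.slope_se == pytest.approx(0.0, abs=1e-12)


def test_constant_series_zero_slope_zero_se():
    fit = fit_gradient(_line(range(1, 11), 0.0, 5.0))
    assert fit.slope == 0.0
    assert fit.slope_se == 0.0
    assert fit.r2 == 1.0


def test_too_few_points_refused():
    with pytest.raises(ValueError, match=">= 3 points"):
        fit_gradient([(1, 2.0), (2, 1.9)])


@settings(max_examples=60, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_ols_matches_scipy_linregress(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 40))
    x = np.sort(rng.choice(np.arange(1, 61), size=n, replace=False))
    y = rng.normal(0, 3, n) + rng.uniform(-0.5, 0.5) * x
    fit = fit_gradient(np.column_stack([x, y]))
    ref = sps.linregress(x, y)
    assert fit.slope == pytest.approx(ref.slope, rel=1e-10, abs=1e-12)
    assert fit.intercept == pytest.approx(ref.intercept, rel=1e-10, abs=1e-12)
    assert fit.slope_se == pytest.approx(ref.stderr, rel=1e-8, abs=1e-12)


def test_monte_carlo_slope_recovery():
    rng = np.random.default_rng(123)
    slopes = []
    for _ in range(200):
        days = np.arange(1, 31)
        y = 12.0 - 0.08 * (days - 1) + rng.normal(0, 1.0, 30)
        slopes.append(fit_gradient(np.column_stack([days, y])).slope)
    assert np.mean(slopes) == pytest.approx(-0.08, abs=0.01)


def test_total_change_examples():
    fit = fit_gradient(_line(range(1, 31), -0.08, 12.0))
    assert total_change(fit, 30) == pytest.approx(2.4)
    fit = fit_gradient(_line(range(1, 31), -0.1, 12.0))
    assert total_change(fit, 30) == pytest.approx(3.0)
    fit = fit_gradient(_line(range(1, 31), 0.0, 12.0))
    assert total_change(fit, 30) == 0.0


def test_pearson_examples():
    x = [1.0, 2.0, 3.0, 4.0]
    assert pearson(x, x).r == pytest.approx(1.0)
    assert pearson(x, [-2 * v + 3 for v in x]).r == pytest.approx(-1.0)
    # hand computation for the 5-pair example: deviations dx=(-2,-1,0,1,2),
    # dy=(-1,-2,1,0,2) give sum(dx*dy)=8, sum(dx²)=sum(dy²)=10, r = 8/10
    res = pearson([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
    assert res.r == pytest.approx(0.8)
    assert res.n == 5


def test_pearson_edge_cases():
    with pytest.raises(ValueError):
        pearson([1, 2], [3, 4])
    res = pearson([1, 1, 1], [2, 3, 4])
    assert not res.valid and np.isnan(res.r)
    # pairwise-complete: NaN members dropped
    res = pearson([1, 2, np.nan, 4, 5], [2, 1, 9, 3, 5])
    assert res.n == 4


def test_bland_altman_hand_examples():
    auto = np.array([3.0, 7.0, 1.5, 12.0])
    res = bland_altman_ratio(0.6 * auto, auto)
    assert res.geometric_mean_ratio == pytest.approx(0.6)
    assert res.loa_lower == pytest.approx(0.6)
    assert res.loa_upper == pytest.approx(0.6)
    assert res.percent_lower == pytest.approx(40.0)  # "40% lower"

    res = bland_altman_ratio(auto, auto)
    assert res.geometric_mean_ratio == pytest.approx(1.0)
    assert (res.loa_lower, res.loa_upper) == (pytest.approx(1.0), pytest.approx(1.0))

    # pairs (2,4),(8,4): d = (ln 1/2, ln 2), mean 0, sd = ln2·sqrt(2)
    res = bland_altman_ratio([2.0, 8.0], [4.0, 4.0])
    sd = np.log(2.0) * np.sqrt(2.0)
    assert res.geometric_mean_ratio == pytest.approx(1.0)
    assert res.loa_lower == pytest.approx(np.exp(-1.96 * sd))
    assert res.loa_upper == pytest.approx(np.exp(+1.96 * sd))


def test_bland_altman_arm_swap_inverts_exactly():
    rng = np.random.default_rng(5)
    a = rng.lognormal(1.0, 0.8, 40)
    b = rng.lognormal(1.2, 0.6, 40)
    fwd = bland_altman_ratio(a, b)
    rev = bland_altman_ratio(b, a)
    assert rev.geometric_mean_ratio == pytest.approx(1.0 / fwd.geometric_mean_ratio, rel=1e-12)
    assert rev.loa_lower == pytest.approx(1.0 / fwd.loa_upper, rel=1e-12)
    assert rev.loa_upper == pytest.approx(1.0 / fwd.loa_lower, rel=1e-12)


def test_bland_altman_rejects_nonpositive():
    with pytest.raises(ValueError):
        bland_altman_ratio([1.0, 0.0], [1.0, 1.0])


def _fits(slopes, channel):
    return {f"L{i}": fit_gradient(_line(range(1, 11), s, 10.0),
                                  lesion_id=f"L{i}", channel=channel)
            for i, s in enumerate(slopes)}


def test_association_null_and_exact():
    rng = np.random.default_rng(42)
    area_slopes = rng.normal(-0.08, 0.05, 50)
    pain_slopes = rng.normal(0.0, 0.05, 50)  # independent of area
    table = pain_gradient_association(
        {"manual": _fits(area_slopes, "manual_area")},
        _fits(2.0 * area_slopes, "colour"),
        _fits(pain_slopes, "pain"))
    by_pair = {(r["x"], r["y"]): r for r in table.to_dict(orient="records")}
    assert abs(by_pair[("manual_area", "pain")]["r"]) < 0.3
    assert by_pair[("manual_area", "colour")]["r"] == pytest.approx(1.0)

    with pytest.raises(ValueError):
        pain_gradient_association(
            {"manual": _fits([-0.1], "manual_area")},
            _fits([-0.2], "colour"), _fits([0.0], "pain"))


def _cohort_frame(rng, n_lesions=12, noise=0.3):
    rows = []
    for i in range(n_lesions):
        slope = rng.normal(-0.08, 0.06)
        base = rng.uniform(5, 20)
        for day in range(1, 31):
            truth = max(base + slope * (day - 1), 0.1)
            for arm in ("manual", "automated"):
                rows.append({"lesion_id": f"L{i:02d}", "day": day, "arm": arm,
                             "area_mm2": truth + rng.normal(0, noise)})
    return pd.DataFrame(rows)


def test_trajectory_model_end_to_end():
    rng = np.random.default_rng(11)
    df = _cohort_frame(rng)
    pain = pd.DataFrame([{"lesion_id": f"L{i:02d}", "day": d,
                          "value": rng.integers(0, 11)}
                         for i in range(12) for d in range(1, 31)])
    res = HealingTrajectoryModel(df, pain=pain, window_days=30).fit()
    mean, se, n = res.mean_gradient("manual_area")
    assert n == 12
    assert mean == pytest.approx(-0.08, abs=3 * 0.06 / np.sqrt(12))
    gc = res.gradient_correlation()
    assert gc.r > 0.9  # both arms see the same truth with small noise
    assert "gradient" in res.summary()
    assert set(res.gradients_frame()["channel"]) >= {"manual_area", "automated_area", "pain"}


def test_mixed_effects_pooling_agrees_with_mean_of_slopes():
    rng = np.random.default_rng(3)
    df = _cohort_frame(rng, n_lesions=10, noise=0.2)
    res_mean = HealingTrajectoryModel(df).fit()
    res_mixed = HealingTrajectoryModel(df, pooling="mixed").fit()
    m, _, _ = res_mean.mean_gradient("manual_area")
    assert res_mixed.mixed_slopes["manual_area"] == pytest.approx(m, abs=0.02)
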