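# lesiontrack

Calibrated planimetry and colour tracking for smartphone photographs of
digital (finger) ulcers, the painful skin lesions that affect roughly half
of patients with systemic sclerosis (SSc). Clinical trials in this disease
struggle for an objective outcome measure: clinicians disagree on what
counts as an ulcer and on when one has healed, so trials fall back on
coarse counts at monthly visits. Daily patient-taken photographs with a
known-size reference sticker offer a way out — if the images can be turned
into reliable areas and colour trajectories.

`lesiontrack` implements that measurement pipeline end to end, for
methodologists who want to study its statistical behaviour and for
developers of lesion-monitoring tools who need a tested reference
implementation:

1. **Scale calibration.** Each photograph contains a 6 mm adhesive dot next
   to the lesion. The dot is detected by colour gating and ellipse fitting;
   the scale is `mm_per_px = 6.0 / (2 · major semi-axis)`. Using the
   *major* axis makes the in-plane scale invariant to camera tilt (an
   obliquely viewed circle keeps its true diameter along the major axis),
   and the minor/major axis ratio measures the tilt itself.
2. **Triage.** Images are classified USED / BETTER_IMAGE_CHOSEN / NO_DOT /
   WRONG_ANGLE (axis ratio < 0.75), with one image selected per lesion-day
   and completeness reported as integer percentages of the expected count.
3. **Dual-arm segmentation.** A *manual* arm rasterizes observer-drawn
   boundary polygons; an *automated* arm segments by CIELAB colour distance
   to the skin reference (median colour), Otsu thresholding and
   morphological cleanup, and can return "no lesion detected" — which is
   propagated as missing data, never as zero area.
4. **Measurement.** Areas in mm²; colour as mean L\*a\*b\* inside a *fixed*
   first-image boundary re-projected into every later image via the dot
   (translation + scale), so the tracked region's colour can converge to
   skin as the lesion heals. ΔE is CIE76 (Euclidean in L\*a\*b\*).
5. **Longitudinal analysis.** Per-lesion OLS gradients (area, ΔE, daily
   pain), cohort mean gradients and 30-day totals, Pearson correlations,
   and ratio-scale Bland–Altman agreement: with `d_i = ln(manual/automated)`,
   the geometric mean ratio is `exp(mean d)` and the 95% limits of
   agreement are `exp(mean d ± 1.96 sd d)`.
6. **PROMs.** Daily pain (0–10), weekly 0–100 visual analogue scales, and
   the 24-item HDISS-DU hand-disability questionnaire (items 0–5; codes 6
   and 7 excluded from the mean, score valid when ≥ 12 items are scorable).

Because no patient image set is publicly available, the package ships a
synthetic-scene generator (`lesiontrack.synthesis`) that renders lesion
photo series with full ground truth — healing schedules, dot geometry,
per-day scale/lighting/tilt nuisance, defect processes (missing days,
missing dot, duplicates, wrong angle) and PROM distributions — so every
stage is tested against a known answer.

## Worked example

```python
from lesiontrack import PipelineConfig, run_pipeline

out = run_pipeline(PipelineConfig(seed=2026), "demo_run")
print((out / "report" / "report.txt").read_text())
```

which prints (abridged):

```
Image accounting
  expected 810  returned 830  used 696 (86%)
  BETTER_IMAGE_CHOSEN    72
  NOT_SUBMITTED          58
  NO_DOT                 48
  WRONG_ANGLE            14
...
Healing trajectory summary
============================================================
   manual arm: day-1 area 9.6 (s.d. 7.3) mm², n=26
               gradient -0.068 mm²/day (SE 0.011, n=27); 30-day change 2.0 mm²
automated arm: day-1 area 9.6 (s.d. 7.4) mm², n=26
               gradient -0.077 mm²/day (SE 0.012, n=27); 30-day change 2.3 mm²
   colour     : gradient -0.7269 ΔE/day (SE 0.1310, n=27)
     pain     : gradient -0.0157 points/day (SE 0.0120, n=27)
paired-area Pearson r = 0.99 (n=652, p=0)
ratio Bland–Altman: geometric mean ratio 1.00 (manual -0% lower), 95% LoA 0.979–1.03 (n=651)
gradient correlation (manual vs automated) r = 0.93 (n=27)
```

Reading this: 27 simulated lesions were photographed over 30 days (810
expected images); after triage 696 images were usable (86%). Both
measurement arms recover the cohort's true mean healing gradient of
−0.08 mm²/day to within sampling error, their per-lesion gradients agree
strongly (r = 0.93), and — since both arms here observe the same rendered
truth — the between-arm geometric mean ratio is ≈ 1 with narrow limits.
On real photographs the two arms disagree far more; the machinery for
quantifying that disagreement is exactly what this package provides.

The same pipeline is scriptable stage by stage from the shell:

```bash
lesiontrack run --out demo_run --seed 2026
lesiontrack segment --out demo_run --arm automated
```

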