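# Methods

## The measurement problem

Digital ulcers in systemic sclerosis are small (millimetres to a couple of
centimetres), irregular skin lesions photographed by patients on their own
phones, one or more images per day over a ~30-day episode. Nothing about
the camera, distance or lighting is controlled; the only metric anchor in
each frame is a 6 mm adhesive dot placed next to the lesion. The pipeline
turns such a photo stream into (a) a calibrated daily area per lesion and
measurement arm, (b) a colour trajectory toward healed skin, and (c) the
longitudinal and agreement statistics that decide whether the automated
arm could serve as a trial outcome measure.

## Scale calibration

The dot is found by gating pixels on hue/saturation proximity to the
reference dot colour, labelling connected components, and scoring each
component by (mean colour-match) × (fill ratio against the
moment-matched ellipse). Detection requires the best score to exceed a
confidence threshold (default 0.5, exposed in the detector signature);
below it the image is declared dot-free — a triage category, not an error.
The scale is `mm_per_px = 6.0 / (2 a)` with `a` the fitted major
semi-axis. The major axis is used because a tilted circle projects to an
ellipse whose major axis preserves the true diameter; the minor/major
ratio equals cos(tilt) and is the basis of the wrong-angle rule. A single
circular fiducial cannot constrain in-plane rotation, and no stage infers
rotation from it.

## Triage

Categories: NO_DOT (undetected fiducial), WRONG_ANGLE (axis ratio below
0.75, i.e. tilt beyond ≈ 41° — the threshold is a package choice, exposed
as `angle_ratio_min`, since no angle criterion is published), otherwise a
USED candidate. When a day has several candidates the pipeline keeps the
one with the highest detector confidence (rounded to 2 decimals so that
near-ties fall through), then the highest sharpness (variance of a
Laplacian high-pass response), then the earliest timestamp; the rest
become BETTER_IMAGE_CHOSEN. Completeness percentages are rounded half-up
to integers, matching the usual printed style. Expected counts default to
the full episode length per lesion and are configurable (a withdrawn
participant contributes a shorter expectation).

## Segmentation arms

*Manual*: observer polygons are filled with a half-open, even-odd
rasterization on the pixel-centre lattice; the pixel count agrees with the
shoelace area to within one boundary-pixel band. Self-intersecting
polygons are rejected.

*Automated*: the learned segmenter used in the original feasibility work
is not reproducible (private training images, unreleased weights), so the
automated arm is a fully specified classical segmenter — dot masked out,
image converted to L\*a\*b\*, skin reference = per-channel median of the
non-dot pixels, per-pixel CIE76 ΔE to that reference, Otsu threshold,
morphological opening with a disc of radius 0.2 mm at the image's scale,
largest connected component. No detection is declared when max ΔE < 10 or
the component is smaller than 0.5 mm²; this reproduces the qualitative
failure mode reported for the learned model (misses on very small or
low-contrast lesions) and keeps the dual-arm comparison machinery — the
analysis this package exists for — fully exercisable. The arm interface is
pluggable so a learned model can be dropped in. Undetected measurements
propagate as missing values, never zero.

## Colour tracking

Colour is measured inside the boundary drawn on the first usable image,
held fixed in millimetre coordinates anchored at the dot centre and
re-projected into each later image by translation + scale. A one-pixel
band at the boundary is eroded away before averaging, because those pixels
mix lesion and skin and sub-pixel re-projection error would otherwise leak
skin colour into the mean. The per-image summary is mean L\*, a\*, b\* and
the CIE76 ΔE between that mean and the image's skin reference. The colour
change scalar used downstream is the per-lesion OLS slope of ΔE-to-skin
versus day — a declared stand-in, since no formula-level definition of a
colour trajectory statistic is published. Simpler ΔE (CIE76 rather than
CIEDE2000) is deliberate: only the colour space, not a difference formula,
is specified by the protocol, and CIE76 keeps the statistic transparent.

## Longitudinal statistics

Per-lesion OLS (closed form; ≥ 3 points required, missing days simply
absent, constant series get slope 0 with SE 0 and R² defined as 1). The
cohort gradient is the unweighted mean of per-lesion slopes; a
mixed-effects alternative (random intercept and slope per lesion,
statsmodels MixedLM) is available via `pooling="mixed"` but off by
default, since mean-of-slopes is the transparent reading of "a regression
per participant, then the average gradient". Agreement: Pearson r on
pairwise-complete pairs, and ratio-scale Bland–Altman on the log scale
with 1.96·sd limits (95% limits of agreement). Ratios require strictly
positive areas; pairs with a missing member are dropped.

## PROMs

Ranges enforced per instrument; fractional VAS values are rounded (the
collection app used an integer slider). HDISS-DU scoring: mean of the 24
items over those scored 0–5; codes 6 and 7 counted separately and
excluded; valid iff ≥ 12 items scorable. The instrument's official manual
may handle codes 6/7 differently — the rule here is declared and
configurable (`min_valid_items`). Pain gradients reuse the same OLS
implementation as every other channel.

## The synthetic cohort

The generator's defaults are the study conditions: 27 lesions, 30 days,
log-normal baseline areas with mean 11.6 and s.d. 16.0 mm² (a normal draw
would go negative since s.d. > mean), linear healing at −0.08 mm²/day mean,
a 6 mm dot, and defect rates consistent with the reported image
accounting (≈10% duplicates, ≈5% no-dot, ≈1.5% wrong angle, 7% missing
days) and pain-score completeness (30% missing). Pain draws centre on
5.7 (s.d. ≈ 2.4 from a between/within split of 1.5/1.8), VAS instruments
on 70.7/72.4/66.0 with s.d. ≈ 22, HDISS-DU on 2.2 (0.9) with a −0.3
day-30 shift. Two quantities have no published value and were fixed once
as field-plausible choices: the between-lesion s.d. of healing gradients
(0.06 mm²/day, allowing some lesions to grow) and per-day area noise on
the true schedule (0 — observed noise instead arises from rendering,
annotation jitter and segmentation). The true pain slope is generated
independently of the area slope, consistent with the reported absence of
an area–pain association.

Each lesion is a star-shaped region (ellipse with a low-order radial
sinusoid) fixed in millimetre coordinates at a fixed offset from the dot;
per-day nuisance comprises the mm-per-px scale (0.05–0.15, resampled
daily), lighting gain (0.85–1.15), colour cast (s.d. 4 counts), sensor
noise (s.d. 3 counts) and small tilt (≤ 10°; wrong-angle defects use
48–65°, rendered as a global affine squash so the dot's axis ratio is
cos(tilt)). Lesion colour interpolates linearly in L\*a\*b\* from ulcer
colour to skin colour in proportion to remaining area. Manual annotations
are emulated by tracing the truth mask's contour with 1 px Gaussian vertex
jitter.

What the generator does **not** emulate: photorealistic skin texture,
specular highlights, shadows, depth-of-field, nail/crease structures,
multi-lesion scenes, or colour-constancy failures beyond a global
gain/cast. Passing tests therefore demonstrate that the measurement and
analysis machinery is correct and well-calibrated on scenes whose
geometry and photometry obey the stated model — not that the automated
segmenter would reach the same accuracy on real photographs, where the
published manual/automated discrepancies (ratio limits spanning orders of
magnitude) are driven by exactly the image structure omitted here.

## Numerical choices and degenerate inputs

- Rasterization: half-open pixel-centre rule; vertex coordinates on the
  corner lattice; agreement with the shoelace area bounded by one
  perimeter-pixel band (property-tested on random star polygons).
- The analytic truth area is the healing-schedule value; the rendered
  mask's pixel-count area differs by rasterization quantization and by
  cos(tilt) foreshortening (≤ 1.5% at the default tilt cap), which is why
  measurement-recovery tests compare against the mask-based oracle.
- Fiducial fit: moment-matched ellipse via region properties; sub-pixel
  axis accuracy in practice (3% scale recovery on ≥ 95% of a 200-image
  batch is the tested contract).
- Detector confidence threshold 0.5; hue tolerance 0.10 on the [0,1) hue
  wheel; components under 30 px ignored.
- Determinism: every stochastic step descends from one seed through
  `numpy` SeedSequence spawning; the full pipeline is byte-reproducible
  (hash-compared in tests), and problem sizes (27 lesions × 30 days demo,
  200-image calibration batches, 200-replicate gradient Monte Carlo) were
  chosen so the whole suite runs comfortably on a laptop-class single
  core.

## Known limitations

- Rotation between days is unobservable with a single circular fiducial;
  boundary re-projection is translation + scale only. The generator keeps
  lesion–dot geometry fixed in mm, so this is exact there; on real hands,
  finger rotation would distort the tracked region.
- The wrong-angle rule judges the *dot's* obliquity, not the finger's.
- Areas are projected 2-D areas; curvature of the finger surface is
  ignored by both arms equally.
- The automated arm's accuracy claims are conditional on the synthetic
  scene model (see above).
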