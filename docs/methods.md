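# Methods

## Problem setting and model

The detector consumes 3-channel 8-bit pseudo-color rasters from an MSX
thermal camera (nominally 400 × 300 px). Two physical regularities drive
the design:

- **Color (thermal) cue.** Fruit retains surface heat longer than leaves
  and twigs, so in the warm display palette fruit renders orange with a
  dominant red channel, while the canopy background renders cool. Bare
  soil, however, stays fruit-warm: color separates fruit from canopy but
  not from soil.
- **Texture cue.** The MSX edge-embossing makes fruit surfaces smooth and
  soil/background surfaces rough. In GLCM terms, soil regions show much
  higher contrast (deep texture grooves) and a more concentrated
  co-occurrence distribution — hence *lower* entropy, because a rough
  two-tone surface plus the constant dark surround occupies few matrix
  cells, whereas a smoothly shaded fruit spreads mass along a wide
  diagonal band.

The pipeline therefore segments warm regions by color, then rejects warm
non-fruit regions by texture with a linear max-margin classifier.

## Pipeline stages and parameter defaults

| Parameter | Default | Notes |
|---|---|---|
| `disk_radius` | 3 px | opening structuring element (Euclidean disk); chosen for 400 × 300 scale, config-exposed |
| `small_area_fraction` | 0.1 | keep components strictly larger than this fraction of the largest component |
| `connectivity` | 8 | component connectivity; 4 available |
| `glcm_levels` | 16 | uniform bins of [0, 255]; keeps matrices populated for small regions |
| `glcm_distance` | 2 px | co-occurrence offset length |
| `glcm_angles` | 0/45/90/135° | diagonal offsets are (±2, ±2), not unit-normalized |
| `feature_set` | contrast, entropy | correlation computed and reported but excluded from the default feature vector |
| `entropy_log_base` | 2 | bits; base e available (rescales, never reorders) |
| `bright_foreground` | true | binarization polarity `pixel > t`; flip for palettes with dark targets |

Stage-specific conventions:

- **Otsu.** Between-class variance over the full 256-bin histogram; ties
  broken toward the lowest maximizing threshold. A constant image is
  degenerate: the threshold is the constant itself, the mask empty, and a
  warning flag is set.
- **Opening.** The discrete disk is the set of integer offsets with
  Euclidean norm ≤ radius. Out-of-image pixels count as foreground during
  erosion, so border-touching regions are retained (fruit at the image
  edge are valid targets). Radius 0 is the identity.
- **Small-area removal.** Strict comparison (`area > fraction × A_max`):
  a component of exactly the cutoff area is removed.
- **Region labels** are assigned in raster-scan order of each component's
  first pixel, which makes label maps reproducible across runs and
  implementations.
- **GLCM.** Matrices are symmetrized (both pair orderings counted) and
  normalized to sum 1. Zero-valued background pixels inside the bounding
  rectangle participate in pair counting — the minimal rectangle itself is
  the mitigation for constant areas; a masked-pair mode
  (`glcm_masked_pairs`) restricts counting to in-region endpoints. A
  region admitting no valid pixel pair in some configured direction is
  degenerate: its features are (0, 0, 0) with a flag, and classification
  assigns it to the non-fruit class without evaluating the model.
  Correlation of a zero-variance marginal is defined as 0.
- **Classifier.** Sign convention −1 = fruit, +1 = non-fruit, kept as-is
  from the field convention it implements. The max-margin separator is fit
  as a soft-margin SVM with a large fixed penalty (C = 1e4, tolerance
  1e-8): hard-margin behaviour on separable data (every training point
  satisfies y(ω·x̃+b) ≥ 1 − 1e-6), graceful degradation otherwise.
  Features are standardized to zero mean / unit spread before
  optimization — contrast and entropy differ by an order of magnitude —
  and the affine parameters are stored in the model, making predictions
  invariant to affine rescaling of the raw features. sign(0) maps to −1
  (fruit), a measure-zero tie-break. A constant training feature would
  have zero spread; its scale is set to 1 so the stored scaling stays
  invertible.
- **Evaluation.** The four counts S_ic, S_il, S_oo, S_oc partition the
  image, and RS + RE = 1 + S_oo/(S_ic+S_il) holds as an algebraic
  identity. Per-region scoring attributes every predicted pixel to a
  manual region — its own if inside one, otherwise the nearest by
  Euclidean distance (ties to the lower region id) — and reports
  unweighted arithmetic means per stratum; image-level pooling
  (`eval_pooling="image"`) merges counts per image before forming ratios.
  RP of an empty prediction is 0 with a flag. Manual regions below a
  16-px floor are skipped: a human annotator does not delineate a
  few-pixel sliver, and ratio metrics on such slivers are noise.
  Non-target fruit (occluded fraction > 0.6) are excluded from the
  stratified report, and the generator returns their visible pixels so
  callers can remove them from predictions before scoring.

## Synthetic scenes

The generator emulates the *statistical appearance* of MSX orchard
images, not their thermal physics: the fruit-vs-background temperature
contrast enters only as the color contrast it produces. A scene (default
400 × 300) contains:

- 2–10 elliptical fruit (semi-axes 14–32 px), red channel shaded radially
  from ~240 at the center to ~178 at the rim plus smooth low-frequency
  noise — low GLCM contrast, broad diagonal co-occurrence support;
- a rough, cool background (red 45–70 base with ±22 blocky texture at
  3-px correlation), far below the fruit's red range so Otsu separates
  them cleanly;
- dark branch-like strips (width 3–7 px) occluding randomly chosen fruit;
- one soil confounder: an ellipse placed clear of the canopy fruit whose
  red channel alternates per-pixel between two warm tones (136 / 248,
  chosen at quantization-bin centers so pixel noise does not smear them
  across bins) — fruit-like color, but high contrast and low entropy;
- global Gaussian pixel noise (σ = 2), clipped to [0, 255].

Annotations follow the field protocol: *incomplete* iff any occlusion or
fruit-fruit overlap; *non-target* iff more than 60% occluded. Everything
is deterministic given the seed.

What the generator does **not** model — and what passing tests therefore
do not show about real data: palette nonlinearity and camera optics,
within-fruit thermal gradients from uneven sunlight (real fruit rims can
drop below threshold), leaves at intermediate temperatures, motion blur,
and scene-to-scene lighting drift. On these synthetic scenes the two
texture features separate fruit from soil linearly by construction; the
tests validate the machinery end to end, not field-condition accuracy.

## Problem sizes

The end-to-end experiment (tests and `scripts/acceptance.py`) trains on
100 generated scenes (~750 labeled regions) and evaluates on 50 held-out
scenes (~280 scored regions); oracle-equivalence checks use 50–500
random instances each. These sizes give stable stratum means while
keeping a full run in tens of seconds on one CPU.

## Known limitations

- The Otsu threshold assumes a bimodal red-channel histogram; scenes that
  are all-warm or all-cool degrade to the degenerate path.
- Heavily occluded fruit fragment into small regions; pieces below one
  tenth of the largest component are lost before classification, which is
  the main sensitivity cost in the incomplete stratum.
- The published procedure does not include trained coefficients, so only
  the training *procedure* is reproducible, not a specific ω*, b*.
- The small-area cutoff compares integer areas against a float product;
  for pathological fraction values a component sitting exactly on a
  float-rounded boundary could be mis-kept. With the default 0.1 and
  realistic areas this does not arise.
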