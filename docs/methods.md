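# Methods

## Scope and data model

`chromahr` analyzes 1 Hz *trends* of facial color during ramped exercise,
not beat-level pulse waveforms: every statistic downstream of patch
averaging operates on per-second series. The core objects are the frame
(`FrameImage`, H×W×3 on the 8-bit scale), the per-model channel triplet at
1 Hz (`ColorSignalSet`), the per-second heart-rate series with the
participant's age (`HRSeries`), and the aligned regression rows
(`DesignTable`).

Two age-predicted maxima coexist by design and are used in different
places: the ramp protocol terminates at 85% of 208 − 0.7·age (this bounds
the synthetic heart-rate generator), while the regression target maxHR% is
HR·100/(220 − age) (the conventional definition for intensity
percentages). They are deliberately not interchangeable.

## Synthetic recordings

The generator emulates a submaximal ramp test under fluorescent lighting.

* **Heart rate.** A linear trend from `initial_hr` to the 85% ceiling over
  the scenario duration, plus AR(1) jitter (coefficient 0.9, innovation sd
  1 bpm — the scale of beat-to-beat variability after 1 Hz averaging),
  clipped at the ceiling. The first sample is anchored at `initial_hr`.
* **Color coupling.** Each ground-truth channel is
  baseline_c + coupling_c·maxHR%(t) + N(0, noise_sd). The defaults —
  baseline (185, 135, 115), coupling (−0.35, +0.25, +0.10) 8-bit units per
  percentage point — encode a modest redness/brightness shift over a
  40-point intensity range, a few 8-bit units per channel. No published
  per-bpm color magnitudes exist, so these are free parameters chosen once
  as a realistic effect size; they sum to zero so that chromaticity
  normalization preserves each channel's trend direction (the sign of
  d/dm[(b_c + k_c·m)/(S + K·m)] is k_c·S − b_c·K, which reduces to the
  sign of k_c when K = Σk = 0).
* **Rendering.** The face is a flat-shaded ellipse (height 0.5·H, width
  0.78·height, horizontally centered) with dark eye/brow/mouth blobs below
  the forehead — enough structure for a boosted frontal-face cascade, not
  a photorealistic skin render. The forehead region is painted uniformly
  with that second's ground-truth color, so its mean is exact before
  corruption; frame metadata records the true face box, forehead
  rectangle, and blur flag.
* **Corruptions.** (i) Multiplicative sinusoidal flicker. A 100 Hz lamp
  ripple sampled at exactly 25 Hz would alias to 0 Hz (a constant), so the
  model uses the ~1 Hz beat of a slightly detuned lamp (e.g. 50.5 Hz mains
  → 101 Hz ripple against a 25 Hz shutter); with a full cycle per second,
  the within-second CV of brightness is amplitude/√2 exactly, and 1 Hz
  block averaging cancels most of it. (ii) Per-pixel Gaussian sensor noise
  (sd `noise_sd`, shared with the signal-level noise parameter). (iii) A
  seeded fraction of frames convolved with a 9-pixel horizontal
  linear-motion kernel.

What the generator does **not** emulate: pulse-synchronous sub-second
color oscillation, head pose changes and tracking drift, specular
highlights, skin-tone diversity, and compression artifacts. Passing tests
therefore demonstrate that the pipeline is a faithful, sign- and
scale-preserving measurement chain under controlled corruption — not that
the physiological effect is recoverable from any given real recording.

All randomness flows from `scenario.seed` through independent
`numpy` substreams (keyed `[seed, k]`), so identical scenarios are
bit-identical.

## Pipeline choices

* **Blur screening.** "Sharpness" defaults to the variance of the
  Laplacian of the grayscale frame (the standard focus measure); raw pixel
  variance is available by config since the statistic is a free choice.
  The default threshold (100) is scene-dependent and exposed; on flat
  synthetic scenes sharp frames sit near it, which is harmless because
  Wiener restoration of an unblurred flat region is near-identity. The
  deconvolution (scikit-image's Wiener–Hunt) runs per channel; by default
  only flagged frames are deblurred (`deblur: always`/`off` available).
* **Face localization.** A boosted LBP frontal-face cascade; the largest
  detection wins, ties broken topmost-then-leftmost. Detection runs every
  `detect_interval` frames (default 25, i.e., once per second) with the
  last box held in between — head position changes slowly relative to the
  1 Hz analysis cadence, and per-frame detection adds cost but no
  information. A missed detection reuses the held box (logged); a video
  with no detectable face requires a manual box. Boxes are 0-based,
  half-open.
* **Forehead patch.** Default center (0.5, 0.18) of the 400×400 crop,
  size 16: just above the brow line of a frontal crop, on the lower
  forehead. The production path samples the patch directly from the frame
  by the same bilinear map as crop-then-extract (verified equivalent to
  machine precision in tests) to avoid materializing the full crop.
* **Color conversions.** Conversions consume the chromaticity image —
  normalization precedes conversion, so brightness is removed before any
  model change; the RGB model is chromaticity ×255. Pinned standards: hexcone HSV (H reported in degrees), BT.601
  YCbCr (8-bit studio offset, chroma centered at 128), BT.601 YUV, Lab via
  sRGB→XYZ (D65). Black pixels normalize to the neutral (1/3, 1/3, 1/3)
  sentinel. Channel names are model-qualified (`Lab.b`, `YUV.V`) to avoid
  collisions.
* **Smoothing.** Median window 201 samples with reflection padding of 40
  samples at each end; the remaining half-window shortfall is filled by
  replicating the outermost reflected value. Signals shorter than the
  window shrink it to the largest odd fit (logged). The moving average is
  causal as defined, with a mirror-reflected prefix so length is
  preserved; its window defaults to 21 s (≈10% of the median window — the
  "small" window is otherwise unspecified). Min-max normalization maps
  constant vectors to 0.5.
* **Degenerate inputs** never crash: black frames → neutral chromaticity;
  constant series → identity smoothing, 0.5 normalization, ADF reported
  stationary with a note; constant or collinear predictors → a rank error
  naming the offending column; perfect collinearity → infinite VIF with a
  warning.

## Statistical layer

* The lag-1 autoregression is OLS of y(t) on [1, y(t−1), CR₁(t−1),
  CR₂(t−1), CR₃(t−1)]; the "wn·CRn" term is a sum over the three channels.
  Standard errors come from σ²(XᵀX)⁻¹. In-sample RMSE is reported (no
  train/test split is defined for this design); a holdout is a caller
  decision, not a default.
* The dependent variable is maxHR% on its natural percent scale; a config
  switch (`normalize_y`) min-max normalizes it instead, which is the scale
  on which per-participant RMSEs of a few tenths arise (versus a few
  percent-points on the natural scale). Both conventions appear in the
  rPPG literature; the package supports both rather than adjudicating.
* The universal model expands the three channels to all polynomial terms
  up to total degree 3 (19 terms) and fits ridge-regularized least squares
  with a vanishing penalty (α = 1e−6) — deterministic and exactly
  reproducible; `estimator: svr` swaps in an epsilon-insensitive linear
  loss (ε = 0.1, C = 1) on the same expansion. The F statistic uses
  df = (p_terms, n − p_terms − 1) with p_terms the number of non-intercept
  terms actually fitted; under a linear-in-channels reading (degree 1)
  this reduces to (3, n − 4).
* ADF: regression with constant, lag order by AIC up to the conventional
  ⌊12·(n/100)^¼⌋ cap; "stationary" means rejection of the unit-root null
  at α (default 0.05).
* VIF_j = 1/(1 − R²_j) from regressing channel j on the other two with
  intercept; the per-channel p-value is the univariate slope p-value
  against y when y is supplied, else the auxiliary regression's F p-value.
* End-to-end coupling recovery is judged by *univariate* slope signs of
  maxHR% on each extracted RGB channel: the three channels are driven by
  the same ramp and are nearly collinear, so multiple-regression
  coefficient signs are not identified and would be meaningless as a
  recovery criterion.

## Problem sizes and numerics

The test suite and acceptance script use desk-scale problems chosen as the
smallest sizes at which each property is statistically sharp: 360 s of
360×640 video for the rendered end-to-end check (and 180 s in the
acceptance script), n = 600 with 100 seeds for coefficient recovery,
n = 500 with 50 seeds for ADF size/power, and the nine reference
participants' actual ramp durations (480–960 s, pooled n ≈ 6300) for the
cohort study. Identity checks against the rendered path use the 8-bit
quantized ground truth as oracle, since the renderer stores uint8 frames.

## Known limitations

Detection-based extraction assumes a frontal, roughly stationary face; no
tracking or landmarking is attempted. Chromaticity normalization discards
brightness by construction, so V/L/Y channels of the normalized image
carry chromaticity information rather than luminance. Video container
reading depends on an imageio plugin being present; PNG frame directories
are the always-available interchange format. The SVR estimator's solver
is iterative and slower than ridge on pooled cohort sizes.
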