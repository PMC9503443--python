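# chromahr

Contactless exercise-intensity monitoring from facial video. During a
ramped cycling test, rising heart rate changes facial blood perfusion and
hence facial skin color; `chromahr` extracts that color trend from video
of the rider's face and regresses exercise intensity on it, with no
contact sensor beyond the reference heart-rate strap used to fit the
models.

The package is aimed at sports-science and remote-photoplethysmography
(rPPG) researchers who want the full chain — video preprocessing, face and
forehead localization, color-model signal extraction, smoothing, and the
statistical models — as reusable, tested components, plus a synthetic
recording generator so every stage can be validated with known ground
truth.

## Method

For each frame: screen for motion blur (variance of the Laplacian below a
threshold) and restore flagged frames by Wiener–Hunt deconvolution with a
linear-motion PSF; denoise with a small Gaussian kernel; detect the face
with a boosted frontal-face cascade; crop and resize it to 400×400; take a
16×16 patch on the lower forehead. Each patch pixel is chromaticity
normalized,

    I_norm[i,j,c] = I[i,j,c] / Σ_c I[i,j,c],   Σ_c I_norm[i,j,c] = 1,

which cancels multiplicative brightness variation (e.g., mains-lamp
flicker). The normalized patch is converted to five color models (RGB,
HSV, YCbCr, Lab, YUV) and spatially averaged per channel,

    ȳ_c = (1 / M·N) Σ_m Σ_n y_c(m, n),

giving one sample per channel per frame, which is block-averaged from
25 Hz to 1 Hz. Each 1 Hz channel series is smoothed by a 201-point median
filter (reflection padding) followed by a short causal moving average

    y(n) = (1/WS) · [x(n) + x(n−1) + … + x(n−WS+1)],

then min-max normalized to [0, 1].

Exercise intensity is the percentage of age-predicted maximum heart rate,
maxHR% = HR·100/(220 − age). Two model families are fit:

* **personalized**, a lag-1 multivariate autoregression per participant
  and color model,

      HR(t) = a1 + w1·HR(t−1) + Σ_n w_n·CR_n(t−1) + e(t),

  with the three channels CR_n as lagged exogenous predictors, fit by OLS
  after augmented Dickey–Fuller stationarity screening; and
* **universal**, a pooled regression of maxHR% on all polynomial terms of
  the three channels up to total degree 3, ridge-regularized by default
  (an epsilon-insensitive SVR loss is available by config).

Reported diagnostics: RMSE, R², the overall F statistic with its degrees
of freedom and p-value, and per-channel variance inflation factors
VIF_j = 1/(1 − R²_j).

The synthetic module emulates the study protocol: a heart-rate ramp that
saturates at 85% of the protocol maximum (208 − 0.7·age), per-channel
color signals coupled linearly to maxHR%, and rendered frames carrying a
cascade-detectable synthetic face, with configurable lamp flicker, sensor
noise, and motion blur. All randomness derives from the scenario seed.

## Worked example

```bash
printf 'duration: 120\n' > demo_scenario.yaml
chromahr simulate --scenario demo_scenario.yaml --seed 5 --out demo
chromahr extract demo/frames --out demo/signals.csv --log demo/frames.log.csv
printf 'participants:\n- {id: S1, age: 25, signals: demo/signals.csv, hr: demo/hr.csv}\n' > demo/meta.yaml
chromahr fit --meta demo/meta.yaml --out demo/fits
chromahr evaluate --scenario demo_scenario.yaml --seed 5 --out demo/eval.json
```

`evaluate` runs the whole chain in memory against ground truth and prints,
for this 120 s scenario:

```
sign match: True; RMSE ratio (RGB): 0.91
```

meaning the sign of every fitted channel–intensity relationship matches
the scenario's coupling (after chromaticity normalization), and the pooled
degree-3 model loses essentially nothing by going through rendered video
rather than the unrendered ground-truth signals (ratio 1 = lossless;
values up to 2 indicate moderate pipeline noise). `demo/fits/` contains
the participant × color-model RMSE matrix (`ar_rmse_matrix.csv`) and, for
multi-participant runs, `universal_report.json` with per-model RMSE, R²,
F, coefficients, and VIFs.

The same can be driven from Python:

```python
import chromahr as ch

scen = ch.SyntheticScenario(duration=180, seed=5)
summary = ch.run_end_to_end(scen)
print(summary["rmse_ratio"]["RGB"], summary["sign_match"])
```

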