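# rppgkit

Contactless heart-rate (HR) estimation from facial video via remote
photoplethysmography (rPPG). The pipeline extracts the forehead region of
interest with an 81-point facial-landmark schema (68 base points + 13
forehead-extension points), spatially averages the ROI colors per frame,
conditions the R/G/B traces in overlapping 30 s windows (1 s slide), and
reads the pulse out with the chrominance (CHROM) projection

```
X(t) = 3 R(t) - 2 G(t)
Y(t) = 1.5 R(t) + G(t) - 1.5 B(t)
rPPG(t) = X(t) - mu * Y(t),   mu = std(X) / std(Y)
```

followed by an FFT peak search restricted to 0.7–4 Hz (42–240 bpm):
`HR = 60 * f_peak`.

A synthetic pulsatile-video generator with known ground-truth HR makes the
whole chain verifiable without human subjects, and an evaluation module
scores estimates with the |error| < 3 bpm accuracy criterion.

## Modules

| module           | purpose                                               |
|------------------|-------------------------------------------------------|
| `synthetic_data` | pulsatile RGB traces & rendered videos with ground truth |
| `video_io`       | frame sources (lossless TIFF stacks, imageio containers, cameras) |
| `face_roi`       | face detection, 81-point landmarks, forehead mask (fixture / dlib / mediapipe backends) |
| `enhancement`    | optional low-light double-plateau histogram equalization (cuckoo-search plateau selection) |
| `traces`         | per-frame ROI color averaging, 30 s / 1 s sliding windows |
| `preprocess`     | detrend, max-abs normalization, moving-average smoothing, 3rd-order 0.7–4 Hz band-pass |
| `pulse`          | CHROM projection and spectral HR estimation           |
| `evaluation`     | accuracy / MAE / RMSE scoring against ground truth    |
| `pipeline` + `cli` | end-to-end orchestration and the `rppg` command     |

## CLI

Generate a synthetic recording (lossless TIFF video + `gt.csv` ground
truth + `roi.json` declared ROI):

```sh
rppg synth --hr 72 --duration 60 --out rec/
```

Run the pipeline on it and evaluate against the ground truth:

```sh
rppg run --source rec/video.tiff --roi-json rec/roi.json \
         --truth rec/gt.csv --out run/
rppg eval --estimates run/estimates.csv --truth rec/gt.csv --tol 3
```

Real-face usage: `rppg run --source clip.mp4 --backend dlib
--model-path shape_predictor_81_face_landmarks.dat`. Low-light
enhancement is off by default; enable with `--enhance`.

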