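# skelquant

Movement quantification from 2D pose keypoint sequences. From per-frame
BODY_25 keypoint detections (OpenPose JSON dialect or a flat CSV), the
pipeline computes 11 per-frame skeleton parameters (shoulder/hip/thigh
angles and lengths, trunk angle), extracts 33 per-recording features
(lag-1 autocorrelation of the original and the differenced series plus a
windowed averaged variance, per parameter), and compares paired
before/after cohorts with two-tailed paired t tests.

Because no clinical recordings are distributable, a synthetic-motion module
generates seated-subject keypoint streams with controllable movement
amplitude (stationary AR(1) jitter), temporal persistence, sinusoidal
trunk sway, hip swivel, and detection dropout — enough to exercise and
calibrate every stage end to end.

## Layout

| module | role |
|---|---|
| `skelquant.keypoints_io` | read/write OpenPose-dialect JSON and flat keypoint CSV; person selection; trimming and gap interpolation |
| `skelquant.skeleton_geometry` | the 11 per-frame parameters and their per-recording time series |
| `skelquant.timeseries_features` | differencing, lag-τ autocorrelation, averaged variance, 33-feature assembly |
| `skelquant.cohort_stats` | paired t tests, mean±SD summaries, significance stars, Holm-adjusted extension column |
| `skelquant.synthetic_motion` | seated-posture simulator and paired-cohort generator |
| `skelquant.pipeline` | thin glue composing the stages programmatically |
| `skelquant.cli` | `skelquant simulate | extract | features | compare` |

## CLI

```bash
# 1. simulate a paired cohort (CSV keypoints + ground-truth manifest)
skelquant simulate --out sim/ --seed 1 --n-subjects 3 --frames 600

# 2. keypoints -> 11-parameter series CSV (per recording)
skelquant extract --input sim/subj_001_before.csv --format csv \
    --subject subj_001 --session before --out params_before.csv

# 3. parameter CSV -> 33-feature CSV (window size is required knowledge: W=30 default)
skelquant features --params params_before.csv --out features_before.csv --window 30

# 4. paired comparison tables (+ optional boxplots)
skelquant compare --before features_before.csv --after features_after.csv \
    --out-dir report/ --plots
```

`simulate` also accepts a YAML config (`--config cohort.yaml`):

```yaml
n_subjects: 25
seed: 1
before: {T: 3000, ar_coefficient: 0.95, jitter_sd: 3.0, sway_amplitude: 4.0, swivel_amplitude_deg: 3.0}
after:  {T: 3000, ar_coefficient: 0.7,  jitter_sd: 1.5, sway_amplitude: 1.0, swivel_amplitude_deg: 1.0}
```

## Conventions and caveats

- Image coordinates are kept raw (origin top-left, y down, pixels); no
  axis flip or pixel-to-metric calibration. Lengths are therefore
  camera-geometry dependent across subjects.
- Segment angles are |arctan(slope)| in [0, 90]°; vertical segments map to
  exactly 90°. The trunk angle folds the signed arctangent into [0, 180)°.
- The autocorrelation estimator is the Pearson correlation of the
  overlapping lagged pairs, each sub-series centred by its own mean; the
  classical stationary estimator is available via
  `AnalysisConfig(acf_estimator="stationary")`.
- Averaged variance uses consecutive non-overlapping windows (population
  denominator); trailing remainder frames are discarded. The window size W
  defaults to 30 frames (~1 s at clinic frame rates) and is recorded in a
  sidecar metadata file next to every feature CSV.
- A constant parameter series has undefined autocorrelation: the feature is
  recorded as missing (NaN) with a warning, and cohort comparisons drop the
  incomplete pair for that column, reporting the effective n.
- No multiple-testing correction is applied to the primary p-values; a
  Holm-adjusted column is emitted alongside as a labelled extension.
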