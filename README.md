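# gaitpath

Stride-by-stride foot-trajectory estimation and spatial gait-feature
analysis from shank-worn IMUs (tri-axial accelerometer + gyroscope at
100 Hz), together with a ground-truthed synthetic gait generator that lets
the whole pipeline be exercised and validated end to end without any
recorded data.

## What it does

1. **`synthetic_gait`** — simulates back-and-forth corridor walking for
   participants drawn from four group profiles (mild PD, advanced PD,
   healthy older, healthy young). World-frame ankle kinematics are built
   from piecewise-polynomial stride models (closed forms, C² joins) and
   rendered into sensor-frame IMU signals with configurable noise, bias
   and heel-strike transients. Every session carries a full ground-truth
   record (per-stride parameters, event times, turn flags, analytic
   features).
2. **`imu_io`** — data model and canonical CSV dialect for IMU sessions
   (`time_s,ax,ay,az,gx,gy,gz`, SI units, one file per leg) plus session
   validation.
3. **`trajectory_estimation`** — heel-strike detection from the sagittal
   gyro spike, stride segmentation, gravity-based orientation
   initialization at the quietest in-stance instant, strapdown orientation
   propagation, and drift-cancelling forward/backward weighted double
   integration under zero-endpoint constraints. Produces per-stride 3-D
   ankle trajectories in a stride-local (forward, lateral, vertical) frame.
4. **`gait_features`** — in-stride events (toe-off, maximum clearance,
   change of supporting leg) and the six spatial features F1–F3 (forward)
   and V1–V3 (vertical); protocol stride selection (drop first/last five
   strides per leg and direction-change strides, keep 20 per leg);
   aggregation to a participant-level feature table.
5. **`group_stats`** — one-way ANOVA, Shaffer sequentially rejective
   pairwise post hocs, PCA (correlation matrix, loadings as
   component–variable correlations), and Horn-style parallel analysis.
6. **`discrimination`** — soft-margin kernel SVM (RBF by default) with
   stratified 10-fold cross-validation over group pairs and feature sets
   (all six features, first two principal components, single vertical
   variables), confusion matrices, ROC/AUC, and decision-boundary grids.
7. **`cli_pipeline`** — a `gaitpath` command that chains everything from a
   single JSON config, with manifests for reproducibility.

## CLI

```bash
gaitpath run-all --out out/                     # full pipeline, defaults
gaitpath simulate --config config.json --out out/
gaitpath estimate --config config.json --sessions out/sessions --out out/
gaitpath features --config config.json --sessions out/sessions --out out/
gaitpath analyze  --table out/feature_table.csv --out out/
gaitpath classify --table out/feature_table.csv --out out/
```

The config is a JSON document validated against a schema; every omitted
field is materialized with its default into `manifest_<stage>.json`, so a
run is fully self-describing. Exit codes: 0 ok, 2 usage/config error,
3 data error.

## Conventions worth knowing

* Sensor frame: x forward, y up, z sagittal (gyro z = pitch rate);
  world frame: x forward, y lateral, z up; gravity 9.80665 m/s².
* Stride identity is heel strike → next ipsilateral heel strike; the
  integration anchor is the minimum-|pitch-rate| sample inside the
  [5 %, 50 %] stride window; `segmentation="midstance"` is available as a
  config alternative.
* Vertical displacements are referenced to the stride's mid-stance
  (foot-flat) level by default (`vertical_reference="onset"` restores the
  literal heel-strike reference; see the `gait_features` docstring for
  why the default differs).
* Event-detection conventions (toe-off method, support-change definition)
  are config enums and are recorded in every output.
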