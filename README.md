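# kidmotion

A toolkit for validating a wrist-worn IMU against optical motion capture
on cyclic arm movements, built around a fully synthetic study design so
every stage is testable offline:

- **`kidmotion.synthetic`** — closed-form simulator of paired recordings:
  sinusoidal trajectories (horizontal, vertical, elliptical, figure-eight
  as a 1:2 Lissajous) sampled at 200 Hz; optical positions with Gaussian
  noise; a device-frame accelerometer stream containing gravity, expressed
  in an arbitrary sensor orientation, with its own noise and an unknown
  integer lag relative to the optical stream.
- **`kidmotion.preprocess`** — zero-phase 2nd-order Butterworth low-pass
  (6 Hz default), quaternion device-to-world rotation with gravity
  removal, double differentiation of marker positions, magnitude channel.
- **`kidmotion.sync_segment`** — cross-correlation lag estimation on the
  magnitude channel (non-negative integer lags), trimming to a common
  length, cycle segmentation at event markers, and time normalization
  into 10 within-bin means per cycle.
- **`kidmotion.agreement`** — intraclass correlations from a two-way
  crossed ANOVA: consistency `(MSR − MSE)/MSR` and absolute agreement
  `(MSR − MSE)/(MSR + (MSC − MSE)/n)`, with F tests against ICC = 0 and
  Bonferroni adjustment.
- **`kidmotion.classification`** — one-vs-one linear SVM under structured
  10-fold nested cross-validation (each fold holds exactly one cycle per
  participant per movement type), cross-modality cross-classification,
  and label-permutation significance testing.
- **`kidmotion.pipeline_io`** — CSV dialects for raw and intermediate
  data, strict YAML configuration, the end-to-end runner, and the CLI.

## CLI

```sh
kidmotion simulate --seed 1 --participants 20 --out-dir data/
kidmotion preprocess --data-dir data/ --out-dir cycles/
kidmotion agree    --cycles-dir cycles/ --out icc.json
kidmotion classify --cycles-dir cycles/ --source cross --n-perm 100 --out cls.json
kidmotion run      --seed 1 --n-perm 0 --out-dir results/   # end-to-end
```

All commands accept `--config <yaml>` (see `kidmotion.pipeline_io.config`
for the block structure and defaults) and `--seed`. Exit codes:
0 success, 1 input error, 2 internal error.

## Conventions and documented choices

- World frame: x mediolateral, y anteroposterior, z vertical; gravity
  acts along −z; a resting accelerometer reads +9.81 m/s² on world z,
  and that constant is subtracted after rotation.
- Quaternions are Hamilton, scalar-first `(w, x, y, z)`, device-to-world.
- Positions are filtered before double differentiation; IMU data are
  rotated, gravity-compensated, then filtered.
- Time bins are within-bin means (not interpolation knots); the magnitude
  channel is binned after the norm, so binned Am is not the norm of the
  binned axes.
- Permutation p-values use the add-one rule, so the smallest attainable
  p with 100 permutations is 1/101.
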