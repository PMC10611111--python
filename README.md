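# coordgait

Instrumented gait analysis for coordination-phenotype classification.
From raw tri-axial IMU recordings of a gait test and a tandem-gait test
(six body-worn sensors at 256 Hz), the pipeline

1. **simulates** synthetic multi-sensor cohorts with known ground-truth gait
   events and group-graded cycle-to-cycle variability (`coordgait.cohort`),
2. **preprocesses** signals: axis standardization, device synchronization,
   block-average decimation (factor 16 ≈ two extra bits for white noise) and
   a zero-phase 0.5–5 Hz fourth-order Butterworth band-pass
   (`coordgait.preprocess`),
3. **segments** gait cycles from the shank mediolateral angular velocity:
   mid-swing peaks with toe-off/heel-strike valleys inside 0.5 s windows,
   heel-strike→heel-strike cycles for gait and toe-off→toe-off for tandem
   gait, with an automated quality gate (`coordgait.segmentation`),
4. **extracts 36 features** per "combined movement" row (24 gait + 12
   tandem): spatiotemporal measures, segment-pitch and hip
   flexion–extension ranges from complementary-filter fusion, DTW
   distance-to-mean-cycle variability, 3-D angular-velocity curvature,
   normalized jerk, and trunk regularity/symmetry (`coordgait.features`),
5. **classifies** participants into EOA / DCD / CTRL with
   leave-one-participant-out cross-validation repeated over iterations,
   per-fold ADASYN oversampling, a 300-tree Gini random forest, per-
   participant majority voting and mean-decrease-impurity importances
   (`coordgait.classify`),
6. **evaluates** confusion matrices: one-vs-rest and pooled-positive
   precision/recall/F1, specificity, balanced accuracy
   (`coordgait.metrics`).

## CLI

```sh
coordgait simulate --preset default --seed 1 --out runs/cohort
coordgait segment  --cohort runs/cohort --out runs/seg
coordgait extract  --cohort runs/cohort --seed 1 --out runs/features
coordgait classify --features runs/features/features.csv \
                   --iterations 100 --seed 1 --out runs/clf
coordgait evaluate                      # bundled reference confusion matrix
coordgait all --preset recovery --sizes 12,10,14 --iterations 10 \
              --seed 1 --out runs/full
```

Presets: `default` (18/13/29 participants, variability ordered
EOA > DCD > CTRL), `recovery` (groups differ only in waveform jitter
3×/2×/1× and hip-range offsets), `null` (identical parameters across
groups), `degenerate` (noise/jitter-free). Stage parameters (filter band,
decimation factor, segment lengths, tree count, …) live in a flat YAML
config (`coordgait.config.RunConfig`) and can be overridden by flags.

Cohorts are written as one CSV per sensor per test
(`t_s, ax_g, ay_g, az_g, gx_dps, gy_dps, gz_dps`), a manifest CSV and a
ground-truth JSON per participant.

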