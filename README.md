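# gaitid — markerless gait analysis and person re-identification

`gaitid` identifies people by how they walk. Starting from 3D body-joint
time series — the output of a markerless vision pipeline (OpenPose 2D
keypoints lifted to 3D by a pose-lifting network), or the package's own
synthetic walker — it:

1. **extracts gait cycles** from the inter-ankle distance signal
   d_t = ‖S_t(3) − S_t(8)‖ (right minus left ankle): after cubic-spline
   interpolation (×5) and moving-average smoothing (M = 12), its local
   maxima are the instants of maximal foot separation (initial contact /
   terminal stance), found with a sliding slope-sign window (N = 7); a full
   cycle spans the pattern max–min–max–min–max and receives eight phase
   timestamps t_a … t_h;
2. **computes a 26-value gait-feature catalogue** per cycle: knee-flexion
   extremes and phase-anchored vertex angles ∡(p₁, p₂, p₃), leg
   inclinations against the world-vertical ray S̄_t = S_t + [0, 0, H],
   cycle-averaged segment lengths relative to the upper body (the 3D
   coordinates are unitless), left/right strides, and foot-dominance
   periods;
3. **identifies individuals two ways**:
   * *feature arm* — ensemble classifiers on the feature table
     (random forest: 750 trees, 6 features per split; XGBoost: depth 3,
     300 rounds; LightGBM: multiclass, 200 iterations), with class
     separability Ψ = tr(Σ_inter) − tr(Σ_intra) and per-method feature
     importance;
   * *spatiotemporal arm* — a Manhattan-distance Siamese LSTM: each cycle
     becomes a sequence Λ_t of the six lower-body joint positions
     (root-centered, 18 values per step), twin encoders with a shared
     18-dimensional hidden state score a pair as exp(−‖h_a − h_b‖₁),
     trained with MSE loss and Adam.

A parametric multi-subject walking simulator (subject-specific limb
proportions, stride length, cadence, joint-angle waveforms, additive joint
noise) makes every stage testable without any dataset download.

Intended users: researchers in gait biometrics, rehabilitation science and
video surveillance who want a reproducible, dataset-free reference pipeline
for skeleton-based re-identification.

## Worked example

```python
from gaitid.cycles import extract_cycles
from gaitid.features import compute_features
from gaitid.synthetic import WalkerParams, generate_walk

params = WalkerParams(stride_len=1.1, cadence=1.0, seed=1)
seq, events = generate_walk(params, n_strides=8, fps=25.0)
cycles = extract_cycles(seq)
print(len(cycles))                     # 8  — matches events.n_cycles
fv = compute_features(cycles[0])
print(round(fv["left_stride"], 3))     # 1.095 — generator stride was 1.1
print(round(fv["min_Rdegree"], 1))     # 124.4 — peak right-knee flexion angle
```

The extractor recovers all 8 simulated cycles; the stride estimate lands
within 0.5% of the generator parameter; the minimum right-knee vertex angle
(124.4°, i.e. ~56° of flexion) reflects the 55° flexion amplitude driving
the synthetic leg.

Each `examples/*.py` script is a self-contained narrative of one
capability (simulation and cycle extraction, the feature catalogue,
ensemble identification, Siamese verification, OpenPose conversion).
The same functionality is scriptable from the shell via the `gaitid` CLI
(`gaitid simulate | extract | features | classify | siamese | convert`).

## Layout

```
src/gaitid/
  skeleton.py    keypoint types, OpenPose JSON parsing, COCO->H3.6M
                 conversion, coordinate normalization, CSV I/O
  cycles.py      ankle-distance signal, interpolation, smoothing,
                 extrema detection, cycle segmentation
  features.py    the per-cycle gait-feature catalogue
  classify.py    scatter-matrix separability, ensemble classifiers
  siamese.py     Lambda sequences, pair sampling, numpy Siamese LSTM
  synthetic.py   parametric multi-subject gait simulator
  cli.py         thin command-line layer over the library
docs/methods.md  models, assumptions, parameter choices, limitations
```
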