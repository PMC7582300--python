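# ectopy

Discriminate premature atrial/ventricular contractions (PAC/PVC) from atrial
fibrillation (AF) and normal sinus rhythm (NSR) in 30-second windows of
beat-to-beat heart-rate data, as derived from wearable photoplethysmography
(PPG).

The method maps every beat triple to a point in a difference plane
(`x` = current→next HR change, `y` = previous→current HR change), partitions
the plane into nine quadrants (a central ±5 BPM "zero" square, four arms and
four corners inside a ±80 BPM field), and mines the resulting quadrant
trajectory for the periodic signatures of ectopy: upward kites `1-2-3`,
downward kites `6-4-5` and bigeminy edges `2-4`/`4-2`. Repeated patterns
whose vector angles cluster tightly (standard deviation ≤ 10°) indicate
PAC/PVC; dispersed trajectories with a low zero-quadrant ratio or many
points outside the cross demarcation indicate AF; quiet trajectories are
NSR. Two decision trees cover windows routed as AF or non-AF by an upstream
detector (the routing bit is a pluggable input; a naive irregularity stub is
bundled and clearly marked in each decision's `rule_fired` trace).

A seeded synthetic generator produces NSR, AF and bigeminy/trigeminy/
quadrigeminy beat sequences (plus optional rendered PPG waveforms) so that
the whole pipeline is testable without clinical recordings, and an
evaluation harness provides one-vs-rest confusion counts, the five standard
metrics, and one-at-a-time threshold sweeps.

## Layout

| module              | contents                                                                  |
| ------------------- | ------------------------------------------------------------------------- |
| `ectopy.signal_io`  | CSV/WFDB input, resampling, 30-s windowing, peak detection, HR series     |
| `ectopy.poincare`   | nine-quadrant geometry, difference points, trajectories, rzero/noutside   |
| `ectopy.patterns`   | kite/edge mining, slope & included angles, angle SDs, feature extraction  |
| `ectopy.classifier` | the AF-window and non-AF-window decision trees, recording orchestration   |
| `ectopy.synthetic`  | rhythm specs, presets for the six published trajectory rows, PPG renderer |
| `ectopy.evaluation` | confusion counts, metrics, threshold sweeps                               |

## CLI

```sh
# generate 90 s of normal-HR trigeminy beats (sidecar JSON holds the spec)
ectopy simulate --rhythm "trigeminy normal" --duration 90 --seed 1 --out beats.csv

# classify each 30-s window (peaks CSV or --format ppg waveform CSV)
ectopy classify --input beats.csv --out decisions.csv

# compare predictions against ground truth
ectopy evaluate --pred decisions.csv --truth truth.csv --out metrics.json

# sweep one threshold on a synthetic cohort
ectopy sweep --param std_angle_max --values 2,5,10,15 --out sweep.csv
```

Thresholds are configurable via `--config thresholds.yaml` with keys matching
`ClassifierConfig` fields (`std_angle_max`, `rzero_af`, `rzero_nsr`,
`outside_min_af`, `min_kites`, `min_bigeminy_pairs`,
`min_edge_pairs_exclusive`, `min_beats`); unknown keys are rejected.

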