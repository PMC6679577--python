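# cprtutor

Multimodal chest-compression (CPR training) quality assessment: parse
multimodal sensor sessions, segment them into individual chest compressions,
label each compression against resuscitation-guideline performance
indicators, build fixed-shape feature tensors, and train/evaluate recurrent
classifiers. A synthetic session simulator with controllable mistake
injection provides ground-truthed data.

## Modules

| Module | Purpose |
| --- | --- |
| `cprtutor.mlt_io` | Read/write MLT session archives (JSON sensor + annotation recordings) and time-align recordings via offsets. |
| `cprtutor.simulate` | Generate synthetic sessions (Kinect-style 15-joint skeleton at 30 Hz, Myo-style 8-channel EMG + IMU at 100 Hz) with known per-compression ground truth, plus a manikin emulator deriving depth/rate/release measurements from the displacement trace. |
| `cprtutor.labeling` | Map measurements to mistake classes: rate and depth are ternary (below/within/above the guideline interval, bounds inclusive), release is binary (residual ≤ 5 mm by default). |
| `cprtutor.preprocessing` | Interval table, consolidated sparse attribute table (sanitised names, deduplication, zero-running-total and joint-exclusion pruning), half-open interval masking, fixed-size bin-mean resampling (default S=8) and min–max scaled N×S×Q tensor assembly. |
| `cprtutor.model` | Numpy LSTM sequence classifier (single hidden layer, default 128 units, dense softmax head, sparse categorical cross-entropy, Adam), train/test splitting, training history, overfit-epoch detection and evaluation (accuracy, loss, ROC-AUC for binary targets, confusion matrix). |
| `cprtutor.pipeline` | End-to-end seeded runs: simulate → label → preprocess → train → evaluate, with summary statistics, class distributions and a reproducibility manifest. |

The LSTM is implemented directly on numpy (forward pass, backpropagation
through time) so no deep-learning framework is required; gradients are
verified against numerical differentiation in the test suite.

## CLI

```sh
cprtutor simulate --rate 110 --depth 55 --release 2 --duration 120 --seed 7 -o session_dir/
cprtutor inspect session_dir/
cprtutor label --session session_dir/ -o labeled.json
cprtutor prep --session session_dir/ --bins 8 --exclude Ankle,Hip,Head -o tensor
cprtutor train --tensor tensor --intervals tensor.intervals.csv --target classRate --epochs 30 -o report.json
cprtutor run config.yaml
```

An example `config.yaml` for a full run:

```yaml
cohort:
  - {rate_cpm: 90,  depth_mm: 45, release_mm: 2}
  - {rate_cpm: 110, depth_mm: 55, release_mm: 2}
  - {rate_cpm: 130, depth_mm: 65, release_mm: 10}
repetitions: 2
targets: [classRate, classDepth, classRelease, armsLocked, bodyWeight]
seed: 7
output_dir: out/
```

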