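# ttstroke

Table-tennis stroke analysis from multi-node wearable inertial
sensors: stream segmentation, stroke recognition with a
multi-dimensional feature-fusion CNN, and per-node action-quality
assessment for auxiliary training.

Amateur players have no coach to point at the body part that ruins a
stroke.  A set of `d` 9-axis inertial nodes (accelerometer, gyroscope,
magnetometer — wrist, upper arm, chest, thigh, calf by default)
records a practice session as a continuous `T x 9d` stream; `ttstroke`
turns that stream into, per stroke:

* the recognized stroke class (forehand stroke, fast push, smash,
  loop, backhand push) with an **overall similarity score** — the
  maximum of the classifier's softmax output
  `y_i = exp(x_i) / Σ_k exp(x_k)`;
* a **per-node cosine similarity** between the stroke's learned
  features and a per-class *standard action model*, with the weakest
  nodes flagged — the spot a trainee should work on.

The pieces, in pipeline order:

1. **Segmentation** — three-layer windowing over the wrist synthetic
   acceleration `|a| = sqrt(ax²+ay²+az²)`: a sliding buffer, a
   detection window that fires when 10 consecutive frames exceed
   `μ₀ + 3σ₀` above the rest baseline, and a 60-frame action window.
   Each stroke is condensed to a canonical **36-frame keyframe window**
   — 18 frames either side of the hitting moment (the wrist
   acceleration peak).
2. **MDFF-CNN** — an Inception-style block mixing a 1-D temporal
   branch (5×1 kernels along the frame axis), a 2-D 3×3 branch, a 1×1
   branch and a pooled branch, with 1×1 reductions and a trailing 3×3
   channel reduction; trunk convolution, global average pooling,
   softmax head.  Trained with Adam, batches of 64, 60 epochs,
   learning rate 0.01 decayed ×0.1 every 20 epochs.
3. **Assessment** — per class, node features cut from the block's
   channel-summed abstract map are embedded (t-SNE, 3-D), clustered
   (K-means, K = node count), matched to nodes, and averaged into
   per-node standard feature vectors; new strokes are scored by cosine
   similarity against them.
4. **Baselines** — handcrafted time/frequency features → PCA (0.9
   retained variance) → KNN / SVM / Gaussian naive Bayes / random
   forest, and plain-CNN / naive-Inception comparators, for the
   comparisons the learned pipeline is judged against.

No public multi-node table-tennis IMU corpus exists, so the package
ships a **synthetic-data generator** (`ttstroke.synth`) that emulates
the study design: 5 stroke classes with wrist-dominant Hann-envelope
bursts, kinetic-chain timing, per-subject sensor-mount/amplitude/tempo
variation, professional vs amateur variability, and per-node
corruption with ground truth — every experiment below runs end to end
on it.

## Worked example

The `ttstroke` CLI chains the stages; every command is deterministic
given `--seed`:

```bash
ttstroke simulate --seed 5 --out-dir run    # synthetic streams + manifest
ttstroke segment  --seed 5 --out-dir run    # streams -> 36-frame keyframes
ttstroke train    --seed 5 --out-dir run    # train the MDFF-CNN
ttstroke evaluate --seed 5 --out-dir run    # macro-F1 + confusion matrices
ttstroke assess run/stream_amateur_test_c1_s0.tsv --seed 5 --out-dir run
```

which prints (seed 5, the bundled default study size):

```
{"simulate": {"streams": 150, "strokes": 1100}}
{"segment": {"windows": 1100}}
{"train": {"final_train_loss": 0.0017156738865282167, "final_val_accuracy": 1.0}}
{"evaluate": {"major_test": 1.0, "amateur_test": 0.9744994793990778}}
{"assess": {"strokes": 5}}
```

Reading the numbers: all 1100 simulated strokes were recovered by
segmentation; the trained network recognizes strokes of two held-out
professional players at macro-F1 1.0 and of eight amateurs at 0.974;
the assessed amateur fast-push session yields 5 per-stroke reports.
The first row of `run/assessment_report.tsv` (rounded):

```
stroke  predicted_class  overall_score  node0 .. node4 similarity        flagged_nodes
0       1                0.951          0.910 0.843 0.816 0.896 0.883    1,2
```

— a fast push with high overall similarity whose upper-arm and chest
nodes score lowest and are flagged; the generator's ground truth
(`run/ground_truth.tsv`) confirms this stroke was synthesized with
wrong local movements at exactly nodes 1 and 2.  Library access gives
the same objects programmatically (`generate_dataset`,
`segment_stream`, `build_model`, `train`, `assess`; see
`docs/methods.md` for the science).

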