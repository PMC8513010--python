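# Methods

## Problem and data model

`ttstroke` analyses table-tennis strokes captured by `d` wearable
9-axis inertial nodes (tri-axial accelerometer `a`, gyroscope `w`,
magnetometer `h`), sampled at `fs = 30` Hz.  One synchronized time step
of all nodes is the observation vector

    S(t) = [N_1(t), N_2(t), ..., N_d(t)],      N_k(t) ∈ R^9,

and `T` consecutive steps form the `T x 9d` action matrix `M`.
Labelled action matrices, one per stroke, make up the per-class sets
`A = {M_1 ... M_i}` and the full corpus `A* = {A_1 ... A_j}` with
`j = 5` stroke classes (forehand stroke, fast push, smash/"speedo",
loop, backhand push).  The default node placement is right wrist,
right upper arm, chest, right thigh, right calf; the wrist must be
node 0 because segmentation watches it.

The pipeline has four stages: (1) segment a continuous stream into
36-frame keyframe windows; (2) classify the stroke with a
multi-dimensional feature-fusion CNN (MDFF-CNN); (3) score the whole
action by its softmax confidence; (4) score each node by cosine
similarity against a per-class *standard action model* built by
clustering the network's abstract features.

## Segmentation and keyframe extraction

A stroke lasts 1–2 s ("two processes, three moments": rise to the
hitting moment, then decay to rest), i.e. 30–60 frames at 30 Hz.  The
segmentation signal is the wrist *synthetic acceleration*
`|a| = sqrt(ax² + ay² + az²)`, which is insensitive to sensor
orientation.

Three windows ride on the stream:

* **sliding window** (`L = 90` frames): the first-layer buffer;
* **detection window** (10 frames) at its tail: a split point fires at
  the earliest frame `s` such that all 10 frames from `s` exceed
  `μ₀ + k·σ₀`, where `(μ₀, σ₀)` are the rest-phase mean and standard
  deviation of the wrist magnitude estimated from the first 30 frames
  and `k = 3.0`.  Requiring a full run of supra-threshold frames makes
  a false trigger at rest essentially impossible
  (`P ≈ 0.00135¹⁰` for Gaussian noise), while a genuine stroke crosses
  within a few frames of onset;
* **action window** (`W = 60` frames) capturing the stroke from the
  split point.  While it fills, the detector is refractory, so each
  stroke fires once.

The *hitting moment* is the argmax of the wrist synthetic acceleration
inside the action window (earliest row on ties).  The keyframe excerpt
is rows `[p−18, p+18)` — 18 frames strictly before the hitting moment
and 18 from it on, exactly 36 rows.  When the peak sits within 18
frames of a window edge the missing rows are filled by edge
replication; discarding such strokes would silently bias the data, and
replication preserves the fixed shape the network requires.  The
36-frame rule condenses the 30–60-frame window to the segment around
the peak that carries most of the action's signature.

Tunables (`SegmenterConfig`): window lengths (frames), baseline length
(frames), trigger multiplier `k`.  Defaults above; only the 36-frame
keyframe length is fixed.

## The MDFF-CNN

A keyframe window is treated as a single-channel `36 x C` image
(`C = 9d`, or `6d` when the magnetometer is excluded).  The fusion
block runs four parallel branches, all stride-1 and "same"-padded so
the `36 x C` extent survives:

1. `1x1` convolution (6 filters);
2. `1x1` reduction (3) → `5x1` temporal convolution (6) — the 1-D
   branch, convolving along the 36-frame axis only;
3. `1x1` reduction (3) → `3x3` convolution (6) — the 2-D branch;
4. `3x3` max-pool (stride 1) → `1x1` convolution (6).

The branch outputs concatenate to 24 channels and a trailing `3x3`
convolution reduces them to 8 — this reduction replaces the classical
`1x1` post-concatenation projection so the model stays small as blocks
cascade.  The trunk is one `3x3` convolution (32 filters) with ReLU,
batch normalization and `2x2` max-pooling, followed by global average
pooling and a final fully connected softmax layer.  Global average
pooling, not flattening, feeds the classifier head, so the parameter
count is independent of `C`.

Filter counts are design choices, sized so the network trains in
minutes on one CPU core while keeping the defining property that the
fused model has *fewer* parameters than a naive Inception block of
matched branch widths (4,601 vs 5,961 at `C = 45`): the 1-D branch
replaces a `5x5` kernel and the trailing reduction shrinks the trunk
input.  Comparators: a plain three-layer `3x3` conv/pool CNN and a
single naive Inception block (`1x1`/`3x3`/`5x5` + passthrough pool, no
reductions), both with the identical trunk and head.

**Input regularization.**  Each keyframe window is regularized
individually: every column has its within-window mean subtracted,
which removes gravity, the earth-field baseline, and whatever constant
offset the sensor's mounting on a particular body adds.  Columns are
then scaled by one shared standard deviation per sensor *type*
(accelerometer / gyroscope / magnetometer), fitted on the training
split.  A per-type rather than per-column scale equalizes physical
units without erasing the relative burst energy across nodes — that
energy profile is class- and node-informative, and it is invariant to
how a sensor happens to be strapped on.  (Per-column standardization
was rejected: it whitens every column to unit variance, which erases
the node-energy signature the assessment stage depends on.)

**Training protocol** (`TrainConfig` defaults): mini-batches of 64,
softmax cross-entropy, Adam, 60 epochs, initial learning rate 0.01
decayed by ×0.1 every 20 epochs.  Weights are updated only on the
training split; per-epoch train loss, validation loss and validation
accuracy are recorded.  All initialization and shuffling derive from
explicit seeds, so a run is bit-reproducible.

The network itself is implemented on a small NumPy layer stack
(`ttstroke.nn`): stride-1 "same" convolution evaluated as a sum of
per-offset GEMMs in channels-last layout, max-pooling with argmax
routing, batch normalization, global average pooling, Adam.  Gradients
are exact (checked against central differences in double precision).

## Action assessment

**Overall score.**  The softmax output
`y_i = exp(x_i) / Σ_k exp(x_k)` is read as a similarity distribution
over stroke classes; the argmax is the recognized stroke and the
maximum probability is the similarity of the whole action to that
stroke's standard form.

**Standard action models.**  Per class, every training keyframe is
pushed through the trained fusion block; the block's output channels
are summed element-wise into one `36 x C` *abstract feature map*
(the block preserves shape, so column blocks still correspond to
nodes).  Each node's columns, flattened (`36 x 9 = 324` values), give
one node-feature vector per action.  All vectors of the class are
embedded to 3-D with t-SNE (seeded; perplexity 30, capped at
`(n−1)/3` for small sets) and clustered with K-means, `K = d`.
Clusters are matched to true node identities by maximum-agreement
bijective assignment (Hungarian algorithm on the contingency table),
and the per-node centroid is the mean of the matched cluster's members
**in the original 324-dimensional space**.

t-SNE cannot embed unseen points, so clustering happens in the
embedding while centroids live — and new actions are scored — in the
original feature space.  This is the one place the construction is
under-determined by its description: scoring in the original space is
our resolution, chosen so that assessment of a new stroke is
well-defined without re-running the embedding.

**Fine-grained score.**  A new action's node features are compared to
the predicted class's centroids by cosine similarity
`u·v / (|u||v|) ∈ [−1, 1]` (scale-invariant, so a weaker but correctly
shaped movement is not punished).  The report flags the two
lowest-scoring nodes plus every node under a threshold `τ = 0.8`
(configurable; the threshold has no empirical calibration — it marks
"clearly dissimilar" on a scale where matched training actions score
near 1).

## The synthetic-data generator

No usable multi-node table-tennis IMU corpus is public, so the
generator produces the study conditions end to end.  What it emulates:

* **Rest baseline**: gravity (9.81 m/s² along a per-node axis) on the
  accelerometer, zero-mean gyro, a shared earth magnetic field
  (~46 arbitrary units) with a slow 0.2 Hz sinusoidal drift; white
  Gaussian noise per channel (accelerometer 0.3 m/s², gyro
  0.12 rad/s, magnetometer 0.5 units at the default noise level).
* **Strokes**: a Hann-envelope acceleration burst along a
  class-specific direction, peaking at the hitting moment; the wrist
  amplitude (16–30 m/s² by class) is strictly the largest across
  nodes, with trunk/leg nodes at 25–35 % of it.  A gyro oscillation
  burst rides the same envelope, with a node-specific carrier
  frequency (7 Hz wrist snap down to 1 Hz calf sway) phase-locked to
  the burst peak — the oscillation is part of the stroke's motor
  program, not of wall-clock time.  A class-specific magnetometer
  deflection stands in for paddle-face orientation.  Proximal
  segments burst earlier and shorter than the wrist (kinetic-chain
  sequencing, up to 0.26 s lead at the calf).
* **Class structure**: five classes with distinct directions,
  amplitudes, gyro factors and characteristic tempos (1.1–1.8 s
  mid-durations, jitter inside the 1–2 s band).  Classes 2 and 3
  (smash and loop) are deliberate near-twins on the accelerometer and
  gyroscope, separable mainly through the magnetometer deflection —
  this is what gives the 9-axis / 6-axis comparison content.
* **Subjects**: the study design uses disjoint people per split
  (10 professionals shared by train/val, 2 held-out professionals for
  the major test, 8 amateurs).  Each subject carries fixed per-node
  sensor-mount rotations (10° std), an amplitude factor (15 % std),
  a tempo factor (8 % std) and a small personal phase style.  Subject
  mount variation is what makes *raw* node features smear across
  people while the regularized network features stay clean — the
  mechanism behind the learned-vs-raw clustering contrast.
* **Amateur behaviour**: a variability multiplier (default 2×) on all
  per-stroke jitters, plus per-node corruption (default probability
  0.15 per non-wrist node): the corrupted node executes a different
  class's local movement — the "wrong local action" the fine-grained
  assessment should catch.
* **Ground truth** per stroke: class, the first frame the noiseless
  wrist profile detectably leaves baseline (exceeds 3× the nominal
  accelerometer noise floor — below that no detector could see it),
  the noiseless-profile peak frame, stroke end, subject id, corrupted
  nodes.

What it does **not** emulate: biomechanically consistent limb
kinematics (bursts are parametric envelopes, not simulated joints),
quaternion-consistent orientation dynamics, sensor error models
(bias instability, scale factor, magnetic disturbances), ball impact
transients, fatigue or learning effects within a session.  Passing
tests therefore demonstrate that the pipeline's machinery — windowing,
learning, clustering, scoring — behaves as designed under controlled
stroke-structured input; they do not certify recognition accuracy on
real athletes.

Default study size: 100 training actions per class, 40 per class for
validation and each test split (the split ratio mirrors a 7:3
train/validation division).  These sizes keep a full three-seed
training comparison within minutes on one CPU core while leaving the
per-class clustering with 500 node-feature points.

## Numerical choices

* Ties in every argmax (hitting moment, overall score) break to the
  earliest index, for determinism.
* Cross-entropy is computed in double precision on shifted logits;
  network arithmetic is float32.
* Cosine similarity of two zero vectors is an error (undefined), one
  zero vector scores 0.
* K-means uses 10 restarts with a fixed seed; an empty cluster (never
  observed with `n_init=10`) would trigger up to 5 reseeded retries.
* t-SNE uses PCA initialization and a fixed random state; on tiny
  point sets exact duplicates have no local geometry, so fixtures add
  small jitter.
* PCA for the baseline arm keeps the smallest component count whose
  cumulative explained variance reaches 0.9, after per-feature
  standardization fitted on the training split.
* Stream files store floats with 17 significant digits so a written
  stream reads back bit-exactly.

## Known limitations

* The assessment scores have no external calibration: they are
  similarities to a synthetic "standard", not validated expert
  ratings, and the flag threshold is a design constant.
* t-SNE + K-means standard-model construction is fragile below ~50
  points per node; the defaults provide 100.
* Edge-replication padding slightly flattens the temporal texture of
  keyframes whose peak sits near a window boundary.
* The plain NumPy training loop is single-threaded BLAS-bound; it is
  sized for the bundled study, not for large corpora.
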