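"""Synthetic multi-node 9-axis inertial stroke generator.

No public table-tennis IMU corpus matches the multi-node setup this
package targets, so the generator emulates the structure real strokes
have: a quiescent baseline (gravity on the accelerometer, near-zero
gyro, a slowly drifting earth-field magnetometer), then a stroke whose
wrist acceleration rises to a single peak at the hitting moment and
decays back to rest ("two processes, three moments"), repeated with
rest gaps in between.

Five stroke classes mirror the basic table-tennis repertoire
(forehand stroke, fast push, "speedo" smash, loop, backhand push).
Each class/node pair has a fixed template: a Hann-envelope acceleration
burst along a class-specific direction, a gyro oscillation burst whose
frequency is node-specific (the wrist snaps fast, the calf barely
rotates), and a class-specific magnetometer deflection standing in for
paddle-face orientation.  The two smash-like classes (2 and 3) are
deliberately near-twins on the accelerometer and gyroscope and differ
mostly in the magnetometer deflection, which is what real forehand
topspin variants look like and what makes the 9-axis/6-axis comparison
meaningful.

Professional-like data are drawn at unit variability; amateur-like data
scale amplitude/direction/timing jitter by a multiplier and may corrupt
individual nodes (the template of a different class is substituted --
the "wrong local movement" a coach would flag).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    ActionMatrix,
    CHANNELS_PER_NODE,
    DEFAULT_FS,
    DEFAULT_NODE_COUNT,
    EmptyInputError,
    LabeledDataset,
    SPLITS,
)

CLASS_NAMES = ("forehand_stroke", "fast_push", "speedo", "loop", "backhand_push")

GRAVITY = 9.81

# Per-node scaling of burst energy: the wrist dominates, the trunk and
# legs move little during a stroke.  Node 0 (wrist) must stay strictly
# highest; segmentation and keyframe extraction rely on it.
_NODE_SCALE = np.array([1.0, 0.55, 0.30, 0.35, 0.25])

# Peak wrist acceleration per class (m/s^2 above gravity).
_CLASS_ACC = np.array([22.0, 16.0, 30.0, 28.0, 18.0])

# Class-typical stroke tempo (seconds): a fast push is short, a loop is
# long.  Repeat-to-repeat jitter around it scales with variability and
# always stays inside the 1-2 s band strokes occupy.
_CLASS_DUR = np.array([1.50, 1.10, 1.35, 1.80, 1.20])
_DUR_JITTER = 0.15  # half-width at unit variability, seconds

# Acceleration burst directions: azimuth/elevation per class, with a
# small fixed per-node offset.  Classes 2 and 3 are close on purpose.
_ACC_AZ = np.array([0.30, 1.20, 0.55, 0.60, -1.00])
_ACC_EL = np.array([0.40, 0.15, 0.60, 0.55, 0.25])

# Gyro burst: wrist amplitude per class (rad/s), node-specific carrier
# frequency (Hz) and a class factor.  Body segments rotate at clearly
# different rates (wrist snap ~7 Hz down to calf sway ~1 Hz) and about
# nearly unrelated axes, so the per-node direction offsets are large.
_CLASS_GYR = np.array([9.0, 6.0, 12.0, 11.0, 7.0])
_NODE_FREQ = np.array([7.0, 4.4, 2.8, 1.7, 1.0])
_CLASS_FREQ_FACTOR = np.array([1.0, 1.15, 0.85, 0.90, 1.10])
_GYR_AZ = np.array([-0.50, 0.80, 1.40, 1.30, 2.20])
_GYR_EL = np.array([0.10, -0.30, 0.35, 0.30, -0.15])

# Kinetic-chain sequencing: force transfers leg -> trunk -> arm -> wrist,
# so proximal segments peak earlier than the wrist (seconds of lead).
_NODE_LEAD_S = np.array([0.0, 0.06, 0.13, 0.20, 0.26])

# Magnetometer: one shared earth field (arbitrary units ~ uT, same
# mounting convention on every segment), slow sinusoidal drift, and a
# class-specific deflection during the stroke (paddle-face orientation
# surrogate).  Classes 2 and 3 separate clearly HERE, not on accel/gyro.
_EARTH_FIELD = np.array([30.0, -5.0, -35.0])
_MAG_DEFL = np.array([8.0, 5.0, 12.0, 10.0, 6.0])
_MAG_AZ = np.array([0.20, 1.00, 2.30, -1.90, -0.70])
_MAG_EL = np.array([0.30, -0.20, 0.50, -0.40, 0.10])
_MAG_DRIFT_AMP = 1.5
_MAG_DRIFT_FREQ = 0.2  # Hz

# Nominal per-channel white-noise standard deviations at sigma_noise=1.
_NOISE_ACC = 0.30
_NOISE_GYR = 0.12
_NOISE_MAG = 0.50

# A stroke has detectably left the rest baseline once the noiseless wrist
# synthetic acceleration deviates by more than 3x the nominal noise floor;
# below that the onset is unobservable in principle.  Ground-truth split
# points use this fixed detectability threshold.
_ONSET_EPS = 3.0 * _NOISE_ACC


def _unit(az: float, el: float) -> np.ndarray:
    """Unit vector from azimuth/elevation; elevation > 0 gives +z."""
    return np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )


def _small_rotation(rng: np.random.Generator, std_rad: float) -> np.ndarray:
    """Random rotation with axis uniform on the sphere, angle ~ N(0, std)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.normal(0.0, std_rad)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


@dataclass(frozen=True)
class StrokeTemplate:
    """Deterministic per-class generation parameters for all ``d`` nodes."""

    class_id: int
    acc_amp: np.ndarray        # (d,) peak synthetic-acceleration amplitude
    acc_dir: np.ndarray        # (d, 3) unit burst directions
    gyr_amp: np.ndarray        # (d,)
    gyr_freq: np.ndarray       # (d,) Hz
    gyr_phase: np.ndarray      # (d,)
    gyr_dir: np.ndarray        # (d, 3)
    mag_defl: np.ndarray       # (d, 3) stroke-time magnetometer deflection
    mag_base: np.ndarray       # (d, 3) rest-state magnetometer baseline
    gravity_dir: np.ndarray    # (d, 3) unit gravity direction per node
    duration_range: tuple[float, float] = (1.0, 2.0)  # seconds

    def __post_init__(self) -> None:
        if not np.all(self.acc_amp[0] > self.acc_amp[1:]):
            raise ValueError("wrist (node 0) amplitude must be strictly highest")


def make_template(class_id: int, d: int = DEFAULT_NODE_COUNT) -> StrokeTemplate:
    """Build the fixed template of one stroke class for ``d`` nodes."""
    if not 0 <= class_id < len(CLASS_NAMES):
        raise ValueError(f"class_id {class_id} outside [0, {len(CLASS_NAMES)})")
    scale = _NODE_SCALE[np.arange(d) % len(_NODE_SCALE)].copy()
    # keep node 0 strictly dominant even if d > 5 recycles scales
    if d > 1:
        scale[1:] = np.minimum(scale[1:], 0.9)
    nodes = np.arange(d)
    # large per-node direction offsets: different limbs move differently
    acc_dir = np.stack([_unit(_ACC_AZ[class_id] + 0.70 * n, _ACC_EL[class_id] + 0.25 * n) for n in nodes])
    gyr_dir = np.stack([_unit(_GYR_AZ[class_id] + 1.20 * n, _GYR_EL[class_id] - 0.30 * n) for n in nodes])
    mag_defl = np.stack(
        [_MAG_DEFL[class_id] * scale[n] * _unit(_MAG_AZ[class_id] + 0.10 * n, _MAG_EL[class_id]) for n in nodes]
    )
    mag_base = np.stack([_EARTH_FIELD.copy() for _ in nodes])
    gravity_dir = np.stack([_unit(0.05 * n, 1.35) for n in nodes])  # near +z
    mid = float(_CLASS_DUR[class_id])
    duration_range = (max(1.0, mid - _DUR_JITTER), min(2.0, mid + _DUR_JITTER))
    return StrokeTemplate(
        class_id=class_id,
        duration_range=duration_range,
        acc_amp=_CLASS_ACC[class_id] * scale,
        acc_dir=acc_dir,
        gyr_amp=_CLASS_GYR[class_id] * scale,
        gyr_freq=_NODE_FREQ[nodes % len(_NODE_FREQ)] * _CLASS_FREQ_FACTOR[class_id],
        gyr_phase=0.3 * class_id + 0.5 * nodes,
        gyr_dir=gyr_dir,
        mag_defl=mag_defl,
        mag_base=mag_base,
        gravity_dir=gravity_dir,
    )


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; the seed fully determines the output."""

    j: int = len(CLASS_NAMES)          # stroke classes
    d: int = DEFAULT_NODE_COUNT        # worn nodes
    fs: float = DEFAULT_FS             # sampling rate, Hz
    actions_per_class: dict[str, int] = field(
        default_factory=lambda: {"train": 100, "val": 40, "major_test": 40, "amateur_test": 40}
    )
    sigma_noise: float = 1.0           # multiplier on nominal channel noise
    professional_variability: float = 1.0
    amateur_variability: float = 2.0
    corruption_prob: float = 0.15      # per-node, amateur split only
    corrupted_node: int | None = None  # None: any non-wrist node may corrupt
    gap_range: tuple[float, float] = (1.5, 2.5)  # rest seconds between strokes
    window_length: int = 60            # frames of the raw action window
    # subject pools: train/val share professionals; the major test holds
    # out different professionals; amateurs are yet other people
    professional_subjects: int = 10
    major_test_subjects: int = 2
    amateur_subjects: int = 8
    subject_mount_std_deg: float = 10.0  # per-node sensor strapping spread
    subject_amp_std: float = 0.15        # body-size amplitude spread
    subject_tempo_std: float = 0.08      # personal tempo spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j < 2 or self.d < 1:
            raise ValueError("need at least 2 classes and 1 node")
        if any(v <= 0 for v in self.actions_per_class.values()):
            raise ValueError("actions_per_class counts must be positive")
        if min(self.gap_range) * self.fs < 1.0 * self.fs:
            raise ValueError("rest gaps must last at least 1 s")
        if min(self.professional_subjects, self.major_test_subjects,
               self.amateur_subjects) < 1:
            raise ValueError("every subject pool needs at least one subject")


@dataclass(frozen=True)
class SubjectProfile:
    """Fixed per-person nuisance parameters: how the sensors sit on this
    body and how this person scales/paces the strokes."""

    mount: np.ndarray       # (d, 3, 3) per-node sensor mounting rotations
    amp_factor: float       # overall burst amplitude scale
    tempo_factor: float     # stroke duration scale
    phase_offset: float     # personal gyro phase


def make_subject(rng: np.random.Generator, config: GeneratorConfig) -> SubjectProfile:
    mount = np.stack(
        [_small_rotation(rng, np.deg2rad(config.subject_mount_std_deg))
         for _ in range(config.d)]
    )
    return SubjectProfile(
        mount=mount,
        amp_factor=float(np.clip(1.0 + config.subject_amp_std * rng.normal(), 0.5, 1.5)),
        tempo_factor=float(np.clip(1.0 + config.subject_tempo_std * rng.normal(), 0.75, 1.25)),
        # personal style shifts the rotation pattern slightly; the pattern
        # itself is locked to the stroke's motor program
        phase_offset=float(0.4 * rng.normal()),
    )


_IDENTITY_SUBJECT_CACHE: dict[int, SubjectProfile] = {}


def identity_subject(d: int) -> SubjectProfile:
    """A neutral subject: sensors mounted exactly as templates assume."""
    if d not in _IDENTITY_SUBJECT_CACHE:
        _IDENTITY_SUBJECT_CACHE[d] = SubjectProfile(
            mount=np.stack([np.eye(3)] * d), amp_factor=1.0,
            tempo_factor=1.0, phase_offset=0.0,
        )
    return _IDENTITY_SUBJECT_CACHE[d]


def subject_pools(config: GeneratorConfig) -> dict[str, list[SubjectProfile]]:
    """Deterministic subject pools per split group."""
    pools = {}
    for gi, (group, count) in enumerate(
        (("professional", config.professional_subjects),
         ("major", config.major_test_subjects),
         ("amateur", config.amateur_subjects))
    ):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(7000 + gi,))
        )
        pools[group] = [make_subject(rng, config) for _ in range(count)]
    return pools


@dataclass
class GroundTruth:
    """Oracle record for one generated stroke."""

    class_id: int
    split_point: int       # first frame detectably off baseline (global index)
    hitting_moment: int    # noiseless wrist-acceleration peak (global index)
    end: int               # one past the last stroke frame (global index)
    onset: int = 0         # first stroke frame (global index)
    subject_id: int = -1   # index into the split group's subject pool
    corrupted_nodes: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.split_point < self.hitting_moment < self.end:
            raise ValueError("need split_point < hitting_moment < end")


# ---------------------------------------------------------------------------
# Stroke and session synthesis
# ---------------------------------------------------------------------------

def _rest_block(
    template: StrokeTemplate, n_frames: int, t0: int, fs: float,
    sigma_noise: float, rng: np.random.Generator, mount: list[np.ndarray],
    subject: SubjectProfile,
) -> np.ndarray:
    """Baseline frames (T x 9d): gravity + drifting earth field + noise,
    seen through each node's (subject x per-action) mounting rotation."""
    d = template.acc_amp.shape[0]
    out = np.zeros((n_frames, CHANNELS_PER_NODE * d))
    tt = (t0 + np.arange(n_frames)) / fs
    for n in range(d):
        k = n * CHANNELS_PER_NODE
        out[:, k : k + 3] = GRAVITY * (subject.mount[n] @ template.gravity_dir[n])
        drift = _MAG_DRIFT_AMP * np.sin(2 * np.pi * _MAG_DRIFT_FREQ * tt + 0.7 * n)
        base = subject.mount[n] @ mount[n] @ template.mag_base[n]
        out[:, k + 6 : k + 9] = base + drift[:, None] * np.array([1.0, 0.5, -0.3])
        out[:, k : k + 3] += rng.normal(0.0, _NOISE_ACC * sigma_noise, (n_frames, 3))
        out[:, k + 3 : k + 6] += rng.normal(0.0, _NOISE_GYR * sigma_noise, (n_frames, 3))
        out[:, k + 6 : k + 9] += rng.normal(0.0, _NOISE_MAG * sigma_noise, (n_frames, 3))
    return out


def generate_stroke(
    template: StrokeTemplate,
    variability: float,
    rng: np.random.Generator,
    *,
    fs: float = DEFAULT_FS,
    sigma_noise: float = 1.0,
    t0: int = 0,
    corrupt_nodes: tuple[int, ...] = (),
    corrupt_template: StrokeTemplate | None = None,
    subject: SubjectProfile | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """One stroke as a ``T x 9d`` frame block plus its ground truth.

    The noiseless wrist synthetic-acceleration profile is unimodal: a
    Hann envelope rises from rest to a single peak (the hitting moment,
    recorded in the ground truth) and decays back.  ``variability``
    scales amplitude/direction/phase jitter; 0 reproduces the template
    exactly up to noise.  ``corrupt_nodes`` substitutes those nodes'
    burst content with ``corrupt_template`` (a wrong local movement).
    ``subject`` applies one person's fixed mounting rotations and
    amplitude/tempo scaling; the default is the neutral subject.
    """
    if variability < 0:
        raise ValueError("variability must be >= 0")
    d = template.acc_amp.shape[0]
    if subject is None:
        subject = identity_subject(d)
    lo, hi = template.duration_range
    mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
    duration = float(np.clip(
        subject.tempo_factor * mid + (2.0 * rng.random() - 1.0) * half * variability,
        1.0, 2.0))
    n_f = max(2, int(round(duration * fs)))

    # per-action mount / posture jitter (static within the stroke)
    mount = [_small_rotation(rng, np.deg2rad(4.0) * variability) for _ in range(d)]
    tilt = [_small_rotation(rng, np.deg2rad(2.0) * variability) for _ in range(d)]

    out = _rest_block(template, n_f, t0, fs, 0.0, rng, mount, subject)  # noiseless base
    for n in range(d):
        src = template
        if n in corrupt_nodes:
            if corrupt_template is None:
                raise ValueError("corrupt_nodes given without corrupt_template")
            src = corrupt_template
        amp_j = subject.amp_factor * (
            1.0 + 0.10 * variability * np.clip(rng.normal(), -2.5, 2.5))
        dir_rot = _small_rotation(rng, np.deg2rad(5.0) * variability)
        phase_j = subject.phase_offset + 0.3 * variability * rng.normal()
        k = n * CHANNELS_PER_NODE
        # kinetic-chain lead: proximal segments burst earlier and shorter
        lead = int(round(_NODE_LEAD_S[n % len(_NODE_LEAD_S)] * fs))
        m = max(2, n_f - lead)
        env_n = np.zeros(n_f)
        env_n[:m] = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(m) / (m - 1)))
        a_dir = tilt[n] @ dir_rot @ src.acc_dir[n]
        if n == 0 and a_dir @ template.gravity_dir[0] < 0:
            a_dir = -a_dir  # keep wrist magnitude unimodal w.r.t. gravity
        a_dir = subject.mount[n] @ a_dir
        out[:, k : k + 3] += (src.acc_amp[n] * amp_j) * env_n[:, None] * a_dir
        # the rotation oscillation is part of the stroke's motor program:
        # its phase is locked to this node's burst peak, not to the clock
        t_rel = (np.arange(n_f) - int(np.argmax(env_n))) / fs
        carrier = np.sin(2 * np.pi * src.gyr_freq[n] * t_rel + src.gyr_phase[n] + phase_j)
        g_dir = subject.mount[n] @ dir_rot @ src.gyr_dir[n]
        out[:, k + 3 : k + 6] += (src.gyr_amp[n] * amp_j) * (env_n * carrier)[:, None] * g_dir
        m_dir = subject.mount[n] @ dir_rot @ src.mag_defl[n]
        out[:, k + 6 : k + 9] += amp_j * env_n[:, None] * m_dir

    # ground truth from the noiseless wrist profile, before noise is added
    wrist_mag = np.sqrt(np.sum(out[:, 0:3] ** 2, axis=1))
    peak = int(np.argmax(wrist_mag))
    off_baseline = np.nonzero(wrist_mag - GRAVITY > _ONSET_EPS)[0]
    split_k = int(off_baseline[0]) if off_baseline.size else 1
    split_k = max(1, min(split_k, peak - 1)) if peak > 1 else 1

    # additive measurement noise, after the noiseless profile fixed the peak
    for n in range(d):
        k = n * CHANNELS_PER_NODE
        out[:, k : k + 3] += rng.normal(0.0, _NOISE_ACC * sigma_noise, (n_f, 3))
        out[:, k + 3 : k + 6] += rng.normal(0.0, _NOISE_GYR * sigma_noise, (n_f, 3))
        out[:, k + 6 : k + 9] += rng.normal(0.0, _NOISE_MAG * sigma_noise, (n_f, 3))

    gt = GroundTruth(
        class_id=template.class_id,
        split_point=t0 + split_k,
        hitting_moment=t0 + peak,
        end=t0 + n_f,
        onset=t0,
        corrupted_nodes=tuple(corrupt_nodes),
    )
    return out, gt


def _draw_corruption(
    config: GeneratorConfig, rng: np.random.Generator, class_id: int,
    templates: list[StrokeTemplate],
) -> tuple[tuple[int, ...], StrokeTemplate | None]:
    """Which nodes (if any) to corrupt, and the wrong-class template."""
    if config.corruption_prob <= 0:
        return (), None
    if config.corrupted_node is not None:
        candidates = [config.corrupted_node]
    else:
        candidates = list(range(1, config.d))
    chosen = tuple(n for n in candidates if rng.random() < config.corruption_prob)
    if not chosen:
        return (), None
    wrong = (class_id + 1 + int(rng.integers(config.j - 1))) % config.j
    return chosen, templates[wrong]


def generate_session(
    config: GeneratorConfig,
    class_sequence: list[int],
    rng: np.random.Generator | None = None,
    variability: float | None = None,
    corruption: bool = False,
    subject: SubjectProfile | None = None,
) -> tuple[np.ndarray, list[GroundTruth]]:
    """A continuous stream: rest gap, stroke, rest gap, stroke, ...

    One person performs the whole session.  The leading gap lets a
    segmenter estimate its rest baseline.  Ground truth split points are
    the first frames where the noiseless wrist profile detectably
    leaves baseline.  ``variability`` defaults to the professional
    level; pass the amateur multiplier (and ``corruption=True``) to
    emulate amateur sessions.
    """
    if not class_sequence:
        raise EmptyInputError("class sequence is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if subject is None:
        subject = identity_subject(config.d)
    templates = [make_template(c, config.d) for c in range(config.j)]
    var = config.professional_variability if variability is None else variability
    eye = [np.eye(3)] * config.d
    blocks: list[np.ndarray] = []
    truths: list[GroundTruth] = []
    t = 0
    for c in class_sequence:
        lo, hi = config.gap_range
        gap = int(round((lo + (hi - lo) * rng.random()) * config.fs))
        blocks.append(
            _rest_block(templates[c], gap, t, config.fs, config.sigma_noise,
                        rng, eye, subject)
        )
        t += gap
        corrupt_nodes: tuple[int, ...] = ()
        corrupt_template = None
        if corruption:
            corrupt_nodes, corrupt_template = _draw_corruption(config, rng, c, templates)
        stroke, gt = generate_stroke(
            templates[c], var, rng, fs=config.fs,
            sigma_noise=config.sigma_noise, t0=t,
            corrupt_nodes=corrupt_nodes, corrupt_template=corrupt_template,
            subject=subject,
        )
        blocks.append(stroke)
        truths.append(gt)
        t = gt.end
    lo, hi = config.gap_range
    gap = int(round((lo + (hi - lo) * rng.random()) * config.fs))
    blocks.append(
        _rest_block(templates[class_sequence[-1]], gap, t, config.fs,
                    config.sigma_noise, rng, eye, subject)
    )
    return np.concatenate(blocks, axis=0), truths


def _stroke_window(
    config: GeneratorConfig, template: StrokeTemplate, variability: float,
    rng: np.random.Generator, corrupt_nodes: tuple[int, ...],
    corrupt_template: StrokeTemplate | None, subject: SubjectProfile,
) -> tuple[ActionMatrix, GroundTruth]:
    """A raw action window of ``window_length`` frames starting at onset."""
    stroke, gt = generate_stroke(
        template, variability, rng, fs=config.fs,
        sigma_noise=config.sigma_noise, t0=0,
        corrupt_nodes=corrupt_nodes, corrupt_template=corrupt_template,
        subject=subject,
    )
    w = config.window_length
    if stroke.shape[0] < w:
        pad = _rest_block(template, w - stroke.shape[0], stroke.shape[0],
                          config.fs, config.sigma_noise, rng,
                          [np.eye(3)] * config.d, subject)
        stroke = np.concatenate([stroke, pad], axis=0)
    window = ActionMatrix(data=stroke[:w], d=config.d, label=template.class_id)
    return window, gt


def generate_dataset(config: GeneratorConfig) -> tuple[LabeledDataset, list[GroundTruth]]:
    """Labelled raw action windows for all four splits.

    Professional-like splits (train / val / major_test) use unit
    variability; the amateur_test split uses the amateur multiplier and
    may corrupt individual non-wrist nodes with probability
    ``corruption_prob`` (or always corrupt ``corrupted_node`` when that
    probability is 1 and a node is pinned).
    """
    rng = np.random.default_rng(config.seed)
    templates = [make_template(c, config.d) for c in range(config.j)]
    pools = subject_pools(config)
    group_of = {"train": "professional", "val": "professional",
                "major_test": "major", "amateur_test": "amateur"}
    actions: list[ActionMatrix] = []
    splits: list[str] = []
    truths: list[GroundTruth] = []
    for split in SPLITS:
        n_per = config.actions_per_class.get(split, 0)
        amateur = split == "amateur_test"
        var = config.amateur_variability if amateur else config.professional_variability
        pool = pools[group_of[split]]
        for c in range(config.j):
            for _ in range(n_per):
                s_idx = int(rng.integers(len(pool)))
                corrupt: tuple[int, ...] = ()
                corrupt_template = None
                if amateur:
                    corrupt, corrupt_template = _draw_corruption(config, rng, c, templates)
                window, gt = _stroke_window(
                    config, templates[c], var, rng, corrupt, corrupt_template,
                    pool[s_idx],
                )
                gt.subject_id = s_idx
                actions.append(window)
                splits.append(split)
                truths.append(gt)
    dataset = LabeledDataset(actions=actions, class_count=config.j, splits=splits)
    return dataset, truths


def dataset_keyframes(
    dataset: LabeledDataset,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per split: (N, 36, 9d) keyframe tensor and label vector.

    Runs keyframe extraction on every raw action window of the dataset.
    """
    from .segmentation import extract_keyframes

    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for split in SPLITS:
        sub = [m for m, s in zip(dataset.actions, dataset.splits) if s == split]
        if not sub:
            continue
        x = np.stack([extract_keyframes(m).data for m in sub])
        y = np.array([m.label for m in sub])
        out[split] = (x, y)
    return out
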