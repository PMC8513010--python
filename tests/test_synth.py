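"""Synthetic-stroke generator: determinism, stroke structure, dataset layout."""

import numpy as np
import pytest

from ttstroke.datamodel import EmptyInputError
from ttstroke.segmentation import synthetic_acceleration
from ttstroke.synth import (
    GeneratorConfig,
    dataset_keyframes,
    generate_dataset,
    generate_session,
    generate_stroke,
    identity_subject,
    make_template,
)


def wrist_magnitude(block):
    return synthetic_acceleration(block[:, 0:3])


class TestStroke:
    def test_same_rng_state_is_bit_identical(self):
        t = make_template(0)
        a, _ = generate_stroke(t, 1.0, np.random.default_rng(5))
        b, _ = generate_stroke(t, 1.0, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_zero_variability_peaks_at_template_midpoint(self):
        t = make_template(2)
        stroke, gt = generate_stroke(t, 0.0, np.random.default_rng(0), sigma_noise=0.0)
        n_f = stroke.shape[0]
        mid = 0.5 * sum(t.duration_range)
        assert n_f == round(mid * 30.0)
        assert gt.hitting_moment == (n_f - 1) // 2
        assert gt.hitting_moment == int(np.argmax(wrist_magnitude(stroke)))

    def test_noiseless_profile_argmax_is_recorded_hitting_moment(self):
        for c in range(5):
            stroke, gt = generate_stroke(
                make_template(c), 1.0, np.random.default_rng(c), sigma_noise=0.0
            )
            assert int(np.argmax(wrist_magnitude(stroke))) == gt.hitting_moment

    def test_duration_stays_within_30_to_60_frames(self):
        rng = np.random.default_rng(1)
        for c in range(5):
            for _ in range(10):
                stroke, _ = generate_stroke(make_template(c), 2.0, rng)
                assert 30 <= stroke.shape[0] <= 60

    def test_ground_truth_ordering_invariant(self):
        rng = np.random.default_rng(2)
        for c in range(5):
            _, gt = generate_stroke(make_template(c), 1.5, rng, t0=100)
            assert gt.onset <= gt.split_point < gt.hitting_moment < gt.end

    def test_wrist_amplitude_strictly_dominates(self):
        for c in range(5):
            t = make_template(c)
            assert np.all(t.acc_amp[0] > t.acc_amp[1:])

    def test_templates_pairwise_distinct(self):
        templates = [make_template(c) for c in range(5)]
        for a in range(5):
            for b in range(a + 1, 5):
                assert not np.allclose(templates[a].acc_dir, templates[b].acc_dir)

    def test_negative_variability_rejected(self):
        with pytest.raises(ValueError):
            generate_stroke(make_template(0), -1.0, np.random.default_rng(0))


class TestSession:
    def test_three_strokes_give_increasing_split_points(self):
        cfg = GeneratorConfig(seed=4)
        _, truths = generate_session(cfg, [0, 1, 2])
        assert len(truths) == 3
        splits = [g.split_point for g in truths]
        assert splits == sorted(splits) and len(set(splits)) == 3

    def test_empty_class_sequence_rejected(self):
        with pytest.raises(EmptyInputError):
            generate_session(GeneratorConfig(seed=0), [])

    def test_two_second_gaps_leave_60_rest_frames(self):
        cfg = GeneratorConfig(seed=5, gap_range=(2.0, 2.0))
        _, truths = generate_session(cfg, [0, 0, 0])
        for prev, nxt in zip(truths, truths[1:]):
            assert nxt.onset - prev.end >= 60

    def test_stream_covers_all_strokes(self):
        cfg = GeneratorConfig(seed=6)
        stream, truths = generate_session(cfg, [1, 3])
        assert stream.shape[1] == 45
        assert truths[-1].end < stream.shape[0]


class TestDataset:
    def test_split_sizes_and_balanced_labels(self, small_config, small_data):
        ds = small_data["dataset"]
        per = small_config.actions_per_class
        for split, n in per.items():
            sub = ds.subset(split)
            assert len(sub) == n * 5
            labels = [m.label for m in sub.actions]
            assert all(labels.count(c) == n for c in range(5))

    def test_same_seed_is_bit_identical(self, small_config):
        a, _ = generate_dataset(small_config)
        b, _ = generate_dataset(small_config)
        for ma, mb in zip(a.actions, b.actions):
            np.testing.assert_array_equal(ma.data, mb.data)

    def test_pinned_corruption_flags_every_amateur_action(self):
        cfg = GeneratorConfig(
            seed=9, corruption_prob=1.0, corrupted_node=3,
            actions_per_class={"amateur_test": 4},
        )
        _, truths = generate_dataset(cfg)
        assert all(g.corrupted_nodes == (3,) for g in truths)

    def test_amateur_at_unit_variability_matches_professional_statistics(self):
        cfg = GeneratorConfig(
            seed=10, amateur_variability=1.0, corruption_prob=0.0,
            actions_per_class={"major_test": 20, "amateur_test": 20},
        )
        ds, _ = generate_dataset(cfg)
        arrays = dataset_keyframes(ds)
        peaks = {
            split: np.array([wrist_magnitude(x).max() for x in arrays[split][0]])
            for split in ("major_test", "amateur_test")
        }
        # same generator path, different subject draw: means agree to ~15%
        ratio = peaks["amateur_test"].mean() / peaks["major_test"].mean()
        assert 0.85 < ratio < 1.18

    def test_nearest_centroid_on_raw_keyframes_beats_chance(self, small_data):
        x, y = small_data["arrays"]["train"]
        xt, yt = small_data["arrays"]["major_test"]
        flat = x.reshape(len(x), -1)
        cents = np.stack([flat[y == c].mean(axis=0) for c in range(5)])
        pred = np.argmin(
            np.linalg.norm(xt.reshape(len(xt), -1)[:, None] - cents[None], axis=-1),
            axis=1,
        )
        assert np.mean(pred == yt) > 1 / 5

    def test_noise_scaling_never_shrinks_within_class_distance(self):
        spreads = []
        for sigma in (0.5, 1.0, 2.0):
            cfg = GeneratorConfig(seed=11, sigma_noise=sigma,
                                  actions_per_class={"train": 10})
            ds, _ = generate_dataset(cfg)
            x, y = dataset_keyframes(ds)["train"]
            flat = x.reshape(len(x), -1)
            d = np.mean(
                [
                    np.linalg.norm(flat[y == c] - flat[y == c].mean(axis=0), axis=1).mean()
                    for c in range(5)
                ]
            )
            spreads.append(d)
        assert spreads[0] <= spreads[1] <= spreads[2]


class TestSubjects:
    def test_identity_subject_is_neutral(self):
        s = identity_subject(5)
        np.testing.assert_array_equal(s.mount[0], np.eye(3))
        assert s.amp_factor == 1.0 and s.tempo_factor == 1.0

    def test_subject_rotations_preserve_wrist_magnitude_profile(self):
        from ttstroke.synth import SubjectProfile, _small_rotation

        rot_rng = np.random.default_rng(3)
        subject = SubjectProfile(
            mount=np.stack([_small_rotation(rot_rng, 0.3) for _ in range(5)]),
            amp_factor=1.0, tempo_factor=1.0, phase_offset=0.0,
        )
        t = make_template(0)
        plain, _ = generate_stroke(t, 0.0, np.random.default_rng(8), sigma_noise=0.0)
        mounted, _ = generate_stroke(t, 0.0, np.random.default_rng(8),
                                     sigma_noise=0.0, subject=subject)
        np.testing.assert_allclose(
            wrist_magnitude(plain), wrist_magnitude(mounted), rtol=1e-10
        )
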