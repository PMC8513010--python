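"""Classifier architectures, the training protocol, and the abstract-feature tap."""

import numpy as np
import pytest

from ttstroke import nn
from ttstroke.models import (
    ModelConfig,
    TrainConfig,
    build_mdff_block,
    build_model,
    evaluate,
    extract_abstract_features,
    load_model,
    save_model,
    train,
)


def cfg(cols=18, j=5, seed=0, **kw):
    return ModelConfig(input_cols=cols, class_count=j, seed=seed, **kw)


class TestFusionBlock:
    @pytest.mark.parametrize("cols", [9, 18, 45])
    def test_spatial_extent_preserved(self, cols):
        block = build_mdff_block(cfg(cols), np.random.default_rng(0))
        x = np.random.default_rng(1).normal(size=(2, 36, cols, 1)).astype(np.float32)
        y = block.forward(x, False)
        assert y.shape == (2, 36, cols, ModelConfig(cols, 5).reduction)

    def test_zero_input_with_zero_biases_gives_zero_output(self):
        block = build_mdff_block(cfg(9), np.random.default_rng(0))
        y = block.forward(np.zeros((1, 36, 9, 1), dtype=np.float32), False)
        assert not y.any()

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError):
            build_mdff_block(ModelConfig(input_cols=2, class_count=5),
                             np.random.default_rng(0))

    def test_reductions_shrink_the_model_versus_naive_inception(self):
        mdff = build_model(cfg(45), "mdff")
        naive = build_model(cfg(45), "naive_inception")
        assert mdff.n_params() < naive.n_params()


class TestVariants:
    @pytest.mark.parametrize("variant", ["mdff", "plain_cnn", "naive_inception"])
    def test_output_is_probability_vector_of_length_j(self, variant):
        model = build_model(cfg(18, j=5), variant)
        x = np.random.default_rng(2).normal(size=(3, 36, 18))
        probs = model.predict_proba(x)
        assert probs.shape == (3, 5)
        assert np.all(probs > 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            build_model(cfg(), "resnet")

    def test_single_logit_softmax_value(self):
        # softmax of (1,0,0,0,0): max component e/(e+4)
        p = nn.softmax(np.array([1.0, 0, 0, 0, 0]))
        assert p[0] == pytest.approx(np.e / (np.e + 4), rel=1e-9)

    def test_gap_head_size_independent_of_column_count(self):
        narrow = build_model(cfg(9), "mdff")
        wide = build_model(cfg(45), "mdff")
        # global average pooling: FC input depends on trunk channels only
        assert narrow.net.layers[-1].layers[-1].w.value.shape == \
            wide.net.layers[-1].layers[-1].w.value.shape


class TestTrainingProtocol:
    def test_learning_rate_schedule_decays_every_20_epochs(self):
        tc = TrainConfig()
        assert [tc.lr_at(e) for e in (0, 19, 20, 39, 40, 59)] == pytest.approx(
            [0.01, 0.01, 0.001, 0.001, 0.0001, 0.0001]
        )

    def test_two_runs_with_same_seed_have_identical_history(self, small_data):
        x, y = small_data["arrays"]["train"]
        runs = []
        for _ in range(2):
            m = build_model(cfg(45), "mdff")
            train(m, x, y, tc=TrainConfig(epochs=3, seed=1))
            runs.append(m)
        assert runs[0].history["train_loss"] == runs[1].history["train_loss"]
        for pa, pb in zip(runs[0].net.params(), runs[1].net.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_empty_training_set_rejected(self):
        m = build_model(cfg(9), "mdff")
        with pytest.raises(ValueError):
            train(m, np.zeros((0, 36, 9)), np.zeros(0, dtype=int))

    def test_labels_outside_range_rejected(self):
        m = build_model(cfg(9, j=2), "mdff")
        with pytest.raises(ValueError):
            train(m, np.zeros((4, 36, 9)), np.array([0, 1, 2, 0]))

    def test_loss_trend_decreases_and_validation_learns(self, small_model):
        h = small_model.history
        assert h["train_loss"][-1] < h["train_loss"][0]
        assert h["val_accuracy"][-1] > 1 / 5  # beats chance

    def test_history_records_every_epoch(self, small_model):
        assert len(small_model.history["train_loss"]) == 8
        assert len(small_model.history["val_accuracy"]) == 8


class TestEvaluation:
    def test_perfect_predictions_give_unit_f1_and_diagonal_confusion(self, small_model, small_data):
        x, y = small_data["arrays"]["train"]
        res = evaluate(small_model, x, y)
        if res["macro_f1"] == 1.0:  # trained model memorized the small set
            assert np.all(res["confusion"] == np.diag(np.diag(res["confusion"])))
        # structural invariants hold regardless
        assert 0.0 <= res["macro_f1"] <= 1.0
        np.testing.assert_array_equal(res["confusion"].sum(axis=1),
                                      np.bincount(y, minlength=5))

    def test_uniform_random_predictions_score_near_chance(self):
        rng = np.random.default_rng(6)
        from sklearn.metrics import f1_score

        f1s = [
            f1_score(np.repeat(np.arange(5), 40), rng.integers(0, 5, 200),
                     average="macro")
            for _ in range(10)
        ]
        assert np.mean(f1s) == pytest.approx(0.2, abs=0.05)


class TestAbstractFeatures:
    def test_map_shape_is_rows_by_columns(self, small_model):
        x = np.random.default_rng(7).normal(size=(36, 45))
        m = extract_abstract_features(small_model, x)
        assert m.shape == (36, 45)

    def test_channel_sum_matches_loop_accumulation_oracle(self, small_model):
        x = np.random.default_rng(8).normal(size=(36, 45))
        prepared = small_model._prepare(x)
        per_channel = small_model.block.forward(prepared, False)[0]
        looped = np.zeros((36, 45))
        for ch in range(per_channel.shape[-1]):
            looped += per_channel[:, :, ch]
        np.testing.assert_allclose(small_model.abstract_map(x), looped, atol=1e-4)

    def test_non_mdff_variant_rejected(self):
        m = build_model(cfg(9), "plain_cnn")
        with pytest.raises(NotImplementedError):
            m.abstract_map(np.zeros((36, 9)))


class TestSerialization:
    def test_checkpoint_round_trip_preserves_predictions(self, small_model, tmp_path):
        x = np.random.default_rng(9).normal(size=(4, 36, 45))
        path = str(tmp_path / "model.npz")
        save_model(small_model, path)
        clone = load_model(path)
        np.testing.assert_allclose(
            small_model.predict_proba(x), clone.predict_proba(x), atol=1e-6
        )
        assert clone.variant == "mdff"
        assert clone.history["train_loss"] == small_model.history["train_loss"]
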