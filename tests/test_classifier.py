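"""Model assembly, the training contract, prediction, and weight transfer."""

import numpy as np
import pytest

from stripeid import (ArchConfig, TrainConfig, assemble_model, predict, train)
from stripeid.classifier import (build_classifier_graph, evaluate_accuracy,
                                 format_table, load_pretrained, save_weights,
                                 summary_table, DROPOUT_SWEEP_RATES)
from stripeid.synthetic import SyntheticConfig, generate_dataset
from stripeid.preprocessing import records_to_arrays


@pytest.fixture(scope="module")
def overfit_sets():
    """3 individuals x 10 face images: a tiny perfectly learnable task."""
    cfg = SyntheticConfig(n_individuals=3, images_per_part=10, seed=1)
    records = [r for r in generate_dataset(cfg) if r.part == "face"]
    X, y, classes = records_to_arrays(records, 96)
    return X, y, classes


@pytest.fixture(scope="module")
def trained_tiny(overfit_sets):
    X, y, _ = overfit_sets
    model = assemble_model(ArchConfig.tiny(n_classes=3, dropout_rate=0.1))
    log = train(model, (X, y), (X, y), TrainConfig(epochs=20, seed=0))
    return model, log


class TestAssembly:
    def test_component_counts_sum_to_full_model(self):
        """backbone + CBAM + dense head = 54,336,736 + 589,922 + 164,459."""
        arch = ArchConfig(n_classes=107)
        g = build_classifier_graph(arch)
        assert g.param_count() == 54_336_736 + 589_922 + 164_459 == 55_091_117

    def test_summary_table_matches_component_structure(self):
        rows = summary_table(ArchConfig(n_classes=107))
        by_name = {name.split(" ")[0]: (shape, count) for name, shape, count in rows}
        assert by_name["inception_resnet_v2"] == ("(None, 8, 8, 1536)", 54_336_736)
        assert by_name["cbam_block"] == ("(None, 8, 8, 1536)", 589_922)
        assert by_name["global_average_pooling2d_1"][1] == 0
        assert by_name["dropout"][1] == 0
        assert by_name["dense_2"] == ("(None, 107)", 164_459)
        assert "55,091,117" in format_table(rows)

    def test_head_count_1536_to_107_with_bias(self):
        assert 1536 * 107 + 107 == 164_459

    def test_probabilities_sum_to_one(self, rng, tiny_arch):
        model = assemble_model(tiny_arch)
        x = rng.standard_normal((3, 96, 96, 3)).astype(np.float32)
        p = model.forward(x).data
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-5)
        assert np.all(p >= 0)

    def test_zero_head_gives_uniform_probabilities(self, rng, tiny_arch):
        model = assemble_model(tiny_arch)
        model.params["head.w"][:] = 0.0
        model.params["head.b"][:] = 0.0
        x = rng.standard_normal((96, 96, 3)).astype(np.float32)
        pred = predict(model, x)
        np.testing.assert_allclose(pred.probabilities, 1.0 / 12, atol=1e-6)

    def test_argmax_tie_returns_lowest_index(self, rng, tiny_arch):
        model = assemble_model(tiny_arch)
        model.params["head.w"][:] = 0.0
        bias = np.zeros(12, np.float32)
        bias[[2, 5]] = 4.0
        model.params["head.b"][:] = bias
        pred = predict(model, rng.standard_normal((96, 96, 3)).astype(np.float32))
        probs = pred.probabilities
        # explicit scan oracle for the first-maximum rule
        best = max(range(12), key=lambda i: (probs[i], -i))
        assert pred.class_index == best == 2

    def test_wrong_input_shape_rejected(self, tiny_arch):
        model = assemble_model(tiny_arch)
        with pytest.raises(ValueError, match="96"):
            predict(model, np.zeros((50, 50, 3), np.float32))

    def test_dropout_sweep_rates_exposed(self):
        assert DROPOUT_SWEEP_RATES == (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
        for rate in DROPOUT_SWEEP_RATES:
            ArchConfig(n_classes=5, dropout_rate=rate)


class TestModes:
    def test_eval_forward_idempotent_and_deterministic(self, rng, tiny_arch):
        model = assemble_model(tiny_arch)
        x = rng.standard_normal((2, 96, 96, 3)).astype(np.float32)
        a = model.forward(x).data
        b = model.forward(x).data
        np.testing.assert_array_equal(a, b)

    def test_dropout_zero_train_eval_agree(self, rng):
        """With dropout 0 and batch-norm statistics pinned to the batch
        (momentum 0), the training flag changes nothing else."""
        arch = ArchConfig.tiny(n_classes=12, dropout_rate=0.0)
        model = assemble_model(arch)
        x = rng.standard_normal((4, 96, 96, 3)).astype(np.float32)
        a = model.forward(x, training=True, bn_momentum=0.0).data
        b = model.forward(x, training=False).data
        np.testing.assert_allclose(a, b, rtol=1e-4, atol=1e-5)

    def test_dropout_active_only_in_training(self, rng):
        arch = ArchConfig.tiny(n_classes=12, dropout_rate=0.6)
        model = assemble_model(arch)
        x = rng.standard_normal((2, 96, 96, 3)).astype(np.float32)
        np.testing.assert_array_equal(model.forward(x).data,
                                      model.forward(x).data)
        r1 = model.forward(x, training=True, rng=np.random.default_rng(1)).data
        r2 = model.forward(x, training=True, rng=np.random.default_rng(2)).data
        assert not np.array_equal(r1, r2)


class TestTraining:
    def test_overfits_three_individuals(self, trained_tiny, overfit_sets):
        """A tiny assembled model reaches 100% training accuracy on
        3 individuals x 10 images within 20 epochs."""
        model, log = trained_tiny
        X, y, _ = overfit_sets
        assert evaluate_accuracy(model, X, y) == 1.0
        assert len(log.loss) == len(log.test_top1) == 20
        assert all(0.0 <= a <= 1.0 for a in log.test_top1)

    def test_loss_decreases_in_trend(self, trained_tiny):
        _, log = trained_tiny
        assert log.loss[-1] < log.loss[0]

    def test_zero_learning_rate_freezes_the_model(self, overfit_sets):
        X, y, _ = overfit_sets
        model = assemble_model(ArchConfig.tiny(n_classes=3, dropout_rate=0.0))
        before = {k: v.copy() for k, v in model.params.items()}
        log = train(model, (X, y), (X, y),
                    TrainConfig(epochs=2, learning_rate=0.0, seed=0))
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])
        # batch-norm running statistics still settle between epochs, so the
        # accuracy series is constant only up to evaluation noise
        assert abs(log.test_top1[0] - log.test_top1[1]) <= 2 / len(y)

    def test_training_is_deterministic_given_seed(self, overfit_sets):
        X, y, _ = overfit_sets
        logs = []
        for _ in range(2):
            model = assemble_model(ArchConfig.tiny(n_classes=3))
            logs.append(train(model, (X[:12], y[:12]), (X[:12], y[:12]),
                              TrainConfig(epochs=2, seed=3)))
        assert logs[0].loss == logs[1].loss
        assert logs[0].test_top1 == logs[1].test_top1

    def test_empty_and_out_of_range_rejected(self, overfit_sets, tiny_arch):
        X, y, _ = overfit_sets
        model = assemble_model(ArchConfig.tiny(n_classes=3))
        with pytest.raises(ValueError, match="empty"):
            train(model, (X[:0], y[:0]), (X, y), TrainConfig(epochs=1))
        bad = y.copy()
        bad[0] = 99
        with pytest.raises(ValueError, match="labels"):
            train(model, (X, bad), (X, y), TrainConfig(epochs=1))

    def test_invalid_train_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-0.1)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="rmsprop")


class TestWeightTransfer:
    def test_roundtrip_and_backbone_only_replacement(self, tmp_path, rng):
        arch = ArchConfig.tiny(n_classes=12)
        donor = assemble_model(arch)
        for k in donor.params:  # make the donor distinguishable
            donor.params[k] = donor.params[k] + 1.0
        path = tmp_path / "weights.npz"
        save_weights(donor, path)

        model = assemble_model(arch)
        head_before = model.params["head.w"].copy()
        att_before = model.params["att_fc1.w"].copy()
        load_pretrained(model, path)
        some_backbone = next(iter(model.backbone_keys))
        np.testing.assert_array_equal(model.params[some_backbone],
                                      donor.params[some_backbone])
        np.testing.assert_array_equal(model.params["head.w"], head_before)
        np.testing.assert_array_equal(model.params["att_fc1.w"], att_before)

    def test_missing_file_errors_and_leaves_model_unchanged(self, tmp_path):
        model = assemble_model(ArchConfig.tiny(n_classes=3))
        before = {k: v.copy() for k, v in model.params.items()}
        with pytest.raises(FileNotFoundError):
            load_pretrained(model, tmp_path / "nope.npz")
        for k in before:
            np.testing.assert_array_equal(model.params[k], before[k])

    def test_shape_mismatch_names_the_layer(self, tmp_path):
        donor = assemble_model(ArchConfig.tiny(n_classes=3,
                                               width_multiplier=0.25))
        path = tmp_path / "weights.npz"
        save_weights(donor, path)
        model = assemble_model(ArchConfig.tiny(n_classes=3))
        with pytest.raises(ValueError, match="shape mismatch for"):
            load_pretrained(model, path)
        # staged loading: nothing was partially overwritten
        fresh = assemble_model(ArchConfig.tiny(n_classes=3))
        for k in model.params:
            np.testing.assert_array_equal(model.params[k], fresh.params[k])
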