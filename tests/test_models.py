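"""Architecture conformance, training recipe, estimator behaviour."""

from __future__ import annotations

import numpy as np
import pytest

import splicevar as sv
from splicevar.models import (Architecture, TrainConfig, build_model,
                              compile_network, lr_schedule,
                              minimum_input_length, parameter_count)

# Golden layer dumps: kind + size parameters for each architecture.
GOLDEN = {
    "CNN_3": [
        {"kind": "conv2d", "filters": 70, "size": (9, 4)},
        {"kind": "dropout", "rate": 0.2},
        {"kind": "conv2d", "filters": 100, "size": (7, 1)},
        {"kind": "maxpool", "pool": 2},
        {"kind": "dropout", "rate": 0.2},
        {"kind": "conv2d", "filters": 150, "size": (7, 1)},
        {"kind": "maxpool", "pool": 2},
        {"kind": "dropout", "rate": 0.2},
        {"kind": "dense", "units": 512},
        {"kind": "dropout", "rate": 0.2},
        {"kind": "softmax", "units": 2},
    ],
    "CNN_4": [
        {"kind": "conv2d", "filters": 70, "size": (3, 4)},
        {"kind": "dropout", "rate": 0.2},
        {"kind": "conv2d", "filters": 100, "size": (3, 1)},
        {"kind": "dropout", "rate": 0.2},
        {"kind": "conv2d", "filters": 100, "size": (3, 1)},
        {"kind": "maxpool", "pool": 2},
        {"kind": "dropout", "rate": 0.2},
        {"kind": "conv2d", "filters": 200, "size": (3, 1)},
        {"kind": "maxpool", "pool": 2},
        {"kind": "dropout", "rate": 0.2},
        {"kind": "dense", "units": 512},
        {"kind": "dropout", "rate": 0.2},
        {"kind": "softmax", "units": 2},
    ],
    "CNN_LSTM": [
        {"kind": "conv1d", "filters": 320, "size": (26,)},
        {"kind": "maxpool", "pool": 13},
        {"kind": "dropout", "rate": 0.2},
        {"kind": "bilstm", "units": 320},
        {"kind": "dropout", "rate": 0.5},
        {"kind": "dense", "units": 925},
        {"kind": "softmax", "units": 2},
    ],
}


class TestArchitectures:
    @pytest.mark.parametrize("name", ["CNN_3", "CNN_4", "CNN_LSTM"])
    def test_layer_dump_matches_golden(self, name):
        spec = build_model(name, 40)
        assert spec.dump() == GOLDEN[name]

    def test_conv_layer_counts(self):
        def convs(name):
            return sum(l.kind.startswith("conv")
                       for l in build_model(name, 40).layers)
        assert convs("CNN_3") == 3
        assert convs("CNN_4") == 4
        assert convs("CNN_LSTM") == 1

    def test_final_layer_is_two_way_softmax(self):
        for name in GOLDEN:
            last = build_model(name, 40).layers[-1]
            assert (last.kind, last.units) == ("softmax", 2)

    def test_aliases_resolve(self):
        assert build_model("cnn4", 40).name is Architecture.CNN_4
        assert build_model("cnn_lstm", 40).name is Architecture.CNN_LSTM

    def test_too_short_input_reports_minimum(self):
        with pytest.raises(ValueError, match="minimum"):
            build_model("CNN_3", 20)

    def test_minimum_lengths_admit_and_below_fails(self):
        for name in GOLDEN:
            m = minimum_input_length(name)
            build_model(name, m)
            with pytest.raises(ValueError):
                build_model(name, m - 1)

    def test_parameter_count_deterministic(self):
        a = parameter_count(build_model("CNN_4", 40))
        b = parameter_count(build_model("CNN_4", 40))
        assert a == b > 100_000

    def test_first_conv_collapses_channel_axis(self):
        net = compile_network(build_model("CNN_4", 40))
        x = np.random.default_rng(0).random((2, 40, 4))
        net.init(0)
        out = net.layers[0].forward(x)
        assert out.shape == (2, 38, 70)


class TestLrSchedule:
    def test_epoch_zero_is_start_rate(self):
        assert lr_schedule(0, TrainConfig()) == 0.05

    def test_constant_within_decay_period_then_halved(self):
        cfg = TrainConfig()
        assert [lr_schedule(e, cfg) for e in range(5)] == [0.05] * 5
        assert lr_schedule(5, cfg) == pytest.approx(0.05 * 0.5)

    def test_closed_form_over_thirty_epochs(self):
        cfg = TrainConfig(decay_factor=0.5)
        rates = [lr_schedule(e, cfg) for e in range(30)]
        assert rates[29] == pytest.approx(0.05 * 0.5 ** 5)
        for e, r in enumerate(rates):
            assert r == pytest.approx(0.05 * 0.5 ** (e // 5))
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_epoch_out_of_range(self):
        with pytest.raises(ValueError):
            lr_schedule(30, TrainConfig())


class TestTrainConfig:
    def test_defaults_follow_recipe(self):
        cfg = TrainConfig()
        assert cfg.optimizer == "sgd-nesterov"
        assert cfg.momentum == 0.9
        assert cfg.loss == "categorical-crossentropy"
        assert cfg.epochs == 30
        assert cfg.batch_size == 64
        assert cfg.lr0 == 0.05
        assert cfg.decay_every == 5

    def test_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(lr0=-1)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)


class TestEstimator:
    def test_history_lr_equals_schedule(self, trained_cnn4):
        cfg = trained_cnn4.train_config()
        for h in trained_cnn4.history_:
            assert h["lr"] == lr_schedule(h["epoch"], cfg)

    def test_loss_decreases_on_learnable_signal(self, trained_cnn4):
        losses = [h["loss"] for h in trained_cnn4.history_]
        assert losses[-1] < losses[0]

    def test_probabilities_sum_to_one(self, trained_cnn4, donor_data):
        _, holdout, _ = donor_data
        p = trained_cnn4.predict_proba(holdout[:20])
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p >= 0) & (p <= 1))

    def test_batched_and_single_calls_agree(self, trained_cnn4, donor_data):
        _, holdout, _ = donor_data
        batch = trained_cnn4.predict_proba_splice(holdout[:10])
        singles = [trained_cnn4.predict_proba_splice([r])[0]
                   for r in holdout[:10]]
        assert np.allclose(batch, singles, atol=1e-6)

    def test_same_input_same_probability(self, trained_cnn4, donor_data):
        _, holdout, _ = donor_data
        a = trained_cnn4.predict_proba_splice(holdout[:5])
        b = trained_cnn4.predict_proba_splice(holdout[:5])
        assert np.array_equal(a, b)

    def test_positives_score_above_negatives(self, trained_cnn4, donor_data):
        _, holdout, y = donor_data
        p = trained_cnn4.predict_proba_splice(holdout)
        assert p[y == 1].mean() > p[y == 0].mean()

    def test_length_mismatch_rejected(self, trained_cnn4):
        with pytest.raises(ValueError, match="length"):
            trained_cnn4.predict_proba(["ACGT" * 20])

    def test_get_params_round_trip(self):
        clf = sv.SpliceSiteClassifier("CNN_3", epochs=2, random_state=5)
        clone = sv.SpliceSiteClassifier(**clf.get_params())
        assert clone.get_params() == clf.get_params()

    def test_save_load_round_trip(self, trained_cnn4, donor_data, tmp_path):
        _, holdout, _ = donor_data
        path = tmp_path / "model.npz"
        trained_cnn4.save(path)
        restored = sv.SpliceSiteClassifier.load(path)
        assert np.allclose(restored.predict_proba_splice(holdout[:20]),
                           trained_cnn4.predict_proba_splice(holdout[:20]))
        assert restored.history_ == trained_cnn4.history_

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            sv.SpliceSiteClassifier().predict_proba(["A" * 40])


class TestTrainingDeterminism:
    def test_identical_seeds_identical_histories(self):
        motif = sv.default_motif("donor", "DLAI40", 1.0)
        pos = sv.sample_positive(motif, 100, 1)
        neg = sv.sample_negative(
            sv.GeneratorConfig("donor", "DLAI40", 0, 100, seed=2))
        data = pos + neg
        y = [r.label for r in data]
        digests = []
        for _ in range(2):
            clf = sv.SpliceSiteClassifier("CNN_4", epochs=2, random_state=3)
            clf.fit(data, y)
            digests.append(clf.history_digest())
        assert digests[0] == digests[1]
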