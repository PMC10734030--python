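"""Backbone construction, freezing policy, training semantics, ensembling."""

import numpy as np
import pytest

from voicescreen.classifier import (
    BackboneSpec, ConfigurationError, HeadSpec, LabeledImageSet, TrainConfig,
    TrainedModel, build_model, ensemble_predict, load_checkpoint, predict_batch,
    predict_window, save_checkpoint, train, train_backbone,
)
from voicescreen.nn import sigmoid


def _dataset(rng, n=40, n_pids=8, size=32, separable=False):
    labels = np.array(["pass" if i % n_pids < n_pids // 2 else "fail" for i in range(n)])
    images = (rng.random((n, size, size, 3)) * 0.2).astype(np.float32)
    if separable:
        images[labels == "pass"] += 0.3
    pids = np.array([f"p{i % n_pids}" for i in range(n)])
    cids = np.array([f"c{i}" for i in range(n)])
    return LabeledImageSet(images, labels, pids, cids)


def _constant_model(prob, seed=0):
    """tinycnn whose head is pinned so every output equals `prob`."""
    model = build_model(BackboneSpec(name="tinycnn"), seed=seed, image_size=32)
    dense = model.network.layers[-1]
    dense.w.value = np.zeros_like(dense.w.value)
    dense.b.value = np.array([np.log(prob / (1 - prob))], dtype=np.float32)
    return TrainedModel(model=model, config=TrainConfig.for_backbone("tinycnn"),
                        history={"val_loss": [0.0]}, best_epoch=0)


@pytest.mark.parametrize("name,size", [
    ("tinycnn", 224), ("densenet121", 64), ("convnext_tiny", 64),
])
def test_output_is_probability(name, size, rng):
    model = build_model(BackboneSpec(name=name), seed=0, image_size=size)
    x = rng.random((2, 3, size, size)).astype(np.float32)
    probs = sigmoid(model.logits(x))
    assert np.all((probs > 0.0) & (probs < 1.0))


def test_unknown_backbone_and_pretrained_rejected():
    with pytest.raises(ConfigurationError, match="unknown backbone"):
        BackboneSpec(name="resnet50")
    with pytest.raises(ConfigurationError, match="pretrained"):
        BackboneSpec(name="densenet121", pretrained=True)
    with pytest.raises(ConfigurationError, match="freeze boundary"):
        BackboneSpec(name="densenet121", freeze_boundary="stage_3")


def test_densenet_frozen_below_last_block():
    model = build_model(BackboneSpec(name="densenet121"), seed=0)
    params = model.network.params()
    frozen = [p for p in params if not p.trainable]
    trainable = [p for p in params if p.trainable]
    assert frozen and trainable
    assert model.network.n_trainable() < model.network.n_params()
    # the first conv is frozen; the last dense block and head train
    assert not params[0].trainable
    assert params[-1].trainable and params[-2].trainable


def test_convnext_frozen_through_stage3():
    model = build_model(BackboneSpec(name="convnext_tiny"), seed=0)
    assert 0 < model.network.n_trainable() < model.network.n_params()
    assert not model.network.params()[0].trainable


def test_tinycnn_fully_trainable():
    model = build_model(BackboneSpec(name="tinycnn"), seed=0)
    assert model.network.n_trainable() == model.network.n_params()


def test_frozen_params_bit_identical_after_training(rng):
    data = _dataset(rng, n=16, n_pids=4, size=32)
    model = build_model(BackboneSpec(name="densenet121"), HeadSpec(dropout_rate=0.8),
                        seed=0, image_size=32)
    frozen_before = [p.value.copy() for p in model.network.params() if not p.trainable]
    trainable_before = [p.value.copy() for p in model.network.params() if p.trainable]
    config = TrainConfig(learning_rate=1e-3, batch_size=8, target_epochs=2,
                         patience=5, seed=0)
    train(model, data, config)
    frozen_after = [p.value for p in model.network.params() if not p.trainable]
    trainable_after = [p.value for p in model.network.params() if p.trainable]
    assert all(np.array_equal(a, b) for a, b in zip(frozen_before, frozen_after))
    assert any(not np.array_equal(a, b)
               for a, b in zip(trainable_before, trainable_after))


def test_single_class_training_rejected(rng):
    data = _dataset(rng, n=10, n_pids=2)
    data.labels[:] = "pass"
    model = build_model(BackboneSpec(name="tinycnn"), seed=0, image_size=32)
    with pytest.raises(ValueError, match="single class"):
        train(model, data, TrainConfig.for_backbone("tinycnn"))


def test_empty_image_set_rejected():
    with pytest.raises(ValueError, match="empty"):
        LabeledImageSet(images=np.zeros((0, 32, 32, 3)), labels=np.array([]),
                        participant_ids=np.array([]), clip_ids=np.array([]))


def test_overfits_separable_images(rng):
    data = _dataset(rng, n=40, n_pids=8, size=224, separable=True)
    config = TrainConfig(learning_rate=1e-2, batch_size=8, target_epochs=30,
                         patience=30, seed=0)
    tm = train_backbone("tinycnn", data, config, seed=0, image_size=224)
    assert max(tm.history["train_acc"]) == 1.0


def test_patience_zero_stops_at_first_non_improvement(rng):
    data = _dataset(rng, n=24, n_pids=6, size=32, separable=True)
    config = TrainConfig(learning_rate=1e-2, batch_size=8, target_epochs=12,
                         patience=0, seed=3)
    tm = train_backbone("tinycnn", data, config, seed=3, image_size=32)
    losses = tm.history["val_loss"]
    # every epoch before the last strictly improved the running best;
    # the run ends at the first epoch that does not (or at target_epochs)
    best = np.inf
    for i, loss in enumerate(losses[:-1]):
        assert loss < best
        best = loss
    if len(losses) < config.target_epochs:
        assert losses[-1] >= best
    assert tm.best_epoch == int(np.argmin(losses))


def test_early_stopping_restores_best_epoch_parameters(trained_pair, small_sets):
    train_set, _ = small_sets
    for tm in trained_pair:
        losses = tm.history["val_loss"]
        assert tm.best_epoch == int(np.argmin(losses))
        assert len(losses) <= tm.best_epoch + tm.config.patience + 2
        assert len(losses) <= tm.config.target_epochs


def test_prediction_is_deterministic_and_bounded(trained_pair, small_sets):
    _, test_set = small_sets
    tm = trained_pair[0]
    image = test_set.images[0].astype(np.float64)
    p1 = predict_window(tm, image)
    p2 = predict_window(tm, image)
    assert p1 == p2
    assert 0.0 < p1 < 1.0


def test_predict_rejects_wrong_shape(trained_pair):
    with pytest.raises(ValueError, match="shape"):
        predict_window(trained_pair[0], np.zeros((100, 100, 3)))


def test_ensemble_mean_and_permutation_invariance(rng):
    m6, m8 = _constant_model(0.6), _constant_model(0.8)
    image = rng.random((32, 32, 3))
    assert ensemble_predict([m6, m8], image) == pytest.approx(0.7, abs=1e-6)
    assert ensemble_predict([m8, m6], image) == pytest.approx(
        ensemble_predict([m6, m8], image), abs=1e-12)
    assert ensemble_predict([m6], image) == pytest.approx(
        predict_window(m6, image), abs=1e-12)
    with pytest.raises(ValueError, match="at least one"):
        ensemble_predict([], image)


def test_ensemble_convex_within_member_range(rng):
    members = [_constant_model(0.3, seed=0), _constant_model(0.9, seed=1)]
    # un-pin the heads so outputs vary with the image
    for m, seed in zip(members, (5, 6)):
        r = np.random.default_rng(seed)
        dense = m.model.network.layers[-1]
        dense.w.value = r.standard_normal(dense.w.value.shape).astype(np.float32)
        dense.b.value = r.standard_normal(1).astype(np.float32)
    for _ in range(20):
        image = rng.random((32, 32, 3))
        probs = [predict_window(m, image) for m in members]
        ens = ensemble_predict(members, image)
        assert min(probs) - 1e-12 <= ens <= max(probs) + 1e-12


def test_checkpoint_roundtrip(tmp_path, trained_pair, small_sets):
    _, test_set = small_sets
    tm = trained_pair[0]
    path = save_checkpoint(tm, tmp_path / "model")
    back = load_checkpoint(path)
    p_orig = predict_batch(tm, test_set.images[:8])
    p_back = predict_batch(back, test_set.images[:8])
    assert np.allclose(p_orig, p_back, atol=1e-12)
    assert back.best_epoch == tm.best_epoch
    assert back.history["val_loss"] == pytest.approx(tm.history["val_loss"])
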