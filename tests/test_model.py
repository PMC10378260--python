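import numpy as np
import pytest

from sleephht.model import (
    CNNOnlyModel,
    MixedModel,
    ModelConfig,
    TrainConfig,
    build_cnn_only,
    build_model,
    predict,
    split_dataset,
    train,
)
from sleephht.nn import softmax

TINY = ModelConfig(conv_filters=(4, 8, 16), image_shape=(8, 8, 1), feature_dim=16)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(conv_filters=(16, 32, 48))  # filters must double
    with pytest.raises(ValueError):
        ModelConfig(cnn_fc_nodes=(16, 4))  # concat width != 16
    with pytest.raises(ValueError):
        ModelConfig(image_shape=(60, 64, 1))  # not divisible by 2^3
    with pytest.raises(ValueError):
        ModelConfig(feature_dim=0)
    with pytest.raises(ValueError):
        ModelConfig(n_classes=1)
    assert ModelConfig().output_activation == "sigmoid"
    assert ModelConfig().output_units == 1
    assert ModelConfig(n_classes=6).output_activation == "softmax"
    assert ModelConfig(n_classes=6).output_units == 6


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(test_fraction=1.5)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")
    assert TrainConfig().loss == "cross-entropy"


def test_default_architecture_layout():
    model = build_model()
    s = model.summary()
    cnn = [d for d in s if d["branch"] == "cnn"]
    convs = [d for d in cnn if d["type"] == "conv2d"]
    assert [d["filters"] for d in convs] == [16, 32, 64]
    assert all(d["kernel"] == 3 and d["activation"] == "relu" for d in convs)
    # every conv layer is immediately followed by a 2x2 max pool
    for i, d in enumerate(cnn):
        if d["type"] == "conv2d":
            assert cnn[i + 1] == {"branch": "cnn", "type": "maxpool2d", "pool": 2}
    cnn_fc = [d["nodes"] for d in cnn if d["type"] == "dense"]
    ann_fc = [d["nodes"] for d in s if d["branch"] == "ann"]
    assert cnn_fc == [16, 8] and ann_fc == [16, 8]
    # no softmax inside either branch
    assert all(d.get("activation") != "softmax" for d in s if d["branch"] != "head")
    head = [d for d in s if d["branch"] == "head"]
    assert head[0]["nodes"] == 4 and head[0]["activation"] == "relu"
    assert head[1]["nodes"] == 1 and head[1]["activation"] == "sigmoid"


def test_parameter_count_matches_hand_tally():
    # conv: (3*3*c_in + 1)*c_out; dense: (n_in + 1)*n_out; 64x64 -> 8x8x64
    expected = (
        (9 * 1 + 1) * 16 + (9 * 16 + 1) * 32 + (9 * 32 + 1) * 64
        + (8 * 8 * 64 + 1) * 16 + (16 + 1) * 8          # cnn fc
        + (64 + 1) * 16 + (16 + 1) * 8                  # ann fc
        + (16 + 1) * 4 + (4 + 1) * 1                    # head
    )
    assert build_model().parameter_count() == expected


def test_forward_shapes_and_concat_width():
    model = build_model(seed=0)
    rng = np.random.default_rng(0)
    imgs = rng.uniform(size=(2, 64, 64, 1)).astype(np.float32)
    feats = rng.normal(size=(2, 64)).astype(np.float32)
    assert model.forward_logits(imgs, feats).shape == (2, 1)
    from sleephht.model import _forward_chain

    ci = _forward_chain(model.cnn, imgs)
    ai = _forward_chain(model.ann, feats)
    assert ci.shape == (2, 8) and ai.shape == (2, 8)  # concat width 16


def test_cnn_only_shares_branch_shape():
    model = build_cnn_only(seed=0)
    assert isinstance(model, CNNOnlyModel)
    s = model.summary()
    assert [d["filters"] for d in s if d["type"] == "conv2d"] == [16, 32, 64]
    assert not [d for d in s if d["branch"] == "ann"]
    imgs = np.zeros((3, 64, 64, 1), dtype=np.float32)
    assert model.forward_logits(imgs).shape == (3, 1)


def test_split_sizes_match_reference_proportions():
    """6880 balanced epochs at a 30% hold-out give a 2064-epoch test set."""
    labels = np.array(["sleep", "wake"] * 3440)
    tr, val, te = split_dataset(labels, TrainConfig(seed=4))
    assert te.size == 2064
    assert tr.size + val.size + te.size == 6880
    assert val.size == int(np.ceil(0.15 * (6880 - 2064)))
    # disjoint and stratified
    assert not (set(tr) & set(val) or set(tr) & set(te) or set(val) & set(te))
    for part in (tr, val, te):
        n_wake = int(np.sum(labels[part] == "wake"))
        assert abs(n_wake - (part.size - n_wake)) <= 1
    # deterministic under the seed
    tr2, _, _ = split_dataset(labels, TrainConfig(seed=4))
    assert np.array_equal(tr, tr2)


def _toy_task(n=48, seed=0):
    """Binary task where both branches carry signal."""
    rng = np.random.default_rng(seed)
    y = np.arange(n) % 2
    feats = rng.normal(size=(n, 16)).astype(np.float32)
    feats[y == 1] += 1.5
    imgs = rng.uniform(0, 0.3, size=(n, 8, 8, 1)).astype(np.float32)
    imgs[y == 1, 2:6, 2:6] += 0.7
    return feats, imgs, y


def test_training_reduces_loss_and_is_deterministic():
    feats, imgs, y = _toy_task()
    cfg = TrainConfig(epochs=40, batch_size=16, seed=3)
    hist1 = train(build_model(TINY, seed=3), feats, imgs, y, cfg)
    hist2 = train(build_model(TINY, seed=3), feats, imgs, y, cfg)
    assert len(hist1) == 40
    assert hist1.loss == hist2.loss and hist1.accuracy == hist2.accuracy
    assert hist1.loss[-1] < hist1.loss[0]
    assert hist1.accuracy[-1] >= 0.9


def test_validation_history_recorded():
    feats, imgs, y = _toy_task()
    cfg = TrainConfig(epochs=2, batch_size=16, seed=0)
    model = build_model(TINY, seed=0)
    hist = train(model, feats[:32], imgs[:32], y[:32], cfg,
                 validation_data=(feats[32:], imgs[32:], y[32:]))
    assert len(hist.val_loss) == 2 and len(hist.val_accuracy) == 2
    with pytest.raises(ValueError):
        train(model, feats[:5], imgs[:4], y[:5], cfg)


def test_predict_threshold_tie_is_positive():
    class _Stub:
        config = ModelConfig()

        def predict_proba(self, images, features):
            return np.array([[0.5], [0.49], [0.51]])

    pred, probs = predict(_Stub(), np.zeros((3, 64)), np.zeros((3, 64, 64, 1)))
    assert pred.tolist() == [1, 0, 1]
    assert probs.tolist() == [0.5, 0.49, 0.51]
    with pytest.raises(ValueError):
        predict(_Stub(), np.zeros((3, 64)), np.zeros((2, 64, 64, 1)))


def test_multiclass_probabilities_sum_to_one():
    cfg = ModelConfig(conv_filters=(4, 8, 16), image_shape=(8, 8, 1),
                      feature_dim=16, n_classes=6)
    model = build_model(cfg, seed=1)
    rng = np.random.default_rng(1)
    probs = model.predict_proba(
        rng.uniform(size=(5, 8, 8, 1)).astype(np.float32),
        rng.normal(size=(5, 16)).astype(np.float32),
    )
    assert probs.shape == (5, 6)
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
    assert np.allclose(softmax(np.zeros((2, 6))), 1 / 6)


def test_multiclass_training_runs():
    cfg = ModelConfig(conv_filters=(4, 8, 16), image_shape=(8, 8, 1),
                      feature_dim=16, n_classes=3)
    rng = np.random.default_rng(2)
    n = 30
    y = np.arange(n) % 3
    feats = rng.normal(size=(n, 16)).astype(np.float32) + y[:, None]
    imgs = rng.uniform(size=(n, 8, 8, 1)).astype(np.float32)
    model = build_model(cfg, seed=2)
    hist = train(model, feats, imgs, y, TrainConfig(epochs=10, batch_size=10, seed=2))
    assert hist.loss[-1] < hist.loss[0]
    pred, probs = predict(model, feats, imgs)
    assert probs.shape == (n, 3)
    assert set(pred.tolist()) <= {0, 1, 2}
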