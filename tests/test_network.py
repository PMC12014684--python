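"""Assembly, fusion, decoding, NMS and checkpoint contracts."""

import numpy as np
import pytest

from fruitdet import nn
from fruitdet.metrics import Detection, iou
from fruitdet.network import (ModelConfig, bifpn_fuse, build_model,
                              decode_level, decode_predictions, load_checkpoint,
                              nms, predict, save_checkpoint)
from oracles import nms_oracle


# -- config -----------------------------------------------------------

def test_config_defaults_valid():
    ModelConfig()


@pytest.mark.parametrize("kw", [
    dict(num_classes=0),
    dict(regmax=1),
    dict(strides=(8, 16, 24)),
    dict(strides=(16, 8, 32)),
    dict(stage_blocks=(0, 1, 1, 1)),
    dict(bifpn_channels=15),
    dict(width_mult=-0.5),
])
def test_config_rejects_with_field_named(kw):
    with pytest.raises(ValueError, match=next(iter(kw))):
        ModelConfig(**kw)


def test_config_yaml_roundtrip(tmp_path, tiny_cfg):
    p = tmp_path / "model.yaml"
    tiny_cfg.to_yaml(p)
    assert ModelConfig.from_yaml(p) == tiny_cfg


def test_config_yaml_unknown_key(tmp_path):
    p = tmp_path / "model.yaml"
    p.write_text("num_classes: 1\nbogus_key: 3\n")
    with pytest.raises(ValueError, match="bogus_key"):
        ModelConfig.from_yaml(p)


# -- build / forward --------------------------------------------------

def test_raw_prediction_spatial_sizes(tiny_cfg):
    model = build_model(tiny_cfg, seed=0)
    model.eval()
    raw = model(nn.Tensor(np.zeros((1, 3, 128, 128), np.float32)))
    sizes = [r.shape[2:] for r, _ in raw]
    assert sizes == [(16, 16), (8, 8), (4, 4)]  # input/8, /16, /32


def test_channel_contract_4regmax(tiny_cfg):
    model = build_model(tiny_cfg, seed=0)
    model.eval()
    raw = model(nn.Tensor(np.zeros((1, 3, 64, 64), np.float32)))
    for reg, cls in raw:
        assert reg.shape[1] == 4 * tiny_cfg.regmax
        assert cls.shape[1] == tiny_cfg.num_classes


def test_channel_contract_regmax16_is_64():
    cfg = ModelConfig(num_classes=1, width_mult=0.25,
                      stage_channels=(8, 16, 32, 64), stage_blocks=(1, 1, 1, 1),
                      bifpn_channels=8, bifpn_repeats=1, regmax=16)
    model = build_model(cfg, seed=0)
    model.eval()
    raw = model(nn.Tensor(np.zeros((1, 3, 64, 64), np.float32)))
    for reg, cls in raw:
        assert reg.shape[1] == 64
        assert cls.shape[1] == 1


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_channel_contract_randomized_configs(seed):
    rng = np.random.default_rng(seed)
    cfg = ModelConfig(
        num_classes=int(rng.integers(1, 5)),
        width_mult=float(rng.uniform(0.2, 0.6)),
        stage_channels=tuple(int(c) for c in rng.integers(8, 32, 4)),
        stage_blocks=tuple(int(b) for b in rng.integers(1, 3, 4)),
        bifpn_channels=int(rng.integers(4, 12)) * 2,
        bifpn_repeats=int(rng.integers(1, 3)),
        regmax=int(rng.integers(4, 17)),
    )
    model = build_model(cfg, seed=seed)
    model.eval()
    raw = model(nn.Tensor(np.zeros((1, 3, 64, 64), np.float32)))
    for (reg, cls), s in zip(raw, cfg.strides):
        assert reg.shape[1:] == (4 * cfg.regmax, 64 // s, 64 // s)
        assert cls.shape[1:] == (cfg.num_classes, 64 // s, 64 // s)


def test_same_seed_identical_weights(tiny_cfg):
    m1 = build_model(tiny_cfg, seed=11)
    m2 = build_model(tiny_cfg, seed=11)
    for (_, p1), (_, p2) in zip(m1.named_parameters(), m2.named_parameters()):
        np.testing.assert_array_equal(p1.data, p2.data)


def test_forward_determinism(tiny_cfg, rng):
    model = build_model(tiny_cfg, seed=3)
    model.eval()
    x = nn.Tensor(rng.random((1, 3, 64, 64)).astype(np.float32))
    raw1 = model(x)
    raw2 = model(x)
    for (r1, c1), (r2, c2) in zip(raw1, raw2):
        np.testing.assert_array_equal(r1.data, r2.data)
        np.testing.assert_array_equal(c1.data, c2.data)


def test_indivisible_input_rejected(tiny_cfg):
    model = build_model(tiny_cfg, seed=0)
    with pytest.raises(ValueError, match="divisible"):
        model(nn.Tensor(np.zeros((1, 3, 100, 100), np.float32)))


# -- fusion -----------------------------------------------------------

def test_fuse_equal_inputs_identity(rng):
    x = rng.normal(size=(2, 4, 8, 8))
    out = bifpn_fuse([x, x.copy()], [1.0, 1.0], eps=0.0)
    np.testing.assert_allclose(out, x, atol=1e-12)


def test_fuse_weight_one_zero(rng):
    eps = 1e-4
    a, b = rng.normal(size=(2, 3, 4, 4))
    out = bifpn_fuse([a, b], [1.0, 0.0], eps=eps)
    np.testing.assert_allclose(out, a / (1.0 + eps), atol=1e-12)


def test_fuse_three_inputs_matches_weighted_mean(rng):
    xs = [rng.normal(size=(1, 2, 3, 3)) for _ in range(3)]
    w = [0.2, 1.3, 0.5]
    eps = 1e-4
    want = sum(wi * xi for wi, xi in zip(w, xs)) / (sum(w) + eps)
    np.testing.assert_allclose(bifpn_fuse(xs, w, eps=eps), want, atol=1e-10)


def test_fuse_negative_weights_clamped(rng):
    a, b = rng.normal(size=(2, 3, 4, 4))
    np.testing.assert_allclose(bifpn_fuse([a, b], [1.0, -5.0]),
                               bifpn_fuse([a, b], [1.0, 0.0]), atol=1e-12)


def test_fuse_shape_mismatch_raises(rng):
    with pytest.raises(ValueError, match="shape"):
        bifpn_fuse([rng.normal(size=(1, 2, 4, 4)),
                    rng.normal(size=(1, 2, 8, 8))], [1.0, 1.0])


def test_fuse_bound_property(rng):
    xs = [rng.normal(size=(1, 2, 5, 5)) for _ in range(3)]
    w = rng.random(3)
    eps = 1e-4
    out = bifpn_fuse(xs, w, eps=eps)
    shrink = w.sum() / (w.sum() + eps)
    lo = np.minimum.reduce(xs) * shrink
    hi = np.maximum.reduce(xs) * shrink
    # convex combination of inputs, then shrunk toward 0 by sum/(sum+eps)
    assert (out >= np.minimum(lo, hi) - 1e-9).all()
    assert (out <= np.maximum(lo, hi) + 1e-9).all()


def test_fuse_tensor_path_matches_numpy(rng):
    xs_np = [rng.normal(size=(1, 2, 4, 4)) for _ in range(2)]
    w = np.array([0.7, 0.4])
    got = bifpn_fuse([nn.Tensor(x) for x in xs_np], nn.Tensor(w))
    np.testing.assert_allclose(got.data, bifpn_fuse(xs_np, w), atol=1e-7)


# -- decode -----------------------------------------------------------

def _raw_level(regmax, nc, h, w):
    return np.zeros((4 * regmax, h, w)), np.zeros((nc, h, w))


def test_decode_one_hot_bins():
    regmax, stride, b = 8, 8, 3
    reg, cls = _raw_level(regmax, 1, 4, 4)
    reg = reg.reshape(4, regmax, 4, 4)
    reg[:, b] = 50.0  # one-hot at bin b on every side
    boxes, conf, _ = decode_level(reg.reshape(-1, 4, 4), cls, stride, regmax)
    cx, cy = 0.5 * stride, 0.5 * stride  # cell (0,0)
    np.testing.assert_allclose(
        boxes[0], [cx - b * stride, cy - b * stride,
                   cx + b * stride, cy + b * stride], atol=1e-5)


def test_decode_uniform_bins():
    regmax, stride = 6, 16
    reg, cls = _raw_level(regmax, 1, 2, 2)
    boxes, _, _ = decode_level(reg, cls, stride, regmax)
    d = (regmax - 1) / 2 * stride
    cx = cy = 0.5 * stride
    np.testing.assert_allclose(boxes[0], [cx - d, cy - d, cx + d, cy + d],
                               atol=1e-5)


def test_decode_expectation_matches_loop(rng):
    regmax, stride = 8, 8
    reg = rng.normal(size=(4 * regmax, 3, 3))
    cls = rng.normal(size=(2, 3, 3))
    boxes, conf, cid = decode_level(reg, cls, stride, regmax)
    # brute-force expectation per cell/side
    r = reg.reshape(4, regmax, 3, 3)
    for cell in range(9):
        y, x = divmod(cell, 3)
        dists = []
        for side in range(4):
            logits = r[side, :, y, x]
            p = np.exp(logits - logits.max())
            p /= p.sum()
            dists.append(sum(k * p[k] for k in range(regmax)) * stride)
        cx, cy = (x + 0.5) * stride, (y + 0.5) * stride
        want = [cx - dists[0], cy - dists[1], cx + dists[2], cy + dists[3]]
        np.testing.assert_allclose(boxes[cell], want, atol=1e-4)
        s = 1 / (1 + np.exp(-cls[:, y, x]))
        assert conf[cell] == pytest.approx(s.max(), abs=1e-6)
        assert cid[cell] == s.argmax()


def test_decoded_boxes_valid_and_clipped(tiny_cfg, rng):
    model = build_model(tiny_cfg, seed=0)
    model.eval()
    raw = model(nn.Tensor(rng.random((1, 3, 64, 64)).astype(np.float32)))
    dets = decode_predictions(raw, tiny_cfg, conf_threshold=0.0, img_size=64)
    assert dets
    for d in dets:
        x1, y1, x2, y2 = d.box
        assert 0 <= x1 < x2 <= 64
        assert 0 <= y1 < y2 <= 64
        assert np.isfinite(d.score)


# -- nms --------------------------------------------------------------

def test_nms_identical_boxes():
    dets = [Detection((0, 0, 2, 2), 0.9), Detection((0, 0, 2, 2), 0.8)]
    kept = nms(dets, 0.5)
    assert len(kept) == 1 and kept[0].score == 0.9


def test_nms_disjoint_boxes_survive():
    dets = [Detection((0, 0, 2, 2), 0.9), Detection((5, 5, 7, 7), 0.1)]
    assert len(nms(dets, 0.0)) == 2


def test_nms_different_classes_not_suppressed():
    dets = [Detection((0, 0, 2, 2), 0.9, 0), Detection((0, 0, 2, 2), 0.8, 1)]
    assert len(nms(dets, 0.5)) == 2


@pytest.mark.parametrize("seed", range(8))
def test_nms_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 10
    xy = rng.uniform(0, 8, (n, 2))
    wh = rng.uniform(1, 5, (n, 2))
    boxes = np.concatenate([xy, xy + wh], axis=1)
    scores = rng.random(n)
    classes = rng.integers(0, 2, n)
    dets = [Detection(tuple(b), float(s), int(c))
            for b, s, c in zip(boxes, scores, classes)]
    thr = float(rng.uniform(0.2, 0.7))
    kept = nms(dets, thr)
    want = [dets[i] for i in nms_oracle(boxes, scores, classes, thr)]
    assert kept == want
    # antichain property: no two same-class survivors overlap above thr
    for i, a in enumerate(kept):
        for b in kept[i + 1:]:
            if a.class_id == b.class_id:
                assert iou(a.box, b.box) <= thr + 1e-12


# -- end-to-end predict / checkpoint ---------------------------------

def test_predict_deterministic(tiny_cfg, rng):
    model = build_model(tiny_cfg, seed=4)
    img = rng.random((3, 64, 64)).astype(np.float32)
    assert predict(model, img, conf_threshold=0.0) == \
        predict(model, img, conf_threshold=0.0)


def test_checkpoint_roundtrip(tmp_path, tiny_cfg, rng):
    model = build_model(tiny_cfg, seed=9)
    path = tmp_path / "model.ckpt"
    save_checkpoint(path, model, seed=9, epoch=3, extra={"note": "x"})
    loaded, header = load_checkpoint(path)
    assert header["seed"] == 9 and header["epoch"] == 3
    assert loaded.cfg == tiny_cfg
    img = rng.random((3, 64, 64)).astype(np.float32)
    assert predict(loaded, img, conf_threshold=0.0) == \
        predict(model, img, conf_threshold=0.0)


def test_checkpoint_rejects_garbage(tmp_path):
    p = tmp_path / "bad.ckpt"
    np.savez(p.with_suffix(".npz"), __header__=np.frombuffer(b'{"magic": "nope"}', dtype=np.uint8))
    with pytest.raises(ValueError, match="checkpoint"):
        load_checkpoint(p.with_suffix(".npz"))
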