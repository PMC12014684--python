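"""Loss semantics, schedules, and small-scale training smoke tests."""

import json

import numpy as np
import pytest

from fruitdet import nn, train_eval
from fruitdet.network import ModelConfig, build_model
from fruitdet.synthetic import SceneParams, generate_dataset
from fruitdet.train_eval import (TrainConfig, detection_loss, evaluate,
                                 evaluate_on_samples, lr_at_epoch,
                                 schedule_at, train, _prepare_samples)


@pytest.fixture(scope="module")
def small_model(tiny_cfg=None):
    cfg = ModelConfig(num_classes=1, width_mult=0.25,
                      stage_channels=(16, 32, 64, 128), stage_blocks=(1, 1, 1, 1),
                      bifpn_channels=16, bifpn_repeats=1, regmax=8)
    return cfg, build_model(cfg, seed=0)


# -- loss -------------------------------------------------------------

def _forward(model, rng, n=1, size=64):
    return model(nn.Tensor(rng.random((n, 3, size, size)).astype(np.float32)))


def test_loss_empty_targets(small_model, rng):
    cfg, model = small_model
    model.eval()
    raw = _forward(model, rng)
    loss = detection_loss(raw, [np.zeros((0, 5))], cfg)
    assert loss.box_loss == 0.0 and loss.dfl_loss == 0.0
    assert loss.cls_loss > 0.0 and loss.finite()
    assert loss.total == pytest.approx(
        7.5 * loss.box_loss + 0.5 * loss.cls_loss + 1.5 * loss.dfl_loss, rel=1e-6)


def test_loss_zero_logits_cls_form(small_model):
    cfg, _ = small_model
    # hand-built raw maps with all-zero logits, one 64x64 image
    raw = []
    for s in cfg.strides:
        h = 64 // s
        raw.append((nn.Tensor(np.zeros((1, 4 * cfg.regmax, h, h), np.float32)),
                    nn.Tensor(np.zeros((1, cfg.num_classes, h, h), np.float32))))
    loss = detection_loss(raw, [np.zeros((0, 5))], cfg)
    # BCE(0, 0) = log(2) per anchor; normalizer is max(sum targets, 1) = 1
    n_anchors = sum((64 // s) ** 2 for s in cfg.strides)
    assert loss.cls_loss == pytest.approx(n_anchors * np.log(2), rel=1e-5)


def _good_raw(cfg, target, size=64, sharp=25.0):
    """Hand-built raw maps decoding near-exactly onto `target` (cls,cx,cy,w,h)."""
    _, cx, cy, w, h = target
    gx1, gy1 = (cx - w / 2) * size, (cy - h / 2) * size
    gx2, gy2 = (cx + w / 2) * size, (cy + h / 2) * size
    raw = []
    for s in cfg.strides:
        hw = size // s
        reg = np.zeros((4, cfg.regmax, hw, hw))
        cls = np.full((cfg.num_classes, hw, hw), -sharp)
        for iy in range(hw):
            for ix in range(hw):
                ax, ay = (ix + 0.5) * s, (iy + 0.5) * s
                dists = [(ax - gx1) / s, (ay - gy1) / s,
                         (gx2 - ax) / s, (gy2 - ay) / s]
                inside = all(d > 0 for d in dists)
                for side, d in enumerate(dists):
                    b = int(round(np.clip(d, 0, cfg.regmax - 1)))
                    reg[side, b, iy, ix] = sharp
                if inside:
                    cls[0, iy, ix] = sharp
        raw.append((nn.Tensor(reg.reshape(1, 4 * cfg.regmax, hw, hw)),
                    nn.Tensor(cls[None])))
    return raw


def test_loss_ordering_good_below_random(small_model, rng):
    cfg, _ = small_model
    target = np.array([[0, 0.5, 0.5, 0.4, 0.4]])
    good = detection_loss(_good_raw(cfg, target[0]), [target], cfg)
    bad_raw = []
    for s in cfg.strides:
        hw = 64 // s
        bad_raw.append((nn.Tensor(rng.normal(size=(1, 4 * cfg.regmax, hw, hw))),
                        nn.Tensor(rng.normal(size=(1, cfg.num_classes, hw, hw)))))
    bad = detection_loss(bad_raw, [target], cfg)
    assert good.total < bad.total


def test_loss_finite_and_grads_finite_randomized(small_model, rng):
    cfg, model = small_model
    model.train()
    for _ in range(5):
        n_t = int(rng.integers(0, 4))
        t = np.zeros((n_t, 5))
        if n_t:
            t[:, 1:3] = rng.uniform(0.2, 0.8, (n_t, 2))
            t[:, 3:5] = rng.uniform(0.05, 0.3, (n_t, 2))
        raw = _forward(model, rng)
        loss = detection_loss(raw, [t], cfg)
        assert loss.finite() and loss.total >= 0
        for p in model.parameters():
            p.grad = None
        loss.tensor.backward()
        assert all(np.isfinite(p.grad).all()
                   for p in model.parameters() if p.grad is not None)


def test_overfit_smoke_20_steps(small_model, rng):
    """20 SGD steps on one fixed batch strictly reduce the loss."""
    cfg = ModelConfig(num_classes=1, width_mult=0.25,
                      stage_channels=(16, 32, 64, 128), stage_blocks=(1, 1, 1, 1),
                      bifpn_channels=16, bifpn_repeats=1, regmax=8)
    model = build_model(cfg, seed=2)
    model.train()
    x = nn.Tensor(rng.random((2, 3, 64, 64)).astype(np.float32))
    targets = [np.array([[0, 0.5, 0.5, 0.4, 0.4]]),
               np.array([[0, 0.3, 0.3, 0.25, 0.25]])]
    opt = nn.SGD([{"params": model.parameters(), "lr": 0.01, "momentum": 0.9}])
    first = None
    for step in range(20):
        loss = detection_loss(model(x), targets, cfg)
        if step == 0:
            first = loss.total
        opt.zero_grad()
        loss.tensor.backward()
        opt.step()
    final = detection_loss(model(x), targets, cfg).total
    assert final < first


# -- schedule ---------------------------------------------------------

def test_flat_schedule_when_lrf_equals_lr0():
    t = TrainConfig(epochs=100, lr0=0.01, lrf=0.01)
    assert lr_at_epoch(t, 0) == lr_at_epoch(t, 50) == lr_at_epoch(t, 99) == 0.01


def test_linear_anneal():
    t = TrainConfig(epochs=11, lr0=0.01, lrf=0.001)
    assert lr_at_epoch(t, 0) == pytest.approx(0.01)
    assert lr_at_epoch(t, 10) == pytest.approx(0.001)
    assert lr_at_epoch(t, 5) == pytest.approx(0.0055)


def test_warmup_continuity_at_junction():
    t = TrainConfig(epochs=20, lr0=0.01, lrf=0.01, warmup_epochs=3.0)
    spe = 10
    lr0_start, bias0, mom0 = schedule_at(t, 0, spe)
    assert lr0_start == 0.0
    assert bias0 == pytest.approx(t.warmup_bias_lr)
    assert mom0 == pytest.approx(t.warmup_momentum)
    # end of warmup meets the annealing curve
    w_iters = int(t.warmup_epochs * spe)
    lr_end, bias_end, mom_end = schedule_at(t, w_iters, spe)
    assert lr_end == pytest.approx(lr_at_epoch(t, 3.0), rel=1e-6)
    assert bias_end == pytest.approx(lr_at_epoch(t, 3.0), rel=1e-6)
    assert mom_end == pytest.approx(t.momentum)
    # just before the junction, values are within one step of the curve
    lr_prev, _, _ = schedule_at(t, w_iters - 1, spe)
    assert abs(lr_prev - lr_end) < 0.02 * t.lr0 + t.lr0 / w_iters


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(momentum=-0.1)


# -- training / evaluation drivers -----------------------------------

@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("data")
    params = SceneParams(image_size=96, n_fruits=(1, 2), radius_range=(12, 24),
                         occluder_prob=0.0, cluster_prob=0.0, seed=0)
    manifest, _ = generate_dataset(10, params, root, ratios=(0.8, 0.1, 0.1),
                                   seed=0)
    return manifest


def _smoke_cfgs():
    mcfg = ModelConfig(num_classes=1, width_mult=0.25,
                       stage_channels=(8, 16, 32, 64), stage_blocks=(1, 1, 1, 1),
                       bifpn_channels=8, bifpn_repeats=1, regmax=8)
    tcfg = TrainConfig(epochs=2, batch=4, imgsz=96, seed=0, augment=False,
                       warmup_epochs=1.0)
    return mcfg, tcfg


def test_train_smoke_two_epochs(tiny_dataset, tmp_path):
    mcfg, tcfg = _smoke_cfgs()
    best, rows = train(mcfg, tiny_dataset, tcfg, tmp_path / "run")
    assert best.exists()
    assert (tmp_path / "run" / "last.ckpt").exists()
    assert len(rows) == 2
    log_lines = (tmp_path / "run" / "log.jsonl").read_text().splitlines()
    assert len(log_lines) == 2
    assert {"epoch", "loss", "map50", "map50_95"} <= set(json.loads(log_lines[0]))


def test_train_deterministic_first_epoch(tiny_dataset, tmp_path):
    mcfg, tcfg = _smoke_cfgs()
    tcfg.epochs = 1
    _, rows1 = train(mcfg, tiny_dataset, tcfg, tmp_path / "r1")
    _, rows2 = train(mcfg, tiny_dataset, tcfg, tmp_path / "r2")
    assert rows1[0]["loss"] == rows2[0]["loss"]
    assert rows1[0]["map50_95"] == rows2[0]["map50_95"]


def test_untrained_model_near_zero_map(tmp_path):
    from fruitdet.data_io import load_split, read_manifest
    params = SceneParams(image_size=96, n_fruits=(3, 5), radius_range=(8, 18),
                         seed=0)
    manifest, _ = generate_dataset(20, params, tmp_path / "d",
                                   ratios=(0.8, 0.1, 0.1), seed=1)
    mcfg, _ = _smoke_cfgs()
    model = build_model(mcfg, seed=0)
    samples = load_split(read_manifest(manifest), "train")
    prepared = _prepare_samples(samples, 96)
    report = evaluate_on_samples(model, prepared)
    assert report.map50 < 0.1


def test_perfect_oracle_detections_score_one(tiny_dataset, monkeypatch):
    """Injecting ground truths in place of model output yields a perfect report."""
    from fruitdet.data_io import load_split, read_manifest
    from fruitdet.metrics import Detection
    mcfg, _ = _smoke_cfgs()
    model = build_model(mcfg, seed=0)
    samples = load_split(read_manifest(tiny_dataset), "train")
    prepared = _prepare_samples(samples, 96)

    state = {"i": 0}

    def perfect_decode(raw, cfg, conf, imgsz):
        t = prepared[state["i"]][1]
        state["i"] += 1
        out = []
        for row in t:
            c, cx, cy, w, h = row
            out.append(Detection((
                (cx - w / 2) * 96, (cy - h / 2) * 96,
                (cx + w / 2) * 96, (cy + h / 2) * 96), 1.0, int(c)))
        return out

    monkeypatch.setattr(train_eval, "decode_predictions", perfect_decode)
    report = evaluate_on_samples(model, prepared)
    assert report.map50 == pytest.approx(1.0)
    assert report.map50_95 == pytest.approx(1.0)
    assert report.precision == pytest.approx(1.0)
    assert report.recall == pytest.approx(1.0)


def test_evaluate_checkpoint_deterministic(tiny_dataset, tmp_path):
    mcfg, tcfg = _smoke_cfgs()
    tcfg.epochs = 1
    best, _ = train(mcfg, tiny_dataset, tcfg, tmp_path / "run")
    r1 = evaluate(best, tiny_dataset, split="train")
    r2 = evaluate(best, tiny_dataset, split="train")
    assert r1.to_dict() == r2.to_dict()


def test_evaluate_empty_split_raises(tiny_dataset, tmp_path):
    mcfg, tcfg = _smoke_cfgs()
    tcfg.epochs = 1
    best, _ = train(mcfg, tiny_dataset, tcfg, tmp_path / "run")
    import yaml
    from pathlib import Path
    m = yaml.safe_load(Path(tiny_dataset).read_text())
    m["val"] = "images/empty"
    bad = tmp_path / "bad.yaml"
    bad.write_text(yaml.safe_dump(m))
    with pytest.raises((ValueError, FileNotFoundError)):
        evaluate(best, bad, split="val")
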