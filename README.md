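# fruitdet

A lightweight, anchor-free fruit detector and its full evaluation stack,
implemented end-to-end in numpy (no deep-learning framework required):

- **blocks** — Hard-Swish, depthwise-separable convolution, inverted-bottleneck
  residual blocks/stages, and ghost convolution, each with a strict shape
  contract and a pure functional form pinned against brute-force convolution
  oracles.
- **network** — backbone (inverted-bottleneck stages emitting C3/C4/C5 at
  strides 8/16/32) → weighted bidirectional feature-pyramid neck with
  ghost-conv projections → decoupled anchor-free head (4×regmax
  distribution-bin regression branch, depthwise-separable classification
  branch), plus decoding, NMS and single-file checkpoints.
- **complexity** — analytic parameter/FLOP accounting (multiply-accumulate
  convention), a whole-model walker, and signed relative-change reporting.
- **metrics** — IoU, greedy score-ordered matching, precision/recall,
  101-point interpolated AP, mAP50 and mAP50-95.
- **data_io** — YOLO-format labels and directory layout, manifest YAML,
  deterministic largest-remainder dataset splitting, letterboxing, and
  rotation/scale/color augmentation with corner-mapped box transforms.
- **synthetic** — a deterministic generator of orchard-like scenes (foliage
  backgrounds, shaded fruit discs, stacking, branch/leaf occluders, lighting
  variation) emitting YOLO labels, so the whole pipeline is testable with no
  external data.
- **train_eval** — detection loss (task-aligned assignment, BCE + complete-IoU
  + distribution loss), SGD with warmup and linear lr schedule, training and
  evaluation drivers with JSONL logging.
- **nn** — the minimal reverse-mode autodiff engine (grouped im2col
  convolution, batch norm, elementwise ops, SGD) everything runs on.

## CLI

```sh
# synthetic dataset (YOLO layout + data.yaml manifest)
fruitdet synth --n 200 --imgsz 256 --seed 7 --out data/synth/

# parameter / FLOP report, and a relative-change comparison of two reports
fruitdet analyze --cfg model.yaml --imgsz 640 --json base.json
fruitdet ablate base.json variant.json

# training and evaluation
fruitdet train --data data/synth/data.yaml --epochs 50 --batch 4 --imgsz 256 --seed 0 --out runs/demo
fruitdet eval --weights runs/demo/best.ckpt --data data/synth/data.yaml --split val --json metrics.json
```

Model config YAML keys: `num_classes`, `width_mult`, `stage_channels`,
`stage_blocks`, `expansion`, `bifpn_channels`, `bifpn_repeats`, `regmax`.

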