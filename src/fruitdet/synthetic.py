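"""Deterministic synthetic orchard scenes.

Renders foliage-noise backgrounds with shaded near-circular fruit blobs,
optional fruit clustering (stacking), elongated branch/leaf occluder
strips, and global brightness variation, emitting YOLO-normalized boxes
for every fruit whose visible fraction stays above a floor. The goal is
statistical structure (scale variation, occlusion, stacking, lighting),
not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib.colors import hsv_to_rgb
from PIL import Image
from scipy import ndimage

from .data_io import (LabeledImage, YoloBox, split_dataset, write_manifest,
                      write_yolo_labels)

__all__ = ["SceneParams", "generate_scene", "generate_dataset", "VISIBILITY_FLOOR"]

# a fruit more than 75% hidden is not annotated
VISIBILITY_FLOOR = 0.25


@dataclass
class SceneParams:
    image_size: int = 256
    n_fruits: tuple | int = (3, 8)
    radius_range: tuple = (12, 36)
    cluster_prob: float = 0.3
    occluder_prob: float = 0.3
    max_occlusion_frac: float = 0.6
    brightness_range: tuple = (0.6, 1.3)
    background: str = "foliage"
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.n_fruits, int):
            self.n_fruits = (self.n_fruits, self.n_fruits)
        if self.n_fruits[0] > self.n_fruits[1]:
            raise ValueError("n_fruits range must be ordered")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be ordered")
        if self.brightness_range[0] > self.brightness_range[1]:
            raise ValueError("brightness_range must be ordered")
        for name in ("cluster_prob", "occluder_prob", "max_occlusion_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class SceneMeta:
    """Render-time bookkeeping for one scene."""

    fruits: list = field(default_factory=list)  # per-fruit dicts
    n_requested: int = 0
    n_placed: int = 0
    n_labeled: int = 0


def _foliage_background(size: int, rng: np.random.Generator) -> np.ndarray:
    """Mottled green canopy: smoothed noise mapped into green hues."""
    noise = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 32.0)
    noise = (noise - noise.min()) / (np.ptp(noise) + 1e-9)
    detail = ndimage.gaussian_filter(rng.standard_normal((size, size)), 1.5)
    detail = (detail - detail.min()) / (np.ptp(detail) + 1e-9)
    h = 0.22 + 0.14 * noise            # yellow-green .. green
    s = 0.45 + 0.3 * detail
    v = 0.25 + 0.45 * (0.6 * noise + 0.4 * detail)
    return hsv_to_rgb(np.stack([h, s, v], axis=-1))


def _fruit_patch(size: int, cx: float, cy: float, r: float,
                 rng: np.random.Generator):
    """(mask, rgb) of one shaded fruit disc."""
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = (xx - cx) ** 2 + (yy - cy) ** 2
    mask = d2 <= r * r
    d = np.sqrt(d2, dtype=np.float64) / max(r, 1e-9)
    hue = (rng.uniform(-0.025, 0.045)) % 1.0          # around orange-red
    sat = rng.uniform(0.75, 0.95)
    # radial shading with an off-center highlight
    lx, ly = rng.uniform(-0.4, 0.4), rng.uniform(-0.4, 0.4)
    hl = np.exp(-(((xx - cx) / r - lx) ** 2 + ((yy - cy) / r - ly) ** 2) / 0.18)
    val = np.clip(0.95 - 0.45 * d ** 2 + 0.25 * hl, 0.0, 1.0)
    hsv = np.stack([np.full((size, size), hue),
                    np.clip(sat - 0.25 * hl, 0, 1),
                    val], axis=-1)
    return mask, hsv_to_rgb(hsv)


def _occluder_band(size: int, cx: float, cy: float, r: float,
                   fruit_mask: np.ndarray, max_frac: float,
                   rng: np.random.Generator):
    """Elongated strip across the fruit; offset is pushed outward until the
    covered fraction of this fruit is at most `max_frac`."""
    yy, xx = np.mgrid[0:size, 0:size]
    theta = rng.uniform(0, np.pi)
    c, s = np.cos(theta), np.sin(theta)
    half_w = rng.uniform(0.12, 0.45) * r
    length = 4.0 * r
    offset = rng.uniform(0.0, 0.8) * r
    area = max(int(fruit_mask.sum()), 1)
    band = None
    for _ in range(8):
        u = (xx - cx) * c + (yy - cy) * s          # along the strip
        v = -(xx - cx) * s + (yy - cy) * c - offset
        band = (np.abs(v) <= half_w) & (np.abs(u) <= length / 2)
        frac = (band & fruit_mask).sum() / area
        if frac <= max_frac:
            break
        offset += 0.25 * r                          # slide the band outward
    leafy = rng.random() < 0.5
    hue = rng.uniform(0.24, 0.34) if leafy else rng.uniform(0.06, 0.1)
    sat = rng.uniform(0.5, 0.8) if leafy else rng.uniform(0.4, 0.6)
    val = rng.uniform(0.25, 0.5) if leafy else rng.uniform(0.15, 0.35)
    rgb = np.broadcast_to(hsv_to_rgb(np.array([hue, sat, val])), (size, size, 3))
    return band, rgb


def generate_scene(params: SceneParams,
                   seed: int | None = None) -> tuple[LabeledImage, SceneMeta]:
    """Render one scene; fully reproducible from (params, seed).

    Fruits that cannot be placed after bounded retries are skipped and
    recorded in the returned metadata.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    size = params.image_size
    img = _foliage_background(size, rng)
    meta = SceneMeta()

    n = int(rng.integers(params.n_fruits[0], params.n_fruits[1] + 1))
    meta.n_requested = n

    # placement pass: centers kept fully inside the frame
    placed = []  # (cx, cy, r)
    for _ in range(n):
        r = rng.uniform(*params.radius_range)
        if 2 * r + 2 >= size:
            r = size / 2 - 2
        ok = False
        for _attempt in range(20):
            if placed and rng.random() < params.cluster_prob:
                bx, by, br = placed[int(rng.integers(len(placed)))]
                ang = rng.uniform(0, 2 * np.pi)
                dist = rng.uniform(0.6, 1.1) * (br + r) / 2
                cx, cy = bx + dist * np.cos(ang), by + dist * np.sin(ang)
                if not (r <= cx <= size - r and r <= cy <= size - r):
                    continue
                ok = True
                break
            cx = rng.uniform(r, size - r)
            cy = rng.uniform(r, size - r)
            # outside of clusters fruits stay fully separated, so stacking
            # only ever comes from the cluster branch
            if all(np.hypot(cx - px, cy - py) > (r + pr) + 2.0
                   for px, py, pr in placed):
                ok = True
                break
        if ok:
            placed.append((float(cx), float(cy), float(r)))
    meta.n_placed = len(placed)

    # render pass: later fruits draw over earlier ones (stacking)
    owner = np.full((size, size), -1, np.int64)
    masks = []
    for i, (cx, cy, r) in enumerate(placed):
        mask, rgb = _fruit_patch(size, cx, cy, r, rng)
        img = np.where(mask[..., None], rgb, img)
        owner[mask] = i
        masks.append(mask)

    # occluders on top
    occluded = np.zeros((size, size), bool)
    for i, (cx, cy, r) in enumerate(placed):
        if rng.random() < params.occluder_prob:
            band, rgb = _occluder_band(size, cx, cy, r, masks[i],
                                       params.max_occlusion_frac, rng)
            img = np.where(band[..., None], rgb, img)
            occluded |= band

    brightness = rng.uniform(*params.brightness_range)
    img = np.clip(img * brightness, 0.0, 1.0)
    out = (img * 255.0 + 0.5).astype(np.uint8)

    boxes = []
    for i, (cx, cy, r) in enumerate(placed):
        total = int(masks[i].sum())
        visible = int(((owner == i) & ~occluded).sum())
        frac = visible / max(total, 1)
        labeled = frac >= VISIBILITY_FLOOR
        meta.fruits.append({
            "center": (cx, cy), "radius": r,
            "visible_frac": frac, "labeled": labeled,
        })
        if labeled:
            boxes.append(YoloBox.from_xyxy(
                cx - r, cy - r, cx + r, cy + r, size, size, class_id=0))
    meta.n_labeled = len(boxes)
    return LabeledImage(image=out, boxes=boxes), meta


def generate_dataset(n_images: int, params: SceneParams, out_dir,
                     ratios=(0.8, 0.1, 0.1), seed: int = 0,
                     names=("fruit",)) -> tuple[Path, dict]:
    """Write a ready-to-train YOLO directory layout plus manifest.

    Per-image seeds are spawned from the master seed, so regeneration
    with the same arguments is byte-identical. Returns (manifest_path,
    log) where the log records fruits placed/labeled per image.
    """
    out_dir = Path(out_dir)
    ids = [f"scene_{i:05d}" for i in range(n_images)]
    split = split_dataset(ids, ratios=ratios, seed=seed)
    membership = {}
    for name, id_list in split.as_dict().items():
        for sid in id_list:
            membership[sid] = name
        (out_dir / "images" / name).mkdir(parents=True, exist_ok=True)
        (out_dir / "labels" / name).mkdir(parents=True, exist_ok=True)

    child_seeds = np.random.SeedSequence(seed).spawn(n_images)
    log = {"per_image": {}, "total_placed": 0, "total_labeled": 0}
    for i, sid in enumerate(ids):
        scene, meta = generate_scene(params, seed=child_seeds[i])
        sname = membership[sid]
        Image.fromarray(scene.image).save(out_dir / "images" / sname / f"{sid}.png")
        write_yolo_labels(scene.boxes, out_dir / "labels" / sname / f"{sid}.txt")
        log["per_image"][sid] = {
            "split": sname, "placed": meta.n_placed, "labeled": meta.n_labeled,
        }
        log["total_placed"] += meta.n_placed
        log["total_labeled"] += meta.n_labeled

    manifest_path = write_manifest(out_dir, names)
    return manifest_path, log
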