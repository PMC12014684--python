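"""Dataset I/O: YOLO-format labels, manifest files, deterministic
splitting, letterboxing, and label-preserving augmentation
(rotation / scaling / color jitter).

Directory layout follows the YOLO convention::

    <root>/images/{train,val,test}/*.png
    <root>/labels/{train,val,test}/*.txt

with a manifest YAML carrying ``path``, the three split subdirs and the
class ``names`` list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from matplotlib.colors import hsv_to_rgb, rgb_to_hsv
from PIL import Image

__all__ = [
    "YoloBox",
    "LabeledImage",
    "DatasetSplit",
    "AugmentParams",
    "read_yolo_labels",
    "write_yolo_labels",
    "split_dataset",
    "augment",
    "export_augmented",
    "letterbox",
    "read_manifest",
    "write_manifest",
    "load_split",
]


@dataclass(frozen=True)
class YoloBox:
    """One normalized label row: class id + center/size in [0,1]."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} out of range [0,1]")
        if self.class_id < 0:
            raise ValueError(f"negative class id {self.class_id}")

    def to_xyxy(self, img_w: int, img_h: int) -> tuple:
        """Pixel corners, clipped to the image."""
        x1 = max(0.0, (self.cx - self.w / 2) * img_w)
        y1 = max(0.0, (self.cy - self.h / 2) * img_h)
        x2 = min(float(img_w), (self.cx + self.w / 2) * img_w)
        y2 = min(float(img_h), (self.cy + self.h / 2) * img_h)
        return (x1, y1, x2, y2)

    @staticmethod
    def from_xyxy(x1, y1, x2, y2, img_w, img_h, class_id=0) -> "YoloBox":
        cx = np.clip((x1 + x2) / 2 / img_w, 0, 1)
        cy = np.clip((y1 + y2) / 2 / img_h, 0, 1)
        w = np.clip((x2 - x1) / img_w, 0, 1)
        h = np.clip((y2 - y1) / img_h, 0, 1)
        return YoloBox(class_id, float(cx), float(cy), float(w), float(h))


@dataclass
class LabeledImage:
    """An HxWx3 uint8 image with its normalized boxes."""

    image: np.ndarray
    boxes: list  # of YoloBox

    @property
    def hw(self) -> tuple:
        return self.image.shape[0], self.image.shape[1]


def read_yolo_labels(path) -> list:
    """Parse a YOLO label txt into a list of :class:`YoloBox`."""
    boxes = []
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(
                f"{path}:{lineno}: expected 'class cx cy w h', got {line!r}")
        try:
            cid = int(parts[0])
            vals = [float(v) for v in parts[1:]]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field in {line!r}") from exc
        try:
            boxes.append(YoloBox(cid, *vals))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return boxes


def write_yolo_labels(boxes, path) -> None:
    """Write boxes as YOLO rows with 6-decimal coordinates; extents are
    clipped so cx +- w/2 stays in [0,1]."""
    lines = []
    for b in boxes:
        x1 = max(0.0, b.cx - b.w / 2)
        x2 = min(1.0, b.cx + b.w / 2)
        y1 = max(0.0, b.cy - b.h / 2)
        y2 = min(1.0, b.cy + b.h / 2)
        cx, w = (x1 + x2) / 2, x2 - x1
        cy, h = (y1 + y2) / 2, y2 - y1
        lines.append(f"{b.class_id} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass
class DatasetSplit:
    train: list
    val: list
    test: list
    ratios: tuple
    seed: int

    def as_dict(self) -> dict:
        return {"train": self.train, "val": self.val, "test": self.test}


def split_dataset(ids, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> DatasetSplit:
    """Shuffle `ids` with a seeded generator and partition by
    largest-remainder apportionment of n*ratio."""
    ids = list(ids)
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 samples to split, got {n}")
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError(f"ratios must be 3 positive reals, got {ratios}")
    if not math.isclose(sum(ratios), 1.0, abs_tol=1e-9):
        raise ValueError(f"ratios must sum to 1, got sum {sum(ratios)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    exact = np.array([n * r for r in ratios])
    sizes = np.floor(exact).astype(int)
    rem = exact - sizes
    # hand leftover slots to the largest remainders (ties: earlier split)
    for k in np.argsort(-rem, kind="stable")[: n - sizes.sum()]:
        sizes[k] += 1
    cuts = np.cumsum(sizes)
    shuffled = [ids[i] for i in perm]
    return DatasetSplit(
        train=shuffled[: cuts[0]],
        val=shuffled[cuts[0]: cuts[1]],
        test=shuffled[cuts[1]: cuts[2]],
        ratios=ratios,
        seed=seed,
    )


@dataclass
class AugmentParams:
    """Rotation in degrees, multiplicative scale range, HSV jitter gains,
    and the minimum surviving box area in squared pixels."""

    rotation: float = 15.0
    scale: tuple = (0.8, 1.2)
    hsv_gains: tuple = (0.015, 0.7, 0.4)
    min_area: float = 4.0


def _affine_about_center(theta_deg: float, scale: float, w: int, h: int):
    """Forward 2x3 affine (rotation + scale about the image center)."""
    t = math.radians(theta_deg)
    c, s = math.cos(t) * scale, math.sin(t) * scale
    cx, cy = w / 2.0, h / 2.0
    # p' = R(p - c) + c
    return np.array([
        [c, -s, cx - c * cx + s * cy],
        [s, c, cy - s * cx - c * cy],
    ])


def _apply_hsv_jitter(img: np.ndarray, gains, rng) -> np.ndarray:
    gh, gs, gv = gains
    dh = rng.uniform(-gh, gh)
    ds = 1.0 + rng.uniform(-gs, gs)
    dv = 1.0 + rng.uniform(-gv, gv)
    hsv = rgb_to_hsv(img.astype(np.float64) / 255.0)
    hsv[..., 0] = (hsv[..., 0] + dh) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * ds, 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * dv, 0, 1)
    return (hsv_to_rgb(hsv) * 255.0 + 0.5).astype(np.uint8)


def transform_boxes(boxes, matrix, img_w, img_h, min_area=4.0) -> list:
    """Map each box's 4 corners through a forward affine, re-enclose
    axis-aligned, clip to the image, and drop boxes below `min_area`."""
    out = []
    for b in boxes:
        x1, y1, x2, y2 = b.to_xyxy(img_w, img_h)
        corners = np.array([[x1, y1, 1], [x2, y1, 1], [x2, y2, 1], [x1, y2, 1]]).T
        mapped = matrix @ corners  # (2,4)
        nx1, ny1 = mapped[0].min(), mapped[1].min()
        nx2, ny2 = mapped[0].max(), mapped[1].max()
        nx1, ny1 = max(0.0, nx1), max(0.0, ny1)
        nx2, ny2 = min(float(img_w), nx2), min(float(img_h), ny2)
        if (nx2 - nx1) * (ny2 - ny1) < min_area:
            continue
        out.append(YoloBox.from_xyxy(nx1, ny1, nx2, ny2, img_w, img_h, b.class_id))
    return out


def augment(sample: LabeledImage, params: AugmentParams | None = None,
            seed: int = 0) -> LabeledImage:
    """Rotation + scale about the image center with HSV color jitter;
    boxes follow the same affine (corner-mapped, re-enclosed, clipped)."""
    params = params or AugmentParams()
    rng = np.random.default_rng(seed)
    h, w = sample.hw
    theta = rng.uniform(-params.rotation, params.rotation)
    scale = rng.uniform(params.scale[0], params.scale[1])
    m = _affine_about_center(theta, scale, w, h)
    if abs(theta) < 1e-12 and abs(scale - 1.0) < 1e-12:
        img = sample.image.copy()
        boxes = list(sample.boxes)
    else:
        # PIL wants the inverse map (output -> input)
        minv = np.linalg.inv(np.vstack([m, [0, 0, 1]]))[:2]
        pil = Image.fromarray(sample.image)
        img = np.asarray(pil.transform(
            (w, h), Image.AFFINE, tuple(minv.reshape(-1)),
            resample=Image.BILINEAR, fillcolor=(114, 114, 114)))
        boxes = transform_boxes(sample.boxes, m, w, h, params.min_area)
    if any(g > 0 for g in params.hsv_gains):
        img = _apply_hsv_jitter(img, params.hsv_gains, rng)
    return LabeledImage(image=img, boxes=boxes)


def letterbox(image: np.ndarray, boxes, size: int,
              pad_value: int = 114) -> LabeledImage:
    """Aspect-preserving resize onto a size x size gray canvas; boxes are
    re-normalized to the canvas."""
    h, w = image.shape[0], image.shape[1]
    r = size / max(h, w)
    nw, nh = max(1, int(round(w * r))), max(1, int(round(h * r)))
    resized = np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    canvas = np.full((size, size, 3), pad_value, np.uint8)
    ox, oy = (size - nw) // 2, (size - nh) // 2
    canvas[oy:oy + nh, ox:ox + nw] = resized
    out_boxes = []
    for b in boxes:
        x1, y1, x2, y2 = b.to_xyxy(w, h)
        out_boxes.append(YoloBox.from_xyxy(
            x1 * r + ox, y1 * r + oy, x2 * r + ox, y2 * r + oy,
            size, size, b.class_id))
    return LabeledImage(image=canvas, boxes=out_boxes)


def export_augmented(manifest: dict, out_dir, copies_per_image: int = 1,
                     params: AugmentParams | None = None, seed: int = 0,
                     split: str = "train") -> int:
    """Offline counterpart of online augmentation: write `copies_per_image`
    augmented variants of one split into a new YOLO-layout directory.
    Returns the number of images written."""
    params = params or AugmentParams()
    out_dir = Path(out_dir)
    (out_dir / "images" / split).mkdir(parents=True, exist_ok=True)
    (out_dir / "labels" / split).mkdir(parents=True, exist_ok=True)
    samples = load_split(manifest, split)
    rng = np.random.default_rng(seed)
    n = 0
    for i, sample in enumerate(samples):
        for c in range(copies_per_image):
            aug = augment(sample, params, seed=int(rng.integers(2 ** 31)))
            stem = f"aug_{i:05d}_{c:02d}"
            Image.fromarray(aug.image).save(out_dir / "images" / split / f"{stem}.png")
            write_yolo_labels(aug.boxes, out_dir / "labels" / split / f"{stem}.txt")
            n += 1
    return n


# ---------------------------------------------------------------------
# manifests and directory layout
# ---------------------------------------------------------------------

def write_manifest(root, names, path=None) -> Path:
    root = Path(root)
    manifest = {
        "path": str(root),
        "train": "images/train",
        "val": "images/val",
        "test": "images/test",
        "names": list(names),
    }
    out = Path(path) if path else root / "data.yaml"
    out.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


def read_manifest(path) -> dict:
    manifest = yaml.safe_load(Path(path).read_text())
    for key in ("path", "train", "val", "names"):
        if key not in manifest:
            raise ValueError(f"manifest {path} missing required key {key!r}")
    return manifest


def load_split(manifest: dict, split: str) -> list:
    """Load (image, boxes) pairs for one split as LabeledImage objects."""
    root = Path(manifest["path"])
    img_dir = root / manifest[split]
    if not img_dir.is_dir():
        raise FileNotFoundError(f"split directory {img_dir} does not exist")
    samples = []
    for img_path in sorted(img_dir.glob("*.png")) + sorted(img_dir.glob("*.jpg")):
        lbl_path = root / "labels" / split / (img_path.stem + ".txt")
        boxes = read_yolo_labels(lbl_path) if lbl_path.exists() else []
        img = np.asarray(Image.open(img_path).convert("RGB"))
        samples.append(LabeledImage(image=img, boxes=boxes))
    return samples
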