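"""Reading the ChestX-ray14-style directory layout and preparing batches.

The on-disk dialect is the one the NIH release uses: a folder of PNG
radiographs, a label table mapping image name to pipe-separated finding
labels, a bounding-box table over the annotated subset, and plain-text
patient-level split lists (``train_val_list.txt`` / ``test_list.txt``).
The synthetic fixture writer (:mod:`camloc.synthetic`) emits the same
dialect, so one reader serves both real and fixture data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage as ndi
from skimage.transform import resize as _sk_resize

__all__ = [
    "NIH_CLASSES", "IMAGENET_MEAN", "IMAGENET_SD",
    "BoundingBox", "LabeledImage", "AugmentPolicy",
    "parse_label_table", "parse_bbox_table", "read_split_lists",
    "build_training_subsets", "augment_batch", "sample_crop_window",
    "load_image", "read_dataset",
]

#: The 14 thoracic finding classes, in the fixed order used throughout the
#: package (multi-hot slot c corresponds to NIH_CLASSES[c]).
NIH_CLASSES: tuple[str, ...] = (
    "Atelectasis", "Cardiomegaly", "Effusion", "Infiltration", "Mass",
    "Nodule", "Pneumonia", "Pneumothorax", "Consolidation", "Edema",
    "Emphysema", "Fibrosis", "Pleural_Thickening", "Hernia",
)

NO_FINDING = "No Finding"

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_SD = np.array([0.229, 0.224, 0.225])


class SchemaError(ValueError):
    """A table is missing required columns."""


class UnknownLabelError(ValueError):
    """A finding string is not in the class vocabulary."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, origin at the image's top-left corner.

    ``(x, y)`` is the top-left corner; ``h``/``w`` are height and width in
    pixels of the coordinate frame the box was annotated in (original image
    resolution unless stated otherwise).  Boxes are closed on the left/top
    edge and exclusive on the right/bottom edge.
    """

    x: float
    y: float
    h: float
    w: float

    def __post_init__(self):
        if self.h <= 0 or self.w <= 0:
            raise ValueError(f"box must have positive extent, got h={self.h}, w={self.w}")

    @property
    def x2(self) -> float:
        return self.x + self.w

    @property
    def y2(self) -> float:
        return self.y + self.h

    @property
    def area(self) -> float:
        return self.h * self.w

    def scaled(self, factor: float) -> "BoundingBox":
        return BoundingBox(self.x * factor, self.y * factor,
                           self.h * factor, self.w * factor)


@dataclass
class LabeledImage:
    """One grayscale radiograph with its image-level multi-hot labels and,
    for the annotated subset, ground-truth boxes."""

    image: np.ndarray                      # 2-D, values in [0, 1]
    labels: np.ndarray                     # (n_classes,) multi-hot
    patient_id: int
    name: str
    boxes: list[tuple[int, BoundingBox]] | None = None


@dataclass(frozen=True)
class AugmentPolicy:
    """Train-time augmentation: random area/aspect crop, horizontal flip and
    small rotation, then 3-channel replication and ImageNet normalization."""

    resize_to: int = 256
    crop_area_range: tuple[float, float] = (0.80, 1.00)
    crop_aspect_range: tuple[float, float] = (0.75, 1.733)
    hflip_prob: float = 0.5
    rotation_range_deg: tuple[float, float] = (-15.0, 15.0)
    normalize_mean: np.ndarray = field(default_factory=lambda: IMAGENET_MEAN.copy())
    normalize_sd: np.ndarray = field(default_factory=lambda: IMAGENET_SD.copy())

    def __post_init__(self):
        lo, hi = self.crop_area_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("crop_area_range must be within (0, 1]")
        alo, ahi = self.crop_aspect_range
        if alo <= 0 or ahi <= 0:
            raise ValueError("crop_aspect_range must be positive")


# ---------------------------------------------------------------------------
# table parsers
# ---------------------------------------------------------------------------

def _canonical(finding: str) -> str:
    return finding.strip().replace(" ", "_").lower()


def parse_label_table(path: str | Path,
                      class_names: Sequence[str] = NIH_CLASSES,
                      ) -> dict[str, np.ndarray]:
    """Parse the label table into ``name -> multi-hot vector``.

    Findings are pipe-separated; ``"No Finding"`` maps to the zero vector;
    any other string outside ``class_names`` raises :class:`UnknownLabelError`.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        name_col = cols["image index"]
        label_col = cols["finding labels"]
    except KeyError as e:
        raise SchemaError(f"label table {path} lacks required column: {e}") from None
    index = {_canonical(c): i for i, c in enumerate(class_names)}
    out: dict[str, np.ndarray] = {}
    for name, findings in zip(df[name_col], df[label_col]):
        vec = np.zeros(len(class_names), dtype=np.int8)
        for f in str(findings).split("|"):
            if _canonical(f) == _canonical(NO_FINDING):
                continue
            try:
                vec[index[_canonical(f)]] = 1
            except KeyError:
                raise UnknownLabelError(
                    f"unknown finding {f!r} for image {name!r}; "
                    f"known classes: {list(class_names)}") from None
        out[str(name)] = vec
    return out


def parse_patient_ids(path: str | Path) -> dict[str, int]:
    """Patient ID column of the label table (needed for patient-level splits)."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        return {str(n): int(p) for n, p in
                zip(df[cols["image index"]], df[cols["patient id"]])}
    except KeyError as e:
        raise SchemaError(f"label table {path} lacks required column: {e}") from None


def parse_bbox_table(path: str | Path,
                     class_names: Sequence[str] = NIH_CLASSES,
                     image_size: tuple[int, int] = (1024, 1024),
                     ) -> dict[str, list[tuple[int, BoundingBox]]]:
    """Parse the bounding-box table into ``name -> [(class_id, box), ...]``.

    Coordinate columns are resolved by header name where possible and
    otherwise taken positionally in the annotated order ``(x, y, h, w)``.
    Boxes are validated against ``image_size`` (height, width).
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        name_col = cols["image index"]
        label_col = cols["finding label"]
    except KeyError as e:
        raise SchemaError(f"bbox table {path} lacks required column: {e}") from None

    def find(token: str) -> str | None:
        for key, orig in cols.items():
            bare = key.strip("[] ").split("[")[-1].strip()
            if bare == token:
                return orig
        return None

    coord_cols = [find(t) for t in ("x", "y", "h", "w")]
    if any(c is None for c in coord_cols):
        numeric = [c for c in df.columns
                   if c not in (name_col, label_col)
                   and pd.api.types.is_numeric_dtype(df[c])]
        if len(numeric) < 4:
            raise SchemaError(f"bbox table {path}: cannot resolve x/y/h/w columns")
        coord_cols = numeric[:4]

    index = {_canonical(c): i for i, c in enumerate(class_names)}
    img_h, img_w = image_size
    out: dict[str, list[tuple[int, BoundingBox]]] = {}
    for row_i, row in df.iterrows():
        name = str(row[name_col])
        finding = _canonical(str(row[label_col]))
        if finding not in index:
            raise UnknownLabelError(f"row {row_i}: unknown finding {row[label_col]!r}")
        x, y, h, w = (float(row[c]) for c in coord_cols)
        if h <= 0 or w <= 0:
            raise ValueError(f"row {row_i}: non-positive box extent h={h}, w={w}")
        if x < 0 or y < 0 or x + w > img_w or y + h > img_h:
            raise ValueError(f"row {row_i}: box ({x},{y},{h},{w}) exceeds "
                             f"image bounds {image_size}")
        out.setdefault(name, []).append((index[finding], BoundingBox(x, y, h, w)))
    return out


def read_split_lists(root: str | Path) -> tuple[list[str], list[str]]:
    root = Path(root)
    read = lambda p: [ln.strip() for ln in p.read_text().splitlines() if ln.strip()]
    return read(root / "train_val_list.txt"), read(root / "test_list.txt")


# ---------------------------------------------------------------------------
# subset construction
# ---------------------------------------------------------------------------

def build_training_subsets(labels: Mapping[str, np.ndarray],
                           patient_ids: Mapping[str, int],
                           train_val_names: Sequence[str],
                           test_names: Sequence[str],
                           n_no_finding: int = 5000,
                           val_fraction: float = 0.20,
                           seed: int = 0,
                           ) -> tuple[list[str], list[str], list[str]]:
    """Build (train, val, test) image-name lists.

    The official test list is used unchanged.  From the train/val pool every
    diseased image is kept plus ``n_no_finding`` randomly sampled disease-free
    images (class-imbalance control); the pool is then split
    ``(1 - val_fraction) : val_fraction`` at the patient level.
    """
    rng = np.random.default_rng(seed)
    pool = [n for n in train_val_names]
    diseased = [n for n in pool if labels[n].any()]
    healthy = sorted(n for n in pool if not labels[n].any())
    if n_no_finding > len(healthy):
        warnings.warn(f"requested {n_no_finding} no-finding images but only "
                      f"{len(healthy)} available; clamping")
        n_no_finding = len(healthy)
    keep_healthy = list(rng.choice(healthy, size=n_no_finding, replace=False)) \
        if n_no_finding else []
    kept = diseased + [str(n) for n in keep_healthy]

    # patient-level split: shuffle patients, fill validation to its quota
    by_patient: dict[int, list[str]] = {}
    for n in kept:
        by_patient.setdefault(patient_ids[n], []).append(n)
    patients = sorted(by_patient)
    rng.shuffle(patients)
    n_val_target = int(round(val_fraction * len(kept)))
    val, train = [], []
    for p in patients:
        bucket = val if len(val) < n_val_target else train
        bucket.extend(sorted(by_patient[p]))
    return train, val, list(test_names)


# ---------------------------------------------------------------------------
# image loading and augmentation
# ---------------------------------------------------------------------------

def load_image(path: str | Path) -> np.ndarray:
    """Load an 8-bit grayscale PNG into a float array in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


def sample_crop_window(rng: np.random.Generator, height: int, width: int,
                       policy: AugmentPolicy) -> tuple[int, int, int, int]:
    """Sample a crop window ``(top, left, crop_h, crop_w)`` whose area fraction
    lies in ``crop_area_range`` and aspect ratio in ``crop_aspect_range``."""
    area = height * width
    for _ in range(20):
        frac = rng.uniform(*policy.crop_area_range)
        log_lo, log_hi = np.log(policy.crop_aspect_range)
        aspect = np.exp(rng.uniform(log_lo, log_hi))  # w / h
        ch = int(round(np.sqrt(frac * area / aspect)))
        cw = int(round(np.sqrt(frac * area * aspect)))
        if 0 < ch <= height and 0 < cw <= width:
            top = int(rng.integers(0, height - ch + 1))
            left = int(rng.integers(0, width - cw + 1))
            return top, left, ch, cw
    return 0, 0, height, width  # degenerate geometry: fall back to full frame


def _normalize_3ch(img: np.ndarray, policy: AugmentPolicy) -> np.ndarray:
    """Replicate a (H, W) grayscale image to 3 channels and apply the
    ImageNet channel statistics; returns (3, H, W)."""
    rgb = np.repeat(img[None], 3, axis=0)
    return (rgb - policy.normalize_mean[:, None, None]) / policy.normalize_sd[:, None, None]


def augment_batch(images: Sequence[LabeledImage] | Sequence[np.ndarray],
                  policy: AugmentPolicy,
                  training: bool,
                  seed: int = 0) -> np.ndarray:
    """Produce a normalized (N, 3, S, S) batch, S = ``policy.resize_to``.

    ``training=True`` applies random resized crop, horizontal flip and
    rotation; ``training=False`` is the deterministic resize-only transform.
    Labels are image-level and untouched by geometry.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((len(images), 3, policy.resize_to, policy.resize_to))
    for i, item in enumerate(images):
        img = item.image if isinstance(item, LabeledImage) else np.asarray(item)
        if training:
            top, left, ch, cw = sample_crop_window(rng, *img.shape, policy)
            img = img[top:top + ch, left:left + cw]
            img = _sk_resize(img, (policy.resize_to, policy.resize_to),
                             order=1, anti_aliasing=False)
            if rng.uniform() < policy.hflip_prob:
                img = img[:, ::-1]
            angle = rng.uniform(*policy.rotation_range_deg)
            img = ndi.rotate(img, angle, reshape=False, order=1, mode="constant")
        elif img.shape != (policy.resize_to, policy.resize_to):
            img = _sk_resize(img, (policy.resize_to, policy.resize_to),
                             order=1, anti_aliasing=False)
        out[i] = _normalize_3ch(np.clip(img, 0.0, 1.0), policy)
    return out


# ---------------------------------------------------------------------------
# whole-tree reader
# ---------------------------------------------------------------------------

def read_dataset(root: str | Path,
                 class_names: Sequence[str] = NIH_CLASSES,
                 ) -> tuple[list[LabeledImage], list[str], list[str]]:
    """Read a ChestX-ray14-style tree into memory.

    Returns ``(images, train_val_names, test_names)``.  Box annotations are
    attached to the images that have them; all others carry ``boxes=None``.
    """
    root = Path(root)
    labels = parse_label_table(root / "labels.csv", class_names)
    patients = parse_patient_ids(root / "labels.csv")
    probe = next(iter((root / "images").glob("*.png")))
    with Image.open(probe) as im:
        size = (im.height, im.width)
    bbox_path = root / "bbox.csv"
    boxes = parse_bbox_table(bbox_path, class_names, size) if bbox_path.exists() else {}
    items = []
    for name in sorted(labels):
        items.append(LabeledImage(
            image=load_image(root / "images" / name),
            labels=labels[name].copy(),
            patient_id=patients[name],
            name=name,
            boxes=boxes.get(name),
        ))
    train_val, test = read_split_lists(root)
    return items, train_val, test
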