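"""Synthetic chest-radiograph-like fixtures.

Renders grayscale images containing class-discriminative geometric "lesions"
(disk, ring, bar) over a smooth low-frequency background with Gaussian noise,
and writes them in the same directory dialect as the NIH ChestX-ray14
release (``images/*.png``, ``labels.csv``, ``bbox.csv``, patient-level split
lists).  The point is not radiographic realism — it is that every stage of
the pipeline (multi-label classification, CAM localization, PCM refinement,
IoBB scoring) can be exercised end-to-end offline, with exact knowledge of
the ground truth.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .dataset_io import BoundingBox

__all__ = ["LesionSpec", "SyntheticDataset", "generate_dataset",
           "write_fixture_tree", "default_specs"]

SHAPE_KINDS = ("disk", "ring", "bar")


@dataclass(frozen=True)
class LesionSpec:
    """Recipe for one lesion class.

    ``size_range`` bounds the side of the lesion's tight bounding box, in
    pixels; ``count_range`` bounds how many lesions a positive image carries.
    """

    class_id: int
    shape_kind: str
    intensity: float = 0.6
    size_range: tuple[int, int] = (10, 16)
    count_range: tuple[int, int] = (1, 2)

    def __post_init__(self):
        if self.shape_kind not in SHAPE_KINDS:
            raise ValueError(f"shape_kind must be one of {SHAPE_KINDS}")
        if not (0 < self.intensity <= 1):
            raise ValueError("intensity must be in (0, 1]")
        if self.size_range[0] < 3:
            raise ValueError("minimum lesion size is 3 px")
        if self.count_range[0] < 1 or self.count_range[1] < self.count_range[0]:
            raise ValueError("count_range must be a non-empty positive range")

    @property
    def name(self) -> str:
        return self.shape_kind.capitalize()


@dataclass
class SyntheticDataset:
    images: list[np.ndarray]
    labels: np.ndarray                    # (n_images, n_classes) multi-hot
    boxes: list[list[tuple[int, BoundingBox]]]
    patient_ids: list[int]
    class_names: list[str]
    seed: int
    image_side: int = field(default=0)

    def __post_init__(self):
        if not self.image_side and self.images:
            self.image_side = self.images[0].shape[0]

    @property
    def names(self) -> list[str]:
        return [f"synth_{i:05d}.png" for i in range(len(self.images))]


def default_specs(n_classes: int = 3) -> list[LesionSpec]:
    """One spec per geometric primitive, in class order disk, ring, bar."""
    base = [
        LesionSpec(0, "disk", intensity=0.6, size_range=(10, 16)),
        LesionSpec(1, "ring", intensity=0.6, size_range=(12, 18)),
        LesionSpec(2, "bar", intensity=0.6, size_range=(12, 18)),
    ]
    return base[:n_classes]


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _smooth_background(rng: np.random.Generator, side: int) -> np.ndarray:
    """Low-frequency background: a few random 2-D cosine modes around 0.35."""
    yy, xx = np.meshgrid(np.linspace(0, 1, side), np.linspace(0, 1, side),
                         indexing="ij")
    bg = np.full((side, side), 0.35)
    for _ in range(3):
        fy, fx = rng.uniform(0.5, 2.0, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.uniform(0.02, 0.08)
        bg += amp * np.cos(2 * np.pi * fy * yy + phase[0]) \
                  * np.cos(2 * np.pi * fx * xx + phase[1])
    return bg


def _render_lesion(img: np.ndarray, spec: LesionSpec,
                   rng: np.random.Generator) -> BoundingBox:
    """Draw one lesion in-place; return its tight bounding box."""
    side = img.shape[0]
    d = int(rng.integers(spec.size_range[0], spec.size_range[1] + 1))
    if spec.shape_kind == "bar":
        thick = max(3, d // 3)
        bh, bw = (thick, d) if rng.uniform() < 0.5 else (d, thick)
    else:
        bh = bw = d
    top = int(rng.integers(0, side - bh + 1))
    left = int(rng.integers(0, side - bw + 1))
    yy, xx = np.mgrid[0:bh, 0:bw]
    cy, cx = (bh - 1) / 2.0, (bw - 1) / 2.0
    if spec.shape_kind == "disk":
        r = (d - 1) / 2.0
        mask = ((yy - cy) ** 2 + (xx - cx) ** 2) <= r ** 2 + 1e-9
    elif spec.shape_kind == "ring":
        r = (d - 1) / 2.0
        rad2 = (yy - cy) ** 2 + (xx - cx) ** 2
        mask = (rad2 <= r ** 2 + 1e-9) & (rad2 >= (0.55 * r) ** 2)
    else:  # bar
        mask = np.ones((bh, bw), dtype=bool)
    patch = img[top:top + bh, left:left + bw]
    patch[mask] = np.clip(patch[mask] + spec.intensity, 0.0, 1.0)
    return BoundingBox(x=left, y=top, h=bh, w=bw)


def generate_dataset(n_images: int,
                     image_side: int,
                     specs: Sequence[LesionSpec],
                     background_noise_sd: float = 0.05,
                     no_finding_fraction: float = 0.25,
                     seed: int = 0,
                     label_only_fraction: float = 0.0,
                     images_per_patient: int = 2) -> SyntheticDataset:
    """Generate a deterministic synthetic dataset.

    Approximately ``no_finding_fraction`` of images carry no lesion (all-zero
    label row); the rest carry 1–3 positive classes, each rendered
    ``count_range`` times.  ``label_only_fraction`` of positive images keep
    their labels but drop their recorded boxes, mirroring real collections
    where only a small subset of images is box-annotated.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if image_side < 32:
        raise ValueError("image_side must be >= 32")
    if not 0 <= no_finding_fraction <= 1:
        raise ValueError("no_finding_fraction must be in [0, 1]")
    kinds = [s.shape_kind for s in specs]
    ids = [s.class_id for s in specs]
    if len(set(kinds)) != len(kinds) or len(set(ids)) != len(ids):
        raise ValueError("specs must use distinct class_ids and shape_kinds")
    for s in specs:
        if s.size_range[1] > image_side // 2:
            raise ValueError(f"lesion size {s.size_range[1]} exceeds "
                             f"image_side/2 = {image_side // 2}")

    rng = np.random.default_rng(seed)
    by_id = {s.class_id: s for s in specs}
    n_classes = len(specs)
    images: list[np.ndarray] = []
    labels = np.zeros((n_images, n_classes), dtype=np.int8)
    boxes: list[list[tuple[int, BoundingBox]]] = []
    for i in range(n_images):
        img = _smooth_background(rng, image_side)
        img_boxes: list[tuple[int, BoundingBox]] = []
        if rng.uniform() >= no_finding_fraction:
            k = int(rng.integers(1, min(3, n_classes) + 1))
            chosen = rng.choice(sorted(by_id), size=k, replace=False)
            for cid in sorted(int(c) for c in chosen):
                spec = by_id[cid]
                count = int(rng.integers(spec.count_range[0],
                                         spec.count_range[1] + 1))
                for _ in range(count):
                    img_boxes.append((cid, _render_lesion(img, spec, rng)))
                labels[i, cid] = 1
            if label_only_fraction and rng.uniform() < label_only_fraction:
                img_boxes = []            # annotated labels, no recorded boxes
        img += rng.normal(0.0, background_noise_sd, img.shape)
        images.append(np.clip(img, 0.0, 1.0))
        boxes.append(img_boxes)

    return SyntheticDataset(
        images=images, labels=labels, boxes=boxes,
        patient_ids=[i // images_per_patient for i in range(n_images)],
        class_names=[by_id[c].name for c in sorted(by_id)],
        seed=seed, image_side=image_side,
    )


# ---------------------------------------------------------------------------
# fixture tree writer
# ---------------------------------------------------------------------------

def write_fixture_tree(ds: SyntheticDataset, root_dir: str | Path,
                       test_fraction: float = 0.2,
                       overwrite: bool = False) -> Path:
    """Write ``ds`` in the NIH directory dialect.

    Produces ``images/*.png`` (8-bit grayscale), ``labels.csv`` with columns
    (Image Index, Finding Labels, Patient ID), ``bbox.csv`` with columns
    (Image Index, Finding Label, x, y, h, w) and patient-level split lists.
    Refuses to write into a non-empty directory unless ``overwrite``.
    """
    root = Path(root_dir)
    if root.exists() and any(root.iterdir()):
        if not overwrite:
            raise FileExistsError(f"{root} is not empty; pass overwrite=True")
        shutil.rmtree(root)
    (root / "images").mkdir(parents=True, exist_ok=True)

    names = ds.names
    for name, img in zip(names, ds.images):
        arr = np.rint(np.clip(img, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(root / "images" / name)

    rows = []
    for name, lab, pid in zip(names, ds.labels, ds.patient_ids):
        findings = "|".join(ds.class_names[c] for c in np.flatnonzero(lab)) \
                   or "No Finding"
        rows.append((name, findings, pid))
    pd.DataFrame(rows, columns=["Image Index", "Finding Labels", "Patient ID"]) \
        .to_csv(root / "labels.csv", index=False)

    brows = []
    for name, img_boxes in zip(names, ds.boxes):
        for cid, b in img_boxes:
            brows.append((name, ds.class_names[cid], b.x, b.y, b.h, b.w))
    pd.DataFrame(brows, columns=["Image Index", "Finding Label",
                                 "x", "y", "h", "w"]) \
        .to_csv(root / "bbox.csv", index=False)

    # patient-level split: first (1 - test_fraction) of shuffled patients train
    rng = np.random.default_rng(ds.seed + 1)
    patients = sorted(set(ds.patient_ids))
    rng.shuffle(patients)
    n_test_patients = int(round(test_fraction * len(patients)))
    test_patients = set(patients[:n_test_patients])
    train_val = [n for n, p in zip(names, ds.patient_ids) if p not in test_patients]
    test = [n for n, p in zip(names, ds.patient_ids) if p in test_patients]
    (root / "train_val_list.txt").write_text("\n".join(train_val) + "\n")
    (root / "test_list.txt").write_text("\n".join(test) + "\n")
    return root
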