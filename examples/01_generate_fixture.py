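"""Generate a synthetic chest-X-ray-style fixture tree and read it back.

Renders 100 grayscale images (64 px) with disk/ring/bar "lesions", writes
them in the NIH ChestX-ray14 directory dialect (images/, labels.csv,
bbox.csv, patient-level split lists), and verifies the round trip.
"""

import tempfile
from pathlib import Path

import numpy as np

from camloc import generate_dataset, read_dataset, write_fixture_tree
from camloc.synthetic import default_specs

ds = generate_dataset(n_images=100, image_side=64, specs=default_specs(3),
                      no_finding_fraction=0.25, seed=7)
root = write_fixture_tree(ds, Path(tempfile.mkdtemp()) / "fixture")
items, train_val, test = read_dataset(root, class_names=ds.class_names)

print(f"wrote {len(items)} images to {root}")
print(f"class names: {ds.class_names}")
print(f"per-class positives: {ds.labels.sum(axis=0).tolist()}")
print(f"images with boxes: {sum(1 for it in items if it.boxes)}")
print(f"train/val pool: {len(train_val)}  official test: {len(test)}")
pid = {it.name: it.patient_id for it in items}
overlap = {pid[n] for n in train_val} & {pid[n] for n in test}
print(f"patients in both splits (must be 0): {len(overlap)}")
# Interpretation: labels are image-level multi-hot vectors; every box's class
# is positive in its image's label vector; splits never share a patient.
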