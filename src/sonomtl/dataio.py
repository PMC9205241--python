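"""Dataset records, manifest/VOC-XML I/O and patient-level splitting.

Labels follow the clinical hierarchy of the problem: a lesion with
axillary lymph-node metastasis (``alnm=1``) is necessarily malignant
(``bm=1``), and the metastatic node count is positive exactly when
``alnm=1``.  Benign lesions carry ``alnm_defined=False`` because nodal
status is not a meaningful supervision target for them.

Bounding boxes use 0-based, half-open pixel coordinates
``(x0, y0, x1, y1)`` with ``x0 < x1`` and ``y0 < y1``.  VOC XML files
written by annotation tools that use 1-based inclusive coordinates can
be converted on load with ``voc_one_based=True``.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from sonomtl.errors import DataError, SplitError

MANIFEST_COLUMNS = ["image_id", "patient_id", "bm", "alnm", "alnm_defined", "node_count"]

Box = tuple[int, int, int, int]


@dataclass
class ImageRecord:
    """One annotated lesion image with its hierarchical labels."""

    image_id: str
    patient_id: str
    pixels: np.ndarray  # 2-D uint8 array
    box: Box  # (x0, y0, x1, y1), 0-based half-open
    bm: int
    alnm: int
    alnm_defined: bool
    node_count: int
    split: str = "unassigned"

    def validate(self) -> "ImageRecord":
        if self.bm not in (0, 1) or self.alnm not in (0, 1):
            raise DataError(f"{self.image_id}: labels must be binary, got bm={self.bm} alnm={self.alnm}")
        if self.alnm == 1 and self.bm == 0:
            raise DataError(f"{self.image_id}: alnm=1 with bm=0 violates the label hierarchy")
        if (not self.alnm_defined) and self.bm == 1:
            raise DataError(f"{self.image_id}: malignant record must have alnm_defined=True")
        if (self.node_count >= 1) != (self.alnm == 1):
            raise DataError(
                f"{self.image_id}: node_count={self.node_count} inconsistent with alnm={self.alnm}"
            )
        if self.pixels.ndim != 2:
            raise DataError(f"{self.image_id}: pixels must be a 2-D grayscale array")
        h, w = self.pixels.shape
        x0, y0, x1, y1 = self.box
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise DataError(f"{self.image_id}: box {self.box} invalid for image of size {w}x{h}")
        return self


@dataclass
class SplitAssignment:
    """Patient-level train/val/test partition parameters.

    The test set takes ``ceil(n_patients * test_fraction)`` patients
    (ties broken toward test), reproducing a 640/1491 split of 2131
    patients at the default 30%.  The remaining patients are divided
    into train and validation by ``val_fraction_of_trainval``.
    """

    test_fraction: float = 0.3
    val_fraction_of_trainval: float = 0.2
    seed: int = 0
    mapping: dict[str, str] = field(default_factory=dict)

    def validate(self) -> "SplitAssignment":
        if not (0.0 < self.test_fraction < 1.0):
            raise SplitError(f"test_fraction must be in (0,1), got {self.test_fraction}")
        if not (0.0 <= self.val_fraction_of_trainval < 1.0):
            raise SplitError(
                f"val_fraction_of_trainval must be in [0,1), got {self.val_fraction_of_trainval}"
            )
        return self


def split_counts(n_patients: int, test_fraction: float = 0.3,
                 val_fraction_of_trainval: float = 0.2) -> tuple[int, int, int]:
    """Return (n_train, n_val, n_test) patient counts for the split rule."""
    n_test = math.ceil(n_patients * test_fraction - 1e-12)
    n_trainval = n_patients - n_test
    n_val = math.ceil(n_trainval * val_fraction_of_trainval - 1e-12)
    return n_trainval - n_val, n_val, n_test


def assign_patients(patient_ids: list[str], cfg: SplitAssignment) -> dict[str, str]:
    """Deterministically assign each patient to train/val/test.

    A pure function of the sorted patient IDs and the seed: the order in
    which records were produced has no influence.
    """
    cfg.validate()
    patients = sorted(set(patient_ids))
    if len(patients) < 3:
        raise SplitError(f"need at least 3 patients to split, got {len(patients)}")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(patients))
    n_train, n_val, n_test = split_counts(
        len(patients), cfg.test_fraction, cfg.val_fraction_of_trainval
    )
    mapping: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_test:
            part = "test"
        elif rank < n_test + n_val:
            part = "val"
        else:
            part = "train"
        mapping[patients[idx]] = part
    return mapping


def split_by_patient(records: list[ImageRecord], cfg: SplitAssignment) -> list[ImageRecord]:
    """Assign a split to every record such that no patient straddles splits."""
    if not records:
        raise SplitError("cannot split an empty record list")
    mapping = assign_patients([r.patient_id for r in records], cfg)
    cfg.mapping = mapping
    out = [replace(r, split=mapping[r.patient_id]) for r in records]
    _assert_group_integrity(out)
    return out


def _assert_group_integrity(records: list[ImageRecord]) -> None:
    parts: dict[str, set[str]] = {}
    for r in records:
        parts.setdefault(r.patient_id, set()).add(r.split)
    bad = {p: s for p, s in parts.items() if len(s) > 1}
    if bad:
        raise SplitError(f"patients straddle splits: {sorted(bad)[:5]}")


# ---------------------------------------------------------------------------
# VOC XML and manifest I/O


def write_voc_xml(path: Path, image_id: str, shape: tuple[int, int], box: Box) -> None:
    """Write a Pascal-VOC-style annotation (0-based, half-open box)."""
    h, w = shape
    x0, y0, x1, y1 = box
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = f"{image_id}.png"
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "1"
    obj = ET.SubElement(root, "object")
    ET.SubElement(obj, "name").text = "lesion"
    bnd = ET.SubElement(obj, "bndbox")
    ET.SubElement(bnd, "xmin").text = str(x0)
    ET.SubElement(bnd, "ymin").text = str(y0)
    ET.SubElement(bnd, "xmax").text = str(x1)
    ET.SubElement(bnd, "ymax").text = str(y1)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_voc_xml(path: Path, voc_one_based: bool = False) -> Box:
    """Read the first object's bounding box from a VOC XML file.

    With ``voc_one_based=True`` the stored 1-based inclusive coordinates
    are converted to the internal 0-based half-open convention.
    """
    root = ET.parse(path).getroot()
    bnd = root.find("./object/bndbox")
    if bnd is None:
        raise DataError(f"{path}: no object/bndbox element")
    x0 = int(float(bnd.findtext("xmin")))
    y0 = int(float(bnd.findtext("ymin")))
    x1 = int(float(bnd.findtext("xmax")))
    y1 = int(float(bnd.findtext("ymax")))
    if voc_one_based:
        x0, y0 = x0 - 1, y0 - 1
    if x1 <= x0 or y1 <= y0:
        raise DataError(f"{path}: degenerate box ({x0},{y0},{x1},{y1})")
    return (x0, y0, x1, y1)


def load_dataset(manifest_path: str | Path, image_root: str | Path | None = None,
                 voc_one_based: bool = False) -> list[ImageRecord]:
    """Load records from a manifest CSV plus per-image PNG and VOC XML files.

    The manifest schema is ``image_id,patient_id,bm,alnm,alnm_defined,
    node_count``; images live under ``<root>/images/<image_id>.png`` and
    annotations under ``<root>/annotations/<image_id>.xml``.
    """
    manifest_path = Path(manifest_path)
    root = Path(image_root) if image_root is not None else manifest_path.parent
    if not manifest_path.exists():
        raise DataError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        image_id = str(row["image_id"])
        png = root / "images" / f"{image_id}.png"
        xml = root / "annotations" / f"{image_id}.xml"
        for p in (png, xml):
            if not p.exists():
                raise DataError(f"manifest row {i} ({image_id}): missing file {p}")
        pixels = np.asarray(Image.open(png).convert("L"))
        box = read_voc_xml(xml, voc_one_based=voc_one_based)
        rec = ImageRecord(
            image_id=image_id,
            patient_id=str(row["patient_id"]),
            pixels=pixels,
            box=box,
            bm=int(row["bm"]),
            alnm=int(row["alnm"]),
            alnm_defined=bool(row["alnm_defined"]),
            node_count=int(row["node_count"]),
        )
        try:
            rec.validate()
        except DataError as exc:
            raise DataError(f"manifest row {i}: {exc}") from exc
        records.append(rec)
    return records
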