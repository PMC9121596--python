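"""Labeled WBC image dataset I/O.

Datasets live on disk as one subdirectory per class under a root directory,
``<root>/<class_name>/<file>``, with 8-bit RGB images (PNG, JPEG or TIFF).
The five-class vocabulary is fixed in the order
[neutrophil, eosinophil, basophil, lymphocyte, monocyte]; index i always
means the same class everywhere in the package.  Subdirectories may use the
full lowercase names or the standard hematology abbreviations
NE/EO/BA/LY/MO.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "CLASS_NAMES",
    "CLASS_ALIASES",
    "ImageRecord",
    "LabeledDataset",
    "load_dataset",
    "save_images",
    "write_report",
    "read_report",
]

#: Fixed class order used throughout the package.
CLASS_NAMES = ("neutrophil", "eosinophil", "basophil", "lymphocyte", "monocyte")

#: Accepted directory-name aliases (tables in the field use the short forms).
CLASS_ALIASES = {
    "ne": "neutrophil", "eo": "eosinophil", "ba": "basophil",
    "ly": "lymphocyte", "mo": "monocyte",
}

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def canonical_class(name: str) -> str:
    """Map a class name or NE/EO/BA/LY/MO alias to the canonical name."""
    low = name.lower()
    if low in CLASS_NAMES:
        return low
    if low in CLASS_ALIASES:
        return CLASS_ALIASES[low]
    raise ValueError(f"unknown class name {name!r}")


@dataclass
class ImageRecord:
    """One image with an optional class label.

    ``pixels`` is height x width x 3: integer 0-255 when raw, float in
    [0, 1] after normalization.
    """

    pixels: np.ndarray
    label: str | None = None
    source_path: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"pixels must be HxWx3, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if self.label is not None:
            self.label = canonical_class(self.label)
        if np.issubdtype(self.pixels.dtype, np.integer):
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("raw integer intensities must be in [0, 255]")


@dataclass
class LabeledDataset:
    """Ordered collection of ImageRecords over the fixed 5-class vocabulary."""

    records: list[ImageRecord] = field(default_factory=list)
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        if tuple(self.class_names) != CLASS_NAMES:
            raise ValueError(f"class_names must be {CLASS_NAMES}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def counts(self) -> dict[str, int]:
        tally = {c: 0 for c in self.class_names}
        for rec in self.records:
            if rec.label is None:
                raise ValueError("dataset contains an unlabeled record")
            tally[rec.label] += 1
        return tally

    def labels(self) -> list[str]:
        return [rec.label for rec in self.records]

    def label_indices(self) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.class_names)}
        return np.array([index[rec.label] for rec in self.records], dtype=np.int64)

    def pixel_stack(self) -> np.ndarray:
        """All images stacked as N x H x W x 3 (requires uniform shapes)."""
        return np.stack([rec.pixels for rec in self.records])

    def subset(self, indices) -> "LabeledDataset":
        return LabeledDataset([self.records[i] for i in indices])

    def restrict_to_class(self, class_name: str) -> "LabeledDataset":
        c = canonical_class(class_name)
        return LabeledDataset([r for r in self.records if r.label == c])


def _class_dir(root: Path, class_name: str) -> Path | None:
    for candidate in (class_name,) + tuple(
            a for a, full in CLASS_ALIASES.items() if full == class_name):
        for variant in (candidate, candidate.upper(), candidate.capitalize()):
            d = root / variant
            if d.is_dir():
                return d
    return None


def load_dataset(root_dir, expected_size: tuple[int, int] | None = None
                 ) -> LabeledDataset:
    """Load a class-per-subdirectory image tree.

    Records are ordered by (class order, filename).  ``expected_size`` is
    (height, width); any mismatch raises a ValueError naming the file.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    records: list[ImageRecord] = []
    for cname in CLASS_NAMES:
        cdir = _class_dir(root, cname)
        if cdir is None:
            raise FileNotFoundError(
                f"missing class subdirectory for {cname!r} under {root}")
        files = sorted(p for p in cdir.iterdir()
                       if p.suffix.lower() in _IMAGE_SUFFIXES)
        for path in files:
            try:
                with Image.open(path) as im:
                    arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
            except Exception as exc:
                raise ValueError(f"cannot decode image file {path}") from exc
            if expected_size is not None and arr.shape[:2] != tuple(expected_size):
                raise ValueError(
                    f"image {path} has size {arr.shape[:2]}, expected "
                    f"{tuple(expected_size)}")
            records.append(ImageRecord(arr, label=cname, source_path=str(path)))
    return LabeledDataset(records)


def save_images(dataset: LabeledDataset, out_dir, format: str = "png") -> int:
    """Write one file per record under class subdirectories; returns the count.

    PNG round-trips are lossless for 8-bit data; JPEG only preserves counts.
    Float images in [0, 1] are scaled to 0-255 on write.
    """
    fmt = format.lower()
    if fmt not in ("png", "jpeg"):
        raise ValueError("format must be 'png' or 'jpeg'")
    out = Path(out_dir)
    n_written = 0
    per_class: dict[str, int] = {c: 0 for c in CLASS_NAMES}
    for rec in dataset.records:
        if rec.label is None:
            raise ValueError("cannot save an unlabeled record into a class tree")
        cdir = out / rec.label
        cdir.mkdir(parents=True, exist_ok=True)
        arr = rec.pixels
        if not np.issubdtype(arr.dtype, np.integer):
            arr = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
        else:
            arr = arr.astype(np.uint8)
        idx = per_class[rec.label]
        per_class[rec.label] += 1
        suffix = "png" if fmt == "png" else "jpg"
        path = cdir / f"{rec.label}_{idx:05d}.{suffix}"
        Image.fromarray(arr).save(path, format=fmt.upper())
        n_written += 1
    for cname in CLASS_NAMES:  # keep empty classes loadable
        (out / cname).mkdir(parents=True, exist_ok=True)
    return n_written


def _flatten_report(report) -> dict:
    if isinstance(report, np.ndarray):
        return {"array": report.tolist()}
    return report


def write_report(report, path, format: str | None = None) -> None:
    """Persist a metrics object (dict / nested dict / array) as JSON or CSV.

    Round-trip through :func:`read_report` preserves values to 1e-12.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("json", "csv"):
        raise ValueError("format must be 'json' or 'csv'")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(f"not serializable: {type(o)}")
        path.write_text(json.dumps(report, indent=2, default=default) + "\n")
        return
    # CSV: either a 2-D array-like (header = column indices) or a flat dict.
    arr = np.asarray(report) if not isinstance(report, dict) else None
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        if arr is not None:
            arr = np.atleast_2d(arr)
            writer.writerow([f"c{j}" for j in range(arr.shape[1])])
            writer.writerows(arr.tolist())
        else:
            writer.writerow(["key", "value"])
            for k, v in report.items():
                writer.writerow([k, repr(float(v)) if isinstance(
                    v, (int, float, np.floating, np.integer)) else json.dumps(v)])


def read_report(path, format: str | None = None):
    """Reload a report written by :func:`write_report`."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        return json.loads(path.read_text())
    with path.open() as fh:
        rows = list(csv.reader(fh))
    header, body = rows[0], rows[1:]
    if header[:2] == ["key", "value"]:
        out = {}
        for k, v in body:
            try:
                out[k] = float(v)
            except ValueError:
                out[k] = json.loads(v)
        return out
    return np.array([[float(x) for x in row] for row in body])
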