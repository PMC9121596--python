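"""Procedural synthetic white-blood-cell image generator.

Renders five visually distinct cell classes on a pale blood-smear
background using simple geometry (ellipses for nuclei, random disks for
granules), at the raw device size of 361 x 360 x 3 (height x width).  The
morphology follows the standard Wright-Giemsa appearance of each type:

* neutrophil  - 3-5 small violet nucleus lobes, pale pink cytoplasm
* eosinophil  - 2 lobes plus coarse bright red-orange granules
* basophil    - dense dark purple granules obscuring the nucleus
* lymphocyte  - single large round dark nucleus with a thin blue rim
* monocyte    - large cell, kidney-shaped (indented) nucleus

This is a test fixture, not a smear simulator: classes are separable by
color and simple shape statistics by construction, so classifiers trained
on it have real signal to learn.  The default class mix is the imbalanced
30/20/6/26/18% distribution typical of curated WBC image datasets.

Determinism: ``render_cell`` is a pure function of (class, seed, size);
``generate_dataset`` derives the seed of record i of class c from the
master seed as ``SeedSequence([master_seed, c, i])`` (documented counter
scheme), so any single record can be re-rendered in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk as _draw_disk

from .dataset_io import (CLASS_NAMES, ImageRecord, LabeledDataset,
                         canonical_class)

__all__ = ["SyntheticConfig", "DEFAULT_CLASS_STYLES", "render_cell",
           "generate_dataset", "default_counts"]

RAW_HEIGHT = 361
RAW_WIDTH = 360

#: Table-2-style class proportions (percent).
CLASS_PERCENTAGES = {"neutrophil": 30, "eosinophil": 20, "basophil": 6,
                     "lymphocyte": 26, "monocyte": 18}

BACKGROUND = (236, 222, 228)  # pale smear pink

#: Per-class rendering parameters: cytoplasm / nucleus colors (RGB),
#: cell radius range (px), nucleus lobe count range, granule spec.
DEFAULT_CLASS_STYLES = {
    "neutrophil": dict(cytoplasm=(224, 202, 222), nucleus=(92, 62, 132),
                       radius=(88, 108), lobes=(3, 5), lobe_radius=(16, 23),
                       granules=None),
    "eosinophil": dict(cytoplasm=(242, 180, 140), nucleus=(84, 56, 124),
                       radius=(88, 108), lobes=(2, 2), lobe_radius=(26, 32),
                       granules=dict(color=(225, 105, 60), count=420,
                                     radius=(2, 4))),
    "basophil": dict(cytoplasm=(150, 120, 178), nucleus=(70, 48, 120),
                     radius=(82, 100), lobes=(1, 2), lobe_radius=(30, 38),
                     granules=dict(color=(52, 34, 96), count=420,
                                   radius=(3, 6))),
    "lymphocyte": dict(cytoplasm=(140, 178, 235), nucleus=(58, 44, 146),
                       radius=(68, 84), lobes=(1, 1), lobe_radius=None,
                       granules=None),
    "monocyte": dict(cytoplasm=(200, 196, 200), nucleus=(126, 100, 150),
                     radius=(104, 124), lobes=(1, 1), lobe_radius=None,
                     granules=None),
}


@dataclass
class SyntheticConfig:
    """Configuration for :func:`generate_dataset`."""

    counts: dict[str, int] = field(default_factory=lambda: default_counts(100))
    image_height: int = RAW_HEIGHT
    image_width: int = RAW_WIDTH
    seed: int = 0
    background_color: tuple[int, int, int] = BACKGROUND
    class_styles: dict = field(
        default_factory=lambda: {c: dict(s) for c, s in
                                 DEFAULT_CLASS_STYLES.items()})

    def __post_init__(self):
        self.counts = {canonical_class(c): int(n) for c, n in self.counts.items()}
        for c in CLASS_NAMES:
            self.counts.setdefault(c, 0)
            if self.counts[c] < 0:
                raise ValueError(f"negative count for class {c}")
            if c not in self.class_styles:
                raise ValueError(f"missing style for class {c}")
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("image dimensions must be positive")


def default_counts(total: int = 100) -> dict[str, int]:
    """Per-class counts proportional to the 30/20/6/26/18% distribution."""
    return {c: round(total * p / 100) for c, p in CLASS_PERCENTAGES.items()}


def _ellipse_mask(h, w, cy, cx, ry, rx, angle=0.0):
    yy, xx = np.mgrid[0:h, 0:w]
    y, x = yy - cy, xx - cx
    if angle:
        ca, sa = np.cos(angle), np.sin(angle)
        y, x = ca * y - sa * x, sa * y + ca * x
    return (y / ry) ** 2 + (x / rx) ** 2 <= 1.0


def _paint(img, mask, color):
    img[mask] = color


def _scatter_granules(img, rng, cell_mask, spec, h, w):
    color = np.array(spec["color"], dtype=np.float64)
    ys, xs = np.nonzero(cell_mask)
    if len(ys) == 0:
        return
    picks = rng.integers(0, len(ys), size=spec["count"])
    radii = rng.integers(spec["radius"][0], spec["radius"][1] + 1,
                         size=spec["count"])
    for p, r in zip(picks, radii):
        rr, cc = _draw_disk((ys[p], xs[p]), int(r), shape=(h, w))
        img[rr, cc] = color


def render_cell(class_label: str, seed: int, height: int = RAW_HEIGHT,
                width: int = RAW_WIDTH, *, style: dict | None = None,
                background=BACKGROUND) -> ImageRecord:
    """Render one centered cell of the given class; deterministic per (class, seed)."""
    label = canonical_class(class_label)
    st = style if style is not None else DEFAULT_CLASS_STYLES[label]
    rng = np.random.default_rng(
        np.random.SeedSequence([CLASS_NAMES.index(label), int(seed) & 0x7FFFFFFF]))
    h, w = int(height), int(width)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = background

    scale = min(h, w) / min(RAW_HEIGHT, RAW_WIDTH)  # styles are tuned at raw size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r_lo, r_hi = st["radius"]
    radius = rng.uniform(r_lo, r_hi) * scale
    squash = rng.uniform(0.88, 1.0)
    cell = _ellipse_mask(h, w, cy, cx, radius * squash, radius,
                         angle=rng.uniform(0, np.pi))
    _paint(img, cell, st["cytoplasm"])

    if st["granules"] is not None:
        spec = dict(st["granules"])
        spec["count"] = max(1, int(spec["count"] * scale * scale))
        _scatter_granules(img, rng, cell, spec, h, w)

    nucleus_color = np.array(st["nucleus"], dtype=np.float64)
    n_lo, n_hi = st["lobes"]
    n_lobes = int(rng.integers(n_lo, n_hi + 1))
    if label == "lymphocyte":
        nr = radius * rng.uniform(0.72, 0.82)
        _paint(img, _ellipse_mask(h, w, cy, cx, nr, nr * rng.uniform(0.9, 1.0)),
               nucleus_color)
    elif label == "monocyte":
        nr = radius * rng.uniform(0.62, 0.72)
        ang = rng.uniform(0, 2 * np.pi)
        nuc = _ellipse_mask(h, w, cy, cx, nr, nr * rng.uniform(0.85, 1.0))
        # kidney shape: carve an offset notch out of the nucleus
        off = nr * rng.uniform(0.75, 0.95)
        notch = _ellipse_mask(h, w, cy + off * np.sin(ang), cx + off * np.cos(ang),
                              nr * 0.75, nr * 0.75)
        _paint(img, nuc & ~notch, nucleus_color)
    else:
        lr_lo, lr_hi = st["lobe_radius"]
        ring = radius * rng.uniform(0.38, 0.55)
        base = rng.uniform(0, 2 * np.pi)
        for i in range(n_lobes):
            ang = base + 2 * np.pi * i / n_lobes + rng.uniform(-0.25, 0.25)
            lr = rng.uniform(lr_lo, lr_hi) * scale
            ly = cy + ring * np.sin(ang)
            lx = cx + ring * np.cos(ang)
            _paint(img, _ellipse_mask(h, w, ly, lx, lr,
                                      lr * rng.uniform(0.8, 1.0),
                                      angle=rng.uniform(0, np.pi)),
                   nucleus_color)
        if label == "basophil":  # granules sit on top of everything
            _scatter_granules(img, rng, cell, st["granules"], h, w)

    img += rng.normal(0.0, 3.0, size=img.shape)  # sensor-like texture noise
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return ImageRecord(pixels, label=label,
                       source_path=f"synthetic://{label}/{int(seed)}")


def generate_dataset(config: SyntheticConfig) -> LabeledDataset:
    """Generate a labeled dataset per the config; reproducible from its seed."""
    records = []
    for ci, cname in enumerate(CLASS_NAMES):
        for i in range(config.counts[cname]):
            child = np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, ci, i])
            rec_seed = int(child.generate_state(1)[0]) & 0x7FFFFFFF
            records.append(render_cell(
                cname, rec_seed, config.image_height, config.image_width,
                style=config.class_styles[cname],
                background=config.background_color))
    return LabeledDataset(records)
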