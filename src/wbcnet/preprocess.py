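"""Image pre-processing: border crop, bilinear resize, min-max normalization.

The standard pipeline for the raw 361 x 360 x 3 device images removes the
top 80, bottom 81, left 80 and right 80 pixel borders (giving 200 x 200 x 3),
resizes to 128 x 128 x 3 and rescales intensities to [0, 1].

Conventions fixed for bit-exact reproducibility:

* Crop is exact sub-array extraction; row 0 is the top of the image and all
  extents are half-open pixel index ranges.
* Resize is bilinear with the align-corners-false convention: output pixel i
  samples source coordinate (i + 0.5) * in/out - 0.5, clipped to the valid
  range.  Per-channel output values stay within the input value bounds.
* Normalization is per-image global min-max, out = (in - min) / (max - min);
  a constant image maps to all zeros.  Alternative modes (per-channel
  min-max, fixed /255) are available behind the ``mode`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import ImageRecord, LabeledDataset

__all__ = ["CropSpec", "crop_borders", "resize_bilinear", "normalize_image",
           "preprocess_pipeline", "TARGET_SIZE"]

TARGET_SIZE = (128, 128)


@dataclass(frozen=True)
class CropSpec:
    """Border margins, in pixels, to remove from each side."""

    top: int = 80
    bottom: int = 81
    left: int = 80
    right: int = 80

    def __post_init__(self):
        if min(self.top, self.bottom, self.left, self.right) < 0:
            raise ValueError("crop margins must be nonnegative")

    def validate_for(self, height: int, width: int) -> None:
        if self.top + self.bottom >= height:
            raise ValueError(
                f"vertical margins {self.top}+{self.bottom} exceed height {height}")
        if self.left + self.right >= width:
            raise ValueError(
                f"horizontal margins {self.left}+{self.right} exceed width {width}")


def crop_borders(image: ImageRecord, spec: CropSpec = CropSpec()) -> ImageRecord:
    """Remove border margins; pure sub-array extraction, label preserved."""
    h, w = image.pixels.shape[:2]
    spec.validate_for(h, w)
    out = image.pixels[spec.top:h - spec.bottom, spec.left:w - spec.right]
    return ImageRecord(out.copy(), label=image.label,
                       source_path=image.source_path)


def _linear_coords(n_in: int, n_out: int):
    """Bilinear sample positions, align-corners-false."""
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    lo = np.floor(src).astype(np.intp)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    return lo, hi, frac


def resize_bilinear(image: ImageRecord, out_height: int, out_width: int
                    ) -> ImageRecord:
    """Separable bilinear resize to (out_height, out_width); float output."""
    if out_height < 1 or out_width < 1:
        raise ValueError("target dimensions must be positive")
    arr = image.pixels.astype(np.float64)
    h, w = arr.shape[:2]
    rlo, rhi, rf = _linear_coords(h, out_height)
    clo, chi, cf = _linear_coords(w, out_width)
    rows = arr[rlo] * (1.0 - rf)[:, None, None] + arr[rhi] * rf[:, None, None]
    out = (rows[:, clo] * (1.0 - cf)[None, :, None]
           + rows[:, chi] * cf[None, :, None])
    return ImageRecord(out, label=image.label, source_path=image.source_path)


def normalize_image(image: ImageRecord, mode: str = "minmax") -> ImageRecord:
    """Rescale intensities to [0, 1].

    ``minmax`` (default): global per-image (x - min)/(max - min); constant
    images map to zeros.  ``minmax_channel``: the same per channel.
    ``scale255``: fixed x/255.
    """
    arr = image.pixels.astype(np.float64)
    if mode == "minmax":
        lo, hi = arr.min(), arr.max()
        out = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    elif mode == "minmax_channel":
        lo = arr.min(axis=(0, 1))
        hi = arr.max(axis=(0, 1))
        span = np.where(hi > lo, hi - lo, 1.0)
        out = np.where(hi > lo, (arr - lo) / span, 0.0)
    elif mode == "scale255":
        out = arr / 255.0
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return ImageRecord(out, label=image.label, source_path=image.source_path)


def preprocess_pipeline(dataset: LabeledDataset, crop: CropSpec = CropSpec(),
                        target: tuple[int, int] = TARGET_SIZE,
                        norm_mode: str = "minmax") -> LabeledDataset:
    """crop -> resize -> normalize each record, in that order."""
    out = []
    for rec in dataset.records:
        try:
            r = crop_borders(rec, crop)
            r = resize_bilinear(r, target[0], target[1])
            r = normalize_image(r, mode=norm_mode)
        except ValueError as exc:
            raise ValueError(
                f"preprocessing failed for {rec.source_path!r}: {exc}") from exc
        out.append(r)
    return LabeledDataset(out)
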