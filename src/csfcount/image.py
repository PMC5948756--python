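"""Grayscale frame container and TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .errors import InputError, ValidationError

MODALITIES = ("bright_field", "fluorescence")


@dataclass(frozen=True)
class ImageFrame:
    """One grayscale micrograph with pixel calibration and modality tag.

    ``pixels`` is a 2-D unsigned-integer array; intensities are bounded by
    the bit depth.  ``pixel_size`` is in μm/px.
    """

    pixels: np.ndarray
    bit_depth: int
    pixel_size: float
    modality: str

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValidationError("bit_depth", "must be 8 or 16")
        if self.modality not in MODALITIES:
            raise ValidationError("modality", f"must be one of {MODALITIES}")
        if self.pixel_size <= 0:
            raise ValidationError("pixel_size", "must be > 0")
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError("pixels", "must be a 2-D array")
        if px.size and (int(px.max()) > 2**self.bit_depth - 1 or int(px.min()) < 0):
            raise ValidationError("pixels", f"intensities exceed {self.bit_depth}-bit range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def to_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)

    def save(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.pixels)


def quantize(canvas: np.ndarray, bit_depth: int) -> np.ndarray:
    """Clip and round a float canvas into the integer range of ``bit_depth``."""
    hi = 2**bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return np.clip(np.rint(canvas), 0, hi).astype(dtype)


def load_frame(path: str | Path, pixel_size: float, modality: str) -> ImageFrame:
    """Read an 8- or 16-bit grayscale TIFF/PNG into an :class:`ImageFrame`."""
    p = Path(path)
    if not p.exists():
        raise InputError(f"image not found: {p}")
    if p.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(str(p))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(p))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # tolerate RGB(A) by averaging
        arr = arr[..., :3].mean(axis=-1).astype(arr.dtype)
    if arr.ndim != 2:
        raise InputError(f"{p}: expected a single-channel 2-D image, got shape {arr.shape}")
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return ImageFrame(pixels=arr, bit_depth=bit_depth, pixel_size=pixel_size, modality=modality)
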