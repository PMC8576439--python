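"""Grayscale TIFF input/output with voxel-spacing metadata.

Images are stored as 8- or 16-bit unsigned grayscale TIFFs (single page for
a 2D plane, one page per z-slice for a stack) and held in memory as floats
for the real-valued decomposition arithmetic.  Voxel spacing in micrometres
travels alongside the array; it is supplied by the caller (or CLI flags),
never parsed from file metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["ImageVolume", "read_volume", "write_volume"]

_DTYPES = {"uint8": np.uint8, "uint16": np.uint16}


@dataclass
class ImageVolume:
    """Non-negative intensity array, ``(y, x)`` plane or ``(z, y, x)`` stack.

    ``spacing`` is micrometres per voxel along each axis of ``data``.
    """

    data: np.ndarray
    dtype_origin: str = "uint8"
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected 2 or 3 axes, got {self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"degenerate shape {self.data.shape}")
        if np.any(self.data < 0):
            raise ValueError("intensities must be >= 0")
        if self.dtype_origin not in _DTYPES:
            raise ValueError(f"unsupported dtype_origin {self.dtype_origin!r}")
        self.spacing = tuple(float(s) for s in self.spacing)[: self.data.ndim]
        if len(self.spacing) < self.data.ndim:
            self.spacing = (1.0,) * (self.data.ndim - len(self.spacing)) + self.spacing
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing values must be > 0")


def read_volume(path, spacing: tuple[float, ...] | None = None) -> ImageVolume:
    """Read a single- or multi-page grayscale TIFF.

    Multi-page files come back as ``(z, y, x)`` stacks with the page index
    as z; pixel values are returned exactly as stored.  RGB or multichannel
    input is rejected.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim not in (2, 3):
        raise ValueError(f"unsupported TIFF layout with {arr.ndim} axes")
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
        raise ValueError(
            f"multichannel image with {arr.shape[-1]} channels is not "
            "supported; expected single-channel grayscale")
    if arr.dtype == np.uint16:
        origin = "uint16"
    elif arr.dtype == np.uint8:
        origin = "uint8"
    else:
        raise ValueError(f"unsupported pixel type {arr.dtype}; "
                         "expected uint8 or uint16")
    ndim = arr.ndim
    sp = tuple(spacing) if spacing is not None else (1.0,) * ndim
    return ImageVolume(data=arr, dtype_origin=origin, spacing=sp)


def write_volume(vol: ImageVolume, path, dtype: str | None = None) -> int:
    """Write a volume as grayscale TIFF (multi-page for stacks, z order).

    Values are rounded half away from zero and clipped to the target range.
    Returns the number of pixels that exceeded the dtype range before
    clipping (also reported as a warning when nonzero).
    """
    dtype = dtype or vol.dtype_origin
    if dtype not in _DTYPES:
        raise ValueError(f"unsupported target dtype {dtype!r}")
    np_dtype = _DTYPES[dtype]
    lo, hi = 0, np.iinfo(np_dtype).max
    # round half away from zero: np.round uses banker's rounding, so build
    # it from floor(x + 0.5) on the (non-negative) data
    rounded = np.floor(vol.data + 0.5)
    n_clipped = int(np.count_nonzero((rounded < lo) | (rounded > hi)))
    if n_clipped:
        warnings.warn(f"{n_clipped} pixel(s) clipped to {dtype} range",
                      stacklevel=2)
    out = np.clip(rounded, lo, hi).astype(np_dtype)
    tifffile.imwrite(str(path), out, photometric="minisblack")
    return n_clipped
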