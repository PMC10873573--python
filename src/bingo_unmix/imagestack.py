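"""Multichannel image stacks and the flattened pixel-by-channel matrix.

A spectral detector delivers one grayscale image per detection channel. The
factorization works on the flattened form: an ``m x n`` matrix whose row *p*
holds pixel *p*'s intensity across the *n* channels (``m = height * width``,
row-major pixel order). Abundance columns produced by the solver are folded
back into images with the same convention, so the flattening order is frozen
here and used everywhere.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "ImageMatrix",
    "read_stack",
    "write_stack",
    "flatten",
    "unflatten",
]

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}


@dataclass(frozen=True)
class ImageStack:
    """Ordered set of same-sized nonnegative single-channel images.

    Parameters
    ----------
    channels
        ``(n, height, width)`` float array, one page per detection channel.
    channel_centers_nm
        Optional per-channel band-center wavelengths (metadata only; the
        channel order is never re-sorted by wavelength).
    """

    channels: np.ndarray
    channel_centers_nm: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.channels, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise ValueError("channels must be a non-empty (n, height, width) array")
        if np.any(arr < 0):
            raise ValueError("channel images must be nonnegative")
        object.__setattr__(self, "channels", arr)
        if self.channel_centers_nm is not None and len(self.channel_centers_nm) != arr.shape[0]:
            raise ValueError("channel_centers_nm length must match channel count")

    @property
    def channel_count(self) -> int:
        return self.channels.shape[0]

    @property
    def height(self) -> int:
        return self.channels.shape[1]

    @property
    def width(self) -> int:
        return self.channels.shape[2]


@dataclass(frozen=True)
class ImageMatrix:
    """Flattened stack: ``m x n`` nonnegative matrix, ``m = height * width``."""

    values: np.ndarray
    height: int
    width: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError("values must be 2-D")
        if arr.shape[0] != self.height * self.width:
            raise ValueError("row count must equal height * width")
        if np.any(arr < 0):
            raise ValueError("image matrix must be nonnegative")
        object.__setattr__(self, "values", arr)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]


def _read_one(path: Path) -> np.ndarray:
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = np.asarray(tifffile.imread(path))
    else:
        from imageio.v3 import imread  # PNG and friends

        arr = np.asarray(imread(path))
    if arr.ndim == 3 and arr.shape[0] == 1:  # single-page file kept 3-D
        arr = arr[0]
    return arr


def read_stack(path: str | os.PathLike) -> ImageStack:
    """Read a multi-page TIFF (page order = channel order) or a directory of
    identically sized single-channel images (lexicographic file order).

    Integer pixel types are promoted to float64 without rescaling.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ValueError(f"no channel images found in {path}")
        pages = [_read_one(p) for p in files]
    else:
        data = np.asarray(tifffile.imread(path))
        pages = [data] if data.ndim == 2 else list(data)
    shapes = {p.shape for p in pages}
    if len(shapes) != 1 or any(p.ndim != 2 for p in pages):
        raise ValueError("inconsistent channel dimensions")
    arr = np.stack(pages).astype(np.float64)
    if np.any(arr < 0):
        raise ValueError("negative pixel values in input stack")
    return ImageStack(arr)


def write_stack(stack: ImageStack, path: str | os.PathLike) -> None:
    """Write the stack as a multi-page 32-bit float TIFF, page k = channel k."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data = stack.channels.astype(np.float32)
    if data.shape[0] == 1:  # single channel: one plain 2-D page
        data = data[0]
    tifffile.imwrite(path, data, photometric="minisblack")


def flatten(stack: ImageStack) -> ImageMatrix:
    """Arrange the stack into the ``m x n`` image matrix.

    Pixel (row a, col b) maps to flat index ``a * width + b`` (row-major);
    row *p* of the result is pixel *p*'s value across the n channels.
    """
    n = stack.channel_count
    values = stack.channels.reshape(n, -1).T
    return ImageMatrix(values.copy(), stack.height, stack.width)


def unflatten(matrix: np.ndarray, height: int, width: int) -> list[np.ndarray]:
    """Fold each column of an ``m x k`` matrix back into a ``height x width``
    image (row-major). Applies to both the image matrix X (k = channels) and
    the abundance matrix W (k = fluorophores)."""
    arr = np.asarray(matrix, dtype=np.float64)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.shape[0] != height * width:
        raise ValueError(
            f"cannot reshape {arr.shape[0]} rows into {height}x{width} images"
        )
    return [arr[:, q].reshape(height, width) for q in range(arr.shape[1])]


def stack_from_images(images: Sequence[np.ndarray]) -> ImageStack:
    """Convenience: build a stack from a list of 2-D images."""
    return ImageStack(np.stack([np.asarray(im, dtype=np.float64) for im in images]))
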