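"""Reading and writing grayscale images and labeled masks.

Grayscale inputs are single-plane TIFF or PNG; intensities are returned
exactly as stored, never rescaled. Label masks are written as unsigned
integer TIFF (16-bit when the labels fit, 32-bit otherwise) so the
write/read round trip is lossless.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import tifffile
from imageio.v3 import imread as _imread, imwrite as _imwrite

__all__ = ["read_gray", "read_labels", "write_labels", "write_gray"]


def _as_gray(arr: np.ndarray, path: os.PathLike | str) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[2] in (2, 3, 4):
        # genuinely multi-channel (RGB/RGBA/LA) -> reject
        raise ValueError(f"multi-channel image not supported: {path!s}")
    if arr.ndim != 2:
        raise ValueError(
            f"expected a single-plane 2-D image, got shape {arr.shape}: {path!s}"
        )
    if not np.issubdtype(arr.dtype, np.number) or np.issubdtype(arr.dtype, np.complexfloating):
        raise ValueError(f"non-numeric or complex pixel type {arr.dtype}: {path!s}")
    if np.issubdtype(arr.dtype, np.floating) and not np.isfinite(arr).all():
        raise ValueError(f"image contains non-finite pixels: {path!s}")
    return arr


def read_gray(path: os.PathLike | str) -> np.ndarray:
    """Read a single-plane grayscale TIFF/PNG as a 2-D array.

    Intensities are returned as stored in the file, without any
    normalization. Multi-channel and multi-page images are rejected.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such image file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            if len(tf.pages) != 1:
                raise ValueError(f"multi-page TIFF not supported: {path}")
            arr = tf.pages[0].asarray()
    else:
        arr = np.asarray(_imread(path))
    return _as_gray(arr, path)


def read_labels(path: os.PathLike | str) -> np.ndarray:
    """Read an integer label image (0 = background)."""
    arr = read_gray(path)
    if not np.issubdtype(arr.dtype, np.integer):
        f = np.asarray(arr)
        if not np.array_equal(f, np.round(f)):
            raise ValueError(f"label image has non-integer values: {path!s}")
        arr = f.astype(np.int64)
    if arr.min() < 0:
        raise ValueError(f"label image has negative labels: {path!s}")
    return arr.astype(np.int64, copy=False)


def write_labels(labels: np.ndarray, path: os.PathLike | str) -> None:
    """Write a label image as an unsigned-integer TIFF.

    Uses 16-bit when the maximum label fits, escalating to 32-bit
    otherwise. The round trip through :func:`read_labels` is bit-exact.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError(f"label image must be 2-D, got shape {labels.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        raise ValueError(f"label image must be integer-typed, got {labels.dtype}")
    if labels.size and labels.min() < 0:
        raise ValueError("label image has negative labels")
    maxlab = int(labels.max()) if labels.size else 0
    dtype = np.uint16 if maxlab <= np.iinfo(np.uint16).max else np.uint32
    tifffile.imwrite(os.fspath(path), labels.astype(dtype), compression=None)


def write_gray(img: np.ndarray, path: os.PathLike | str) -> None:
    """Write a 2-D grayscale image; TIFF for float data, else per suffix."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"image must be 2-D, got shape {img.shape}")
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(os.fspath(path), img, compression=None)
    else:
        _imwrite(path, img)
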