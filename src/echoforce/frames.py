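"""Reading, writing and validating B-mode ultrasound frames.

A frame is a 2-D ``numpy.uint8`` array with the B-mode convention that
row index increases with tissue depth and column index runs laterally.
On disk frames are 8-bit grayscale PNG or TIFF files; a multi-frame
acquisition is a directory of such files ordered lexicographically.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np

FRAME_SUFFIXES = (".png", ".tif", ".tiff")


class ShapeMismatchError(ValueError):
    """Two frames that must share dimensions do not."""


def validate_frame(frame: np.ndarray) -> np.ndarray:
    """Check that ``frame`` is a valid B-mode intensity grid.

    Accepts integer or floating arrays (filtered frames are real-valued)
    but requires 2-D shape with both sides >= 2 and intensities within
    the 8-bit range for integer input.
    """
    arr = np.asarray(frame)
    if arr.ndim != 2:
        raise ValueError(f"frame must be 2-D, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"frame must be at least 2x2, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("integer frame intensities must lie in [0, 255]")
    return arr


def check_same_shape(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ShapeMismatchError(f"frame shapes differ: {a.shape} vs {b.shape}")


def load_frame(path: str | os.PathLike) -> np.ndarray:
    """Load an 8-bit grayscale frame from PNG or TIFF."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"no such frame file: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        # tolerate saved grayscale with a redundant channel axis
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise ValueError(f"{path}: expected single-channel grayscale, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit pixels, got dtype {arr.dtype}")
    return validate_frame(arr)


def save_frame(frame: np.ndarray, path: str | os.PathLike) -> None:
    """Write a frame as 8-bit grayscale; real-valued input is clipped and rounded."""
    arr = np.asarray(frame)
    if not np.issubdtype(arr.dtype, np.integer):
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    else:
        arr = arr.astype(np.uint8)
    validate_frame(arr)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, arr)


def list_frame_files(directory: str | os.PathLike) -> list[Path]:
    """Frame files in a directory, ordered lexicographically by name."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such directory: {directory}")
    return sorted(
        p for p in directory.iterdir() if p.suffix.lower() in FRAME_SUFFIXES
    )
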