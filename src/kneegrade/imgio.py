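"""8-bit grayscale image I/O (PNG/TIFF)."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_gray", "write_gray"]


def read_gray(path) -> np.ndarray:
    """Read an image as a 2-D uint8 array; RGB(A) inputs are luma-converted."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse color/alpha to luminance
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    return arr


def write_gray(path, image) -> None:
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)
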