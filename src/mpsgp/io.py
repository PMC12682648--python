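"""Grayscale image I/O (TIFF and PNG, 8/16-bit or float)."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as a float64 2-D array on its native scale."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        img = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        img = iio.imread(path)
    img = np.squeeze(np.asarray(img))
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel grayscale image, got shape {img.shape}")
    return img.astype(np.float64)


def write_image(path: str | Path, img: np.ndarray, dtype: np.dtype | str | None = None) -> None:
    """Write an image, clipping to the representable range only at write time.

    ``dtype`` of ``uint8``/``uint16`` rounds and clips to the integer range;
    the default keeps float32.
    """
    path = Path(path)
    img = np.asarray(img, dtype=float)
    if dtype is not None:
        dt = np.dtype(dtype)
        if dt.kind == "u":
            info = np.iinfo(dt)
            out = np.clip(np.rint(img), info.min, info.max).astype(dt)
        else:
            out = img.astype(dt)
    else:
        out = img.astype(np.float32)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, out)
    else:
        import imageio.v3 as iio

        if out.dtype.kind == "f":
            # PNG cannot hold floats; round-trip through 16-bit
            info = np.iinfo(np.uint16)
            out = np.clip(np.rint(out), info.min, info.max).astype(np.uint16)
        iio.imwrite(path, out)
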