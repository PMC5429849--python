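"""Image reading/writing helpers (PNG, TIFF, PGM) for the CLI layer."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["read_grayscale", "write_mask", "write_image"]

# ITU-R 709 luminance, as used by skimage.color.rgb2gray
_LUMA = np.array([0.2125, 0.7154, 0.0721])


def read_grayscale(path: str | Path) -> np.ndarray:
    """Read an image as a 2D float array; RGB(A) is converted to luminance."""
    arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(float) @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"cannot interpret {path} as a 2D grayscale image")
    return arr.astype(float)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as 8-bit PNG: 0 background, 255 foreground."""
    out = np.where(np.asarray(mask).astype(bool), 255, 0).astype(np.uint8)
    iio.imwrite(path, out)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a grayscale image; float TIFF as-is, else clipped 8-bit."""
    path = Path(path)
    img = np.asarray(image)
    if path.suffix.lower() in {".tif", ".tiff"}:
        iio.imwrite(path, img.astype(np.float32))
    else:
        iio.imwrite(path, np.clip(np.round(img), 0, 255).astype(np.uint8))
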