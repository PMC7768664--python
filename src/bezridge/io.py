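"""Image reading/writing helpers (8-bit grayscale PNG/BMP/TIFF)."""

from __future__ import annotations

import numpy as np
from PIL import Image


def read_gray(path) -> np.ndarray:
    """Read an image as 8-bit grayscale (float array in [0, 255])."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=float)


def write_gray(path, img: np.ndarray) -> None:
    arr = np.clip(np.asarray(img, dtype=float), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_mask(path) -> np.ndarray:
    """Read a 0/255 PNG mask as a boolean array."""
    return read_gray(path) > 127


def write_mask(path, mask: np.ndarray) -> None:
    write_gray(path, np.asarray(mask).astype(np.uint8) * 255)
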