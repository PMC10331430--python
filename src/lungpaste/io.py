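"""PNG and table I/O helpers.

Images are 8-bit grayscale PNG on disk and float64 grids in [0, 1] in
memory. All tables are plain CSV written through pandas.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = ["save_image", "load_image", "save_mask", "load_mask"]


def save_image(path: str | os.PathLike, image: np.ndarray) -> None:
    """Write a float image in [0, 1] as an 8-bit grayscale PNG."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite values")
    u8 = np.clip(np.round(arr * 255.0), 0, 255).astype(np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(u8, mode="L").save(path)


def load_image(path: str | os.PathLike, size: int | None = None) -> np.ndarray:
    """Read a grayscale PNG to float64 in [0, 1], optionally resizing to square."""
    with Image.open(path) as im:
        im = im.convert("L")
        if size is not None and im.size != (size, size):
            im = im.resize((size, size), Image.BILINEAR)
        return np.asarray(im, dtype=np.float64) / 255.0


def save_mask(path: str | os.PathLike, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    m = np.asarray(mask)
    save_image(path, m.astype(np.float64))


def load_mask(path: str | os.PathLike, size: int | None = None) -> np.ndarray:
    """Read a mask PNG as a boolean grid (any value > 127 is foreground)."""
    with Image.open(path) as im:
        im = im.convert("L")
        if size is not None and im.size != (size, size):
            im = im.resize((size, size), Image.NEAREST)
        return np.asarray(im) > 127
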