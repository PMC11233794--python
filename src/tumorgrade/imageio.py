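"""8-bit grayscale image I/O.

Internal arithmetic is float64 throughout the pipeline; quantization to
0-255 happens only here, with round-half-up and clipping.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image

__all__ = ["read_gray", "write_gray_png", "quantize_u8"]


def quantize_u8(img: np.ndarray) -> np.ndarray:
    """Round-half-up to integers and clip to the 8-bit range."""
    return np.clip(np.floor(np.asarray(img, dtype=np.float64) + 0.5), 0, 255).astype(np.uint8)


def read_gray(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG as a float64 grayscale array in [0, 255]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.float64)


def write_gray_png(path: str | os.PathLike, img: np.ndarray) -> None:
    Image.fromarray(quantize_u8(img), mode="L").save(path, format="PNG")
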