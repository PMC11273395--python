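"""PNG image / mask round-trip helpers.

Images are stored as 8-bit grayscale PNG and exposed in memory as float
arrays in [0, 1]; binary masks are stored as 0/255 PNG and exposed as bool.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np


def write_image(path, image: np.ndarray) -> None:
    img = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(Path(path), (np.round(img * 255)).astype(np.uint8))


def read_image(path) -> np.ndarray:
    raw = np.asarray(iio.imread(Path(path)))
    if raw.ndim == 3:
        raw = raw[..., 0]
    if raw.dtype == np.uint16:
        return raw.astype(np.float64) / 65535.0
    return raw.astype(np.float64) / 255.0


def write_mask(path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path) -> np.ndarray:
    raw = np.asarray(iio.imread(Path(path)))
    if raw.ndim == 3:
        raw = raw[..., 0]
    return raw > (np.iinfo(raw.dtype).max // 2 if raw.dtype.kind == "u" else 0)
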