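"""8-bit grayscale image I/O and label-map export.

Conversion rules are fixed so every downstream number is reproducible:
multi-channel rasters collapse by Rec.709 luminance (0.2126 R + 0.7152 G
+ 0.0722 B, round half up), images deeper than 8 bits are min-max
rescaled to [0, 255], and label maps are written either as plain index
rasters (lossless round trip) or colorized with a fixed 10-color palette
(one color per region).
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

LUMA_WEIGHTS = np.array([0.2126, 0.7152, 0.0722])

#: fixed palette for up to 10 regions (index 1 first)
PALETTE = np.array(
    [
        [68, 1, 84],
        [59, 82, 139],
        [33, 145, 140],
        [94, 201, 98],
        [253, 231, 37],
        [220, 50, 32],
        [0, 90, 181],
        [255, 140, 0],
        [155, 89, 182],
        [127, 127, 127],
    ],
    dtype=np.uint8,
)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5).astype(np.uint8)


def read_gray_image(path: str | Path) -> np.ndarray:
    """Read a raster as an 8-bit grayscale array.

    RGB(A) inputs collapse by luminance weighting; >8-bit inputs are
    min-max rescaled to [0, 255].
    """
    arr = iio.imread(Path(path))
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64) @ LUMA_WEIGHTS
        arr = _round_half_up(arr)
    elif arr.ndim != 2:
        raise ValueError(f"unsupported raster dimensionality {arr.ndim}")
    if arr.dtype != np.uint8:
        x = arr.astype(np.float64)
        lo, hi = float(x.min()), float(x.max())
        if hi > lo:
            x = (x - lo) / (hi - lo) * 255.0
        else:
            x = np.clip(x, 0.0, 255.0)
        arr = _round_half_up(x)
    return arr


def write_gray_image(img: np.ndarray, path: str | Path) -> None:
    iio.imwrite(Path(path), np.asarray(img, dtype=np.uint8))


def write_label_map(labels: np.ndarray, path: str | Path, colorize: bool = False) -> None:
    """Write a label map as an index raster or a fixed-palette RGB image."""
    lab = np.asarray(labels)
    if lab.min() < 1 or lab.max() > 255:
        raise ValueError("labels must lie in [1, 255]")
    if colorize:
        if lab.max() > PALETTE.shape[0]:
            raise ValueError("palette supports at most 10 regions")
        iio.imwrite(Path(path), PALETTE[lab.astype(np.int64) - 1])
    else:
        iio.imwrite(Path(path), lab.astype(np.uint8))


def read_label_map(path: str | Path) -> np.ndarray:
    """Read back an index raster written with ``colorize=False``."""
    arr = iio.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError("not an index raster")
    return arr.astype(np.int64)
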