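"""Cartilage-region extraction and clinical shape features.

From a multiregional label map, one region is isolated into a binary mask
(optionally keeping only its largest connected lobes) and three features
are measured:

* **area** -- set-pixel count;
* **perimeter** -- pixels where the 3x3 Sobel gradient magnitude of the
  0/1 mask is nonzero (the border band the edge operator responds to);
* **skeleton length** -- pixel count of the 8-connected morphological
  thinning skeleton.

Masks are padded by one background pixel before Sobel/thinning so borders
touching the image frame behave like interior borders.  Percentage
differences against a gold feature set use the gold value as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.morphology import skeletonize

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.int64)
SOBEL_Y = SOBEL_X.T


@dataclass(frozen=True)
class FeatureSet:
    """The three cartilage shape features, in pixels."""

    area_px: int
    perimeter_px: int
    skeleton_px: int


def extract_region_mask(
    labels: np.ndarray, region_id: int, keep_components: int | None = None
) -> np.ndarray:
    """Binary mask of one region; optionally keep only the k largest lobes
    (8-connected components)."""
    lab = np.asarray(labels)
    if region_id < 1 or region_id > lab.max():
        raise ValueError(f"region_id {region_id} outside [1, {lab.max()}]")
    mask = lab == region_id
    if keep_components is not None and mask.any():
        comp = measure.label(mask, connectivity=2)
        sizes = np.bincount(comp.ravel())
        sizes[0] = 0
        keep = np.argsort(sizes)[::-1][:keep_components]
        mask = np.isin(comp, keep[sizes[keep] > 0])
    return mask


def region_area(mask: np.ndarray) -> int:
    """Total count of set pixels."""
    return int(np.count_nonzero(np.asarray(mask, dtype=bool)))


def _padded(mask: np.ndarray) -> np.ndarray:
    return np.pad(np.asarray(mask, dtype=np.uint8), 1)


def region_perimeter_sobel(mask: np.ndarray) -> int:
    """Count pixels with nonzero Sobel gradient magnitude on the 0/1 mask.

    Integer arithmetic, so "nonzero" is exact; an isolated set pixel
    yields 8 (its eight neighbors respond, the pixel itself does not).
    """
    m = _padded(mask).astype(np.int64)
    gx = ndimage.convolve(m, SOBEL_X, mode="constant", cval=0)
    gy = ndimage.convolve(m, SOBEL_Y, mode="constant", cval=0)
    return int(np.count_nonzero((gx != 0) | (gy != 0)))


def region_skeleton_length(mask: np.ndarray) -> int:
    """Pixel count of the thinning skeleton (8-connected medial line)."""
    m = _padded(mask)
    if not m.any():
        return 0
    return int(np.count_nonzero(skeletonize(m.astype(bool))))


def extract_features(mask: np.ndarray) -> FeatureSet:
    """Bundle area, Sobel perimeter and skeleton length for one mask."""
    return FeatureSet(
        area_px=region_area(mask),
        perimeter_px=region_perimeter_sobel(mask),
        skeleton_px=region_skeleton_length(mask),
    )


def feature_difference_pct(auto: FeatureSet, gold: FeatureSet) -> dict[str, float]:
    """Per-feature 100*|auto - gold|/gold (gold is the denominator)."""
    out = {}
    for name in ("area_px", "perimeter_px", "skeleton_px"):
        g = getattr(gold, name)
        if g <= 0:
            raise ValueError(f"gold feature {name} must be positive")
        out[name] = 100.0 * abs(getattr(auto, name) - g) / g
    return out
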