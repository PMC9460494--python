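"""Synthetic knee-like phantoms with known region structure.

A phantom emulates an MR slice with ``L`` separable tissue classes laid
out as nested geometry: a background, a bone-like filled ellipse, a
cartilage-like ribbon (half-annulus arc hugging the ellipse) and a
fluid-like horizontal band; region counts above four add small disks in
the lower corners.  Per-region mean intensities sit on a ladder separated
by ``contrast`` and carry Gaussian texture of standard deviation
``texture_sd`` (clipped to [0, 255], 8-bit sensor semantics).

The ground truth records the exact label map, the ribbon mask, and the
ribbon's rasterized area, Sobel perimeter and thinning-skeleton length,
standing in for the manual gold-standard annotations real MR protocols
rely on.  Coordinates are 0-based row/column with the pixel-center
convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class PhantomTruth:
    """Exact ground truth of a generated phantom."""

    truth_labels: np.ndarray
    region_means: np.ndarray
    ribbon_mask: np.ndarray
    true_area: int
    true_perimeter: int
    true_skeleton_length: int
    ribbon_region: int
    seed: int


def _disk(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse(shape, center, semi):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _half_annulus(shape, center, r_outer, r_inner):
    """Upper half-annulus: inner <= radius < outer, rows above the center."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return (d2 >= r_inner**2) & (d2 < r_outer**2) & (rr <= center[0])


def generate_phantom(
    height: int = 256,
    width: int = 256,
    n_regions: int = 4,
    contrast: float = 50.0,
    texture_sd: float = 8.0,
    seed: int = 0,
    ribbon_outer: float | None = None,
    ribbon_inner: float | None = None,
) -> tuple[np.ndarray, PhantomTruth]:
    """Generate an 8-bit phantom image and its exact ground truth.

    Deterministic for a fixed argument tuple including ``seed``.  The
    feasibility precondition ``contrast * (n_regions - 1) + 4 * texture_sd
    <= 255`` keeps the intensity ladder inside the 8-bit range.
    """
    from .features import region_perimeter_sobel, region_skeleton_length

    if height < 8 or width < 8:
        raise ValueError("phantom must be at least 8 x 8")
    if not 2 <= n_regions <= 10:
        raise ValueError("n_regions must lie in [2, 10]")
    if contrast <= 0 or texture_sd < 0:
        raise ValueError("contrast must be positive, texture_sd nonnegative")
    if contrast * (n_regions - 1) + 4 * texture_sd > 255:
        raise ValueError("infeasible contrast/texture combination for 8-bit range")

    L = n_regions
    scale = min(height, width) / 256.0
    cy, cx = int(height * 0.58), int(width * 0.5)
    r_out = ribbon_outer if ribbon_outer is not None else 40.0 * scale
    r_in = ribbon_inner if ribbon_inner is not None else 34.0 * scale
    if not 0 < r_in < r_out:
        raise ValueError("ribbon radii must satisfy 0 < inner < outer")

    labels = np.ones((height, width), dtype=np.int64)  # background = 1
    if L >= 2:
        bone = _ellipse((height, width), (cy, cx), (r_in * 0.85, r_in * 0.95))
        labels[bone] = 2
    ribbon = _half_annulus((height, width), (cy, cx), r_out, r_in)
    ribbon_region = min(3, L)
    if L >= 3:
        labels[ribbon] = 3
    else:
        labels[ribbon] = 2
        ribbon_region = 2
    if L >= 4:
        band_top = min(height - 1, int(cy + r_out * 1.25))
        band = np.zeros((height, width), dtype=bool)
        band[band_top : min(height, band_top + max(4, int(10 * scale))), :] = True
        band &= ~ribbon
        labels[band] = 4
    for extra in range(5, L + 1):
        # small disks along the top edge, clear of the ribbon
        k = extra - 5
        center = (int(height * 0.12), int(width * (0.15 + 0.18 * k)))
        disk = _disk((height, width), center, max(3.0, 9.0 * scale))
        disk &= ~ribbon
        labels[disk] = extra

    if L >= 3:
        ribbon_mask = labels == 3
    else:
        ribbon_mask = ribbon & (labels == 2)

    base = (255.0 - contrast * (L - 1)) / 2.0
    region_means = base + contrast * np.arange(L)
    img = region_means[labels - 1]
    if texture_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, texture_sd, size=img.shape)
    img = np.floor(np.clip(img, 0.0, 255.0) + 0.5).astype(np.uint8)

    truth = PhantomTruth(
        truth_labels=labels,
        region_means=region_means,
        ribbon_mask=ribbon_mask,
        true_area=int(ribbon_mask.sum()),
        true_perimeter=int(region_perimeter_sobel(ribbon_mask)),
        true_skeleton_length=int(region_skeleton_length(ribbon_mask)),
        ribbon_region=ribbon_region,
        seed=seed,
    )
    return img, truth


# ---------------------------------------------------------------------------
# truth serialization (JSON sidecar, run-length encoded mask)
# ---------------------------------------------------------------------------


def _rle_encode(mask: np.ndarray) -> list[int]:
    """Run lengths of the flattened mask, starting with a zero-run."""
    flat = np.asarray(mask, dtype=np.uint8).ravel()
    changes = np.flatnonzero(np.diff(flat)) + 1
    runs = np.diff(np.concatenate(([0], changes, [flat.size]))).tolist()
    if flat.size and flat[0] == 1:
        runs = [0] + runs
    return [int(r) for r in runs]


def _rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    val = False
    for r in runs:
        if val:
            flat[pos : pos + r] = True
        pos += r
        val = not val
    return flat.reshape(shape)


def save_truth(truth: PhantomTruth, path: str | Path) -> None:
    """Serialize a :class:`PhantomTruth` as a JSON sidecar."""
    shape = truth.truth_labels.shape
    payload = {
        "shape": list(shape),
        "labels_rle": {
            str(l): _rle_encode(truth.truth_labels == l)
            for l in np.unique(truth.truth_labels)
        },
        "region_means": truth.region_means.tolist(),
        "ribbon_rle": _rle_encode(truth.ribbon_mask),
        "true_area": truth.true_area,
        "true_perimeter": truth.true_perimeter,
        "true_skeleton_length": truth.true_skeleton_length,
        "ribbon_region": truth.ribbon_region,
        "seed": truth.seed,
    }
    Path(path).write_text(json.dumps(payload))


def load_truth(path: str | Path) -> PhantomTruth:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["shape"])
    labels = np.zeros(shape, dtype=np.int64)
    for l, runs in payload["labels_rle"].items():
        labels[_rle_decode(runs, shape)] = int(l)
    return PhantomTruth(
        truth_labels=labels,
        region_means=np.array(payload["region_means"]),
        ribbon_mask=_rle_decode(payload["ribbon_rle"], shape),
        true_area=int(payload["true_area"]),
        true_perimeter=int(payload["true_perimeter"]),
        true_skeleton_length=int(payload["true_skeleton_length"]),
        ribbon_region=int(payload["ribbon_region"]),
        seed=int(payload["seed"]),
    )
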