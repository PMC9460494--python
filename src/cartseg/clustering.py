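"""Intensity K-means baseline.

One-dimensional Lloyd iteration over the 256-bin intensity histogram
(mathematically identical to clustering the raw pixels, but linear in the
number of bins rather than pixels): assign every intensity to its nearest
centroid, recompute centroids as count-weighted means, and stop when no
pixel changes class.  Labels are renumbered 1..k by ascending centroid so
the output is order-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .objectives import compute_histogram


@dataclass
class KMeansState:
    """Converged clustering state."""

    centroids: np.ndarray
    iterations: int
    inertia: float
    inertia_history: list[float] = field(default_factory=list)
    bin_labels: np.ndarray | None = None
    counts: np.ndarray | None = None


def _init_centroids(counts: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct intensities spread over the intensity quantiles.

    Quantile positions carry a small seeded jitter; collisions fall back to
    the unused intensity farthest from the chosen set.
    """
    present = np.flatnonzero(counts)
    cdf = np.cumsum(counts) / counts.sum()
    q = (np.arange(k) + rng.uniform(0.25, 0.75, size=k)) / k
    picks: list[int] = []
    for qi in np.sort(q):
        c = int(np.searchsorted(cdf, qi))
        c = int(present[np.argmin(np.abs(present - c))])
        if c in picks:
            free = np.setdiff1d(present, picks)
            c = int(free[np.argmax(np.min(np.abs(free[:, None] - np.array(picks)[None, :]), axis=1))])
        picks.append(c)
    return np.sort(np.array(picks, dtype=np.float64))


def kmeans_segment(
    img: np.ndarray, k: int, seed: int = 0, max_iter: int = 300
) -> tuple[np.ndarray, KMeansState]:
    """Cluster pixel intensities into k classes; labels 1..k by centroid.

    Raises if ``k`` exceeds the number of distinct intensities present.
    """
    arr = np.asarray(img)
    h = compute_histogram(arr)
    counts = h.counts.astype(np.float64)
    present = np.flatnonzero(counts)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > present.size:
        raise ValueError("k exceeds the number of distinct intensities")

    rng = np.random.default_rng(seed)
    centroids = _init_centroids(h.counts, k, rng)
    intens = np.arange(256, dtype=np.float64)
    labels = None
    inertia_history: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        d = np.abs(intens[:, None] - centroids[None, :])
        new_labels = np.argmin(d, axis=1)
        # empty cluster -> re-seed at the farthest populated intensity
        for j in range(k):
            if counts[new_labels == j].sum() == 0:
                far = present[
                    np.argmax(np.min(np.abs(present[:, None] - centroids[None, :]), axis=1))
                ]
                centroids[j] = far
                d = np.abs(intens[:, None] - centroids[None, :])
                new_labels = np.argmin(d, axis=1)
        inertia = float(((intens - centroids[new_labels]) ** 2 * counts).sum())
        inertia_history.append(inertia)
        if labels is not None and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(k):
            sel = labels == j
            w = counts[sel].sum()
            if w > 0:
                centroids[j] = (intens[sel] * counts[sel]).sum() / w

    order = np.argsort(centroids)
    rank = np.empty(k, dtype=np.int64)
    rank[order] = np.arange(k)
    bin_labels = rank[labels] + 1
    state = KMeansState(
        centroids=np.sort(centroids),
        iterations=it,
        inertia=inertia_history[-1],
        inertia_history=inertia_history,
        bin_labels=bin_labels,
        counts=h.counts,
    )
    return bin_labels[arr], state


def kmeans_centroid_mode(state: KMeansState) -> list[int]:
    """Per-class modal intensity (the maximum-frequency pixel value)."""
    if state.bin_labels is None or state.counts is None:
        raise ValueError("state does not carry assignment information")
    modes = []
    k = int(state.bin_labels.max())
    for j in range(1, k + 1):
        sel = state.bin_labels == j
        masked = np.where(sel, state.counts, -1)
        modes.append(int(np.argmax(masked)))
    return modes
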