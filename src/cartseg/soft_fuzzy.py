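"""Pseudo trapezoid-shaped (PTS) fuzzy soft thresholding.

A soft segmentation model over the 8-bit intensity axis is a strictly
increasing vertex sequence ``V1 < ... < VL`` in ``[0, 255]``, one vertex
per region.  Each region ``l`` carries a piecewise-linear membership
function that peaks (value 1) at ``V_l``, falls linearly to 0 at the
adjacent vertices and is 0 elsewhere; the first and last functions extend
their plateau to the ends of the axis.  The construction satisfies the
fuzzy-partition laws at every intensity:

* complete division -- some membership is positive everywhere;
* consistency/normality -- ``mu_l(V_l) = 1`` and ``mu_k(V_l) = 0``, k != l;
* adjacency -- at most two (adjacent) memberships are nonzero, and they
  sum to exactly 1.

Crisp labels are recovered by argmax defuzzification, which is provably
identical to hard thresholding at the midpoints between adjacent vertices;
the vertex fitness maximized by the bee-colony optimizer is the Kapur
entropy of that midpoint-equivalent partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .objectives import Histogram, apply_hard_thresholds, kapur_entropy

N_BINS = 256


@dataclass(frozen=True)
class MembershipModel:
    """PTS vertex sequence and the derived L x 256 membership table."""

    vertices: np.ndarray
    table: np.ndarray

    @property
    def n_regions(self) -> int:
        return int(self.vertices.size)


def _validate_vertices(vertices: np.ndarray) -> np.ndarray:
    v = np.asarray(vertices, dtype=np.int64).ravel()
    if v.size < 2:
        raise ValueError("need at least two vertices")
    if np.any(np.diff(v) <= 0) or v[0] < 0 or v[-1] > 255:
        raise ValueError("vertices must be strictly increasing integers in [0, 255]")
    return v


def build_pts_model(vertices: np.ndarray, n_regions: int | None = None) -> MembershipModel:
    """Construct the PTS membership table for a vertex sequence."""
    v = _validate_vertices(vertices)
    if n_regions is not None and n_regions != v.size:
        raise ValueError("number of vertices must equal number of regions")
    L = v.size
    x = np.arange(N_BINS, dtype=np.float64)
    table = np.zeros((L, N_BINS))
    for l in range(L):
        mu = np.zeros(N_BINS)
        if l == 0:
            mu[x <= v[0]] = 1.0
            span = (x > v[0]) & (x < v[1])
            mu[span] = (v[1] - x[span]) / (v[1] - v[0])
        elif l == L - 1:
            mu[x >= v[-1]] = 1.0
            span = (x > v[-2]) & (x < v[-1])
            mu[span] = (x[span] - v[-2]) / (v[-1] - v[-2])
        else:
            rise = (x > v[l - 1]) & (x <= v[l])
            mu[rise] = (x[rise] - v[l - 1]) / (v[l] - v[l - 1])
            fall = (x > v[l]) & (x < v[l + 1])
            mu[fall] = (v[l + 1] - x[fall]) / (v[l + 1] - v[l])
        table[l] = mu
    return MembershipModel(vertices=v, table=table)


def midpoint_thresholds(vertices: np.ndarray) -> np.ndarray:
    """Crisp thresholds equivalent to argmax defuzzification.

    The smallest intensity labelled ``l + 1`` is ``floor((V_l+V_{l+1})/2)+1``
    (the exact midpoint ties toward the lower region).
    """
    v = _validate_vertices(vertices)
    return (v[:-1] + v[1:]) // 2 + 1


def defuzzify(img: np.ndarray, model: MembershipModel) -> np.ndarray:
    """Crisp label map by maximal membership; ties toward the lower index."""
    arr = np.asarray(img)
    # np.argmax returns the first (lowest) index on ties
    lut = np.argmax(model.table, axis=0).astype(np.int64) + 1
    return lut[arr]


def vertex_fitness(h: Histogram, vertices: np.ndarray) -> float:
    """Kapur entropy of the midpoint-equivalent crisp partition."""
    return kapur_entropy(h, midpoint_thresholds(vertices))


def vertex_objective(h: Histogram):
    """Vectorized vertex fitness for optimizer populations.

    Maps an integer array ``(P, L)`` of sorted vertex rows to a length-``P``
    fitness vector by scoring each row's midpoint-equivalent thresholds.
    """
    from .objectives import kapur_objective

    kap = kapur_objective(h)

    def objective(V: np.ndarray) -> np.ndarray:
        V = np.atleast_2d(np.asarray(V, dtype=np.int64))
        T = (V[:, :-1] + V[:, 1:]) // 2 + 1
        return kap(T)

    return objective


def soft_labels(img: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Convenience: hard labels equivalent to the full fuzzy pipeline."""
    return apply_hard_thresholds(img, midpoint_thresholds(vertices))
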