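"""Histogram objectives for multilevel thresholding.

The segmentation model is an ordered vector of integer thresholds
``T1 < T2 < ... < Tn`` in ``[1, 255]`` splitting the 256-bin intensity
histogram into ``L = n + 1`` regions with half-open intervals
``T_{l-1} <= I < T_l`` (sentinels ``T_0 = 0``, ``T_L = 256``).  Two
objectives are provided:

* **Kapur entropy** -- the sum of the Shannon entropies (nats) of the
  normalized intensity distribution within each region; the quantity every
  metaheuristic in :mod:`cartseg.optimizers` maximizes.
* **Between-class variance** -- the classic Otsu criterion, used both by
  the equal-area multi-Otsu baseline and as a second objective of the
  exhaustive-search oracle.

:func:`exhaustive_search` returns the true global optimum by enumeration
and anchors every optimizer test in the suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

N_BINS = 256

#: hard cap on the number of threshold combinations the oracle will enumerate
MAX_COMBINATIONS = 2_000_000


class SearchSpaceError(ValueError):
    """Raised when the exhaustive oracle would exceed its enumeration guard."""


@dataclass(frozen=True)
class Histogram:
    """256-bin intensity histogram with counts and normalized probabilities."""

    counts: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape != (N_BINS,):
            raise ValueError(f"histogram must have {N_BINS} bins")
        if self.counts.min() < 0:
            raise ValueError("negative bin count")
        if abs(float(self.probs.sum()) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def active_bins(self) -> np.ndarray:
        return np.flatnonzero(self.counts)


def compute_histogram(img: np.ndarray) -> Histogram:
    """Count pixels per intensity and normalize to probabilities."""
    arr = np.asarray(img)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    counts = np.bincount(arr.ravel().astype(np.int64), minlength=N_BINS)
    probs = counts / counts.sum()
    return Histogram(counts=counts, probs=probs)


def histogram_from_counts(counts: np.ndarray) -> Histogram:
    """Build a :class:`Histogram` directly from a 256-bin count vector."""
    counts = np.asarray(counts, dtype=np.int64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("histogram has no mass")
    return Histogram(counts=counts, probs=counts / total)


def validate_thresholds(thresholds: np.ndarray) -> np.ndarray:
    tv = np.asarray(thresholds, dtype=np.int64).ravel()
    if tv.size and (np.any(np.diff(tv) <= 0) or tv[0] < 1 or tv[-1] > 255):
        raise ValueError(
            "thresholds must be strictly increasing integers in [1, 255]"
        )
    return tv


def apply_hard_thresholds(img: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Label pixels 1..L by the half-open intervals the thresholds define.

    A pixel with intensity exactly equal to a threshold belongs to the
    *upper* region (upper-exclusive intervals).
    """
    tv = validate_thresholds(thresholds)
    arr = np.asarray(img)
    return (np.searchsorted(tv, arr.ravel(), side="right") + 1).reshape(arr.shape)


# ---------------------------------------------------------------------------
# cumulative-sum machinery shared by both objectives
# ---------------------------------------------------------------------------


def _cumsums(h: Histogram):
    """Prefix sums of p, p*ln(p) and j*p with a leading zero (length 257)."""
    p = h.probs
    with np.errstate(divide="ignore", invalid="ignore"):
        plnp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    S = np.concatenate(([0.0], np.cumsum(p)))
    C = np.concatenate(([0.0], np.cumsum(plnp)))
    M = np.concatenate(([0.0], np.cumsum(np.arange(N_BINS) * p)))
    return S, C, M


def _kapur_terms(S, C, lo, hi):
    """Entropy of regions [lo, hi); empty regions contribute 0."""
    w = S[hi] - S[lo]
    dC = C[hi] - C[lo]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)) - dC / np.where(w > 0, w, 1.0), 0.0)
    return out


def _bcv_terms(S, M, lo, hi):
    """omega * mu^2 contribution of regions [lo, hi); empty regions -> 0."""
    w = S[hi] - S[lo]
    dM = M[hi] - M[lo]
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(w > 0, dM * dM / np.where(w > 0, w, 1.0), 0.0)


def _boundaries(X: np.ndarray) -> np.ndarray:
    """Stack sentinel boundaries 0 and 256 around threshold rows."""
    X = np.atleast_2d(np.asarray(X, dtype=np.int64))
    P = X.shape[0]
    return np.hstack(
        [np.zeros((P, 1), np.int64), X, np.full((P, 1), N_BINS, np.int64)]
    )


def kapur_entropy(h: Histogram, thresholds: np.ndarray) -> float:
    """Total Kapur entropy (nats) of the partition the thresholds induce.

    ``0 * ln 0`` counts as 0 and a region with zero mass contributes 0.
    """
    tv = validate_thresholds(thresholds)
    S, C, _ = _cumsums(h)
    B = _boundaries(tv[None, :])
    return float(_kapur_terms(S, C, B[:, :-1], B[:, 1:]).sum())


def between_class_variance(h: Histogram, thresholds: np.ndarray) -> float:
    """Otsu between-class variance sum_l w_l*(mu_l - mu)^2 of the partition."""
    tv = validate_thresholds(thresholds)
    S, _, M = _cumsums(h)
    B = _boundaries(tv[None, :])
    total = float(_bcv_terms(S, M, B[:, :-1], B[:, 1:]).sum())
    mu = float(M[-1])
    return total - mu * mu


def kapur_objective(h: Histogram):
    """Vectorized Kapur fitness for optimizer populations.

    Returns a callable mapping an integer array of shape ``(P, n)`` of
    sorted threshold rows to a length-``P`` fitness vector.
    """
    S, C, _ = _cumsums(h)

    def objective(X: np.ndarray) -> np.ndarray:
        B = _boundaries(X)
        return _kapur_terms(S, C, B[:, :-1], B[:, 1:]).sum(axis=1)

    return objective


def bcv_objective(h: Histogram):
    """Vectorized between-class-variance fitness (same contract as Kapur)."""
    S, _, M = _cumsums(h)
    mu2 = float(M[-1]) ** 2

    def objective(X: np.ndarray) -> np.ndarray:
        B = _boundaries(X)
        return _bcv_terms(S, M, B[:, :-1], B[:, 1:]).sum(axis=1) - mu2

    return objective


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


def _candidate_thresholds(h: Histogram, n: int) -> np.ndarray:
    """Candidate thresholds containing the lex-smallest global optimum.

    Threshold values are equivalent when they induce the same partition of
    the *active* bins; the candidates are the minima of those equivalence
    classes, augmented with ``+k`` (k < n) offsets so that vectors with
    empty middle regions remain representable.
    """
    active = h.active_bins
    reps = {1}
    for a in active:
        if 1 <= a + 1 <= 255:
            reps.add(int(a) + 1)
    cands = {min(r + k, 255) for r in reps for k in range(max(n, 1))}
    return np.array(sorted(c for c in cands if 1 <= c <= 255), dtype=np.int64)


def exhaustive_search(
    h: Histogram, n_thresholds: int, objective: str = "kapur"
) -> tuple[np.ndarray, float]:
    """Global optimum of the chosen objective by full enumeration.

    Ties are broken toward the lexicographically smallest threshold vector.
    Intended as the oracle anchoring optimizer tests; refuses search spaces
    beyond its enumeration guard (``n_thresholds`` > 3 with more than 64
    active bins, or more than :data:`MAX_COMBINATIONS` combinations).
    """
    if objective == "kapur":
        S, C, _ = _cumsums(h)
        term = lambda lo, hi: _kapur_terms(S, C, lo, hi)  # noqa: E731
        offset = 0.0
    elif objective == "between_class_variance":
        S, _, M = _cumsums(h)
        term = lambda lo, hi: _bcv_terms(S, M, lo, hi)  # noqa: E731
        offset = -float(M[-1]) ** 2
    else:
        raise ValueError(f"unknown objective {objective!r}")

    n = int(n_thresholds)
    if n < 0:
        raise ValueError("n_thresholds must be >= 0")
    if n == 0:
        empty = np.empty(0, dtype=np.int64)
        return empty, float(term(np.array([0]), np.array([N_BINS]))[0] + offset)
    if n > 3 and h.active_bins.size > 64:
        raise SearchSpaceError(
            "exhaustive search requires n_thresholds <= 3 or <= 64 active bins"
        )

    cand = _candidate_thresholds(h, n)
    K = cand.size
    if K < n:
        raise SearchSpaceError("fewer candidate thresholds than requested")
    # region-term matrix over boundary values [0, cand..., 256]
    bvals = np.concatenate(([0], cand, [N_BINS]))
    nb = bvals.size
    lo = np.repeat(bvals, nb).reshape(nb, nb)
    hi = np.tile(bvals, nb).reshape(nb, nb)
    E = np.where(hi > lo, term(lo.ravel(), hi.ravel()).reshape(nb, nb), -np.inf)

    last = nb - 1
    if n == 1:
        F = E[0, 1:last] + E[1:last, last]
        i = int(np.argmax(F)) + 1
        return cand[[i - 1]].copy(), float(F[i - 1] + offset)
    if n == 2:
        idx = np.arange(nb)
        F = E[0, idx][:, None] + E + E[idx, last][None, :]
        F = np.where((idx[:, None] < idx[None, :]) & (idx[:, None] >= 1) & (idx[None, :] <= last - 1), F, -np.inf)
        i, j = np.unravel_index(int(np.argmax(F)), F.shape)
        return cand[[i - 1, j - 1]].copy(), float(F[i, j] + offset)
    if n == 3:
        idx = np.arange(nb)
        tail = E[idx, last]
        inner_mask = idx[:, None] < idx[None, :]
        best_f = -np.inf
        best_vec = None
        for i in range(1, last - 1):
            F = E[i, idx][:, None] + E + tail[None, :]
            F = np.where(
                inner_mask & (idx[:, None] > i) & (idx[None, :] <= last - 1),
                F,
                -np.inf,
            )
            jk = int(np.argmax(F))
            j, k = np.unravel_index(jk, F.shape)
            f = float(E[0, i] + F[j, k])
            if f > best_f:
                best_f = f
                best_vec = (i, j, k)
        i, j, k = best_vec
        return cand[[i - 1, j - 1, k - 1]].copy(), float(best_f + offset)

    # generic fallback for n >= 4 on condensed histograms
    n_comb = math.comb(K, n)
    if n_comb > MAX_COMBINATIONS:
        raise SearchSpaceError(f"{n_comb} combinations exceed the guard")
    best_f = -np.inf
    best = None
    for combo in itertools.combinations(range(1, last), n):
        b = (0,) + combo + (last,)
        f = sum(E[b[i], b[i + 1]] for i in range(n + 1))
        if f > best_f:
            best_f = f
            best = combo
    return cand[np.array(best) - 1].copy(), float(best_f + offset)


# ---------------------------------------------------------------------------
# equal-area multi-Otsu
# ---------------------------------------------------------------------------


def multi_otsu(h: Histogram, n_thresholds: int) -> np.ndarray:
    """Equal-area multi-threshold Otsu.

    The 256-bin axis is split into ``p = n_thresholds`` equal-width areas
    (width ``a = 256 / p``); within each area the single threshold that
    maximizes the between-class variance of that area's sub-histogram is
    selected, ties toward the smallest threshold.  An area with no mass
    falls back to its midpoint.  With ``p = 1`` this is the classic
    full-range Otsu threshold.
    """
    p = int(n_thresholds)
    if p < 1:
        raise ValueError("n_thresholds must be >= 1")
    if p > 128:
        raise ValueError("too many areas for a 256-bin histogram")
    edges = np.rint(np.arange(p + 1) * (N_BINS / p)).astype(np.int64)
    thresholds = np.empty(p, dtype=np.int64)
    for a in range(p):
        lo, hi = int(edges[a]), int(edges[a + 1])
        sub = np.zeros(N_BINS, dtype=np.int64)
        sub[lo:hi] = h.counts[lo:hi]
        t_lo = max(lo + 1, 1)
        t_hi = min(hi, 255)
        if sub.sum() == 0:
            thresholds[a] = min(max(lo + (hi - lo) // 2, t_lo), t_hi)
            continue
        sh = histogram_from_counts(sub)
        S, _, M = _cumsums(sh)
        ts = np.arange(t_lo, t_hi + 1)
        zeros = np.zeros_like(ts)
        full = np.full_like(ts, N_BINS)
        var = _bcv_terms(S, M, zeros, ts) + _bcv_terms(S, M, ts, full)
        thresholds[a] = ts[int(np.argmax(var))]
    return np.sort(thresholds)
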