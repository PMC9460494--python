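"""Label-map comparison metrics and the protocol's statistical tests.

All four metrics compare two *labeling matrices* (integer region indices
1..L), never raw intensities: the gold standard is a method's own
segmentation of the noise-free image, and the metrics quantify how far
the same method's segmentation of a corrupted image drifts from it.

Degenerate cases carry explicit flags instead of exceptions: a zero
variance map makes Pearson correlation undefined (NaN), identical maps
make the SNR ratio infinite (+inf), and the literal signed SNR numerator
can go nonpositive (NaN).  Aggregation layers skip flagged entries and
report their count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class MetricRecord:
    """One gold-vs-test comparison plus its run metadata."""

    ssim: float
    mse: float
    corr: float
    snr_db: float
    method: str = ""
    noise_kind: str = ""
    level_index: int = 0
    n_regions: int = 0
    image_id: str = ""


def _check_shapes(gold: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(gold, dtype=np.float64)
    f = np.asarray(test, dtype=np.float64)
    if g.shape != f.shape:
        raise ValueError("label maps must share a shape")
    return g, f


def mse(gold: np.ndarray, test: np.ndarray) -> float:
    """Mean squared label-index difference."""
    g, f = _check_shapes(gold, test)
    return float(np.mean((g - f) ** 2))


def ssim_global(
    gold: np.ndarray, test: np.ndarray, k: float = 0.02, dynamic_range: float | None = None
) -> float:
    """Single global SSIM from whole-image statistics.

    ``C1 = C2 = (k * dynamic_range)^2``; the dynamic range defaults to
    ``L - 1`` for maps with L regions (max label minus min label, at least
    1).  Variances and the covariance use the n-1 convention.
    """
    g, f = _check_shapes(gold, test)
    if dynamic_range is None:
        dynamic_range = float(max(max(g.max(), f.max()) - min(g.min(), f.min()), 1.0))
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    c = (k * dynamic_range) ** 2
    mu_g, mu_f = g.mean(), f.mean()
    vg = g.var(ddof=1) if g.size > 1 else 0.0
    vf = f.var(ddof=1) if f.size > 1 else 0.0
    cov = float(((g - mu_g) * (f - mu_f)).sum() / max(g.size - 1, 1))
    num = (2 * mu_g * mu_f + c) * (2 * cov + c)
    den = (mu_g**2 + mu_f**2 + c) * (vg + vf + c)
    return float(num / den)


def pearson_corr(gold: np.ndarray, test: np.ndarray) -> float:
    """Pearson correlation of the flattened maps; NaN flag when either map
    has zero variance."""
    g, f = _check_shapes(gold, test)
    if g.std() == 0 or f.std() == 0:
        return math.nan
    return float(np.corrcoef(g.ravel(), f.ravel())[0, 1])


def snr_db(gold: np.ndarray, test: np.ndarray, conventional: bool = False) -> float:
    """Signal-to-noise ratio 10*log10(sum(g^2 - f^2) / sum((g - f)^2)) in dB.

    The literal signed numerator is the default (it can go nonpositive, in
    which case NaN is returned); ``conventional=True`` switches the
    numerator to ``sum(g^2)``.  Identical maps give +inf.
    """
    g, f = _check_shapes(gold, test)
    den = float(((g - f) ** 2).sum())
    num = float((g**2).sum()) if conventional else float((g**2 - f**2).sum())
    if den == 0:
        return math.inf
    if num <= 0:
        return math.nan
    return float(10.0 * np.log10(num / den))


def evaluate_against_gold(
    gold: np.ndarray,
    test: np.ndarray,
    method: str = "",
    noise_kind: str = "",
    level_index: int = 0,
    n_regions: int = 0,
    image_id: str = "",
) -> MetricRecord:
    """Bundle the four metrics for one gold-vs-test pair."""
    L = max(int(np.asarray(gold).max()), int(np.asarray(test).max()), 2)
    return MetricRecord(
        ssim=ssim_global(gold, test, dynamic_range=float(L - 1)),
        mse=mse(gold, test),
        corr=pearson_corr(gold, test),
        snr_db=snr_db(gold, test),
        method=method,
        noise_kind=noise_kind,
        level_index=level_index,
        n_regions=n_regions,
        image_id=image_id,
    )


# ---------------------------------------------------------------------------
# statistical testing scheme
# ---------------------------------------------------------------------------


def chi_square_normality(sample: np.ndarray) -> float:
    """Chi-square goodness-of-fit p-value against a fitted normal.

    Equal-probability binning with ``round(sqrt(n))`` bins (capped at
    ``n // 5`` so every expected count is at least 5), degrees of freedom
    ``bins - 3`` (two estimated parameters).
    """
    x = np.asarray(sample, dtype=np.float64).ravel()
    n = x.size
    if n < 30:
        raise ValueError("need at least 30 observations")
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    k = int(round(math.sqrt(n)))
    k = max(4, min(k, n // 5))
    edges = stats.norm.ppf(np.arange(1, k) / k, loc=mu, scale=sd)
    observed = np.bincount(np.searchsorted(edges, x), minlength=k)
    expected = n / k
    stat = float(((observed - expected) ** 2 / expected).sum())
    df = k - 3
    return float(stats.chi2.sf(stat, df))


def wilcoxon_rank_sum_one_sided(
    x: np.ndarray, y: np.ndarray, direction: str = "greater"
) -> float:
    """One-sided two-sample rank-sum p-value (normal approximation with tie
    correction).  ``greater`` tests a location shift of x above y, ``less``
    the reverse (the MSE convention)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be nonempty")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    res = stats.mannwhitneyu(x, y, alternative=direction, method="asymptotic")
    return float(res.pvalue)


def aggregate_metric(values: np.ndarray) -> tuple[float, int]:
    """Mean over defined entries plus the count of excluded flags
    (NaN/inf)."""
    v = np.asarray(values, dtype=np.float64).ravel()
    ok = np.isfinite(v)
    excluded = int((~ok).sum())
    if ok.sum() == 0:
        return math.nan, excluded
    return float(v[ok].mean()), excluded
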