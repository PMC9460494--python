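"""Noise-robustness benchmarking protocol.

For every image x method x region count the protocol segments the native
image once (that method's *gold standard*), then re-segments each of the
20 noise levels of each noise kind with identical settings and scores the
result against the gold with the four label-map metrics.  Per-cell noise
seeds derive from the master seed and the cell coordinates, so the whole
sweep is reproducible end to end and the noise streams are independent.

Aggregation computes per-level means across images (trend curves) and a
grand mean of those per-level means per method (summary-table analog);
significance testing compares each optimized method against the Otsu and
K-means baselines with one-sided rank-sum tests (``greater`` for
SSIM/CORR/SNR, ``less`` for MSE), with a chi-square normality pre-check
recorded per cell.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import clustering, noise, objectives, optimizers, soft_fuzzy
from .evaluation import chi_square_normality, evaluate_against_gold, wilcoxon_rank_sum_one_sided

METRICS = ("ssim", "mse", "corr", "snr_db")
BASELINES = ("otsu", "kmeans")
METHODS = ("otsu", "kmeans", "abc", "pso", "fpso", "dpso", "ga", "abc-fuzzy")


@dataclass
class SweepConfig:
    """Configuration of one robustness sweep."""

    methods: Sequence[str] = ("otsu", "kmeans", "abc-fuzzy", "pso")
    n_regions: Sequence[int] = (4,)
    noise_kinds: Sequence[str] = ("salt_pepper",)
    n_images: int = 10
    image_shape: tuple[int, int] = (256, 256)
    master_seed: int = 0
    optimizer: optimizers.OptimizerConfig = field(default_factory=optimizers.OptimizerConfig)
    phantom_contrast: float = 22.0
    phantom_texture_sd: float = 8.0
    include_level0: bool = False

    def __post_init__(self) -> None:
        if not self.methods or self.n_images < 1:
            raise ValueError("need at least one method and one image")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        for L in self.n_regions:
            if not 2 <= L <= 10:
                raise ValueError("region counts must lie in [2, 10]")


def derive_seed(master_seed: int, *parts) -> int:
    """Stable per-cell seed below 2^31 from the master seed and cell id."""
    key = ":".join(str(p) for p in (master_seed, *parts))
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def segment(
    img: np.ndarray,
    method: str,
    n_regions: int,
    cfg: optimizers.OptimizerConfig | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Segment an image into ``n_regions`` with the named method.

    Returns the label map (1..L) and a run record (method, thresholds or
    vertices, fitness where applicable).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    L = int(n_regions)
    h = objectives.compute_histogram(img)
    info: dict = {"method": method, "n_regions": L, "seed": seed}
    if method == "otsu":
        tv = objectives.multi_otsu(h, L - 1)
        info["thresholds"] = tv.tolist()
        return objectives.apply_hard_thresholds(img, tv), info
    if method == "kmeans":
        labels, state = clustering.kmeans_segment(img, L, seed=seed)
        info["centroids"] = state.centroids.tolist()
        return labels, info
    run_cfg = dataclasses.replace(cfg or optimizers.OptimizerConfig(), seed=seed)
    if method == "abc-fuzzy":
        obj = soft_fuzzy.vertex_objective(h)
        res = optimizers.optimize_abc(obj, L, (0, 255), run_cfg)
        info["vertices"] = res.best_vector.tolist()
        info["fitness"] = res.best_fitness
        model = soft_fuzzy.build_pts_model(res.best_vector)
        return soft_fuzzy.defuzzify(img, model), info
    obj = objectives.kapur_objective(h)
    res = optimizers.OPTIMIZERS[method](obj, L - 1, (1, 255), run_cfg)
    info["thresholds"] = res.best_vector.tolist()
    info["fitness"] = res.best_fitness
    return objectives.apply_hard_thresholds(img, res.best_vector), info


def run_robustness_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """Run the full protocol; one row per image x method x region count x
    noise kind x level."""
    from .phantom import generate_phantom

    rows = []
    for i in range(cfg.n_images):
        img_seed = derive_seed(cfg.master_seed, "phantom", i)
        image_id = f"phantom{i:02d}"
        for L in cfg.n_regions:
            img, _ = generate_phantom(
                cfg.image_shape[0],
                cfg.image_shape[1],
                n_regions=L,
                contrast=cfg.phantom_contrast,
                texture_sd=cfg.phantom_texture_sd,
                seed=img_seed,
            )
            for method in cfg.methods:
                seg_seed = derive_seed(cfg.master_seed, image_id, method, L)
                try:
                    gold, _ = segment(img, method, L, cfg.optimizer, seed=seg_seed)
                except Exception as exc:  # pragma: no cover - per-cell failure path
                    rows.append(_failed_row(image_id, method, L, "native", 0, exc))
                    continue
                for kind in cfg.noise_kinds:
                    specs = noise.noise_level_grid(kind, L)
                    if cfg.include_level0:
                        specs = [noise.NoiseSpec(kind, 0)] + specs
                    for spec in specs:
                        cell_seed = derive_seed(
                            cfg.master_seed, image_id, method, L, kind, spec.level_index
                        )
                        try:
                            noisy = noise.apply_noise(
                                img, dataclasses.replace(spec, seed=cell_seed)
                            )
                            test, _ = segment(img=noisy, method=method, n_regions=L,
                                              cfg=cfg.optimizer, seed=seg_seed)
                            rec = evaluate_against_gold(
                                gold,
                                test,
                                method=method,
                                noise_kind=kind,
                                level_index=spec.level_index,
                                n_regions=L,
                                image_id=image_id,
                            )
                            rows.append(dataclasses.asdict(rec) | {"failed": False})
                        except Exception as exc:  # pragma: no cover
                            rows.append(
                                _failed_row(image_id, method, L, kind, spec.level_index, exc)
                            )
    return pd.DataFrame(rows)


def _failed_row(image_id, method, L, kind, level, exc) -> dict:
    return {
        "ssim": np.nan,
        "mse": np.nan,
        "corr": np.nan,
        "snr_db": np.nan,
        "method": method,
        "noise_kind": kind,
        "level_index": level,
        "n_regions": L,
        "image_id": image_id,
        "failed": True,
        "error": repr(exc),
    }


def aggregate(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-level means across images, and per-method grand means.

    Flagged (NaN/inf) entries are excluded; their counts are reported in
    ``*_excluded`` columns.  The grand mean is the mean of the per-level
    means.
    """
    if table.empty:
        raise ValueError("empty result table")
    df = table.copy()
    for m in METRICS:
        df[m] = df[m].where(np.isfinite(df[m]))
    keys = ["method", "n_regions", "noise_kind", "level_index"]
    per_level = df.groupby(keys, as_index=False).agg(
        **{m: (m, "mean") for m in METRICS},
        **{f"{m}_excluded": (m, lambda s: int(s.isna().sum())) for m in METRICS},
    )
    grand = per_level.groupby(["method", "n_regions", "noise_kind"], as_index=False).agg(
        **{m: (m, "mean") for m in METRICS},
        **{f"{m}_excluded": (f"{m}_excluded", "sum") for m in METRICS},
    )
    return per_level, grand


def significance_matrix(
    table: pd.DataFrame, baselines: Sequence[str] = BASELINES
) -> pd.DataFrame:
    """One-sided rank-sum p-values of every optimized method against each
    baseline, per metric and noise kind."""
    methods = [m for m in table["method"].unique() if m not in baselines]
    for b in baselines:
        if b not in set(table["method"]):
            raise ValueError(f"baseline {b!r} missing from the table")
    if not methods:
        raise ValueError("no optimized method present")
    rows = []
    for method in methods:
        for kind in table["noise_kind"].unique():
            for metric in METRICS:
                direction = "less" if metric == "mse" else "greater"
                x = table.query("method == @method and noise_kind == @kind")[metric]
                x = x[np.isfinite(x)].to_numpy()
                for b in baselines:
                    y = table.query("method == @b and noise_kind == @kind")[metric]
                    y = y[np.isfinite(y)].to_numpy()
                    if x.size == 0 or y.size == 0:
                        p = np.nan
                        norm_p = np.nan
                    else:
                        p = wilcoxon_rank_sum_one_sided(x, y, direction)
                        pooled = np.concatenate([x, y])
                        norm_p = (
                            chi_square_normality(pooled) if pooled.size >= 30 else np.nan
                        )
                    rows.append(
                        {
                            "method": method,
                            "baseline": b,
                            "noise_kind": kind,
                            "metric": metric,
                            "direction": direction,
                            "p_value": p,
                            "normality_p": norm_p,
                        }
                    )
    return pd.DataFrame(rows)
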