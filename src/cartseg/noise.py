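"""Deterministic-parameter noise generators and sweep grids.

Four generators emulate the degradations MR-like images are benchmarked
under: additive Gaussian, multiplicative speckle, impulse salt-and-pepper
and Rician magnitude noise (the MRI-specific model -- Rayleigh where the
signal vanishes, near-Gaussian where it dominates).  All arithmetic runs
on the normalized [0, 1] intensity scale (the sweep parameters are unit
scale), after which the image is clipped and re-quantized to 8 bits.

Every generator is a pure function of ``(image, parameters, seed)``; a
zero noise parameter returns the input bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NOISE_KINDS = ("gaussian", "speckle", "salt_pepper", "rician")

#: steering-parameter ranges of the 20-level sweeps
GRID_RANGES = {
    "gaussian": (0.01, 0.2),  # mean mu, with fixed variance 0.01
    "salt_pepper": (0.17, 0.33),  # density d
    "speckle": (0.01, 0.2),  # variance sigma^2
    "rician": (0.02, 0.4),  # variance sigma^2
}

GAUSSIAN_FIXED_VARIANCE = 0.01
N_LEVELS = 20


@dataclass(frozen=True)
class NoiseSpec:
    """One point of a noise sweep.

    ``level_index`` 0 means the native (noise-free) image; 1..20 index the
    linearly spaced steering-parameter grid.
    """

    kind: str
    level_index: int
    mu: float = 0.0
    sigma2: float = 0.0
    d: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not 0 <= self.level_index <= N_LEVELS:
            raise ValueError("level_index must be in [0, 20]")
        if self.sigma2 < 0 or not 0 <= self.d <= 1:
            raise ValueError("invalid noise parameters")


def noise_level_grid(kind: str, n_regions: int = 4) -> list[NoiseSpec]:
    """The 20 sweep specs for a noise kind (identical for all region counts)."""
    if kind not in NOISE_KINDS:
        raise ValueError(f"unknown noise kind {kind!r}")
    lo, hi = GRID_RANGES[kind]
    values = np.linspace(lo, hi, N_LEVELS)
    specs = []
    for i, v in enumerate(values, start=1):
        if kind == "gaussian":
            specs.append(
                NoiseSpec(kind, i, mu=float(v), sigma2=GAUSSIAN_FIXED_VARIANCE)
            )
        elif kind == "salt_pepper":
            specs.append(NoiseSpec(kind, i, d=float(v)))
        else:
            specs.append(NoiseSpec(kind, i, sigma2=float(v)))
    return specs


def _to_unit(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return arr.astype(np.float64) / 255.0


def _to_uint8(x: np.ndarray) -> np.ndarray:
    return np.floor(np.clip(x, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def add_gaussian_noise(img: np.ndarray, mu: float, sigma2: float, seed: int = 0) -> np.ndarray:
    """Additive per-pixel N(mu, sigma2) noise on the unit scale."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    arr = np.asarray(img)
    if sigma2 == 0 and mu == 0:
        return arr.astype(np.uint8, copy=True)
    rng = np.random.default_rng(seed)
    x = _to_unit(arr)
    return _to_uint8(x + rng.normal(mu, np.sqrt(sigma2), size=x.shape))


def add_speckle_noise(img: np.ndarray, sigma2: float, seed: int = 0) -> np.ndarray:
    """Multiplicative noise J = I + n*I with zero-mean uniform n.

    ``n`` is uniform on ``[-sigma*sqrt(3), sigma*sqrt(3)]`` (mean 0,
    variance ``sigma2``), the dominant imaging-toolbox convention.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    arr = np.asarray(img)
    if sigma2 == 0:
        return arr.astype(np.uint8, copy=True)
    rng = np.random.default_rng(seed)
    x = _to_unit(arr)
    half = np.sqrt(3.0 * sigma2)
    n = rng.uniform(-half, half, size=x.shape)
    return _to_uint8(x + n * x)


def add_salt_pepper_noise(img: np.ndarray, d: float, seed: int = 0) -> np.ndarray:
    """Impulse noise: exactly round(d*N) pixels forced to 0 or 255.

    Corrupted pixels are chosen without replacement; each flips to salt
    (255) or pepper (0) with probability one half.
    """
    if not 0 <= d <= 1:
        raise ValueError("density must lie in [0, 1]")
    arr = np.asarray(img)
    out = arr.astype(np.uint8, copy=True)
    n_corrupt = int(round(d * arr.size))
    if n_corrupt == 0:
        return out
    rng = np.random.default_rng(seed)
    flat = out.reshape(-1)
    idx = rng.choice(arr.size, size=n_corrupt, replace=False)
    flat[idx] = np.where(rng.random(n_corrupt) < 0.5, 0, 255)
    return out


def add_rician_noise(img: np.ndarray, sigma2: float, seed: int = 0) -> np.ndarray:
    """Rician magnitude noise M = sqrt((I + n1)^2 + n2^2) on the unit scale.

    ``n1, n2`` are independent N(0, sigma2) (the real and imaginary channel
    perturbations of the complex MR signal).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    arr = np.asarray(img)
    if sigma2 == 0:
        return arr.astype(np.uint8, copy=True)
    rng = np.random.default_rng(seed)
    x = _to_unit(arr)
    sigma = np.sqrt(sigma2)
    n1 = rng.normal(0.0, sigma, size=x.shape)
    n2 = rng.normal(0.0, sigma, size=x.shape)
    return _to_uint8(np.sqrt((x + n1) ** 2 + n2**2))


def apply_noise(img: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Dispatch a :class:`NoiseSpec`; level 0 returns the input bit-exactly."""
    if spec.level_index == 0:
        return np.asarray(img).astype(np.uint8, copy=True)
    if spec.kind == "gaussian":
        return add_gaussian_noise(img, spec.mu, spec.sigma2, spec.seed)
    if spec.kind == "speckle":
        return add_speckle_noise(img, spec.sigma2, spec.seed)
    if spec.kind == "salt_pepper":
        return add_salt_pepper_noise(img, spec.d, spec.seed)
    return add_rician_noise(img, spec.sigma2, spec.seed)
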