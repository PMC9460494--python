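# cartseg

Optimization-driven multilevel segmentation of MR-like grayscale images,
with a noise-robustness benchmarking protocol and cartilage shape-feature
extraction.

## What problem this addresses

Regional segmentation of articular-cartilage MR slices is routinely done
by partitioning the intensity histogram: a vector of thresholds
`T1 < T2 < ... < Tn` splits the 256 gray levels into `L = n + 1` regions
(tissue classes). Classic methods (Otsu thresholding, K-means clustering)
are fast but fragile under image noise. This package implements the
alternative: treat threshold selection as a global optimization problem,
score a candidate partition by **Kapur's entropy**

    H(T1..Tn) = Σ_l H_l ,   H_l = − Σ_{j ∈ region l} (p_j/ω_l) ln(p_j/ω_l) ,
    ω_l = Σ_{j ∈ region l} p_j ,

and maximize it with a population metaheuristic — artificial bee colony
(ABC), particle swarm optimization (PSO), its fuzzy-adaptive (FPSO) and
Darwinian (DPSO) variants, or a genetic algorithm (GA). ABC additionally
drives a *soft* model: a pseudo trapezoid-shaped (PTS) fuzzy partition of
the intensity axis defined by one vertex per region, defuzzified to crisp
labels by maximal membership.

Because real MR data and manual annotations are not required, everything
is testable end to end on synthetic knee-like phantoms with exact ground
truth (region label map, cartilage-ribbon mask, analytic geometry).
The robustness protocol corrupts an image with Gaussian, speckle,
salt-and-pepper or Rician noise over a 20-level intensity grid,
re-segments, and scores each result against the method's own noise-free
segmentation (the gold standard) with four label-map metrics: global
SSIM, MSE, Pearson correlation and SNR. One-sided Wilcoxon rank-sum tests
(with a chi-square normality pre-check) compare optimized methods against
the Otsu and K-means baselines.

## Worked example

```python
import dataclasses
from cartseg import generate_phantom, segment, evaluate_against_gold, apply_noise
from cartseg.noise import noise_level_grid

img, truth = generate_phantom(256, 256, n_regions=4, contrast=50, texture_sd=8, seed=0)

gold, info = segment(img, "abc-fuzzy", 4, seed=1)
print("vertices:", info["vertices"], " fitness:", round(info["fitness"], 4))

spec = dataclasses.replace(noise_level_grid("salt_pepper")[9], seed=2)
noisy = apply_noise(img, spec)
test, _ = segment(noisy, "abc-fuzzy", 4, seed=1)
rec = evaluate_against_gold(gold, test)
print(f"d={spec.d:.3f}  SSIM={rec.ssim:.4f}  MSE={rec.mse:.4f}  "
      f"CORR={rec.corr:.4f}  SNR={rec.snr_db:.3f} dB")
```

Output:

```
vertices: [33, 108, 124, 251]  fitness: 14.2859
d=0.246  SSIM=0.3765  MSE=1.0775  CORR=0.4402  SNR=nan dB
```

The bee colony placed four PTS vertices whose midpoint-equivalent
thresholds maximize Kapur entropy (14.29 nats). Corrupting a quarter of
the pixels with impulse noise reclassifies enough of them that structural
similarity with the noise-free segmentation drops to 0.38 and the mean
squared label difference rises to 1.08; the SNR's signed numerator went
nonpositive here, so it carries the documented undefined flag (`nan`)
and is excluded from aggregation.

A command-line interface mirrors the library
(`cartseg phantom | noise | segment | features | sweep | report`); e.g.

```sh
cartseg phantom --regions 4 --seed 0 phantom.png
cartseg segment --method abc-fuzzy --regions 4 --seed 1 phantom.png labels.png
```

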