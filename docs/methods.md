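# Methods

This note records the models implemented by `cartseg`, the conventions
that make its numbers reproducible, and the design choices made where the
problem statement left the design open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Threshold model and objectives

A segmentation model is an ordered vector of integer thresholds
`T1 < ... < Tn`, each in `[1, 255]`, over the 256-bin histogram of an
8-bit image. Regions are half-open, upper-exclusive intervals
`T_{l-1} <= I < T_l` with sentinels `T_0 = 0`, `T_L = 256`; a pixel whose
intensity equals a threshold therefore belongs to the upper region.
Labels run 1..L.

**Kapur entropy** (the fitness all metaheuristics maximize) is the sum of
the Shannon entropies, in nats, of the normalized intensity distribution
within each region. Conventions: `0·ln 0 = 0`; a region with zero
probability mass contributes zero entropy. For L regions the sum is
bounded by `L · ln(256/L)` (equal-width uniform regions attain it).

**Between-class variance** (the Otsu criterion) is
`Σ_l ω_l (μ_l − μ)²`. The multi-threshold Otsu baseline follows the
equal-area scheme: the axis is split into `p = n` areas of width
`256/p`; within each area the single threshold maximizing the
between-class variance of that area's (renormalized) sub-histogram is
chosen, ties toward the smallest threshold, and an area with no mass
falls back to its midpoint. With `p = 1` this is the classic full-range
Otsu threshold and coincides exactly with the exhaustive
between-class-variance optimum.

**Exhaustive oracle.** `exhaustive_search` returns the true global
optimum by enumeration and anchors every optimizer test. Threshold
values inducing the same partition of the active (nonzero) bins are
equivalent; the search enumerates only the minima of those equivalence
classes, augmented with `+k` offsets (`k < n`) so vectors with empty
middle regions stay representable — a set provably containing the
lexicographically smallest global optimum, which is the tie-break. The
`n <= 3` paths are vectorized over a precomputed region-term matrix;
`n >= 4` falls back to combination enumeration behind a 2×10⁶ guard.

## Fuzzy soft thresholding

A soft model is a strictly increasing vertex vector `V1 < ... < VL` in
`[0, 255]`, one vertex per region. Membership functions are pseudo
trapezoid-shaped: `μ_l` peaks (value 1) at `V_l`, falls linearly to 0 at
the adjacent vertices, and the first/last functions extend their plateau
to the axis ends. Adjacent pairs are exact complements, so the functions
sum to 1 at every intensity, at most two are nonzero anywhere, and
`μ_k(V_l) = δ_kl` (the fuzzy-partition laws).

Defuzzification takes the maximal membership, ties toward the lower
region index. This is identical to hard thresholding at
`floor((V_l + V_{l+1})/2) + 1`, and the vertex fitness is defined as the
Kapur entropy of that midpoint-equivalent partition — one fitness for
hard and soft models, so all methods compete on the same objective. A
fuzzy-weighted entropy was deliberately not invented.

## Optimizers

All five methods maximize a vectorized objective over sorted distinct
integer vectors. Candidates are real-valued internally and repaired at
evaluation (round, clip, sort, then minimal shifts to enforce strict
increase within bounds). Each run uses a single seeded NumPy generator
and keeps elitist bookkeeping: the per-iteration best-fitness history is
non-decreasing and the reported fitness always equals the objective of
the reported vector. Defaults: 100 iterations, population 50
(`preset_2`: 500/200).

* **ABC** — `population // 2` food sources; employed and onlooker phases
  perturb one coordinate toward/away from a random partner
  (`v = x + φ(x − x_k)`, `φ ~ U(−1,1)`) with greedy acceptance; onlookers
  select sources fitness-proportionally; sources stuck past `limit = 50`
  trials are re-scouted uniformly.
* **PSO** — velocity `v ← w v + c1 r1 (p_i − x) + c2 r2 (p_g − x)` with
  `c1 = c2 = 2`, per-dimension `r1, r2 ~ U(0,1)`, velocity clamped to 20%
  of the search range, inertia `w` decaying linearly 0.9 → 0.4. The
  inertia term is included even though the plain velocity rule is often
  written without one, because the fuzzy variant explicitly modulates it.
* **FPSO** — PSO whose `w` is steered each iteration by a two-input
  (NCBPE, current `w`), one-output (Δw) fuzzy controller: 3×3 rule base
  over triangular low/medium/high sets, singleton outputs ±0.05/0,
  min-AND rule strength, weighted-average defuzzification, `w` clamped
  to `[0.2, 1.2]`. The progress input NCBPE is the number of iterations
  since the global best improved, normalized over a 10-iteration window
  (0 = improving now, 1 = stalled): steady progress shrinks `w`
  (exploitation), prolonged stagnation raises it unless `w` is already
  high. With the input pinned at 0 the controller output is −0.05
  everywhere, driving `w` monotonically to its lower clamp. The rule
  base and the NCBPE source are this package's documented design; a
  fitness-gap normalization was evaluated and rejected during
  development because it collapsed the inertia weight prematurely.
* **DPSO** — multiple PSO swarms (4 initial, floor 2, cap 6; ~12
  particles each from a population of 50, 5–50 per swarm). A swarm that
  improves its best resets its stagnancy counter and may spawn a
  particle; a new global best may found a new swarm with probability
  `f/NS` (`f ~ U(0,1)`, `NS` = swarm count). A swarm stagnating 10
  iterations loses its worst particle and its counter restarts at
  `SCC_max (1 − 1/(N_kill + 1))`, so repeated failure is punished sooner;
  a swarm shrinking below the particle floor is deleted, or re-scouted
  with fresh particles when the swarm count is already at its floor.
  Structural constants are this package's defaults (all configurable) —
  the dynamics are specified, the constants were not.
* **GA** — generational: roulette selection (fitness shifted by the
  minimum when negative; degenerate all-equal populations select
  uniformly), single-point crossover on the sorted vector at rate 0.8,
  per-gene uniform-reset mutation at rate 0.1, elitism of 1.

## K-means baseline

One-dimensional Lloyd iteration over the 256-bin histogram
(mathematically identical to clustering raw pixels). Initialization
picks k distinct intensities spread over the intensity quantiles with a
small seeded jitter; an emptied cluster re-seeds at the populated
intensity farthest from the current centroids; iteration stops when no
pixel changes class. Labels are renumbered 1..k by ascending centroid.
Intensity is the only feature — the benchmark compares intensity-region
models, and spatial coordinates would change the model class.

## Noise generators

All noise arithmetic runs on the normalized `[0, 1]` scale (the sweep
parameters are unit-scale), followed by clipping and re-quantization to
8 bits (round half up). Zero parameters return the input bit-exactly.

* Gaussian: additive per-pixel `N(μ, σ²)`; the sweep varies
  `μ ∈ [0.01, 0.2]` with `σ² = 0.01` fixed.
* Speckle: `J = I + nI` with `n` uniform on `[−σ√3, σ√3]` (zero mean,
  variance σ²) — the dominant imaging-toolbox convention; a Gaussian
  `n` would be a one-line change. Sweep `σ² ∈ [0.01, 0.2]`.
* Salt-and-pepper: exactly `round(d·N)` pixels chosen without
  replacement, each set to 0 or 255 with probability ½ (exact count
  rather than per-pixel Bernoulli, making tests deterministic in count).
  Sweep `d ∈ [0.17, 0.33]`.
* Rician: `M = sqrt((I + n1)² + n2²)`, `n1, n2 ~ N(0, σ²)` independent —
  the MRI magnitude model; Rayleigh with mean `σ√(π/2)` where `I = 0`,
  near-Gaussian for `I ≫ σ`. Sweep `σ² ∈ [0.02, 0.4]`.

Each sweep has 20 linearly spaced levels (level 0 = native image).
Noisy images are re-quantized before segmentation, since all objectives
operate on 256-bin histograms. Note one consequence of clipping: at
intensities near the range ends part of the noise distribution is
clipped away, so moment checks in the tests are made at mid-range
intensities where clipping never triggers.

## Evaluation metrics

All metrics compare integer label matrices. SSIM uses whole-image
statistics (no sliding window): `C1 = C2 = (k·dynamic_range)²` with
`k = 0.02` and dynamic range `L − 1`; variances and covariance use the
n−1 convention. MSE is the mean squared label difference. Pearson
correlation is undefined (NaN flag) when either map has zero variance.
SNR is implemented literally as `10·log10(Σ(g² − f²) / Σ(g − f)²)` —
the signed numerator can go nonpositive, producing a NaN flag, and
identical maps give +inf; a conventional `Σg²` numerator is available
behind a switch for sensitivity analysis. Aggregation excludes flagged
entries and reports their count.

Statistical scheme: chi-square goodness-of-fit against a fitted normal
(equal-probability bins, `round(√n)` capped at `n/5` so expected counts
stay ≥ 5, df = bins − 3) as the normality pre-check; one-sided
two-sample Wilcoxon rank-sum (normal approximation, tie-corrected, via
`scipy.stats.mannwhitneyu`) for the method-vs-baseline comparisons —
`greater` for SSIM/CORR/SNR, `less` for MSE.

## Phantoms and the robustness protocol

A phantom emulates an MR slice with `L` separable tissue classes:
background, a bone-like ellipse, a cartilage-like ribbon (upper
half-annulus, default outer radius 40 px and inner 34 px at 256×256),
a fluid-like band, and small disks for region counts above four.
Region mean intensities sit on a ladder separated by `contrast`,
centered in `[0, 255]`, with Gaussian texture of sd `texture_sd`;
feasibility requires `contrast·(L−1) + 4·texture_sd ≤ 255`. Coordinates
are 0-based row/column, pixel centers; generation is a pure function of
its arguments including the seed. The truth records the label map, the
ribbon mask and the ribbon's rasterized area, Sobel perimeter and
thinning-skeleton length.

Defaults: a single phantom uses contrast 50 / texture 8 (classes ~6σ
apart — cleanly separable, as in a good-quality acquisition); the sweep
uses contrast 22 so one ladder stays feasible up to 10 regions. Note
that entropy-based thresholding *requires* nonzero texture: on a
degenerate image with L exact intensity values, Kapur entropy is
maximized by grouping deltas, not separating them, so zero-texture
phantoms are used only for geometry and I/O tests.

The protocol: per image × method × region count, segment the native
image once — that method's gold standard (never a cross-method
reference) — then corrupt at each of the 20 levels of each noise kind,
re-segment with identical settings and the same method seed, and score
against the gold. Per-cell noise seeds derive from the master seed and
the cell coordinates via CRC-32, giving independent reproducible
streams. Records are emitted for levels 1..20 (a level-0
self-comparison, always perfect, is available behind a flag).
Aggregation takes per-level means across images, then the grand mean of
per-level means. Failures are recorded per cell and the sweep continues.

What the phantom suite does and does not show: phantoms have piecewise
constant tissue classes with independent Gaussian texture — no bias
fields, partial-volume edges, anatomical shape variability, or spatially
correlated noise. Passing the protocol demonstrates the pipeline's
correctness, determinism and relative noise-robustness ordering under
controlled conditions, not clinical segmentation accuracy on real MR
data.

## Cartilage features

One region of a label map is isolated into a binary mask, optionally
keeping only the largest 8-connected lobes. Features: **area** = set
pixel count; **perimeter** = pixels with nonzero 3×3 Sobel gradient
magnitude on the 0/1 mask (integer arithmetic, so "nonzero" is exact;
an isolated pixel scores 8); **skeleton length** = pixel count of the
morphological thinning skeleton (scikit-image's Zhang-style thinning;
pixel count, not geodesic length — thinning variants may differ by a
couple of end pixels, which the tests acknowledge with an explicit
tolerance against an independent textbook implementation). Masks are
padded by one background pixel before Sobel/thinning so frame-touching
borders behave like interior borders. Percentage differences use the
gold feature as denominator: `100·|auto − gold|/gold`.

## Problem sizes used by the checks

The acceptance script and suite run: 20 random histograms with 12–64
active bins for the oracle-equivalence protocol (ABC/PSO/FPSO/DPSO at
100 iterations / population 50, GA at 500/200); 100 random vertex
vectors for the fuzzy laws; 256×256 fields (65 536 samples) for noise
moments; ten 256×256 four-region phantoms for the salt-and-pepper
robustness sweep plus a 4-vs-10-region comparison; three phantoms for
feature recovery; and 20 seeded 10⁴-sample draws for the normality
calibration. These sizes make the whole acceptance run finish in well
under a minute on one CPU while keeping every estimate's sampling error
far inside the asserted tolerances.
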