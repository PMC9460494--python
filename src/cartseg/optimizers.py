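"""Population metaheuristics over ordered integer vectors.

Five maximizers -- artificial bee colony (ABC), particle swarm
optimization (PSO), fuzzy-adaptive PSO (FPSO), Darwinian PSO (DPSO) and a
generational genetic algorithm (GA) -- share one contract: they maximize a
vectorized objective ``f(X) -> (P,)`` over strictly increasing integer
vectors of a given dimension within inclusive bounds (histogram thresholds
in ``[1, 255]`` or PTS vertices in ``[0, 255]``).

Candidates are real-valued internally (keeping the velocity dynamics
smooth) and repaired to sorted distinct integers at every evaluation.
All methods are deterministic given ``cfg.seed`` (one NumPy Generator per
run) and keep elitist bookkeeping: the per-iteration best-fitness history
never decreases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class OptimizerConfig:
    """Run settings shared by all metaheuristics.

    Defaults follow the study conditions: 100 iterations with a population
    of 50 (``preset_2`` switches to the heavy 500/200 setting).
    """

    iterations: int = 100
    population: int = 50
    seed: int = 0
    # PSO family
    c1: float = 2.0
    c2: float = 2.0
    w_start: float = 0.9
    w_end: float = 0.4
    w_min: float = 0.2
    w_max: float = 1.2
    velocity_clamp_frac: float = 0.2
    # ABC
    abc_limit: int = 50
    # DPSO structure
    dpso_initial_swarms: int = 4
    dpso_min_swarms: int = 2
    dpso_max_swarms: int = 6
    dpso_min_particles: int = 5
    dpso_max_particles: int = 50
    dpso_stagnancy: int = 10
    # GA
    ga_crossover: float = 0.8
    ga_mutation: float = 0.1
    ga_elitism: int = 1
    # FPSO progress window: iterations without global improvement that
    # saturate the controller's NCBPE input
    fpso_stag_window: int = 10

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.population < 2:
            raise ValueError("population must be >= 2")


def preset_1(seed: int = 0) -> OptimizerConfig:
    """Standard setting: 100 iterations, population 50."""
    return OptimizerConfig(iterations=100, population=50, seed=seed)


def preset_2(seed: int = 0) -> OptimizerConfig:
    """Heavy setting: 500 iterations, population 200."""
    return OptimizerConfig(iterations=500, population=200, seed=seed)


@dataclass
class OptResult:
    """Outcome of one optimizer run."""

    best_vector: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)
    evaluations: int = 0
    seed: int = 0


# ---------------------------------------------------------------------------
# shared plumbing
# ---------------------------------------------------------------------------


def repair_int_vectors(X: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Map real candidate rows to sorted distinct integers within bounds."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    dim = X.shape[1]
    if hi - lo + 1 < dim:
        raise ValueError("bounds too narrow for distinct integers")
    R = np.sort(np.clip(np.rint(X), lo, hi).astype(np.int64), axis=1)
    for j in range(1, dim):
        R[:, j] = np.maximum(R[:, j], R[:, j - 1] + 1)
    for j in range(dim - 2, -1, -1):
        R[:, j] = np.minimum(R[:, j], R[:, j + 1] - 1)
    R[:, -1] = np.minimum(R[:, -1], hi)
    for j in range(dim - 2, -1, -1):
        R[:, j] = np.minimum(R[:, j], R[:, j + 1] - 1)
    return R


def roulette_probabilities(fitness: np.ndarray) -> np.ndarray:
    """Fitness-proportional selection probabilities p_i = f_i / sum(f).

    Negative entries are rejected; an all-zero vector has no valid
    distribution and raises.
    """
    f = np.asarray(fitness, dtype=np.float64).ravel()
    if f.size == 0 or np.any(f < 0):
        raise ValueError("fitness entries must be nonnegative")
    total = f.sum()
    if total <= 0:
        raise ValueError("at least one fitness entry must be positive")
    return f / total


def _selection_probs(fitness: np.ndarray) -> np.ndarray:
    """Internal roulette with shift-by-min for negative fitness and a
    uniform fallback for degenerate (constant zero-range) populations."""
    f = np.asarray(fitness, dtype=np.float64).ravel()
    f = f - min(f.min(), 0.0)
    total = f.sum()
    if total <= 0:
        return np.full(f.size, 1.0 / f.size)
    return f / total


def ncbpe(cbpe: float, cbpe_min: float, cbpe_max: float) -> float:
    """Normalized current best performance evaluation in [0, 1].

    Values at or above ``cbpe_max`` saturate to 1; at or below ``cbpe_min``
    to 0.
    """
    if not cbpe_max > cbpe_min:
        raise ValueError("cbpe_max must exceed cbpe_min")
    return float(np.clip((cbpe - cbpe_min) / (cbpe_max - cbpe_min), 0.0, 1.0))


def scc_reset(n_kill: int, scc_max: float) -> float:
    """Post-punishment search-counter reset scc_max * (1 - 1/(n_kill+1))."""
    if n_kill < 0:
        raise ValueError("n_kill must be >= 0")
    return scc_max * (1.0 - 1.0 / (n_kill + 1))


def _tri(x: float, a: float, b: float, c: float) -> float:
    """Triangular membership with peak b and feet a, c (shoulders at ends)."""
    if x <= a:
        return 1.0 if a == b else 0.0
    if x >= c:
        return 1.0 if b == c else 0.0
    if x < b:
        return (x - a) / (b - a)
    if x == b:
        return 1.0
    return (c - x) / (c - b)


#: rule-base output centers (rows: NCBPE low/med/high, cols: w low/med/high)
_FUZZY_DELTAS = np.array(
    [
        [-0.05, -0.05, -0.05],  # good progress: shrink inertia, exploit
        [+0.05, 0.0, -0.05],  # moderate progress: steer w toward mid-range
        [+0.05, +0.05, -0.05],  # poor progress: explore unless w already high
    ]
)

#: largest possible magnitude of the controller output
FUZZY_DELTA_BOUND = 0.05


def fuzzy_inertia_update(ncbpe_value: float, w: float, w_min: float = 0.2, w_max: float = 1.2) -> float:
    """Inertia-weight increment from the 3x3 fuzzy controller.

    Two inputs (NCBPE in [0, 1] and the current inertia weight), one output
    (the increment), with triangular low/medium/high sets over each input
    range and singleton output centers aggregated by the rule strengths
    (min-AND, weighted-average defuzzification).
    """
    u = float(np.clip(ncbpe_value, 0.0, 1.0))
    wn = float(np.clip((w - w_min) / (w_max - w_min), 0.0, 1.0))
    mu_n = np.array([_tri(u, 0.0, 0.0, 0.5), _tri(u, 0.0, 0.5, 1.0), _tri(u, 0.5, 1.0, 1.0)])
    mu_w = np.array([_tri(wn, 0.0, 0.0, 0.5), _tri(wn, 0.0, 0.5, 1.0), _tri(wn, 0.5, 1.0, 1.0)])
    strength = np.minimum(mu_n[:, None], mu_w[None, :])
    total = strength.sum()
    if total == 0:
        return 0.0
    return float((strength * _FUZZY_DELTAS).sum() / total)


# ---------------------------------------------------------------------------
# PSO core (plain, fuzzy-adaptive)
# ---------------------------------------------------------------------------


def _pso_core(objective, dim, bounds, cfg: OptimizerConfig, adaptive: bool) -> OptResult:
    lo, hi = bounds
    rng = np.random.default_rng(cfg.seed)
    P = cfg.population
    span = hi - lo
    vmax = cfg.velocity_clamp_frac * span

    X = rng.uniform(lo, hi, size=(P, dim))
    V = rng.uniform(-vmax, vmax, size=(P, dim)) * 0.1
    fit = objective(repair_int_vectors(X, lo, hi))
    evals = P
    pbest_x = X.copy()
    pbest_f = fit.copy()
    g = int(np.argmax(fit))
    gbest_x = X[g].copy()
    gbest_f = float(fit[g])

    if adaptive:
        w = cfg.w_start
        stagnation = 0

    history = []
    for t in range(cfg.iterations):
        if adaptive:
            # progress input: iterations since the global best last improved,
            # normalized over the stagnation window (0 = improving now)
            u = ncbpe(stagnation, 0.0, float(cfg.fpso_stag_window))
            w = float(np.clip(
                w + fuzzy_inertia_update(u, w, cfg.w_min, cfg.w_max),
                cfg.w_min, cfg.w_max,
            ))
        else:
            if cfg.iterations > 1:
                w = cfg.w_start + (cfg.w_end - cfg.w_start) * t / (cfg.iterations - 1)
            else:
                w = cfg.w_start
        r1 = rng.random((P, dim))
        r2 = rng.random((P, dim))
        V = w * V + cfg.c1 * r1 * (pbest_x - X) + cfg.c2 * r2 * (gbest_x[None, :] - X)
        V = np.clip(V, -vmax, vmax)
        X = np.clip(X + V, lo, hi)
        fit = objective(repair_int_vectors(X, lo, hi))
        evals += P
        improved = fit > pbest_f
        pbest_x[improved] = X[improved]
        pbest_f[improved] = fit[improved]
        g = int(np.argmax(pbest_f))
        if pbest_f[g] > gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
            if adaptive:
                stagnation = 0
        elif adaptive:
            stagnation += 1
        history.append(gbest_f)

    best_vec = repair_int_vectors(gbest_x[None, :], lo, hi)[0]
    return OptResult(best_vec, gbest_f, history, evals, cfg.seed)


def optimize_pso(objective, dim: int, bounds: tuple[int, int], cfg: OptimizerConfig) -> OptResult:
    """Plain PSO with linearly decaying inertia weight."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    return _pso_core(objective, dim, bounds, cfg, adaptive=False)


def optimize_fpso(objective, dim: int, bounds: tuple[int, int], cfg: OptimizerConfig) -> OptResult:
    """PSO whose inertia weight is steered by the fuzzy controller.

    The controller's progress input (NCBPE) is the number of iterations
    since the global best last improved, normalized by
    ``cfg.fpso_stag_window`` -- 0 while the swarm is improving, saturating
    at 1 under prolonged stagnation; ``w`` stays clamped to
    ``[w_min, w_max]``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    return _pso_core(objective, dim, bounds, cfg, adaptive=True)


# ---------------------------------------------------------------------------
# ABC
# ---------------------------------------------------------------------------


def optimize_abc(objective, dim: int, bounds: tuple[int, int], cfg: OptimizerConfig) -> OptResult:
    """Artificial bee colony with employed/onlooker/scout phases.

    The population splits equally into employed and onlooker bees, giving
    ``population // 2`` food sources; each phase perturbs one coordinate of
    a source toward/away from a random other source (standard neighbor
    operator ``v = x_ij + phi * (x_ij - x_kj)``, ``phi ~ U(-1, 1)``) with
    greedy acceptance, and sources stuck longer than ``abc_limit`` trials
    are abandoned and re-scouted uniformly.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    lo, hi = bounds
    rng = np.random.default_rng(cfg.seed)
    n_src = max(2, cfg.population // 2)

    X = rng.uniform(lo, hi, size=(n_src, dim))
    fit = objective(repair_int_vectors(X, lo, hi))
    evals = n_src
    trials = np.zeros(n_src, dtype=np.int64)
    g = int(np.argmax(fit))
    gbest_x = X[g].copy()
    gbest_f = float(fit[g])

    def perturb(sources: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = sources
        k = rng.integers(0, n_src - 1, size=idx.size)
        k = np.where(k >= idx, k + 1, k)  # any partner but itself
        j = rng.integers(0, dim, size=idx.size)
        phi = rng.uniform(-1.0, 1.0, size=idx.size)
        cand = X[idx].copy()
        rows = np.arange(idx.size)
        cand[rows, j] = np.clip(
            cand[rows, j] + phi * (cand[rows, j] - X[k, j]), lo, hi
        )
        return cand, objective(repair_int_vectors(cand, lo, hi))

    history = []
    for _ in range(cfg.iterations):
        # employed phase: one trial per source
        src = np.arange(n_src)
        cand, cand_f = perturb(src)
        evals += n_src
        better = cand_f > fit
        X[better] = cand[better]
        fit[better] = cand_f[better]
        trials = np.where(better, 0, trials + 1)

        # onlooker phase: fitness-proportional source selection
        probs = _selection_probs(fit)
        chosen = rng.choice(n_src, size=n_src, p=probs)
        cand, cand_f = perturb(chosen)
        evals += n_src
        for i, s in enumerate(chosen):
            if cand_f[i] > fit[s]:
                X[s] = cand[i]
                fit[s] = cand_f[i]
                trials[s] = 0
            else:
                trials[s] += 1

        g = int(np.argmax(fit))
        if fit[g] > gbest_f:
            gbest_f = float(fit[g])
            gbest_x = X[g].copy()

        # scout phase: abandon exhausted sources
        burnt = np.flatnonzero(trials > cfg.abc_limit)
        if burnt.size:
            X[burnt] = rng.uniform(lo, hi, size=(burnt.size, dim))
            fit[burnt] = objective(repair_int_vectors(X[burnt], lo, hi))
            evals += burnt.size
            trials[burnt] = 0
            g = int(np.argmax(fit))
            if fit[g] > gbest_f:
                gbest_f = float(fit[g])
                gbest_x = X[g].copy()

        history.append(gbest_f)

    best_vec = repair_int_vectors(gbest_x[None, :], lo, hi)[0]
    return OptResult(best_vec, gbest_f, history, evals, cfg.seed)


# ---------------------------------------------------------------------------
# DPSO
# ---------------------------------------------------------------------------


class _Swarm:
    __slots__ = ("X", "V", "pbest_x", "pbest_f", "gbest_x", "gbest_f", "stag", "n_kill")

    def __init__(self, X, V, fit):
        self.X = X
        self.V = V
        self.pbest_x = X.copy()
        self.pbest_f = fit.copy()
        g = int(np.argmax(fit))
        self.gbest_x = X[g].copy()
        self.gbest_f = float(fit[g])
        self.stag = 0.0
        self.n_kill = 0


def optimize_dpso(objective, dim: int, bounds: tuple[int, int], cfg: OptimizerConfig) -> OptResult:
    """Darwinian PSO: multiple swarms with reward/punishment dynamics.

    A swarm that improves its best resets its stagnancy counter and may
    spawn a particle; when it finds a new *global* best it may found a new
    swarm with probability ``f / NS`` (``f ~ U(0,1)``, ``NS`` the current
    swarm count), capped at ``dpso_max_swarms``.  A swarm stagnating past
    the threshold loses its worst particle and its counter restarts at
    ``scc_reset(n_kill, threshold)`` so repeated failure is punished
    sooner; swarms shrinking below the minimum size are deleted (down to
    ``dpso_min_swarms``).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    lo, hi = bounds
    rng = np.random.default_rng(cfg.seed)
    span = hi - lo
    vmax = cfg.velocity_clamp_frac * span
    n0 = cfg.dpso_initial_swarms
    per = max(cfg.dpso_min_particles, cfg.population // n0)
    per = min(per, cfg.dpso_max_particles)

    def new_swarm(size: int) -> _Swarm:
        X = rng.uniform(lo, hi, size=(size, dim))
        V = rng.uniform(-vmax, vmax, size=(size, dim)) * 0.1
        fit = objective(repair_int_vectors(X, lo, hi))
        return _Swarm(X, V, fit)

    swarms = [new_swarm(per) for _ in range(n0)]
    evals = per * n0
    gbest_f = max(s.gbest_f for s in swarms)
    gbest_x = max(swarms, key=lambda s: s.gbest_f).gbest_x.copy()

    history = []
    for t in range(cfg.iterations):
        if cfg.iterations > 1:
            w = cfg.w_start + (cfg.w_end - cfg.w_start) * t / (cfg.iterations - 1)
        else:
            w = cfg.w_start
        spawned: list[_Swarm] = []
        doomed: list[_Swarm] = []
        for s in swarms:
            P = s.X.shape[0]
            r1 = rng.random((P, dim))
            r2 = rng.random((P, dim))
            s.V = (
                w * s.V
                + cfg.c1 * r1 * (s.pbest_x - s.X)
                + cfg.c2 * r2 * (s.gbest_x[None, :] - s.X)
            )
            s.V = np.clip(s.V, -vmax, vmax)
            s.X = np.clip(s.X + s.V, lo, hi)
            fit = objective(repair_int_vectors(s.X, lo, hi))
            evals += P
            improved = fit > s.pbest_f
            s.pbest_x[improved] = s.X[improved]
            s.pbest_f[improved] = fit[improved]
            g = int(np.argmax(s.pbest_f))
            if s.pbest_f[g] > s.gbest_f:
                s.gbest_f = float(s.pbest_f[g])
                s.gbest_x = s.pbest_x[g].copy()
                s.stag = 0.0
                # reward: spawn a particle
                if P < cfg.dpso_max_particles:
                    x = rng.uniform(lo, hi, size=(1, dim))
                    v = rng.uniform(-vmax, vmax, size=(1, dim)) * 0.1
                    f = objective(repair_int_vectors(x, lo, hi))
                    evals += 1
                    s.X = np.vstack([s.X, x])
                    s.V = np.vstack([s.V, v])
                    s.pbest_x = np.vstack([s.pbest_x, x])
                    s.pbest_f = np.concatenate([s.pbest_f, f])
                if s.gbest_f > gbest_f:
                    gbest_f = s.gbest_f
                    gbest_x = s.gbest_x.copy()
                    if len(swarms) + len(spawned) < cfg.dpso_max_swarms:
                        if rng.random() < rng.random() / (len(swarms) + len(spawned)):
                            spawned.append(new_swarm(per))
                            evals += per
            else:
                s.stag += 1.0
                if s.stag >= cfg.dpso_stagnancy and s.X.shape[0] > 1:
                    worst = int(np.argmin(s.pbest_f))
                    keep = np.ones(s.X.shape[0], dtype=bool)
                    keep[worst] = False
                    s.X, s.V = s.X[keep], s.V[keep]
                    s.pbest_x, s.pbest_f = s.pbest_x[keep], s.pbest_f[keep]
                    s.n_kill += 1
                    s.stag = scc_reset(s.n_kill, cfg.dpso_stagnancy)
                    if s.X.shape[0] < cfg.dpso_min_particles:
                        doomed.append(s)
        for s in doomed:
            if len(swarms) > cfg.dpso_min_swarms:
                swarms.remove(s)
            else:
                # cannot delete below the swarm floor: re-scout it instead
                fresh = new_swarm(per)
                evals += per
                idx = swarms.index(s)
                swarms[idx] = fresh
        swarms.extend(spawned)
        history.append(gbest_f)

    best_vec = repair_int_vectors(gbest_x[None, :], lo, hi)[0]
    return OptResult(best_vec, gbest_f, history, evals, cfg.seed)


# ---------------------------------------------------------------------------
# GA
# ---------------------------------------------------------------------------


def optimize_ga(objective, dim: int, bounds: tuple[int, int], cfg: OptimizerConfig) -> OptResult:
    """Generational GA: roulette selection, single-point crossover on the
    sorted vector, per-gene uniform-reset mutation, elitism of 1."""
    if dim < 1:
        raise ValueError("dim must be >= 1")
    lo, hi = bounds
    rng = np.random.default_rng(cfg.seed)
    P = cfg.population

    X = repair_int_vectors(rng.uniform(lo, hi, size=(P, dim)), lo, hi)
    fit = objective(X)
    evals = P
    g = int(np.argmax(fit))
    gbest_x = X[g].copy()
    gbest_f = float(fit[g])

    history = []
    for _ in range(cfg.iterations):
        probs = _selection_probs(fit)
        parents = X[rng.choice(P, size=P, p=probs)]
        children = parents.copy()
        # single-point crossover on consecutive pairs
        for i in range(0, P - 1, 2):
            if rng.random() < cfg.ga_crossover and dim > 1:
                cut = int(rng.integers(1, dim))
                children[i, cut:], children[i + 1, cut:] = (
                    parents[i + 1, cut:].copy(),
                    parents[i, cut:].copy(),
                )
        # per-gene uniform-reset mutation
        mask = rng.random((P, dim)) < cfg.ga_mutation
        resets = rng.integers(lo, hi + 1, size=(P, dim))
        children = np.where(mask, resets, children)
        children = repair_int_vectors(children, lo, hi)
        child_f = objective(children)
        evals += P
        # elitism: preserve the best-so-far individual
        worst = int(np.argmin(child_f))
        children[worst] = gbest_x
        child_f[worst] = gbest_f
        X, fit = children, child_f
        g = int(np.argmax(fit))
        if fit[g] > gbest_f:
            gbest_f = float(fit[g])
            gbest_x = X[g].copy()
        history.append(gbest_f)

    return OptResult(gbest_x.copy(), gbest_f, history, evals, cfg.seed)


#: registry used by the benchmark layer
OPTIMIZERS = {
    "abc": optimize_abc,
    "pso": optimize_pso,
    "fpso": optimize_fpso,
    "dpso": optimize_dpso,
    "ga": optimize_ga,
}
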