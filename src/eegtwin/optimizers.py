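"""Population-based hyperparameter search: PSO, chaotic PSO, GA, quantum GA.

All four optimizers MAXIMIZE a scalar fitness over a bounded box, report the
elitist best-so-far trace (non-decreasing by construction) and are
bit-reproducible under a fixed seed.  Defaults follow the evaluation setup
they were designed for: 300 iterations; population 40 with 20-bit encoding,
generation gap 0.95, crossover 0.7, mutation 0.01 for the genetic pair
(rotation angle 0.01 rad for the quantum variant); population 20 with
acceleration constants c1 = 1.5, c2 = 1.70 for the particle-swarm pair.

The intended fitness for classifier tuning is stratified 10-fold CV accuracy
on the *training* data (see :func:`cv_fitness`); any callable works, e.g.
analytic test surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureMatrix


# ---------------------------------------------------------------------------
# search space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dimension:
    name: str
    lower: float
    upper: float
    scale: str = "linear"  # or "log"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"{self.name}: scale must be linear or log")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log scale requires positive bounds")


@dataclass(frozen=True)
class SearchSpace:
    """Named box; log-scaled dimensions are searched in log coordinates."""

    dimensions: Tuple[Dimension, ...]

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise ValueError("search space must have at least one dimension")

    @property
    def n_dims(self) -> int:
        return len(self.dimensions)

    def internal_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        lo = np.array([np.log(d.lower) if d.scale == "log" else d.lower
                       for d in self.dimensions])
        hi = np.array([np.log(d.upper) if d.scale == "log" else d.upper
                       for d in self.dimensions])
        return lo, hi

    def to_params(self, internal: np.ndarray) -> Dict[str, float]:
        """Map an internal-coordinate point to named parameter values."""
        out = {}
        for v, d in zip(np.atleast_1d(internal), self.dimensions):
            out[d.name] = float(np.exp(v)) if d.scale == "log" else float(v)
        return out


def classifier_search_space(kernel_family: str = "rbf") -> SearchSpace:
    """Standard tuning box: log-scale costs in [2^-8, 2^8], rbf gamma in [2^-10, 2^4]."""
    dims = [
        Dimension("c1", 2.0**-8, 2.0**8, "log"),
        Dimension("c2", 2.0**-8, 2.0**8, "log"),
    ]
    if kernel_family == "rbf":
        dims.append(Dimension("gamma", 2.0**-10, 2.0**4, "log"))
    return SearchSpace(tuple(dims))


# ---------------------------------------------------------------------------
# configuration / result
# ---------------------------------------------------------------------------

@dataclass
class OptimizerConfig:
    algorithm: str = "pso"              # pso | cpso | ga | qga
    max_iterations: int = 300
    population: Optional[int] = None    # default 20 (pso/cpso), 40 (ga/qga)
    chromosome_length: int = 20         # bits per encoded dimension (ga/qga)
    generation_gap: float = 0.95
    p_crossover: float = 0.7
    p_mutation: float = 0.01
    rotation_angle: float = 0.01        # radians (qga)
    acceleration: Tuple[float, float] = (1.5, 1.70)
    inertia: Tuple[float, float] = (0.9, 0.4)   # linear decay start -> end
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("pso", "cpso", "ga", "qga"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        for p in (self.generation_gap, self.p_crossover, self.p_mutation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.max_iterations < 1 or self.chromosome_length < 1:
            raise ValueError("counts must be positive")
        if self.population is not None and self.population < 2:
            raise ValueError("population must be >= 2")

    @property
    def effective_population(self) -> int:
        if self.population is not None:
            return self.population
        return 20 if self.algorithm in ("pso", "cpso") else 40


@dataclass
class OptimizerResult:
    best_params: Dict[str, float]
    best_fitness: float
    fitness_trace: np.ndarray   # per-iteration best-so-far (non-decreasing)
    evaluations: int
    seed: int
    best_internal: np.ndarray = field(default_factory=lambda: np.zeros(0))


Fitness = Callable[[Dict[str, float]], float]


def _evaluate(fitness: Fitness, space: SearchSpace, points: np.ndarray) -> np.ndarray:
    return np.array([fitness(space.to_params(p)) for p in points])


# ---------------------------------------------------------------------------
# CV fitness
# ---------------------------------------------------------------------------

def cv_fitness(params: Dict[str, float], features: FeatureMatrix,
               classifier_factory: Callable[[Dict[str, float]], object],
               folds: int = 10, seed: int = 0) -> float:
    """Stratified k-fold CV accuracy of the classifier built from ``params``.

    Deterministic given the seed; this is the optimization fitness for
    classifier tuning.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = features.labels
    _, counts = np.unique(y, return_counts=True)
    if folds > counts.min():
        raise ValueError(
            f"folds={folds} exceeds the smallest class count ({counts.min()})"
        )
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for train, test in cv.split(features.values, y):
        clf = classifier_factory(params)
        clf.fit(features.values[train], y[train])
        accs.append(np.mean(clf.predict(features.values[test]) == y[test]))
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# particle swarm (and chaotic variant)
# ---------------------------------------------------------------------------

def logistic_map(x: np.ndarray | float, r: float = 4.0) -> np.ndarray | float:
    """One step of the logistic map x -> r x (1 - x) on (0, 1)."""
    return r * x * (1.0 - x)


def _pso_core(fitness: Fitness, space: SearchSpace, config: OptimizerConfig,
              chaotic: bool) -> OptimizerResult:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    lo, hi = space.internal_bounds()
    span = hi - lo
    n, d = config.effective_population, space.n_dims
    c1, c2 = config.acceleration
    w_start, w_end = config.inertia

    if chaotic:
        # logistic-map initialization: one chaotic sequence per dimension
        z = rng.uniform(0.1, 0.9, size=d)
        unit = np.empty((n, d))
        for i in range(n):
            z = logistic_map(z)
            unit[i] = z
        pos = lo + unit * span
    else:
        pos = lo + rng.uniform(size=(n, d)) * span
    vel = rng.uniform(-1.0, 1.0, size=(n, d)) * span * 0.1
    vmax = 0.5 * span

    fit = _evaluate(fitness, space, pos)
    evals = n
    pbest, pbest_fit = pos.copy(), fit.copy()
    g = int(np.argmax(fit))
    gbest, gbest_fit = pos[g].copy(), float(fit[g])

    if chaotic:
        zg = float(rng.uniform(0.1, 0.9))

    trace = np.empty(config.max_iterations)
    for it in range(config.max_iterations):
        w = w_start + (w_end - w_start) * it / max(config.max_iterations - 1, 1)
        r1 = rng.uniform(size=(n, d))
        r2 = rng.uniform(size=(n, d))
        vel = w * vel + c1 * r1 * (pbest - pos) + c2 * r2 * (gbest - pos)
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        fit = _evaluate(fitness, space, pos)
        evals += n
        better = fit > pbest_fit
        pbest[better] = pos[better]
        pbest_fit[better] = fit[better]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

        if chaotic:
            # chaotic perturbation of the global best, shrinking radius
            zg = float(logistic_map(zg))
            radius = 0.1 * (1.0 - it / config.max_iterations)
            zs = np.empty(d)
            zz = zg
            for k in range(d):
                zz = float(logistic_map(zz))
                zs[k] = zz
            cand = np.clip(gbest + radius * span * (2.0 * zs - 1.0), lo, hi)
            cand_fit = fitness(space.to_params(cand))
            evals += 1
            if cand_fit > gbest_fit:
                gbest, gbest_fit = cand, float(cand_fit)
        trace[it] = gbest_fit

    return OptimizerResult(
        best_params=space.to_params(gbest), best_fitness=gbest_fit,
        fitness_trace=trace, evaluations=evals, seed=config.seed,
        best_internal=gbest.copy(),
    )


def pso_optimize(fitness: Fitness, space: SearchSpace,
                 config: OptimizerConfig) -> OptimizerResult:
    """Canonical global-best PSO with linearly decaying inertia."""
    if config.algorithm != "pso":
        raise ValueError("config.algorithm must be 'pso'")
    return _pso_core(fitness, space, config, chaotic=False)


def cpso_optimize(fitness: Fitness, space: SearchSpace,
                  config: OptimizerConfig) -> OptimizerResult:
    """PSO with logistic-map initialization and chaotic global-best refinement."""
    if config.algorithm != "cpso":
        raise ValueError("config.algorithm must be 'cpso'")
    return _pso_core(fitness, space, config, chaotic=True)


# ---------------------------------------------------------------------------
# binary-coded GA
# ---------------------------------------------------------------------------

def decode_bits(bits: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                n_bits: int) -> np.ndarray:
    """Map (pop, d * n_bits) bit arrays to points in the box [lo, hi]."""
    pop = bits.reshape(bits.shape[0], len(lo), n_bits)
    weights = 2.0 ** np.arange(n_bits - 1, -1, -1)
    ints = pop @ weights
    frac = ints / (2.0**n_bits - 1.0)
    return lo + frac * (hi - lo)


def encode_point(point: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                 n_bits: int) -> np.ndarray:
    """Nearest-grid binary encoding of a point (inverse of decode_bits)."""
    frac = (np.asarray(point) - lo) / (hi - lo)
    ints = np.rint(np.clip(frac, 0.0, 1.0) * (2.0**n_bits - 1.0)).astype(np.int64)
    out = np.zeros((len(lo), n_bits), dtype=np.int8)
    for d, v in enumerate(ints):
        out[d] = [(v >> (n_bits - 1 - b)) & 1 for b in range(n_bits)]
    return out.reshape(-1)


def _roulette(rng: np.random.Generator, fit: np.ndarray, k: int) -> np.ndarray:
    shifted = fit - fit.min() + 1e-12
    p = shifted / shifted.sum()
    return rng.choice(len(fit), size=k, p=p)


def ga_optimize(fitness: Fitness, space: SearchSpace,
                config: OptimizerConfig) -> OptimizerResult:
    """Binary GA: roulette selection with generation gap, single-point
    crossover, bit-flip mutation, elitist reinsertion."""
    if config.algorithm != "ga":
        raise ValueError("config.algorithm must be 'ga'")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    lo, hi = space.internal_bounds()
    n, d, L = config.effective_population, space.n_dims, config.chromosome_length
    total_bits = d * L

    pop = (rng.uniform(size=(n, total_bits)) < 0.5).astype(np.int8)
    fit = _evaluate(fitness, space, decode_bits(pop, lo, hi, L))
    evals = n
    g = int(np.argmax(fit))
    best_bits, best_fit = pop[g].copy(), float(fit[g])

    trace = np.empty(config.max_iterations)
    n_off = max(int(round(config.generation_gap * n)), 0)
    for it in range(config.max_iterations):
        if n_off >= 1:
            parents = pop[_roulette(rng, fit, n_off)]
            off = parents.copy()
            # single-point crossover on consecutive pairs
            for i in range(0, n_off - 1, 2):
                if rng.uniform() < config.p_crossover:
                    cut = int(rng.integers(1, total_bits))
                    off[i, cut:], off[i + 1, cut:] = (
                        parents[i + 1, cut:].copy(), parents[i, cut:].copy())
            flip = rng.uniform(size=off.shape) < config.p_mutation
            off ^= flip.astype(np.int8)
            off_fit = _evaluate(fitness, space, decode_bits(off, lo, hi, L))
            evals += n_off
            # elitist reinsertion: offspring replace the worst individuals
            worst = np.argsort(fit)[:n_off]
            pop[worst] = off
            fit[worst] = off_fit
        g = int(np.argmax(fit))
        if fit[g] > best_fit:
            best_bits, best_fit = pop[g].copy(), float(fit[g])
        trace[it] = best_fit

    best = decode_bits(best_bits[None, :], lo, hi, L)[0]
    return OptimizerResult(
        best_params=space.to_params(best), best_fitness=best_fit,
        fitness_trace=trace, evaluations=evals, seed=config.seed,
        best_internal=best,
    )


# ---------------------------------------------------------------------------
# quantum GA
# ---------------------------------------------------------------------------

def _rotation_direction(bit: np.ndarray, best_bit: np.ndarray,
                        worse: np.ndarray, alpha: np.ndarray,
                        beta: np.ndarray) -> np.ndarray:
    """Sign of the rotation angle per qubit (standard lookup table).

    A chromosome whose fitness is below the best's rotates each qubit so that
    the probability of measuring the best individual's bit increases; the
    sign depends on the quadrant of (alpha, beta).
    """
    s = np.zeros(bit.shape)
    differ = (bit != best_bit) & worse[:, None]
    toward_one = differ & (best_bit == 1)
    toward_zero = differ & (best_bit == 0)
    quad = np.sign(alpha * beta)
    quad[quad == 0] = 1.0
    s[toward_one] = quad[toward_one]        # increase |beta|
    s[toward_zero] = -quad[toward_zero]     # increase |alpha|
    return s


def qga_optimize(fitness: Fitness, space: SearchSpace,
                 config: OptimizerConfig) -> OptimizerResult:
    """Quantum-inspired GA: qubit-amplitude chromosomes, measurement collapse,
    rotation-gate update toward the best-so-far bitstring."""
    if config.algorithm != "qga":
        raise ValueError("config.algorithm must be 'qga'")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    lo, hi = space.internal_bounds()
    n, d, L = config.effective_population, space.n_dims, config.chromosome_length
    total_bits = d * L

    # qubit register: amplitudes (alpha, beta), all in equal superposition
    alpha = np.full((n, total_bits), 1.0 / np.sqrt(2.0))
    beta = np.full((n, total_bits), 1.0 / np.sqrt(2.0))

    def measure() -> np.ndarray:
        return (rng.uniform(size=(n, total_bits)) < beta**2).astype(np.int8)

    bits = measure()
    fit = _evaluate(fitness, space, decode_bits(bits, lo, hi, L))
    evals = n
    g = int(np.argmax(fit))
    best_bits, best_fit = bits[g].copy(), float(fit[g])

    trace = np.empty(config.max_iterations)
    for it in range(config.max_iterations):
        worse = fit < best_fit
        sign = _rotation_direction(bits, best_bits[None, :].repeat(n, axis=0),
                                   worse, alpha, beta)
        theta = config.rotation_angle * sign
        cos, sin = np.cos(theta), np.sin(theta)
        alpha, beta = cos * alpha - sin * beta, sin * alpha + cos * beta

        bits = measure()
        fit = _evaluate(fitness, space, decode_bits(bits, lo, hi, L))
        evals += n
        g = int(np.argmax(fit))
        if fit[g] > best_fit:
            best_bits, best_fit = bits[g].copy(), float(fit[g])
        trace[it] = best_fit

    best = decode_bits(best_bits[None, :], lo, hi, L)[0]
    return OptimizerResult(
        best_params=space.to_params(best), best_fitness=best_fit,
        fitness_trace=trace, evaluations=evals, seed=config.seed,
        best_internal=best,
    )


# ---------------------------------------------------------------------------
# dispatch + random-search baseline
# ---------------------------------------------------------------------------

_ALGORITHMS = {
    "pso": pso_optimize,
    "cpso": cpso_optimize,
    "ga": ga_optimize,
    "qga": qga_optimize,
}


def optimize(fitness: Fitness, space: SearchSpace,
             config: OptimizerConfig) -> OptimizerResult:
    """Run the optimizer named in ``config.algorithm``."""
    return _ALGORITHMS[config.algorithm](fitness, space, config)


def random_search(fitness: Fitness, space: SearchSpace, n_evaluations: int,
                  seed: int = 0) -> OptimizerResult:
    """Uniform random baseline at a given evaluation budget."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 19]))
    lo, hi = space.internal_bounds()
    pts = lo + rng.uniform(size=(n_evaluations, space.n_dims)) * (hi - lo)
    fit = _evaluate(fitness, space, pts)
    trace = np.maximum.accumulate(fit)
    g = int(np.argmax(fit))
    return OptimizerResult(
        best_params=space.to_params(pts[g]), best_fitness=float(fit[g]),
        fitness_trace=trace, evaluations=n_evaluations, seed=seed,
        best_internal=pts[g].copy(),
    )
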