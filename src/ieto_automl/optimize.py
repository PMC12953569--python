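"""Population metaheuristics over box-bounded continuous spaces.

Implements the Exponential-Trigonometric Optimization (ETO) baseline, the
improved variant IETO — logistic-chaotic initialization, a spiral-exploration
plus Cauchy-mutation balanced search, and an adaptive linear
exploration/exploitation schedule — together with Whale Optimization (WOA)
and Particle Swarm Optimization (PSO) comparators, and the sigmoid
binarization used to drive the AutoML bit-vector search.

All optimizers minimize, respect box bounds by clipping, and record a
monotone best-fitness trajectory (elitism contract). A single
``numpy.random.Generator`` seeded from the settings makes every run
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

_LOGISTIC_FIXED_POINTS = np.array([0.0, 0.25, 0.5, 0.75, 1.0])

ALGORITHMS = ("eto", "ieto", "woa", "pso")


@dataclass(frozen=True)
class Bounds:
    """Box constraints ``lower[i] <= x[i] <= upper[i]``."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if lower.shape != upper.shape or lower.ndim != 1 or lower.size < 1:
            raise ValueError("lower and upper must be 1-D vectors of equal length")
        if not np.all(lower < upper):
            raise ValueError("degenerate bounds: require lower[i] < upper[i] for all i")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    @property
    def dimension(self) -> int:
        return self.lower.size

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray, atol: float = 0.0) -> bool:
        return bool(
            np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol)
        )

    @classmethod
    def cube(cls, lower: float, upper: float, dimension: int) -> "Bounds":
        return cls(np.full(dimension, lower), np.full(dimension, upper))


@dataclass(frozen=True)
class OptimizerSettings:
    """Run configuration shared by all algorithms.

    ``spiral_b`` is the logarithmic-spiral shape constant; ``cauchy_scale_hi``
    and ``cauchy_scale_lo`` give the Cauchy-mutation scale as a fraction of
    the box range, decayed linearly over the run.
    """

    algorithm: str = "ieto"
    population_size: int = 30
    max_iterations: int = 500
    seed: int = 0
    spiral_b: float = 1.0
    cauchy_scale_hi: float = 0.1
    cauchy_scale_lo: float = 0.01
    exploration_schedule: str = "linear"

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.cauchy_scale_hi < 0 or self.cauchy_scale_lo < 0:
            raise ValueError("Cauchy scales must be >= 0")
        if self.exploration_schedule != "linear":
            raise ValueError("only the linear exploration schedule is implemented")


@dataclass
class Trajectory:
    """Per-iteration best and population-mean fitness."""

    best_fitness: np.ndarray
    mean_fitness: np.ndarray

    def to_records(self) -> list[dict]:
        return [
            {"iteration": i, "best": float(b), "mean": float(m)}
            for i, (b, m) in enumerate(zip(self.best_fitness, self.mean_fitness))
        ]


@dataclass
class Optimum:
    """Result of one optimizer run."""

    position: np.ndarray
    fitness: float
    trajectory: Trajectory
    evaluations: int
    settings: OptimizerSettings | None = field(default=None, repr=False)


def logistic_chaotic_init(n: int, bounds: Bounds, seed: int, burn_in: int = 30) -> np.ndarray:
    """Initial positions from iterates of the fully chaotic logistic map.

    Each (individual, dimension) cell carries an independent chain
    ``x <- 4 x (1 - x)`` started from a uniform draw excluding the map's
    fixed points / short cycles {0, 0.25, 0.5, 0.75, 1}, iterated ``burn_in``
    steps, then affinely mapped onto the box. The r=4 regime has the arcsine
    (Beta(1/2,1/2)) invariant density, giving high-entropy coverage.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, size=(n, bounds.dimension))
    # redraw anything too close to a fixed point of the map
    for _ in range(100):
        bad = np.min(np.abs(x[..., None] - _LOGISTIC_FIXED_POINTS), axis=-1) < 1e-6
        if not bad.any():
            break
        x[bad] = rng.uniform(0.0, 1.0, size=int(bad.sum()))
    for _ in range(burn_in):
        x = logistic_map_step(x)
    return bounds.lower + x * bounds.range


def logistic_map_step(x: np.ndarray | float, r: float = 4.0) -> np.ndarray | float:
    """One iterate of the logistic map ``x <- r x (1 - x)``."""
    return r * x * (1.0 - x)


def spiral_step(
    current: np.ndarray,
    best: np.ndarray,
    rng: np.random.Generator,
    bounds: Bounds,
    b: float = 1.0,
) -> np.ndarray:
    """Logarithmic-spiral move around the incumbent best.

    ``x' = |best - x| * exp(b l) * cos(2 pi l) + best`` applied elementwise
    with independent ``l ~ U(-1, 1)`` per coordinate, clipped to the box.
    Independent draws keep coordinates from collapsing jointly onto the best
    (a scalar ``l`` with ``cos(2 pi l)`` near zero would duplicate the best
    and drain population diversity). At ``current == best`` the radius is
    zero and the move is the identity.
    """
    l = rng.uniform(-1.0, 1.0, size=np.shape(current))
    radius = np.abs(best - current)
    return bounds.clip(radius * np.exp(b * l) * np.cos(2.0 * np.pi * l) + best)


def cauchy_mutation(
    position: np.ndarray,
    scale: float | np.ndarray,
    rng: np.random.Generator,
    bounds: Bounds,
) -> np.ndarray:
    """Heavy-tailed perturbation ``x + scale * C`` with standard Cauchy C, clipped."""
    scale = np.asarray(scale, dtype=float)
    if np.any(scale < 0):
        raise ValueError("scale must be >= 0")
    c = rng.standard_cauchy(size=position.shape)
    return bounds.clip(position + scale * c)


def exploration_probability(iteration: int, max_iterations: int) -> float:
    """Linear schedule: 1 at the start of the run, 0 at the end."""
    if not 0 <= iteration <= max_iterations:
        raise ValueError("iteration must lie in [0, max_iterations]")
    return 1.0 - iteration / max_iterations


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic transfer function."""
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def binarize(position: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Stochastic sigmoid transfer: bit_i = 1 iff u_i < S(x_i)."""
    position = np.asarray(position, dtype=float)
    return (rng.random(position.shape) < sigmoid(position)).astype(np.int64)


def _safe_eval(objective: Callable, x: np.ndarray) -> float:
    v = float(objective(x))
    if not np.isfinite(v):
        logger.warning("objective returned non-finite value; assigning +inf")
        return np.inf
    return v


class _Evaluator:
    """Evaluates populations, counting calls and sanitizing non-finite values."""

    def __init__(self, objective: Callable, bounds: Bounds):
        self.objective = objective
        self.bounds = bounds
        self.count = 0
        self.vectorized = bool(getattr(objective, "vectorized", False))

    def __call__(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        self.count += X.shape[0]
        if self.vectorized:
            f = np.asarray(self.objective(X), dtype=float).ravel()
            if f.size != X.shape[0]:
                raise ValueError("vectorized objective returned wrong-length result")
            bad = ~np.isfinite(f)
            if bad.any():
                logger.warning("%d non-finite objective values set to +inf", int(bad.sum()))
                f[bad] = np.inf
            return f
        return np.array([_safe_eval(self.objective, row) for row in X])


def run_optimizer(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    settings: OptimizerSettings,
) -> Optimum:
    """Minimize ``objective`` over the box with the configured algorithm.

    The returned ``Optimum`` carries the best position ever evaluated, its
    fitness, the per-iteration trajectory and the evaluation count. Identical
    settings (including seed) reproduce the result bit-for-bit.
    """
    rng = np.random.default_rng(settings.seed)
    ev = _Evaluator(objective, bounds)
    runner = {
        "ieto": _run_ieto,
        "eto": _run_eto,
        "woa": _run_woa,
        "pso": _run_pso,
    }[settings.algorithm]
    position, fitness, best_traj, mean_traj = runner(ev, bounds, settings, rng)
    opt = Optimum(
        position=position,
        fitness=float(fitness),
        trajectory=Trajectory(np.asarray(best_traj), np.asarray(mean_traj)),
        evaluations=ev.count,
        settings=settings,
    )
    return opt


def _init_state(ev, bounds, settings, rng, chaotic: bool):
    n = settings.population_size
    if chaotic:
        X = logistic_chaotic_init(n, bounds, seed=int(rng.integers(2**31)))
    else:
        X = bounds.lower + rng.random((n, bounds.dimension)) * bounds.range
    F = ev(X)
    i = int(np.argmin(F))
    return X, F, X[i].copy(), float(F[i])


def _eto_update(X, best, t, T, rng):
    """Exponential-trigonometric local update (documented baseline variant).

    Moves each individual toward the incumbent best along a sine/cosine
    oscillation whose amplitude decays exponentially over the run:
    ``x' = x + a * trig(r1) * |r2 * best - x|`` with ``a = 2 exp(-4 t / T)``,
    ``r1 ~ U(0, 2 pi)``, ``r2 ~ U(0, 2)`` and an equiprobable sine/cosine
    branch per coordinate. Greedy acceptance preserves elitism.
    """
    n, d = X.shape
    amp = 2.0 * np.exp(-4.0 * t / T)
    r1 = rng.uniform(0.0, 2.0 * np.pi, size=(n, d))
    r2 = rng.uniform(0.0, 2.0, size=(n, d))
    branch = rng.random((n, d)) < 0.5
    trig = np.where(branch, np.sin(r1), np.cos(r1))
    return X + amp * trig * np.abs(r2 * best - X)


def _greedy_accept(ev, X, F, cand, best, best_f):
    Fc = ev(cand)
    better = Fc < F
    X[better] = cand[better]
    F[better] = Fc[better]
    i = int(np.argmin(F))
    if F[i] < best_f:
        best, best_f = X[i].copy(), float(F[i])
    return X, F, best, best_f


def _run_eto(ev, bounds, settings, rng):
    X, F, best, best_f = _init_state(ev, bounds, settings, rng, chaotic=False)
    bt, mt = [], []
    T = settings.max_iterations
    for t in range(T):
        cand = bounds.clip(_eto_update(X, best, t, T, rng))
        X, F, best, best_f = _greedy_accept(ev, X, F, cand, best, best_f)
        bt.append(best_f)
        mt.append(float(np.mean(F)))
    return best, best_f, bt, mt


def _run_ieto(ev, bounds, settings, rng):
    X, F, best, best_f = _init_state(ev, bounds, settings, rng, chaotic=True)
    bt, mt = [], []
    T = settings.max_iterations
    for t in range(T):
        p = exploration_probability(t, T)
        explore = rng.random(X.shape[0]) < p
        cand = np.empty_like(X)
        # spiral exploration around the incumbent best
        for i in np.flatnonzero(explore):
            cand[i] = spiral_step(X[i], best, rng, bounds, b=settings.spiral_b)
        # exponential-trigonometric refinement for the rest
        if (~explore).any():
            sub = _eto_update(X[~explore], best, t, T, rng)
            cand[~explore] = bounds.clip(sub)
        X, F, best, best_f = _greedy_accept(ev, X, F, cand, best, best_f)
        # Cauchy mutation of the incumbent best, greedy acceptance
        frac = settings.cauchy_scale_hi + (
            settings.cauchy_scale_lo - settings.cauchy_scale_hi
        ) * (t / T)
        mut = cauchy_mutation(best, frac * bounds.range, rng, bounds)
        fm = ev(mut[None, :])[0]
        if fm < best_f:
            best, best_f = mut, float(fm)
            j = int(np.argmax(F))
            X[j], F[j] = mut, fm
        bt.append(best_f)
        mt.append(float(np.mean(F)))
    return best, best_f, bt, mt


def _run_woa(ev, bounds, settings, rng):
    """Standard Whale Optimization comparator (encircle / search / spiral)."""
    X, F, best, best_f = _init_state(ev, bounds, settings, rng, chaotic=False)
    bt, mt = [], []
    n, d = X.shape
    T = settings.max_iterations
    for t in range(T):
        a = 2.0 * (1.0 - t / T)
        cand = np.empty_like(X)
        for i in range(n):
            r = rng.random(d)
            A = 2.0 * a * r - a
            C = 2.0 * rng.random(d)
            if rng.random() < 0.5:
                if np.all(np.abs(A) < 1.0) or rng.random() < 0.5:
                    cand[i] = best - A * np.abs(C * best - X[i])
                else:
                    leader = X[rng.integers(n)]
                    cand[i] = leader - A * np.abs(C * leader - X[i])
            else:
                l = rng.uniform(-1.0, 1.0)
                cand[i] = (
                    np.abs(best - X[i]) * np.exp(settings.spiral_b * l)
                    * np.cos(2.0 * np.pi * l) + best
                )
        cand = bounds.clip(cand)
        Fc = ev(cand)
        X, F = cand, Fc  # WOA replaces unconditionally
        i = int(np.argmin(F))
        if F[i] < best_f:
            best, best_f = X[i].copy(), float(F[i])
        bt.append(best_f)
        mt.append(float(np.mean(F)))
    return best, best_f, bt, mt


def _run_pso(ev, bounds, settings, rng):
    """Standard constricted PSO comparator (w=0.729, c1=c2=1.49445)."""
    w, c1, c2 = 0.729, 1.49445, 1.49445
    X, F, best, best_f = _init_state(ev, bounds, settings, rng, chaotic=False)
    vmax = 0.5 * bounds.range
    V = rng.uniform(-1.0, 1.0, size=X.shape) * vmax * 0.1
    P, Pf = X.copy(), F.copy()
    bt, mt = [], []
    for _ in range(settings.max_iterations):
        r1 = rng.random(X.shape)
        r2 = rng.random(X.shape)
        V = w * V + c1 * r1 * (P - X) + c2 * r2 * (best - X)
        V = np.clip(V, -vmax, vmax)
        X = bounds.clip(X + V)
        F = ev(X)
        improved = F < Pf
        P[improved] = X[improved]
        Pf[improved] = F[improved]
        i = int(np.argmin(Pf))
        if Pf[i] < best_f:
            best, best_f = P[i].copy(), float(Pf[i])
        bt.append(best_f)
        mt.append(float(np.mean(F)))
    return best, best_f, bt, mt


def trajectory_to_csv(optimum: Optimum, path) -> None:
    """Export a run trajectory as ``iteration,best,mean`` CSV."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["iteration", "best", "mean"])
        writer.writeheader()
        writer.writerows(optimum.trajectory.to_records())
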