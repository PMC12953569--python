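"""Analytic shifted/rotated benchmark suite and the comparison experiment.

The suite mirrors the design of modern competition test sets — 12 functions
F1..F12 at configurable dimension, each composed as ``base(R (x - shift)) +
bias`` with a seeded random shift inside the box and a seeded random rotation
— but uses closed-form classical bases (sphere, Rastrigin, Rosenbrock,
Ackley, Griewank, rotated hyper-ellipsoid, Levy, Zakharov and four hybrid
sums) so that every function and its optimum are known analytically, with no
external data files. ``run_experiment`` reproduces the comparison protocol:
a full algorithm x function x seeded-run factorial with per-run
trajectories, summarized to medians/IQR tables and convergence curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ieto_automl.optimize import Bounds, OptimizerSettings, Optimum, run_optimizer

__all__ = [
    "BenchmarkFunction",
    "ExperimentResult",
    "make_suite",
    "run_experiment",
    "summarize",
]


def _sphere(z):
    return np.sum(z**2, axis=-1)


def _rastrigin(z):
    return np.sum(z**2 - 10.0 * np.cos(2.0 * np.pi * z) + 10.0, axis=-1)


def _rosenbrock(z):
    # optimum of the base form is at z = 0 after the +1 reparameterization
    y = z + 1.0
    return np.sum(100.0 * (y[..., 1:] - y[..., :-1] ** 2) ** 2 + (y[..., :-1] - 1.0) ** 2, axis=-1)


def _ackley(z):
    d = z.shape[-1]
    s1 = np.sum(z**2, axis=-1) / d
    s2 = np.sum(np.cos(2.0 * np.pi * z), axis=-1) / d
    return -20.0 * np.exp(-0.2 * np.sqrt(s1)) - np.exp(s2) + 20.0 + np.e


def _griewank(z):
    d = z.shape[-1]
    idx = np.sqrt(np.arange(1, d + 1))
    return np.sum(z**2, axis=-1) / 4000.0 - np.prod(np.cos(z / idx), axis=-1) + 1.0


def _hyper_ellipsoid(z):
    # Schwefel 1.2 cumulative-sum-of-squares form
    return np.sum(np.cumsum(z, axis=-1) ** 2, axis=-1)


def _levy(z):
    w = 1.0 + z / 4.0
    term1 = np.sin(np.pi * w[..., 0]) ** 2
    term3 = (w[..., -1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * w[..., -1]) ** 2)
    wi = w[..., :-1]
    term2 = np.sum((wi - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * wi + 1.0) ** 2), axis=-1)
    return term1 + term2 + term3


def _zakharov(z):
    d = z.shape[-1]
    s = np.sum(0.5 * np.arange(1, d + 1) * z, axis=-1)
    return np.sum(z**2, axis=-1) + s**2 + s**4


_BASES = {
    "sphere": _sphere,
    "rastrigin": _rastrigin,
    "rosenbrock": _rosenbrock,
    "ackley": _ackley,
    "griewank": _griewank,
    "hyper_ellipsoid": _hyper_ellipsoid,
    "levy": _levy,
    "zakharov": _zakharov,
}

# hybrids: weighted sums of bases over a disjoint dimension partition
_HYBRIDS = [
    (("sphere", "rastrigin", "zakharov"), (0.3, 0.4, 0.3)),
    (("ackley", "hyper_ellipsoid", "griewank"), (0.4, 0.3, 0.3)),
    (("rosenbrock", "levy", "sphere"), (0.3, 0.3, 0.4)),
    (("rastrigin", "griewank", "zakharov"), (0.4, 0.3, 0.3)),
]


@dataclass
class BenchmarkFunction:
    """Shifted, rotated test function with a known optimum.

    Calling with a 1-D vector returns a scalar; a 2-D array returns a vector
    (vectorized population evaluation).
    """

    name: str
    dimension: int
    bounds: Bounds
    shift: np.ndarray
    rotation: np.ndarray
    bias: float
    components: tuple = ()
    weights: tuple = ()
    base_name: str = ""
    vectorized: bool = field(default=True, repr=False)

    @property
    def known_optimum_value(self) -> float:
        return self.bias

    def __call__(self, x: np.ndarray) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 1
        z = (np.atleast_2d(x) - self.shift) @ self.rotation.T
        if self.components:
            cuts = np.array_split(np.arange(self.dimension), len(self.components))
            val = sum(
                w * _BASES[c](z[..., idx])
                for c, w, idx in zip(self.components, self.weights, cuts)
            )
        else:
            val = _BASES[self.base_name](z)
        val = val + self.bias
        return float(val[0]) if scalar else val


def _random_rotation(dim: int, rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    return q * np.sign(np.diag(r))


def make_suite(dimension: int = 10, seed: int = 0) -> list[BenchmarkFunction]:
    """Build the 12-function suite F1..F12 at the given dimension.

    Shift vectors are drawn uniformly from the central 60% of the
    [-100, 100]^D box; rotations are seeded random orthogonal matrices.
    Biases follow the 100*k convention so optima are distinct per function.
    """
    if dimension < 2:
        raise ValueError("dimension must be >= 2")
    rng = np.random.default_rng(seed)
    bounds = Bounds.cube(-100.0, 100.0, dimension)
    suite: list[BenchmarkFunction] = []
    bases = list(_BASES)
    for k in range(12):
        shift = rng.uniform(-60.0, 60.0, size=dimension)
        rotation = _random_rotation(dimension, rng)
        if k < len(bases):
            fn = BenchmarkFunction(
                name=f"F{k + 1}",
                dimension=dimension,
                bounds=bounds,
                shift=shift,
                rotation=rotation,
                bias=100.0 * (k + 1),
                base_name=bases[k],
            )
        else:
            comps, weights = _HYBRIDS[k - len(bases)]
            fn = BenchmarkFunction(
                name=f"F{k + 1}",
                dimension=dimension,
                bounds=bounds,
                shift=shift,
                rotation=rotation,
                bias=100.0 * (k + 1),
                components=comps,
                weights=weights,
            )
        suite.append(fn)
    return suite


@dataclass
class ExperimentResult:
    """Raw factorial outcome: per (algorithm, function) the seeded runs."""

    finals: dict  # (algorithm, function) -> np.ndarray of final best fitness
    trajectories: dict  # (algorithm, function) -> list[np.ndarray] best-fitness curves
    errors: list = field(default_factory=list)
    base_seed: int = 0


def run_experiment(
    algorithms: Sequence[str],
    suite: Sequence[BenchmarkFunction],
    runs: int,
    settings: OptimizerSettings,
) -> ExperimentResult:
    """Full algorithm x function x run factorial with seed = base_seed + run.

    A single failed run is recorded in ``errors`` and does not abort the
    factorial; its slot is filled with +inf.
    """
    if runs < 2:
        raise ValueError("runs must be >= 2")
    result = ExperimentResult(finals={}, trajectories={}, base_seed=settings.seed)
    for alg in algorithms:
        for fn in suite:
            finals = np.empty(runs)
            trajs = []
            for r in range(runs):
                run_settings = OptimizerSettings(
                    algorithm=alg,
                    population_size=settings.population_size,
                    max_iterations=settings.max_iterations,
                    seed=settings.seed + r,
                    spiral_b=settings.spiral_b,
                    cauchy_scale_hi=settings.cauchy_scale_hi,
                    cauchy_scale_lo=settings.cauchy_scale_lo,
                )
                try:
                    opt: Optimum = run_optimizer(fn, fn.bounds, run_settings)
                    finals[r] = opt.fitness
                    trajs.append(opt.trajectory.best_fitness)
                except Exception as exc:  # surfaced, never silently dropped
                    result.errors.append((alg, fn.name, r, repr(exc)))
                    finals[r] = np.inf
                    trajs.append(np.full(settings.max_iterations, np.inf))
            result.finals[(alg, fn.name)] = finals
            result.trajectories[(alg, fn.name)] = trajs
    return result


def summarize(result: ExperimentResult, out_dir: str | Path | None = None,
              plots: bool = False) -> pd.DataFrame:
    """Per-(algorithm, function) medians/IQR, optionally written with curves.

    With ``out_dir`` set, writes ``summary.csv`` and per-function convergence
    CSVs (median best-fitness curve per algorithm); with ``plots=True`` also
    writes box plots (whiskers at +/-1.5 IQR) and convergence figures.
    """
    if not result.finals:
        raise ValueError("empty experiment result")
    rows = []
    for (alg, fname), finals in result.finals.items():
        q1, med, q3 = np.percentile(finals, [25, 50, 75])
        rows.append(
            {
                "algorithm": alg,
                "function": fname,
                "runs": len(finals),
                "median": med,
                "iqr": q3 - q1,
                "best": float(np.min(finals)),
                "worst": float(np.max(finals)),
                "mean": float(np.mean(finals)),
                "std": float(np.std(finals)),
            }
        )
    table = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "summary.csv", index=False)
        functions = sorted({f for _, f in result.finals}, key=lambda s: int(s[1:]))
        algorithms = sorted({a for a, _ in result.finals})
        for fname in functions:
            curves = {
                alg: np.median(np.vstack(result.trajectories[(alg, fname)]), axis=0)
                for alg in algorithms
                if (alg, fname) in result.trajectories
            }
            pd.DataFrame(curves).to_csv(out / f"convergence_{fname}.csv", index_label="iteration")
        if plots:
            _write_plots(result, functions, algorithms, out)
    return table


def _write_plots(result: ExperimentResult, functions, algorithms, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 4, figsize=(16, 10))
    for ax, fname in zip(axes.ravel(), functions):
        data = [result.finals[(alg, fname)] for alg in algorithms]
        ax.boxplot(data, tick_labels=algorithms, whis=1.5)
        ax.set_title(fname)
        ax.set_yscale("symlog")
    fig.tight_layout()
    fig.savefig(out / "boxplots.png", dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(3, 4, figsize=(16, 10))
    for ax, fname in zip(axes.ravel(), functions):
        for alg in algorithms:
            curve = np.median(np.vstack(result.trajectories[(alg, fname)]), axis=0)
            ax.plot(curve, label=alg)
        ax.set_title(fname)
        ax.set_yscale("symlog")
    axes[0, 0].legend()
    fig.tight_layout()
    fig.savefig(out / "convergence.png", dpi=120)
    plt.close(fig)
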