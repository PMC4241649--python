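"""Iteration of the stochastic recursion X_{t+1} = f(X_t, xi_t) X_t.

Single trajectories (:func:`iterate`), vectorized replicate ensembles,
empirical occupation measures, finite-horizon run classification, and the
Monte-Carlo protocols used by the experiments: persistence curves over
initial density, final-point scatters over a parameter grid, and the
minimum-density (accessibility-of-zero) probe.

Numerical conventions: densities evolve in linear scale; values below
``UNDERFLOW`` (1e-300) are clamped to zero (zero is absorbing) and values
above ``OVERFLOW_CAP`` (1e300) are capped so that saturating terms such as
``x/(h+x)`` stay well defined for runs that diverge.  Run classification is
based on the final density only, mirroring a 'final density greater than
threshold' persistence protocol; the thresholds are always reported.
Replicate sub-streams are derived with ``numpy.random.SeedSequence.spawn``,
never ad-hoc seed arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fitness_models import FitnessModel

__all__ = [
    "Trajectory",
    "EmpiricalMeasure",
    "RunClassification",
    "iterate",
    "simulate_ensemble",
    "empirical_measure",
    "classify_run",
    "classify_finals",
    "persistence_curve",
    "final_points_scatter",
    "min_density_probe",
]

UNDERFLOW = 1e-300
OVERFLOW_CAP = 1e300
DELTA_EXT_DEFAULT = 1e-8
M_BIG_DEFAULT = 1e8

EXTINCT, EXPLODED, INTERIOR, UNDETERMINED = "EXTINCT", "EXPLODED", "INTERIOR", "UNDETERMINED"


@dataclass
class Trajectory:
    """A realized path X_0..X_T with seed provenance."""

    x0: float
    densities: np.ndarray
    T: int
    seed: object
    model_id: str
    env_draws: np.ndarray | None = None  # (T,) or (T, dim) in random-name order

    def __post_init__(self):
        assert self.densities.shape == (self.T + 1,)


@dataclass
class EmpiricalMeasure:
    """Occupation fractions of a trajectory over density bins."""

    bin_edges: np.ndarray
    weights: np.ndarray
    t: int

    def mass_below(self, eta: float) -> float:
        """Occupation fraction of [0, eta) (bins fully below eta plus partial none)."""
        below = self.bin_edges[1:] <= eta
        return float(self.weights[below].sum())


@dataclass
class RunClassification:
    verdict: str
    thresholds: tuple[float, float, float | None]  # (delta_ext, m_big, persistence threshold)


def _clamp(x: np.ndarray) -> np.ndarray:
    x = np.where(x < UNDERFLOW, 0.0, x)
    return np.minimum(x, OVERFLOW_CAP)


def _step(model: FitnessModel, x: np.ndarray, xi_row) -> np.ndarray:
    f = model.eval(x, xi_row)
    f = np.asarray(f, dtype=float)
    if np.any(np.isnan(f)) or np.any(f < 0):
        bad = int(np.argmax(np.isnan(f) | (f < 0)))
        raise FloatingPointError(
            f"fitness evaluated to NaN/negative at x={np.atleast_1d(x)[bad]!r}, xi={xi_row!r}"
        )
    return _clamp(np.asarray(x, dtype=float) * f)


def iterate(
    model: FitnessModel,
    x0: float,
    T: int,
    seed: int | np.random.SeedSequence | None = None,
    record_env: bool = False,
    env_draws: np.ndarray | None = None,
) -> Trajectory:
    """Iterate the recursion for one trajectory.

    Deterministic given (model, x0, T, seed).  ``env_draws`` replays a
    recorded environment sequence (common random numbers); otherwise the
    model's environment is sampled one draw per step.
    """
    if x0 < 0:
        raise ValueError("x0 must be >= 0")
    if T < 1:
        raise ValueError("T must be >= 1")
    dim = 0 if model.env is None else model.env.dim
    if env_draws is not None:
        draws = np.asarray(env_draws, dtype=float).reshape(T, -1)
    elif dim > 0:
        draws = model.env.sample(T, seed).reshape(T, -1)
    else:
        draws = np.zeros((T, 0))

    dens = np.empty(T + 1)
    dens[0] = x0
    x = np.asarray(float(x0))
    names = model.random_names
    for t in range(T):
        xi = {n: draws[t, j] for j, n in enumerate(names)}
        x = _step(model, x, xi)
        dens[t + 1] = x
    keep = draws if (record_env or env_draws is not None) and dim > 0 else None
    if keep is not None and keep.shape[1] == 1:
        keep = keep[:, 0]
    return Trajectory(x0=float(x0), densities=dens, T=T, seed=seed, model_id=model.name,
                      env_draws=keep)


def simulate_ensemble(
    model: FitnessModel,
    x0: float | Sequence[float],
    T: int,
    n_reps: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
    keep_last: int = 0,
    track_min: bool = False,
    track_max: bool = False,
):
    """Vectorized batch of independent replicates (one env draw per step,
    shared across no replicates — each replicate gets its own draws).

    ``x0`` may be a scalar (all replicates identical start, ``n_reps``
    required) or a vector of starts (one replicate each).  Returns a dict
    with ``finals`` (n,), optionally ``kept`` (keep_last, n) and ``mins``.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float))
    if n_reps is not None and x.size == 1:
        x = np.repeat(x, n_reps)
    n = x.size
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dim = 0 if model.env is None else model.env.dim
    names = model.random_names

    mins = x.copy() if track_min else None
    maxs = x.copy() if track_max else None
    kept = np.empty((keep_last, n)) if keep_last else None
    for t in range(T):
        if dim > 0:
            draws = model.env.sample(n, rng).reshape(n, -1)
            xi = {nm: draws[:, j] for j, nm in enumerate(names)}
        else:
            xi = {}
        x = _step(model, x, xi)
        if track_min:
            np.minimum(mins, x, out=mins)
        if track_max:
            np.maximum(maxs, x, out=maxs)
        if keep_last and t >= T - keep_last:
            kept[t - (T - keep_last)] = x
    out = {"finals": x}
    if track_min:
        out["mins"] = mins
    if track_max:
        out["maxs"] = maxs
    if keep_last:
        out["kept"] = kept
    return out


def empirical_measure(traj: Trajectory, bin_edges: Sequence[float]) -> EmpiricalMeasure:
    """Fraction of time the trajectory spends in each density interval.

    Edges must be strictly increasing; bins not covering the realized range
    are extended with an underflow/overflow bin so weights always sum to 1.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing, length >= 2")
    d = traj.densities
    lo, hi = d.min(), d.max()
    if lo < edges[0]:
        edges = np.concatenate([[lo], edges])
    if hi >= edges[-1]:
        edges = np.concatenate([edges, [np.nextafter(hi, np.inf)]])
    counts, _ = np.histogram(d, bins=edges)
    weights = counts / d.size
    return EmpiricalMeasure(bin_edges=edges, weights=weights, t=d.size)


def classify_run(
    traj: Trajectory,
    delta_ext: float = DELTA_EXT_DEFAULT,
    m_big: float = M_BIG_DEFAULT,
) -> RunClassification:
    """Finite-horizon proxy for the limit outcome, from the final density only."""
    if not (0 < delta_ext < m_big):
        raise ValueError("need 0 < delta_ext < m_big")
    final = traj.densities[-1]
    if final < delta_ext:
        verdict = EXTINCT
    elif final > m_big:
        verdict = EXPLODED
    else:
        verdict = INTERIOR
    return RunClassification(verdict=verdict, thresholds=(delta_ext, m_big, None))


def classify_finals(
    finals: np.ndarray,
    delta_ext: float = DELTA_EXT_DEFAULT,
    m_big: float = M_BIG_DEFAULT,
) -> dict[str, float]:
    """Outcome fractions for a vector of final densities."""
    finals = np.asarray(finals)
    n = finals.size
    ext = float(np.mean(finals < delta_ext))
    exp_ = float(np.mean(finals > m_big))
    return {
        "n": n,
        EXTINCT: ext,
        EXPLODED: exp_,
        INTERIOR: 1.0 - ext - exp_,
    }


def _wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


def persistence_curve(
    model: FitnessModel,
    x0_grid: Sequence[float],
    T: int,
    n_reps: int,
    threshold: float,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fraction of replicates whose final density exceeds ``threshold``.

    One row per initial density with a Wilson binomial confidence interval.
    Replicates use independent sub-streams spawned from ``seed``.
    """
    if n_reps < 1 or threshold <= 0:
        raise ValueError("need n_reps >= 1 and threshold > 0")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(list(x0_grid)))
    rows = []
    for x0, child in zip(x0_grid, children):
        finals = simulate_ensemble(model, x0, T, n_reps=n_reps, seed=child)["finals"]
        k = int(np.sum(finals > threshold))
        lo, hi = _wilson_ci(k, n_reps, alpha)
        rows.append({"x0": float(x0), "p_hat": k / n_reps, "ci_low": lo, "ci_high": hi,
                     "n_reps": n_reps})
    return pd.DataFrame(rows)


def final_points_scatter(
    model_family: Callable[[float], FitnessModel],
    param_grid: Sequence[float],
    x0_set: Sequence[float],
    T: int,
    n_keep: int,
    seed: int | np.random.SeedSequence = 0,
    param_name: str = "param",
) -> pd.DataFrame:
    """Tail of one long run per (parameter value, initial density).

    For each grid value ``p`` the model ``model_family(p)`` is simulated for
    ``T`` steps from every start in ``x0_set`` and the last ``n_keep``
    densities are emitted tidily (one row per kept point).
    """
    if n_keep > T:
        raise ValueError("n_keep must be <= T")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(list(param_grid)))
    x0s = np.asarray(list(x0_set), dtype=float)
    frames = []
    for p, child in zip(param_grid, children):
        model = model_family(p)
        out = simulate_ensemble(model, x0s, T, seed=child, keep_last=n_keep)
        kept = out["kept"]  # (n_keep, n_x0)
        step = np.arange(T - n_keep + 1, T + 1)
        frames.append(pd.DataFrame({
            param_name: p,
            "x0": np.tile(x0s, n_keep),
            "step": np.repeat(step, x0s.size),
            "density": kept.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def min_density_probe(
    model: FitnessModel,
    x0: float,
    T: int,
    n_reps: int,
    gamma: float,
    seed: int | np.random.SeedSequence = 0,
    alpha: float = 0.05,
) -> dict:
    """Monte-Carlo estimate of P[min_{t<=T} X_t <= gamma].

    A finite-horizon proxy for accessibility of the extinction state: a
    strictly positive estimate witnesses that the dynamics can push the
    density below ``gamma`` from ``x0``.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    out = simulate_ensemble(model, x0, T, n_reps=n_reps, seed=seed, track_min=True)
    k = int(np.sum(out["mins"] <= gamma))
    lo, hi = _wilson_ci(k, n_reps, alpha)
    return {"estimate": k / n_reps, "ci_low": lo, "ci_high": hi, "n_reps": n_reps,
            "gamma": gamma, "T": T}
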