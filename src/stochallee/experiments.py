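"""End-to-end simulation experiments.

Three canonical protocols, each a Monte-Carlo study of an Allee-effect
model under environmental noise, plus a generic regime map and a golden
fixture generator:

- :func:`run_figure1` — persistence probability versus initial density for
  the stochastic mate-limitation model (lognormal fecundity, h = 10,
  persistence threshold 100), one curve per noise level sigma;
- :func:`run_figure2` — long-run density scatter for the mate-limitation
  model with Ricker-type competition, growth rate uniform on
  [4.5 - eps, 4.5 + eps], as a function of the noise half-width eps;
- :func:`run_figure3` — the same scatter for the predator-saturation model
  with Ricker competition, fitness exp(4 - 4x - P/(1/12 + x)), predation
  intensity P uniform on Pbar [1 - eps, 1 + eps], as a function of Pbar.

Full-size protocol defaults (10,000 replicates / 10,000 steps with the
final 1,000 points kept) are exposed alongside scaled-down defaults used by
the test suite; every run is deterministic given its config, and each
output directory receives results.csv plus a metadata.json with the
resolved configuration and seeds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import criteria, dynamics, skeleton
from .env_noise import make_distribution
from .fitness_models import CATALOGUE, FitnessModel, build_model

__all__ = [
    "ExperimentConfig",
    "run_figure1",
    "run_figure2",
    "run_figure3",
    "regime_map",
    "generate_fixtures",
    "mate_limitation_model",
    "mate_limitation_ricker_model",
    "predator_saturation_ricker_model",
]

# protocol constants stated by the source experiments
FIG1_H = 10.0
FIG1_LOGMEAN = 0.1
FIG1_THRESHOLD = 100.0
FIG2_RBAR = 4.5
FIG3_R = 4.0
FIG3_A = 4.0
FIG3_H = 1.0 / 12.0

#: default initial densities for the scatter protocols (geometric grid; the
#: source protocol says only 'multiple initial conditions')
X0_SET_DEFAULT = tuple(np.geomspace(1e-2, 10.0, 8))


@dataclass
class ExperimentConfig:
    """Resolved, fully serializable description of one experiment run."""

    experiment: str
    model: dict = field(default_factory=dict)
    grids: dict = field(default_factory=dict)
    T: int = 1000
    n_reps: int = 1000
    n_keep: int = 1000
    threshold: float = FIG1_THRESHOLD
    delta_ext: float = dynamics.DELTA_EXT_DEFAULT
    m_big: float = dynamics.M_BIG_DEFAULT
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_outputs(out: str | Path | None, results: pd.DataFrame, config: ExperimentConfig,
                   extra_meta: dict | None = None) -> None:
    if out is None:
        return
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results.csv", index=False)
    meta = {"config": config.to_dict()}
    if extra_meta:
        meta.update(extra_meta)
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))


# ---------------------------------------------------------------------------
# Model builders for the three protocols
# ---------------------------------------------------------------------------

def mate_limitation_model(sigma: float, h: float = FIG1_H,
                          logmean: float = FIG1_LOGMEAN) -> FitnessModel:
    """Mate-limitation fitness with lognormal fecundity (point mass at sigma=0)."""
    if sigma == 0:
        lam = make_distribution("point_mass", value=float(np.exp(logmean)))
    else:
        lam = make_distribution("lognormal", logmean=logmean, logsd=sigma)
    return build_model("mate_limitation", {"lam": lam, "h": h})


def mate_limitation_ricker_model(eps: float, rbar: float = FIG2_RBAR, a: float = 1.0,
                                 h: float = FIG1_H) -> FitnessModel:
    """Ricker-competition mate-limitation model, growth rate uniform on [rbar-eps, rbar+eps]."""
    r = make_distribution("uniform", center=rbar, halfwidth=eps)
    return build_model("mate_limitation_ricker", {"r": r, "a": a, "h": h})


def predator_saturation_ricker_model(pbar: float, eps: float, r: float = FIG3_R,
                                     a: float = FIG3_A, h: float = FIG3_H) -> FitnessModel:
    """Ricker-competition predator-saturation model, P uniform on pbar*[1-eps, 1+eps]."""
    P = make_distribution("uniform", center=pbar, halfwidth=pbar * eps)
    return build_model("predator_saturation_ricker", {"r": r, "a": a, "h": h, "P": P})


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def run_figure1(
    sigmas: Sequence[float] = (0.0, 0.25, 0.5, 1.0),
    x0_grid: Sequence[float] = (1, 5, 10, 20, 30, 50, 70, 85, 90, 95, 100, 110, 130, 160, 200, 300),
    T: int = 1000,
    n_reps: int = 1000,
    threshold: float = FIG1_THRESHOLD,
    h: float = FIG1_H,
    logmean: float = FIG1_LOGMEAN,
    seed: int = 0,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Persistence probability versus initial density, one curve per sigma.

    Full-size protocol: n_reps = 10,000 per initial density.  The horizon T
    is not part of the protocol statement; the default 1000 steps is long
    enough that the curves are insensitive to doubling it.
    """
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(list(sigmas)))
    frames = []
    for sigma, child in zip(sigmas, children):
        model = mate_limitation_model(sigma, h=h, logmean=logmean)
        curve = dynamics.persistence_curve(model, x0_grid, T=T, n_reps=n_reps,
                                           threshold=threshold, seed=child)
        curve.insert(0, "sigma", sigma)
        frames.append(curve)
    results = pd.concat(frames, ignore_index=True)
    config = ExperimentConfig(experiment="figure1", T=T, n_reps=n_reps, threshold=threshold,
                              seed=seed, grids={"sigmas": list(sigmas), "x0": list(x0_grid)},
                              model={"name": "mate_limitation", "h": h, "logmean": logmean})
    _write_outputs(out, results, config)
    return results


def run_figure2(
    eps_grid: Sequence[float] = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 4.4),
    x0_set: Sequence[float] = X0_SET_DEFAULT,
    T: int = 10_000,
    n_keep: int = 1000,
    rbar: float = FIG2_RBAR,
    a: float = 1.0,
    h: float = FIG1_H,
    seed: int = 0,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Long-run density scatter over the noise half-width eps (eps < rbar)."""
    if not all(0 <= e < rbar for e in eps_grid):
        raise ValueError("eps grid must lie in [0, rbar)")
    results = dynamics.final_points_scatter(
        lambda e: mate_limitation_ricker_model(e, rbar=rbar, a=a, h=h),
        eps_grid, x0_set, T=T, n_keep=n_keep, seed=seed, param_name="eps")
    config = ExperimentConfig(experiment="figure2", T=T, n_keep=n_keep, seed=seed,
                              grids={"eps": list(eps_grid), "x0": list(x0_set)},
                              model={"name": "mate_limitation_ricker", "rbar": rbar,
                                     "a": a, "h": h})
    _write_outputs(out, results, config)
    return results


def run_figure3(
    pbar_grid: Sequence[float] = (0.15, 0.25, 0.35, 0.45, 0.55, 0.7, 0.85, 1.0),
    eps: float = 0.1,
    x0_set: Sequence[float] = X0_SET_DEFAULT,
    T: int = 10_000,
    n_keep: int = 1000,
    r: float = FIG3_R,
    a: float = FIG3_A,
    h: float = FIG3_H,
    seed: int = 0,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Long-run density scatter over the mean predation intensity Pbar."""
    if not all(p > 0 for p in pbar_grid):
        raise ValueError("pbar grid must be positive")
    results = dynamics.final_points_scatter(
        lambda p: predator_saturation_ricker_model(p, eps, r=r, a=a, h=h),
        pbar_grid, x0_set, T=T, n_keep=n_keep, seed=seed, param_name="pbar")
    config = ExperimentConfig(experiment="figure3", T=T, n_keep=n_keep, seed=seed,
                              grids={"pbar": list(pbar_grid), "eps": eps, "x0": list(x0_set)},
                              model={"name": "predator_saturation_ricker", "r": r, "a": a,
                                     "h": h})
    _write_outputs(out, results, config)
    return results


def regime_map(
    model_family,
    param1: tuple[str, Sequence[float]],
    param2: tuple[str, Sequence[float]],
    x0: float = 1.0,
    T: int = 500,
    n_reps: int = 50,
    seed: int = 0,
    x_max: float = 50.0,
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Regime classification plus a small corroborating ensemble per grid cell.

    ``model_family(v1, v2)`` builds the model for one cell.  Per-cell errors
    are recorded in the table and do not abort the sweep.
    """
    name1, grid1 = param1
    name2, grid2 = param2
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(list(grid1)) * len(list(grid2))))
    rows = []
    for v1 in grid1:
        for v2 in grid2:
            child = next(children)
            row = {name1: v1, name2: v2, "regime": None, "skeleton_verdict": None,
                   "extinct_frac": None, "interior_frac": None, "error": None}
            try:
                model = model_family(v1, v2)
                report = criteria.classify_regime(model, x_max=x_max)
                row["regime"] = report.regime
                try:
                    row["skeleton_verdict"] = skeleton.classify_skeleton(model, x_max=x_max).verdict
                except Exception:
                    row["skeleton_verdict"] = "N/A"
                finals = dynamics.simulate_ensemble(model, x0, T, n_reps=n_reps,
                                                    seed=child)["finals"]
                fracs = dynamics.classify_finals(finals)
                row["extinct_frac"] = fracs[dynamics.EXTINCT]
                row["interior_frac"] = fracs[dynamics.INTERIOR]
            except Exception as exc:  # per-cell failures logged, sweep continues
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    results = pd.DataFrame(rows)
    config = ExperimentConfig(experiment="regime_map", T=T, n_reps=n_reps, seed=seed,
                              grids={name1: list(grid1), name2: list(grid2)})
    _write_outputs(out, results, config)
    return results


# ---------------------------------------------------------------------------
# Golden fixtures
# ---------------------------------------------------------------------------

def _fixture_models() -> dict[str, FitnessModel]:
    """One representative parameterization per catalogue model."""
    return {
        "ricker": build_model("ricker", {"r": make_distribution("normal", mean=0.3, sd=0.5),
                                         "a": 1.0}),
        "beverton_holt": build_model(
            "beverton_holt", {"a": make_distribution("lognormal", logmean=0.5, logsd=0.3),
                              "b": 1.0}),
        "mate_limitation": mate_limitation_model(0.5),
        "predator_saturation": build_model(
            "predator_saturation",
            {"r": make_distribution("normal", mean=1.0, sd=0.2), "P": 0.5, "h": 1.0}),
        "mate_limitation_ricker": mate_limitation_ricker_model(0.5),
        "predator_saturation_ricker": predator_saturation_ricker_model(0.5, 0.1),
        "liebhold_bascompte": build_model(
            "liebhold_bascompte",
            {"gamma": 0.05, "C": 50.0,
             "noise": make_distribution("normal", mean=0.0, sd=0.3)}),
    }


def generate_fixtures(seed: int, out_dir: str | Path, T: int = 64) -> list[Path]:
    """Write seeded golden trajectories for every catalogue model.

    Regenerable bit-identically from the same seed; used as regression
    references by the test suite.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    models = _fixture_models()
    written = []
    for (name, model), child in zip(models.items(), ss.spawn(len(models))):
        traj = dynamics.iterate(model, x0=1.0, T=T, seed=child, record_env=True)
        df = pd.DataFrame({"t": np.arange(T + 1),
                           "density": [repr(float(v)) for v in traj.densities]})
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written.append(path)
    return written
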