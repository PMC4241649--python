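"""Catalogue of per-capita fitness functions f(x, xi).

Each model gives the fitness of a population at density ``x`` under an
environment state ``xi``; the population updates as
``X_{t+1} = f(X_t, xi_t) X_t``.  The catalogue covers the standard
single-species forms:

- ``ricker``                       f = exp(r - a x)                   (negative density dependence)
- ``beverton_holt``                f = a / (1 + b x)                  (negative density dependence)
- ``mate_limitation``              f = lam * x / (h + x)              (positive density dependence)
- ``predator_saturation``          f = exp(r - P / (h + x))           (positive density dependence)
- ``mate_limitation_ricker``       f = exp(r - a x) * x / (h + x)     (mixed)
- ``predator_saturation_ricker``   f = exp(r - a x - P / (h + x))     (mixed)
- ``liebhold_bascompte``           f = exp(gamma (x - C) + noise)     (positive; reconstruction)

Parameters: r is the intrinsic growth rate, a the strength of
intraspecific competition, h a half-saturation density (for mate finding
or predation), lam the number of daughters per mated female, P the
predation intensity, gamma the intrinsic rate of increase and C the
deterministic Allee threshold of the Liebhold–Bascompte form.  The
Liebhold–Bascompte fitness here is a reconstruction from its qualitative
properties (log-linear in density, additive normal noise with mean zero,
f(0) < 1 < f(infinity)); it is intended for qualitative use only.

Any parameter may be supplied as a constant or as an
:class:`~stochallee.env_noise.EnvDistribution`, in which case it is drawn
i.i.d. each generation.  Where the random parameters' moments admit it, a
closed form of the mean log-fitness ``E[log f(x, .)]`` is registered and
used by the criteria module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .env_noise import (
    EnvDistribution,
    NoClosedFormError,
    make_distribution,
    product_distribution,
)

__all__ = ["FitnessModel", "build_model", "monotonicity_probe", "CATALOGUE"]

_BIG_X = 1e8  # proxy density for numeric infinity checks


def _as_param_dict(model: "FitnessModel", xi) -> dict:
    """Merge constants with an environment draw (array in random-name order,
    scalar for a single random coordinate, or an explicit mapping)."""
    p = dict(model.constants)
    if isinstance(xi, Mapping):
        missing = [n for n in model.random_names if n not in xi]
        if missing:  # default unspecified random parameters to the mean environment
            ref = model.reference_environment()
            for n in missing:
                p[n] = ref[n]
        p.update(xi)
        return p
    if model.random_names:
        arr = np.atleast_1d(np.asarray(xi, dtype=float)) if np.ndim(xi) <= 1 else np.asarray(xi)
        if arr.ndim == 1 and len(model.random_names) == 1:
            p[model.random_names[0]] = arr if arr.size > 1 else float(arr[0])
        elif arr.ndim == 1:
            for i, name in enumerate(model.random_names):
                p[name] = float(arr[i])
        else:  # (n, dim) batch
            for i, name in enumerate(model.random_names):
                p[name] = arr[:, i]
    return p


@dataclass(frozen=True)
class FitnessModel:
    """A fitness map f(x, xi) together with its analytic metadata."""

    name: str
    constants: Mapping[str, float]
    random_names: tuple[str, ...]
    env: EnvDistribution | None
    monotonicity: str  # 'decreasing' | 'increasing' | 'mixed'
    _formula: Callable = field(repr=False)
    _zero_limit: Callable = field(repr=False)
    _infinity_limit: Callable = field(repr=False)
    log_fitness_closed_form: Callable | None = field(default=None, repr=False)
    #: True when some random coordinate makes log f(x, .) unbounded below for
    #: x > 0 (normal growth-rate noise, lognormal/gamma multiplicative noise):
    #: the multiplicative 'large noise' regime in which the extinction state is
    #: reachable from everywhere.
    noise_support_unbounded: bool = False

    def eval(self, x, xi) -> np.ndarray:
        """Fitness at density ``x`` under environment ``xi`` (broadcasting)."""
        with np.errstate(over="ignore", under="ignore", invalid="ignore", divide="ignore"):
            out = self._formula(np.asarray(x, dtype=float), _as_param_dict(self, xi))
        return out

    def zero_limit(self, xi) -> np.ndarray:
        return np.asarray(self._zero_limit(_as_param_dict(self, xi)), dtype=float)

    def infinity_limit(self, xi) -> np.ndarray:
        return np.asarray(self._infinity_limit(_as_param_dict(self, xi)), dtype=float)

    @property
    def params(self) -> dict:
        """All named parameters: constants plus random parameter specs."""
        out = dict(self.constants)
        if self.env is not None:
            comps = self.env.components if self.env.family == "product" else (self.env,)
            for name, c in zip(self.random_names, comps):
                out[name] = c
        return out

    def reference_environment(self) -> dict[str, float]:
        """Coordinatewise mean of the environment (the skeleton's xi-bar)."""
        if self.env is None:
            return {}
        means = np.atleast_1d(self.env.mean())
        return {name: float(means[i]) for i, name in enumerate(self.random_names)}

    def to_dict(self) -> dict:
        spec: dict = {"name": self.name, "params": {}}
        for k, v in self.constants.items():
            spec["params"][k] = v
        if self.env is not None:
            comps = self.env.components if self.env.family == "product" else (self.env,)
            for name, c in zip(self.random_names, comps):
                spec["params"][name] = c.to_dict()
        return spec

    @staticmethod
    def from_dict(spec: Mapping) -> "FitnessModel":
        params = {
            k: (EnvDistribution.from_dict(v) if isinstance(v, Mapping) else v)
            for k, v in spec["params"].items()
        }
        return build_model(spec["name"], params)


# ---------------------------------------------------------------------------
# Catalogue formulas
# ---------------------------------------------------------------------------

def _f_ricker(x, p):
    return np.exp(p["r"] - p["a"] * x)


def _f_beverton_holt(x, p):
    return p["a"] / (1.0 + p["b"] * x)


def _f_mate_limitation(x, p):
    return p["lam"] * x / (p["h"] + x)


def _f_predator_saturation(x, p):
    return np.exp(p["r"] - p["P"] / (p["h"] + x))


def _f_mate_limitation_ricker(x, p):
    return np.exp(p["r"] - p["a"] * x) * x / (p["h"] + x)


def _f_predator_saturation_ricker(x, p):
    return np.exp(p["r"] - p["a"] * x - p["P"] / (p["h"] + x))


def _f_liebhold_bascompte(x, p):
    return np.exp(p["gamma"] * (x - p["C"]) + p["noise"])


def _lim(value):
    return lambda p: value


_CAT = {
    "ricker": dict(
        formula=_f_ricker,
        required=("r", "a"),
        monotonicity="decreasing",
        zero=lambda p: np.exp(p["r"]),
        inf=lambda p: np.where(np.asarray(p["a"]) > 0, 0.0, np.exp(p["r"])),
    ),
    "beverton_holt": dict(
        formula=_f_beverton_holt,
        required=("a", "b"),
        monotonicity="decreasing",
        zero=lambda p: np.asarray(p["a"], dtype=float),
        inf=lambda p: np.where(np.asarray(p["b"]) > 0, 0.0, p["a"]),
    ),
    "mate_limitation": dict(
        formula=_f_mate_limitation,
        required=("lam", "h"),
        monotonicity="increasing",
        zero=lambda p: np.zeros_like(np.asarray(p["lam"], dtype=float)),
        inf=lambda p: np.asarray(p["lam"], dtype=float),
    ),
    "predator_saturation": dict(
        formula=_f_predator_saturation,
        required=("r", "P", "h"),
        monotonicity="increasing",
        zero=lambda p: np.exp(p["r"] - p["P"] / p["h"]),
        inf=lambda p: np.exp(np.asarray(p["r"], dtype=float)),
    ),
    "mate_limitation_ricker": dict(
        formula=_f_mate_limitation_ricker,
        required=("r", "a", "h"),
        monotonicity="mixed",
        zero=lambda p: np.zeros_like(np.asarray(p["r"], dtype=float)),
        inf=lambda p: np.where(np.asarray(p["a"]) > 0, 0.0, np.exp(p["r"])),
    ),
    "predator_saturation_ricker": dict(
        formula=_f_predator_saturation_ricker,
        required=("r", "a", "P", "h"),
        monotonicity="mixed",
        zero=lambda p: np.exp(p["r"] - p["P"] / p["h"]),
        inf=lambda p: np.where(np.asarray(p["a"]) > 0, 0.0, np.exp(p["r"])),
    ),
    "liebhold_bascompte": dict(
        formula=_f_liebhold_bascompte,
        required=("gamma", "C", "noise"),
        monotonicity="increasing",
        zero=lambda p: np.exp(-p["gamma"] * p["C"] + p["noise"]),
        inf=lambda p: np.full_like(np.asarray(p["noise"], dtype=float), np.inf),
    ),
}


def _try_mean(dist_or_const) -> float | None:
    if isinstance(dist_or_const, EnvDistribution):
        m = dist_or_const.mean()
        return float(m)
    return float(dist_or_const)


def _try_log_mean(dist_or_const) -> float | None:
    if isinstance(dist_or_const, EnvDistribution):
        try:
            return dist_or_const.log_mean()
        except NoClosedFormError:
            return None
    v = float(dist_or_const)
    return math.log(v) if v > 0 else -math.inf


def _closed_log_fitness(name: str, params: Mapping) -> Callable | None:
    """Build x -> E[log f(x, .)] when the parameter moments admit one.

    Accepts ``x = inf`` and returns -inf / +inf where the limit demands it.
    """
    const = {k: v for k, v in params.items() if not isinstance(v, EnvDistribution)}

    if name == "ricker":
        er, ea = _try_mean(params["r"]), _try_mean(params["a"])

        def g(x):
            x = np.asarray(x, dtype=float)
            return np.where(np.isinf(x), -np.inf if ea > 0 else er, er - ea * x)

        return g
    if name == "beverton_holt":
        ela = _try_log_mean(params["a"])
        if ela is None or isinstance(params["b"], EnvDistribution):
            return None
        b = float(params["b"])

        def g(x):
            x = np.asarray(x, dtype=float)
            return np.where(np.isinf(x), -np.inf if b > 0 else ela, ela - np.log1p(b * x))

        return g
    if name == "mate_limitation":
        ell = _try_log_mean(params["lam"])
        if ell is None or isinstance(params["h"], EnvDistribution):
            return None
        h = float(params["h"])

        def g(x):
            x = np.asarray(x, dtype=float)
            safe = np.where(np.isfinite(x) & (x > 0), x, 1.0)
            body = ell + np.log(safe) - np.log(h + safe)
            return np.where(np.isinf(x), ell, np.where(x == 0, -np.inf, body))

        return g
    if name == "predator_saturation":
        er, ep = _try_mean(params["r"]), _try_mean(params["P"])
        if isinstance(params["h"], EnvDistribution):
            return None
        h = float(params["h"])

        def g(x):
            x = np.asarray(x, dtype=float)
            return np.where(np.isinf(x), er, er - ep / (h + x))

        return g
    if name == "mate_limitation_ricker":
        er, ea = _try_mean(params["r"]), _try_mean(params["a"])
        if isinstance(params["h"], EnvDistribution):
            return None
        h = float(params["h"])

        def g(x):
            x = np.asarray(x, dtype=float)
            safe = np.where(np.isfinite(x) & (x > 0), x, 1.0)
            body = er - ea * safe + np.log(safe) - np.log(h + safe)
            return np.where(
                np.isinf(x), -np.inf if ea > 0 else er, np.where(x == 0, -np.inf, body)
            )

        return g
    if name == "predator_saturation_ricker":
        er, ea, ep = _try_mean(params["r"]), _try_mean(params["a"]), _try_mean(params["P"])
        if isinstance(params["h"], EnvDistribution):
            return None
        h = float(params["h"])

        def g(x):
            x = np.asarray(x, dtype=float)
            return np.where(np.isinf(x), -np.inf if ea > 0 else er, er - ea * x - ep / (h + x))

        return g
    if name == "liebhold_bascompte":
        gam, c = float(params["gamma"]), float(params["C"])
        enoise = _try_mean(params["noise"])

        def g(x):
            x = np.asarray(x, dtype=float)
            return np.where(np.isinf(x), np.inf if gam > 0 else enoise, gam * (x - c) + enoise)

        return g
    return None


def _noise_unbounded(name: str, params: Mapping) -> bool:
    """Does some random coordinate make log f(x, .) unbounded below (x > 0)?"""
    def family(k):
        v = params.get(k)
        return v.family if isinstance(v, EnvDistribution) else None

    if name in ("ricker", "mate_limitation_ricker"):
        return family("r") == "normal" or family("a") in ("lognormal", "gamma")
    if name == "beverton_holt":
        return family("a") in ("lognormal", "gamma")
    if name == "mate_limitation":
        return family("lam") in ("lognormal", "gamma")
    if name in ("predator_saturation", "predator_saturation_ricker"):
        return family("r") == "normal" or family("P") in ("lognormal", "gamma")
    if name == "liebhold_bascompte":
        return family("noise") == "normal"
    return False


def build_model(
    name: str,
    params: Mapping[str, float | EnvDistribution] | None = None,
    *,
    fitness: Callable | None = None,
    monotonicity: str | None = None,
    zero_limit: Callable | None = None,
    infinity_limit: Callable | None = None,
) -> FitnessModel:
    """Build a catalogue (or user-defined) fitness model.

    ``params`` maps parameter names to constants or environment
    distributions; random parameters are drawn i.i.d. each generation,
    jointly independent, in declaration order.

    For ``name='user_defined'`` supply ``fitness(x, param_dict)`` plus
    ``monotonicity`` (or accept 'mixed' and verify with
    :func:`monotonicity_probe`) and optional limit callables.
    """
    params = dict(params or {})
    if name == "user_defined":
        if fitness is None:
            raise ValueError("user_defined model requires a fitness callable")
        entry = dict(
            formula=fitness,
            required=tuple(params),
            monotonicity=monotonicity or "mixed",
            zero=zero_limit or (lambda p: fitness(np.asarray(0.0), p)),
            inf=infinity_limit or (lambda p: fitness(np.asarray(_BIG_X), p)),
        )
    elif name in _CAT:
        entry = dict(_CAT[name])
        if monotonicity is not None:
            entry["monotonicity"] = monotonicity
        missing = [k for k in entry["required"] if k not in params]
        if missing:
            raise ValueError(f"model '{name}' missing parameter(s): {', '.join(missing)}")
    else:
        raise ValueError(f"unknown model name '{name}'")

    constants, random_names, comps = {}, [], []
    for k, v in params.items():
        if isinstance(v, EnvDistribution):
            if v.dim != 1:
                raise ValueError(f"parameter '{k}': per-parameter distributions must be scalar")
            random_names.append(k)
            comps.append(v)
        else:
            constants[k] = float(v)
    env = None
    if comps:
        env = comps[0] if len(comps) == 1 else product_distribution(*comps)

    closed = None if name == "user_defined" else _closed_log_fitness(name, params)
    return FitnessModel(
        name=name,
        constants=constants,
        random_names=tuple(random_names),
        env=env,
        monotonicity=entry["monotonicity"],
        _formula=entry["formula"],
        _zero_limit=entry["zero"],
        _infinity_limit=entry["inf"],
        log_fitness_closed_form=closed,
        noise_support_unbounded=_noise_unbounded(name, params),
    )


# ---------------------------------------------------------------------------
# Monotonicity probe
# ---------------------------------------------------------------------------

@dataclass
class MonotonicityReport:
    is_decreasing: bool
    is_increasing: bool
    increasing_near_zero: bool
    gamma_prefix: float  # largest grid density up to which f increases for all sampled xi
    violation_points: list


def monotonicity_probe(
    model: FitnessModel,
    grid: Sequence[float],
    n_env: int = 64,
    seed: int | np.random.SeedSequence = 0,
    tol: float = 1e-12,
) -> MonotonicityReport:
    """Finite-difference monotonicity verdicts over sampled environments.

    ``gamma_prefix`` reports the largest prefix [grid[0], gamma) of the grid
    on which f is non-decreasing in density for every sampled environment —
    the numeric form of the 'increasing at low density' (Allee) assumption.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing with length >= 2")
    if model.env is not None:
        draws = model.env.sample(n_env, seed)
        draws = draws.reshape(n_env, -1)
    else:
        draws = np.zeros((1, 0))

    vals = np.empty((draws.shape[0], len(grid)))
    for i, xi in enumerate(draws):
        vals[i] = model.eval(grid, {n: xi[j] for j, n in enumerate(model.random_names)})
    diffs = np.diff(vals, axis=1)
    scale = np.maximum(np.abs(vals[:, :-1]), np.abs(vals[:, 1:])) + 1.0
    inc_ok = diffs >= -tol * scale
    dec_ok = diffs <= tol * scale

    all_inc = bool(np.all(inc_ok))
    all_dec = bool(np.all(dec_ok))
    inc_prefix_ok = np.all(inc_ok, axis=0)  # per grid gap, across environments
    k = int(np.argmin(inc_prefix_ok)) if not np.all(inc_prefix_ok) else len(inc_prefix_ok)
    gamma_prefix = float(grid[k]) if k > 0 else float(grid[0])

    violations = []
    if not all_inc and not all_dec:
        bad = np.where(~inc_ok & ~dec_ok)
        violations = [(float(grid[j]), int(i)) for i, j in zip(*bad)][:16]

    return MonotonicityReport(
        is_decreasing=all_dec,
        is_increasing=all_inc,
        increasing_near_zero=k > 0,
        gamma_prefix=gamma_prefix,
        violation_points=violations,
    )


CATALOGUE: dict[str, dict] = {
    name: {
        "formula": {
            "ricker": "f = exp(r - a*x)",
            "beverton_holt": "f = a / (1 + b*x)",
            "mate_limitation": "f = lam * x / (h + x)",
            "predator_saturation": "f = exp(r - P/(h + x))",
            "mate_limitation_ricker": "f = exp(r - a*x) * x/(h + x)",
            "predator_saturation_ricker": "f = exp(r - a*x - P/(h + x))",
            "liebhold_bascompte": "f = exp(gamma*(x - C) + noise)   [reconstruction]",
        }[name],
        "params": entry["required"],
        "monotonicity": entry["monotonicity"],
    }
    for name, entry in _CAT.items()
}
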