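"""Independent, identically distributed environmental drivers.

The population model ``X_{t+1} = f(X_t, xi_t) X_t`` is forced by an i.i.d.
sequence of environment states ``xi_t``.  This module represents the law of a
single environment state as an :class:`EnvDistribution` — one of a small set
of families (point mass, normal, log-normal, uniform, gamma) or an
independent product of them — and provides seeded sampling plus an
expectation engine ``E[g(xi)]`` with closed-form, quadrature and Monte-Carlo
backends.  The expectation engine is what ultimately powers the geometric
mean fitness ``G(x) = exp(E[log f(x, xi)])``.

All randomness flows through :class:`numpy.random.Generator` seeded with the
caller's integer seed (or a ``SeedSequence``); there is no hidden global
state.  Sub-streams elsewhere in the package are derived with
``SeedSequence.spawn``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "EnvDistribution",
    "make_distribution",
    "product_distribution",
    "sample",
    "expectation_of",
    "NoClosedFormError",
    "InvalidParameterError",
]

FAMILIES = ("point_mass", "normal", "lognormal", "uniform", "gamma", "product")

#: relative tail mass discarded when truncating unbounded supports for quadrature
QUAD_TAIL_TOL = 1e-10
DEFAULT_QUAD_NODES = 128
DEFAULT_MC_BUDGET = 10_000


class InvalidParameterError(ValueError):
    """A distribution parameter is missing or outside its family's domain."""


class NoClosedFormError(ValueError):
    """closed_form expectation requested for an unregistered (family, g) pair."""


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise InvalidParameterError(f"parameter '{field_name}': {msg}")


@dataclass(frozen=True)
class EnvDistribution:
    """Law of one i.i.d. environment state (possibly vector valued).

    ``dim`` is the number of independent real coordinates; the ``product``
    family composes one scalar distribution per coordinate and samples them
    independently.  ``support`` is the closed hull of attainable values,
    one ``(low, high)`` pair per coordinate.
    """

    family: str
    params: Mapping[str, float] = field(default_factory=dict)
    components: tuple["EnvDistribution", ...] = ()

    # -- structure ---------------------------------------------------------
    @property
    def dim(self) -> int:
        if self.family == "product":
            return sum(c.dim for c in self.components)
        return 1

    @property
    def support(self) -> tuple[tuple[float, float], ...]:
        if self.family == "product":
            return tuple(s for c in self.components for s in c.support)
        p = self.params
        if self.family == "point_mass":
            return ((p["value"], p["value"]),)
        if self.family == "normal":
            return ((-math.inf, math.inf),)
        if self.family == "lognormal":
            return ((0.0, math.inf),)
        if self.family == "uniform":
            return ((p["lower"], p["upper"]),)
        if self.family == "gamma":
            return ((0.0, math.inf),)
        raise AssertionError(self.family)

    @property
    def bounded_support(self) -> bool:
        return all(math.isfinite(lo) and math.isfinite(hi) for lo, hi in self.support)

    # -- moments -----------------------------------------------------------
    def mean(self) -> np.ndarray:
        """Coordinatewise mean; defined for every supported family."""
        if self.family == "product":
            return np.concatenate([np.atleast_1d(c.mean()) for c in self.components])
        p = self.params
        if self.family == "point_mass":
            m = p["value"]
        elif self.family == "normal":
            m = p["mean"]
        elif self.family == "lognormal":
            m = math.exp(p["logmean"] + 0.5 * p["logsd"] ** 2)
        elif self.family == "uniform":
            m = 0.5 * (p["lower"] + p["upper"])
        elif self.family == "gamma":
            m = p["shape"] / p["rate"]
        else:
            raise AssertionError(self.family)
        return np.asarray(m, dtype=float)

    def log_mean(self) -> float:
        """E[log xi] for scalar positive-support families (closed form)."""
        if self.dim != 1:
            raise NoClosedFormError("log_mean is defined for scalar distributions")
        p = self.params
        if self.family == "point_mass":
            v = p["value"]
            return math.log(v) if v > 0 else -math.inf
        if self.family == "lognormal":
            return p["logmean"]
        if self.family == "gamma":
            return float(special.digamma(p["shape"]) - math.log(p["rate"]))
        if self.family == "uniform":
            lo, hi = p["lower"], p["upper"]
            if lo < 0:
                raise NoClosedFormError("uniform log_mean requires non-negative support")
            if lo == hi:
                return math.log(lo) if lo > 0 else -math.inf
            # integral of log on [lo, hi] divided by width; x log x - x -> 0 at 0
            upper_term = hi * (math.log(hi) - 1.0) if hi > 0 else 0.0
            lower_term = lo * (math.log(lo) - 1.0) if lo > 0 else 0.0
            return (upper_term - lower_term) / (hi - lo)
        raise NoClosedFormError(f"no closed-form E[log xi] for family '{self.family}'")

    # -- sampling ----------------------------------------------------------
    def sample(self, n: int, seed: int | np.random.SeedSequence | np.random.Generator) -> np.ndarray:
        """``n`` i.i.d. draws; shape ``(n,)`` for scalars, ``(n, dim)`` for products."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        return self._draw(n, rng)

    def _draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        p = self.params
        if self.family == "product":
            cols = [np.atleast_2d(c._draw(n, rng).reshape(n, -1)) for c in self.components]
            return np.hstack(cols)
        if self.family == "point_mass":
            return np.full(n, p["value"], dtype=float)
        if self.family == "normal":
            return rng.normal(p["mean"], p["sd"], size=n)
        if self.family == "lognormal":
            return rng.lognormal(p["logmean"], p["logsd"], size=n)
        if self.family == "uniform":
            return rng.uniform(p["lower"], p["upper"], size=n)
        if self.family == "gamma":
            return rng.gamma(p["shape"], 1.0 / p["rate"], size=n)
        raise AssertionError(self.family)

    def frozen(self):
        """scipy.stats frozen distribution for scalar non-degenerate families."""
        p = self.params
        if self.family == "normal":
            return stats.norm(p["mean"], p["sd"])
        if self.family == "lognormal":
            return stats.lognorm(s=p["logsd"], scale=math.exp(p["logmean"]))
        if self.family == "uniform":
            return stats.uniform(loc=p["lower"], scale=p["upper"] - p["lower"])
        if self.family == "gamma":
            return stats.gamma(a=p["shape"], scale=1.0 / p["rate"])
        raise NoClosedFormError(f"no scipy frozen form for family '{self.family}'")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        if self.family == "product":
            return {"family": "product", "components": [c.to_dict() for c in self.components]}
        return {"family": self.family, "params": dict(self.params)}

    @staticmethod
    def from_dict(d: Mapping) -> "EnvDistribution":
        if d["family"] == "product":
            return product_distribution(*[EnvDistribution.from_dict(c) for c in d["components"]])
        return make_distribution(d["family"], **d.get("params", {}))


def make_distribution(family: str, **params: float) -> EnvDistribution:
    """Validate parameters and build an :class:`EnvDistribution`.

    Accepted parameterizations:

    - ``point_mass``: ``value``
    - ``normal``: ``mean``, ``sd`` (sd > 0)
    - ``lognormal``: ``logmean``, ``logsd`` (logsd > 0); samples are strictly positive
    - ``uniform``: either ``center`` and ``halfwidth`` (>= 0) or ``lower``/``upper``
    - ``gamma``: ``shape`` and ``rate`` (both > 0; ``scale`` accepted as 1/rate)
    """
    if family == "product":
        comps = params.get("components")
        if not comps:
            raise InvalidParameterError("parameter 'components': product family needs components")
        return product_distribution(*comps)
    if family not in FAMILIES:
        raise InvalidParameterError(f"parameter 'family': unknown family '{family}'")

    p = dict(params)
    if family == "point_mass":
        _require("value" in p, "value", "required")
        out = {"value": float(p["value"])}
    elif family == "normal":
        _require("mean" in p, "mean", "required")
        _require("sd" in p, "sd", "required")
        _require(p["sd"] > 0, "sd", "must be > 0")
        out = {"mean": float(p["mean"]), "sd": float(p["sd"])}
    elif family == "lognormal":
        _require("logmean" in p, "logmean", "required")
        _require("logsd" in p, "logsd", "required")
        _require(p["logsd"] > 0, "logsd", "must be > 0")
        out = {"logmean": float(p["logmean"]), "logsd": float(p["logsd"])}
    elif family == "uniform":
        if "center" in p or "halfwidth" in p:
            _require("center" in p, "center", "required with halfwidth")
            _require("halfwidth" in p, "halfwidth", "required with center")
            _require(p["halfwidth"] >= 0, "halfwidth", "must be >= 0")
            lo = float(p["center"]) - float(p["halfwidth"])
            hi = float(p["center"]) + float(p["halfwidth"])
        else:
            _require("lower" in p, "lower", "required")
            _require("upper" in p, "upper", "required")
            lo, hi = float(p["lower"]), float(p["upper"])
        _require(hi >= lo, "upper", "must be >= lower")
        if lo == hi:
            return EnvDistribution("point_mass", {"value": lo})
        out = {"lower": lo, "upper": hi}
    elif family == "gamma":
        _require("shape" in p, "shape", "required")
        _require(p["shape"] > 0, "shape", "must be > 0")
        if "rate" in p:
            rate = float(p["rate"])
        elif "scale" in p:
            _require(p["scale"] > 0, "scale", "must be > 0")
            rate = 1.0 / float(p["scale"])
        else:
            _require(False, "rate", "required (or scale)")
        _require(rate > 0, "rate", "must be > 0")
        out = {"shape": float(p["shape"]), "rate": rate}
    else:  # pragma: no cover
        raise AssertionError(family)
    return EnvDistribution(family, out)


def product_distribution(*components: EnvDistribution) -> EnvDistribution:
    """Independent product of scalar (or product) distributions."""
    flat: list[EnvDistribution] = []
    for c in components:
        if c.family == "product":
            flat.extend(c.components)
        else:
            flat.append(c)
    if not flat:
        raise InvalidParameterError("parameter 'components': must be non-empty")
    return EnvDistribution("product", components=tuple(flat))


def point_mass(value: float) -> EnvDistribution:
    return make_distribution("point_mass", value=value)


def sample(dist: EnvDistribution, n: int, seed) -> np.ndarray:
    """Module-level alias for :meth:`EnvDistribution.sample`."""
    return dist.sample(n, seed)


# ---------------------------------------------------------------------------
# Expectation engine
# ---------------------------------------------------------------------------

def _resolve_g(dist: EnvDistribution, g) -> Callable[[np.ndarray], np.ndarray]:
    if g == "identity":
        return lambda x: x
    if g == "log":
        if dist.dim != 1:
            raise ValueError("'log' template applies to scalar distributions")
        return lambda x: np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), -np.inf)
    if callable(g):
        return g
    raise ValueError(f"g must be callable or one of 'identity', 'log'; got {g!r}")


def _closed_form(dist: EnvDistribution, g):
    """Return (value, 0.0) if a closed form is registered, else raise."""
    if dist.family == "point_mass":
        fn = _resolve_g(dist, g)
        val = fn(np.asarray(dist.params["value"], dtype=float))
        return float(val), 0.0
    if g == "identity":
        m = dist.mean()
        return (float(m) if m.size == 1 else m), 0.0
    if g == "log":
        return dist.log_mean(), 0.0
    raise NoClosedFormError(
        f"no closed form registered for family '{dist.family}' with g={g!r}"
    )


def _scalar_quad_rule(dist: EnvDistribution, n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and probability weights integrating E[g(xi)] ~ sum w_i g(x_i)."""
    p = dist.params
    if dist.family == "point_mass":
        return np.array([p["value"]]), np.array([1.0])
    if dist.family == "normal":
        t, w = np.polynomial.hermite.hermgauss(n_nodes)
        nodes = p["mean"] + math.sqrt(2.0) * p["sd"] * t
        return nodes, w / math.sqrt(math.pi)
    if dist.family == "uniform":
        t, w = np.polynomial.legendre.leggauss(n_nodes)
        lo, hi = p["lower"], p["upper"]
        nodes = 0.5 * (hi - lo) * t + 0.5 * (hi + lo)
        return nodes, 0.5 * w  # (hi-lo)/2 * w * pdf, pdf = 1/(hi-lo)
    if dist.family in ("lognormal", "gamma"):
        fr = dist.frozen()
        lo = fr.ppf(QUAD_TAIL_TOL)
        hi = fr.ppf(1.0 - QUAD_TAIL_TOL)
        t, w = np.polynomial.legendre.leggauss(n_nodes)
        nodes = 0.5 * (hi - lo) * t + 0.5 * (hi + lo)
        weights = 0.5 * (hi - lo) * w * fr.pdf(nodes)
        weights = weights / weights.sum()  # renormalize the truncated tail mass
        return nodes, weights
    raise NoClosedFormError(f"no quadrature rule for family '{dist.family}'")


def _quadrature(dist: EnvDistribution, fn, n_nodes: int):
    def eval_rule(nn: int) -> float:
        if dist.family == "product":
            per = nn if dist.dim == 1 else max(8, min(nn, 64))
            grids = [_scalar_quad_rule(c, per) for c in dist.components]
            mesh = np.meshgrid(*[g[0] for g in grids], indexing="ij")
            pts = np.stack([m.ravel() for m in mesh], axis=-1)
            wmesh = np.meshgrid(*[g[1] for g in grids], indexing="ij")
            wts = np.prod(np.stack([m.ravel() for m in wmesh], axis=-1), axis=-1)
            vals = np.asarray(fn(pts), dtype=float)
        else:
            nodes, wts = _scalar_quad_rule(dist, nn)
            vals = np.asarray(fn(nodes), dtype=float)
        if np.any(np.isnan(vals)):
            raise ValueError("g evaluated to NaN on quadrature nodes")
        if np.any(np.isposinf(vals)):
            return math.inf
        if np.any(np.isneginf(vals) & (wts > 0)):
            return -math.inf
        return float(np.sum(wts * vals))

    est = eval_rule(n_nodes)
    if not math.isfinite(est):
        return est, 0.0
    coarse = eval_rule(max(8, n_nodes // 2))
    err = abs(est - coarse) if math.isfinite(coarse) else math.inf
    return est, err


def _monte_carlo(dist: EnvDistribution, fn, budget: int, seed):
    draws = dist.sample(budget, np.random.default_rng(seed))
    vals = np.asarray(fn(draws), dtype=float)
    if np.any(np.isnan(vals)):
        raise ValueError("g evaluated to NaN on Monte-Carlo draws")
    if np.any(np.isposinf(vals)):
        return math.inf, 0.0
    if np.any(np.isneginf(vals)):
        return -math.inf, 0.0
    est = float(vals.mean())
    se = float(vals.std(ddof=1) / math.sqrt(budget)) if budget > 1 else math.inf
    return est, se


def expectation_of(
    dist: EnvDistribution,
    g,
    method: str = "quadrature",
    budget: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
):
    """Compute ``E[g(xi)]`` with the requested backend.

    Returns ``(estimate, error_bound)``.  For ``closed_form`` the error is 0
    and an unregistered (family, g) pair raises :class:`NoClosedFormError`
    (never a silent fallback).  ``quadrature`` reports a node-refinement
    error estimate; ``monte_carlo`` reports the standard error of the mean.
    If g equals -inf on a positive-probability set the expectation is -inf.
    """
    if method == "closed_form":
        return _closed_form(dist, g)
    fn = _resolve_g(dist, g)
    if method == "quadrature":
        return _quadrature(dist, fn, budget or DEFAULT_QUAD_NODES)
    if method == "monte_carlo":
        return _monte_carlo(dist, fn, budget or DEFAULT_MC_BUDGET, seed)
    raise ValueError(f"unknown method '{method}'")
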