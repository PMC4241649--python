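"""Geometric-mean fitness and theorem-based regime classification.

Under multiplicative dynamics the growth-relevant average of fitness is the
geometric mean ``G(x) = exp(E[log f(x, xi)])``.  Its values at the extremes
of density determine the long-run fate of the population:

- purely negative density dependence (f decreasing in x): G(0) < 1 means
  extinction from everywhere, G(infinity) > 1 unbounded growth, and
  G(0) > 1 > G(infinity) stochastic persistence;
- purely positive density dependence (f increasing): G(infinity) < 1 means
  unconditional extinction, G(0) > 1 unbounded growth, and
  G(0) < 1 < G(infinity) conditional persistence (a strong stochastic
  Allee effect: extinction and escape both have positive probability);
- mixed density dependence: G(0) > 1 together with a decreasing tail whose
  geometric mean falls below one gives stochastic persistence; with
  G(0) < 1 the outcome depends on the noise — multiplicatively unbounded
  noise (normal growth-rate or lognormal/gamma factors) with bounded
  one-step growth makes the extinction state reachable from everywhere
  (unconditional extinction), while small compactly supported noise defers
  to the deterministic skeleton's attractor/essential-extinction dichotomy.

A strong Allee effect is a property of G, not of the mean environment:
because G(0) generally differs from the fitness at the average environment
(Jensen's inequality, :func:`jensen_gap`), environmental fluctuations alone
can shift a weak Allee effect to a strong one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .env_noise import expectation_of
from .fitness_models import FitnessModel, monotonicity_probe

__all__ = [
    "GeoMeanResult",
    "RegimeReport",
    "geo_mean_fitness",
    "classify_regime",
    "check_assumptions",
    "jensen_gap",
]

UNCONDITIONAL_EXTINCTION = "UNCONDITIONAL_EXTINCTION"
UNBOUNDED_GROWTH = "UNBOUNDED_GROWTH"
STOCHASTIC_PERSISTENCE = "STOCHASTIC_PERSISTENCE"
CONDITIONAL_PERSISTENCE = "CONDITIONAL_PERSISTENCE"
INDETERMINATE = "INDETERMINATE"

#: |log G| must exceed max(3*error, this) to count as != 1
CRITICAL_BAND = 1e-6


@dataclass
class GeoMeanResult:
    """G(x) = exp(E[log f(x, .)]) with the method and error that produced it."""

    x: float  # density; math.inf for the high-density limit
    G: float
    log_G: float
    method: str
    error: float  # on the log scale: 0 for closed form, quad bound, or MC standard error

    def side_of_one(self) -> str:
        """'below', 'above', or 'critical' when |log G| is within error of 0."""
        band = max(3.0 * self.error, CRITICAL_BAND)
        if self.log_G < -band:
            return "below"
        if self.log_G > band:
            return "above"
        return "critical"


@dataclass
class RegimeReport:
    regime: str
    theorem_trail: str
    evidence: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        ev = {}
        for k, v in self.evidence.items():
            if isinstance(v, GeoMeanResult):
                ev[k] = {"x": v.x, "G": v.G, "log_G": v.log_G, "method": v.method,
                         "error": v.error}
            else:
                ev[k] = v
        return {"regime": self.regime, "theorem_trail": self.theorem_trail, "evidence": ev}


def geo_mean_fitness(
    model: FitnessModel,
    x: float,
    method: str = "auto",
    budget: int | None = None,
    seed=None,
) -> GeoMeanResult:
    """Geometric mean fitness at density ``x`` (``math.inf`` for the limit).

    ``method='auto'`` uses the registered closed form when one exists, else
    quadrature.  G = 0 when the mean log fitness is -inf (e.g. mate
    limitation at zero density) and G = +inf propagates unbounded limits.
    """
    if not (x >= 0 or math.isinf(x)):
        raise ValueError("x must be >= 0 or inf")

    if method in ("auto", "closed_form") and model.log_fitness_closed_form is not None:
        lg = float(model.log_fitness_closed_form(x))
        return GeoMeanResult(x=x, G=math.exp(lg) if lg < 700 else math.inf,
                             log_G=lg, method="closed_form", error=0.0)
    if method == "closed_form":
        raise ValueError(f"no closed-form mean log fitness registered for '{model.name}'")
    if method == "auto":
        method = "quadrature"

    if model.env is None:  # deterministic model: G is just the fitness value
        val = float(model.infinity_limit({}) if math.isinf(x) else model.eval(x, {}))
        lg = math.log(val) if val > 0 else (-math.inf if val == 0 else math.nan)
        if val == math.inf:
            lg = math.inf
        return GeoMeanResult(x=x, G=val, log_G=lg, method="closed_form", error=0.0)

    names = model.random_names

    def g(draws):
        draws = np.asarray(draws, dtype=float).reshape(-1, model.env.dim)
        xi = {n: draws[:, j] for j, n in enumerate(names)}
        vals = model.infinity_limit(xi) if math.isinf(x) else model.eval(np.asarray(x), xi)
        vals = np.asarray(vals, dtype=float)
        with np.errstate(divide="ignore"):
            out = np.where(vals > 0, np.log(np.where(vals > 0, vals, 1.0)), -np.inf)
        return np.where(np.isposinf(vals), np.inf, out)

    lg, err = expectation_of(model.env, g, method=method, budget=budget, seed=seed)
    if lg == -math.inf:
        return GeoMeanResult(x=x, G=0.0, log_G=-math.inf, method=method, error=err)
    if lg == math.inf:
        return GeoMeanResult(x=x, G=math.inf, log_G=math.inf, method=method, error=err)
    return GeoMeanResult(x=x, G=math.exp(lg), log_G=lg, method=method, error=err)


def _g_infinity(model: FitnessModel, method: str, budget, seed) -> GeoMeanResult:
    """G at the high-density limit, with a numeric fallback when no limit is declared."""
    try:
        return geo_mean_fitness(model, math.inf, method=method, budget=budget, seed=seed)
    except Exception:
        a = geo_mean_fitness(model, 1e6, method=method, budget=budget, seed=seed)
        b = geo_mean_fitness(model, 1e8, method=method, budget=budget, seed=seed)
        if not math.isclose(a.log_G, b.log_G, rel_tol=1e-3, abs_tol=1e-6):
            return GeoMeanResult(x=math.inf, G=math.nan, log_G=math.nan,
                                 method=method, error=math.inf)
        return GeoMeanResult(x=math.inf, G=b.G, log_G=b.log_G, method=method, error=b.error)


def check_assumptions(
    model: FitnessModel,
    grid: Sequence[float] | None = None,
    n_env: int = 64,
    seed=0,
    budget: int | None = None,
) -> dict:
    """Numeric verdicts for the low-density and tail assumptions.

    - ``allee_at_zero``: G(0) < 1 (extinction with positive probability at
      low density — the strong-Allee low-density condition);
    - ``increasing_near_zero``: fitness increasing on a prefix [0, gamma) of
      the grid for all sampled environments, with the gamma prefix found;
    - ``decreasing_tail``: a candidate x_c past the maximizer of the mean
      log fitness such that f decreases beyond x_c for all sampled
      environments and G(x_c) < 1 (the sufficient tail condition for
      persistence under mixed density dependence);
    - ``bounded_growth``: sup over the grid of x * f(x, xi_bar) finite and
      attained away from the right edge (heuristic one-step growth bound).
    """
    if grid is None:
        grid = np.geomspace(1e-6, 50.0, 512)
    grid = np.asarray(grid, dtype=float)

    g0 = geo_mean_fitness(model, 0.0, budget=budget, seed=seed)
    report = {"allee_at_zero": {"holds": g0.side_of_one() == "below", "G0": g0.G,
                                "log_G0": g0.log_G}}

    probe = monotonicity_probe(model, grid, n_env=n_env, seed=seed)
    report["increasing_near_zero"] = {
        "holds": probe.increasing_near_zero,
        "gamma_prefix": probe.gamma_prefix,
    }

    # tail: look for the smallest grid point beyond the mean-log-fitness peak
    # after which f is decreasing for all sampled xi and G drops below one
    logg = np.array([geo_mean_fitness(model, float(x), budget=budget, seed=seed).log_G
                     for x in grid])
    finite = np.isfinite(logg)
    tail = {"holds": False, "x_c": None, "tail_G": None}
    if finite.any():
        peak = int(np.nanargmax(np.where(finite, logg, -np.inf)))
        for j in range(peak, len(grid)):
            if logg[j] < 0 and np.isfinite(logg[j]):
                sub = grid[j:]
                if len(sub) >= 2:
                    p2 = monotonicity_probe(model, sub, n_env=n_env, seed=seed)
                    if p2.is_decreasing:
                        tail = {"holds": True, "x_c": float(grid[j]),
                                "tail_G": float(math.exp(logg[j]))}
                break
    report["decreasing_tail"] = tail

    xi_bar = model.reference_environment()
    with np.errstate(over="ignore", under="ignore"):
        growth = grid * np.asarray(model.eval(grid, xi_bar), dtype=float)
    finite_growth = bool(np.all(np.isfinite(growth)))
    peak_at_edge = bool(np.argmax(growth) >= len(grid) - 2)
    report["bounded_growth"] = {
        "holds": finite_growth and not peak_at_edge,
        "sup_x_f": float(np.max(growth)) if finite_growth else math.inf,
        "heuristic": "grid-based; sup of x*f(x, xi_bar) away from the right edge",
    }
    return report


def classify_regime(
    model: FitnessModel,
    grid: Sequence[float] | None = None,
    budget: int | None = None,
    seed=0,
    x_max: float = 50.0,
) -> RegimeReport:
    """Decision tree over G(0), G(infinity) and the model's monotonicity.

    Any geometric mean within error of one yields INDETERMINATE —
    classification at criticality is not statistically meaningful.  For
    mixed models with G(0) < 1 and compact noise the verdict defers to the
    deterministic skeleton and is reported with the skeleton's evidence.
    """
    g0 = geo_mean_fitness(model, 0.0, budget=budget, seed=seed)
    ginf = _g_infinity(model, "auto", budget, seed)
    ev: dict = {"G0": g0, "Ginf": ginf,
                "noise_support_unbounded": model.noise_support_unbounded}
    s0, sinf = g0.side_of_one(), ginf.side_of_one()
    if math.isnan(ginf.log_G):
        return RegimeReport(INDETERMINATE, "no-declared-high-density-limit", ev)

    mono = model.monotonicity
    if mono == "decreasing":
        trail = "decreasing-fitness-trichotomy"
        if s0 == "below":
            return RegimeReport(UNCONDITIONAL_EXTINCTION, trail, ev)
        if sinf == "above":
            return RegimeReport(UNBOUNDED_GROWTH, trail, ev)
        if s0 == "above" and sinf == "below":
            return RegimeReport(STOCHASTIC_PERSISTENCE, trail, ev)
        return RegimeReport(INDETERMINATE, trail, ev)

    if mono == "increasing":
        trail = "increasing-fitness-trichotomy"
        if sinf == "below":
            return RegimeReport(UNCONDITIONAL_EXTINCTION, trail, ev)
        if s0 == "above":
            return RegimeReport(UNBOUNDED_GROWTH, trail, ev)
        if s0 == "below" and sinf == "above":
            return RegimeReport(CONDITIONAL_PERSISTENCE, trail, ev)
        return RegimeReport(INDETERMINATE, trail, ev)

    # mixed density dependence
    assumptions = check_assumptions(model, grid=grid, n_env=32, seed=seed, budget=budget)
    ev["assumptions"] = assumptions
    if s0 == "above":
        tail = assumptions["decreasing_tail"]
        if tail["holds"]:
            ev["x_c"] = tail["x_c"]
            return RegimeReport(STOCHASTIC_PERSISTENCE, "mixed-tail-persistence", ev)
        return RegimeReport(INDETERMINATE, "mixed-tail-persistence", ev)
    if s0 == "critical":
        return RegimeReport(INDETERMINATE, "mixed-critical-low-density", ev)

    # G(0) < 1: strong stochastic Allee effect; outcome depends on the noise
    if model.noise_support_unbounded and assumptions["bounded_growth"]["holds"]:
        return RegimeReport(UNCONDITIONAL_EXTINCTION, "large-noise-accessibility", ev)
    if model.env is None or model.env.bounded_support:
        from .skeleton import (ESSENTIAL_EXTINCTION, GLOBAL_EXTINCTION,
                               NO_ALLEE_PERSISTENCE, POSITIVE_ATTRACTOR,
                               classify_skeleton)

        sk = classify_skeleton(model, x_max=x_max)
        ev["skeleton_verdict"] = sk.verdict
        ev["skeleton"] = sk.to_dict()
        if sk.verdict in (POSITIVE_ATTRACTOR, NO_ALLEE_PERSISTENCE):
            return RegimeReport(CONDITIONAL_PERSISTENCE, "small-noise-skeleton", ev)
        if sk.verdict in (ESSENTIAL_EXTINCTION, GLOBAL_EXTINCTION):
            return RegimeReport(UNCONDITIONAL_EXTINCTION, "small-noise-skeleton", ev)
        return RegimeReport(INDETERMINATE, "small-noise-skeleton", ev)
    return RegimeReport(INDETERMINATE, "mixed-unclassified-noise", ev)


def jensen_gap(
    model: FitnessModel,
    x: float,
    budget: int | None = None,
    seed=None,
) -> dict:
    """Arithmetic versus geometric mean fitness at density ``x``.

    The gap E[f] - G is non-negative (AM-GM) and zero exactly for
    degenerate noise; a model with E[f(0, .)] > 1 > G(0) is a weak Allee
    effect turned strong by environmental fluctuation alone.
    """
    if model.env is None:
        val = float(model.eval(x, {}))
        return {"arithmetic_mean_fitness": val, "geometric_mean": val, "gap": 0.0}
    names = model.random_names

    def g(draws):
        draws = np.asarray(draws, dtype=float).reshape(-1, model.env.dim)
        xi = {n: draws[:, j] for j, n in enumerate(names)}
        return np.asarray(model.eval(np.asarray(x), xi), dtype=float)

    am, _ = expectation_of(model.env, g, method="quadrature", budget=budget, seed=seed)
    gm = geo_mean_fitness(model, x, budget=budget, seed=seed).G
    return {"arithmetic_mean_fitness": am, "geometric_mean": gm, "gap": am - gm}
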