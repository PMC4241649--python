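"""Deterministic skeleton analysis of the unperturbed map F0(x) = x f(x, xi_bar).

Freezing the environment at its coordinatewise mean xi_bar yields a
one-dimensional map whose geometry governs the fate of the stochastic
system under small bounded noise.  For unimodal maps with a strong Allee
effect the key quantities are the smallest positive fixed point M (the
deterministic Allee threshold) and the critical point C (the maximizer of
F0): if F0(F0(C)) > M the map has a positive attractor in (M, inf), while
F0(F0(C)) < M produces essential extinction — almost every initial density
is eventually driven below the threshold even though infinitely many
unstable positive periodic orbits remain.

For compactly supported ('eps-small') noise these deterministic verdicts
transfer to the stochastic model: a positive attractor admits a positive
invariant interval certificate (:func:`invariant_interval`), and absence of
a positive attractor plus the low-density Allee assumptions forces
unconditional extinction (:func:`small_noise_extinction_check`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

from .fitness_models import FitnessModel

__all__ = [
    "SkeletonReport",
    "skeleton_map",
    "smallest_positive_fixed_point",
    "critical_point",
    "classify_skeleton",
    "invariant_interval",
    "small_noise_extinction_check",
    "UnimodalityError",
]

GLOBAL_EXTINCTION = "GLOBAL_EXTINCTION"
NO_ALLEE_PERSISTENCE = "NO_ALLEE_PERSISTENCE"
POSITIVE_ATTRACTOR = "POSITIVE_ATTRACTOR"
ESSENTIAL_EXTINCTION = "ESSENTIAL_EXTINCTION"
BOUNDARY = "BOUNDARY"

X_MAX_DEFAULT = 50.0
BOUNDARY_TOL = 1e-8


class UnimodalityError(RuntimeError):
    """The skeleton map is not unimodal on the probed range."""


@dataclass
class SkeletonReport:
    """Skeleton quantities and the attractor/essential-extinction verdict."""

    verdict: str
    M: float | None = None
    C: float | None = None
    FC: float | None = None
    FFC: float | None = None
    f0: float | None = None  # skeleton fitness at zero density
    xi_bar: dict = field(default_factory=dict)
    attractor_interval: tuple[float, float] | None = None
    invariant_interval_cert: dict | None = None

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "M": self.M,
            "C": self.C,
            "FC": self.FC,
            "FFC": self.FFC,
            "f0": self.f0,
            "xi_bar": self.xi_bar,
            "attractor_interval": self.attractor_interval,
            "invariant_interval_cert": self.invariant_interval_cert,
        }


def skeleton_map(model: FitnessModel) -> tuple[Callable[[np.ndarray], np.ndarray], dict]:
    """The unperturbed map F0 and the reference environment xi_bar.

    xi_bar is the coordinatewise mean of the environment distribution (the
    natural center for the uniform noise families used in the experiments);
    every supported family has a finite mean.
    """
    xi_bar = model.reference_environment()

    def F0(x):
        x = np.asarray(x, dtype=float)
        with np.errstate(over="ignore", under="ignore"):
            return x * model.eval(x, xi_bar)

    return F0, xi_bar


def smallest_positive_fixed_point(
    F0: Callable,
    x_max: float = X_MAX_DEFAULT,
    grid_n: int = 4096,
    x_min: float = 1e-12,
) -> float | None:
    """Smallest positive root of F0(x) = x by grid bracketing plus bisection.

    Requires F0(x_max) < x_max (the map must eventually fall below the
    diagonal; raise ``x_max`` if not).  Returns ``None`` when F0(x) - x has
    no sign change on (x_min, x_max], i.e. F0 stays below the diagonal.
    """
    if not F0(x_max) < x_max:
        raise ValueError(f"x_max={x_max} insufficient: F0(x_max) >= x_max")
    xs = np.geomspace(x_min, x_max, grid_n)
    h = F0(xs) - xs
    sign = np.sign(h)
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if flips.size == 0:
        return None
    i = flips[0]
    if h[i] == 0.0:
        return float(xs[i])
    root = optimize.brentq(lambda x: F0(x) - x, xs[i], xs[i + 1], xtol=1e-300, rtol=1e-12)
    return float(root)


def critical_point(
    F0: Callable,
    x_max: float = X_MAX_DEFAULT,
    grid_n: int = 4096,
    x_min: float = 1e-9,
) -> float:
    """Interior maximizer of F0 on (0, x_max], assuming unimodality.

    The probe grid checks for a unique interior local maximum; multiple
    maxima raise :class:`UnimodalityError`, and a maximizer at the grid edge
    (monotone map, no interior peak) raises as well.
    """
    xs = np.geomspace(x_min, x_max, grid_n)
    vals = F0(xs)
    d = np.diff(vals)
    rising = d > 0
    # indices where slope flips from rising to falling = local maxima
    flip = np.nonzero(rising[:-1] & ~rising[1:])[0]
    if flip.size == 0:
        raise UnimodalityError("no interior maximum of F0 on the probed range")
    if flip.size > 1:
        peaks = [float(xs[i + 1]) for i in flip]
        raise UnimodalityError(f"multiple local maxima of F0 detected near {peaks}")
    i = int(flip[0])
    lo, hi = xs[max(i - 1, 0)], xs[min(i + 3, grid_n - 1)]
    res = optimize.minimize_scalar(
        lambda x: -F0(x), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-12 * max(1.0, hi)},
    )
    return float(res.x)


def _orbit_hull(F0: Callable, start: float, burn: int = 1000, keep: int = 4096):
    x = start
    for _ in range(burn):
        x = float(F0(x))
    lo = hi = x
    for _ in range(keep):
        x = float(F0(x))
        lo, hi = min(lo, x), max(hi, x)
    return lo, hi


def classify_skeleton(model: FitnessModel, x_max: float = X_MAX_DEFAULT) -> SkeletonReport:
    """Classify the skeleton per the fixed-point / critical-point geometry.

    Branches: skeleton fitness above one at zero density means no Allee
    effect and a globally attracting positive attractor; skeleton fitness
    below one everywhere means global extinction; otherwise the verdict is
    the F0(F0(C)) versus M dichotomy, with a BOUNDARY verdict when the two
    agree within ``BOUNDARY_TOL`` (classification is numerically meaningless
    there).
    """
    F0, xi_bar = skeleton_map(model)
    f0 = float(model.zero_limit(xi_bar))
    report = SkeletonReport(verdict="", f0=f0, xi_bar=xi_bar)

    if f0 > 1.0:
        report.verdict = NO_ALLEE_PERSISTENCE
        try:
            C = critical_point(F0, x_max)
            report.C = C
            report.FC = float(F0(C))
            report.FFC = float(F0(report.FC))
            report.attractor_interval = _orbit_hull(F0, C)
        except UnimodalityError:
            pass
        return report

    xs = np.geomspace(1e-9, x_max, 4096)
    with np.errstate(over="ignore", under="ignore"):
        fvals = model.eval(xs, xi_bar)
    if float(np.max(fvals)) <= 1.0:
        report.verdict = GLOBAL_EXTINCTION
        return report

    M = smallest_positive_fixed_point(F0, x_max)
    if M is None:
        report.verdict = GLOBAL_EXTINCTION
        return report
    C = critical_point(F0, x_max)
    FC = float(F0(C))
    FFC = float(F0(FC))
    report.M, report.C, report.FC, report.FFC = M, C, FC, FFC

    tol = BOUNDARY_TOL * max(1.0, M)
    if abs(FFC - M) <= tol:
        report.verdict = BOUNDARY
    elif FFC > M:
        report.verdict = POSITIVE_ATTRACTOR
        report.attractor_interval = _orbit_hull(F0, C)
    else:
        report.verdict = ESSENTIAL_EXTINCTION
    return report


def _support_corners(model: FitnessModel) -> list[dict]:
    """Corner environments of the (bounded) support box, by random name."""
    support = model.env.support
    names = model.random_names
    corners = [{}]
    for name, (lo, hi) in zip(names, support):
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError("invariant-interval certificates require bounded noise support")
        new = []
        for c in corners:
            for v in ({lo, hi} if lo != hi else {lo}):
                d = dict(c)
                d[name] = v
                new.append(d)
        corners = new
    return corners


def invariant_interval(
    model: FitnessModel,
    report: SkeletonReport,
    n_grid: int = 4096,
    max_iter: int = 200,
) -> tuple[float, float] | None:
    """Search for a positive interval [alpha, beta] invariant under all noise.

    Starting from the skeleton's attractor hull, the interval is expanded by
    the worst-case one-step images ``F_lo(x) = min_xi x f(x, xi)`` and
    ``F_hi = max_xi`` evaluated over the corners of the noise support box
    (all catalogue fitnesses are coordinatewise monotone in their random
    parameters, so the extremes are attained at corners).  Interval
    extremes are located on a dense grid and sharpened by bounded scalar
    optimization; at the fixed point the one-step image of [alpha, beta]
    equals [alpha, beta], so the interval is invariant up to the certificate
    tolerance (relative 1e-9, recorded in the certificate).  Returns
    ``None`` — never a claim of non-existence — if the expansion collapses
    toward zero or below the Allee threshold M.

    Requires a positive-attractor skeleton and bounded noise support.  A
    noise-free model certifies its own attractor hull.
    """
    if report.verdict not in (POSITIVE_ATTRACTOR, NO_ALLEE_PERSISTENCE):
        return None
    if report.attractor_interval is None:
        return None
    if model.env is None:
        alpha, beta = report.attractor_interval
        report.invariant_interval_cert = {"n_grid": 0, "corners": 0, "noise_free": True}
        return (alpha, beta)
    if not model.env.bounded_support:
        return None

    corners = _support_corners(model)

    def _corner_map(c):
        def F(x):
            with np.errstate(over="ignore", under="ignore"):
                return np.asarray(x, dtype=float) * model.eval(np.asarray(x, dtype=float), c)
        return F

    corner_maps = [_corner_map(c) for c in corners]

    def image_bounds(alpha: float, beta: float) -> tuple[float, float]:
        """Sharp [min, max] of the one-step image of [alpha, beta] over all corners."""
        xs = np.linspace(alpha, beta, n_grid)
        lo, hi = math.inf, -math.inf
        for F in corner_maps:
            vals = F(xs)
            i_min, i_max = int(np.argmin(vals)), int(np.argmax(vals))
            lo = min(lo, float(vals[i_min]), float(vals[0]), float(vals[-1]))
            hi = max(hi, float(vals[i_max]))
            # sharpen interior extremes by bounded optimization
            if 0 < i_min < n_grid - 1:
                res = optimize.minimize_scalar(F, bounds=(xs[i_min - 1], xs[i_min + 1]),
                                               method="bounded")
                lo = min(lo, float(res.fun))
            if 0 < i_max < n_grid - 1:
                res = optimize.minimize_scalar(lambda x: -F(x),
                                               bounds=(xs[i_max - 1], xs[i_max + 1]),
                                               method="bounded")
                hi = max(hi, float(-res.fun))
        return lo, hi

    alpha, beta = report.attractor_interval
    floor = (report.M or 0.0)
    converged = False
    for _ in range(max_iter):
        lo, hi = image_bounds(alpha, beta)
        new_alpha = min(alpha, lo)
        new_beta = max(beta, hi)
        if new_alpha <= max(floor, 1e-12):
            return None
        if (alpha - new_alpha) <= 1e-12 * max(1.0, alpha) and \
           (new_beta - beta) <= 1e-12 * max(1.0, beta):
            alpha, beta = new_alpha, new_beta
            converged = True
            break
        alpha, beta = new_alpha, new_beta
    if not converged:
        return None

    lo, hi = image_bounds(alpha, beta)
    tol_a, tol_b = 1e-9 * max(1.0, alpha), 1e-9 * max(1.0, beta)
    if lo < alpha - tol_a or hi > beta + tol_b:
        return None
    report.invariant_interval_cert = {
        "n_grid": n_grid,
        "corners": len(corners),
        "min_image": lo,
        "max_image": hi,
        "rel_tolerance": 1e-9,
    }
    return (float(alpha), float(beta))


def small_noise_extinction_check(
    model: FitnessModel,
    report: SkeletonReport,
    x_max: float = X_MAX_DEFAULT,
    dissipativity_T: int = 100,
) -> dict:
    """Small-noise unconditional-extinction verdict.

    When the skeleton has no positive attractor (essential or global
    extinction), the noise support is bounded, the low-density Allee
    assumptions hold (fitness below one at zero density in geometric mean;
    fitness increasing near zero), and the skeleton is dissipative
    (iterates of [0, x_max] settle into a compact interval), the stochastic
    model goes extinct from every initial density for small enough noise.
    Anything else returns NO_CONCLUSION — absence of a verdict, not a claim
    of persistence.
    """
    from .criteria import check_assumptions  # lazy: criteria also uses skeleton

    out = {"verdict": "NO_CONCLUSION", "reasons": []}
    if report.verdict not in (ESSENTIAL_EXTINCTION, GLOBAL_EXTINCTION):
        out["reasons"].append("skeleton has a positive attractor or boundary verdict")
        return out
    if model.env is not None and not model.env.bounded_support:
        out["reasons"].append("noise support unbounded (eps-small hypothesis fails)")
        return out

    grid = np.geomspace(1e-6, x_max, 512)
    assumptions = check_assumptions(model, grid=grid, n_env=32, seed=0)
    if not assumptions["allee_at_zero"]["holds"]:
        out["reasons"].append("geometric mean fitness at zero density is not < 1")
        return out
    if not assumptions["increasing_near_zero"]["holds"]:
        out["reasons"].append("fitness is not increasing near zero density")
        return out

    # dissipativity: iterate the skeleton from a spread of starts incl. x_max
    F0, _ = skeleton_map(model)
    xs = np.linspace(1e-6, x_max, 64)
    for _ in range(dissipativity_T):
        xs = F0(xs)
    bound = float(np.max(xs))
    if not (bound < x_max):
        out["reasons"].append("dissipativity not confirmed on [0, x_max]")
        return out

    out["verdict"] = "UNCONDITIONAL_EXTINCTION_SMALL_NOISE"
    out["dissipative_bound"] = bound
    out["assumptions"] = {
        "allee_at_zero": assumptions["allee_at_zero"],
        "increasing_near_zero": assumptions["increasing_near_zero"],
    }
    return out
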