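"""Deterministic-skeleton analysis: fixed points, critical point, verdicts."""

import math

import numpy as np
import pytest
from scipy import optimize

from stochallee import build_model, classify_skeleton, invariant_interval, make_distribution, skeleton_map
from stochallee.dynamics import classify_finals, simulate_ensemble
from stochallee.experiments import (
    mate_limitation_model,
    mate_limitation_ricker_model,
    predator_saturation_ricker_model,
)
from stochallee.skeleton import (
    ESSENTIAL_EXTINCTION,
    GLOBAL_EXTINCTION,
    NO_ALLEE_PERSISTENCE,
    POSITIVE_ATTRACTOR,
    UnimodalityError,
    critical_point,
    small_noise_extinction_check,
    smallest_positive_fixed_point,
)


def brute_force_skeleton(F0, x_max=50.0, n=10_000):
    """Independent oracle: dense grid + bisection for M, C, F(C), F(F(C))."""
    xs = np.geomspace(1e-10, x_max, n)
    h = F0(xs) - xs
    idx = np.nonzero(np.sign(h[:-1]) != np.sign(h[1:]))[0]
    M = optimize.bisect(lambda x: F0(x) - x, xs[idx[0]], xs[idx[0] + 1],
                        xtol=1e-14) if idx.size else None
    vals = F0(xs)
    i = int(np.argmax(vals))
    C = optimize.minimize_scalar(lambda x: -F0(x), bounds=(xs[i - 1], xs[i + 1]),
                                 method="bounded", options={"xatol": 1e-13}).x
    return M, C, float(F0(C)), float(F0(F0(C)))


class TestSkeletonMap:
    def test_reference_environment_is_coordinatewise_mean(self):
        m = mate_limitation_ricker_model(0.5, rbar=4.5)  # r uniform on [4, 5]
        F0, xi_bar = skeleton_map(m)
        assert xi_bar == {"r": 4.5}
        xs = np.geomspace(1e-3, 30, 50)
        np.testing.assert_allclose(F0(xs), xs * np.exp(4.5 - xs) * xs / (xs + 10),
                                   rtol=1e-12)

    def test_point_mass_environment_recovers_stochastic_map(self):
        m = build_model("ricker", {"r": make_distribution("point_mass", value=2.0),
                                   "a": 1.0})
        F0, _ = skeleton_map(m)
        assert float(F0(1.0)) == pytest.approx(math.exp(1.0), rel=1e-14)

    def test_zero_is_always_fixed(self, mlr_attractor):
        F0, _ = skeleton_map(mlr_attractor)
        assert float(F0(0.0)) == 0.0


class TestFixedAndCriticalPoints:
    def test_ricker_closed_forms(self):
        m = build_model("ricker", {"r": 0.5, "a": 1.0})
        F0, _ = skeleton_map(m)
        assert smallest_positive_fixed_point(F0) == pytest.approx(0.5, rel=1e-10)
        assert critical_point(F0) == pytest.approx(1.0, rel=1e-8)

    def test_subcritical_map_has_no_positive_fixed_point(self):
        m = build_model("ricker", {"r": -1.0, "a": 1.0})
        F0, _ = skeleton_map(m)
        assert smallest_positive_fixed_point(F0) is None

    def test_insufficient_x_max_rejected(self, mlr_attractor):
        F0, _ = skeleton_map(mlr_attractor)
        with pytest.raises(ValueError, match="x_max"):
            smallest_positive_fixed_point(F0, x_max=1.0)

    def test_monotone_map_has_no_interior_maximum(self):
        F0, _ = skeleton_map(mate_limitation_model(0.0))
        with pytest.raises(UnimodalityError):
            critical_point(F0, x_max=1000.0)

    @pytest.mark.parametrize("rbar", [4.5, 7.0])
    def test_matches_brute_force_oracle(self, rbar):
        m = mate_limitation_ricker_model(0.0, rbar=rbar)
        F0, _ = skeleton_map(m)
        M_o, C_o, FC_o, FFC_o = brute_force_skeleton(F0)
        rep = classify_skeleton(m)
        assert rep.M == pytest.approx(M_o, rel=1e-8)
        assert rep.C == pytest.approx(C_o, rel=1e-8)
        assert rep.FC == pytest.approx(FC_o, rel=1e-8)
        assert rep.FFC == pytest.approx(FFC_o, rel=1e-8)
        # internal consistency: F0(M) = M
        assert float(F0(rep.M)) == pytest.approx(rep.M, rel=1e-10)


class TestClassifySkeleton:
    def test_positive_attractor_branch(self, mlr_attractor):
        rep = classify_skeleton(mlr_attractor)
        assert rep.verdict == POSITIVE_ATTRACTOR
        assert rep.FFC > rep.M
        a, b = rep.attractor_interval
        assert rep.M < a <= b

    def test_essential_extinction_branch(self, mlr_essential_extinction):
        rep = classify_skeleton(mlr_essential_extinction)
        assert rep.verdict == ESSENTIAL_EXTINCTION
        assert rep.FFC < rep.M
        assert rep.FFC < 1e-10  # the second iterate of C crashes to ~1e-17

    def test_no_allee_branch_for_weak_predation(self):
        # skeleton fitness at zero density exp(4 - 12*Pbar) > 1 for Pbar < 1/3
        m = predator_saturation_ricker_model(0.25, 0.1)
        rep = classify_skeleton(m)
        assert rep.verdict == NO_ALLEE_PERSISTENCE
        assert rep.f0 == pytest.approx(math.exp(4 - 3.0), rel=1e-10)

    def test_global_extinction_when_fitness_below_one(self):
        m = build_model("mate_limitation_ricker", {"r": -1.0, "a": 1.0, "h": 10.0})
        assert classify_skeleton(m).verdict == GLOBAL_EXTINCTION

    def test_point_mass_ensembles_corroborate_verdicts(self, mlr_essential_extinction,
                                                       mlr_attractor):
        # essential extinction: runs from scattered starts die out
        finals = simulate_ensemble(mlr_essential_extinction,
                                   np.linspace(0.2, 10, 50), T=5000, seed=0)["finals"]
        assert classify_finals(finals)["EXTINCT"] == 1.0
        # positive attractor: runs started at C stay interior
        rep = classify_skeleton(mlr_attractor)
        finals = simulate_ensemble(mlr_attractor, rep.C, T=5000, n_reps=50, seed=1)["finals"]
        assert classify_finals(finals)["INTERIOR"] == 1.0


class TestInvariantInterval:
    def test_noise_free_certificate_contains_attractor_hull(self, mlr_attractor):
        rep = classify_skeleton(mlr_attractor)
        iv = invariant_interval(mlr_attractor, rep)
        assert iv is not None
        a, b = iv
        hull_lo, hull_hi = rep.attractor_interval
        assert a <= hull_lo and b >= hull_hi
        # deterministic invariance: alpha is the image minimum F0(F0(C))
        assert a == pytest.approx(rep.FFC, rel=1e-9)

    def test_small_noise_certificate_is_never_escaped(self):
        m = mate_limitation_ricker_model(0.05, rbar=4.5)
        rep = classify_skeleton(m)
        iv = invariant_interval(m, rep)
        assert iv is not None
        a, b = iv
        assert rep.M < a < b
        out = simulate_ensemble(m, np.full(20, 0.5 * (a + b)), T=20_000, seed=2,
                                track_min=True, track_max=True)
        assert np.all(out["mins"] >= a * (1 - 1e-9))
        assert np.all(out["maxs"] <= b * (1 + 1e-9))

    def test_unbounded_noise_returns_none(self):
        m = build_model("mate_limitation_ricker",
                        {"r": make_distribution("normal", mean=4.5, sd=0.05),
                         "a": 1.0, "h": 10.0})
        rep = classify_skeleton(m)
        assert invariant_interval(m, rep) is None

    def test_large_noise_has_no_certificate_and_zero_is_reachable(self):
        from stochallee.dynamics import min_density_probe

        m = mate_limitation_ricker_model(4.0, rbar=4.5)  # r uniform on [0.5, 8.5]
        rep = classify_skeleton(m)
        assert invariant_interval(m, rep) is None
        probe = min_density_probe(m, 2.0, T=2000, n_reps=100, gamma=rep.M, seed=3)
        assert probe["estimate"] > 0.0


class TestSmallNoiseExtinction:
    def test_essential_extinction_small_noise_verdict(self):
        m = mate_limitation_ricker_model(0.05, rbar=7.0)
        rep = classify_skeleton(m)
        check = small_noise_extinction_check(m, rep)
        assert check["verdict"] == "UNCONDITIONAL_EXTINCTION_SMALL_NOISE"
        finals = simulate_ensemble(m, np.linspace(0.5, 5, 100), T=10_000, seed=4)["finals"]
        assert classify_finals(finals)["EXTINCT"] == 1.0

    def test_positive_attractor_gives_no_conclusion(self):
        m = mate_limitation_ricker_model(0.05, rbar=4.5)
        rep = classify_skeleton(m)
        assert small_noise_extinction_check(m, rep)["verdict"] == "NO_CONCLUSION"

    def test_unbounded_noise_gives_no_conclusion(self):
        m = build_model("mate_limitation_ricker",
                        {"r": make_distribution("normal", mean=7.0, sd=0.05),
                         "a": 1.0, "h": 10.0})
        rep = classify_skeleton(m)
        check = small_noise_extinction_check(m, rep)
        assert check["verdict"] == "NO_CONCLUSION"
        assert any("unbounded" in r for r in check["reasons"])
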