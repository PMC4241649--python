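"""Geometric-mean fitness, regime classification, assumption checks, Jensen gap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stochallee import build_model, classify_regime, geo_mean_fitness, jensen_gap, make_distribution
from stochallee.criteria import (
    CONDITIONAL_PERSISTENCE,
    INDETERMINATE,
    STOCHASTIC_PERSISTENCE,
    UNCONDITIONAL_EXTINCTION,
    check_assumptions,
)
from stochallee.experiments import (
    mate_limitation_model,
    mate_limitation_ricker_model,
    predator_saturation_ricker_model,
)


class TestGeoMeanFitness:
    def test_mate_limitation_g0_is_zero(self, mate_limitation_stochastic):
        res = geo_mean_fitness(mate_limitation_stochastic, 0.0)
        assert res.G == 0.0 and res.log_G == -math.inf

    def test_ricker_g0_closed_form_vs_quadrature(self):
        m = build_model("ricker", {"r": make_distribution("normal", mean=0.5, sd=0.2),
                                   "a": 1.0})
        closed = geo_mean_fitness(m, 0.0, method="closed_form")
        quad = geo_mean_fitness(m, 0.0, method="quadrature")
        assert closed.G == pytest.approx(math.exp(0.5), rel=1e-12)
        assert quad.G == pytest.approx(closed.G, rel=1e-10)
        assert closed.error == 0.0

    def test_fig3_model_g0_at_critical_predation(self):
        # P uniform on Pbar*[1-eps, 1+eps] has mean Pbar; at Pbar=1/3 and
        # h=1/12, G(0) = exp(4 - 12/3) = 1 exactly
        m = predator_saturation_ricker_model(1.0 / 3.0, 0.5)
        assert geo_mean_fitness(m, 0.0).G == pytest.approx(1.0, abs=1e-12)
        m2 = predator_saturation_ricker_model(0.25, 0.5)
        assert geo_mean_fitness(m2, 0.0).G == pytest.approx(math.exp(4 - 3.0), rel=1e-12)

    def test_infinity_sentinel_uses_declared_limit(self, mate_limitation_stochastic):
        res = geo_mean_fitness(mate_limitation_stochastic, math.inf)
        assert res.G == pytest.approx(math.exp(0.1), rel=1e-12)

    def test_unbounded_limit_propagates_to_infinite_g(self):
        m = build_model("liebhold_bascompte",
                        {"gamma": 0.05, "C": 50.0,
                         "noise": make_distribution("normal", mean=0.0, sd=0.3)})
        assert geo_mean_fitness(m, math.inf).G == math.inf

    def test_monte_carlo_agrees_with_quadrature_within_4se(self):
        m = build_model("predator_saturation",
                        {"r": make_distribution("normal", mean=1.0, sd=0.3),
                         "P": make_distribution("lognormal", logmean=-0.5, logsd=0.2),
                         "h": 2.0})
        for x in (0.0, 1.0, 10.0):
            quad = geo_mean_fitness(m, x, method="quadrature")
            mc = geo_mean_fitness(m, x, method="monte_carlo", budget=50_000, seed=3)
            assert abs(mc.log_G - quad.log_G) < 4 * mc.error

    def test_monotone_in_density_matches_model_monotonicity(self):
        dec = build_model("ricker", {"r": make_distribution("normal", mean=0.3, sd=0.5),
                                     "a": 1.0})
        inc = mate_limitation_model(0.5)
        xs = np.geomspace(1e-3, 50, 30)
        g_dec = [geo_mean_fitness(dec, float(x)).log_G for x in xs]
        g_inc = [geo_mean_fitness(inc, float(x)).log_G for x in xs]
        assert np.all(np.diff(g_dec) <= 1e-12)
        assert np.all(np.diff(g_inc) >= -1e-12)


class TestClassifyRegime:
    def test_supercritical_ricker_stochastically_persistent(self, ricker_persistent):
        rep = classify_regime(ricker_persistent)
        assert rep.regime == STOCHASTIC_PERSISTENCE
        assert rep.theorem_trail == "decreasing-fitness-trichotomy"

    def test_subcritical_ricker_unconditional_extinction(self, ricker_subcritical):
        assert classify_regime(ricker_subcritical).regime == UNCONDITIONAL_EXTINCTION

    def test_mate_limitation_conditional_persistence(self, mate_limitation_stochastic):
        rep = classify_regime(mate_limitation_stochastic)
        assert rep.regime == CONDITIONAL_PERSISTENCE
        assert rep.evidence["G0"].G == 0.0
        assert rep.evidence["Ginf"].G > 1.0

    def test_mate_limitation_subcritical_fecundity_goes_extinct(self):
        m = build_model("mate_limitation",
                        {"lam": make_distribution("lognormal", logmean=-0.1, logsd=0.5),
                         "h": 10.0})
        assert classify_regime(m).regime == UNCONDITIONAL_EXTINCTION

    def test_critical_geometric_mean_is_indeterminate(self):
        m = build_model("ricker", {"r": make_distribution("normal", mean=0.0, sd=0.5),
                                   "a": 1.0})
        assert classify_regime(m).regime == INDETERMINATE

    def test_mixed_model_with_supercritical_g0_persists_via_tail(self):
        # Pbar < 1/3 so G(0) = exp(4-12*Pbar) > 1, with a decreasing Ricker tail
        m = predator_saturation_ricker_model(0.25, 0.1)
        rep = classify_regime(m)
        assert rep.regime == STOCHASTIC_PERSISTENCE
        assert rep.theorem_trail == "mixed-tail-persistence"

    def test_mixed_model_small_noise_defers_to_skeleton(self):
        attract = mate_limitation_ricker_model(0.05, rbar=4.5)
        rep = classify_regime(attract)
        assert rep.regime == CONDITIONAL_PERSISTENCE
        assert rep.theorem_trail == "small-noise-skeleton"
        assert rep.evidence["skeleton_verdict"] == "POSITIVE_ATTRACTOR"

        essential = mate_limitation_ricker_model(0.05, rbar=7.0)
        rep2 = classify_regime(essential)
        assert rep2.regime == UNCONDITIONAL_EXTINCTION
        assert rep2.evidence["skeleton_verdict"] == "ESSENTIAL_EXTINCTION"

    def test_mixed_model_large_noise_unconditional_extinction(self):
        # normal growth-rate noise makes the multiplicative factor unbounded
        # below; with G(0) < 1 and bounded one-step growth the extinction
        # state is reachable from everywhere
        m = build_model("mate_limitation_ricker",
                        {"r": make_distribution("normal", mean=4.5, sd=1.0),
                         "a": 1.0, "h": 10.0})
        rep = classify_regime(m)
        assert rep.regime == UNCONDITIONAL_EXTINCTION
        assert rep.theorem_trail == "large-noise-accessibility"


class TestCheckAssumptions:
    def test_mixed_model_low_density_assumptions(self, mlr_attractor):
        grid = np.geomspace(1e-4, 30, 400)
        rep = check_assumptions(mlr_attractor, grid=grid, n_env=16, seed=0)
        assert rep["allee_at_zero"]["holds"]  # G(0) = 0 < 1
        assert rep["increasing_near_zero"]["holds"]
        assert rep["increasing_near_zero"]["gamma_prefix"] > grid[0]
        assert rep["decreasing_tail"]["holds"]
        # x_c sits beyond the maximizer of log f: -1 + 2/x - 1/(x+10) = 0
        xs = np.geomspace(1e-4, 30, 100_000)
        peak = xs[np.argmax(np.log(mlr_attractor.eval(xs, {})))]
        assert rep["decreasing_tail"]["x_c"] > peak

    def test_pure_ricker_has_no_allee_assumption(self, ricker_persistent):
        rep = check_assumptions(ricker_persistent, n_env=16, seed=0)
        assert not rep["increasing_near_zero"]["holds"]
        assert not rep["allee_at_zero"]["holds"]  # G(0) = e^0.3 > 1

    def test_predator_saturation_supercritical_g0_fails_allee_at_zero(self):
        # G(0) = exp(E r - E P/h) > 1 for weak predation
        m = build_model("predator_saturation",
                        {"r": make_distribution("normal", mean=1.0, sd=0.2),
                         "P": 0.5, "h": 1.0})
        rep = check_assumptions(m, n_env=8, seed=0)
        assert not rep["allee_at_zero"]["holds"]
        g0 = geo_mean_fitness(m, 0.0)
        assert g0.G == pytest.approx(math.exp(1.0 - 0.5), rel=1e-10)


class TestJensenGap:
    def test_point_mass_noise_has_zero_gap(self):
        m = build_model("ricker", {"r": 0.5, "a": 1.0})
        assert jensen_gap(m, 1.0)["gap"] == 0.0

    def test_fluctuating_half_saturation_shrinks_g0(self):
        # E[exp(-P/h)] vs exp(-P E[1/h]): fluctuations in h lower the
        # geometric mean below the arithmetic-mean fitness at zero density
        m = build_model("predator_saturation",
                        {"r": 0.5,
                         "P": 1.0,
                         "h": make_distribution("lognormal", logmean=0.0, logsd=0.6)})
        res = jensen_gap(m, 0.0)
        assert res["gap"] > 0.0
        assert res["geometric_mean"] < res["arithmetic_mean_fitness"]

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(mean=st.floats(-0.5, 1.5), sd=st.floats(0.05, 1.0), x=st.floats(0.0, 5.0))
    def test_gap_nonnegative_under_parameter_fuzzing(self, mean, sd, x):
        m = build_model("ricker", {"r": make_distribution("normal", mean=mean, sd=sd),
                                   "a": 1.0})
        assert jensen_gap(m, x)["gap"] >= -1e-10
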