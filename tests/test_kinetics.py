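"""Kinetic core: IRF quadrature, convolved exponentials, cascade solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from thiokin.kinetics import (
    IRFModel,
    InvalidInputError,
    KineticParameters,
    asymptotic_recovery,
    exp_gauss,
    ode_oracle,
    quadrature_irf_width,
    recombined_fraction,
    solve_populations,
)

from conftest import random_scheme


class TestQuadratureIRFWidth:
    @pytest.mark.parametrize(
        "components, expected",
        [
            ([0.020, 0.045, 0.065, 0.030], 0.0869),  # pulse widths + GVM + jitter
            ([0.123], 0.123),
            ([0.003, 0.004], 0.005),
        ],
    )
    def test_quadrature_sum(self, components, expected):
        assert quadrature_irf_width(components) == pytest.approx(expected, abs=5e-5)

    def test_experimental_budget_rounds_to_87_fs(self):
        sigma_ps = quadrature_irf_width([0.020, 0.045, 0.065, 0.030])
        assert round(sigma_ps * 1000) == 87

    @pytest.mark.parametrize("bad", [[], [0.0, 0.1], [-0.02], [math.inf]])
    def test_invalid_components_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            quadrature_irf_width(bad)


class TestExpGauss:
    def test_zero_width_irf_is_bare_exponential(self):
        t = np.linspace(-1, 5, 200)
        out = exp_gauss(t, tau=0.7, sigma=0.0, t0=0.2)
        expected = np.where(t >= 0.2, np.exp(-(t - 0.2) / 0.7), 0.0)
        np.testing.assert_allclose(out, expected, atol=1e-14)

    def test_half_rise_at_time_zero(self):
        # for tau >> sigma the profile is a smoothed step: half height at t0
        val = exp_gauss(np.array([0.0]), tau=1e4, sigma=0.087, t0=0.0)
        assert val[0] == pytest.approx(0.5, abs=1e-3)

    def test_infinite_tau_is_gaussian_cumulative_step(self):
        from scipy.stats import norm

        t = np.linspace(-1, 1, 101)
        out = exp_gauss(t, tau=math.inf, sigma=0.1, t0=0.05)
        np.testing.assert_allclose(out, norm.cdf((t - 0.05) / 0.1), atol=1e-12)

    def test_matches_adaptive_quadrature(self):
        tau, sigma = 0.41, 0.087
        t = np.linspace(-1, 5, 61)

        def brute(ti):
            f = lambda s: math.exp(-s / tau) * math.exp(
                -((ti - s) ** 2) / (2 * sigma**2)
            ) / (sigma * math.sqrt(2 * math.pi))
            return quad(f, 0.0, ti + 12 * sigma if ti > -12 * sigma else 1e-9, limit=400)[0]

        expected = np.array([brute(ti) for ti in t])
        np.testing.assert_allclose(exp_gauss(t, tau, sigma), expected, atol=1e-6)

    def test_stable_for_large_sigma_over_tau(self):
        # naive erfc formulation overflows here; the erfcx path must not
        t = np.linspace(-5, 50, 300)
        out = exp_gauss(t, tau=0.01, sigma=2.0)
        assert np.all(np.isfinite(out))
        # convolution of unit-area Gaussian with exp: peak bounded by 1
        assert 0 < out.max() <= 1.0

    def test_invalid_tau_rejected(self):
        with pytest.raises(InvalidInputError):
            exp_gauss(np.array([0.0]), tau=-1.0, sigma=0.1)
        with pytest.raises(InvalidInputError):
            exp_gauss(np.array([0.0]), tau=0.0, sigma=0.1)


class TestKineticParameters:
    def test_simplex_closure(self, table1):
        params, _ = table1
        assert params.q23 == pytest.approx(0.14)
        assert params.q32 == pytest.approx(0.34)
        assert params.q42 == pytest.approx(0.58)

    def test_roundtrip_serialization(self, table1):
        params, _ = table1
        again = KineticParameters.from_dict(params.to_dict())
        assert again == params

    def test_invalid_yields_rejected(self):
        with pytest.raises(InvalidInputError):
            KineticParameters(tau1=0.1, q21=0.7, tau21=0.4, q22=0.5, tau22=5.0)
        with pytest.raises(InvalidInputError):
            KineticParameters(tau1=-0.1, q21=0.5, tau21=0.4, q22=0.3, tau22=5.0)
        with pytest.raises(InvalidInputError):
            KineticParameters(tau1=0.1, q21=0.5, tau21=0.0, q22=0.3, tau22=5.0)

    def test_unknown_keys_rejected(self):
        with pytest.raises(InvalidInputError):
            KineticParameters.from_dict({"tau1": 0.1, "k_boom": 2.0})


class TestSolvePopulations:
    def test_frozen_radicals_accumulate(self):
        # no thiyl branch decays: all excitation ends up as thiyl, none recovers
        p = KineticParameters(
            tau1=0.14, q21=0.5, tau21=math.inf, q22=0.3, tau22=math.inf, tau23=math.inf
        )
        traj = solve_populations(p, np.array([0.0, 1.0, 50.0, 5000.0]))
        assert traj.N2[-1] == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(traj.N0, 0.0, atol=1e-12)
        np.testing.assert_allclose(traj.N4, 0.0, atol=1e-12)

    def test_recovery_at_one_nanosecond(self, table1):
        # ~70 % of dissociated molecules back in the ground state at 1 ns
        params, _ = table1
        traj = solve_populations(params, np.array([1000.0]))
        assert traj.N0[0] == pytest.approx(0.69, abs=0.01)

    def test_conservation_and_monotonicity_random_schemes(self):
        rng = np.random.default_rng(42)
        t = np.concatenate([[0.0], np.geomspace(1e-3, 2000.0, 120)])
        for _ in range(25):
            p = random_scheme(rng, allow_infinite=True)
            traj = solve_populations(p, t)
            np.testing.assert_allclose(traj.total, 1.0, atol=1e-9)
            assert np.all(np.diff(traj.N1) <= 1e-12)
            assert np.all(np.diff(traj.N0) >= -1e-12)
            assert np.all((traj.N2 >= -1e-9) & (traj.N2 <= 1 + 1e-9))

    def test_matches_ode_oracle_random_schemes(self):
        rng = np.random.default_rng(7)
        t = np.linspace(0.0, 50.0, 101)
        for _ in range(20):
            p = random_scheme(rng)
            a = solve_populations(p, t)
            o = ode_oracle(p, t)
            for name in ("N1", "N2", "N3", "N4", "N0"):
                np.testing.assert_allclose(
                    getattr(a, name), getattr(o, name), atol=1e-6,
                    err_msg=f"{name} mismatch for {p.to_dict()}",
                )

    def test_irf_convolution_consistency(self, table1):
        # IRF-on solution equals discrete convolution of the IRF-free one
        params, irf = table1
        sigma = irf.sigma
        dt = 2e-4
        fine = np.arange(-2.0, 9.0 + dt, dt)
        free = solve_populations(params, fine)
        kt = np.arange(-6 * sigma, 6 * sigma + dt, dt)
        kernel = np.exp(-(kt**2) / (2 * sigma**2))
        kernel /= kernel.sum()
        grid = np.linspace(-0.8, 5.0, 60)
        conv = solve_populations(params, grid, irf=irf)
        # N2, N4, N0 are continuous at t=0 so the trapezoid kernel applies
        for name in ("N2", "N4", "N0"):
            ref = np.interp(grid, fine, np.convolve(getattr(free, name), kernel, mode="same"))
            np.testing.assert_allclose(getattr(conv, name), ref, atol=1e-5)
        # N1 jumps at t=0; its convolution is the closed-form EMG profile
        np.testing.assert_allclose(
            conv.N1, exp_gauss(grid, params.tau1, sigma), atol=1e-12
        )

    def test_degenerate_rate_continuity(self):
        base = dict(q21=0.6, q22=0.3, q31=0.5, q41=0.5, tau41=10.0)
        t = np.linspace(0.0, 20.0, 200)
        # tau21 == tau1 exactly vs perturbed by 1e-10 relative
        p_eq = KineticParameters(tau1=0.5, tau21=0.5, tau22=5.0, tau31=0.5, tau32=0.5, **base)
        p_pert = KineticParameters(
            tau1=0.5, tau21=0.5 * (1 + 1e-10), tau22=5.0, tau31=0.5, tau32=0.5, **base
        )
        a, b = solve_populations(p_eq, t), solve_populations(p_pert, t)
        for name in ("N1", "N2", "N3", "N4", "N0"):
            np.testing.assert_allclose(getattr(a, name), getattr(b, name), atol=1e-6)
        # triple coincidence tau1 = tau21 = tau31 stays finite and conserved
        assert np.all(np.isfinite(a.total))
        np.testing.assert_allclose(a.total, 1.0, atol=1e-9)

    def test_unsorted_times_rejected(self, table1):
        params, _ = table1
        with pytest.raises(InvalidInputError):
            solve_populations(params, np.array([1.0, 0.5]))

    def test_components_cover_sub_ensembles(self, table1):
        params, _ = table1
        traj = solve_populations(params, np.linspace(0, 10, 11))
        assert "N21" in traj.components and "N31^22" in traj.components
        # aggregation of raw components with yields reproduces N2
        n2 = sum(
            q * traj.components[f"N2{i + 1}"]
            for i, (q, _) in enumerate(params.thiyl_branches)
        )
        np.testing.assert_allclose(n2, traj.N2, atol=1e-12)


_log_tau = st.floats(min_value=np.log(0.05), max_value=np.log(500.0))
_frac = st.floats(min_value=0.0, max_value=1.0)


class TestSchemeProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        lt1=_log_tau, lt21=_log_tau, lt22=_log_tau, lt31=_log_tau,
        lt32=_log_tau, lt41=_log_tau, a=_frac, b=_frac, q31=_frac, q41=_frac,
    )
    def test_conservation_monotonicity_and_recovery_bound(
        self, lt1, lt21, lt22, lt31, lt32, lt41, a, b, q31, q41
    ):
        # any valid scheme conserves total population, never un-excites N1,
        # never un-recovers N0, and never recovers past the closed-form limit
        p = KineticParameters(
            tau1=math.exp(lt1), q21=a, tau21=math.exp(lt21),
            q22=(1 - a) * b, tau22=math.exp(lt22), tau23=math.inf,
            q31=q31, tau31=math.exp(lt31), tau32=math.exp(lt32),
            q41=q41, tau41=math.exp(lt41), tau42=math.inf,
        )
        t = np.concatenate([[0.0], np.geomspace(1e-3, 5e3, 80)])
        traj = solve_populations(p, t)
        np.testing.assert_allclose(traj.total, 1.0, atol=1e-9)
        assert np.all(np.diff(traj.N1) <= 1e-12)
        assert np.all(np.diff(traj.N0) >= -1e-12)
        assert np.all(traj.N0 <= asymptotic_recovery(p) + 1e-9)


class TestOdeOracle:
    def test_two_step_chain_matches_bateman_closed_form(self):
        # A -> B -> C with k_a != k_b: textbook two-exponential solution
        p = KineticParameters(
            tau1=1.0, q21=1.0, tau21=3.0, q22=0.0, tau22=1.0, tau23=math.inf,
            q31=1.0, tau31=math.inf, tau32=1.0, q41=0.0, tau41=1.0,
        )
        t = np.linspace(0, 20, 81)
        o = ode_oracle(p, t)
        ka, kb = 1.0, 1.0 / 3.0
        bateman_b = ka / (kb - ka) * (np.exp(-ka * t) - np.exp(-kb * t))
        np.testing.assert_allclose(o.N1, np.exp(-ka * t), atol=1e-8)
        np.testing.assert_allclose(o.N2, bateman_b, atol=1e-8)

    def test_frozen_chain_populations_constant(self):
        p = KineticParameters(
            tau1=0.2, q21=1.0, tau21=math.inf, q22=0.0, tau22=math.inf, tau23=math.inf
        )
        t = np.array([5.0, 50.0, 500.0])
        o = ode_oracle(p, t)
        np.testing.assert_allclose(o.N2, o.N2[0], atol=1e-8)
        np.testing.assert_allclose(o.N2[0], 1.0, atol=1e-6)


class TestDerivedQuantities:
    def test_recombined_fraction_at_20ps(self, table1):
        # >80 % of thiyl pairs have recombined by 20 ps (dominated by q21+q22)
        params, _ = table1
        frac = recombined_fraction(params, 20.0)
        assert frac >= 0.80
        assert frac == pytest.approx(params.q21 + params.q22, abs=0.01)

    def test_recombined_fraction_zero_at_time_zero(self, table1):
        params, _ = table1
        assert recombined_fraction(params, 0.0) == 0.0

    def test_no_recombination_when_all_branches_frozen(self):
        p = KineticParameters(
            tau1=0.14, q21=0.5, tau21=math.inf, q22=0.3, tau22=math.inf, tau23=math.inf
        )
        for t in (0.5, 20.0, 800.0):
            assert recombined_fraction(p, t) == pytest.approx(0.0, abs=1e-12)

    def test_recombined_fraction_nondecreasing(self, table1):
        params, _ = table1
        ts = [0.0, 0.1, 0.5, 2.0, 5.0, 20.0, 100.0, 800.0]
        vals = [recombined_fraction(params, t) for t in ts]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_asymptotic_recovery_closed_form(self, table1):
        params, _ = table1
        expected = 0.86 * (0.66 + 0.34 * 0.42)
        assert asymptotic_recovery(params) == pytest.approx(expected, abs=1e-12)
        # long-time limit of the full solver agrees
        traj = solve_populations(params, np.array([5e4]))
        assert traj.N0[0] == pytest.approx(asymptotic_recovery(params), abs=1e-4)

    def test_asymptotic_recovery_limits(self):
        p = KineticParameters(
            tau1=0.1, q21=0.6, tau21=0.5, q22=0.3, tau22=4.0, tau23=math.inf,
            q31=1.0, tau31=0.5, tau32=0.5, q41=0.3, tau41=10.0,
        )
        assert asymptotic_recovery(p) == pytest.approx(0.9, abs=1e-12)
        frozen = KineticParameters(
            tau1=0.1, q21=0.6, tau21=math.inf, q22=0.4, tau22=math.inf, tau23=math.inf
        )
        assert asymptotic_recovery(frozen) == 0.0
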