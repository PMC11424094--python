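"""Two-phase radial FRAP model: closed form, solver, and fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condex import (
    TwoPhaseParams,
    approx_recovery_curve,
    fit_finite_recovery,
    fit_single_exponential,
    recovery_timescale,
    solve_frap_radial,
    solve_slab_decay,
    slab_kappa_from_decay,
    unbleached_fraction,
)


class TestRecoveryTimescale:
    def test_laf1_decomposition(self, laf1):
        ts = recovery_timescale(laf1)
        assert ts.tau_dil == pytest.approx(4.2, abs=0.1)
        assert ts.tau_den == pytest.approx(60.0, abs=1.0)
        assert ts.tau_total == pytest.approx(64.0, abs=1.0)
        assert ts.tau_int == 0.0

    def test_laf1_with_interface_resistance(self, laf1):
        p = laf1.with_(kappa=7.4e-5)
        assert recovery_timescale(p).tau_total == pytest.approx(4570, rel=0.01)

    def test_fast_diffusion_limit_is_interface_time(self):
        p = TwoPhaseParams(R=2.0, D_den=1e9, D_dil=1e9, c_den=5.0, c_dil=1.0,
                           kappa=0.1)
        ts = recovery_timescale(p)
        assert ts.tau_total == pytest.approx(p.R / (3 * 0.1), rel=1e-6)

    @pytest.mark.parametrize(
        "field,factor",
        [("R", 2.0), ("D_den", 0.5), ("D_dil", 0.5), ("kappa", 0.5)],
    )
    def test_monotone_in_parameters(self, field, factor):
        base = TwoPhaseParams(R=1.0, D_den=0.01, D_dil=10.0, c_den=100.0,
                              c_dil=1.0, kappa=1e-3)
        worse = base.with_(**{field: getattr(base, field) * factor})
        assert recovery_timescale(worse).tau_total > recovery_timescale(base).tau_total
        if field == "R":
            # superlinear growth in R
            r1 = recovery_timescale(base).tau_total
            r2 = recovery_timescale(worse).tau_total
            assert r2 > factor * r1

    @pytest.mark.parametrize("bad", [
        dict(R=-1.0), dict(D_den=0.0), dict(c_dil=-2.0), dict(kappa=0.0),
    ])
    def test_invalid_parameters_raise(self, bad):
        kwargs = dict(R=1.0, D_den=1.0, D_dil=10.0, c_den=10.0, c_dil=1.0,
                      kappa=1.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            TwoPhaseParams(**kwargs)

    def test_cdil_above_cden_rejected(self):
        with pytest.raises(ValueError):
            TwoPhaseParams(R=1, D_den=1, D_dil=1, c_den=1.0, c_dil=2.0)


class TestApproxCurve:
    def test_endpoints_and_63_percent(self, laf1):
        tau = recovery_timescale(laf1).tau_total
        curve = approx_recovery_curve(laf1, [0.0, tau, 50 * tau])
        assert curve.f[0] == 0.0
        assert curve.f[1] == pytest.approx(1 - 1 / math.e, abs=1e-12)
        assert curve.f[2] == pytest.approx(1.0, abs=1e-6)

    def test_negative_time_rejected(self, laf1):
        with pytest.raises(ValueError):
            approx_recovery_curve(laf1, [-1.0, 0.0])

    def test_monotone_nondecreasing(self, laf1):
        curve = approx_recovery_curve(laf1, np.linspace(0, 500, 200))
        assert np.all(np.diff(curve.f) >= 0)


class TestRadialSolver:
    def test_equilibrium_profile_is_stationary(self):
        p = TwoPhaseParams(R=1.0, D_den=0.1, D_dil=2.0, c_den=50.0, c_dil=1.0,
                           kappa=0.05)
        field = solve_frap_radial(
            p, outer_radius=3.0, domain="finite", t_max=5.0,
            initial=None, n_inside=40,
        )
        # replace the bleach initial condition with the equilibrium one
        eq = np.where(field.r_grid < p.R, p.c_den, p.c_dil)
        field2 = solve_frap_radial(
            p, outer_radius=3.0, domain="finite", t_max=5.0, initial=eq,
            n_inside=40,
        )
        assert np.allclose(field2.values, eq[None, :], rtol=1e-6, atol=1e-8 * p.c_den)

    def test_mass_conserved_in_closed_domain(self):
        p = TwoPhaseParams(R=1.0, D_den=0.05, D_dil=5.0, c_den=100.0,
                           c_dil=1.0, kappa=0.01)
        field = solve_frap_radial(p, outer_radius=4.0, domain="finite",
                                  t_max=50.0)
        mass = field.total_mass()
        assert np.max(np.abs(mass - mass[0])) / mass[0] < 1e-6

    def test_values_nonnegative_and_f_monotone(self):
        p = TwoPhaseParams(R=1.0, D_den=0.1, D_dil=10.0, c_den=100.0,
                           c_dil=1.0, kappa=0.02)
        field = solve_frap_radial(p, t_max=None)
        assert field.values.min() > -1e-8 * p.c_den
        curve = unbleached_fraction(field)
        assert np.all(np.diff(curve.f) > -1e-8)

    def test_dense_eigenmode_limit(self):
        # kappa = inf and very fast dilute diffusion: the decay time is the
        # slowest dense-phase mode R^2/(pi^2 D_den)
        p = TwoPhaseParams(R=1.0, D_den=1.0, D_dil=1e4, c_den=100.0,
                           c_dil=1.0, kappa=math.inf)
        field = solve_frap_radial(p, t_max=0.6, n_inside=60)
        curve = unbleached_fraction(field)
        # slowest mode lives in the tail of the recovery
        tail = (curve.f > 0.7) & (curve.f < 0.99)
        tau = -1.0 / np.polyfit(curve.times[tail],
                                np.log(1 - curve.f[tail]), 1)[0]
        assert tau == pytest.approx(1.0 / math.pi**2, rel=0.02)

    def test_closed_form_matches_solver_at_validity_bound(self):
        # D_dil = 20 D_den, A6B6-like concentration ratio: within 10%
        p = TwoPhaseParams(R=1.0, D_den=1.0, D_dil=20.0, c_den=154.0,
                           c_dil=1.0, kappa=math.inf)
        tau_eq = recovery_timescale(p).tau_total
        field = solve_frap_radial(p, t_max=5 * tau_eq)
        tau_fit = fit_single_exponential(unbleached_fraction(field))
        assert abs(tau_fit - tau_eq) / tau_eq < 0.10

    def test_unbleached_fraction_uniform_levels(self):
        p = TwoPhaseParams(R=1.0, D_den=0.1, D_dil=1.0, c_den=10.0,
                           c_dil=1.0, kappa=1.0)
        field = solve_frap_radial(p, outer_radius=3.0, domain="finite",
                                  t_max=1e-6, n_times=2)
        inside = field.r_grid < p.R
        # c = c_den inside -> f = 0
        field.values[:] = np.where(inside, p.c_den, 0.0)[None]
        assert unbleached_fraction(field).f[0] == pytest.approx(0.0, abs=1e-12)
        # c = c_den/2 inside -> f = 0.5
        field.values[:] = np.where(inside, p.c_den / 2, 0.0)[None]
        assert unbleached_fraction(field).f[0] == pytest.approx(0.5, abs=1e-12)

    def test_fraction_agrees_with_dilute_mass_balance(self):
        # closed box: f from the droplet integral equals f from the
        # bleached mass that has left the droplet
        p = TwoPhaseParams(R=1.0, D_den=0.1, D_dil=5.0, c_den=20.0,
                           c_dil=1.0, kappa=0.05)
        field = solve_frap_radial(p, outer_radius=4.0, domain="finite",
                                  t_max=20.0)
        curve = unbleached_fraction(field)
        inside = field.r_grid < p.R
        vol = field.cell_volumes
        n0 = p.c_den * vol[inside].sum()
        outside_mass = field.values[:, ~inside] @ vol[~inside]
        assert np.allclose(curve.f, outside_mass / n0, atol=1e-6)

    def test_too_coarse_grid_rejected(self):
        p = TwoPhaseParams(R=1.0, D_den=1.0, D_dil=10.0, c_den=10.0, c_dil=1.0)
        with pytest.raises(ValueError):
            solve_frap_radial(p, n_inside=10)

    def test_kappa_recovered_from_solver_output(self):
        # invert the fitted decay time back to kappa given the other
        # parameters, in interface-dominated regimes
        for ratio, rel in [(154.0, 3.0), (154.0, 10.0), (1190.0, 3.0)]:
            p0 = TwoPhaseParams(R=1.0, D_den=1.0, D_dil=20.0, c_den=ratio,
                                c_dil=1.0, kappa=math.inf)
            ts0 = recovery_timescale(p0)
            kap = 1.0 / (3.0 * rel * ts0.tau_total)
            p = p0.with_(kappa=kap)
            tau_eq = recovery_timescale(p).tau_total
            field = solve_frap_radial(p, t_max=5 * tau_eq)
            tau_fit = fit_single_exponential(unbleached_fraction(field))
            kap_rec = (p.R / 3.0) / (tau_fit - ts0.tau_den - ts0.tau_dil)
            assert kap_rec == pytest.approx(kap, rel=0.05)


class TestFits:
    def test_finite_recovery_roundtrip_exact(self):
        t = np.linspace(0, 0.6, 200)
        f = 0.5 * (1 - np.exp(-t / (0.5 * 0.071)))
        from condex import RecoveryCurve

        A, tau = fit_finite_recovery(RecoveryCurve(t, f))
        assert A == pytest.approx(0.5, abs=1e-6)
        assert tau == pytest.approx(0.071, abs=1e-6)

    def test_full_pool_reduces_to_single_exponential(self):
        from condex import RecoveryCurve

        t = np.linspace(0, 10, 300)
        f = 1 - np.exp(-t / 2.0)
        A, tau = fit_finite_recovery(RecoveryCurve(t, f))
        assert A == pytest.approx(1.0, abs=1e-6)
        assert tau == pytest.approx(2.0, abs=1e-6)
        tau_single = fit_single_exponential(RecoveryCurve(t, f))
        assert tau_single == pytest.approx(tau, rel=1e-4)

    def test_fixed_A_option(self):
        from condex import RecoveryCurve

        t = np.linspace(0, 10, 100)
        f = 1 - np.exp(-t / 3.0)
        A, tau = fit_finite_recovery(RecoveryCurve(t, f), fix_A=1.0)
        assert A == 1.0
        assert tau == pytest.approx(3.0, abs=1e-8)

    def test_too_few_points_rejected(self):
        from condex import RecoveryCurve

        with pytest.raises(ValueError):
            fit_finite_recovery(RecoveryCurve(np.arange(5.0), np.arange(5.0) / 5))

    def test_t_at_1me(self):
        from condex import RecoveryCurve

        t = np.linspace(0, 20, 400)
        curve = RecoveryCurve(t, 1 - np.exp(-t / 4.0))
        assert curve.t_at_1me() == pytest.approx(4.0, rel=1e-3)

    @given(
        A=st.floats(0.2, 1.0),
        tau=st.floats(0.01, 10.0),
    )
    @settings(max_examples=25, deadline=None)
    def test_finite_recovery_roundtrip_property(self, A, tau):
        from condex import RecoveryCurve

        t = np.linspace(0, 5 * A * tau, 120)
        f = A * (1 - np.exp(-t / (A * tau)))
        A2, tau2 = fit_finite_recovery(RecoveryCurve(t, f))
        assert A2 == pytest.approx(A, rel=1e-4)
        assert tau2 == pytest.approx(tau, rel=1e-4)


class TestSlabDecay:
    def test_roundtrip_through_inversion(self):
        # the tangent inversion is the exact inverse of the slab problem's
        # slowest mode
        for g, kap, d, D in [(100.0, 2e-3, 50.0, 1.0), (10.0, 0.05, 20.0, 1.0)]:
            t, frac = solve_slab_decay(d, D, kap, g)
            m = frac < 0.5
            tau = -1.0 / np.polyfit(t[m], np.log(frac[m]), 1)[0]
            k_rec = slab_kappa_from_decay(tau, d, D, 1.0, g)
            assert k_rec == pytest.approx(kap, rel=0.03)
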