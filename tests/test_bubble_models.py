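"""Continuum bubble models: thresholds, RP integration, pulsation, nucleation."""

import math

import numpy as np
import pytest

from nanocav import (
    GEL,
    WATER,
    BubbleInitialState,
    FluidMedium,
    NucleationSetting,
    PressureSchedule,
    damped_volume_relaxation,
    equilibrium_cavitation_pressure,
    fisher_threshold_ratio,
    network_pressure,
    oscillation_parameters,
    rayleigh_collapse_time,
    solve_rp,
)
from nanocav.media import INITIAL_RADIUS_M


class TestEquilibriumPressure:
    def test_zero_surface_tension_gives_zero(self):
        m = FluidMedium("ideal", 1000.0, 0.0, 0.0)
        assert equilibrium_cavitation_pressure(m, 1e-8) == 0.0

    @pytest.mark.parametrize(
        "medium, radius_m, expected_mpa",
        [
            (WATER, 95.16e-10, -11.707),  # -2*0.0557/95.16 Å
            (GEL, 95.35e-10, -20.472),  # -2*0.0976/95.35 Å
        ],
    )
    def test_preset_thresholds(self, medium, radius_m, expected_mpa):
        p = equilibrium_cavitation_pressure(medium, radius_m) / 1e6
        assert p == pytest.approx(expected_mpa, rel=1e-3)

    def test_gel_threshold_magnitude_exceeds_water(self):
        pw = equilibrium_cavitation_pressure(WATER, INITIAL_RADIUS_M["water"])
        pg = equilibrium_cavitation_pressure(GEL, INITIAL_RADIUS_M["gel"])
        assert abs(pg) > abs(pw)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_cavitation_pressure(WATER, 0.0)


class TestNetworkPressure:
    def test_measured_decomposition(self):
        # gel threshold -101 MPa, water -93 MPa -> network part -8 MPa
        assert network_pressure(-101e6, -93e6) == pytest.approx(-8e6)

    def test_identical_media_give_zero(self):
        assert network_pressure(-50e6, -50e6) == 0.0

    def test_derived_from_equilibrium_presets(self):
        pg = equilibrium_cavitation_pressure(GEL, 95.35e-10)
        pw = equilibrium_cavitation_pressure(WATER, 95.16e-10)
        assert network_pressure(pg, pw) / 1e6 == pytest.approx(-8.77, rel=0.01)


class TestRayleighCollapseTime:
    def test_reference_value(self):
        assert rayleigh_collapse_time(1000.0, 1e-6, 1e5) == pytest.approx(9.15e-8, rel=1e-3)

    def test_pressure_scaling_sqrt(self):
        t1 = rayleigh_collapse_time(1000.0, 1e-6, 1e5)
        t4 = rayleigh_collapse_time(1000.0, 1e-6, 4e5)
        assert t4 == pytest.approx(t1 / 2.0, rel=1e-12)

    def test_radius_scaling_linear(self):
        t1 = rayleigh_collapse_time(1000.0, 1e-6, 1e5)
        t2 = rayleigh_collapse_time(1000.0, 2e-6, 1e5)
        assert t2 == pytest.approx(2.0 * t1, rel=1e-12)

    @pytest.mark.parametrize("bad", [dict(density=0), dict(radius0=-1e-6), dict(delta_p=0)])
    def test_nonpositive_inputs_rejected(self, bad):
        kwargs = dict(density=1000.0, radius0=1e-6, delta_p=1e5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            rayleigh_collapse_time(**kwargs)


class TestSolveRP:
    def test_stationary_at_equilibrium_pressure(self):
        r0 = 95.16e-10
        peq = equilibrium_cavitation_pressure(WATER, r0)
        sol = solve_rp(
            WATER, BubbleInitialState(r0), PressureSchedule.constant(peq), 1e-10
        )
        assert sol.termination == "horizon_reached"
        assert np.allclose(sol.radius, r0)

    def test_inviscid_collapse_matches_rayleigh(self):
        medium = FluidMedium("ideal", 1000.0, 0.0, 0.0)
        sol = solve_rp(
            medium, BubbleInitialState(1e-6), PressureSchedule.constant(1e5), 1e-6
        )
        assert sol.termination == "collapsed"
        assert sol.collapse_time == pytest.approx(9.15e-8, rel=5e-3)

    def test_gel_collapses_slower_than_water(self):
        times = {}
        for name, medium in (("water", WATER), ("gel", GEL)):
            sol = solve_rp(
                medium,
                BubbleInitialState(INITIAL_RADIUS_M[name]),
                PressureSchedule.constant(10e6),
                1e-8,
            )
            assert sol.termination == "collapsed"
            times[name] = sol.collapse_time
        assert times["gel"] > times["water"]

    def test_radius_trace_positive_and_times_increasing(self):
        sol = solve_rp(
            WATER, BubbleInitialState(50e-10), PressureSchedule.constant(50e6), 1e-9
        )
        assert np.all(sol.radius > 0)
        assert np.all(np.diff(sol.times) > 0)
        assert (sol.collapse_time is not None) == (sol.termination == "collapsed")

    def test_sampled_schedule_must_cover_horizon(self):
        sched = PressureSchedule.sampled([0.0, 1e-9], [1e5, 1e5])
        with pytest.raises(ValueError):
            solve_rp(WATER, BubbleInitialState(1e-8), sched, 1e-8)

    def test_sampled_schedule_integrates(self):
        sched = PressureSchedule.sampled([0.0, 1e-8], [20e6, 20e6])
        sol = solve_rp(WATER, BubbleInitialState(95.16e-10), sched, 1e-8)
        assert sol.termination == "collapsed"


class TestOscillationModel:
    def test_inviscid_medium_is_undamped(self):
        m = FluidMedium("ideal", 1000.0, 0.0, 0.0)
        model = oscillation_parameters(m, 1e-8)
        assert model.damping_b == 0.0
        assert model.relaxation_rate == 0.0

    def test_water_relaxation_rate(self):
        # b/m = 4η/(ρR²) for the water preset at its initial radius
        model = oscillation_parameters(WATER, 95.16e-10)
        assert model.relaxation_rate == pytest.approx(1.39e10, rel=0.005)

    def test_gel_damps_about_twice_as_fast_as_water(self):
        bw = oscillation_parameters(WATER, INITIAL_RADIUS_M["water"]).relaxation_rate
        bg = oscillation_parameters(GEL, INITIAL_RADIUS_M["gel"]).relaxation_rate
        assert bg / bw == pytest.approx(2.06, rel=0.03)
        assert bg > bw  # collagen presence damps the pulsation faster

    def test_strasberg_constants(self):
        r = 1e-8
        model = oscillation_parameters(WATER, r)
        assert model.damping_b == pytest.approx(WATER.viscosity / (math.pi * r**3))
        assert model.inertia_m == pytest.approx(WATER.density / (4 * math.pi * r))

    def test_zero_stiffness_has_no_frequency(self):
        model = oscillation_parameters(WATER, 1e-8)
        assert model.natural_frequency is None
        assert model.damping_ratio is None
        assert model.damping_ratio_delta is None

    def test_underdamped_frequency_and_ratios(self):
        model = oscillation_parameters(WATER, 1e-6, stiffness_k=1e30)
        omega0 = math.sqrt(model.stiffness_k / model.inertia_m)
        zeta = model.damping_ratio
        assert 0 < zeta < 1
        assert model.natural_frequency == pytest.approx(
            omega0 / (2 * math.pi) * math.sqrt(1 - zeta**2)
        )
        # the verbatim ratio differs from the standard one by a factor 2m
        assert model.damping_ratio_delta == pytest.approx(2 * model.inertia_m * zeta)

    def test_overdamped_has_no_real_frequency(self):
        model = oscillation_parameters(WATER, 95.16e-10, stiffness_k=1e-3)
        assert model.damping_ratio > 1
        assert model.natural_frequency is None

    def test_negative_stiffness_rejected(self):
        with pytest.raises(ValueError):
            oscillation_parameters(WATER, 1e-8, stiffness_k=-1.0)


class TestDampedVolumeRelaxation:
    def test_zero_rate_stays_constant(self):
        model = oscillation_parameters(WATER, 95.16e-10)
        t = np.linspace(0, 1e-9, 50)
        sol = damped_volume_relaxation(model, 1e-24, 0.0, t)
        assert np.allclose(sol.volume, 1e-24)

    def test_halving_time_of_decaying_component(self):
        model = oscillation_parameters(WATER, 95.16e-10)
        rate = model.relaxation_rate
        v0, vdot0 = 1e-24, 1e-14
        c1 = -vdot0 / rate
        t_half = math.log(2) / rate
        sol = damped_volume_relaxation(model, v0, vdot0, [0.0, t_half])
        decayed0 = sol.volume[0] - (v0 + vdot0 / rate)
        decayed1 = sol.volume[1] - (v0 + vdot0 / rate)
        assert decayed0 == pytest.approx(c1, rel=1e-12)
        assert decayed1 == pytest.approx(c1 / 2.0, rel=1e-9)

    def test_satisfies_pulsation_equation(self):
        model = oscillation_parameters(GEL, 95.35e-10)
        t = np.linspace(0, 5e-10, 200)
        sol = damped_volume_relaxation(model, 2e-24, -3e-14, t)
        residual = model.inertia_m * sol.d2vdt2 + model.damping_b * sol.dvdt
        leading = np.abs(model.damping_b * sol.dvdt).max()
        assert np.abs(residual).max() < 1e-9 * leading

    def test_undamped_limit_linear(self):
        m = FluidMedium("ideal", 1000.0, 0.0, 0.0)
        model = oscillation_parameters(m, 1e-8)
        t = np.linspace(0, 1.0, 11)
        sol = damped_volume_relaxation(model, 1.0, 2.0, t)
        assert np.allclose(sol.volume, 1.0 + 2.0 * t)

    def test_negative_times_rejected(self):
        model = oscillation_parameters(WATER, 1e-8)
        with pytest.raises(ValueError):
            damped_volume_relaxation(model, 1.0, 0.0, [-1.0, 0.0])

    def test_nonzero_stiffness_rejected(self):
        model = oscillation_parameters(WATER, 1e-8, stiffness_k=1.0)
        with pytest.raises(ValueError):
            damped_volume_relaxation(model, 1.0, 0.0, [0.0])


class TestFisherThresholdRatio:
    def test_equal_times_give_unity(self):
        s = NucleationSetting(1e-6)
        assert fisher_threshold_ratio(s, s) == 1.0

    def test_vibration_to_universe_age_ratio(self):
        # 33 decades of waiting time move the critical pressure by only ~1.58x
        r = fisher_threshold_ratio(NucleationSetting(1e-15), NucleationSetting(1e18))
        assert r == pytest.approx(1.58, rel=0.01)

    def test_monotone_in_second_waiting_time(self):
        s1 = NucleationSetting(1e-15)
        ratios = [
            fisher_threshold_ratio(s1, NucleationSetting(t2)) for t2 in (1.0, 1e6, 1e12, 1e18)
        ]
        assert all(b > a for a, b in zip(ratios, ratios[1:]))

    def test_mismatched_conditions_rejected(self):
        with pytest.raises(ValueError):
            fisher_threshold_ratio(
                NucleationSetting(1.0, temperature=300.0),
                NucleationSetting(2.0, temperature=310.0),
            )

    def test_undefined_log_argument_rejected(self):
        with pytest.raises(ValueError):
            NucleationSetting(1e-40, molecule_count=1.0, temperature=1e-6).log_attempt_factor()
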