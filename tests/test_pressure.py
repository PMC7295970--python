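"""Virial pressure, density, threshold extraction, strain schedules, volume bookkeeping."""

import numpy as np
import pytest

from nanocav import (
    Box,
    ParticleFrame,
    ScalarTimeSeries,
    density_excluding_cavity,
    global_pressure,
    make_fluid_with_cavity,
    threshold_pressure,
    volume_decomposition,
    volume_strain_schedule,
)


def _stress_frame(n=100, pressure_mpa=-20.0, seed=0, shear_only=False):
    """Frame whose isotropic per-atom stress realises the requested pressure."""
    rng = np.random.default_rng(seed)
    box = Box.from_lengths([30.0, 30.0, 30.0])
    coords = rng.uniform(0, 30, size=(n, 3))
    vols = np.full(n, box.volume / n)
    stress = np.zeros((n, 6))
    if shear_only:
        stress[:, 3:] = rng.normal(size=(n, 3))
    else:
        p_atm = pressure_mpa / 0.101325
        stress[:, 0:3] = (p_atm * vols)[:, None]
    return ParticleFrame(
        0.0, box, coords, np.full(n, 18.0), per_atom_stress=stress, per_atom_volume=vols
    )


class TestGlobalPressure:
    def test_recovers_prescribed_pressure(self):
        assert global_pressure(_stress_frame(pressure_mpa=-20.0)) == pytest.approx(-20.0)

    def test_zero_stress_gives_zero(self):
        frame = _stress_frame()
        frame.per_atom_stress[:] = 0.0
        assert global_pressure(frame) == 0.0

    def test_pure_shear_gives_zero(self):
        assert global_pressure(_stress_frame(shear_only=True)) == 0.0

    def test_missing_fields_named_in_error(self):
        frame = _stress_frame()
        frame.per_atom_stress = None
        with pytest.raises(ValueError, match="per_atom_stress"):
            global_pressure(frame)
        frame = _stress_frame()
        frame.per_atom_volume = None
        with pytest.raises(ValueError, match="per_atom_volume"):
            global_pressure(frame)

    def test_invariant_under_translation_and_reordering(self, rng):
        frame = _stress_frame(pressure_mpa=-45.0, seed=3)
        p0 = global_pressure(frame)
        shifted = ParticleFrame(
            0.0, frame.box, frame.coordinates + 11.3, frame.masses,
            per_atom_stress=frame.per_atom_stress, per_atom_volume=frame.per_atom_volume,
        )
        perm = rng.permutation(frame.n_atoms)
        shuffled = ParticleFrame(
            0.0, frame.box, frame.coordinates[perm], frame.masses[perm],
            per_atom_stress=frame.per_atom_stress[perm],
            per_atom_volume=frame.per_atom_volume[perm],
        )
        assert global_pressure(shifted) == pytest.approx(p0, rel=1e-12)
        assert global_pressure(shuffled) == pytest.approx(p0, rel=1e-12)

    def test_species_selection(self):
        frame = _stress_frame(pressure_mpa=-30.0)
        frame.species = np.array(["W"] * 50 + ["C"] * 50)
        assert global_pressure(frame, "W") == pytest.approx(-30.0)
        with pytest.raises(ValueError, match="no atoms"):
            global_pressure(frame, "X")


class TestDensityExcludingCavity:
    def test_zero_cavity_is_bulk_density(self, homogeneous_frame):
        frame, truth = homogeneous_frame
        rho = density_excluding_cavity(frame, None)
        assert rho == pytest.approx(truth["density_realized_g_cm3"], rel=1e-6)

    def test_carved_void_recovers_fluid_density(self, carved_field):
        field, truth = carved_field
        frame, _ = make_fluid_with_cavity([120, 120, 120], cavity_radius=50.0, seed=1)
        from nanocav import cavity_metrics

        rho = density_excluding_cavity(frame, cavity_metrics(field))
        assert rho == pytest.approx(1.02, rel=0.02)

    def test_ignoring_the_cavity_lowers_density(self, carved_frame):
        frame, truth = carved_frame
        with_cavity = density_excluding_cavity(frame, truth["cavity_volume_A3"])
        without = density_excluding_cavity(frame, 0.0)
        assert without < with_cavity

    def test_cavity_exceeding_box_rejected(self, homogeneous_frame):
        frame, _ = homogeneous_frame
        with pytest.raises(ValueError):
            density_excluding_cavity(frame, frame.box.volume)


class TestThresholdPressure:
    @staticmethod
    def _parabola(depth=-93.0, t_min=6.2, dt=0.05, span=12.4):
        t = np.arange(0.0, span + dt / 2, dt)
        return ScalarTimeSeries(t, depth + 4.0 * (t - t_min) ** 2, unit="MPa")

    def test_noiseless_minimum_located_exactly_without_smoothing(self):
        # a single-sample window leaves the trace untouched
        res = threshold_pressure(self._parabola(), window=0.05)
        assert res.value == pytest.approx(-93.0, rel=1e-12)
        assert res.time == pytest.approx(6.2, abs=1e-9)
        assert not res.boundary_minimum

    def test_noiseless_minimum_with_default_window(self):
        # a 1 ps moving average biases a parabola minimum by 4·Var(window) ≈ 0.37 MPa
        res = threshold_pressure(self._parabola(), window=1.0)
        assert res.value == pytest.approx(-93.0, rel=0.005)
        assert res.time == pytest.approx(6.2, abs=0.1)

    def test_noisy_minimum_within_two_percent(self, rng):
        series = self._parabola()
        for _ in range(5):
            noisy = ScalarTimeSeries(
                series.times,
                series.values + rng.uniform(-0.05 * 93, 0.05 * 93, size=len(series)),
                unit="MPa",
            )
            res = threshold_pressure(noisy, window=1.0)
            assert res.value == pytest.approx(-93.0, rel=0.02)
            assert res.time == pytest.approx(6.2, abs=0.6)

    def test_monotone_trace_flagged_as_boundary(self):
        t = np.linspace(0, 10, 101)
        res = threshold_pressure(ScalarTimeSeries(t, -t, unit="MPa"), window=1.0)
        assert res.boundary_minimum
        assert res.time == pytest.approx(t[-1] - res.window / 2, abs=res.window)

    def test_tie_broken_by_earliest_time(self):
        t = np.arange(0.0, 10.0, 0.1)
        v = np.zeros_like(t)
        v[30] = v[60] = -5.0  # two equal minima
        res = threshold_pressure(ScalarTimeSeries(t, v, unit="MPa"), window=0.1)
        assert res.time == pytest.approx(t[30])

    def test_window_longer_than_series_rejected(self):
        s = ScalarTimeSeries(np.arange(5.0), np.zeros(5), unit="MPa")
        with pytest.raises(ValueError, match="window"):
            threshold_pressure(s, window=100.0)

    def test_too_few_samples_rejected(self):
        s = ScalarTimeSeries(np.array([0.0, 1.0]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            threshold_pressure(s)


class TestVolumeStrainSchedule:
    def test_low_and_high_rate_reach_equal_final_strain(self):
        # X for 60 ps vs 2X for 30 ps: same percentage of volume expansion
        low = volume_strain_schedule(6.7e9, 60.0)
        high = volume_strain_schedule(1.35e10, 30.0)
        assert high.values[-1] == pytest.approx(low.values[-1], rel=0.01)

    def test_zero_duration_gives_zero_strain(self):
        s = volume_strain_schedule(6.7e9, 0.0)
        assert s.values[-1] == 0.0

    def test_doubling_rate_halves_time_to_fixed_strain(self):
        s1 = volume_strain_schedule(6.7e9, 60.0, n_points=601)
        s2 = volume_strain_schedule(2 * 6.7e9, 60.0, n_points=601)
        target = 0.2
        t1 = s1.times[np.searchsorted(s1.values, target)]
        t2 = s2.times[np.searchsorted(s2.values, target)]
        assert t2 == pytest.approx(t1 / 2.0, abs=s1.times[1])

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            volume_strain_schedule(0.0, 10.0)


class TestVolumeDecomposition:
    def test_no_network_no_growth_means_no_bubble(self):
        d = volume_decomposition(1000.0, 1000.0, 0.0)
        assert d.v_bubble == 0.0

    def test_growth_at_fixed_water_network_goes_to_bubble(self):
        base = volume_decomposition(1000.0, 900.0, 100.0)
        grown = volume_decomposition(1250.0, 900.0, 100.0)
        assert grown.v_bubble - base.v_bubble == pytest.approx(250.0)

    def test_bubble_radius_from_volume(self):
        d = volume_decomposition(2000.0, 1000.0, 500.0)
        assert 4.0 / 3.0 * np.pi * d.bubble_radius**3 == pytest.approx(500.0)

    def test_cross_agreement_with_cavity_detection(self, carved_field):
        field, truth = carved_field
        from nanocav import cavity_metrics

        v_box = float(np.prod(truth["box_lengths_A"]))
        v_water = v_box - truth["cavity_volume_A3"]
        d = volume_decomposition(v_box, v_water, 0.0)
        assert cavity_metrics(field).volume_c == pytest.approx(d.v_bubble, rel=0.05)

    def test_negative_residual_rejected(self):
        with pytest.raises(ValueError):
            volume_decomposition(100.0, 90.0, 20.0)
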