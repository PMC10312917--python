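"""Solver unit checks: grid design numbers, bowl voxelization, oracles,
and cheap field-level invariants on small grids."""

import numpy as np
import pytest

from echoplan.ct_props import AcousticMediumMap
from echoplan.solver import (
    GridSource,
    SimulationConfig,
    cfl,
    layer_transmission_coefficient,
    make_bowl_source,
    on_axis_bowl_pressure,
    point_source_field,
    ppw,
    rayleigh_free_field,
    simulate,
)
from echoplan.transducer import TransducerGeometry


class TestGridDesignNumbers:
    @pytest.mark.parametrize(
        "c,f0,dx,expected",
        [(1500.0, 250e3, 0.4, 15.0), (1500.0, 250e3, 1.0, 6.0), (3000.0, 250e3, 0.4, 30.0)],
    )
    def test_points_per_wavelength(self, c, f0, dx, expected):
        assert ppw(c, f0, dx) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "c,dt,dx,expected",
        [(1481.5, 54e-9, 0.4, 0.2), (2996.0, 26.7e-9, 0.4, 0.2)],
    )
    def test_cfl_number(self, c, dt, dx, expected):
        assert cfl(c, dt, dx) == pytest.approx(expected, abs=5e-4)

    def test_cfl_round_trips_through_dt(self):
        dt = 0.2 * 0.4e-3 / 1500.0
        assert cfl(1500.0, dt, 0.4) == pytest.approx(0.2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ppw(0.0, 250e3, 0.4)
        with pytest.raises(ValueError):
            cfl(1500.0, -1e-9, 0.4)


class TestBowlSource:
    def test_full_cap_voxel_count_matches_area(self):
        # 3D cap without central opening: count ~ cap area / dx^2
        geom = TransducerGeometry(outer_diameter=40.0, inner_diameter=0.0, focal_distance=40.0)
        dx = 1.0
        bowl = make_bowl_source(geom, (96, 96, 96), dx, apex_index=12)
        F = 40.0
        cap_area = 2 * np.pi * F * F * (1 - np.cos(geom.outer_half_angle))
        assert abs(len(bowl) - cap_area / dx**2) / (cap_area / dx**2) < 0.10

    def test_degenerate_annulus_rejected(self):
        with pytest.raises(ValueError):
            TransducerGeometry(outer_diameter=44.0, inner_diameter=44.0)

    def test_source_voxels_equidistant_from_focus(self):
        geom = TransducerGeometry()
        dx = 0.4
        bowl = make_bowl_source(geom, (320, 320), dx, apex_index=15)
        r = np.linalg.norm((bowl.indices - bowl.focus_index) * dx, axis=1)
        assert np.all(np.abs(r - 110.0) <= dx)

    def test_clipped_bowl_rejected(self):
        geom = TransducerGeometry()
        with pytest.raises(ValueError, match="clipped"):
            make_bowl_source(geom, (100, 100), 0.4, apex_index=15)


class TestSimulateBasics:
    def _small_setup(self, amp=1.0):
        med = AcousticMediumMap.homogeneous_water((96, 96), (0.5, 0.5))
        src = GridSource(indices=[[30, 48]])
        cfg = SimulationConfig(f0=250e3, source_amplitude=amp, n_cycles=8, t_end=40e-6)
        return med, src, cfg

    def test_zero_amplitude_source_gives_zero_field(self):
        med, src, cfg = self._small_setup(amp=0.0)
        field = simulate(med, src, cfg)
        assert np.all(field.max_pressure == 0.0)

    def test_linearity_in_source_amplitude(self):
        med, src, cfg1 = self._small_setup(amp=1.0)
        _, _, cfg3 = self._small_setup(amp=3.0)
        f1 = simulate(med, src, cfg1)
        f3 = simulate(med, src, cfg3)
        sig = f1.max_pressure > 1e-3 * f1.max_pressure.max()
        ratio = f3.max_pressure[sig] / f1.max_pressure[sig]
        assert np.allclose(ratio, 3.0, rtol=1e-3)

    def test_cfl_violation_refused(self):
        med = AcousticMediumMap.homogeneous_water((64, 64), (0.5, 0.5))
        src = GridSource(indices=[[30, 30]])
        cfg = SimulationConfig(f0=250e3, dt=2e-7, t_end=10e-6)  # CFL 0.6
        with pytest.raises(ValueError, match="CFL"):
            simulate(med, src, cfg)

    def test_reciprocity_between_two_points_in_water(self):
        med = AcousticMediumMap.homogeneous_water((112, 112), (0.5, 0.5))
        a, b = [35, 40], [70, 75]
        cfg = SimulationConfig(f0=250e3, n_cycles=8, t_end=60e-6)
        f_ab = simulate(med, GridSource(indices=[a]), cfg)
        f_ba = simulate(med, GridSource(indices=[b]), cfg)
        p_at_b = f_ab.max_pressure[tuple(b)]
        p_at_a = f_ba.max_pressure[tuple(a)]
        assert p_at_b == pytest.approx(p_at_a, rel=0.02)

    def test_pml_returns_less_than_one_percent(self):
        # a pulse crosses the probe, hits the boundary layer, and whatever
        # returns must be tiny compared with the direct arrival
        med = AcousticMediumMap.homogeneous_water((220, 32), (0.4, 0.4))
        ys = np.arange(32)
        src = GridSource(indices=np.stack([np.full(32, 30), ys], axis=1), delays=np.zeros(32))
        cfg = SimulationConfig(
            f0=250e3, n_cycles=5, pml_thickness=30, pml_alpha=1.0,
            periodic_axes=(1,), t_end=120e-6,
        )
        f = simulate(med, src, cfg, probes=[[140, 16]])
        tr = np.abs(f.probe_traces[:, 0])
        t = np.arange(len(tr)) * f.probe_dt
        incident = tr[(t > 20e-6) & (t < 50e-6)].max()
        returned = tr[t > 70e-6].max()
        assert returned < 0.01 * incident

    def test_absorbing_medium_attenuates_bone_path(self):
        shape = (200, 48)
        c = np.full(shape, 1500.0)
        rho = np.full(shape, 1000.0)
        alpha = np.zeros(shape)
        ys = np.arange(48)
        src = GridSource(indices=np.stack([np.full(48, 30), ys], axis=1), delays=np.zeros(48))
        cfg = SimulationConfig(f0=250e3, n_cycles=10, periodic_axes=(1,), t_end=80e-6)
        lossless = simulate(AcousticMediumMap(c, rho, alpha, (0.4, 0.4)), src, cfg)
        alpha2 = alpha.copy()
        alpha2[60:160, :] = 5.0  # dB/cm over a 40 mm path -> 20 dB
        lossy = simulate(AcousticMediumMap(c, rho, alpha2, (0.4, 0.4)), src, cfg)
        ratio = lossy.max_pressure[180, 24] / lossless.max_pressure[180, 24]
        assert ratio == pytest.approx(10 ** (-20 / 20), rel=0.15)


class TestThreeDimensional:
    def test_point_source_field_is_spherically_symmetric(self):
        med = AcousticMediumMap.homogeneous_water((48, 48, 48), (1.0, 1.0, 1.0))
        src = GridSource(indices=[[24, 24, 24]])
        cfg = SimulationConfig(f0=250e3, n_cycles=4, pml_thickness=8, t_end=25e-6)
        field = simulate(med, src, cfg)
        # same-radius samples along the three axes agree
        p = field.max_pressure
        r = 10
        vals = [p[24 + r, 24, 24], p[24 - r, 24, 24], p[24, 24 + r, 24],
                p[24, 24, 24 + r], p[24, 24, 24 - r]]
        assert np.ptp(vals) / np.mean(vals) < 0.05
        # amplitude falls roughly as 1/R between radii 6 and 12
        ratio = p[24 + 6, 24, 24] / p[24 + 12, 24, 24]
        assert ratio == pytest.approx(2.0, rel=0.2)


class TestRayleighOracle:
    def test_on_axis_quadrature_matches_closed_form_within_one_percent(self):
        geom = TransducerGeometry(inner_diameter=0.0)
        z = np.array([60.0, 80.0, 95.0, 105.0])
        pts = np.zeros((len(z), 3))
        pts[:, 2] = -z  # beam fires along -z from the origin
        num = np.abs(rayleigh_free_field(geom, pts))
        closed = np.abs(on_axis_bowl_pressure(geom, z))
        assert np.allclose(num, closed, rtol=0.01)

    def test_focus_is_global_on_axis_maximum(self):
        geom = TransducerGeometry(inner_diameter=0.0)
        z = np.linspace(20.0, 108.0, 45)
        pts = np.zeros((len(z), 3))
        pts[:, 2] = -z
        p = np.abs(rayleigh_free_field(geom, pts))
        # the profile must peak near the focus, not at the aperture
        assert z[np.argmax(p)] > 95.0

    def test_linearity_in_surface_velocity(self):
        geom = TransducerGeometry()
        pts = [(0.0, 0.0, -90.0)]
        p1 = rayleigh_free_field(geom, pts, u0=1.0)
        p2 = rayleigh_free_field(geom, pts, u0=2.0)
        assert np.allclose(p2, 2.0 * p1)

    def test_green_function_kernels_decay_correctly(self):
        # 3D point source: amplitude falls as 1/R
        src = [[0.0, 0.0, 0.0]]
        p = np.abs(point_source_field(src, 1e-9, [[10.0, 0, 0], [20.0, 0, 0]], 250e3, 1500.0, ndim=3))
        assert p[0] / p[1] == pytest.approx(2.0, rel=1e-6)


class TestLayerTransmissionCoefficient:
    def test_no_contrast_is_transparent(self):
        T = layer_transmission_coefficient(1500, 1000, 1500, 1000, 7.3, 250e3, 12.0)
        assert abs(T) == pytest.approx(1.0)

    def test_half_wavelength_layer_resonance(self):
        # layer thickness = lambda/2 in the layer: full transmission
        lam2_mm = 3000.0 / 250e3 * 1e3
        T = layer_transmission_coefficient(1500, 1000, 3000, 2200, lam2_mm / 2, 250e3, 0.0)
        assert abs(T) == pytest.approx(1.0, abs=1e-9)

    def test_quarter_wave_layer_is_the_transmission_minimum(self):
        lam2_mm = 3000.0 / 250e3 * 1e3
        Tq = abs(layer_transmission_coefficient(1500, 1000, 3000, 2200, lam2_mm / 4, 250e3, 0.0))
        z = 2200 * 3000 / (1000 * 1500)
        assert Tq == pytest.approx(2 / (z + 1 / z), rel=1e-9)
        for d in (lam2_mm / 8, lam2_mm / 3):
            assert abs(layer_transmission_coefficient(1500, 1000, 3000, 2200, d, 250e3, 0.0)) > Tq

    def test_transfer_matrix_reference_value(self):
        # water/bone 5 mm layer at 250 kHz, normal incidence; frozen from an
        # independent transfer-matrix evaluation
        T = abs(layer_transmission_coefficient(1500, 1000, 3000, 2200, 5.0, 250e3, 0.0))
        assert T == pytest.approx(0.6919, abs=2e-4)

    def test_beyond_critical_angle_warns_and_tunnels(self):
        with pytest.warns(UserWarning, match="critical"):
            T = layer_transmission_coefficient(1500, 1000, 3000, 2200, 5.0, 250e3, 40.0)
        assert 0 < abs(T) < 0.2
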