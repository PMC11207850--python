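"""Solver tests: fixed points, conservation, closed-form oracles, rendering."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import erfc

from crystaldiff import (
    ConcentrationField,
    CrystalGeometry,
    DiffusionParams,
    OpticsModel,
    build_field,
    render_frame,
    simulate,
    stability_limit_s,
    step_diffusion,
)
from crystaldiff.optics import occupancy_column_um, transmitted_rgb
from crystaldiff.sim import _Stencil


class TestGeometryAndField:
    def test_empty_crystal_builds_zero_grid(self):
        geom = CrystalGeometry((100.0, 100.0, 100.0), 2.0)
        field = build_field(geom, 0.0)
        assert field.occupancy.shape == (50, 50, 50)
        assert np.all(field.occupancy == 0.0)
        assert field.time_min == 0.0

    def test_saturated_start_for_release(self):
        geom = CrystalGeometry((20.0, 20.0, 20.0), 2.0)
        field = build_field(geom, 1.0)
        assert np.all(field.occupancy == 1.0)

    def test_pitch_coarser_than_extent_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|positive"):
            build_field(CrystalGeometry((50.0, 50.0, 50.0), 120.0), 0.0)

    def test_defect_must_lie_on_surface(self):
        with pytest.raises(ValueError, match="surface"):
            CrystalGeometry((20.0, 20.0, 20.0), 2.0, defects=((5, 5, 5),))

    def test_occupancy_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ConcentrationField(np.full((4, 4, 4), 1.5))


class TestStepDiffusion:
    def test_zero_field_with_zero_bath_is_fixed_point(self):
        geom = CrystalGeometry((16.0, 16.0, 16.0), 2.0)
        params = DiffusionParams(D=1e-13, boundary_occupancy=0.0, dt_s=1.0)
        out = step_diffusion(build_field(geom, 0.0), geom, params)
        assert np.all(out.occupancy == 0.0)

    def test_sealed_crystal_conserves_mass(self, rng):
        geom = CrystalGeometry((20.0, 20.0, 20.0), 1.0, exposed_faces=())
        params = DiffusionParams(D=1e-13)
        dt = stability_limit_s(geom, params)
        c0 = rng.random((20, 20, 20))
        stencil = _Stencil(geom, params)
        c = c0.copy()
        for _ in range(1000):
            c = stencil.step(c, dt, 0.0)
        assert abs(c.sum() - c0.sum()) / c0.sum() < 1e-9
        # still a genuine diffusion step, not a no-op
        assert not np.allclose(c, c0)

    def test_unstable_dt_refused(self):
        geom = CrystalGeometry((16.0, 16.0, 16.0), 2.0)
        params = DiffusionParams(D=1e-13, boundary_occupancy=1.0, dt_s=1e9)
        with pytest.raises(ValueError, match="[Uu]nstable"):
            step_diffusion(build_field(geom, 0.0), geom, params)

    def test_occupancy_stays_in_unit_interval(self):
        geom = CrystalGeometry((32.0, 32.0, 32.0), 2.0)
        params = DiffusionParams(D=1e-13)
        for mode in ("uptake", "release"):
            for f in simulate(geom, params, mode, [1.0, 10.0, 60.0]):
                assert f.occupancy.min() >= 0.0
                assert f.occupancy.max() <= 1.0

    def test_one_face_uptake_matches_erfc_half_space(self):
        """Uptake through one face reproduces c = erfc(x / 2√(Dt))."""
        geom = CrystalGeometry((64.0, 16.0, 16.0), 1.0, exposed_faces=("x-",))
        d_um2_s = 0.1
        t_s = 640.0
        params = DiffusionParams(D=d_um2_s * 1e-12, boundary_occupancy=None)
        (field,) = simulate(geom, params, "uptake", [t_s / 60.0])
        profile = field.occupancy.mean(axis=(1, 2))
        x_um = (np.arange(64) + 0.5) * geom.voxel_pitch
        exact = erfc(x_um / (2.0 * np.sqrt(d_um2_s * t_s)))
        rms = np.sqrt(np.mean((profile - exact) ** 2))
        assert rms < 0.02

    def test_face_layer_slows_ingress_through_slow_face(self):
        """A slow face admits less guest than a fast face by the same time."""
        geom = CrystalGeometry(
            (32.0, 32.0, 32.0), 2.0, exposed_faces=("x-", "x+")
        )
        params = DiffusionParams(D={"x-": 1e-13, "x+": 1e-14})
        (field,) = simulate(geom, params, "uptake", [30.0])
        n = field.occupancy.shape[0]
        fast_side = field.occupancy[: n // 2].sum()
        slow_side = field.occupancy[n // 2 :].sum()
        assert fast_side > 1.2 * slow_side
        # the slow-face skin itself lags the fast-face skin
        assert field.occupancy[1].mean() > field.occupancy[-2].mean()

    def test_defect_voxel_acts_as_bath_contact(self):
        geom = CrystalGeometry(
            (32.0, 32.0, 32.0), 2.0, exposed_faces=(), defects=((0, 8, 8),)
        )
        params = DiffusionParams(D=1e-13)
        (field,) = simulate(geom, params, "uptake", [10.0])
        assert field.occupancy[0, 8, 8] == 1.0
        assert field.occupancy[1, 8, 8] > field.occupancy[10, 8, 8]


class TestSimulateRuns:
    def test_short_time_uptake_scales_as_sqrt_t(self):
        """Total early uptake of a cube grows as √t (log–log slope 1/2)."""
        geom = CrystalGeometry((48.0, 48.0, 48.0), 1.0)
        params = DiffusionParams(D=1e-13)
        t_sat_min = (24.0**2 / 0.1) / 60.0
        times = np.geomspace(0.001 * t_sat_min, 0.01 * t_sat_min, 8)
        fields = simulate(geom, params, "uptake", list(times))
        total = np.array([f.total_occupancy for f in fields])
        slope = np.polyfit(np.log(times), np.log(total), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_release_total_occupancy_monotone_nonincreasing(self, small_cube):
        params = DiffusionParams(D=1e-13)
        fields = simulate(small_cube, params, "release", [1, 5, 20, 60, 200])
        totals = [f.total_occupancy for f in fields]
        assert all(b <= a for a, b in zip(totals, totals[1:]))

    def test_sample_times_must_increase(self, small_cube):
        with pytest.raises(ValueError, match="increasing"):
            simulate(small_cube, DiffusionParams(D=1e-13), "uptake", [5.0, 5.0])

    def test_snapshots_reported_at_requested_times(self, small_cube):
        times = [1.5, 4.0, 9.0]
        fields = simulate(small_cube, DiffusionParams(D=1e-13), "uptake", times)
        assert [f.time_min for f in fields] == times


class TestRendering:
    def test_empty_crystal_renders_background(self, small_cube):
        optics = OpticsModel(noise_sd=0.0, pad_px=0)
        frame = render_frame(build_field(small_cube, 0.0), small_cube, optics)
        assert np.all(frame.pixels == np.rint(optics.background_rgb).astype(np.uint8))

    def test_opaque_limit_blocks_green_blue_transmits_red(self, small_cube):
        """With red fully transparent and huge extinction the crystal is pure red."""
        optics = OpticsModel(
            extinction=1e6, extinction_rgb=(0.0, 1.0, 1.0),
            noise_sd=0.0, pad_px=0,
        )
        frame = render_frame(build_field(small_cube, 1.0), small_cube, optics)
        assert np.all(frame.pixels[:, :, 0] == 200)
        assert np.all(frame.pixels[:, :, 1:] == 0)

    def test_attenuation_monotone_in_occupancy(self, small_cube):
        low = build_field(small_cube, 0.3)
        high = build_field(small_cube, 0.7)
        optics = OpticsModel(noise_sd=0.0, pad_px=0)
        rgb_low = transmitted_rgb(
            occupancy_column_um(low, small_cube), optics
        )
        rgb_high = transmitted_rgb(
            occupancy_column_um(high, small_cube), optics
        )
        assert np.all(rgb_high[..., 1:] < rgb_low[..., 1:])
        assert np.all(rgb_high[..., 0] < rgb_low[..., 0])

    def test_identical_seed_bit_identical_frame(self, small_cube):
        field = build_field(small_cube, 0.5)
        optics = OpticsModel(seed=77)
        a = render_frame(field, small_cube, optics)
        b = render_frame(field, small_cube, optics)
        assert np.array_equal(a.pixels, b.pixels)

    def test_noisy_render_without_seed_refused(self, small_cube):
        field = build_field(small_cube, 0.5)
        with pytest.raises(ValueError, match="seed"):
            render_frame(field, small_cube, OpticsModel(seed=None))
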