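"""Sensing design calculations: capacity, pore access, rates, orderings."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crystaldiff import (
    CrystalGeometry,
    DiffusionParams,
    IntensityTrace,
    SensingConstants,
    capacity,
    initial_uptake_rate,
    release_to_uptake_ratio,
    saturation_ordering,
    simulate,
    smallest_passable_window,
    window_accessibility,
)
from crystaldiff.sim import build_field

B12_DIMS = (1.41, 1.83, 1.14)


class TestConstants:
    def test_packaged_constants_load(self):
        c = SensingConstants.load()
        assert c.max_load_mg_per_mg == 0.33
        assert c.initial_uptake_rate_per_hr == 0.112
        assert c.detection_limit_ng_per_ml == 10.0
        assert c.window_diameters_nm == (1.3, 1.7)
        assert c.molecule_dims_nm == B12_DIMS

    def test_molecule_dims_sorted_descending(self):
        c = SensingConstants.load()
        dims = c.molecule_dims_sorted_nm
        assert dims == tuple(sorted(dims, reverse=True))

    def test_release_to_uptake_ratio_rounds_to_four(self):
        ratio = release_to_uptake_ratio()
        assert round(ratio) == 4


class TestCapacity:
    def test_one_mg_loads_a_third_mg(self):
        assert capacity(1.0) == pytest.approx(0.33)

    def test_zero_mass(self):
        assert capacity(0.0) == 0.0

    def test_ten_mg(self):
        assert capacity(10.0) == pytest.approx(3.3)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError):
            capacity(-1.0)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.0, 1e3), st.floats(0.0, 1e3))
    def test_exactly_linear(self, m1, m2):
        c = SensingConstants.load()
        assert capacity(m1 + m2, c) == pytest.approx(
            capacity(m1, c) + capacity(m2, c), rel=1e-12, abs=1e-12
        )


class TestWindowAccessibility:
    def test_b12_passes_large_window(self):
        assert window_accessibility(B12_DIMS, 1.7)

    def test_b12_blocked_by_small_window(self):
        assert not window_accessibility(B12_DIMS, 1.3)

    def test_equality_is_inclusive(self):
        assert window_accessibility((1.0, 1.0, 1.0), 1.0)

    def test_monotone_in_window_diameter(self):
        # if passable at d, passable at every d' > d
        for d in np.linspace(0.5, 3.0, 11):
            if window_accessibility(B12_DIMS, d):
                assert window_accessibility(B12_DIMS, d + 0.25)

    def test_smallest_passable_of_printed_windows(self):
        assert smallest_passable_window(B12_DIMS, (1.3, 1.7)) == 1.7

    def test_no_passable_window_raises(self):
        with pytest.raises(ValueError, match="none"):
            smallest_passable_window((5.0, 5.0, 5.0), (1.3, 1.7))


class TestInitialUptakeRate:
    def test_exact_linear_trace(self):
        # 10% of saturation (=100 counts) per hour, sampled every 6 min
        t = np.arange(0.0, 61.0, 6.0)
        y = 100.0 * 0.10 * t / 60.0
        trace = IntensityTrace(t, y, np.full(t.size, 1))
        assert initial_uptake_rate(trace, 60.0, saturation_intensity=100.0) == (
            pytest.approx(0.10, rel=1e-9)
        )

    def test_simulated_uptake_matches_short_time_law(self):
        """Early cube uptake follows F(t) = 6·√(Dt/π)/a; the fitted linear
        rate must match the same estimator applied to the analytic curve.

        Conditions keep the 60 min window inside the short-time regime
        (uptake stays below ~20 % of saturation, as for a real slow-loading
        100 µm crystal)."""
        a = 50.0  # half-width, µm
        d_um2_s = 2e-3
        geom = CrystalGeometry((2 * a, 2 * a, 2 * a), 1.0)
        fields = simulate(
            geom, DiffusionParams(D=d_um2_s * 1e-12), "uptake",
            list(np.linspace(6.0, 60.0, 10)),
        )
        t = np.array([0.0] + [f.time_min for f in fields])
        frac = np.array([0.0] + [f.mean_occupancy for f in fields])
        trace = IntensityTrace(t, 255 * frac, np.full(t.size, 1))
        rate = initial_uptake_rate(trace, 60.0, saturation_intensity=255.0)
        t_s = t[1:] * 60.0
        analytic = np.concatenate(
            [[0.0], 6.0 * np.sqrt(d_um2_s * t_s / np.pi) / a]
        )
        oracle_rate = np.polyfit(t, analytic, 1)[0] * 60.0
        assert 0.0 < rate < 1.0  # genuinely in the early, sub-saturation regime
        assert rate == pytest.approx(oracle_rate, rel=0.15)

    def test_longer_window_lowers_rate(self):
        """√t uptake is concave, so widening the fit window lowers the slope."""
        t = np.linspace(0.0, 240.0, 41)
        y = 20.0 * np.sqrt(t)
        trace = IntensityTrace(t, np.clip(y, 0, 255), np.full(t.size, 1))
        short = initial_uptake_rate(trace, 60.0, saturation_intensity=255.0)
        long = initial_uptake_rate(trace, 240.0, saturation_intensity=255.0)
        assert long < short

    def test_window_outside_trace_rejected(self):
        trace = IntensityTrace([0.0, 50.0, 100.0], [0.0, 1.0, 2.0], [1, 1, 1])
        with pytest.raises(ValueError, match="window"):
            initial_uptake_rate(trace, 0.5)

    def test_rate_decreases_with_crystal_size(self):
        """Bigger crystals load more slowly per unit capacity at fixed D."""
        rates = []
        for a in (20.0, 40.0):
            geom = CrystalGeometry((2 * a, 2 * a, 2 * a), 1.0)
            fields = simulate(
                geom, DiffusionParams(D=2e-15), "uptake",
                list(np.linspace(6.0, 60.0, 8)),
            )
            t = np.array([0.0] + [f.time_min for f in fields])
            frac = np.array([0.0] + [f.mean_occupancy for f in fields])
            trace = IntensityTrace(t, 255 * frac, np.full(t.size, 1))
            rates.append(
                initial_uptake_rate(trace, 60.0, saturation_intensity=255.0)
            )
        assert rates[1] < rates[0]


class TestSaturationOrdering:
    @pytest.fixture(scope="class")
    @staticmethod
    def cube_run():
        geom = CrystalGeometry((64.0, 64.0, 64.0), 2.0)
        times = list(np.geomspace(0.03, 60.0, 40))
        return geom, simulate(geom, DiffusionParams(D=1e-13), "uptake", times)

    def test_corner_edge_face_center_ordering(self, cube_run):
        """Corners saturate first, then edges, faces, and finally the core."""
        geom, fields = cube_run
        result = saturation_ordering(fields, geom)
        t = result.t50_min
        assert result.ordered
        assert t["corner"] < t["edge"] < t["face"] < t["center"]

    def test_single_exposed_face_corner_beats_center(self):
        geom = CrystalGeometry((64.0, 64.0, 64.0), 2.0, exposed_faces=("x-",))
        times = list(np.geomspace(0.05, 400.0, 40))
        fields = simulate(geom, DiffusionParams(D=1e-13), "uptake", times)
        result = saturation_ordering(fields, geom)
        # all probes sit on the exposed face except the body centre
        assert result.t50_min["corner"] < result.t50_min["center"]

    def test_saturated_input_gives_zero_times(self, small_cube):
        fields = [build_field(small_cube, 1.0)]
        result = saturation_ordering(fields, small_cube)
        assert all(v == 0.0 for v in result.t50_min.values())

    def test_never_reaching_probe_raises(self, small_cube):
        fields = [build_field(small_cube, 0.0)]
        with pytest.raises(ValueError, match="never reaches"):
            saturation_ordering(fields, small_cube)
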