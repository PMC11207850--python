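"""Shared fixtures: small crystals, rendered sequences, deterministic seeds."""

from __future__ import annotations

import numpy as np
import pytest

from crystaldiff import (
    CrystalGeometry,
    DiffusionParams,
    OpticsModel,
    build_field,
    render_sequence,
    simulate,
)

#: diffusivity used by most miniature runs: 0.1 µm²/s, fast enough that a
#: ~50 µm crystal equilibrates within simulated hours
D_FAST = 1e-13


@pytest.fixture(scope="session")
def small_cube() -> CrystalGeometry:
    """32³ cube, 50 µm across, all faces exposed."""
    return CrystalGeometry((50.0, 50.0, 50.0), 50.0 / 32)


@pytest.fixture(scope="session")
def lateral_slab() -> CrystalGeometry:
    """100 µm crystal footprint at 64² lateral resolution, open only through
    its four side faces (viewing axis sealed), thin along the viewing axis —
    lateral transport is uniform in depth, so the slab reproduces the full
    crystal's image sequence at a fraction of the cost."""
    return CrystalGeometry(
        (100.0, 100.0, 12.5), 100.0 / 64, exposed_faces=("x-", "x+", "y-", "y+")
    )


@pytest.fixture(scope="session")
def release_sequence(lateral_slab):
    """Seeded synthetic release run rendered to an image sequence.

    Log-spaced cadence starting at ~1% of the half-signal time and ending
    well past the plateau, mirroring a real monitoring protocol (half-width
    50 µm, D = 0.1 µm²/s → half-signal time ≈ 30 min).  The extinction is
    scaled by the slab-thickness ratio so the frames have the optical depth
    of a full 100 µm crystal.
    """
    params = DiffusionParams(D=D_FAST)
    times = [0.22, 0.45, 0.9, 1.5, 3, 4.5, 7.5, 15, 24, 35, 75, 105, 150,
             210, 300, 420, 600, 850]
    fields = simulate(lateral_slab, params, "release", times)
    start = build_field(lateral_slab, 1.0)
    optics = OpticsModel(seed=123, extinction=0.039 * 8)
    return render_sequence([start] + fields, lateral_slab, optics)


@pytest.fixture(scope="session")
def uptake_sequence(small_cube):
    params = DiffusionParams(D=D_FAST)
    times = [1, 3, 8, 20, 45, 90, 180, 360, 700]
    fields = simulate(small_cube, params, "uptake", times)
    start = build_field(small_cube, 0.0)
    optics = OpticsModel(seed=321)
    return render_sequence([start] + fields, small_cube, optics)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
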