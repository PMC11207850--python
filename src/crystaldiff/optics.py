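"""Rendering of concentration fields into microscopy-like RGB frames.

A bright-field micrograph of a clear crystal infused with a red chromophore
is modelled by Beer–Lambert attenuation of the illumination along the viewing
axis: per-pixel absorbance is the extinction coefficient times the occupancy
column (path integral of fractional occupancy, in µm).  The chromophore is
red, so green and blue are absorbed strongly; the camera's red passband is
attenuated only weakly — its overlap with the short-wavelength edge of the
absorption band is represented by a small relative extinction weight.  That
weak red response is what makes the red channel of a reference-subtracted
frame a usable concentration readout: with a fully transparent red channel
the differential red signal would vanish identically.

Frames are quantized to 8 bits with optional seeded Gaussian read noise, and
identical seeds reproduce bit-identical frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import ImageFrame, ImageSequence
from .sim import ConcentrationField, CrystalGeometry, _AXIS_OF


@dataclass(frozen=True)
class OpticsModel:
    """Optical/camera model used by :func:`render_frame`.

    ``extinction`` is the absorbance per unit occupancy per µm of path for the
    strongly absorbed channels; ``extinction_rgb`` gives the relative weight
    per channel (red small, green/blue 1).  The defaults make a fully loaded
    ~100 µm crystal essentially opaque in green/blue (transmittance ≈ 2 %),
    i.e. intensely red, while its red channel keeps roughly half of the
    background level.  ``background_rgb`` is the empty-scene colour,
    ``noise_sd`` the additive read-noise standard deviation in counts, and
    ``pad_px`` a margin of background pixels around the crystal footprint.
    """

    view_axis: str = "z"
    extinction: float = 0.039  # 1/µm at unit occupancy (green/blue)
    extinction_rgb: tuple[float, float, float] = (0.2, 1.0, 1.0)
    background_rgb: tuple[float, float, float] = (200.0, 200.0, 200.0)
    bit_depth: int = 8
    noise_sd: float = 2.0
    pad_px: int = 4
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.view_axis not in _AXIS_OF:
            raise ValueError("view_axis must be 'x', 'y' or 'z'")
        if self.extinction < 0:
            raise ValueError("extinction must be >= 0")
        if any(w < 0 for w in self.extinction_rgb):
            raise ValueError("extinction weights must be >= 0")
        if any(not 0 <= b <= 255 for b in self.background_rgb):
            raise ValueError("background channels must lie in [0, 255]")
        if self.bit_depth != 8:
            raise ValueError("only 8-bit rendering is supported")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.pad_px < 0:
            raise ValueError("pad_px must be >= 0")


def occupancy_column_um(
    field: ConcentrationField, geometry: CrystalGeometry, view_axis: str = "z"
) -> np.ndarray:
    """Path integral of occupancy along the view axis (µm), image-oriented.

    The image plane keeps the two remaining axes in (row, column) = (second,
    first) order so that an observer looking down ``z`` sees ``x`` across and
    ``y`` down.
    """
    axis = _AXIS_OF[view_axis]
    col = field.occupancy.sum(axis=axis) * geometry.voxel_pitch
    return col.T


def transmitted_rgb(
    column_um: np.ndarray, optics: OpticsModel
) -> np.ndarray:
    """Noise-free transmitted intensity per channel (float, 0–255 scale)."""
    out = np.empty(column_um.shape + (3,))
    for c in range(3):
        absorbance = optics.extinction * optics.extinction_rgb[c] * column_um
        out[..., c] = optics.background_rgb[c] * np.exp(-absorbance)
    return out


def render_frame(
    field: ConcentrationField,
    geometry: CrystalGeometry,
    optics: OpticsModel,
    seed: int | None = None,
) -> ImageFrame:
    """Render one concentration field into an 8-bit RGB frame.

    ``seed`` overrides ``optics.seed`` for this frame (used by
    :func:`render_sequence` to decorrelate noise between frames).  Rendering
    with noise and no seed is refused so that every stochastic run is
    reproducible.
    """
    if not np.isfinite(field.occupancy).all():
        raise ValueError("field contains non-finite values")
    col = occupancy_column_um(field, geometry, optics.view_axis)
    rgb = transmitted_rgb(col, optics)
    if optics.pad_px:
        p = optics.pad_px
        bg = transmitted_rgb(np.zeros((1, 1)), optics)[0, 0]
        padded = np.empty((rgb.shape[0] + 2 * p, rgb.shape[1] + 2 * p, 3))
        padded[:] = bg
        padded[p:-p, p:-p] = rgb
        rgb = padded
    if optics.noise_sd > 0:
        use_seed = seed if seed is not None else optics.seed
        if use_seed is None:
            raise ValueError("noisy rendering requires an explicit seed")
        rng = np.random.default_rng(use_seed)
        rgb = rgb + rng.normal(0.0, optics.noise_sd, rgb.shape)
    pixels = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return ImageFrame(
        pixels, time_min=field.time_min, pixel_size_um=geometry.voxel_pitch
    )


def render_sequence(
    fields: "list[ConcentrationField]",
    geometry: CrystalGeometry,
    optics: OpticsModel,
) -> ImageSequence:
    """Render snapshots into a time-stamped sequence.

    Frame ``k`` uses seed ``optics.seed + k`` so noise is independent between
    frames yet the whole sequence is reproducible from one seed.
    """
    if optics.noise_sd > 0 and optics.seed is None:
        raise ValueError("noisy rendering requires optics.seed")
    frames = [
        render_frame(
            f, geometry, optics,
            seed=None if optics.seed is None else optics.seed + k,
        )
        for k, f in enumerate(fields)
    ]
    return ImageSequence(frames)
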