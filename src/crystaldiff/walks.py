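"""Brownian random-walk ensembles for mean-square-displacement validation.

Free diffusion satisfies ⟨x²⟩ = q_i·D·t with q_i = 2, 4, 6 in one, two and
three dimensions.  These walks provide a ground-truth stochastic process on
which the MSD estimator in :mod:`crystaldiff.kinetics` can be validated:
positions take per-axis Gaussian increments of variance 2·D·dt per step, so
the exact relation holds in expectation at every dimension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import units


@dataclass
class WalkEnsemble:
    """Final particle positions of an ensemble of free Brownian walks.

    Positions are in µm relative to each particle's origin; ``true_D`` is the
    generating diffusivity in m²/s and ``elapsed_s`` the walk duration.
    """

    dim: int
    positions: np.ndarray  # (n_particles, dim), µm
    true_D: float  # m²/s
    elapsed_s: float
    seed: int

    def __post_init__(self) -> None:
        if self.dim not in (1, 2, 3):
            raise ValueError("dim must be 1, 2 or 3")
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != self.dim:
            raise ValueError("positions must have shape (n_particles, dim)")
        if self.positions.shape[0] < 1:
            raise ValueError("ensemble needs at least one particle")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def msd_um2(self) -> float:
        """Mean squared displacement from the origin, µm²."""
        return float((self.positions**2).sum(axis=1).mean())

    @property
    def q_i(self) -> int:
        """Dimensionality constant of ⟨x²⟩ = q_i·D·t."""
        return 2 * self.dim


def simulate_walk(
    dim: int,
    true_D: float,
    n_particles: int,
    total_time_s: float,
    dt_s: float,
    seed: int,
) -> WalkEnsemble:
    """Simulate free Brownian motion and return the final ensemble.

    ``true_D`` is in m²/s (1 µm²/s = 1e-12 m²/s).  The walk takes
    ``ceil(total_time_s / dt_s)`` steps, the last one shortened so the elapsed
    time is exactly ``total_time_s``.  Fixed seeds reproduce trajectories
    bit-for-bit.
    """
    if dim not in (1, 2, 3):
        raise ValueError("dim must be 1, 2 or 3")
    if true_D <= 0:
        raise ValueError("true_D must be positive")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if total_time_s < 0:
        raise ValueError("total_time_s must be >= 0")
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")

    d_um2_s = units.m2_to_um2(true_D)
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_particles, dim))
    remaining = total_time_s
    n_full = int(math.floor(total_time_s / dt_s))
    sigma = math.sqrt(2.0 * d_um2_s * dt_s)
    for _ in range(n_full):
        pos += rng.normal(0.0, sigma, (n_particles, dim))
        remaining -= dt_s
    if remaining > 1e-12 * max(dt_s, 1.0):
        pos += rng.normal(
            0.0, math.sqrt(2.0 * d_um2_s * remaining), (n_particles, dim)
        )
    return WalkEnsemble(
        dim=dim, positions=pos, true_D=true_D,
        elapsed_s=total_time_s, seed=seed,
    )
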