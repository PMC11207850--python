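"""Finite-difference simulation of guest-molecule diffusion in a faceted crystal.

The crystal is voxelized on an isotropic grid and the fractional guest
occupancy ``c(x, t) ∈ [0, 1]`` evolves by the diffusion equation, solved with
an explicit forward-time centred-space (FTCS) scheme.  Faces in contact with
the bath impose a Dirichlet condition at the crystal surface through mirror
ghost cells, ``ghost = 2·b − c_surface`` (bath occupancy ``b`` = 1 for uptake
from a saturated solution, 0 for release into pure solvent); sealed faces are
zero-flux.  The mirror form places the boundary exactly on the surface
(second-order accurate); imposing the bath value at the ghost-cell centre
instead would shift the boundary half a voxel outward and visibly distort
short-time uptake at practical resolutions.  Face-dependent ingress speed — a well-documented feature
of single-crystal uptake — is modelled as a per-face diffusivity in a thin
near-surface layer, with the interior taking the fastest face value.  Surface
defects (chips, scratches, broken corners) are modelled as extra bath-contact
voxels, since their effect in practice is molecular intake from multiple
directions.

The FTCS update with interface-averaged diffusivity is a convex combination
of neighbour values whenever ``dt ≤ h²/((6 + k)·max D)``, where ``k`` is the
largest number of exposed faces meeting at one voxel (each mirror ghost
doubles the effective coupling to the bath).  Under that bound occupancy
stays in [0, 1] by construction; the solver refuses an unstable ``dt``
outright rather than producing out-of-range values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import units

#: The six axis-aligned faces of the voxel box, named by axis and side.
FACES: tuple[str, ...] = ("x-", "x+", "y-", "y+", "z-", "z+")

_AXIS_OF = {"x": 0, "y": 1, "z": 2}


def _face_axis_side(face: str) -> tuple[int, int]:
    """Map a face name like ``"y+"`` to (axis index, side) with side ∈ {0, 1}."""
    if len(face) != 2 or face[0] not in _AXIS_OF or face[1] not in "-+":
        raise ValueError(f"unknown face {face!r}; expected one of {FACES}")
    return _AXIS_OF[face[0]], (0 if face[1] == "-" else 1)


@dataclass(frozen=True)
class CrystalGeometry:
    """Axis-aligned faceted crystal on an isotropic voxel grid.

    Parameters
    ----------
    extents : physical size along x, y, z in µm.  The crystal occupies the
        half-open box ``[0, extent)`` per axis; voxel ``i`` is centred at
        ``(i + 1/2) · voxel_pitch``.
    voxel_pitch : isotropic voxel edge length in µm.
    exposed_faces : subset of :data:`FACES` in contact with the bath.  An
        empty tuple seals the crystal completely (used for conservation
        checks); all six exposed is the free-floating crystal.
    defects : voxel index triples on the crystal surface that act as extra
        bath-contact sites (chips, bumps, scratches).
    """

    extents: tuple[float, float, float]
    voxel_pitch: float
    exposed_faces: tuple[str, ...] = FACES
    defects: tuple[tuple[int, int, int], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.extents) != 3 or any(e <= 0 for e in self.extents):
            raise ValueError("extents must be three positive lengths (µm)")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive (µm)")
        seen = set()
        for f in self.exposed_faces:
            _face_axis_side(f)
            if f in seen:
                raise ValueError(f"duplicate exposed face {f!r}")
            seen.add(f)
        shape = self._try_shape()
        if shape is not None:
            for ijk in self.defects:
                if len(ijk) != 3 or any(
                    not (0 <= ijk[a] < shape[a]) for a in range(3)
                ):
                    raise ValueError(f"defect voxel {ijk} outside the grid")
                if not any(ijk[a] in (0, shape[a] - 1) for a in range(3)):
                    raise ValueError(
                        f"defect voxel {ijk} is not on the crystal surface"
                    )

    def _try_shape(self) -> tuple[int, int, int] | None:
        shape = tuple(int(round(e / self.voxel_pitch)) for e in self.extents)
        return shape if min(shape) >= 1 else None

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape after voxelization; raises if any axis rounds to zero."""
        shape = self._try_shape()
        if shape is None:
            raise ValueError(
                "degenerate grid: voxel_pitch too coarse for the extents"
            )
        return shape


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusion parameters for one run.

    ``D`` is either a single diffusivity (m²/s) applied everywhere, or a
    mapping face-name → diffusivity realising face-dependent ingress; the
    interior then diffuses at the fastest face value.  ``boundary_occupancy``
    is the fractional surface concentration imposed by the bath (1 = uptake
    from saturated solution, 0 = release into pure solvent).  ``dt_s`` is the
    explicit-scheme time step in seconds; ``None`` lets the solver choose
    90 % of the stability limit.
    """

    D: float | dict[str, float]
    boundary_occupancy: float | None = None
    dt_s: float | None = None
    #: depth (voxels) of the per-face diffusivity layer under each exposed face
    face_layer_voxels: int = 2

    def __post_init__(self) -> None:
        for d in self.face_diffusivities().values():
            if d < 0 or not math.isfinite(d):
                raise ValueError("diffusivities must be finite and >= 0")
        if self.boundary_occupancy is not None and not (
            0.0 <= self.boundary_occupancy <= 1.0
        ):
            raise ValueError("boundary_occupancy must lie in [0, 1]")
        if self.dt_s is not None and self.dt_s <= 0:
            raise ValueError("dt_s must be positive")

    def face_diffusivities(self) -> dict[str, float]:
        if isinstance(self.D, dict):
            bad = set(self.D) - set(FACES)
            if bad:
                raise ValueError(f"unknown faces in D mapping: {sorted(bad)}")
            if not self.D:
                raise ValueError("D mapping must not be empty")
            d = {f: float(self.D.get(f, max(self.D.values()))) for f in FACES}
            return d
        return {f: float(self.D) for f in FACES}

    @property
    def D_max(self) -> float:
        return max(self.face_diffusivities().values())


@dataclass
class ConcentrationField:
    """Fractional guest occupancy on the voxel grid at one instant."""

    occupancy: np.ndarray  # 3-D float array, values in [0, 1]
    time_min: float = 0.0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3-D array")
        if self.time_min < 0:
            raise ValueError("time must be >= 0")
        if not np.isfinite(self.occupancy).all():
            raise ValueError("occupancy contains non-finite values")
        if self.occupancy.min() < -1e-12 or self.occupancy.max() > 1 + 1e-12:
            raise ValueError("occupancy must lie in [0, 1]")

    @property
    def total_occupancy(self) -> float:
        """Sum of voxel occupancies (proportional to total guest load)."""
        return float(self.occupancy.sum())

    @property
    def mean_occupancy(self) -> float:
        return float(self.occupancy.mean())


def _max_exposed_per_voxel(geometry: CrystalGeometry) -> int:
    """Largest number of exposed faces meeting at a single voxel."""
    shape = geometry._try_shape() or (2, 2, 2)
    k = 0
    for axis in range(3):
        sides = [
            s for f in geometry.exposed_faces
            for a, s in [_face_axis_side(f)] if a == axis
        ]
        k += len(sides) if shape[axis] == 1 else min(len(sides), 1)
    return k


def stability_limit_s(geometry: CrystalGeometry, params: DiffusionParams) -> float:
    """Largest stable explicit time step in seconds.

    ``h²/((6 + k)·max D)`` with ``k`` the largest number of exposed faces
    meeting at one voxel: each mirror-ghost boundary doubles that voxel's
    coupling to the bath, so a fully exposed corner (k = 3) is the binding
    constraint.  Sealed crystals recover the classic ``h²/(6·D)``.
    """
    d_max = params.D_max
    if d_max == 0.0:
        return math.inf
    h_m = units.um_to_m(geometry.voxel_pitch)
    return h_m * h_m / ((6.0 + _max_exposed_per_voxel(geometry)) * d_max)


def build_field(
    geometry: CrystalGeometry, initial_occupancy: float
) -> ConcentrationField:
    """Uniform occupancy field at time zero."""
    if not 0.0 <= initial_occupancy <= 1.0:
        raise ValueError("initial_occupancy must lie in [0, 1]")
    return ConcentrationField(
        np.full(geometry.shape, float(initial_occupancy)), time_min=0.0
    )


def _diffusivity_map(
    geometry: CrystalGeometry, params: DiffusionParams
) -> np.ndarray:
    """Per-voxel diffusivity (m²/s): interior at max(D_face), a thin layer
    under each exposed face at that face's value (max where layers overlap)."""
    d_face = params.face_diffusivities()
    d_map = np.full(geometry.shape, params.D_max)
    depth = params.face_layer_voxels
    layer = np.zeros_like(d_map)
    touched = np.zeros(geometry.shape, dtype=bool)
    for f in geometry.exposed_faces:
        axis, side = _face_axis_side(f)
        sl = [slice(None)] * 3
        sl[axis] = slice(0, depth) if side == 0 else slice(-depth, None)
        sl = tuple(sl)
        layer[sl] = np.maximum(layer[sl], d_face[f])
        touched[sl] = True
    d_map[touched] = layer[touched]
    return d_map


class _Stencil:
    """Precomputed FTCS stencil: interface diffusivities, boundary planes,
    and defect indices.  Built once per run, reused every step."""

    def __init__(self, geometry: CrystalGeometry, params: DiffusionParams):
        self.geometry = geometry
        self.params = params
        self.h2_m2 = units.um_to_m(geometry.voxel_pitch) ** 2
        d_map = _diffusivity_map(geometry, params)
        d_pad = np.pad(d_map, 1, mode="edge")
        # Interface diffusivity between voxel and its +/- neighbour per axis
        # (arithmetic mean; ghost interfaces reuse the surface voxel value).
        self.d_if: list[tuple[np.ndarray, np.ndarray]] = []
        core = tuple([slice(1, -1)] * 3)
        for axis in range(3):
            plus = [slice(1, -1)] * 3
            plus[axis] = slice(2, None)
            minus = [slice(1, -1)] * 3
            minus[axis] = slice(0, -2)
            d_plus = 0.5 * (d_pad[core] + d_pad[tuple(plus)])
            d_minus = 0.5 * (d_pad[core] + d_pad[tuple(minus)])
            self.d_if.append((d_plus, d_minus))
        self.exposed = [_face_axis_side(f) for f in geometry.exposed_faces]
        if geometry.defects:
            idx = np.asarray(geometry.defects, dtype=int)
            self.defect_idx = (idx[:, 0], idx[:, 1], idx[:, 2])
        else:
            self.defect_idx = None

    def step(self, c: np.ndarray, dt_s: float, boundary: float) -> np.ndarray:
        cp = np.pad(c, 1, mode="edge")  # zero-flux ghosts by default
        for axis, side in self.exposed:
            ghost = [slice(None)] * 3
            surf = [slice(None)] * 3
            ghost[axis] = 0 if side == 0 else -1
            surf[axis] = 1 if side == 0 else -2
            # mirror ghost: Dirichlet value held at the crystal surface
            cp[tuple(ghost)] = 2.0 * boundary - cp[tuple(surf)]
        core = tuple([slice(1, -1)] * 3)
        flux = np.zeros_like(c)
        for axis in range(3):
            plus = [slice(1, -1)] * 3
            plus[axis] = slice(2, None)
            minus = [slice(1, -1)] * 3
            minus[axis] = slice(0, -2)
            d_plus, d_minus = self.d_if[axis]
            flux += d_plus * (cp[tuple(plus)] - c)
            flux += d_minus * (cp[tuple(minus)] - c)
        c_new = c + (dt_s / self.h2_m2) * flux
        if self.defect_idx is not None:
            c_new[self.defect_idx] = boundary
        return c_new


def _resolve_boundary(params: DiffusionParams, mode: str | None) -> float:
    if params.boundary_occupancy is not None:
        return params.boundary_occupancy
    if mode == "uptake":
        return 1.0
    if mode == "release":
        return 0.0
    raise ValueError(
        "boundary_occupancy not set and no uptake/release mode given"
    )


def step_diffusion(
    field: ConcentrationField,
    geometry: CrystalGeometry,
    params: DiffusionParams,
) -> ConcentrationField:
    """Advance the field by one explicit step of ``params.dt_s``.

    Raises if ``dt_s`` violates the stability bound or the field has gone
    non-finite.  For long runs prefer :func:`simulate`, which builds the
    stencil once.
    """
    if params.dt_s is None:
        raise ValueError("step_diffusion requires an explicit dt_s")
    limit = stability_limit_s(geometry, params)
    if params.dt_s > limit * (1 + 1e-12):
        raise ValueError(
            f"unstable time step: dt={params.dt_s:g} s exceeds the explicit "
            f"stability bound {limit:g} s"
        )
    if not np.isfinite(field.occupancy).all():
        raise FloatingPointError("field contains non-finite values")
    if params.boundary_occupancy is None and geometry.exposed_faces:
        raise ValueError("boundary_occupancy must be set when faces are exposed")
    boundary = params.boundary_occupancy if params.boundary_occupancy is not None else 0.0
    stencil = _Stencil(geometry, params)
    c_new = stencil.step(field.occupancy, params.dt_s, boundary)
    return ConcentrationField(
        c_new, time_min=field.time_min + units.s_to_min(params.dt_s)
    )


def simulate(
    geometry: CrystalGeometry,
    params: DiffusionParams,
    mode: str,
    sample_times_min: "list[float] | np.ndarray",
    initial_occupancy: float | None = None,
    include_initial: bool = False,
) -> list[ConcentrationField]:
    """Run an uptake or release experiment, returning snapshots.

    ``mode`` is ``"uptake"`` (start empty, bath at occupancy 1) or
    ``"release"`` (start saturated, bath at 0); an explicit
    ``params.boundary_occupancy`` or ``initial_occupancy`` overrides the mode
    default.  Snapshot times (minutes, strictly increasing) are hit exactly by
    subdividing each interval into uniform steps no longer than the requested
    (or 90 %-of-stability) ``dt``.  With ``include_initial`` the t = 0 state
    is prepended (unless the first sample time is already 0) — rendered, it
    is the reference frame of the experiment.
    """
    if mode not in ("uptake", "release"):
        raise ValueError("mode must be 'uptake' or 'release'")
    times = np.asarray(sample_times_min, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("sample_times_min must be a non-empty 1-D sequence")
    if np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("sample times must be non-negative, strictly increasing")

    boundary = _resolve_boundary(params, mode)
    if initial_occupancy is None:
        initial_occupancy = 0.0 if mode == "uptake" else 1.0
    limit = stability_limit_s(geometry, params)
    dt_target = params.dt_s if params.dt_s is not None else (
        0.9 * limit if math.isfinite(limit) else units.min_to_s(times[-1]) or 1.0
    )
    if dt_target > limit * (1 + 1e-12):
        raise ValueError(
            f"unstable time step: dt={dt_target:g} s exceeds the explicit "
            f"stability bound {limit:g} s"
        )

    stencil = _Stencil(geometry, params)
    c = build_field(geometry, initial_occupancy).occupancy
    snapshots: list[ConcentrationField] = []
    if include_initial and times[0] > 0:
        snapshots.append(ConcentrationField(c.copy(), time_min=0.0))
    t_s = 0.0
    for t_target_min in times:
        t_target_s = units.min_to_s(float(t_target_min))
        span = t_target_s - t_s
        if span > 0:
            n = max(1, math.ceil(span / dt_target - 1e-12))
            dt_loc = span / n
            for _ in range(n):
                c = stencil.step(c, dt_loc, boundary)
            t_s = t_target_s
        if not np.isfinite(c).all():
            raise FloatingPointError("diffusion solve produced non-finite values")
        snapshots.append(
            ConcentrationField(c.copy(), time_min=float(t_target_min))
        )
    return snapshots
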