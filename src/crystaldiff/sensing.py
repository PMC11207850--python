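"""Design calculations for MOF-based colorimetric sensing.

A porous crystal that visibly changes colour as a guest molecule loads is a
single-particle sensor.  Its useful operating envelope is set by a handful of
numbers: the saturation capacity (how much guest a crystal of given mass can
report), the geometric accessibility of the pore windows to the guest, the
initial uptake rate (how fast a reading can be taken while uptake is still
linear), and the spatial order in which the crystal saturates (corners first,
interior last), which limits colorimetric readout at low concentrations.

Literature-derived constants for the Tb-mesoMOF / cobalamin system ship as a
versioned JSON file with per-field provenance notes; they are design inputs
and are never used to calibrate the simulator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .pipeline import IntensityTrace
from .sim import ConcentrationField, CrystalGeometry, _face_axis_side


@dataclass(frozen=True)
class SensingConstants:
    """Cited constants of the Tb-mesoMOF / vitamin-B12 sensing system."""

    max_load_mg_per_mg: float
    initial_uptake_rate_per_hr: float
    detection_limit_ng_per_ml: float
    cage_diameters_nm: tuple[float, float]
    window_diameters_nm: tuple[float, float]
    molecule_dims_nm: tuple[float, float, float]
    uptake_duration_min: float
    release_duration_min: float

    def __post_init__(self) -> None:
        scalars = (
            self.max_load_mg_per_mg,
            self.initial_uptake_rate_per_hr,
            self.detection_limit_ng_per_ml,
            self.uptake_duration_min,
            self.release_duration_min,
        )
        if any(v <= 0 for v in scalars):
            raise ValueError("all sensing constants must be positive")
        for seq in (
            self.cage_diameters_nm,
            self.window_diameters_nm,
            self.molecule_dims_nm,
        ):
            if any(v <= 0 for v in seq):
                raise ValueError("all dimensions must be positive")

    @property
    def molecule_dims_sorted_nm(self) -> tuple[float, ...]:
        """Molecule bounding-box dimensions, largest first."""
        return tuple(sorted(self.molecule_dims_nm, reverse=True))

    @classmethod
    def load(cls) -> "SensingConstants":
        """Load the packaged constants file."""
        raw = json.loads(
            resources.files("crystaldiff.data")
            .joinpath("sensing_constants.json")
            .read_text()
        )
        c = {k: v["value"] for k, v in raw["constants"].items()}
        return cls(
            max_load_mg_per_mg=c["max_load_mg_per_mg"],
            initial_uptake_rate_per_hr=c["initial_uptake_rate_per_hr"],
            detection_limit_ng_per_ml=c["detection_limit_ng_per_ml"],
            cage_diameters_nm=tuple(c["cage_diameters_nm"]),
            window_diameters_nm=tuple(c["window_diameters_nm"]),
            molecule_dims_nm=tuple(c["molecule_dims_nm"]),
            uptake_duration_min=c["uptake_duration_min"],
            release_duration_min=c["release_duration_min"],
        )


def capacity(mass_mof_mg: float, constants: SensingConstants | None = None) -> float:
    """Guest mass (mg) a crystal batch of ``mass_mof_mg`` holds at saturation."""
    if mass_mof_mg < 0:
        raise ValueError("mass must be >= 0")
    constants = constants or SensingConstants.load()
    return mass_mof_mg * constants.max_load_mg_per_mg


def window_accessibility(
    molecule_dims_nm: tuple[float, float, float], window_diameter_nm: float
) -> bool:
    """Can a rigid box-shaped molecule pass a circular window?

    The molecule presents its two smallest axes to the aperture, so the
    criterion is ``max(two smallest dims) <= window diameter`` (inclusive at
    equality).  Monotone in the window diameter by construction.
    """
    if len(molecule_dims_nm) != 3 or any(d <= 0 for d in molecule_dims_nm):
        raise ValueError("molecule_dims_nm must be three positive lengths")
    if window_diameter_nm <= 0:
        raise ValueError("window diameter must be positive")
    two_smallest = sorted(molecule_dims_nm)[:2]
    return max(two_smallest) <= window_diameter_nm


def smallest_passable_window(
    molecule_dims_nm: tuple[float, float, float],
    window_diameters_nm: "tuple[float, ...] | list[float]",
) -> float:
    """Smallest of the given window diameters that the molecule can pass."""
    passable = [
        d for d in window_diameters_nm
        if window_accessibility(molecule_dims_nm, d)
    ]
    if not passable:
        raise ValueError("molecule passes none of the given windows")
    return min(passable)


def initial_uptake_rate(
    trace: IntensityTrace,
    window_min: float,
    saturation_intensity: float | None = None,
) -> float:
    """Initial uptake rate as a fraction of saturation per hour.

    A least-squares line is fitted to the trace over ``[0, window_min]`` and
    its slope normalised by the saturation intensity (default: the trace
    maximum, valid only if the trace actually reaches saturation).  Short
    windows approximate the √t uptake law by its tangent; lengthening the
    window can only lower the estimate (concavity).
    """
    sel = trace.times_min <= window_min
    if sel.sum() < 3:
        raise ValueError("need at least 3 trace points inside the window")
    if saturation_intensity is None:
        saturation_intensity = float(trace.mean_intensity.max())
    if saturation_intensity <= 0:
        raise ValueError("saturation intensity must be positive")
    slope_per_min = np.polyfit(
        trace.times_min[sel], trace.mean_intensity[sel], 1
    )[0]
    return float(slope_per_min) * 60.0 / saturation_intensity


@dataclass
class SaturationOrdering:
    """Half-saturation times (min) of the four canonical probe voxels."""

    t50_min: dict  # probe name -> time (min)

    _ORDER = ("corner", "edge", "face", "center")

    @property
    def ordered(self) -> bool:
        """True when corner < edge < face < center strictly."""
        vals = [self.t50_min[k] for k in self._ORDER if k in self.t50_min]
        return all(a < b for a, b in zip(vals, vals[1:]))


def _probe_indices(
    geometry: CrystalGeometry,
) -> dict:
    """Probe voxels: corner, edge midpoint, face centre, body centre.

    Probes sit on (or at the centre of) an exposed face so that sealed-face
    probes are never reported; with no exposed face the geometric positions
    on the first axis are used.
    """
    n = geometry.shape
    if geometry.exposed_faces:
        axis, side = _face_axis_side(geometry.exposed_faces[0])
    else:
        axis, side = 0, 0
    lo = [0, 0, 0]
    hi = [n[0] - 1, n[1] - 1, n[2] - 1]
    mid = [n[0] // 2, n[1] // 2, n[2] // 2]
    face_coord = lo[axis] if side == 0 else hi[axis]

    def on_face(rest: "list[int]") -> tuple[int, int, int]:
        idx = list(rest)
        idx.insert(axis, face_coord)
        return tuple(idx)

    others = [a for a in range(3) if a != axis]
    corner = on_face([lo[others[0]], lo[others[1]]])
    edge = on_face([lo[others[0]], mid[others[1]]])
    face = on_face([mid[others[0]], mid[others[1]]])
    center = (mid[0], mid[1], mid[2])
    return {"corner": corner, "edge": edge, "face": face, "center": center}


def saturation_ordering(
    fields: "list[ConcentrationField]",
    geometry: CrystalGeometry,
    threshold: float = 0.5,
) -> SaturationOrdering:
    """Half-saturation times of corner/edge/face-centre/body-centre probes.

    ``fields`` must be an uptake run sampled densely enough that every probe
    crosses ``threshold``; crossing times are linearly interpolated between
    snapshots.  A probe already above threshold in the first snapshot gets
    t50 = 0 (saturated input).
    """
    if len(fields) < 1:
        raise ValueError("need at least one field snapshot")
    probes = _probe_indices(geometry)
    times = np.array([f.time_min for f in fields])
    t50: dict = {}
    for name, idx in probes.items():
        series = np.array([float(f.occupancy[idx]) for f in fields])
        if series[0] >= threshold:
            t50[name] = 0.0
            continue
        above = np.nonzero(series >= threshold)[0]
        if above.size == 0:
            raise ValueError(
                f"probe {name!r} never reaches {threshold:.0%} occupancy"
            )
        j = int(above[0])
        t0, t1 = times[j - 1], times[j]
        c0, c1 = series[j - 1], series[j]
        t50[name] = float(t0 + (threshold - c0) / (c1 - c0) * (t1 - t0))
    return SaturationOrdering(t50_min=t50)


def release_to_uptake_ratio(constants: SensingConstants | None = None) -> float:
    """Ratio of the observed release duration to the full-infusion time."""
    constants = constants or SensingConstants.load()
    return constants.release_duration_min / constants.uptake_duration_min
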