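"""Readers and writers: frame stacks with CSV manifests, traces, results.

The manifest CSV (columns ``filename, time_min, pixel_size_um``) is the
single source of timing truth for a sequence — frame filenames carry no
semantics.  Traces round-trip through CSV at full float precision; results
are JSON with a provenance block (package version, seed, config hash) so any
output can be traced back to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .kinetics import DiffusionEstimate
from .pipeline import ImageFrame, ImageSequence, IntensityTrace

MANIFEST_COLUMNS = ("filename", "time_min", "pixel_size_um")


@dataclass
class Manifest:
    """Ordered record of the frames of one sequence."""

    entries: pd.DataFrame  # columns: filename, time_min, pixel_size_um
    root: Path

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.entries.columns)
        if missing:
            raise ValueError(f"manifest is missing columns {sorted(missing)}")
        times = self.entries["time_min"].to_numpy(dtype=float)
        if np.unique(times).size != times.size:
            raise ValueError("manifest contains duplicate timestamps")
        if self.entries["pixel_size_um"].nunique() != 1:
            raise ValueError("a sequence must have a single pixel size")
        if np.any(np.diff(times) < 0):
            warnings.warn(
                "manifest rows were not time-ordered; sorting by time_min",
                stacklevel=3,
            )
            self.entries = self.entries.sort_values("time_min").reset_index(
                drop=True
            )


def _write_image(path: Path, pixels: np.ndarray) -> None:
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def write_sequence(
    seq: ImageSequence, outdir: "str | Path", fmt: str = "png"
) -> Path:
    """Write frames plus ``manifest.csv``; returns the manifest path."""
    if fmt not in ("png", "tif", "tiff"):
        raise ValueError("fmt must be 'png', 'tif' or 'tiff'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, frame in enumerate(seq.frames):
        name = f"frame_{k:04d}.{fmt}"
        _write_image(outdir / name, frame.pixels)
        rows.append(
            {
                "filename": name,
                "time_min": frame.time_min,
                "pixel_size_um": frame.pixel_size_um,
            }
        )
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest_path, index=False
    )
    return manifest_path


def read_manifest(manifest_path: "str | Path") -> Manifest:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    return Manifest(entries=df, root=manifest_path.parent)


def read_sequence(manifest_path: "str | Path") -> ImageSequence:
    """Load a frame stack through its manifest, sorted by time."""
    manifest = read_manifest(manifest_path)
    frames = []
    px = float(manifest.entries["pixel_size_um"].iloc[0])
    for row in manifest.entries.itertuples(index=False):
        path = manifest.root / row.filename
        if not path.exists():
            raise FileNotFoundError(f"frame listed in manifest not found: {path}")
        frames.append(
            ImageFrame(
                _read_image(path), time_min=float(row.time_min),
                pixel_size_um=px,
            )
        )
    return ImageSequence(frames)


def write_trace(
    trace: IntensityTrace, path: "str | Path", settings: dict | None = None
) -> Path:
    """Write a trace as CSV (+ JSON sidecar with pipeline settings)."""
    if len(trace) == 0:
        raise ValueError("refusing to write an empty trace")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    trace.to_dataframe().to_csv(path, index=False)
    if settings is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(settings, indent=2, sort_keys=True))
    return path


def read_trace(path: "str | Path") -> IntensityTrace:
    return IntensityTrace.from_dataframe(pd.read_csv(path))


def config_hash(config: dict) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def provenance_block(
    seed: int | None = None, config: dict | None = None
) -> dict:
    from . import __version__

    block = {"artifact": "crystaldiff", "version": __version__}
    if seed is not None:
        block["seed"] = seed
    if config is not None:
        block["config_sha256"] = config_hash(config)
    return block


def write_results(
    results: "DiffusionEstimate | dict",
    path: "str | Path",
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """Write an estimate (or any result mapping) as JSON with provenance."""
    if isinstance(results, DiffusionEstimate):
        payload = results.to_dict()
    else:
        payload = dict(results)
    payload["provenance"] = provenance_block(seed=seed, config=config)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
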