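"""File formats and configuration.

Movies travel as multi-page TIFF, trajectories and curves as CSV with a
small ``# key = value`` metadata header, configuration as YAML, reports as
JSON. Numeric round-trips are exact for integers and to full float
precision (``%.17g``) for reals.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .tracking import Trajectory


@dataclass
class Movie:
    """An intensity time series with acquisition metadata.

    ``frames`` has shape (T, Y, X) for planar movies or (T, Z, Y, X) for
    volumetric ones. Pixel centres sit at ``(i + 0.5) * pixel_size_xy``.
    """

    frames: np.ndarray
    pixel_size_xy: float
    frame_interval: float
    voxel_size_z: Optional[float] = None
    channel_label: str = ""
    embryo_position_el: Optional[float] = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (T, Y, X) or (T, Z, Y, X)")
        if self.pixel_size_xy <= 0:
            raise ValueError("pixel_size_xy must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.frames.ndim == 4 and not self.voxel_size_z:
            raise ValueError("4-D movies need voxel_size_z")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def is_volumetric(self) -> bool:
        return self.frames.ndim == 4


def read_movie(path, metadata: Optional[dict] = None) -> Movie:
    """Read a TIFF stack into a :class:`Movie`.

    ``metadata`` supplies acquisition parameters absent from the TIFF
    tags: ``pixel_size_xy`` and ``frame_interval`` (required), optionally
    ``voxel_size_z`` and ``n_z``. When ``n_z`` is given, a stack of
    ``n_z * T`` planes is reshaped into a (T, Z, Y, X) volume series.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    metadata = dict(metadata or {})
    try:
        arr = tifffile.imread(path)
    except Exception as exc:  # includes truncated/empty files
        raise ValueError(f"unreadable stack: {path}") from exc
    if arr.size == 0:
        raise ValueError(f"unreadable stack: {path}")
    if arr.ndim == 2:
        arr = arr[None]
    n_z = metadata.pop("n_z", None)
    if n_z:
        if arr.ndim != 3 or arr.shape[0] % n_z:
            raise ValueError("plane count is not a multiple of n_z")
        arr = arr.reshape(arr.shape[0] // n_z, n_z, *arr.shape[1:])
    return Movie(frames=arr, **metadata)


def write_movie(movie: Movie, path) -> None:
    arr = movie.frames
    if movie.is_volumetric:
        arr = arr.reshape(-1, *arr.shape[2:])
    tifffile.imwrite(path, arr)


# ---------------------------------------------------------------------------
# trajectory CSV
# ---------------------------------------------------------------------------

def write_trajectories(trajectories: Sequence[Trajectory], path) -> None:
    """Write trajectories as CSV with a metadata header."""
    if not trajectories:
        raise ValueError("no trajectories to write")
    dt = trajectories[0].frame_interval
    exp = trajectories[0].exposure
    with open(path, "w") as fh:
        fh.write(f"# frame_interval = {dt!r}\n")
        fh.write(f"# exposure = {exp!r}\n")
        has_int = any(t.intensity is not None for t in trajectories)
        cols = "trajectory_id,frame,x,y" + (",intensity" if has_int else "")
        fh.write(cols + "\n")
        for t in trajectories:
            inten = (
                t.intensity
                if t.intensity is not None
                else np.zeros(len(t))
            )
            for i in range(len(t)):
                row = f"{t.id},{t.frames[i]},{t.xy[i, 0]:.17g},{t.xy[i, 1]:.17g}"
                if has_int:
                    row += f",{inten[i]:.17g}"
                fh.write(row + "\n")


def read_trajectories(path) -> list[Trajectory]:
    """Read a trajectory CSV written by :func:`write_trajectories`.

    Raises on duplicated (id, frame) rows; localizations are returned
    sorted by frame within each trajectory.
    """
    path = Path(path)
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = float(val.strip())
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, float_precision="round_trip")
    if df.duplicated(["trajectory_id", "frame"]).any():
        raise ValueError("duplicate (trajectory_id, frame) rows")
    dt = meta.get("frame_interval", 0.01)
    exp = meta.get("exposure", 0.0)
    out = []
    for tid, g in df.groupby("trajectory_id", sort=True):
        g = g.sort_values("frame")
        out.append(
            Trajectory(
                id=int(tid),
                frames=g["frame"].to_numpy(),
                xy=g[["x", "y"]].to_numpy(),
                frame_interval=dt,
                exposure=exp,
                intensity=(
                    g["intensity"].to_numpy() if "intensity" in g else None
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Named parameter blocks for every pipeline stage plus the RNG seed.

    Blocks are plain mappings; stages interpret their own block and fall
    back to module defaults for missing keys, so a partial config is
    valid. Serializes to/from YAML without loss.
    """

    rng_seed: int = 0
    paths: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    track: dict = field(default_factory=dict)
    kinetics: dict = field(default_factory=dict)
    residence: dict = field(default_factory=dict)
    msd: dict = field(default_factory=dict)
    hubs: dict = field(default_factory=dict)
    locus: dict = field(default_factory=dict)
    frap: dict = field(default_factory=dict)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def write_report(path, payload: dict, config: Optional[PipelineConfig] = None):
    """Write a JSON stage report, embedding config hash and seed."""
    out = dict(payload)
    if config is not None:
        out["_config_hash"] = config.config_hash()
        out["_seed"] = config.rng_seed
    Path(path).write_text(json.dumps(out, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
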