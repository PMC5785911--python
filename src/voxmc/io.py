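"""JSON configuration and raw binary volume/fluence readers and writers.

Binary conventions (fixed, documented):

* label volumes: raw unsigned 8-bit, x-fastest ordering, dimensions declared
  in the JSON config;
* fluence output: flat 32-bit floats, x-fastest ordering, with a JSON sidecar
  recording dimensions, pitch, photon count, the seed actually used, the
  normalization constant, and the conservation tallies.
"""

from __future__ import annotations

import json
import secrets
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .accumulate import FluenceVolume
from .scene import OpticalProperties, PencilSource, VoxelScene

__all__ = [
    "SimulationConfig",
    "read_volume",
    "write_volume",
    "read_fluence",
    "write_fluence",
    "parse_config",
    "serialize_config",
    "scene_from_config",
    "resolve_seed",
]


@dataclass
class SimulationConfig:
    """The simulation-parameter bundle accepted by the CLI."""

    nphoton: int
    seed: int | str = "auto"
    benchmark: str | None = None
    scene: dict | None = None  # explicit scene description (see scene_from_config)
    accumulation: str = "nonatomic"
    workers: int | str = 1
    strategy: str = "S3"
    devices: str | None = None
    output_prefix: str = "voxmc_out"

    def __post_init__(self) -> None:
        if self.nphoton < 1:
            raise ValueError("nphoton must be >= 1")
        if (self.benchmark is None) == (self.scene is None):
            raise ValueError("exactly one of benchmark or scene must be given")
        if self.accumulation not in ("atomic", "nonatomic"):
            raise ValueError(f"unknown accumulation mode {self.accumulation!r}")
        if self.strategy not in ("S1", "S2", "S3"):
            raise ValueError(f"unknown strategy {self.strategy!r}")


def parse_config(data: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a parsed JSON mapping."""
    known = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(**data)


def serialize_config(config: SimulationConfig) -> dict:
    """Inverse of :func:`parse_config`; round-trips exactly."""
    out = asdict(config)
    return {k: v for k, v in out.items() if v is not None}


def resolve_seed(seed: int | str) -> int:
    """Resolve the ``--seed`` flag; ``"auto"`` draws from system entropy."""
    if seed == "auto":
        return secrets.randbits(63)
    return int(seed)


def read_volume(path, dims) -> np.ndarray:
    """Read a raw uint8 label volume in x-fastest order."""
    dims = tuple(int(d) for d in dims)
    expected = int(np.prod(dims))
    raw = Path(path).read_bytes()
    if len(raw) != expected:
        raise ValueError(
            f"{path}: file has {len(raw)} bytes but dims {dims} need {expected}")
    flat = np.frombuffer(raw, dtype=np.uint8)
    return flat.reshape(dims, order="F").copy()


def write_volume(labels: np.ndarray, path) -> None:
    """Write a uint8 label volume in x-fastest order."""
    np.asarray(labels, dtype=np.uint8).flatten(order="F").tofile(path)


def read_fluence(path, dims) -> np.ndarray:
    """Read a raw float32 fluence volume in x-fastest order (as float64)."""
    dims = tuple(int(d) for d in dims)
    expected = int(np.prod(dims)) * 4
    raw = Path(path).read_bytes()
    if len(raw) != expected:
        raise ValueError(
            f"{path}: file has {len(raw)} bytes but dims {dims} need {expected}")
    flat = np.frombuffer(raw, dtype=np.float32)
    return flat.reshape(dims, order="F").astype(np.float64)


def write_fluence(volume: FluenceVolume, path) -> None:
    """Write a fluence volume as flat float32 in x-fastest order."""
    volume.values.astype(np.float32).flatten(order="F").tofile(path)


def scene_from_config(cfg: dict, base_dir: Path | None = None
                      ) -> tuple[VoxelScene, PencilSource]:
    """Build a scene from the explicit JSON schema.

    Schema::

        {"dim": [nx, ny, nz], "pitch_mm": float,
         "media": [{"mua": .., "mus": .., "g": .., "n": ..}, ...],
         "boundary": "terminate" | "reflect",
         "source": {"pos": [x, y, z], "dir": [dx, dy, dz]},
         "volume_file": "labels.bin"}   # optional; defaults to all label 1

    ``media[k]`` describes label ``k + 1`` (label 0 is exterior air).
    """
    dims = cfg["dim"]
    pitch = float(cfg["pitch_mm"])
    if cfg.get("volume_file"):
        vpath = Path(cfg["volume_file"])
        if base_dir is not None and not vpath.is_absolute():
            vpath = base_dir / vpath
        labels = read_volume(vpath, dims)
    else:
        labels = np.ones(tuple(int(d) for d in dims), dtype=np.uint8)
    props = {
        k + 1: OpticalProperties(mua=m["mua"], mus=m["mus"], g=m["g"], n=m["n"])
        for k, m in enumerate(cfg["media"])
    }
    scene = VoxelScene(labels=labels, pitch=pitch, props=props,
                       boundary_mode=cfg.get("boundary", "terminate"))
    src = cfg["source"]
    source = PencilSource(position=src["pos"], direction=src["dir"])
    return scene, source


def write_sidecar(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
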