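"""Fluence accumulation: per-worker deposit volumes, merging, normalization.

Two accumulation contracts exist: ``atomic`` guarantees no lost updates under
concurrent workers, ``nonatomic`` does not.  In this artifact concurrency is
realized by a private volume per worker reduced at the end, which makes both
modes race-free; the mode flag is preserved for interface compatibility and
recorded in output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FluenceVolume", "deposit", "merge", "normalize"]

ACCUMULATION_MODES = ("atomic", "nonatomic")


@dataclass
class FluenceVolume:
    """A 3-D accumulator grid aligned with a :class:`~voxmc.scene.VoxelScene`.

    ``kind`` is ``"raw"`` (dimensionless deposited weight) until
    :func:`normalize` converts it to ``"fluence"`` (per launched photon,
    1/mm^2).
    """

    values: np.ndarray
    kind: str = "raw"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D grid")
        if self.kind not in ("raw", "fluence"):
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def total(self) -> float:
        return float(self.values.sum())


def deposit(volume: FluenceVolume, voxel, amount: float,
            mode: str = "nonatomic") -> FluenceVolume:
    """Add ``amount`` of absorbed weight into one voxel.

    Both modes behave identically here (single-writer volumes); see module
    docstring.
    """
    if mode not in ACCUMULATION_MODES:
        raise ValueError(f"unknown accumulation mode {mode!r}")
    if amount < 0:
        raise ValueError("deposit amount must be >= 0")
    ix, iy, iz = voxel
    shape = volume.values.shape
    if not (0 <= ix < shape[0] and 0 <= iy < shape[1] and 0 <= iz < shape[2]):
        raise IndexError(f"voxel {voxel} outside grid of shape {shape}")
    volume.values[ix, iy, iz] += amount
    return volume


def merge(volumes: list[FluenceVolume], mode: str = "nonatomic") -> FluenceVolume:
    """Reduce per-worker volumes into one; total equals the sum of parts."""
    if mode not in ACCUMULATION_MODES:
        raise ValueError(f"unknown accumulation mode {mode!r}")
    if not volumes:
        raise ValueError("nothing to merge")
    out = np.zeros_like(volumes[0].values)
    for v in volumes:
        if v.values.shape != out.shape:
            raise ValueError("worker volumes have mismatched shapes")
        if v.kind != "raw":
            raise ValueError("only raw volumes can be merged")
        out += v.values
    return FluenceVolume(values=out, kind="raw",
                         metadata={"accumulation_mode": mode,
                                   "workers": len(volumes)})


def normalize(volume: FluenceVolume, scene, launched_weight: float) -> FluenceVolume:
    """Convert raw deposited weight to fluence per launched photon (1/mm^2).

    Per voxel: ``fluence = deposited / (mua * pitch^3 * launched_weight)``.
    Voxels whose medium has ``mua == 0`` cannot be estimated from absorbed
    energy; they are set to 0 and flagged in the metadata.
    """
    if launched_weight <= 0:
        raise ValueError("launched_weight must be > 0")
    if volume.kind != "raw":
        raise ValueError("volume is already normalized")
    mua_t, _, _, _ = scene.property_tables()
    mua_map = mua_t[scene.labels]
    out = np.zeros_like(volume.values)
    ok = mua_map > 0
    out[ok] = volume.values[ok] / (mua_map[ok] * scene.pitch**3 * launched_weight)
    meta = dict(volume.metadata)
    meta.update(
        normalization="deposited / (mua * pitch^3 * launched_weight)",
        launched_weight=float(launched_weight),
        pitch_mm=float(scene.pitch),
        zero_mua_voxels=int(np.count_nonzero(~ok)),
    )
    return FluenceVolume(values=out, kind="fluence", metadata=meta)
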