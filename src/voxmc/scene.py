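"""Voxelized simulation domains, optical media, sources, and benchmark scenes.

Conventions
-----------
* Voxel indices are 0-based; voxel ``i`` spans the half-open interval
  ``[i * pitch, (i + 1) * pitch)`` on each axis, grid origin at (0, 0, 0).
* Label arrays are indexed ``labels[x, y, z]``.
* Label 0 is the exterior (air, n = 1.0); it never appears inside a scene's
  label grid — positions outside the grid map to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EXTERIOR",
    "OpticalProperties",
    "VoxelScene",
    "PencilSource",
    "IsotropicPointSource",
    "make_benchmark",
    "label_at",
]

#: Sentinel label for positions outside the voxel grid (ambient air).
EXTERIOR = 0

#: Optical properties of the ambient air surrounding every scene.
AIR_N = 1.0


@dataclass(frozen=True)
class OpticalProperties:
    """Optical properties of one medium.

    Parameters
    ----------
    mua : float
        Absorption coefficient, 1/mm (>= 0).
    mus : float
        Scattering coefficient, 1/mm (>= 0).
    g : float
        Scattering anisotropy (mean cosine), |g| < 1.
    n : float
        Refractive index, >= 1 (1.0 allowed: clear media / air).
    """

    mua: float
    mus: float
    g: float
    n: float

    def __post_init__(self) -> None:
        if self.mua < 0:
            raise ValueError(f"mua must be >= 0, got {self.mua}")
        if self.mus < 0:
            raise ValueError(f"mus must be >= 0, got {self.mus}")
        if abs(self.g) >= 1:
            raise ValueError(f"|g| must be < 1, got {self.g}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")


@dataclass
class VoxelScene:
    """A 3-D labeled voxel grid plus per-label optical properties.

    Attributes
    ----------
    labels : ndarray of uint8, shape (nx, ny, nz)
        Media labels; every nonzero label present must have an entry in
        ``props``.
    pitch : float
        Voxel edge length in mm (> 0).
    props : dict[int, OpticalProperties]
        Label -> optical properties.  Label 0 (exterior) is implicit air and
        need not be listed.
    boundary_mode : {"terminate", "reflect"}
        ``terminate``: photons die with their full weight tallied as escaped
        the moment they reach the labeled region's surface.  ``reflect``:
        Fresnel reflection/refraction is evaluated at every refractive-index
        mismatch, including the outer surface against air.
    """

    labels: np.ndarray
    pitch: float
    props: dict[int, OpticalProperties]
    boundary_mode: str = "terminate"

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)
        if self.labels.ndim != 3 or min(self.labels.shape) < 1:
            raise ValueError("labels must be a 3-D grid with every axis >= 1")
        if self.pitch <= 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")
        if self.boundary_mode not in ("terminate", "reflect"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        present = set(np.unique(self.labels).tolist()) - {EXTERIOR}
        missing = present - set(self.props)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no optical properties")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid along each axis, mm."""
        nx, ny, nz = self.labels.shape
        return (nx * self.pitch, ny * self.pitch, nz * self.pitch)

    def property_tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Dense (mua, mus, g, n) arrays indexed by label, for the kernel.

        Index 0 holds exterior air (mua=mus=0, g=0, n=1).
        """
        nlab = int(self.labels.max()) + 1
        mua = np.zeros(nlab)
        mus = np.zeros(nlab)
        g = np.zeros(nlab)
        n = np.full(nlab, AIR_N)
        for lab, p in self.props.items():
            if lab == EXTERIOR or lab >= nlab:
                continue
            mua[lab], mus[lab], g[lab], n[lab] = p.mua, p.mus, p.g, p.n
        return mua, mus, g, n


def _unit(v: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError("direction must be a 3-vector")
    norm = float(np.linalg.norm(v))
    if abs(norm - 1.0) > tol:
        raise ValueError(f"direction must be unit length (|v| = {norm})")
    return v / norm


@dataclass
class PencilSource:
    """Zero-width collimated beam entering at one point and direction."""

    position: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        self.direction = _unit(self.direction)


@dataclass
class IsotropicPointSource:
    """Interior point source emitting uniformly over 4*pi steradians.

    Used by the diffusion-theory validation; not part of the benchmark set.
    """

    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")


# Printed benchmark parameters: 60 mm cube of (mua=0.005, mus=1.0, g=0.01,
# n=1.37); B2/B2a add a 15 mm radius sphere of (0.002, 5.0, 0.9, 1.0) at the
# cube center; pencil beam enters at (30, 30, 0) along +z.
_DOMAIN_MM = 60.0
_CUBE_MEDIUM = OpticalProperties(mua=0.005, mus=1.0, g=0.01, n=1.37)
_SPHERE_MEDIUM = OpticalProperties(mua=0.002, mus=5.0, g=0.9, n=1.0)
_SPHERE_RADIUS_MM = 15.0
_SPHERE_CENTER_MM = (30.0, 30.0, 30.0)

BENCHMARK_NAMES = ("B1", "B2", "B2a")

#: Accumulation mode each benchmark requests (identical physics for B2/B2a).
BENCHMARK_ACCUMULATION = {"B1": "nonatomic", "B2": "nonatomic", "B2a": "atomic"}


def make_benchmark(name: str, pitch: float = 1.0) -> tuple[VoxelScene, PencilSource]:
    """Build one of the three benchmark scenes.

    B1 is a homogeneous 60 mm cube with terminating boundaries.  B2 and B2a
    add a centered 15 mm-radius spherical inclusion and use Fresnel
    reflection at every refractive-index mismatch; they differ only in the
    accumulation mode they request (see :data:`BENCHMARK_ACCUMULATION`).
    A voxel belongs to the sphere iff its center lies within the radius.

    Parameters
    ----------
    name : {"B1", "B2", "B2a"}
    pitch : float
        Voxel edge length in mm; must divide the 60 mm domain evenly.

    Returns
    -------
    (VoxelScene, PencilSource)
    """
    if name not in BENCHMARK_NAMES:
        raise ValueError(f"unknown benchmark {name!r}; expected one of {BENCHMARK_NAMES}")
    if pitch <= 0:
        raise ValueError(f"pitch must be > 0, got {pitch}")
    nvox = _DOMAIN_MM / pitch
    if abs(nvox - round(nvox)) > 1e-9:
        raise ValueError(f"pitch {pitch} mm does not divide the {_DOMAIN_MM} mm domain evenly")
    nvox = int(round(nvox))

    labels = np.ones((nvox, nvox, nvox), dtype=np.uint8)
    props = {1: _CUBE_MEDIUM}
    boundary_mode = "terminate"

    if name in ("B2", "B2a"):
        centers = (np.arange(nvox) + 0.5) * pitch
        cx, cy, cz = _SPHERE_CENTER_MM
        dx2 = (centers - cx) ** 2
        dy2 = (centers - cy) ** 2
        dz2 = (centers - cz) ** 2
        r2 = dx2[:, None, None] + dy2[None, :, None] + dz2[None, None, :]
        labels[r2 <= _SPHERE_RADIUS_MM**2] = 2
        props[2] = _SPHERE_MEDIUM
        boundary_mode = "reflect"

    scene = VoxelScene(labels=labels, pitch=pitch, props=props, boundary_mode=boundary_mode)
    source = PencilSource(position=(30.0, 30.0, 0.0), direction=(0.0, 0.0, 1.0))
    return scene, source


def label_at(scene: VoxelScene, position) -> int:
    """Map a continuous position (mm) to its voxel's label.

    Voxel membership uses floor(position / pitch) with half-open voxel
    extents; any position outside the grid returns :data:`EXTERIOR`.
    """
    pos = np.asarray(position, dtype=float)
    idx = np.floor(pos / scene.pitch).astype(np.int64)
    if np.any(idx < 0) or np.any(idx >= np.asarray(scene.labels.shape)):
        return EXTERIOR
    return int(scene.labels[idx[0], idx[1], idx[2]])
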