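"""The photon simulation loop: launch, hop, drop, spin, reflect, terminate.

The bulk path is a numba-compiled kernel (:func:`_simulate_kernel`) that
marches photons voxel by voxel: each sub-step advances by the minimum of the
remaining physical scattering path and the exact distance to the nearest
axis-aligned voxel face, deposits ``w * (1 - exp(-mua * d))`` in the current
voxel, and then either crosses the face (with Fresnel physics when the scene
reflects) or scatters via Henyey-Greenstein sampling.  Low-weight photons are
terminated unbiasedly by Russian roulette.

Scalar physics primitives (HG cosine, direction rotation, Fresnel
reflectance) are shared between the kernel and the single-photon Python API
so unit tests exercise exactly the compiled code paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numba as nb
import numpy as np

from . import scheduler
from .accumulate import FluenceVolume, merge
from .rng import RandomStream, next_uniform
from .scene import (
    EXTERIOR,
    IsotropicPointSource,
    PencilSource,
    VoxelScene,
)

__all__ = [
    "PhotonState",
    "RunResult",
    "launch",
    "sample_scat_length",
    "step",
    "scatter",
    "fresnel_interact",
    "fresnel_reflectance",
    "hg_cos_theta",
    "roulette",
    "run",
    "DEFAULT_ROULETTE_THRESHOLD",
    "DEFAULT_SURVIVE_P",
]

#: Russian-roulette defaults (configurable; standard variance-preserving
#: termination values).
DEFAULT_ROULETTE_THRESHOLD = 1e-4
DEFAULT_SURVIVE_P = 0.1

_LAUNCH_NUDGE = 1e-9  # entry nudge, in units of pitch


# ---------------------------------------------------------------------------
# jitted scalar physics (shared by kernel and Python API)
# ---------------------------------------------------------------------------


@nb.njit(nb.float64(nb.float64, nb.float64), cache=True)
def hg_cos_theta(g, u1):
    """Sample the Henyey-Greenstein scattering cosine.

    ``cos(theta) = (1 + g^2 - ((1 - g^2) / (1 - g + 2 g u1))^2) / (2 g)``
    for g != 0; isotropic ``2 u1 - 1`` otherwise.
    """
    if g == 0.0:
        return 2.0 * u1 - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
    ct = (1.0 + g * g - frac * frac) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@nb.njit(nb.types.UniTuple(nb.float64, 3)(
    nb.float64, nb.float64, nb.float64, nb.float64, nb.float64), cache=True)
def rotate_direction(dx, dy, dz, cos_t, phi):
    """Rotate a unit direction by polar angle theta and azimuth phi.

    Standard local-frame rotation with the |dz| ~ 1 degenerate branch.
    """
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p = math.cos(phi)
    sin_p = math.sin(phi)
    if abs(dz) > 0.99999:
        ndx = sin_t * cos_p
        ndy = sin_t * sin_p
        ndz = cos_t if dz >= 0.0 else -cos_t
    else:
        tmp = math.sqrt(1.0 - dz * dz)
        ndx = sin_t * (dx * dz * cos_p - dy * sin_p) / tmp + dx * cos_t
        ndy = sin_t * (dy * dz * cos_p + dx * sin_p) / tmp + dy * cos_t
        ndz = -sin_t * cos_p * tmp + dz * cos_t
    # guard against drift over millions of rotations
    norm = math.sqrt(ndx * ndx + ndy * ndy + ndz * ndz)
    return ndx / norm, ndy / norm, ndz / norm


@nb.njit(nb.float64(nb.float64, nb.float64, nb.float64), cache=True)
def fresnel_reflectance(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance for incidence cosine ``cos_i``.

    Returns 1.0 beyond the critical angle (total internal reflection).
    """
    if n1 == n2:
        return 0.0
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n1 / n2) * (n1 / n2) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


# ---------------------------------------------------------------------------
# bulk transport kernel
# ---------------------------------------------------------------------------


@nb.njit(cache=True)
def _simulate_kernel(labels, mua_t, mus_t, g_t, n_t, pitch,
                     sx, sy, sz, sdx, sdy, sdz, isotropic,
                     reflect_mode, nphoton, rstate, vol,
                     roulette_threshold, survive_p):
    """Transport ``nphoton`` photons; deposit into ``vol`` (same shape as labels).

    Returns (absorbed, escaped, roulette_killed, roulette_boosted).
    """
    nx, ny, nz = labels.shape
    absorbed = 0.0
    escaped = 0.0
    rkilled = 0.0
    rboosted = 0.0
    eps = _LAUNCH_NUDGE * pitch

    for _ in range(nphoton):
        # --- launch ---
        if isotropic:
            ct = 2.0 * next_uniform(rstate) - 1.0
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi0 = 2.0 * math.pi * next_uniform(rstate)
            dx = st * math.cos(phi0)
            dy = st * math.sin(phi0)
            dz = ct
        else:
            dx, dy, dz = sdx, sdy, sdz
        px = sx + eps * dx
        py = sy + eps * dy
        pz = sz + eps * dz
        ix = int(math.floor(px / pitch))
        iy = int(math.floor(py / pitch))
        iz = int(math.floor(pz / pitch))
        w = 1.0
        s = -math.log(next_uniform(rstate))  # dimensionless scattering length
        alive = True

        while alive:
            lab = labels[ix, iy, iz]
            mua = mua_t[lab]
            mus = mus_t[lab]

            # exact distance to the nearest voxel face along the direction
            if dx > 0.0:
                tx = ((ix + 1) * pitch - px) / dx
            elif dx < 0.0:
                tx = (ix * pitch - px) / dx
            else:
                tx = np.inf
            if dy > 0.0:
                ty = ((iy + 1) * pitch - py) / dy
            elif dy < 0.0:
                ty = (iy * pitch - py) / dy
            else:
                ty = np.inf
            if dz > 0.0:
                tz = ((iz + 1) * pitch - pz) / dz
            elif dz < 0.0:
                tz = (iz * pitch - pz) / dz
            else:
                tz = np.inf

            if tx <= ty and tx <= tz:
                db = tx
                axis = 0
            elif ty <= tz:
                db = ty
                axis = 1
            else:
                db = tz
                axis = 2
            if db < 0.0:
                db = 0.0

            ds = s / mus if mus > 0.0 else np.inf

            # ties resolve to the boundary crossing (deterministic ordering)
            hit = db <= ds
            d = db if hit else ds

            if mua > 0.0 and d > 0.0:
                att = math.exp(-mua * d)
                dep = w * (1.0 - att)
                vol[ix, iy, iz] += dep
                absorbed += dep
                w *= att
            s -= mus * d
            if s < 0.0:
                s = 0.0

            px += dx * d
            py += dy * d
            pz += dz * d

            if hit:
                # snap onto the crossed plane and identify the next voxel
                if axis == 0:
                    if dx > 0.0:
                        nix, niy, niz = ix + 1, iy, iz
                        px = nix * pitch
                    else:
                        nix, niy, niz = ix - 1, iy, iz
                        px = ix * pitch
                elif axis == 1:
                    if dy > 0.0:
                        nix, niy, niz = ix, iy + 1, iz
                        py = niy * pitch
                    else:
                        nix, niy, niz = ix, iy - 1, iz
                        py = iy * pitch
                else:
                    if dz > 0.0:
                        nix, niy, niz = ix, iy, iz + 1
                        pz = niz * pitch
                    else:
                        nix, niy, niz = ix, iy, iz - 1
                        pz = iz * pitch

                outside = (nix < 0 or nix >= nx or niy < 0 or niy >= ny
                           or niz < 0 or niz >= nz)
                next_lab = 0 if outside else labels[nix, niy, niz]
                exits = outside or next_lab == EXTERIOR

                if not reflect_mode:
                    if exits:
                        escaped += w
                        alive = False
                    else:
                        ix, iy, iz = nix, niy, niz
                    continue

                n1 = n_t[lab]
                n2 = 1.0 if exits else n_t[next_lab]
                if n1 != n2:
                    if axis == 0:
                        cos_i = abs(dx)
                    elif axis == 1:
                        cos_i = abs(dy)
                    else:
                        cos_i = abs(dz)
                    refl = fresnel_reflectance(n1, n2, cos_i)
                    do_reflect = True
                    if refl < 1.0:
                        do_reflect = next_uniform(rstate) <= refl
                    if do_reflect:
                        # mirror the normal component; stay in this voxel
                        if axis == 0:
                            dx = -dx
                        elif axis == 1:
                            dy = -dy
                        else:
                            dz = -dz
                        continue
                    # refract: rescale tangentials by n1/n2, recompute normal
                    ratio = n1 / n2
                    cos_t = math.sqrt(max(0.0, 1.0 - ratio * ratio * (1.0 - cos_i * cos_i)))
                    if axis == 0:
                        dy *= ratio
                        dz *= ratio
                        dx = cos_t if dx > 0.0 else -cos_t
                    elif axis == 1:
                        dx *= ratio
                        dz *= ratio
                        dy = cos_t if dy > 0.0 else -cos_t
                    else:
                        dx *= ratio
                        dy *= ratio
                        dz = cos_t if dz > 0.0 else -cos_t

                if exits:
                    escaped += w
                    alive = False
                else:
                    ix, iy, iz = nix, niy, niz
                continue

            # --- scattering event ---
            g = g_t[lab]
            u1 = next_uniform(rstate)
            u2 = next_uniform(rstate)
            ct = hg_cos_theta(g, u1)
            phi = 2.0 * math.pi * u2
            dx, dy, dz = rotate_direction(dx, dy, dz, ct, phi)
            s = -math.log(next_uniform(rstate))

            # --- Russian roulette ---
            if w < roulette_threshold:
                if next_uniform(rstate) < survive_p:
                    boosted = w / survive_p
                    rboosted += boosted - w
                    w = boosted
                else:
                    rkilled += w
                    alive = False

    return absorbed, escaped, rkilled, rboosted


# ---------------------------------------------------------------------------
# Python-level photon state and single-photon operations
# ---------------------------------------------------------------------------


@dataclass
class PhotonState:
    """One photon: the unit of work of the transport loop."""

    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0
    remaining_scat: float = 0.0  # dimensionless, units of mean free paths
    pathlength: float = 0.0  # mm
    alive: bool = True

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)


@dataclass
class RunResult:
    """Aggregated outcome of a transport run."""

    deposited: FluenceVolume
    escaped_weight: float
    absorbed_weight: float
    roulette_killed_weight: float
    roulette_boosted_weight: float
    launched: int
    launched_weight: float
    seed: int = 0
    workers: int = 1
    accumulation_mode: str = "nonatomic"

    @property
    def conservation_residual(self) -> float:
        """Signed relative residual of the energy-conservation identity."""
        if self.launched_weight == 0:
            return 0.0
        net = (self.absorbed_weight + self.escaped_weight
               + self.roulette_killed_weight - self.roulette_boosted_weight)
        return (self.launched_weight - net) / self.launched_weight


def launch(source: PencilSource, rng: RandomStream,
           pitch: float = 1.0) -> PhotonState:
    """Launch one photon from a pencil source.

    The entry position is nudged by ``1e-9 * pitch`` along the beam so the
    photon starts strictly inside its entry voxel; the remaining scattering
    length is sampled fresh.
    """
    d = source.direction
    pos = source.position + _LAUNCH_NUDGE * pitch * d
    s = sample_scat_length(next_uniform(rng.state))
    return PhotonState(position=pos, direction=d.copy(), weight=1.0,
                       remaining_scat=s)


def sample_scat_length(u: float) -> float:
    """Dimensionless scattering length ``-ln(u)`` for a uniform ``u`` in (0,1]."""
    if not 0.0 < u <= 1.0:
        raise ValueError(f"u must be in (0, 1], got {u}")
    return -math.log(u)


def scatter(photon: PhotonState, g: float, u1: float, u2: float) -> PhotonState:
    """Redirect a photon by one Henyey-Greenstein scattering event.

    The remaining scattering length is left for the caller to resample via
    :func:`sample_scat_length`.
    """
    if abs(g) >= 1:
        raise ValueError(f"|g| must be < 1, got {g}")
    ct = hg_cos_theta(g, u1)
    phi = 2.0 * math.pi * u2
    dx, dy, dz = rotate_direction(*photon.direction, ct, phi)
    photon.direction = np.array([dx, dy, dz])
    return photon


def fresnel_interact(photon: PhotonState, n1: float, n2: float,
                     surface_normal, u: float) -> PhotonState:
    """Reflect or refract a photon at a refractive-index mismatch.

    Beyond the critical angle the photon always mirrors (total internal
    reflection); otherwise it reflects with probability equal to the
    unpolarized Fresnel reflectance (``u <= R``) and refracts with the
    tangential component rescaled by ``n1/n2`` otherwise.
    """
    normal = np.asarray(surface_normal, dtype=float)
    if abs(np.linalg.norm(normal) - 1.0) > 1e-9:
        raise ValueError("surface normal must be a unit vector")
    d = photon.direction
    cos_i = abs(float(np.dot(d, normal)))
    refl = fresnel_reflectance(n1, n2, cos_i)
    if refl >= 1.0 or u <= refl:
        photon.direction = d - 2.0 * np.dot(d, normal) * normal
    else:
        ratio = n1 / n2
        cos_t = math.sqrt(max(0.0, 1.0 - ratio * ratio * (1.0 - cos_i * cos_i)))
        sign = 1.0 if np.dot(d, normal) > 0 else -1.0
        tangential = d - np.dot(d, normal) * normal
        photon.direction = ratio * tangential + sign * cos_t * normal
    return photon


def roulette(photon: PhotonState, u: float,
             threshold: float = DEFAULT_ROULETTE_THRESHOLD,
             survive_p: float = DEFAULT_SURVIVE_P) -> PhotonState:
    """Unbiased stochastic termination of low-weight photons."""
    if not 0.0 < survive_p <= 1.0:
        raise ValueError(f"survive_p must be in (0, 1], got {survive_p}")
    if photon.weight >= threshold:
        return photon
    if u < survive_p:
        photon.weight /= survive_p
    else:
        photon.weight = 0.0
        photon.alive = False
    return photon


def step(photon: PhotonState, scene: VoxelScene,
         rng: RandomStream | None = None) -> tuple[PhotonState, dict]:
    """Advance one photon by a single sub-step (Python reference path).

    Moves by ``min(remaining physical scattering path, distance to nearest
    voxel face)``, deposits ``w (1 - exp(-mua d))`` in the current voxel, and
    handles the resulting boundary crossing, Fresnel interaction, scattering
    event, or escape.  Returns the photon and an event record with keys
    ``type`` ("boundary" | "scatter" | "escape"), ``deposit``, ``voxel``,
    ``d`` and, for escapes, ``escaped``.

    ``rng`` is needed only when a Fresnel decision or a scatter resample can
    occur.
    """
    if not photon.alive:
        raise ValueError("photon is dead")
    d_vec = photon.direction
    if np.allclose(d_vec, 0):
        raise ValueError("zero direction vector")
    if np.any(np.isnan(photon.position)):
        raise ValueError("NaN position")

    pitch = scene.pitch
    idx = np.floor(photon.position / pitch).astype(np.int64)
    shape = np.asarray(scene.labels.shape)
    if np.any(idx < 0) or np.any(idx >= shape):
        raise ValueError("photon is outside the grid")
    lab = int(scene.labels[idx[0], idx[1], idx[2]])
    props = scene.props[lab]

    # distance to the nearest voxel face along the direction
    t = np.full(3, np.inf)
    for k in range(3):
        if d_vec[k] > 0:
            t[k] = ((idx[k] + 1) * pitch - photon.position[k]) / d_vec[k]
        elif d_vec[k] < 0:
            t[k] = (idx[k] * pitch - photon.position[k]) / d_vec[k]
    axis = int(np.argmin(t))
    db = max(float(t[axis]), 0.0)
    ds = photon.remaining_scat / props.mus if props.mus > 0 else np.inf
    hit = db <= ds
    d = db if hit else ds

    att = math.exp(-props.mua * d)
    dep = photon.weight * (1.0 - att)
    photon.weight *= att
    photon.remaining_scat = max(photon.remaining_scat - props.mus * d, 0.0)
    photon.pathlength += d
    photon.position = photon.position + d_vec * d
    event: dict = {"type": "boundary", "deposit": dep,
                   "voxel": tuple(int(i) for i in idx), "d": d}

    if not hit:
        event["type"] = "scatter"
        if rng is not None:
            u1, u2 = rng.uniform(2)
            scatter(photon, props.g, u1, u2)
            photon.remaining_scat = sample_scat_length(next_uniform(rng.state))
        return photon, event

    nidx = idx.copy()
    nidx[axis] += 1 if d_vec[axis] > 0 else -1
    # snap exactly onto the crossed plane
    photon.position[axis] = (idx[axis] + (1 if d_vec[axis] > 0 else 0)) * pitch
    outside = nidx[axis] < 0 or nidx[axis] >= shape[axis]
    next_lab = EXTERIOR if outside else int(scene.labels[nidx[0], nidx[1], nidx[2]])
    exits = outside or next_lab == EXTERIOR

    if scene.boundary_mode == "terminate":
        if exits:
            event.update(type="escape", escaped=photon.weight)
            photon.alive = False
        return photon, event

    n1 = props.n
    n2 = 1.0 if exits else scene.props[next_lab].n
    if n1 != n2:
        normal = np.zeros(3)
        normal[axis] = 1.0
        before = d_vec[axis]
        u = next_uniform(rng.state) if rng is not None else 1.0
        fresnel_interact(photon, n1, n2, normal, u)
        if photon.direction[axis] * before < 0:  # reflected: stays
            return photon, event
    if exits:
        event.update(type="escape", escaped=photon.weight)
        photon.alive = False
    return photon, event


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run(scene: VoxelScene, source, nphoton: int, seed: int = 0,
        workers: int = 1, accumulation_mode: str = "nonatomic",
        roulette_threshold: float = DEFAULT_ROULETTE_THRESHOLD,
        survive_p: float = DEFAULT_SURVIVE_P) -> RunResult:
    """Simulate ``nphoton`` photons and return merged raw deposits.

    Photons are partitioned across ``workers`` logical workers (equal-core
    static split via the scheduler), each with its own random stream
    ``(seed, worker_index)`` and a private deposit volume; volumes are merged
    at the end, which makes both accumulation modes race-free.  With
    ``workers=1`` and a fixed seed the output is bit-reproducible.
    """
    if nphoton < 1:
        raise ValueError("nphoton must be >= 1")
    if workers < 1:
        raise ValueError("workers must be >= 1")
    if accumulation_mode not in ("atomic", "nonatomic"):
        raise ValueError(f"unknown accumulation mode {accumulation_mode!r}")

    if isinstance(source, IsotropicPointSource):
        isotropic = True
        spos = source.position
        sdir = np.array([0.0, 0.0, 1.0])
    elif isinstance(source, PencilSource):
        isotropic = False
        spos = source.position
        sdir = source.direction
        probe = spos + _LAUNCH_NUDGE * scene.pitch * sdir
        idx = np.floor(probe / scene.pitch).astype(np.int64)
        if (np.any(idx < 0) or np.any(idx >= np.asarray(scene.labels.shape))
                or scene.labels[idx[0], idx[1], idx[2]] == EXTERIOR):
            raise ValueError("source does not enter the labeled domain")
    else:
        raise TypeError(f"unsupported source type {type(source).__name__}")

    unit = scheduler.DeviceProfile(name="worker", cores=1,
                                   max_threads_per_cu=1, num_cus=1,
                                   a=1.0, T0=0.0)
    alloc = scheduler.partition(nphoton, [unit] * workers, "S1").allocations
    counts = [alloc[i] for i in range(workers)]

    mua_t, mus_t, g_t, n_t = scene.property_tables()
    reflect_mode = scene.boundary_mode == "reflect"

    volumes = []
    absorbed = escaped = rkilled = rboosted = 0.0
    for wid, count in enumerate(counts):
        vol = np.zeros(scene.labels.shape, dtype=np.float64)
        if count > 0:
            stream = RandomStream(seed, wid)
            a, e, k, b = _simulate_kernel(
                scene.labels, mua_t, mus_t, g_t, n_t, scene.pitch,
                spos[0], spos[1], spos[2], sdir[0], sdir[1], sdir[2],
                isotropic, reflect_mode, count, stream.state, vol,
                roulette_threshold, survive_p)
            absorbed += a
            escaped += e
            rkilled += k
            rboosted += b
        volumes.append(FluenceVolume(values=vol, kind="raw"))

    deposited = merge(volumes, mode=accumulation_mode)
    return RunResult(
        deposited=deposited,
        escaped_weight=escaped,
        absorbed_weight=absorbed,
        roulette_killed_weight=rkilled,
        roulette_boosted_weight=rboosted,
        launched=nphoton,
        launched_weight=float(nphoton),
        seed=seed,
        workers=workers,
        accumulation_mode=accumulation_mode,
    )
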