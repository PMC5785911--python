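"""Analytical and statistical oracles: diffusion theory, Fresnel closed forms,
Henyey-Greenstein moments, conservation audits.

These are deliberately written independently of the transport kernel (angle-
based Fresnel formulation, closed-form diffusion Green's function) so the
test suite can cross-check the two routes against each other.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiffusionParams",
    "infinite_medium_fluence",
    "fresnel_unpolarized_oracle",
    "hg_moments",
    "shell_average_fluence",
    "audit",
    "run_validation",
]


@dataclass(frozen=True)
class DiffusionParams:
    """Derived diffusion-approximation parameters for a turbid medium.

    ``musp`` is the reduced scattering coefficient ``mus * (1 - g)``; the
    diffusion coefficient is ``D = 1 / (3 (mua + musp))`` and the effective
    attenuation ``mueff = sqrt(3 mua (mua + musp))``.
    """

    mua: float
    musp: float

    def __post_init__(self) -> None:
        if self.mua < 0 or self.musp < 0:
            raise ValueError("coefficients must be >= 0")
        if self.mua + self.musp == 0:
            raise ValueError("mua + musp must be > 0")

    @property
    def D(self) -> float:
        return 1.0 / (3.0 * (self.mua + self.musp))

    @property
    def mueff(self) -> float:
        return math.sqrt(3.0 * self.mua * (self.mua + self.musp))


def infinite_medium_fluence(params: DiffusionParams, r) -> np.ndarray | float:
    """Diffusion-theory fluence of a unit isotropic point source at radius r.

    ``Phi(r) = exp(-mueff * r) / (4 pi D r)``, in 1/mm^2 per unit source
    power.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be > 0")
    out = np.exp(-params.mueff * r) / (4.0 * math.pi * params.D * r)
    return float(out) if out.ndim == 0 else out


def fresnel_unpolarized_oracle(n1: float, n2: float, theta_i: float) -> float:
    """Unpolarized Fresnel reflectance from the angle-form equations.

    ``R = (sin^2(ti - tt) / sin^2(ti + tt) + tan^2(ti - tt) / tan^2(ti + tt)) / 2``
    via Snell's law; 1 beyond the critical angle.  Independent of the
    cosine-form expression used by the transport kernel.
    """
    if theta_i == 0.0:
        return ((n1 - n2) / (n1 + n2)) ** 2
    sin_t = n1 / n2 * math.sin(theta_i)
    if sin_t >= 1.0:
        return 1.0
    theta_t = math.asin(sin_t)
    sm = theta_i - theta_t
    sp = theta_i + theta_t
    return 0.5 * (math.sin(sm) ** 2 / math.sin(sp) ** 2
                  + math.tan(sm) ** 2 / math.tan(sp) ** 2)


def hg_moments(g: float) -> tuple[float, float]:
    """Mean and second moment of the Henyey-Greenstein scattering cosine.

    ``E[cos] = g``; ``E[cos^2] = 1 - 2 (1 - g^2) (1 - g * atanh-form) ...``
    evaluated here by high-resolution numerical quadrature of the HG density
    so the sampler is checked against an independent route.
    """
    if g == 0.0:
        return 0.0, 1.0 / 3.0
    x = np.linspace(-1.0, 1.0, 200001)
    pdf = 0.5 * (1 - g * g) / (1 + g * g - 2 * g * x) ** 1.5
    m1 = float(np.trapezoid(x * pdf, x))
    m2 = float(np.trapezoid(x * x * pdf, x))
    return m1, m2


def shell_average_fluence(volume, scene, center_mm, radii_mm,
                          shell_half_width_mm: float = 0.5) -> np.ndarray:
    """Average a normalized fluence volume over spherical shells.

    For each radius, averages voxel fluence over voxels whose centers lie
    within ``radius +/- shell_half_width_mm`` of ``center_mm``.
    """
    nx, ny, nz = scene.labels.shape
    p = scene.pitch
    cx, cy, cz = center_mm
    xs = (np.arange(nx) + 0.5) * p - cx
    ys = (np.arange(ny) + 0.5) * p - cy
    zs = (np.arange(nz) + 0.5) * p - cz
    r = np.sqrt(xs[:, None, None] ** 2 + ys[None, :, None] ** 2
                + zs[None, None, :] ** 2)
    out = np.empty(len(radii_mm))
    for i, radius in enumerate(radii_mm):
        mask = np.abs(r - radius) <= shell_half_width_mm
        if not mask.any():
            raise ValueError(f"no voxels in shell at r = {radius} mm")
        out[i] = float(volume.values[mask].mean())
    return out


def audit(result, tol: float = 1e-6) -> dict:
    """Energy-conservation audit of a completed run.

    Returns the signed relative residual
    ``(launched - absorbed - escaped - roulette_net) / launched`` and a
    pass/fail verdict at ``tol``.
    """
    if result.launched == 0 or result.launched_weight == 0:
        return {"residual": 0.0, "passed": True, "tolerance": tol}
    residual = result.conservation_residual
    return {
        "residual": float(residual),
        "passed": bool(abs(residual) <= tol),
        "tolerance": tol,
        "launched_weight": result.launched_weight,
        "absorbed_weight": result.absorbed_weight,
        "escaped_weight": result.escaped_weight,
        "roulette_killed_weight": result.roulette_killed_weight,
        "roulette_boosted_weight": result.roulette_boosted_weight,
    }


def run_validation(seed: int = 1, nphoton: int = 200_000,
                   grid: int = 120) -> dict:
    """Run the built-in oracle checks and return a JSON-serializable report.

    Checks: Fresnel implementation vs the angle-form oracle, HG sampling
    moments vs quadrature, energy conservation on the benchmarks, and
    MC-vs-diffusion shell fluence for an interior isotropic source in a
    homogeneous medium.
    """
    from . import transport
    from .accumulate import normalize
    from .rng import RandomStream
    from .scene import (IsotropicPointSource, OpticalProperties, VoxelScene,
                        make_benchmark)

    report: dict = {"seed": seed}

    # Fresnel: implementation vs angle-form oracle on a grid of angles
    angles = np.linspace(0.0, math.pi / 2 * 0.999, 181)
    err = max(abs(transport.fresnel_reflectance(1.37, 1.0, math.cos(t))
                  - fresnel_unpolarized_oracle(1.37, 1.0, t)) for t in angles)
    report["fresnel_max_abs_err"] = err
    report["fresnel_ok"] = err < 1e-12

    # HG sampling moments vs quadrature
    hg = {}
    for g in (0.0, 0.01, 0.9):
        stream = RandomStream(seed, 0)
        u = stream.uniform(200_000)
        cts = np.array([transport.hg_cos_theta(g, ui) for ui in u])
        m1, m2 = hg_moments(g)
        se = math.sqrt(max(m2 - m1 * m1, 1e-30) / len(cts))
        hg[str(g)] = {"sample_mean": float(cts.mean()), "expected_mean": m1,
                      "ok": bool(abs(cts.mean() - m1) <= 4 * se)}
    report["hg"] = hg

    # conservation on the three benchmarks (scaled-down photon count)
    cons = {}
    for name in ("B1", "B2", "B2a"):
        scene, src = make_benchmark(name)
        res = transport.run(scene, src, nphoton=20_000, seed=seed)
        cons[name] = audit(res)
    report["conservation"] = cons

    # diffusion agreement, interior isotropic source
    medium = OpticalProperties(mua=0.005, mus=1.0, g=0.01, n=1.37)
    labels = np.ones((grid, grid, grid), dtype=np.uint8)
    scene = VoxelScene(labels=labels, pitch=1.0, props={1: medium},
                       boundary_mode="terminate")
    center = np.array([grid / 2.0] * 3)
    src = IsotropicPointSource(position=center)
    res = transport.run(scene, src, nphoton=nphoton, seed=seed)
    flu = normalize(res.deposited, scene, res.launched_weight)
    radii = (5.0, 10.0, 15.0)
    mc = shell_average_fluence(flu, scene, center, radii)
    params = DiffusionParams(mua=medium.mua, musp=medium.mus * (1 - medium.g))
    theory = infinite_medium_fluence(params, np.asarray(radii))
    rel = np.abs(mc - theory) / theory
    report["diffusion"] = {
        "radii_mm": list(radii),
        "mc_fluence": mc.tolist(),
        "theory_fluence": theory.tolist(),
        "rel_err": rel.tolist(),
        "nphoton": nphoton,
        "ok": bool(np.all(rel < 0.10)),
    }
    report["all_ok"] = bool(report["fresnel_ok"]
                            and all(v["ok"] for v in hg.values())
                            and all(c["passed"] for c in cons.values())
                            and report["diffusion"]["ok"])
    return report
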