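"""Sphere-sphere intersection dosimetry for a perinuclear gold shell.

The nucleus is a sphere of radius R.  An electron born at distance d from
the nucleus centre deposits its energy uniformly inside a sphere of radius
r (its water penetration range).  The fraction of that energy landing in
the nucleus is the two-sphere intersection volume over the electron
sphere's volume, and the model averages this fraction over a homogeneous
spherical shell of emitters between radii d1 and d2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "NucleusGeometry",
    "GoldShell",
    "sphere_intersection_volume",
    "nuclear_energy_fraction",
    "shell_averaged_fraction",
    "mc_fraction_oracle",
]

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


@dataclass(frozen=True)
class NucleusGeometry:
    """Spherical cell nucleus."""

    R: float  # radius, um
    density: float = 1.0  # g/cm^3

    def __post_init__(self) -> None:
        if self.R <= 0 or self.density <= 0:
            raise ValueError("nucleus radius and density must be positive")


@dataclass(frozen=True)
class GoldShell:
    """Homogeneous spherical shell of gold emitters, radii from nucleus centre."""

    d1: float  # inner radius, um
    d2: float  # outer radius, um

    def __post_init__(self) -> None:
        if not 0 <= self.d1 < self.d2:
            raise ValueError("gold shell requires 0 <= d1 < d2")

    def validate_against(self, nucleus: NucleusGeometry) -> None:
        if self.d1 < nucleus.R:
            raise ValueError(
                "gold shell must be extranuclear: d1 >= nucleus radius"
            )


def sphere_intersection_volume(r: float, R: float, d: float) -> float:
    """Volume (um^3) of the intersection of spheres of radii r and R at centre distance d.

    Branches: zero overlap (d >= r + R), one sphere enclosing the other,
    and the general two-cap lens.  Continuous across all branch boundaries
    and symmetric in (r, R).
    """
    if r <= 0 or R <= 0 or d < 0:
        raise ValueError("radii must be positive and distance non-negative")
    if d >= r + R:
        return 0.0
    if r >= d + R:
        return _FOUR_THIRDS_PI * R**3
    if R >= d + r:
        return _FOUR_THIRDS_PI * r**3
    # standard two-sphere lens volume
    return (
        math.pi
        * (r + R - d) ** 2
        * (d**2 + 2 * d * (r + R) - 3 * (r - R) ** 2)
        / (12 * d)
    )


def nuclear_energy_fraction(r: float, R: float, d: float) -> float:
    """Fraction of an electron's energy deposited in the nucleus: V_i / V_electron."""
    return sphere_intersection_volume(r, R, d) / (_FOUR_THIRDS_PI * r**3)


def shell_averaged_fraction(
    range_r: float, nucleus: NucleusGeometry, shell: GoldShell
) -> float:
    """Nuclear energy fraction averaged over the emitter shell.

    The average is volume-weighted: integral of f(r, R, d) d^2 dd over
    [d1, d2], normalised by the shell volume integral.  The integrand is
    only piecewise smooth, so the quadrature is split exactly at the
    branch boundaries d = |r - R| and d = r + R.
    """
    shell.validate_against(nucleus)
    if range_r <= 0:
        raise ValueError("electron range must be positive")
    R, d1, d2 = nucleus.R, shell.d1, shell.d2
    if range_r + R <= d1:
        return 0.0  # no emitter in the shell can reach the nucleus
    if range_r >= d2 + R:
        return (R / range_r) ** 3  # nucleus enclosed from every emitter

    breakpoints = [b for b in (abs(range_r - R), range_r + R) if d1 < b < d2]

    def integrand(d: float) -> float:
        return nuclear_energy_fraction(range_r, R, d) * d * d

    num, _ = integrate.quad(
        integrand, d1, d2, points=breakpoints or None,
        limit=200, epsabs=1e-12, epsrel=1e-10,
    )
    return num / ((d2**3 - d1**3) / 3.0)


def mc_fraction_oracle(
    range_r: float,
    nucleus: NucleusGeometry,
    shell: GoldShell,
    n_samples: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the shell-averaged fraction, with standard error.

    Emission points are sampled uniformly by volume in the shell and a
    deposition point uniformly in the range-r sphere around each; the
    returned fraction is the hit rate on the nucleus with its binomial
    standard error.  Deterministic for a fixed seed.
    """
    shell.validate_against(nucleus)
    if n_samples < 1000:
        raise ValueError("need at least 1000 samples")
    if range_r + nucleus.R <= shell.d1:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    # emitter radius: uniform in volume between d1 and d2; by symmetry the
    # emitter can sit on the x axis
    u = rng.random(n_samples)
    d = np.cbrt(shell.d1**3 + u * (shell.d2**3 - shell.d1**3))
    # deposition point: uniform in the sphere of radius range_r
    v = rng.normal(size=(n_samples, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    rho = range_r * np.cbrt(rng.random(n_samples))
    pts = v * rho[:, None]
    pts[:, 0] += d
    hits = np.einsum("ij,ij->i", pts, pts) <= nucleus.R**2
    p = float(hits.mean())
    se = math.sqrt(max(p * (1 - p), 1e-300) / n_samples)
    return p, se
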