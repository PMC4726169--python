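"""Atomic and radiological constants for the dose-enhancement model.

This module packages everything the biophysical model needs to know about
photons and electrons in gold and water:

* an electron range-energy relation in water, reconstructed as a power law
  ``r = A * E**B`` (r in um, E in keV) fitted in log-log space to published
  penetration anchors;
* the gold shell structure (binding energies and absorption-edge jump
  ratios) that gates and partitions the photoelectric channel;
* mass attenuation / energy-absorption coefficient tables for gold, water
  and aluminum on a 1-160 keV grid, with doubled grid points at each gold
  absorption edge so interpolation never crosses an edge.

Soft tissue is approximated by liquid water throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClosedChannel",
    "RangeValidityError",
    "ElectronRangeModel",
    "AtomicShell",
    "AttenuationTable",
    "DEFAULT_RANGE_ANCHORS",
    "fit_range_model",
    "electron_range",
    "photoelectron_energy",
    "load_gold_shells",
    "load_attenuation_table",
    "shell_weights",
    "shell_partial_coefficient",
]

#: Published water-penetration anchors: (electron energy keV, range um).
DEFAULT_RANGE_ANCHORS = ((2.0, 0.1), (10.0, 1.5), (50.0, 20.0))


class RangeValidityError(ValueError):
    """Electron energy outside the range law's domain of validity."""


class ClosedChannel(Exception):
    """Photon energy at or below the shell binding energy: no photoelectron."""


@dataclass(frozen=True)
class ElectronRangeModel:
    """Power-law range-energy relation ``r = A * E**B`` in water."""

    coefficient_A: float  # um * keV**-B
    exponent_B: float  # dimensionless
    valid_range: tuple[float, float] = (1.0, 100.0)  # keV

    def __post_init__(self) -> None:
        if self.coefficient_A <= 0 or self.exponent_B <= 0:
            raise ValueError("range model requires A > 0 and B > 0")


def fit_range_model(
    anchors: Iterable[tuple[float, float]] = DEFAULT_RANGE_ANCHORS,
    valid_range: tuple[float, float] = (1.0, 100.0),
) -> ElectronRangeModel:
    """Least-squares straight-line fit in log-log space through the anchors."""
    pts = [(float(e), float(r)) for e, r in anchors]
    if len(pts) < 2:
        raise ValueError("need at least two (energy, range) anchors")
    if any(e <= 0 or r <= 0 for e, r in pts):
        raise ValueError("anchor energies and ranges must be positive")
    x = np.log([e for e, _ in pts])
    y = np.log([r for _, r in pts])
    B, lnA = np.polyfit(x, y, 1)
    return ElectronRangeModel(float(np.exp(lnA)), float(B), valid_range)


def electron_range(model: ElectronRangeModel, energy_keV: float) -> float:
    """Maximum water penetration (um) of an electron of the given energy."""
    lo, hi = model.valid_range
    if not lo <= energy_keV <= hi:
        raise RangeValidityError(
            f"{energy_keV} keV outside range-law validity [{lo}, {hi}] keV"
        )
    return model.coefficient_A * energy_keV**model.exponent_B


@dataclass(frozen=True)
class AtomicShell:
    """One (possibly merged) atomic shell of gold."""

    label: str
    binding_energy: float  # keV
    jump_ratio: float  # absorption-edge jump, dimensionless

    def __post_init__(self) -> None:
        if self.binding_energy <= 0 or self.jump_ratio < 1:
            raise ValueError("shell requires E_B > 0 and jump ratio >= 1")


def photoelectron_energy(shell: AtomicShell, photon_energy_keV: float) -> float:
    """Photoelectron energy E_e = E_hv - E_B; raises ClosedChannel below edge."""
    if photon_energy_keV <= 0:
        raise ValueError("photon energy must be positive")
    if photon_energy_keV < shell.binding_energy:
        raise ClosedChannel(
            f"{photon_energy_keV} keV below {shell.label} edge "
            f"({shell.binding_energy} keV)"
        )
    return photon_energy_keV - shell.binding_energy


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("goldendose.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_gold_shells() -> list[AtomicShell]:
    """Packaged gold shells, ordered K > L1 > L2 > L3 > M by binding energy."""
    df = _read_csv("gold_shells.csv")
    shells = [
        AtomicShell(r.shell, float(r.binding_keV), float(r.jump_ratio))
        for r in df.itertuples()
    ]
    return sorted(shells, key=lambda s: -s.binding_energy)


@dataclass(frozen=True)
class AttenuationTable:
    """Log-log interpolable coefficient table for one material and process.

    Absorption edges appear as doubled grid energies (below-edge value
    first); interpolation therefore never bridges an edge, and queries at
    exactly an edge energy must pass ``side='below'`` or ``'above'``.
    """

    material: str
    kind: str
    energies: np.ndarray = field(repr=False)  # keV, non-decreasing
    values: np.ndarray = field(repr=False)  # cm^2/g

    def __post_init__(self) -> None:
        if np.any(np.diff(self.energies) < 0) or np.any(self.values <= 0):
            raise ValueError("energies must be sorted and values positive")

    @property
    def edge_energies(self) -> np.ndarray:
        e = self.energies
        return np.unique(e[:-1][np.diff(e) == 0])

    def coefficient(self, energy_keV: float, side: str | None = None) -> float:
        """Log-log linear interpolation; edge queries require ``side``."""
        e = self.energies
        if not e[0] <= energy_keV <= e[-1]:
            raise ValueError(
                f"{energy_keV} keV outside {self.material}/{self.kind} "
                f"table range [{e[0]}, {e[-1]}] keV"
            )
        dup = np.isclose(energy_keV, self.edge_energies, rtol=0, atol=1e-9)
        if dup.any():
            if side not in ("below", "above"):
                raise ValueError(
                    f"query at the {self.edge_energies[dup][0]} keV edge is "
                    "ambiguous: pass side='below' or side='above'"
                )
            idx = np.flatnonzero(np.isclose(e, self.edge_energies[dup][0]))
            return float(self.values[idx[0] if side == "below" else idx[-1]])
        i = int(np.searchsorted(e, energy_keV))
        x0, x1 = np.log(e[i - 1]), np.log(e[i])
        y0, y1 = np.log(self.values[i - 1]), np.log(self.values[i])
        t = (math.log(energy_keV) - x0) / (x1 - x0)
        return float(math.exp(y0 + t * (y1 - y0)))


def load_attenuation_table(material: str, kind: str) -> AttenuationTable:
    df = _read_csv("attenuation.csv")
    if material == "soft-tissue":  # treated as liquid water throughout
        material = "water"
    sub = df[(df.material == material) & (df.kind == kind)]
    if sub.empty:
        raise KeyError(f"no packaged table for {material}/{kind}")
    return AttenuationTable(
        material, kind, sub.energy_keV.to_numpy(float), sub.value_cm2_per_g.to_numpy(float)
    )


def shell_weights(
    shells: Sequence[AtomicShell], photon_energy_keV: float
) -> dict[str, float]:
    """Fraction of the photoelectric coefficient carried by each open shell.

    Crossing below an edge divides the photoelectric coefficient by that
    shell's jump ratio, so the shell just above its own edge carries the
    fraction (1 - 1/J) of whatever remains after the deeper closed shells.
    The deepest packaged group (merged M) absorbs the full residual, so the
    weights of the open shells always sum to one.
    """
    ordered = sorted(shells, key=lambda s: -s.binding_energy)
    weights: dict[str, float] = {}
    remaining = 1.0
    for i, s in enumerate(ordered):
        if photon_energy_keV <= s.binding_energy:
            weights[s.label] = 0.0
            continue
        if i == len(ordered) - 1:
            weights[s.label] = remaining
        else:
            weights[s.label] = remaining * (1.0 - 1.0 / s.jump_ratio)
            remaining *= 1.0 / s.jump_ratio
    return weights


def shell_partial_coefficient(
    energy_keV: float,
    shell: AtomicShell,
    shells: Sequence[AtomicShell] | None = None,
    table: AttenuationTable | None = None,
    side: str | None = None,
) -> float:
    """Gold photoelectric coefficient assigned to one shell (cm^2/g).

    Zero when the photon energy is at or below the shell's edge.
    """
    if shells is None:
        shells = load_gold_shells()
    if table is None:
        table = load_attenuation_table("gold", "photoelectric")
    if energy_keV <= shell.binding_energy:
        return 0.0
    # a query exactly at *another* shell's edge still needs a side
    w = shell_weights(shells, energy_keV)[shell.label]
    return w * table.coefficient(energy_keV, side=side)
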