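"""Forward simulators of reflectance over a submerged bottom.

Two reflectance models generate the synthetic "truth" used throughout the
package:

* the two-flow irradiance model (M94 family):
  ``R_w = R_inf + (rho_b - R_inf) exp(-2 Kd z)``;
* the semi-analytical quasi-single-scattering model (L99 family), with
  separate water-column and bottom path attenuations controlled by the
  coefficients ``DuC = 1.03 (1 + 2.4 u)^0.5`` and
  ``DuB = 1.04 (1 + 5.4 u)^0.5``.

A rational single-bounce form (Gordon-Brown style) is also provided with
user-supplied Monte-Carlo coefficients.

The optically deep end member is closed with the quasi-single-scattering
polynomial ``rrs_inf = (0.084 + 0.17 u) u``, consistent with the L99 model
family; it is an argument everywhere, so other closures can be swapped in.

Bottom spectra (coral sand, green algae, brown algae) are parametric
shapes: only their relative/shape properties are asserted anywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .optics_core import (
    Geometry,
    IOPSet,
    Kind,
    Side,
    Spectrum,
    WaterType,
    WATER_TYPES,
    build_iops,
)

__all__ = [
    "BottomSpectrum",
    "Scenario",
    "DeepWaterReference",
    "BOTTOM_LABELS",
    "CANONICAL_DEPTHS",
    "make_bottom",
    "mix_bottoms",
    "canonical_scenarios",
    "deep_water_reflectance",
    "du_c",
    "du_b",
    "m94_forward",
    "l99_forward",
    "gordon_brown_forward",
]

BOTTOM_LABELS = ("coral_sand", "green_algae", "brown_algae")
CANONICAL_DEPTHS = (3.0, 5.0, 10.0, 15.0)


@dataclass(frozen=True)
class BottomSpectrum:
    """Bottom albedo rho_b(lambda), decomposed as scale B times a shape
    normalized to 1 at 550 nm.

    ``albedo_550`` is the scale factor B; ``shape_550`` the normalized
    shape.  Mixtures carry non-negative weights summing to 1.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    label: str = "custom"
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("bottom albedo must lie in [0, 1]")
        if self.weights is not None:
            w = np.array(list(self.weights.values()), dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("mixture weights must be >= 0 and sum to 1")

    @property
    def albedo_550(self) -> float:
        return float(np.interp(550.0, self.wavelengths, self.values))

    @property
    def shape_550(self) -> np.ndarray:
        return self.values / self.albedo_550

    def as_spectrum(self) -> Spectrum:
        return Spectrum(self.wavelengths, self.values, Kind.RHO_B, Side.NA)


def _gauss(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def make_bottom(label: str, grid=None) -> BottomSpectrum:
    """Parametric albedo spectrum for one of the three canonical bottoms.

    coral_sand : bright, monotonically increasing 0.25 -> 0.5 over 400-700.
    green_algae: chlorophyll troughs at 435 and 675 nm, green peak near
                 550 nm, peak albedo 0.15.
    brown_algae: depressed blue, shoulder near 575 nm, trough at 675 nm,
                 peak albedo 0.12.
    """
    grid = np.arange(400.0, 701.0) if grid is None else np.asarray(grid, dtype=float)
    if label == "coral_sand":
        vals = 0.25 + 0.25 * (grid - 400.0) / 300.0
    elif label == "green_algae":
        base = 0.03 + 0.12 * _gauss(grid, 555.0, 55.0)
        vals = base * (1.0 - 0.6 * _gauss(grid, 435.0, 22.0)) * (1.0 - 0.55 * _gauss(grid, 675.0, 12.0))
        vals = vals / vals.max() * 0.15
    elif label == "brown_algae":
        ramp = 1.0 / (1.0 + np.exp(-(grid - 540.0) / 25.0))  # depressed blue
        shoulder = 1.0 + 0.35 * _gauss(grid, 575.0, 18.0)
        vals = (0.015 + 0.10 * ramp) * shoulder * (1.0 - 0.5 * _gauss(grid, 675.0, 12.0))
        vals = vals / vals.max() * 0.12
    else:
        raise ValueError(f"unknown bottom label {label!r}")
    return BottomSpectrum(grid, vals, label=label)


def mix_bottoms(bottoms: list[BottomSpectrum], weights) -> BottomSpectrum:
    """Non-negative convex combination of bottom spectra."""
    w = np.asarray(weights, dtype=float)
    if len(bottoms) != w.size:
        raise ValueError("one weight per bottom required")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be >= 0 and sum to 1")
    grid = bottoms[0].wavelengths
    vals = np.zeros_like(grid)
    for b, wi in zip(bottoms, w):
        if not np.array_equal(b.wavelengths, grid):
            raise ValueError("bottoms must share one wavelength grid")
        vals = vals + wi * b.values
    wmap = {b.label: float(wi) for b, wi in zip(bottoms, w)}
    return BottomSpectrum(grid, vals, label="mixture", weights=wmap)


@dataclass(frozen=True)
class Scenario:
    """(water, bottom, depth, geometry) cell of the simulation grid."""

    water: WaterType
    bottom: BottomSpectrum
    depth_z: float
    geometry: Geometry = field(default_factory=Geometry)

    def __post_init__(self) -> None:
        if self.depth_z <= 0:
            raise ValueError("depth_z must be > 0")


def canonical_scenarios(grid=None) -> list[Scenario]:
    """The canonical 48-cell grid: 4 waters x 4 depths x 3 bottoms.

    Deterministic ordering (water, depth, bottom).
    """
    grid = np.arange(400.0, 701.0) if grid is None else np.asarray(grid, dtype=float)
    bottoms = [make_bottom(lbl, grid) for lbl in BOTTOM_LABELS]
    out = []
    for wname in ("water-a", "water-b", "water-c", "water-d"):
        for z in CANONICAL_DEPTHS:
            for b in bottoms:
                out.append(Scenario(WATER_TYPES[wname], b, z))
    return out


@dataclass(frozen=True)
class DeepWaterReference:
    """Optically deep end members: rrs_inf (sr^-1, 0-) and R_inf = pi*rrs_inf."""

    wavelengths: np.ndarray
    rrs_inf: np.ndarray

    def __post_init__(self) -> None:
        rrs = np.asarray(self.rrs_inf, dtype=float)
        if np.any(rrs < 0):
            raise ValueError("deep-water reflectance must be >= 0")
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "rrs_inf", rrs)

    @property
    def r_inf(self) -> np.ndarray:
        return math.pi * self.rrs_inf


def deep_water_reflectance(iops: IOPSet) -> DeepWaterReference:
    """Quasi-single-scattering deep-water closure ``rrs_inf = (0.084 + 0.17 u) u``."""
    rrs = (0.084 + 0.17 * iops.u) * iops.u
    return DeepWaterReference(iops.wavelengths, rrs)


def du_c(u):
    """Path-elongation coefficient of the water-column term: 1.03 (1 + 2.4 u)^0.5."""
    return 1.03 * np.sqrt(1.0 + 2.4 * np.asarray(u, dtype=float))


def du_b(u):
    """Path-elongation coefficient of the bottom term: 1.04 (1 + 5.4 u)^0.5."""
    return 1.04 * np.sqrt(1.0 + 5.4 * np.asarray(u, dtype=float))


def _check_grids(*grids) -> None:
    first = grids[0]
    for g in grids[1:]:
        if not np.array_equal(first, g):
            raise ValueError("wavelength grid mismatch")


def m94_forward(sc: Scenario, iops: IOPSet, deep: DeepWaterReference) -> Spectrum:
    """Two-flow irradiance reflectance over a submerged bottom.

    ``R_w(0-) = R_inf + (rho_b - R_inf) exp(-2 Kd z)``
    """
    _check_grids(sc.bottom.wavelengths, iops.wavelengths, deep.wavelengths)
    att = np.exp(-2.0 * iops.kd * sc.depth_z)
    rw = deep.r_inf + (sc.bottom.values - deep.r_inf) * att
    return Spectrum(iops.wavelengths, rw, Kind.R, Side.BELOW)


def l99_forward(sc: Scenario, iops: IOPSet, deep: DeepWaterReference) -> Spectrum:
    """Semi-analytical below-surface remote-sensing reflectance.

    ``rrs(0-) = rrs_inf (1 - exp(-(1/mu_s + DuC/mu_v) k z))
              + rho_b/pi * exp(-(1/mu_s + DuB/mu_v) k z)``
    """
    _check_grids(sc.bottom.wavelengths, iops.wavelengths, deep.wavelengths)
    g = sc.geometry
    kz = iops.k * sc.depth_z
    col = np.exp(-(1.0 / g.mu_s + du_c(iops.u) / g.mu_v) * kz)
    bot = np.exp(-(1.0 / g.mu_s + du_b(iops.u) / g.mu_v) * kz)
    rrs = deep.rrs_inf * (1.0 - col) + sc.bottom.values / math.pi * bot
    return Spectrum(iops.wavelengths, rrs, Kind.RRS, Side.BELOW)


def gordon_brown_forward(rho_b: BottomSpectrum, r1, r2, s) -> Spectrum:
    """Single/double-bounce rational form ``R = R1 + rho_b R2 / (1 - s rho_b)``.

    ``R1``, ``R2`` and ``s`` are user-supplied per-wavelength Monte-Carlo
    coefficients (photons missing the bottom, single-bounce contribution
    for rho_b = 1, and double-to-single bounce ratio).
    """
    r1 = np.broadcast_to(np.asarray(r1, dtype=float), rho_b.values.shape)
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), rho_b.values.shape)
    s = np.broadcast_to(np.asarray(s, dtype=float), rho_b.values.shape)
    denom = 1.0 - s * rho_b.values
    if np.any(denom <= 0):
        raise ValueError("s * rho_b must be < 1 (singularity)")
    vals = r1 + rho_b.values * r2 / denom
    return Spectrum(rho_b.wavelengths, vals, Kind.R, Side.ABOVE)
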