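"""Radiometric conventions, attenuation laws and bio-optical parameterizations.

Everything downstream (forward models, correctors, the benchmark) consumes
the types defined here: :class:`Spectrum` for wavelength-indexed radiometric
quantities, :class:`WaterType` for the optically active constituents of a
water column, :class:`IOPSet` for the derived inherent optical properties,
and :class:`Geometry` for the sun/view angles.

Conventions
-----------
* Wavelengths are in nanometres, strictly increasing, within [350, 1000].
* Remote-sensing reflectance ``rrs`` carries units of sr^-1; irradiance
  reflectance ``R`` is dimensionless.  For a Lambertian water body
  ``R = pi * rrs``.
* Depth ``z`` is in metres, positive downward.
* The air-water interface conversion for rrs is
  ``rrs(0-) = rrs(0+) / (0.5 + 1.5 * rrs(0+))`` and its algebraic inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import stats

__all__ = [
    "Kind",
    "Side",
    "Spectrum",
    "WaterType",
    "IOPSet",
    "Geometry",
    "WATER_TYPES",
    "water_absorption",
    "phytoplankton_absorption_shape",
    "convert_interface",
    "attenuate_ed",
    "penetration_depth_z90",
    "build_iops",
    "kd_from_profile",
]


class Kind:
    """Radiometric quantity identifiers carried by every Spectrum."""

    RADIANCE = "radiance"
    ED = "downwelling_irradiance"
    R = "irradiance_reflectance_R"
    RRS = "remote_sensing_reflectance_rrs"
    RHO_W = "water_reflectance_rho"
    RHO_B = "bottom_albedo_rho_b"

    ALL = (RADIANCE, ED, R, RRS, RHO_W, RHO_B)
    REFLECTANCES = (R, RRS, RHO_W, RHO_B)


class Side:
    """Which side of the air-water interface a quantity refers to."""

    ABOVE = "above_surface"
    BELOW = "below_surface"
    NA = "not_applicable"

    ALL = (ABOVE, BELOW, NA)


@dataclass(frozen=True)
class Spectrum:
    """A wavelength-indexed series of one radiometric quantity.

    Parameters
    ----------
    wavelengths : array of float
        Strictly increasing, nm, within [350, 1000].
    values : array of float
        Per-wavelength magnitudes; finite, and non-negative for
        reflectance kinds.
    kind : str
        One of :class:`Kind`.
    side : str
        One of :class:`Side`.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str
    side: str

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < 350.0 or wl[-1] > 1000.0:
            raise ValueError("wavelengths must lie within [350, 1000] nm")
        if not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite")
        if self.kind not in Kind.ALL:
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.side not in Side.ALL:
            raise ValueError(f"unknown side {self.side!r}")
        if self.kind in Kind.REFLECTANCES and np.any(vals < 0):
            raise ValueError(f"{self.kind} values must be >= 0")

    def with_values(self, values, kind: str | None = None, side: str | None = None) -> "Spectrum":
        return Spectrum(
            self.wavelengths,
            values,
            self.kind if kind is None else kind,
            self.side if side is None else side,
        )

    def require(self, kind: str, side: str | None = None) -> None:
        """Raise ValueError unless this spectrum has the stated kind/side."""
        if self.kind != kind:
            raise ValueError(f"expected kind {kind!r}, got {self.kind!r}")
        if side is not None and self.side != side:
            raise ValueError(f"expected side {side!r}, got {self.side!r}")


@dataclass(frozen=True)
class WaterType:
    """Concentration set defining a water column.

    Attributes
    ----------
    chl : float
        Chlorophyll-a concentration, mg m^-3.
    acdom440 : float
        CDOM absorption at 440 nm, m^-1.
    particles_i : float
        Suspended particles of Type I, mg L^-1 (scattering contribution
        configurable; zero by default).
    particles_ii : float
        Suspended particles of Type II (Mie scatterers), mg L^-1.
    ad440 : float
        Detritus absorption at 440 nm, m^-1.
    n_exponent : float
        Spectral exponent of Type-II particle backscattering, in [-2, 1].
    """

    chl: float
    acdom440: float
    particles_i: float
    particles_ii: float
    ad440: float
    n_exponent: float
    name: str = "custom"

    def __post_init__(self) -> None:
        for fname in ("chl", "acdom440", "particles_i", "particles_ii", "ad440"):
            if getattr(self, fname) < 0:
                raise ValueError(f"{fname} must be >= 0")
        if not -2.0 <= self.n_exponent <= 1.0:
            raise ValueError("n_exponent must lie in [-2, 1]")


#: The four canonical water types (clearest 'a' to most turbid 'd').
WATER_TYPES: dict[str, WaterType] = {
    "water-a": WaterType(0.01, 0.0017, 0.01, 0.0, 0.0, -1.0, name="water-a"),
    "water-b": WaterType(1.0, 0.0316, 1.0, 0.8, 0.0, -1.0, name="water-b"),
    "water-c": WaterType(3.0, 0.15, 3.5, 2.2, 0.2, 0.0, name="water-c"),
    "water-d": WaterType(9.0, 0.3, 10.0, 1.0, 0.5, 0.0, name="water-d"),
}


@dataclass(frozen=True)
class Geometry:
    """Solar and viewing zenith angles in degrees (defaults: nadir sun/view)."""

    theta_s: float = 0.0
    theta_v: float = 0.0

    def __post_init__(self) -> None:
        for ang in (self.theta_s, self.theta_v):
            if not 0.0 <= ang < 90.0:
                raise ValueError("zenith angles must lie in [0, 90)")

    @property
    def mu_s(self) -> float:
        return math.cos(math.radians(self.theta_s))

    @property
    def mu_v(self) -> float:
        return math.cos(math.radians(self.theta_v))


@dataclass(frozen=True)
class IOPSet:
    """Derived optical properties of a water column on a wavelength grid.

    ``a`` total absorption (m^-1), ``bb`` total backscattering (m^-1),
    ``u = bb/(a+bb)``, ``k = a+bb`` (m^-1) and the diffuse attenuation
    ``kd`` (m^-1, closure ``kd = k / cos(theta_s)``).
    """

    wavelengths: np.ndarray
    a: np.ndarray
    bb: np.ndarray
    u: np.ndarray = field(default=None)  # type: ignore[assignment]
    k: np.ndarray = field(default=None)  # type: ignore[assignment]
    kd: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        bb = np.asarray(self.bb, dtype=float)
        if np.any(a <= 0):
            raise ValueError("absorption must be > 0 everywhere (pure-water floor)")
        if np.any(bb < 0):
            raise ValueError("backscattering must be >= 0")
        k = a + bb
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "bb", bb)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "u", bb / k)
        if self.kd is None:
            object.__setattr__(self, "kd", k.copy())
        else:
            kd = np.asarray(self.kd, dtype=float)
            if np.any(kd < a - 1e-12):
                raise ValueError("kd must be >= a under the adopted closure")
            object.__setattr__(self, "kd", kd)


# ---------------------------------------------------------------------------
# Bio-optical building blocks
# ---------------------------------------------------------------------------

_AW_CACHE: tuple[np.ndarray, np.ndarray] | None = None


def _load_water_absorption_table() -> tuple[np.ndarray, np.ndarray]:
    global _AW_CACHE
    if _AW_CACHE is None:
        with resources.files("watercolumn.data").joinpath("water_absorption.csv").open() as fh:
            rows = [
                line.split(",")
                for line in fh
                if line.strip() and not line.startswith("#") and not line.startswith("wavelength")
            ]
        wl = np.array([float(r[0]) for r in rows])
        aw = np.array([float(r[1]) for r in rows])
        _AW_CACHE = (wl, aw)
    return _AW_CACHE


def water_absorption(grid) -> np.ndarray:
    """Pure-water absorption a_w(lambda) in m^-1 on the requested grid.

    The packaged table covers 400-700 nm; requesting wavelengths outside
    raises ValueError.
    """
    grid = np.asarray(grid, dtype=float)
    wl, aw = _load_water_absorption_table()
    if grid.min() < wl[0] or grid.max() > wl[-1]:
        raise ValueError(
            f"pure-water absorption table covers [{wl[0]:.0f}, {wl[-1]:.0f}] nm; "
            f"requested [{grid.min():.1f}, {grid.max():.1f}]"
        )
    return np.interp(grid, wl, aw)


def phytoplankton_absorption_shape(grid) -> np.ndarray:
    """Normalized phytoplankton specific-absorption shape (1 at 440 nm).

    A smooth two-peak shape with the chlorophyll-a absorption maxima near
    440 nm (Soret) and 675 nm (red), the conventional structure of in vivo
    phytoplankton absorption.  Only relative behavior matters downstream;
    the 440-nm specific absorption scale lives in :func:`build_iops`.
    """
    grid = np.asarray(grid, dtype=float)
    blue = np.exp(-0.5 * ((grid - 440.0) / 35.0) ** 2)
    red = 0.45 * np.exp(-0.5 * ((grid - 675.0) / 12.0) ** 2)
    shape = blue + red + 0.04
    return shape / (1.0 + 0.04)  # value at 440 ~= 1 (red peak negligible there)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def convert_interface(s: Spectrum, direction: str) -> Spectrum:
    """Move remote-sensing reflectance across the air-water interface.

    ``above_to_below`` applies ``rrs(0-) = rrs(0+) / (0.5 + 1.5 rrs(0+))``;
    ``below_to_above`` applies the algebraic inverse
    ``rrs(0+) = 0.5 rrs(0-) / (1 - 1.5 rrs(0-))``.  The round trip is the
    identity to machine precision.
    """
    s.require(Kind.RRS)
    v = s.values
    if direction == "above_to_below":
        s.require(Kind.RRS, Side.ABOVE)
        out = v / (0.5 + 1.5 * v)
        return s.with_values(out, side=Side.BELOW)
    if direction == "below_to_above":
        s.require(Kind.RRS, Side.BELOW)
        out = 0.5 * v / (1.0 - 1.5 * v)
        return s.with_values(out, side=Side.ABOVE)
    raise ValueError(f"unknown direction {direction!r}")


def attenuate_ed(ed0, kd, z: float):
    """Beer-Lambert attenuation of downwelling irradiance to depth ``z``.

    ``Ed(z) = Ed(0-) * exp(-Kd z)``.  Accepts a :class:`Spectrum` (kind
    downwelling_irradiance) or plain arrays/scalars; returns the same type.
    """
    kd = np.asarray(kd, dtype=float)
    if np.any(kd < 0):
        raise ValueError("Kd must be >= 0")
    if z < 0:
        raise ValueError("depth must be >= 0")
    factor = np.exp(-kd * z)
    if isinstance(ed0, Spectrum):
        ed0.require(Kind.ED)
        return ed0.with_values(ed0.values * factor, side=Side.BELOW)
    return np.asarray(ed0, dtype=float) * factor


def penetration_depth_z90(kd):
    """Effective penetration depth z90 ~= 2.3 / Kd (m).

    The layer thickness contributing 90% of the remotely sensed radiance
    over optically deep water.
    """
    kd = np.asarray(kd, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("Kd must be > 0")
    out = 2.3 / kd
    return float(out) if out.ndim == 0 else out


def build_iops(
    water: WaterType,
    geom: Geometry | None = None,
    grid=None,
    *,
    s_cdom: float = 0.014,
    s_d: float = 0.011,
    aphy_star_440: float = 0.03,
    bb_phy_coeff: float = 0.0006,
    bb_phy_exponent: float = -0.37,
    particles_i_coeff: float = 0.0,
) -> IOPSet:
    """Derive an :class:`IOPSet` from a water type on a wavelength grid.

    Absorption is the sum of pure water, phytoplankton (chl-scaled shape,
    ``aphy_star_440`` m^2 mg^-1 at 440 nm), CDOM and detritus exponentials
    anchored at 440 nm with slopes ``s_cdom``/``s_d`` (nm^-1).

    Backscattering follows the three-term parameterization::

        bb = 0.00144 (lambda/500)^-4.32            # pure water
           + chl * 0.0006 (lambda/500)^-0.37       # phytoplankton
           + C_MieII * 0.0042 (lambda/500)^n       # Mie particles (Type II)

    Type-I particles contribute only through ``particles_i_coeff`` (kg-for-kg
    folded into the Type-II term; default 0).

    The diffuse attenuation closure is ``Kd = (a + bb) / cos(theta_s)``.
    """
    geom = geom or Geometry()
    grid = np.arange(400.0, 701.0) if grid is None else np.asarray(grid, dtype=float)
    if grid.min() < 400.0 or grid.max() > 700.0:
        raise ValueError("wavelength grid must lie within [400, 700] nm")

    lam = grid / 500.0
    aw = water_absorption(grid)
    a = (
        aw
        + water.chl * aphy_star_440 * phytoplankton_absorption_shape(grid)
        + water.acdom440 * np.exp(-s_cdom * (grid - 440.0))
        + water.ad440 * np.exp(-s_d * (grid - 440.0))
    )
    mie = water.particles_ii + particles_i_coeff * water.particles_i
    bb = (
        0.00144 * lam ** -4.32
        + water.chl * bb_phy_coeff * lam ** bb_phy_exponent
        + mie * 0.0042 * lam ** water.n_exponent
    )
    kd = (a + bb) / geom.mu_s
    return IOPSet(wavelengths=grid, a=a, bb=bb, kd=kd)


def kd_from_profile(depths, ed) -> float:
    """Estimate Kd as minus the OLS slope of ln(Ed) against depth.

    Requires at least 3 strictly positive irradiance samples at distinct
    depths.
    """
    depths = np.asarray(depths, dtype=float)
    ed = np.asarray(ed, dtype=float)
    if depths.shape != ed.shape or depths.ndim != 1:
        raise ValueError("depths and ed must be 1-D and equal length")
    if depths.size < 3:
        raise ValueError("need at least 3 profile samples")
    if np.any(ed <= 0):
        raise ValueError("irradiance samples must be strictly positive")
    if np.ptp(depths) == 0:
        raise ValueError("depths must span a range")
    res = stats.linregress(depths, np.log(ed))
    return -float(res.slope)
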