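"""Spectral-library matching and semi-analytical mixture inversion.

Two retrieval families that treat the water column by *simulating* it
rather than algebraically removing it:

* LUT/SAM matching: a library of above-surface remote-sensing reflectance
  spectra is pre-computed over grids of water constituents, depth and
  bottom type; a measured spectrum is assigned the bottom label (and,
  implicitly, the depth and constituent concentrations) of the library
  entry with the minimum spectral angle.
* Mixture inversion: bounded nonlinear least squares over seven unknowns
  (three endmember scaling coefficients, three bio-optical parameters
  anchored at 440 nm, and depth), with the semi-analytical forward model
  inside the loop and the bottom expressed as a linear combination of
  endmember spectra.  Normalized endmember weights are interpretable as
  proportional cover.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .forward_models import (
    BottomSpectrum,
    deep_water_reflectance,
    du_b,
    du_c,
)
from .optics_core import (
    Geometry,
    Kind,
    Side,
    Spectrum,
    WaterType,
    build_iops,
    phytoplankton_absorption_shape,
    water_absorption,
)

__all__ = [
    "LibraryEntry",
    "SpectralLibrary",
    "MixtureFit",
    "CHL_GRID",
    "ACDOM_GRID",
    "PARTICLE_GRID",
    "LIBRARY_DEPTHS",
    "canonical_library_waters",
    "build_library",
    "spectral_angle",
    "lut_classify",
    "classify_batch",
    "add_noise",
    "mixture_invert",
    "DEFAULT_MIXTURE_BOUNDS",
]

# Constituent grids of the canonical spectral library (chl in mg m^-3,
# aCDOM(440) in m^-1, Type-II particles in mg L^-1, depths 1-16 m).
CHL_GRID = (0.01, 0.02, 0.1, 0.2, 0.3, 0.9, 1.0, 1.1, 2.5, 2.8, 3.0, 3.1, 3.2, 8.0, 8.5, 9.0)
ACDOM_GRID = (0.0017, 0.00269, 0.0074, 0.1, 0.15, 0.2, 0.25)
PARTICLE_GRID = (0.0, 0.5, 0.8, 1.0, 2.0, 2.2, 2.5)
LIBRARY_DEPTHS = tuple(float(z) for z in range(1, 17))


def canonical_library_waters() -> list[WaterType]:
    """Cartesian product of the canonical constituent grids.

    Detritus absorption and the Mie exponent are not varied by the grids;
    they stay at the clear-water defaults (ad440 = 0, n = -1), so waters
    whose optics depend on detritus or a flat Mie exponent are not exactly
    representable in the library.
    """
    waters = []
    for chl in CHL_GRID:
        for acdom in ACDOM_GRID:
            for cii in PARTICLE_GRID:
                waters.append(WaterType(chl, acdom, 0.0, cii, 0.0, -1.0))
    return waters


@dataclass(frozen=True)
class LibraryEntry:
    """One pre-computed spectrum with its generating parameters."""

    spectrum: Spectrum
    water: WaterType
    depth: float
    bottom_weights: dict[str, float]

    @property
    def bottom_label(self) -> str:
        return max(self.bottom_weights, key=self.bottom_weights.get)


@dataclass
class SpectralLibrary:
    """Columnar store of library spectra (rows) with generating parameters.

    ``values`` has shape (n_entries, n_wavelengths); ``params`` is a
    DataFrame with one row per entry (water constituents, depth, bottom
    label).  Ordering is deterministic: (water, depth, bottom).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    params: pd.DataFrame
    forward_model_id: str = "l99"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.params), self.wavelengths.size):
            raise ValueError("values shape must be (n_entries, n_wavelengths)")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def labels(self) -> np.ndarray:
        return self.params["bottom"].to_numpy()

    def entry(self, i: int) -> LibraryEntry:
        row = self.params.iloc[i]
        water = WaterType(
            row["chl"],
            row["acdom440"],
            row.get("particles_i", 0.0),
            row["particles_ii"],
            row["ad440"],
            row["n_exponent"],
        )
        return LibraryEntry(
            Spectrum(self.wavelengths, self.values[i], Kind.RRS, Side.ABOVE),
            water,
            float(row["depth"]),
            {row["bottom"]: 1.0},
        )

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.round(self.wavelengths, 6).tobytes())
        h.update(np.round(self.values, 12).tobytes())
        h.update(self.params.to_csv(index=False).encode())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        """Parameters plus spectrum columns, one row per entry."""
        spec = pd.DataFrame(
            self.values, columns=[f"rrs_{w:.1f}" for w in self.wavelengths]
        )
        return pd.concat([self.params.reset_index(drop=True), spec], axis=1)

    def concat(self, other: "SpectralLibrary") -> "SpectralLibrary":
        """Append another library sharing the same grid and forward model."""
        if not np.array_equal(self.wavelengths, other.wavelengths):
            raise ValueError("libraries must share one wavelength grid")
        if self.forward_model_id != other.forward_model_id:
            raise ValueError("libraries must share one forward model")
        return SpectralLibrary(
            self.wavelengths,
            np.vstack([self.values, other.values]),
            pd.concat([self.params, other.params], ignore_index=True),
            forward_model_id=self.forward_model_id,
        )


def build_library(
    waters: list[WaterType],
    depths,
    bottoms: list[BottomSpectrum],
    grid=None,
    forward: str = "l99",
    geom: Geometry | None = None,
) -> SpectralLibrary:
    """Render the Cartesian product of (water, depth, bottom) grids.

    Every cell is pushed through the chosen forward model and converted to
    above-surface remote-sensing reflectance (the quantity the classifier
    works on).  Ordering is (water, depth, bottom), stable across runs.
    """
    if not waters or len(list(depths)) == 0 or not bottoms:
        raise ValueError("water, depth and bottom grids must be nonempty")
    geom = geom or Geometry()
    grid = np.arange(400.0, 701.0) if grid is None else np.asarray(grid, dtype=float)
    depths = [float(z) for z in depths]
    bmat = np.stack([b.values for b in bottoms])  # (n_bottoms, n_wl)
    blabels = [b.label for b in bottoms]

    rows = []
    specs = np.empty((len(waters) * len(depths) * len(bottoms), grid.size))
    i = 0
    for w in waters:
        iops = build_iops(w, geom, grid)
        deep = deep_water_reflectance(iops)
        if forward == "l99":
            col_rate = (1.0 / geom.mu_s + du_c(iops.u) / geom.mu_v) * iops.k
            bot_rate = (1.0 / geom.mu_s + du_b(iops.u) / geom.mu_v) * iops.k
        elif forward == "m94":
            col_rate = bot_rate = 2.0 * iops.kd
        else:
            raise ValueError(f"unknown forward model {forward!r}")
        for z in depths:
            col = np.exp(-col_rate * z)
            bot = np.exp(-bot_rate * z)
            if forward == "l99":
                rrs_below = deep.rrs_inf * (1.0 - col) + bmat / math.pi * bot
            else:  # m94 in rrs units: R/pi
                r_below = deep.r_inf * (1.0 - col) + bmat * bot
                rrs_below = r_below / math.pi
            rrs_above = 0.5 * rrs_below / (1.0 - 1.5 * rrs_below)
            for bi, lbl in enumerate(blabels):
                specs[i] = rrs_above[bi]
                rows.append(
                    {
                        "chl": w.chl,
                        "acdom440": w.acdom440,
                        "particles_i": w.particles_i,
                        "particles_ii": w.particles_ii,
                        "ad440": w.ad440,
                        "n_exponent": w.n_exponent,
                        "depth": z,
                        "bottom": lbl,
                    }
                )
                i += 1
    return SpectralLibrary(grid, specs, pd.DataFrame(rows), forward_model_id=forward)


def spectral_angle(x, y) -> float:
    """Angle (radians, in [0, pi]) between two spectra viewed as vectors.

    Scale-invariant: angle(x, c*x) = 0 for c > 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("spectra must share a grid of length >= 2")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero-norm spectrum")
    return float(np.arccos(np.clip(np.dot(x, y) / (nx * ny), -1.0, 1.0)))


def classify_batch(queries: np.ndarray, lib: SpectralLibrary) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-spectral-angle match for many queries at once.

    ``queries`` has shape (n_queries, n_wavelengths).  Returns
    ``(best_indices, angles)``; ties break to the first entry in library
    order (argmin semantics).
    """
    if len(lib) == 0:
        raise ValueError("empty library")
    q = np.atleast_2d(np.asarray(queries, dtype=float))
    qn = np.linalg.norm(q, axis=1, keepdims=True)
    ln = np.linalg.norm(lib.values, axis=1)
    if np.any(qn == 0) or np.any(ln == 0):
        raise ValueError("zero-norm spectrum")
    cos = (q / qn) @ (lib.values / ln[:, None]).T
    best = np.argmax(cos, axis=1)
    angles = np.arccos(np.clip(cos[np.arange(q.shape[0]), best], -1.0, 1.0))
    return best, angles


def lut_classify(query: Spectrum, lib: SpectralLibrary) -> tuple[LibraryEntry, float, str]:
    """Assign a query spectrum the best-fitting library entry.

    Returns (entry, angle, bottom label); the entry carries all its
    generating parameters, so depth and constituent concentrations are
    retrieved simultaneously with the bottom type.
    """
    if not np.array_equal(query.wavelengths, lib.wavelengths):
        raise ValueError("query must be on the library wavelength grid")
    best, angles = classify_batch(query.values[None, :], lib)
    entry = lib.entry(int(best[0]))
    return entry, float(angles[0]), entry.bottom_label


def add_noise(s: Spectrum, level: float, seed=None) -> Spectrum:
    """Multiplicative Gaussian band noise: ``v * (1 + eps)``, eps ~ N(0, level).

    The factor is truncated at 0 so reflectances stay non-negative; seeded
    and bitwise-reproducible.  ``seed`` may be an int or a Generator.
    """
    if level < 0:
        raise ValueError("noise level must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    factor = np.maximum(1.0 + rng.normal(0.0, level, size=s.values.shape), 0.0)
    return s.with_values(s.values * factor)


# ---------------------------------------------------------------------------
# Mixture inversion
# ---------------------------------------------------------------------------

#: (lo, hi) for (aphy440 m^-1, ag440 m^-1, bbp440 m^-1, B per endmember, z m)
DEFAULT_MIXTURE_BOUNDS = {
    "aphy440": (0.0, 0.5),
    "ag440": (0.0, 0.5),
    "bbp440": (0.0, 0.05),
    "B": (0.0, 2.0),
    "z": (0.1, 20.0),
}


@dataclass
class MixtureFit:
    """Result of the seven-parameter semi-analytical mixture inversion."""

    b_weights: np.ndarray
    aphy440: float
    ag440: float
    bbp440: float
    z_est: float
    residual: float
    success: bool
    message: str = ""
    n_starts: int = 0

    @property
    def iop_params(self) -> tuple[float, float, float]:
        return (self.aphy440, self.ag440, self.bbp440)

    @property
    def normalized_weights(self) -> np.ndarray:
        tot = self.b_weights.sum()
        return self.b_weights / tot if tot > 0 else self.b_weights


def _mixture_forward(theta, grid, endmember_mat, geom, aw, aphy_shape, bbw, bbp_shape):
    n_end = endmember_mat.shape[0]
    aphy440, ag440, bbp440 = theta[0], theta[1], theta[2]
    b = np.asarray(theta[3 : 3 + n_end])
    z = theta[3 + n_end]
    a = aw + aphy440 * aphy_shape + ag440 * np.exp(-0.014 * (grid - 440.0))
    bb = bbw + bbp440 * bbp_shape
    k = a + bb
    u = bb / k
    rrs_inf = (0.084 + 0.17 * u) * u
    col = np.exp(-(1.0 / geom.mu_s + du_c(u) / geom.mu_v) * k * z)
    bot = np.exp(-(1.0 / geom.mu_s + du_b(u) / geom.mu_v) * k * z)
    rho_b = b @ endmember_mat
    return rrs_inf * (1.0 - col) + rho_b / math.pi * bot


def mixture_invert(
    query: Spectrum,
    endmembers: list[BottomSpectrum],
    geom: Geometry | None = None,
    bounds: dict | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """Bounded least-squares fit of the semi-analytical model to one spectrum.

    Unknowns: aphyto(440), ag(440) (CDOM+detritus), bbp(440), one scaling
    coefficient B per endmember (1-3 endmembers), and depth z.  The bottom
    is ``rho_b = sum_e B_e R_e``; with two endmembers and weights
    (g, 1 - g) this is exactly the two-substrate linear bottom model.

    The parameter landscape is multimodal, so the optimizer (trust-region
    reflective least squares) restarts from ``n_starts`` Latin-hypercube
    points plus the box centre and keeps the best fit.  Non-convergence is
    reported in the result (``success`` False), never raised.
    """
    if not 1 <= len(endmembers) <= 3:
        raise ValueError("1-3 endmembers required")
    geom = geom or Geometry()
    bounds = {**DEFAULT_MIXTURE_BOUNDS, **(bounds or {})}
    query.require(Kind.RRS)
    target = query.values
    if query.side == Side.ABOVE:
        target = target / (0.5 + 1.5 * target)

    grid = query.wavelengths
    emat = np.stack([np.interp(grid, e.wavelengths, e.values) for e in endmembers])
    aw = water_absorption(grid)
    aphy_shape = phytoplankton_absorption_shape(grid)
    bbw = 0.00144 * (grid / 500.0) ** -4.32
    bbp_shape = (grid / 440.0) ** -1.0

    n_end = len(endmembers)
    lo = np.array(
        [bounds["aphy440"][0], bounds["ag440"][0], bounds["bbp440"][0]]
        + [bounds["B"][0]] * n_end
        + [bounds["z"][0]]
    )
    hi = np.array(
        [bounds["aphy440"][1], bounds["ag440"][1], bounds["bbp440"][1]]
        + [bounds["B"][1]] * n_end
        + [bounds["z"][1]]
    )

    def resid(theta):
        return (
            _mixture_forward(theta, grid, emat, geom, aw, aphy_shape, bbw, bbp_shape) - target
        )

    sampler = qmc.LatinHypercube(d=lo.size, seed=seed)
    starts = [0.5 * (lo + hi)]
    starts += list(lo + sampler.random(n_starts) * (hi - lo))

    best = None
    for x0 in starts:
        try:
            sol = least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:  # pragma: no cover - optimizer pathologies
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return MixtureFit(
            np.full(n_end, np.nan), np.nan, np.nan, np.nan, np.nan,
            residual=np.inf, success=False, message="all starts failed",
            n_starts=len(starts),
        )
    theta = best.x
    return MixtureFit(
        b_weights=np.asarray(theta[3 : 3 + n_end]),
        aphy440=float(theta[0]),
        ag440=float(theta[1]),
        bbp440=float(theta[2]),
        z_est=float(theta[3 + n_end]),
        residual=float(np.sqrt(2.0 * best.cost)),
        success=bool(best.success),
        message=str(best.message),
        n_starts=len(starts),
    )
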