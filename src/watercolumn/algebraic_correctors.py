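"""Model-based algebraic inversions returning bottom-reflectance spectra.

Each corrector inverts one forward reflectance model per wavelength and
returns a :class:`RetrievalResult` with the retrieved albedo, a validity
mask and named flags.  Threshold values live in
:class:`~watercolumn.validity.ValidityConfig`, shared with the benchmark.

The exact inverse pairing with the matching forward model (round-trip
relative error < 1e-10) is the defining contract of this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forward_models import DeepWaterReference, du_b, du_c
from .optics_core import Geometry, IOPSet, Kind, Side, Spectrum
from .validity import DEFAULT_VALIDITY, FLAGS, ValidityConfig

__all__ = [
    "RetrievalResult",
    "m94_invert",
    "l99_invert",
    "purkis_invert",
    "bierwirth_correct",
    "mumby_correct",
    "gordon_brown_invert",
]


@dataclass
class RetrievalResult:
    """Retrieved bottom reflectance plus per-wavelength diagnostics.

    ``flags`` maps flag name -> boolean array; any raised flag forces the
    corresponding ``valid_mask`` entry to False.  ``contribution_pct`` is
    filled by the benchmark's contribution calculators.
    """

    wavelengths: np.ndarray
    rho_b: np.ndarray
    method: str
    flags: dict[str, np.ndarray] = field(default_factory=dict)
    contribution_pct: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.rho_b = np.asarray(self.rho_b, dtype=float)
        for name in FLAGS:
            self.flags.setdefault(name, np.zeros(self.wavelengths.shape, dtype=bool))

    @property
    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.wavelengths.shape, dtype=bool)
        for arr in self.flags.values():
            mask &= ~arr
        return mask

    def flag(self, name: str, where: np.ndarray) -> None:
        if name not in FLAGS:
            raise ValueError(f"unknown flag {name!r}")
        self.flags[name] = self.flags[name] | np.asarray(where, dtype=bool)


def _check_grids(*grids) -> None:
    first = np.asarray(grids[0])
    for g in grids[1:]:
        if not np.array_equal(first, np.asarray(g)):
            raise ValueError("wavelength grid mismatch")


def _range_flags(res: RetrievalResult, cfg: ValidityConfig) -> None:
    lo, hi = cfg.rho_b_range
    res.flag("out_of_range", (res.rho_b <= lo) | (res.rho_b >= hi))


def m94_invert(
    rw: Spectrum,
    deep: DeepWaterReference,
    kd,
    z: float,
    cfg: ValidityConfig = DEFAULT_VALIDITY,
) -> RetrievalResult:
    """Invert the two-flow model: ``rho_b = (R - R_inf) e^{+2 Kd z} + R_inf``.

    The ``exponential_regime`` flag is raised where ``e^{-2 Kd z}`` drops
    below ``cfg.exponential_threshold`` (the same numeric threshold the
    semi-analytical inversion uses, adopted for symmetry).
    """
    rw.require(Kind.R, Side.BELOW)
    _check_grids(rw.wavelengths, deep.wavelengths)
    kd = np.broadcast_to(np.asarray(kd, dtype=float), rw.values.shape)
    if z <= 0:
        raise ValueError("z must be > 0")
    att = np.exp(-2.0 * kd * z)
    rho = (rw.values - deep.r_inf) / att + deep.r_inf
    res = RetrievalResult(rw.wavelengths, rho, method="m94")
    res.flag("exponential_regime", att < cfg.exponential_threshold)
    _range_flags(res, cfg)
    return res


def l99_invert(
    rrs: Spectrum,
    deep: DeepWaterReference,
    iops: IOPSet,
    z: float,
    geom: Geometry | None = None,
    cfg: ValidityConfig = DEFAULT_VALIDITY,
) -> RetrievalResult:
    """Invert the semi-analytical model.

    Subtracts the water-column path term, removes the bottom-path
    attenuation and multiplies by pi::

        rho_b = pi [rrs(0-) - rrs_inf (1 - e^{-(1/mu_s + DuC/mu_v) k z})]
                * e^{+(1/mu_s + DuB/mu_v) k z}
    """
    rrs.require(Kind.RRS, Side.BELOW)
    _check_grids(rrs.wavelengths, deep.wavelengths, iops.wavelengths)
    geom = geom or Geometry()
    kz = iops.k * z
    col = np.exp(-(1.0 / geom.mu_s + du_c(iops.u) / geom.mu_v) * kz)
    bot = np.exp(-(1.0 / geom.mu_s + du_b(iops.u) / geom.mu_v) * kz)
    rho = math.pi * (rrs.values - deep.rrs_inf * (1.0 - col)) / bot
    res = RetrievalResult(rrs.wavelengths, rho, method="l99")
    res.flag("exponential_regime", bot < cfg.exponential_threshold)
    _range_flags(res, cfg)
    return res


def purkis_invert(
    rrs_above: Spectrum,
    deep_above,
    kd,
    z: float,
    cfg: ValidityConfig = DEFAULT_VALIDITY,
) -> RetrievalResult:
    """Above-surface two-flow inversion with the 1/0.54 interface factor.

    ``rho_b^RS = [rrs(0+)/0.54 - (1 - e^{-2 Kd z}) rrs_inf(0+)] e^{+2 Kd z}``

    Distinguishing feature: inputs stay above the surface; the refractive
    effect of the interface is folded into the multiplicative 1/0.54.
    """
    rrs_above.require(Kind.RRS, Side.ABOVE)
    deep_above = np.broadcast_to(np.asarray(deep_above, dtype=float), rrs_above.values.shape)
    kd = np.broadcast_to(np.asarray(kd, dtype=float), rrs_above.values.shape)
    att = np.exp(-2.0 * kd * z)
    rho = (rrs_above.values / 0.54 - (1.0 - att) * deep_above) / att
    res = RetrievalResult(rrs_above.wavelengths, rho, method="purkis")
    res.flag("exponential_regime", att < cfg.exponential_threshold)
    _range_flags(res, cfg)
    return res


def bierwirth_correct(rrs: Spectrum, kd) -> tuple[Spectrum, float]:
    """Depth-free pseudo-reflectance via a per-pixel pseudo-depth.

    ``Z_alpha = mean_i [ ln rrs_i / (-2 Kd_i) ]`` and
    ``rho_B_i = rrs_i e^{2 Kd_i Z_alpha}``.

    No true depth is needed; the result differs from the real bottom
    reflectance by a common factor ``e^{dz}`` per pixel, so band ratios
    (the spectral hue) are preserved.
    """
    rrs.require(Kind.RRS)
    kd = np.broadcast_to(np.asarray(kd, dtype=float), rrs.values.shape)
    if np.any(rrs.values <= 0):
        raise ValueError("Bierwirth correction requires strictly positive reflectances")
    z_alpha = float(np.mean(np.log(rrs.values) / (-2.0 * kd)))
    pseudo = rrs.values * np.exp(2.0 * kd * z_alpha)
    return rrs.with_values(pseudo), z_alpha


def mumby_correct(
    rw: Spectrum,
    kd,
    z: float,
    two_way_factor: float = 2.0,
    cfg: ValidityConfig = DEFAULT_VALIDITY,
) -> RetrievalResult:
    """Single-term exponential correction ``rho_b = R_w e^{+g Kd z}``.

    ``g`` (``two_way_factor``) defaults to 2, the two-way optical path, in
    which case the method equals the two-flow inversion with R_inf = 0.
    ``g = 1`` exposes the one-way variant.
    """
    if z < 0:
        raise ValueError("z must be >= 0")
    kd = np.broadcast_to(np.asarray(kd, dtype=float), rw.values.shape)
    rho = rw.values * np.exp(two_way_factor * kd * z)
    res = RetrievalResult(rw.wavelengths, rho, method="mumby")
    res.flag("exponential_regime", np.exp(-two_way_factor * kd * z) < cfg.exponential_threshold)
    _range_flags(res, cfg)
    return res


def gordon_brown_invert(
    r: Spectrum,
    r1,
    r2,
    s,
    cfg: ValidityConfig = DEFAULT_VALIDITY,
) -> RetrievalResult:
    """Invert the rational single-bounce form.

    ``rho_b = (R - R1) / (R2 + s (R - R1))``; wavelengths where the
    denominator is <= 0 are flagged (``deep_exceeds_signal``).
    """
    r1 = np.broadcast_to(np.asarray(r1, dtype=float), r.values.shape)
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), r.values.shape)
    s = np.broadcast_to(np.asarray(s, dtype=float), r.values.shape)
    if np.any(r2 <= 0):
        raise ValueError("R2 must be > 0")
    diff = r.values - r1
    denom = r2 + s * diff
    bad = denom <= 0
    rho = np.where(bad, np.nan, diff / np.where(bad, 1.0, denom))
    rho = np.where(bad, 0.0, rho)
    res = RetrievalResult(r.wavelengths, rho, method="gordon_brown")
    res.flag("deep_exceeds_signal", bad)
    _range_flags(res, cfg)
    return res
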