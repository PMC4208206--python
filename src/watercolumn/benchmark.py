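"""Inter-comparison harness for the water-column correctors.

Drives everything end to end on the canonical 48-scenario grid
(4 waters x 4 depths x 3 bottoms): bottom-contribution accounting,
validity filtering, retrieval uncertainty, one-at-a-time sensitivity
analysis, detectable-wavelength ranges, and the LUT/SAM classification
experiment with its confusion matrix.

Since the radiative-transfer spectra behind the original inter-comparison
are not reproducible, the cross-model tables here use the semi-analytical
forward model as the surrogate truth generator and invert with the
two-flow model; same-model round trips are exact by construction and are
reported as a consistency check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .algebraic_correctors import RetrievalResult, l99_invert, m94_invert
from .forward_models import (
    BOTTOM_LABELS,
    BottomSpectrum,
    CANONICAL_DEPTHS,
    DeepWaterReference,
    Scenario,
    canonical_scenarios,
    deep_water_reflectance,
    du_b,
    du_c,
    l99_forward,
    m94_forward,
    make_bottom,
)
from .matching import (
    LIBRARY_DEPTHS,
    SpectralLibrary,
    build_library,
    canonical_library_waters,
    classify_batch,
)
from .optics_core import (
    Geometry,
    IOPSet,
    Kind,
    Side,
    Spectrum,
    WATER_TYPES,
    WaterType,
    build_iops,
)
from .validity import DEFAULT_VALIDITY, ValidityConfig

__all__ = [
    "ValidityConfig",
    "DEFAULT_VALIDITY",
    "SensitivityCase",
    "ConfusionMatrix",
    "bottom_contribution_m94",
    "bottom_contribution_l99",
    "apply_validity",
    "retrieval_uncertainty",
    "sensitivity_single",
    "sensitivity_analysis",
    "detectable_wavelength_range",
    "standard_bottom",
    "run_intercomparison",
]


def bottom_contribution_m94(res: RetrievalResult, deep: DeepWaterReference, kd, z, rw: Spectrum) -> np.ndarray:
    """Percent of the below-surface signal contributed by the bottom
    (two-flow accounting)::

        100 * (rho_b_retrieved - R_inf) e^{-2 Kd z} / R(0-)

    Wavelengths where R(0-) = 0 are undefined: NaN, flagged
    ``deep_exceeds_signal``.  Stores the result on ``res.contribution_pct``.
    """
    kd = np.broadcast_to(np.asarray(kd, dtype=float), res.rho_b.shape)
    undefined = rw.values == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (res.rho_b - deep.r_inf) * np.exp(-2.0 * kd * z) / rw.values
    pct = np.where(undefined, np.nan, pct)
    res.flag("deep_exceeds_signal", undefined)
    res.contribution_pct = pct
    return pct


def bottom_contribution_l99(
    res: RetrievalResult, iops: IOPSet, z, geom: Geometry, rrs: Spectrum
) -> np.ndarray:
    """Percent bottom contribution under the semi-analytical model::

        100 * (rho_b_retrieved / pi) e^{-(1/mu_s + DuB/mu_v) k z} / rrs(0-)

    i.e. the bottom path term of the forward model over the total signal;
    at z = 0 over an exposed bottom (rrs = rho_b/pi) this is exactly 100%.
    """
    bot = np.exp(-(1.0 / geom.mu_s + du_b(iops.u) / geom.mu_v) * iops.k * z)
    undefined = rrs.values == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * res.rho_b / math.pi * bot / rrs.values
    pct = np.where(undefined, np.nan, pct)
    res.flag("deep_exceeds_signal", undefined)
    res.contribution_pct = pct
    return pct


def apply_validity(res: RetrievalResult, cfg: ValidityConfig = DEFAULT_VALIDITY) -> RetrievalResult:
    """Mask wavelengths failing any validity rule; idempotent.

    Requires ``res.contribution_pct`` for the low-contribution rule (skip
    that rule when contribution has not been computed).
    """
    lo, hi = cfg.rho_b_range
    res.flag("out_of_range", (res.rho_b <= lo) | (res.rho_b >= hi))
    if res.contribution_pct is not None:
        with np.errstate(invalid="ignore"):
            res.flag("low_contribution", res.contribution_pct < cfg.min_contribution_pct)
    return res


def retrieval_uncertainty(res: RetrievalResult, truth: BottomSpectrum) -> np.ndarray:
    """Signed per-wavelength retrieval error in percent::

        100 * (rho_b_retrieved - rho_b) / rho_b

    NaN (and flagged) where the true albedo is zero.
    """
    zero = truth.values == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        unc = 100.0 * (res.rho_b - truth.values) / truth.values
    unc = np.where(zero, np.nan, unc)
    res.flag("deep_exceeds_signal", zero)
    return unc


# ---------------------------------------------------------------------------
# Sensitivity analysis
# ---------------------------------------------------------------------------

_M94_PARAMS = ("z", "Kd", "R_inf")
_L99_PARAMS = ("z", "a", "bb", "rho_inf")


@dataclass(frozen=True)
class SensitivityCase:
    """One cell of the one-at-a-time sensitivity design.

    Extreme corners of the scenario grid: water-a or water-d, sand or
    brown algae, 3 or 10 m, evaluated at 450/550/650 nm, with fractional
    perturbations inside [-95%, +100%].
    """

    water: str = "water-a"
    bottom: str = "coral_sand"
    depth: float = 3.0
    wavelengths: tuple[float, ...] = (450.0, 550.0, 650.0)
    perturbations: tuple[float, ...] = tuple(np.round(np.arange(-0.95, 1.0001, 0.05), 4))

    def __post_init__(self) -> None:
        if self.water not in ("water-a", "water-d"):
            raise ValueError("water must be water-a or water-d")
        if self.bottom not in ("coral_sand", "brown_algae"):
            raise ValueError("bottom must be coral_sand or brown_algae")
        if self.depth not in (3.0, 10.0):
            raise ValueError("depth must be 3 or 10 m")
        for d in self.perturbations:
            if not -0.95 <= d <= 1.0:
                raise ValueError("perturbations must lie in [-0.95, 1.0]")


def sensitivity_single(
    water: WaterType,
    bottom: BottomSpectrum,
    depth: float,
    method: str,
    param: str,
    delta: float,
    geom: Geometry | None = None,
) -> np.ndarray:
    """Per-wavelength sensitivity (%) to scaling one input by (1 + delta).

    The baseline is the same-model forward/inverse retrieval (exact, so
    rho_b1 equals the true albedo); the perturbed retrieval re-runs the
    *inversion* with the single parameter scaled.  Reported as
    ``100 |rho_b1 - rho_b2| / rho_b1``.
    """
    if not -0.95 <= delta <= 1.0:
        raise ValueError("perturbation must lie in [-0.95, 1.0]")
    geom = geom or Geometry()
    grid = bottom.wavelengths
    iops = build_iops(water, geom, grid)
    deep = deep_water_reflectance(iops)
    sc = Scenario(water, bottom, depth, geom)
    scale = 1.0 + delta

    if method == "m94":
        if param not in _M94_PARAMS:
            raise ValueError(f"m94 sensitivity accepts {_M94_PARAMS}, got {param!r}")
        rw = m94_forward(sc, iops, deep)

        def retrieve_m94(s: float) -> np.ndarray:
            z2, kd2, rinf2 = depth, iops.kd, deep.r_inf
            if param == "z":
                z2 = depth * s
            elif param == "Kd":
                kd2 = iops.kd * s
            else:
                rinf2 = deep.r_inf * s
            return (rw.values - rinf2) / np.exp(-2.0 * kd2 * z2) + rinf2

        rho1, rho2 = retrieve_m94(1.0), retrieve_m94(scale)
    elif method == "l99":
        if param not in _L99_PARAMS:
            raise ValueError(f"l99 sensitivity accepts {_L99_PARAMS}, got {param!r}")
        rrs = l99_forward(sc, iops, deep)

        def retrieve_l99(s: float) -> np.ndarray:
            a2, bb2, z2, rrs_inf2 = iops.a, iops.bb, depth, deep.rrs_inf
            if param == "z":
                z2 = depth * s
            elif param == "a":
                a2 = iops.a * s
            elif param == "bb":
                bb2 = iops.bb * s
            else:
                rrs_inf2 = deep.rrs_inf * s
            k2 = a2 + bb2
            u2 = bb2 / k2
            col = np.exp(-(1.0 / geom.mu_s + du_c(u2) / geom.mu_v) * k2 * z2)
            bot = np.exp(-(1.0 / geom.mu_s + du_b(u2) / geom.mu_v) * k2 * z2)
            return math.pi * (rrs.values - rrs_inf2 * (1.0 - col)) / bot

        rho1, rho2 = retrieve_l99(1.0), retrieve_l99(scale)
    else:
        raise ValueError(f"unknown method {method!r}")

    # rho1 is the baseline *retrieval* (the same computation at scale 1),
    # so the zero perturbation is exactly zero by construction
    return 100.0 * np.abs(rho1 - rho2) / rho1


def sensitivity_analysis(
    case: SensitivityCase,
    method: str = "m94",
    param: str = "Kd",
    geom: Geometry | None = None,
    grid=None,
) -> pd.DataFrame:
    """Sensitivity surface over the case's perturbation grid.

    Rows: fractional perturbations; columns: the case's evaluation
    wavelengths; values: Sensitivity (%).
    """
    grid = np.arange(400.0, 701.0) if grid is None else np.asarray(grid, dtype=float)
    water = WATER_TYPES[case.water]
    bottom = make_bottom(case.bottom, grid)
    cols = {}
    idx = [float(w) for w in case.wavelengths]
    wl_pos = [int(np.argmin(np.abs(grid - w))) for w in case.wavelengths]
    rows = []
    for delta in case.perturbations:
        sens = sensitivity_single(water, bottom, case.depth, method, param, delta, geom)
        rows.append([sens[p] for p in wl_pos])
    return pd.DataFrame(rows, index=list(case.perturbations), columns=idx)


# ---------------------------------------------------------------------------
# Detectable wavelength range
# ---------------------------------------------------------------------------


def standard_bottom(grid=None) -> BottomSpectrum:
    """Equal-thirds mixture of coral sand, green and brown algae."""
    from .forward_models import mix_bottoms

    grid = np.arange(400.0, 701.0) if grid is None else np.asarray(grid, dtype=float)
    parts = [make_bottom(lbl, grid) for lbl in BOTTOM_LABELS]
    return mix_bottoms(parts, [1 / 3, 1 / 3, 1 / 3])


def detectable_wavelength_range(
    water: WaterType,
    bottom: BottomSpectrum,
    depths,
    cfg: ValidityConfig = DEFAULT_VALIDITY,
    geom: Geometry | None = None,
) -> dict[float, tuple[float, float] | None]:
    """Per-depth wavelength interval with bottom contribution >= threshold.

    Contribution follows the two-flow accounting with the true albedo.
    Returns {depth: (lambda_min, lambda_max)} with None when no wavelength
    passes; intervals are nested (never grow) as depth increases.
    """
    geom = geom or Geometry()
    grid = bottom.wavelengths
    iops = build_iops(water, geom, grid)
    deep = deep_water_reflectance(iops)
    out: dict[float, tuple[float, float] | None] = {}
    for z in depths:
        if z <= 0:
            raise ValueError("depths must be > 0")
        att = np.exp(-2.0 * iops.kd * z)
        rw = deep.r_inf + (bottom.values - deep.r_inf) * att
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (bottom.values - deep.r_inf) * att / rw
        ok = pct >= cfg.min_contribution_pct
        if not ok.any():
            out[float(z)] = None
            continue
        # longest contiguous run of passing wavelengths
        edges = np.flatnonzero(np.diff(np.concatenate(([0], ok.astype(int), [0]))))
        starts, stops = edges[::2], edges[1::2]
        best = np.argmax(stops - starts)
        out[float(z)] = (float(grid[starts[best]]), float(grid[stops[best] - 1]))
    return out


# ---------------------------------------------------------------------------
# Confusion matrix and the end-to-end inter-comparison
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMatrix:
    """True-class x assigned-class counts, order (sand, green, brown)."""

    counts: np.ndarray = field(default_factory=lambda: np.zeros((3, 3), dtype=int))
    class_order: tuple[str, ...] = BOTTOM_LABELS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        n = len(self.class_order)
        if self.counts.shape != (n, n) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative square matrix")

    def add(self, true_label: str, assigned_label: str, n: int = 1) -> None:
        i = self.class_order.index(true_label)
        j = self.class_order.index(assigned_label)
        self.counts[i, j] += n

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def accuracy_by_class(self) -> dict[str, float]:
        out = {}
        for i, lbl in enumerate(self.class_order):
            tot = self.counts[i].sum()
            out[lbl] = 100.0 * self.counts[i, i] / tot if tot else float("nan")
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order, columns=self.class_order)


def _render_queries(scenarios, grid, geom) -> tuple[np.ndarray, list[str], list[str]]:
    """Above-surface rrs of each scenario under the semi-analytical model."""
    specs = np.empty((len(scenarios), grid.size))
    labels, waters = [], []
    for i, sc in enumerate(scenarios):
        iops = build_iops(sc.water, geom, grid)
        deep = deep_water_reflectance(iops)
        below = l99_forward(sc, iops, deep)
        specs[i] = 0.5 * below.values / (1.0 - 1.5 * below.values)
        labels.append(sc.bottom.label)
        waters.append(sc.water.name)
    return specs, labels, waters


def run_intercomparison(
    seed: int = 0,
    n_seeds: int = 25,
    noise_level: float = 0.05,
    grid=None,
    library: SpectralLibrary | None = None,
    cfg: ValidityConfig = DEFAULT_VALIDITY,
) -> dict:
    """The full inter-comparison: round trips, cross-model uncertainty,
    and the seeded LUT/SAM classification experiment.

    Returns a report dict with:

    * ``scenario_count`` (48) and per-model round-trip max relative error;
    * ``cross_model`` — DataFrame of mean |uncertainty| per scenario when
      the semi-analytical model generates and the two-flow model inverts;
    * ``confusion`` — :class:`ConfusionMatrix` summed over ``n_seeds``
      noise realizations, ``accuracy_by_class`` averaged over seeds,
      ``confusion_noiseless`` control, and ``offdiag_by_water`` showing
      where the confusion occurs.
    """
    geom = Geometry()
    grid = np.arange(400.0, 701.0, 5.0) if grid is None else np.asarray(grid, dtype=float)
    scenarios = canonical_scenarios(grid)

    # -- same-model round trips ------------------------------------------
    max_rel = {"m94": 0.0, "l99": 0.0}
    cross_rows = []
    for sc in scenarios:
        iops = build_iops(sc.water, geom, grid)
        deep = deep_water_reflectance(iops)
        # round-trip error over valid wavelengths only: past the
        # exponential-regime threshold the attenuation factor underflows
        # and the inversion is (correctly) flagged, not assessed
        rw = m94_forward(sc, iops, deep)
        rho_m = m94_invert(rw, deep, iops.kd, sc.depth_z, cfg)
        ok = rho_m.valid_mask
        if ok.any():
            max_rel["m94"] = max(
                max_rel["m94"],
                float(np.max(np.abs(rho_m.rho_b[ok] - sc.bottom.values[ok]) / sc.bottom.values[ok])),
            )
        rrs = l99_forward(sc, iops, deep)
        rho_l = l99_invert(rrs, deep, iops, sc.depth_z, geom, cfg)
        ok = rho_l.valid_mask
        if ok.any():
            max_rel["l99"] = max(
                max_rel["l99"],
                float(np.max(np.abs(rho_l.rho_b[ok] - sc.bottom.values[ok]) / sc.bottom.values[ok])),
            )

        # -- cross-model: generate l99, invert m94 (Kd = k/mu_s) ---------
        rrs_as_r = Spectrum(grid, np.maximum(rrs.values, 0.0) * math.pi, Kind.R, Side.BELOW)
        res = m94_invert(rrs_as_r, deep, iops.kd, sc.depth_z, cfg)
        bottom_contribution_m94(res, deep, iops.kd, sc.depth_z, rrs_as_r)
        apply_validity(res, cfg)
        unc = retrieval_uncertainty(res, sc.bottom)
        valid = res.valid_mask & np.isfinite(unc)
        cross_rows.append(
            {
                "water": sc.water.name,
                "depth": sc.depth_z,
                "bottom": sc.bottom.label,
                "optical_path": float(np.mean(2.0 * iops.kd * sc.depth_z)),
                "valid_fraction": float(valid.mean()),
                "mean_abs_uncertainty_pct": float(np.mean(np.abs(unc[valid]))) if valid.any() else float("nan"),
            }
        )

    # -- LUT/SAM experiment ----------------------------------------------
    # The library is the constituent-grid product *plus* the 48 noiseless
    # scenario spectra themselves (the queries are their noisy versions).
    if library is None:
        bottoms = [make_bottom(lbl, grid) for lbl in BOTTOM_LABELS]
        library = build_library(
            canonical_library_waters(), LIBRARY_DEPTHS, bottoms,
            grid=grid, forward="l99", geom=geom,
        ).concat(
            build_library(
                [WATER_TYPES[w] for w in ("water-a", "water-b", "water-c", "water-d")],
                CANONICAL_DEPTHS, bottoms, grid=grid, forward="l99", geom=geom,
            )
        )
    queries, labels, waters = _render_queries(scenarios, grid, geom)
    lib_labels = library.labels

    best0, _ = classify_batch(queries, library)
    cm0 = ConfusionMatrix()
    for lbl, b in zip(labels, best0):
        cm0.add(lbl, lib_labels[b])

    rng_master = np.random.SeedSequence(seed)
    cm = ConfusionMatrix()
    acc_per_seed = []
    offdiag_by_water = {w: 0 for w in ("water-a", "water-b", "water-c", "water-d")}
    for child in rng_master.spawn(n_seeds):
        rng = np.random.default_rng(child)
        factor = np.maximum(1.0 + rng.normal(0.0, noise_level, size=queries.shape), 0.0)
        best, _ = classify_batch(queries * factor, library)
        cm_seed = ConfusionMatrix()
        for qi, (lbl, b) in enumerate(zip(labels, best)):
            assigned = lib_labels[b]
            cm_seed.add(lbl, assigned)
            if assigned != lbl:
                offdiag_by_water[waters[qi]] += 1
        cm.counts += cm_seed.counts
        acc_per_seed.append(cm_seed.accuracy_by_class())

    acc_mean = {
        lbl: float(np.mean([a[lbl] for a in acc_per_seed])) for lbl in BOTTOM_LABELS
    }

    return {
        "scenario_count": len(scenarios),
        "roundtrip_max_rel_error": max_rel,
        "cross_model": pd.DataFrame(cross_rows),
        "confusion": cm,
        "confusion_noiseless": cm0,
        "accuracy_by_class": acc_mean,
        "offdiag_by_water": offdiag_by_water,
        "n_seeds": n_seeds,
        "noise_level": noise_level,
        "library_size": len(library),
    }
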