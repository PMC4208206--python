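"""File formats, sensor bands, per-pixel raster application and fixtures.

All serialization is plain text: spectra as two-column tables with a
small header naming kind and side, scenes as whitespace-separated grids,
spectral libraries as CSV (via :meth:`SpectralLibrary.to_frame`).  Readers
and writers round-trip losslessly on their own output.

"Raster" scenes are in-memory numpy arrays (bands, rows, cols) with a
co-registered bathymetry layer; georeferencing is carried as an opaque
metadata dict so scenes survive a write/read cycle unchanged.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .forward_models import (
    BOTTOM_LABELS,
    CANONICAL_DEPTHS,
    canonical_scenarios,
    deep_water_reflectance,
    l99_forward,
    m94_forward,
    make_bottom,
)
from .matching import add_noise
from .optics_core import (
    Geometry,
    Kind,
    Side,
    Spectrum,
    WATER_TYPES,
    build_iops,
    convert_interface,
)
from .validity import DEFAULT_VALIDITY, FLAGS, ValidityConfig

__all__ = [
    "BandSet",
    "PixelScene",
    "band_integrate",
    "extract_deep_reference",
    "apply_corrector_to_scene",
    "read_spectrum",
    "write_spectrum",
    "write_scene",
    "read_scene",
    "make_synthetic_scene",
    "generate_fixtures",
    "NODATA",
]

#: No-data value written into corrected rasters (declared in scene headers).
NODATA = -9999.0


@dataclass(frozen=True)
class BandSet:
    """Sensor band definition: centers plus half-open edge intervals [lo, hi).

    The WorldView-2 preset has centers 427/478/546/608/659/724/831/908 nm;
    water-column correction work is restricted to bands with center
    <= 700 nm (five bands for WV02).
    """

    centers: tuple[float, ...]
    edges: tuple[tuple[float, float], ...]
    sensor: str = "custom"

    def __post_init__(self) -> None:
        prev_hi = -np.inf
        for c, (lo, hi) in zip(self.centers, self.edges):
            if not lo <= c < hi:
                raise ValueError("band center must lie inside its edges")
            if lo < prev_hi:
                raise ValueError("band intervals must be non-overlapping and increasing")
            prev_hi = hi

    @classmethod
    def worldview2(cls) -> "BandSet":
        centers = (427.0, 478.0, 546.0, 608.0, 659.0, 724.0, 831.0, 908.0)
        # edges: midpoints between adjacent centers, outermost clipped
        mids = [(a + b) / 2 for a, b in zip(centers[:-1], centers[1:])]
        lo = [400.0] + mids
        hi = mids + [950.0]
        return cls(centers, tuple(zip(lo, hi)), sensor="WV02")

    def visible(self, max_center: float = 700.0) -> "BandSet":
        """Restrict to bands whose center is at/below ``max_center`` nm."""
        keep = [i for i, c in enumerate(self.centers) if c <= max_center]
        return BandSet(
            tuple(self.centers[i] for i in keep),
            tuple(self.edges[i] for i in keep),
            sensor=self.sensor,
        )

    def __len__(self) -> int:
        return len(self.centers)


def band_integrate(s: Spectrum, bands: BandSet) -> np.ndarray:
    """Boxcar band integration: unweighted mean of the spectrum over each
    band interval [lo, hi).

    The spectrum must cover every interval; a coverage gap raises an error
    naming the band.
    """
    out = np.empty(len(bands))
    wl = s.wavelengths
    for i, (c, (lo, hi)) in enumerate(zip(bands.centers, bands.edges)):
        if lo < wl[0] or hi > wl[-1] + (wl[-1] - wl[-2] if wl.size > 1 else 0):
            raise ValueError(f"spectrum does not cover band {i} ({c:g} nm: [{lo:g}, {hi:g}))")
        sel = (wl >= lo) & (wl < hi)
        if not sel.any():
            raise ValueError(f"no spectrum samples inside band {i} ({c:g} nm)")
        out[i] = s.values[sel].mean()
    return out


@dataclass
class PixelScene:
    """Multiband image with a co-registered bathymetry layer.

    ``image`` has shape (n_bands, rows, cols); ``bathymetry`` (m, positive
    down) shape (rows, cols), NaN where depth is unknown.  Depths are
    corrected by ``tide_offset`` (signed, m) before any correction is
    applied.  ``mask`` marks land/cloud pixels to skip.
    """

    image: np.ndarray
    bathymetry: np.ndarray
    deep_reference: np.ndarray
    band_centers: tuple[float, ...]
    tide_offset: float = 0.0
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=float)
        self.bathymetry = np.asarray(self.bathymetry, dtype=float)
        self.deep_reference = np.asarray(self.deep_reference, dtype=float)
        if self.image.ndim != 3:
            raise ValueError("image must be (bands, rows, cols)")
        if self.bathymetry.shape != self.image.shape[1:]:
            raise ValueError("bathymetry must be co-registered with the image")
        if self.deep_reference.size != self.image.shape[0]:
            raise ValueError("one deep-reference value per band required")
        if self.mask is not None and self.mask.shape != self.bathymetry.shape:
            raise ValueError("mask must be co-registered with the image")

    @property
    def depths(self) -> np.ndarray:
        return self.bathymetry + self.tide_offset


def extract_deep_reference(scene: PixelScene, deep_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-band mean (and sd, for QC) over analyst-selected deep pixels."""
    deep_mask = np.asarray(deep_mask, dtype=bool)
    if not deep_mask.any():
        raise ValueError("deep mask selects no pixels")
    px = scene.image[:, deep_mask]
    return px.mean(axis=1), px.std(axis=1)


def apply_corrector_to_scene(
    scene: PixelScene,
    corrector: str,
    kd=None,
    iops_per_band=None,
    cfg: ValidityConfig = DEFAULT_VALIDITY,
    geom: Geometry | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel water-column correction of a multiband scene.

    ``corrector`` is ``"m94"`` (needs per-band ``kd``) or ``"l99"`` (needs
    ``iops_per_band = (a, bb)``).  Pixels without depth, or masked, become
    ``NODATA``; the returned flag raster encodes the validity rules as bit
    codes (bit i = FLAGS[i], bit 7 = no data).  Output is independent of
    pixel visitation order (fully vectorized).
    """
    geom = geom or Geometry()
    nb, nr, nc = scene.image.shape
    z = scene.depths
    nodata = ~np.isfinite(z) | (z <= 0)
    if scene.mask is not None:
        nodata |= scene.mask
    if corrector == "m94":
        if kd is None:
            raise ValueError("m94 requires per-band Kd")
        kd = np.asarray(kd, dtype=float).reshape(nb, 1, 1)
        att = np.exp(-2.0 * kd * z[None, :, :])
        deep = scene.deep_reference.reshape(nb, 1, 1)
        rho = (scene.image - deep) / att + deep
        expo = att < cfg.exponential_threshold
    elif corrector == "l99":
        if iops_per_band is None:
            raise ValueError("l99 requires per-band (a, bb)")
        from .forward_models import du_b, du_c

        a, bb = (np.asarray(v, dtype=float).reshape(nb, 1, 1) for v in iops_per_band)
        k = a + bb
        u = bb / k
        col = np.exp(-(1.0 / geom.mu_s + du_c(u) / geom.mu_v) * k * z[None, :, :])
        bot = np.exp(-(1.0 / geom.mu_s + du_b(u) / geom.mu_v) * k * z[None, :, :])
        deep = scene.deep_reference.reshape(nb, 1, 1)
        rho = math.pi * (scene.image - deep * (1.0 - col)) / bot
        expo = bot < cfg.exponential_threshold
    else:
        raise ValueError(f"unknown corrector {corrector!r} for scene application")

    lo, hi = cfg.rho_b_range
    flags = np.zeros((nb, nr, nc), dtype=np.uint8)
    flags |= np.uint8(1 << FLAGS.index("out_of_range")) * ((rho <= lo) | (rho >= hi))
    flags |= np.uint8(1 << FLAGS.index("exponential_regime")) * expo
    flags |= np.uint8(128) * nodata[None, :, :]
    rho = np.where(nodata[None, :, :], NODATA, rho)
    return rho, flags


# ---------------------------------------------------------------------------
# Plain-text serialization
# ---------------------------------------------------------------------------


def write_spectrum(s: Spectrum, path) -> None:
    """Two-column table (wavelength_nm, value) with a kind/side header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind: {s.kind}\n# side: {s.side}\n")
        for w, v in zip(s.wavelengths, s.values):
            fh.write(f"{w:.17g} {v:.17g}\n")  # .17g round-trips float64 exactly


def read_spectrum(path) -> Spectrum:
    path = Path(path)
    kind = side = None
    wl, vals = [], []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                if key.strip() == "kind":
                    kind = val.strip()
                elif key.strip() == "side":
                    side = val.strip()
            elif line:
                w, v = line.split()
                wl.append(float(w))
                vals.append(float(v))
    if kind is None or side is None:
        raise ValueError(f"{path}: missing kind/side header")
    return Spectrum(np.array(wl), np.array(vals), kind, side)


def write_scene(scene: PixelScene, path) -> None:
    """Whitespace-separated text serialization of a scene (lossless)."""
    path = Path(path)
    nb, nr, nc = scene.image.shape
    header = {
        "bands": nb,
        "rows": nr,
        "cols": nc,
        "band_centers": list(scene.band_centers),
        "deep_reference": [float(v) for v in scene.deep_reference],
        "tide_offset": scene.tide_offset,
        "nodata": NODATA,
        "meta": scene.meta,
        "has_mask": scene.mask is not None,
    }
    with path.open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        np.savetxt(fh, scene.image.reshape(nb * nr, nc), fmt="%.17g")
        np.savetxt(fh, scene.bathymetry, fmt="%.17g")
        if scene.mask is not None:
            np.savetxt(fh, scene.mask.astype(int), fmt="%d")


def read_scene(path) -> PixelScene:
    path = Path(path)
    with path.open() as fh:
        header = json.loads(fh.readline())
        data = np.loadtxt(fh)
    nb, nr, nc = header["bands"], header["rows"], header["cols"]
    image = data[: nb * nr].reshape(nb, nr, nc)
    bathy = data[nb * nr : nb * nr + nr]
    mask = data[nb * nr + nr :].astype(bool) if header["has_mask"] else None
    return PixelScene(
        image,
        bathy,
        np.array([float(v) for v in header["deep_reference"]]),
        tuple(header["band_centers"]),
        tide_offset=header["tide_offset"],
        mask=mask,
        meta=header["meta"],
    )


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------


def make_synthetic_scene(
    seed: int = 0,
    shape: tuple[int, int] = (16, 16),
    water: str = "water-b",
    bands: BandSet | None = None,
) -> PixelScene:
    """Small synthetic multiband scene with a depth gradient.

    Per-pixel two-flow forward simulation over a random sand/algae bottom
    patchwork, band-integrated to the (visible) sensor bands; depths ramp
    from 1 m to 15 m across rows.  Used by tests and the fixtures command.
    """
    rng = np.random.default_rng(seed)
    bands = (bands or BandSet.worldview2()).visible()
    grid = np.arange(400.0, 701.0)
    geom = Geometry()
    iops = build_iops(WATER_TYPES[water], geom, grid)
    deep = deep_water_reflectance(iops)
    bottoms = [make_bottom(lbl, grid) for lbl in BOTTOM_LABELS]

    kd_b = np.array([band_integrate(Spectrum(grid, iops.kd, Kind.R, Side.NA), bands)]).ravel()
    deep_b = band_integrate(Spectrum(grid, deep.r_inf, Kind.R, Side.BELOW), bands)
    rho_b = np.stack(
        [band_integrate(b.as_spectrum(), bands) for b in bottoms]
    )  # (n_bottoms, n_bands)

    nr, nc = shape
    depth = np.linspace(1.0, 15.0, nr)[:, None] * np.ones((1, nc))
    which = rng.integers(0, len(bottoms), size=shape)
    att = np.exp(-2.0 * kd_b[:, None, None] * depth[None, :, :])
    rho_px = rho_b[which].transpose(2, 0, 1)  # (n_bands, nr, nc)
    image = deep_b[:, None, None] + (rho_px - deep_b[:, None, None]) * att
    return PixelScene(
        image,
        depth,
        deep_b,
        bands.centers,
        meta={"water": water, "bottom_index": which.tolist(), "generator": "m94"},
    )


def generate_fixtures(seed: int = 0, outdir="fixtures") -> dict:
    """Write the canonical dataset: 48 scenario spectra (both models,
    above/below surface), noisy versions, IOP tables, bottom spectra, a
    synthetic raster scene and the library configuration.  Deterministic
    for a fixed seed; returns {relative path: sha256}.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geom = Geometry()
    grid = np.arange(400.0, 701.0, 5.0)
    hashes: dict[str, str] = {}

    def record(path: Path) -> None:
        hashes[str(path.relative_to(outdir))] = hashlib.sha256(path.read_bytes()).hexdigest()

    for lbl in BOTTOM_LABELS:
        p = outdir / f"bottom_{lbl}.txt"
        write_spectrum(make_bottom(lbl, grid).as_spectrum(), p)
        record(p)

    for wname, water in WATER_TYPES.items():
        iops = build_iops(water, geom, grid)
        p = outdir / f"iops_{wname}.csv"
        with p.open("w") as fh:
            fh.write("wavelength_nm,a,bb,u,k,kd\n")
            for i, w in enumerate(grid):
                fh.write(
                    f"{w:.17g},{iops.a[i]:.17g},{iops.bb[i]:.17g},"
                    f"{iops.u[i]:.17g},{iops.k[i]:.17g},{iops.kd[i]:.17g}\n"
                )
        record(p)

    rng = np.random.SeedSequence(seed)
    noise_streams = iter(rng.spawn(len(canonical_scenarios(grid))))
    for sc in canonical_scenarios(grid):
        iops = build_iops(sc.water, geom, grid)
        deep = deep_water_reflectance(iops)
        stem = f"{sc.water.name}_z{sc.depth_z:g}_{sc.bottom.label}"
        rw = m94_forward(sc, iops, deep)
        write_spectrum(rw, outdir / f"m94_R_below_{stem}.txt")
        record(outdir / f"m94_R_below_{stem}.txt")
        rrs = l99_forward(sc, iops, deep)
        write_spectrum(rrs, outdir / f"l99_rrs_below_{stem}.txt")
        record(outdir / f"l99_rrs_below_{stem}.txt")
        above = convert_interface(rrs, "below_to_above")
        write_spectrum(above, outdir / f"l99_rrs_above_{stem}.txt")
        record(outdir / f"l99_rrs_above_{stem}.txt")
        noisy = add_noise(above, 0.05, np.random.default_rng(next(noise_streams)))
        write_spectrum(noisy, outdir / f"l99_rrs_above_noisy_{stem}.txt")
        record(outdir / f"l99_rrs_above_noisy_{stem}.txt")

    scene = make_synthetic_scene(seed=seed)
    write_scene(scene, outdir / "scene.txt")
    record(outdir / "scene.txt")

    config = {
        "waters": {name: vars(w) for name, w in WATER_TYPES.items()},
        "depths": list(CANONICAL_DEPTHS),
        "bottoms": list(BOTTOM_LABELS),
        "library": {
            "chl": "canonical 16-point grid",
            "acdom440": "canonical 7-point grid",
            "particles_ii": "canonical 7-point grid",
            "depths_m": [1, 16],
            "forward_model": "l99",
        },
        "noise_level": 0.05,
        "seed": seed,
    }
    with (outdir / "library_config.yaml").open("w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    record(outdir / "library_config.yaml")
    return hashes
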