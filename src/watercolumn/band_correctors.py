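"""Band-combination (depth-invariant index) algorithms and PIF normalization.

These methods operate on multiband samples (per-pixel radiances or
reflectances) rather than full spectra.  They all start from the
deep-water-subtracted signal ``v_i - deep_i``: under a single-exponential
attenuation model its logarithm is linear in depth, which is what every
index in this family exploits.  The math is identical whether the inputs
are top-of-atmosphere radiances with a deep-water reference or
atmospherically corrected reflectances.

Pixels where ``v_i <= deep_i`` (log undefined) are *flagged*, never
silently dropped: index outputs carry NaN there and the flagged indices
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BandSampleSet",
    "KdRatio",
    "FlaggedPixelError",
    "estimate_kd_ratio",
    "lyzenga_index",
    "spitzer_dirks_indices",
    "tassan_classify",
    "sagawa_index",
    "conger_rotation",
    "pif_normalize",
]


class FlaggedPixelError(ValueError):
    """Raised when an operation cannot proceed because of flagged pixels.

    Carries the offending pixel indices in ``pixels``.
    """

    def __init__(self, message: str, pixels: np.ndarray):
        super().__init__(f"{message}: pixels {pixels.tolist()}")
        self.pixels = pixels


@dataclass
class BandSampleSet:
    """Per-pixel, per-band samples with a deep-water reference.

    ``values`` has shape (n_pixels, n_bands); ``deep_reference`` is the
    per-band deep-water value (subtracted before any log transform).
    ``depths`` (m) and ``substrate_label`` are optional per-pixel metadata.
    """

    values: np.ndarray
    deep_reference: np.ndarray
    depths: np.ndarray | None = None
    substrate_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.deep_reference = np.asarray(self.deep_reference, dtype=float)
        if self.values.shape[1] != self.deep_reference.size:
            raise ValueError("deep_reference must have one value per band")
        if self.values.shape[1] < 2:
            raise ValueError("at least 2 bands required")
        if self.depths is not None:
            self.depths = np.asarray(self.depths, dtype=float)
            if self.depths.size != self.n_pixels:
                raise ValueError("depths must have one value per pixel")
        if self.substrate_label is not None:
            self.substrate_label = np.asarray(self.substrate_label)

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def log_difference(self, band: int) -> np.ndarray:
        """ln(v - deep) for one band, NaN where the difference is <= 0."""
        diff = self.values[:, band] - self.deep_reference[band]
        out = np.full(diff.shape, np.nan)
        ok = diff > 0
        out[ok] = np.log(diff[ok])
        return out

    def flagged_pixels(self, bands) -> np.ndarray:
        """Indices of pixels at/below the deep reference in any listed band."""
        bad = np.zeros(self.n_pixels, dtype=bool)
        for b in bands:
            bad |= self.values[:, b] - self.deep_reference[b] <= 0
        return np.nonzero(bad)[0]


@dataclass(frozen=True)
class KdRatio:
    """Attenuation-coefficient ratio Kd_i/Kd_j estimated by regression."""

    ratio: float
    band_pair: tuple[int, int]
    fit_r2: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be > 0")
        if not 0.0 <= self.fit_r2 <= 1.0 + 1e-12:
            raise ValueError("fit_r2 must lie in [0, 1]")


def estimate_kd_ratio(samples: BandSampleSet, band_i: int, band_j: int) -> KdRatio:
    """Slope of ln(v_i - deep_i) on ln(v_j - deep_j) over same-substrate pixels.

    For pixels of one substrate spanning several depths under a
    single-exponential model, this slope is the attenuation ratio
    Kd_i/Kd_j.
    """
    if samples.n_pixels < 3:
        raise ValueError("need at least 3 same-substrate pixels")
    bad = samples.flagged_pixels([band_i, band_j])
    if bad.size:
        raise FlaggedPixelError("values at/below deep reference", bad)
    xi = samples.log_difference(band_i)
    xj = samples.log_difference(band_j)
    if band_i == band_j:
        return KdRatio(1.0, (band_i, band_j), 1.0)
    if np.ptp(xj) == 0:
        raise ValueError("no depth spread in band j (degenerate regression)")
    res = stats.linregress(xj, xi)
    r2 = min(float(res.rvalue) ** 2, 1.0)
    return KdRatio(float(res.slope), (band_i, band_j), r2)


def lyzenga_index(samples: BandSampleSet, ratio: KdRatio) -> np.ndarray:
    """Depth-invariant index for a band pair.

    ``index = ln(v_i - deep_i) - (Kd_i/Kd_j) ln(v_j - deep_j)``

    One substrate maps to one index value regardless of depth (when the
    generating model is single-exponential); flagged pixels yield NaN.
    """
    i, j = ratio.band_pair
    return samples.log_difference(i) - ratio.ratio * samples.log_difference(j)


def spitzer_dirks_indices(
    samples: BandSampleSet,
    h_b1: float = 0.0,
    h_b2: float = 0.0,
    h_b3: float = 0.0,
) -> np.ndarray:
    """Three fixed-coefficient indices for the renamed visible bands 1..3.

    Bands are (blue, green, red) = columns 0, 1, 2::

        index_b1 = ln d2 - 0.30 ln d3 + h_b1
        index_b2 = ln d1 + ln d2 - 0.60 ln d3 + h_b2
        index_b3 = ln d2 - 1.05 ln d1 + h_b3

    where ``d_k = v_k - deep_k``.  Returns shape (n_pixels, 3).
    """
    if samples.n_bands < 3:
        raise ValueError("three visible bands (blue, green, red) required")
    d1 = samples.log_difference(0)
    d2 = samples.log_difference(1)
    d3 = samples.log_difference(2)
    b1 = d2 - 0.30 * d3 + h_b1
    b2 = d1 + d2 - 0.60 * d3 + h_b2
    b3 = d2 - 1.05 * d1 + h_b3
    return np.column_stack([b1, b2, b3])


def tassan_classify(
    samples: BandSampleSet,
    low_albedo_ratio: KdRatio,
    high_albedo_ratio: KdRatio,
    training: dict[str, "BandSampleSet"] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential two-slope partition for scenes with high/low albedo bottoms.

    Computes the pair of indices ``X'_ij = X'_i - slope * X'_j`` with the
    slope fitted on the low- and the high-albedo training substrate
    respectively, then partitions pixels by thresholding each index at the
    midpoint between the training-class index means (simplest reproducible
    reading of the method's unspecified "statistical analysis" step).

    Returns ``(index_pair, labels)`` where ``index_pair`` has shape
    (n_pixels, 2) and ``labels`` is 0 for the high-albedo class and 1 for
    the low-albedo class.  Training sets must be substrate-labelled; when
    ``training`` is None the sample set's own labels (exactly two) are
    used.
    """
    if training is None:
        if samples.substrate_label is None:
            raise ValueError("substrate-labelled training data required")
        labels = np.unique(samples.substrate_label)
        if labels.size != 2:
            raise ValueError("exactly two training substrates required")
        training = {
            str(lbl): BandSampleSet(
                samples.values[samples.substrate_label == lbl],
                samples.deep_reference,
            )
            for lbl in labels
        }
    idx_low = lyzenga_index(samples, low_albedo_ratio)
    idx_high = lyzenga_index(samples, high_albedo_ratio)
    pair = np.column_stack([idx_low, idx_high])

    means = {}
    for name, tset in training.items():
        means[name] = (
            np.nanmean(lyzenga_index(tset, low_albedo_ratio)),
            np.nanmean(lyzenga_index(tset, high_albedo_ratio)),
        )
    names = sorted(means)
    # high-albedo class = the one with larger mean low-albedo-slope index
    hi_name, lo_name = sorted(names, key=lambda n: -means[n][0])
    thr_low = 0.5 * (means[hi_name][0] + means[lo_name][0])
    labels_out = np.where(idx_low >= thr_low, 0, 1)
    return pair, labels_out


def sagawa_index(
    samples: BandSampleSet,
    kd=None,
    q: float = 2.0,
    depths=None,
) -> np.ndarray:
    """Bottom-reflectance-proportional index using known depths.

    ``index_i = (v_i - deep_i) / exp(-Kd_i q z)``; the depth attenuation is
    divided out so the index is proportional to rho_b with a constant
    factor per band.  ``Kd*q`` can be given (``kd`` per band times the
    geometric factor ``q``, default 2 = two-way nadir path) or estimated by
    regressing ln(v - deep) on z over a homogeneous substrate when ``kd``
    is None.
    """
    z = depths if depths is not None else samples.depths
    if z is None:
        raise ValueError("depths required for the Sagawa index")
    z = np.asarray(z, dtype=float)
    if z.size != samples.n_pixels:
        raise ValueError("one depth per pixel required")
    if kd is None:
        kdq = np.empty(samples.n_bands)
        for b in range(samples.n_bands):
            ln_d = samples.log_difference(b)
            ok = np.isfinite(ln_d)
            if ok.sum() < 3:
                raise ValueError("need >= 3 unflagged pixels to estimate Kd*q")
            res = stats.linregress(z[ok], ln_d[ok])
            kdq[b] = -res.slope
    else:
        kdq = np.asarray(kd, dtype=float) * q
    diff = samples.values - samples.deep_reference
    out = np.where(diff > 0, diff, np.nan) / np.exp(-np.outer(z, np.ones(samples.n_bands)) * kdq)
    return out


def conger_rotation(samples: BandSampleSet, band_i: int = 0, band_j: int = 1) -> np.ndarray:
    """Principal-axis rotation of a log-difference band pair.

    PCA on {ln(v_i - deep_i), ln(v_j - deep_j)}: the first component
    captures the common depth attenuation, the second is returned as the
    depth-independent pseudo-band.  Output shape (n_pixels, 2) =
    (depth axis score, pseudo-band); invariant to pixel ordering.
    """
    if samples.n_pixels < 3:
        raise ValueError("need at least 3 pixels")
    x = np.column_stack([samples.log_difference(band_i), samples.log_difference(band_j)])
    ok = np.all(np.isfinite(x), axis=1)
    if ok.sum() < 3:
        raise ValueError("need at least 3 unflagged pixels")
    mu = x[ok].mean(axis=0)
    cov = np.cov((x[ok] - mu).T)
    if not np.all(np.isfinite(cov)) or np.allclose(cov, 0):
        raise ValueError("singular covariance (constant image)")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    # deterministic sign: depth axis points along +x
    for c in range(2):
        if evecs[np.argmax(np.abs(evecs[:, c])), c] < 0:
            evecs[:, c] = -evecs[:, c]
    return (x - mu) @ evecs


def pif_normalize(reference_pif, target_pif) -> tuple[np.ndarray, np.ndarray]:
    """Per-band gain/offset mapping a target image onto a reference image.

    Least-squares line through pseudo-invariant-feature (PIF) samples:
    ``reference ~= gain * target + offset`` per band.  Requires >= 2
    distinct samples per band spanning bright and dark targets.

    Returns ``(gain, offset)`` arrays of length n_bands.
    """
    ref = np.atleast_2d(np.asarray(reference_pif, dtype=float))
    tgt = np.atleast_2d(np.asarray(target_pif, dtype=float))
    if ref.shape != tgt.shape:
        raise ValueError("reference and target PIF tables must have equal shape")
    if ref.shape[0] < 2:
        raise ValueError("need at least 2 PIF samples")
    n_bands = ref.shape[1]
    gain = np.empty(n_bands)
    offset = np.empty(n_bands)
    for b in range(n_bands):
        if np.ptp(tgt[:, b]) == 0:
            raise ValueError("PIF samples must span distinct values (bright and dark)")
        res = stats.linregress(tgt[:, b], ref[:, b])
        gain[b] = res.slope
        offset[b] = res.intercept
    return gain, offset
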