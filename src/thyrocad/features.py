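"""First-order texture features and the GLCM (Haralick) baseline.

The six first-order features — entropy ``e``, uniformity ``u``, mean
intensity ``m``, standard deviation ``sd``, excess kurtosis ``k`` and
skewness ``s`` — describe the histogram of HU values inside one ROI and
ignore spatial arrangement.  Homogeneous normal thyroid tissue yields low
entropy / high uniformity; nodules (necrosis, cysts, calcification) yield
the opposite.

Entropy and uniformity are functions of a binned gray-level histogram
``p(l)``; the moments are computed directly on the pixel values with the
bias-corrected sample conventions:

    e  = -sum_l p(l) log2 p(l)            (0*log 0 := 0)
    u  =  sum_l p(l)^2
    m  = (1/n) sum a
    sd = sqrt( sum (a - abar)^2 / (n-1) )
    s  = n / ((n-1)(n-2)) * sum ((a - abar)/sd)^3
    k  = n(n+1) / ((n-1)(n-2)(n-3)) * sum ((a - abar)/sd)^4
         - 3 (n-1)^2 / ((n-2)(n-3))

``k`` is *excess* kurtosis: 0 for a Gaussian.  When ``sd == 0`` (constant
ROI) skewness and kurtosis are reported as 0 with a degeneracy flag so that
constant phantoms survive the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging_io import CTImage, ROIMask, ROISample

__all__ = [
    "HistogramModel",
    "FeatureVector",
    "FIRST_ORDER_NAMES",
    "GLCM_FEATURE_NAMES",
    "DEFAULT_N_BINS",
    "FIXED_HU_RANGE",
    "histogram_probabilities",
    "extract_first_order",
    "glcm_features",
]

FIRST_ORDER_NAMES = ("e", "u", "m", "sd", "k", "s")

#: 8-bit quantization, the de facto standard for first-order radiomics.
DEFAULT_N_BINS = 256

#: Alternative fixed binning range covering the full 12-bit CT HU scale.
FIXED_HU_RANGE = (-1024.0, 3071.0)


@dataclass
class HistogramModel:
    """Equal-width gray-level histogram of an ROI: ``p[l]``, ``l = 0..k-1``."""

    edges: np.ndarray
    p: np.ndarray

    @property
    def k(self) -> int:
        return int(self.p.size)


@dataclass
class FeatureVector:
    e: float
    u: float
    m: float
    sd: float
    k: float
    s: float
    group_tag: str = "non-filter"
    degenerate: bool = False

    def as_dict(self) -> dict[str, float]:
        return {"e": self.e, "u": self.u, "m": self.m, "sd": self.sd,
                "k": self.k, "s": self.s}


def histogram_probabilities(roi: ROISample, n_bins: int = DEFAULT_N_BINS,
                            range_policy: str = "roi_minmax") -> HistogramModel:
    """Bin the ROI values into ``n_bins`` equal-width bins and normalize.

    ``range_policy="roi_minmax"`` spans the ROI's own min-max (a constant ROI
    degenerates to a single occupied bin); ``"fixed_hu"`` uses the full CT
    scale [-1024, 3071] HU.  The rightmost bin is closed.
    """
    if roi.n < 1:
        raise ValueError("empty ROI")
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    v = roi.values
    if range_policy == "roi_minmax":
        lo, hi = float(v.min()), float(v.max())
        if lo == hi:
            edges = np.linspace(lo - 0.5, lo + 0.5, n_bins + 1)
            p = np.zeros(n_bins)
            p[0] = 1.0
            return HistogramModel(edges=edges, p=p)
    elif range_policy == "fixed_hu":
        lo, hi = FIXED_HU_RANGE
    else:
        raise ValueError(f"unknown range_policy {range_policy!r}")
    counts, edges = np.histogram(v, bins=n_bins, range=(lo, hi))
    return HistogramModel(edges=edges, p=counts / roi.n)


def extract_first_order(roi: ROISample, hist: HistogramModel | None = None,
                        n_bins: int = DEFAULT_N_BINS,
                        range_policy: str = "roi_minmax") -> FeatureVector:
    """Compute the six first-order features of one ROI sample.

    Requires ``n >= 4`` (the kurtosis denominator contains ``n - 3``); with
    fewer pixels the higher moments are not estimable and an error is raised
    rather than fabricating values.
    """
    n = roi.n
    if n < 4:
        raise ValueError(f"ROI has {n} pixels; >= 4 required for kurtosis")
    if hist is None:
        hist = histogram_probabilities(roi, n_bins=n_bins, range_policy=range_policy)

    p = hist.p[hist.p > 0]
    e = float(-(p * np.log2(p)).sum())
    u = float((hist.p ** 2).sum())

    a = roi.values
    m = float(a.mean())
    dev = a - m
    sd = float(math.sqrt((dev ** 2).sum() / (n - 1)))

    degenerate = sd == 0.0
    if degenerate:
        s = 0.0
        k = 0.0
    else:
        z = dev / sd
        s = n / ((n - 1) * (n - 2)) * float((z ** 3).sum())
        k = (n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * float((z ** 4).sum())
             - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3)))

    return FeatureVector(e=e, u=u, m=m, sd=sd, k=k, s=s,
                         group_tag=roi.group_tag, degenerate=degenerate)


# --------------------------------------------------------------------------
# GLCM baseline

GLCM_FEATURE_NAMES = (
    "angular_second_moment",
    "correlation",
    "entropy",
    "contrast",
    "inverse_difference_moment",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "variance",
    "difference_average",
    "inertia",
    "difference_variance",
    "difference_entropy",
)

#: Distance-1 offsets at 0, 45, 90 and 135 degrees (row, col deltas).
DEFAULT_OFFSETS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


def _quantize(values: np.ndarray, levels: int) -> np.ndarray:
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros(values.shape, dtype=np.intp)
    q = np.floor((values - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm_features(roi_image: CTImage, mask: ROIMask, levels: int = 64,
                  offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
                  ) -> dict[str, float]:
    """Haralick features from a masked gray-level co-occurrence matrix.

    Pixels inside the mask are quantized to ``levels`` gray levels over the
    ROI min-max.  A pair contributes only when *both* pixels lie inside the
    mask.  Counts are accumulated over all offsets, symmetrized, and
    normalized to sum 1 before the 13 statistics are computed.  ``contrast``
    and ``inertia`` share one formula and are reported under both names.
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    inside = mask.inside
    if inside.shape != roi_image.pixels.shape:
        raise ValueError("mask / image shape mismatch")
    if not inside.any():
        raise ValueError("empty ROI")

    quant = np.zeros(inside.shape, dtype=np.intp)
    quant[inside] = _quantize(roi_image.pixels[inside], levels)

    cm = np.zeros((levels, levels), dtype=float)
    rows, cols = inside.shape
    for dr, dc in offsets:
        r0s, r0e = max(0, -dr), min(rows, rows - dr)
        c0s, c0e = max(0, -dc), min(cols, cols - dc)
        src = np.s_[r0s:r0e, c0s:c0e]
        dst = np.s_[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
        valid = inside[src] & inside[dst]
        if not valid.any():
            continue
        i = quant[src][valid]
        j = quant[dst][valid]
        np.add.at(cm, (i, j), 1.0)
    if cm.sum() == 0:
        raise ValueError("no valid pixel pair inside the mask for any offset")
    cm = cm + cm.T  # symmetrize
    p = cm / cm.sum()

    lv = np.arange(levels, dtype=float)
    pi = p.sum(axis=1)  # marginal over rows (== cols by symmetry)
    mu = float((lv * pi).sum())
    sigma2 = float(((lv - mu) ** 2 * pi).sum())
    sigma = math.sqrt(sigma2)

    ii, jj = np.meshgrid(lv, lv, indexing="ij")
    nz = p > 0

    asm = float((p ** 2).sum())
    entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    if sigma > 0:
        correlation = float(((ii - mu) * (jj - mu) * p).sum() / sigma2)
    else:
        correlation = 1.0  # constant ROI: perfectly correlated by convention

    # sum (i+j) and difference |i-j| distributions
    ksum = np.arange(2 * levels - 1, dtype=float)
    p_sum = np.bincount((ii + jj).astype(np.intp).ravel(),
                        weights=p.ravel(), minlength=2 * levels - 1)
    kdiff = np.arange(levels, dtype=float)
    p_diff = np.bincount(np.abs(ii - jj).astype(np.intp).ravel(),
                         weights=p.ravel(), minlength=levels)

    sum_avg = float((ksum * p_sum).sum())
    snz = p_sum > 0
    sum_entropy = float(-(p_sum[snz] * np.log2(p_sum[snz])).sum())
    sum_variance = float(((ksum - sum_avg) ** 2 * p_sum).sum())
    diff_avg = float((kdiff * p_diff).sum())
    dnz = p_diff > 0
    diff_entropy = float(-(p_diff[dnz] * np.log2(p_diff[dnz])).sum())
    diff_variance = float(((kdiff - diff_avg) ** 2 * p_diff).sum())

    return {
        "angular_second_moment": asm,
        "correlation": correlation,
        "entropy": entropy,
        "contrast": contrast,
        "inverse_difference_moment": idm,
        "sum_average": sum_avg,
        "sum_entropy": sum_entropy,
        "sum_variance": sum_variance,
        "variance": sigma2,
        "difference_average": diff_avg,
        "inertia": contrast,
        "difference_variance": diff_variance,
        "difference_entropy": diff_entropy,
    }
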