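"""3x3 denoising filter bank: average, median and adaptive Wiener filters.

CT photon noise masks the genuine tissue heterogeneity that first-order
texture features quantify, so each slice can be smoothed before the masked
pixels are gathered.  Filtering always runs on the *full* slice and the mask
is applied afterwards; smoothing a masked product would blend artificial
background values across the ROI boundary.

Borders are handled by edge replication (``mode="nearest"``), which avoids
darkening at the image edge.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .imaging_io import CTImage

__all__ = [
    "FilterSpec",
    "FILTER_KINDS",
    "average_filter",
    "median_filter",
    "wiener_filter",
    "apply_filter",
    "build_filter_bank",
]

FILTER_KINDS = ("none", "average", "median", "wiener")

#: Filter kind -> group tag used in feature-table column suffixes.
#: Group 1 = wiener, 2 = median, 3 = average, 4 = unfiltered.
GROUP_TAGS = {"wiener": "W6", "median": "M6", "average": "A6", "none": "non-filter"}
GROUP_INDEX = {"wiener": 1, "median": 2, "average": 3, "none": 4}


@dataclass(frozen=True)
class FilterSpec:
    kind: str = "none"
    window: int = 3

    def __post_init__(self) -> None:
        if self.kind not in FILTER_KINDS:
            raise ValueError(f"kind must be one of {FILTER_KINDS}, got {self.kind!r}")
        if self.kind != "none":
            if self.window % 2 == 0 or self.window < 3:
                raise ValueError(f"window must be odd and >= 3, got {self.window}")

    @property
    def group_tag(self) -> str:
        return GROUP_TAGS[self.kind]


def _check_window(window: int) -> None:
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")


def average_filter(image: CTImage, window: int = 3) -> CTImage:
    """Arithmetic-mean filter over a ``window x window`` neighbourhood."""
    _check_window(window)
    out = ndimage.uniform_filter(image.pixels, size=window, mode="nearest")
    return replace(image, pixels=out, group_tag=GROUP_TAGS["average"])


def median_filter(image: CTImage, window: int = 3) -> CTImage:
    """Median filter; removes impulse noise without shifting edges."""
    _check_window(window)
    out = ndimage.median_filter(image.pixels, size=window, mode="nearest")
    return replace(image, pixels=out, group_tag=GROUP_TAGS["median"])


def wiener_filter(image: CTImage, window: int = 3) -> CTImage:
    """Local adaptive Wiener filter (Lee filter / ``wiener2`` variant).

    Per pixel, with local mean ``mu`` and local variance ``s2`` over the
    window and noise power ``nu`` estimated as the mean of all local
    variances::

        out = mu + max(s2 - nu, 0) / max(s2, nu) * (pixel - mu)

    Smooth regions (``s2 <= nu``) collapse to the local mean; strongly
    structured regions pass through nearly unchanged.
    """
    _check_window(window)
    x = image.pixels
    mu = ndimage.uniform_filter(x, size=window, mode="nearest")
    mu2 = ndimage.uniform_filter(x * x, size=window, mode="nearest")
    s2 = np.maximum(mu2 - mu * mu, 0.0)
    nu = float(s2.mean())
    denom = np.maximum(s2, nu)
    if nu == 0.0:
        # noise-free (e.g. constant) image: gain is 0/0 -> keep the signal
        gain = np.where(s2 > 0, 1.0, 0.0)
    else:
        gain = np.maximum(s2 - nu, 0.0) / denom
    out = mu + gain * (x - mu)
    return replace(image, pixels=out, group_tag=GROUP_TAGS["wiener"])


_FILTER_FUNCS = {
    "average": average_filter,
    "median": median_filter,
    "wiener": wiener_filter,
}


def apply_filter(image: CTImage, spec: FilterSpec) -> CTImage:
    if spec.kind == "none":
        return replace(image, group_tag=GROUP_TAGS["none"])
    return _FILTER_FUNCS[spec.kind](image, spec.window)


def build_filter_bank(image: CTImage, specs: list[FilterSpec]) -> list[CTImage]:
    """Apply each filter spec to the slice, preserving order and source_id."""
    if not specs:
        raise ValueError("filter bank needs at least one FilterSpec")
    return [apply_filter(image, spec) for spec in specs]
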