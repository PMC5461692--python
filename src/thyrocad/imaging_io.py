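"""Reading CT slices and ROI masks, and gathering masked pixel samples.

The unit of analysis throughout the package is the *ROI sample*: the multiset
of Hounsfield-unit (HU) values lying inside a radiologist-drawn (or synthetic)
binary mask on a single axial CT slice.  Pixels outside the mask are excluded
outright — they are never carried along as zeros, which would corrupt every
histogram and moment computed downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CTImage",
    "ROIMask",
    "ROISample",
    "HU_SANITY_RANGE",
    "MIN_ROI_PIXELS",
    "load_ct_image",
    "load_mask",
    "apply_mask",
    "read_manifest",
]

#: Plausible HU interval for clinical CT after rescale (air ... dense bone/metal).
HU_SANITY_RANGE = (-1100.0, 3200.0)

#: Smallest ROI accepted by default; tiny ROIs make higher moments meaningless.
MIN_ROI_PIXELS = 16

LABELS = ("nodule", "normal", "unknown")


@dataclass
class CTImage:
    """A single 2-D CT slice in Hounsfield units."""

    pixels: np.ndarray
    source_id: str = ""
    pixel_spacing_mm: Optional[tuple[float, float]] = None
    group_tag: str = "non-filter"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"CTImage expects a 2-D grid, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("CTImage contains non-finite pixel values")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    def check_hu_range(self, bounds: tuple[float, float] = HU_SANITY_RANGE) -> None:
        lo, hi = bounds
        pmin, pmax = float(self.pixels.min()), float(self.pixels.max())
        if pmin < lo or pmax > hi:
            raise ValueError(
                f"pixel values [{pmin:.1f}, {pmax:.1f}] outside HU sanity range [{lo}, {hi}]"
            )


@dataclass
class ROIMask:
    """Binary inside/outside grid paired with a CT slice of the same shape."""

    inside: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.inside = np.asarray(self.inside) != 0
        if self.inside.ndim != 2:
            raise ValueError(f"ROIMask expects a 2-D grid, got shape {self.inside.shape}")

    @property
    def n_inside(self) -> int:
        return int(self.inside.sum())

    def validate(self, image: CTImage, min_pixels: int = MIN_ROI_PIXELS) -> None:
        if self.inside.shape != image.pixels.shape:
            raise ValueError(
                f"mask shape {self.inside.shape} != image shape {image.pixels.shape}"
            )
        if self.n_inside == 0:
            raise ValueError("empty ROI: mask has no nonzero cells")
        if self.n_inside < min_pixels:
            raise ValueError(
                f"ROI too small: {self.n_inside} pixels < minimum {min_pixels}"
            )


@dataclass
class ROISample:
    """Ordered HU values gathered from inside one mask, with class label.

    ``values`` are in row-major scan order of the masked cells, but every
    downstream statistic treats them as a multiset.
    """

    values: np.ndarray
    label: str = "unknown"
    group_tag: str = "non-filter"
    source_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n(self) -> int:
        return int(self.values.size)


def load_ct_image(path: str | Path, rescale_policy: str = "hu") -> CTImage:
    """Read a single-frame CT DICOM and convert stored values to HU.

    Parameters
    ----------
    path
        DICOM file containing one frame.
    rescale_policy
        ``"hu"`` applies ``stored * RescaleSlope + RescaleIntercept``, falling
        back to slope 1 / intercept 0 with a warning when the tags are absent;
        ``"strict"`` raises if the tags are missing; ``"raw"`` returns the
        stored values untouched.
    """
    import pydicom

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ds = pydicom.dcmread(str(path))
    pixels = ds.pixel_array.astype(float)
    if pixels.ndim != 2:
        raise ValueError(f"{path.name}: expected a single-frame image, got shape {pixels.shape}")

    modality = str(getattr(ds, "Modality", ""))
    if modality and modality != "CT":
        warnings.warn(f"{path.name}: modality {modality!r} is not CT", stacklevel=2)

    if rescale_policy not in ("hu", "strict", "raw"):
        raise ValueError(f"unknown rescale_policy {rescale_policy!r}")
    if rescale_policy != "raw":
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is None or intercept is None:
            if rescale_policy == "strict":
                raise ValueError(f"{path.name}: missing RescaleSlope/RescaleIntercept")
            warnings.warn(
                f"{path.name}: missing rescale tags, assuming slope 1 / intercept 0",
                stacklevel=2,
            )
        else:
            pixels = pixels * float(slope) + float(intercept)

    spacing = None
    ps = getattr(ds, "PixelSpacing", None)
    if ps is not None and len(ps) == 2:
        spacing = (float(ps[0]), float(ps[1]))

    return CTImage(pixels=pixels, source_id=path.stem, pixel_spacing_mm=spacing)


def _read_mask_array(path: Path) -> np.ndarray:
    suffix = "".join(path.suffixes).lower()
    if suffix.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj)
        return np.squeeze(data)
    if suffix.endswith((".png", ".bmp", ".tif", ".tiff")):
        from PIL import Image

        with Image.open(path) as im:
            return np.array(im.convert("L"))
    # default: DICOM, the dialect the study's masks were stored in
    import pydicom

    ds = pydicom.dcmread(str(path))
    return ds.pixel_array


def load_mask(path: str | Path, image: CTImage) -> ROIMask:
    """Read a binary ROI mask (DICOM, PNG or NIfTI); nonzero cells are inside."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _read_mask_array(path)
    if arr.ndim != 2:
        raise ValueError(f"{path.name}: mask must be 2-D, got shape {arr.shape}")
    mask = ROIMask(inside=arr, source_id=path.stem)
    if mask.inside.shape != image.pixels.shape:
        raise ValueError(
            f"{path.name}: mask shape {mask.inside.shape} != image shape {image.pixels.shape}"
        )
    if mask.n_inside == 0:
        raise ValueError(f"{path.name}: empty ROI")
    return mask


def apply_mask(image: CTImage, mask: ROIMask, label: str = "unknown",
               patient_id: str = "") -> ROISample:
    """Gather the HU values of the masked cells in row-major order.

    Pixels outside the mask are dropped entirely; the ROI is the masked pixel
    *set*, so background never enters the statistics as zeros.
    """
    if mask.inside.shape != image.pixels.shape:
        raise ValueError(
            f"mask shape {mask.inside.shape} != image shape {image.pixels.shape}"
        )
    if mask.n_inside == 0:
        raise ValueError("empty ROI: mask has no nonzero cells")
    values = image.pixels[mask.inside]
    return ROISample(
        values=values,
        label=label,
        group_tag=image.group_tag,
        source_id=image.source_id,
        patient_id=patient_id,
    )


MANIFEST_COLUMNS = ("image_path", "mask_path", "label", "patient_id")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read an ROI manifest CSV (image_path, mask_path, label, patient_id)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"manifest has unknown labels: {sorted(bad)}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=list(MANIFEST_COLUMNS))
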