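"""Seeded CT phantom generator for normal thyroid tissue and nodules.

The phantoms reproduce the intensity structure that separates the two
classes on non-enhanced CT.  Normal thyroid parenchyma takes up iodine and
is homogeneous; nodules lose that uptake, so their mean attenuation drops,
and they are intrinsically heterogeneous — necrosis, water-like cystic
regions (~10 HU) and bright calcifications (~300 HU) all perturb the
histogram.  Per-ROI mean attenuation is drawn from truncated normal
distributions matching the measured per-class ROI means of a clinical
thyroid cohort (normal 89.5 +- 17.3 HU, nodule 68.9 +- 42.0 HU), so the
two classes overlap in mean intensity and no single feature is a perfect
separator.

Tissue heterogeneity is modelled as a spatially *correlated* Gaussian
random field (correlation length ~2 px), while CT photon noise is additive
iid Gaussian per pixel.  The distinction matters: a 3x3 smoothing filter
suppresses iid noise by roughly a factor of three but largely preserves
structure at coarser scales, which is exactly the mechanism that makes a
denoising filter bank useful before texture extraction.

Everything is driven by a single integer seed: per-phantom RNG streams are
spawned deterministically from the master seed, so a dataset is bit-for-bit
reproducible.  Phantoms can be used in memory or written to disk as the
same DICOM dialect the reader consumes (slope 1, intercept -1024).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging_io import CTImage, ROIMask, write_manifest

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset"]


@dataclass
class PhantomConfig:
    """Generative parameters for one phantom ROI.

    HU anchors: normal thyroid mean attenuation 89.5 +- 17.3 HU, nodule
    68.9 +- 42.0 HU (per-ROI truncated-normal draws); cysts near water
    (10 HU), calcification at 300 HU — well above the 120 HU ceiling of
    normal parenchyma.  Per-ROI texture spread is drawn around 8 HU for
    homogeneous normal tissue and around 25 HU for heterogeneous nodules;
    photon noise adds 5 HU iid by default.
    """

    image_size: tuple[int, int] = (64, 64)
    roi_axes_px: tuple[float, float] = (10.0, 18.0)  # semi-axis draw range
    label: str = "normal"
    normal_mean_hu: tuple[float, float] = (89.491, 17.295)  # (mu, sd) of draw
    normal_mean_bounds: tuple[float, float] = (40.0, 140.0)
    nodule_mean_hu: tuple[float, float] = (68.851, 42.019)
    nodule_mean_bounds: tuple[float, float] = (-20.0, 160.0)
    normal_sd_range: tuple[float, float] = (4.0, 12.0)    # per-ROI texture sd
    nodule_sd_range: tuple[float, float] = (12.0, 38.0)
    texture_corr_px: float = 2.0
    p_cyst: float = 0.4
    p_calc: float = 0.3
    cyst_hu: float = 10.0
    cyst_sd_hu: float = 5.0
    calc_hu: float = 300.0
    calc_sd_hu: float = 20.0
    lesion_radius_px: tuple[float, float] = (2.0, 6.0)
    noise_sd_hu: float = 5.0
    surround_hu: float = 60.0     # neck soft tissue around the gland
    surround_px: int = 4
    background_hu: float = -1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.label not in ("normal", "nodule"):
            raise ValueError(f"label must be 'normal' or 'nodule', got {self.label!r}")
        for p in (self.p_cyst, self.p_calc):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for lo, hi in (self.normal_sd_range, self.nodule_sd_range):
            if lo < 0 or hi < lo:
                raise ValueError("texture sd ranges must be 0 <= lo <= hi")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")
        rows, cols = self.image_size
        if 2 * self.roi_axes_px[1] >= min(rows, cols) - 2:
            raise ValueError("ROI axes do not fit inside the image")
        if self.lesion_radius_px[1] > self.roi_axes_px[0]:
            raise ValueError("lesion larger than the smallest ROI")


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float,
                      bounds: tuple[float, float]) -> float:
    if sd == 0:
        return float(np.clip(mu, *bounds))
    for _ in range(1000):
        v = rng.normal(mu, sd)
        if bounds[0] <= v <= bounds[1]:
            return float(v)
    return float(np.clip(mu, *bounds))


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float], angle: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    u = dr * np.cos(angle) + dc * np.sin(angle)
    v = -dr * np.sin(angle) + dc * np.cos(angle)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def _correlated_field(rng: np.random.Generator, shape: tuple[int, int],
                      corr_px: float) -> np.ndarray:
    """Unit-variance Gaussian field with ~corr_px correlation length."""
    white = rng.standard_normal(shape)
    if corr_px <= 0:
        return white
    smooth = ndimage.gaussian_filter(white, sigma=corr_px, mode="wrap")
    sd = smooth.std()
    return smooth / (sd if sd > 0 else 1.0)


def generate_phantom(config: PhantomConfig) -> tuple[CTImage, ROIMask, str]:
    """Generate one phantom slice, its elliptical ROI mask, and the label."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    rows, cols = config.image_size
    axes = (rng.uniform(*config.roi_axes_px), rng.uniform(*config.roi_axes_px))
    margin = max(axes) + 1.5
    center = (rng.uniform(margin, rows - margin), rng.uniform(margin, cols - margin))
    angle = rng.uniform(0, np.pi)
    inside = _ellipse_mask((rows, cols), center, axes, angle)

    # air far field, a soft-tissue annulus hugging the gland: filtering must
    # not smear an air/tissue edge through the ROI rim
    pixels = np.full((rows, cols), config.background_hu, dtype=float)
    if config.surround_px > 0:
        surround = ndimage.binary_dilation(inside, iterations=config.surround_px)
        pixels[surround] = config.surround_hu
    field = _correlated_field(rng, (rows, cols), config.texture_corr_px)
    if config.label == "normal":
        mean = _truncated_normal(rng, *config.normal_mean_hu, config.normal_mean_bounds)
        texture_sd = rng.uniform(*config.normal_sd_range)
    else:
        mean = _truncated_normal(rng, *config.nodule_mean_hu, config.nodule_mean_bounds)
        texture_sd = rng.uniform(*config.nodule_sd_range)
    pixels[inside] = mean + texture_sd * field[inside]

    if config.label == "nodule":
        if rng.uniform() < config.p_cyst:
            radius = rng.uniform(*config.lesion_radius_px)
            cy = _place_lesion(inside, center, axes, rng)
            blob = _disk((rows, cols), cy, radius) & inside
            pixels[blob] = (config.cyst_hu
                            + config.cyst_sd_hu * field[blob])
        if rng.uniform() < config.p_calc:
            for _ in range(rng.integers(1, 4)):
                radius = rng.uniform(1.0, 2.0)
                cy = _place_lesion(inside, center, axes, rng)
                speck = _disk((rows, cols), cy, radius) & inside
                pixels[speck] = (config.calc_hu
                                 + config.calc_sd_hu * field[speck])
    if config.noise_sd_hu > 0:
        pixels += config.noise_sd_hu * rng.standard_normal((rows, cols))

    image = CTImage(pixels=pixels, source_id=f"phantom_{config.label}_{config.seed}")
    mask = ROIMask(inside=inside, source_id=image.source_id + "_mask")
    return image, mask, config.label


def _place_lesion(inside: np.ndarray, center: tuple[float, float],
                  axes: tuple[float, float],
                  rng: np.random.Generator) -> tuple[float, float]:
    # rejection-sample a lesion centre inside the ellipse
    for _ in range(100):
        cand = (center[0] + rng.uniform(-axes[0], axes[0]),
                center[1] + rng.uniform(-axes[1], axes[1]))
        r, c = int(round(cand[0])), int(round(cand[1]))
        if 0 <= r < inside.shape[0] and 0 <= c < inside.shape[1] and inside[r, c]:
            return cand
    return center


# ---------------------------------------------------------------------------
# dataset generation + DICOM round-trip

def _write_dicom(path: Path, pixels: np.ndarray, modality: str = "CT",
                 rescale: bool = True) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid(entropy_srcs=[path.stem])
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    if rescale:
        ds.RescaleSlope = 1
        ds.RescaleIntercept = -1024
        stored = np.clip(np.round(pixels) + 1024, 0, 65535).astype(np.uint16)
    else:
        stored = np.clip(np.round(pixels), 0, 65535).astype(np.uint16)
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


def generate_dataset(template: PhantomConfig, n_normal: int, n_nodule: int,
                     seed: int, out_dir: str | Path | None = None,
                     ) -> pd.DataFrame | tuple[pd.DataFrame, list]:
    """Generate a phantom cohort with requested class counts.

    Per-sample seeds are spawned deterministically from the master ``seed``.
    With ``out_dir`` set, image and mask DICOM pairs plus a manifest CSV are
    written and the manifest DataFrame is returned; without it, the
    in-memory (CTImage, ROIMask, label) triples are returned alongside the
    manifest.  Synthetic patient ids bundle two or three consecutive images,
    mirroring a cohort where each case contributes a couple of slices.
    """
    if n_normal < 1 or n_nodule < 1:
        raise ValueError("need at least one sample per class")
    ss = np.random.SeedSequence(seed)
    labels = ["normal"] * n_normal + ["nodule"] * n_nodule
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(len(labels))]

    rows = []
    triples = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    patient_counter = {"normal": 0, "nodule": 0}
    images_left = {"normal": 0, "nodule": 0}
    pid_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(999,)))
    for i, (label, child_seed) in enumerate(zip(labels, child_seeds)):
        if images_left[label] == 0:
            patient_counter[label] += 1
            images_left[label] = int(pid_rng.integers(2, 4))
        images_left[label] -= 1
        patient_id = f"{label[:3]}_case_{patient_counter[label]:03d}"
        cfg = replace(template, label=label, seed=child_seed)
        image, mask, _ = generate_phantom(cfg)
        sample_id = f"{label}_{i:04d}"
        if out_path is not None:
            img_file = out_path / f"{sample_id}.dcm"
            msk_file = out_path / f"{sample_id}_mask.dcm"
            _write_dicom(img_file, image.pixels, rescale=True)
            _write_dicom(msk_file, mask.inside.astype(float), modality="OT", rescale=False)
            rows.append({"image_path": str(img_file), "mask_path": str(msk_file),
                         "label": label, "patient_id": patient_id})
        else:
            rows.append({"image_path": "", "mask_path": "", "label": label,
                         "patient_id": patient_id})
            triples.append((image, mask, label))
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        write_manifest(manifest, out_path / "manifest.csv")
        return manifest
    return manifest, triples
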