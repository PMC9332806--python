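"""Synthetic CT crop phantoms with controlled HU-band texture.

Real HRCT crops of lung parenchyma cannot be redistributed, so every stage
of the pipeline is exercised on phantoms that emulate the two texture
regimes of interest:

* ``normal_like`` — aerated parenchyma: a spatially correlated HU field
  centred near −850 HU confined to the normal-parenchyma band, plus sparse
  uncorrelated out-of-band speckle (scattered GGO-, emphysema- and
  consolidation-valued pixels such as small vessels and noise produce).
* ``emphysema_bubbles`` / ``ggo_blobs`` / ``consolidation_clusters`` /
  ``mixed_dild`` — pathological texture: the same background with seeded
  compact structures whose HU values sit inside the corresponding band
  (air-density bubbles, irregular ground-glass blobs, water-density
  clusters); ``mixed_dild`` superimposes all three, emulating overlapping
  patterns.

The generator reproduces band occupancy and spatial clustering only; it does
not attempt radiological realism (no septal anatomy, no reconstruction-kernel
noise spectrum, no partial-volume gradients). HU values are integers, as a
scanner would store them, so phantoms round-trip exactly through the DICOM
writer. All randomness flows from the single integer seed in the spec;
identical spec, identical phantom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid
from scipy import ndimage

from .dicom_io import HU_MAX, HU_MIN, CropSample
from .errors import ConfigurationError, EncodingError
from .hu_layers import HUBandTable, default_band_table

PHANTOM_KINDS = (
    "uniform",
    "checkerboard",
    "normal_like",
    "emphysema_bubbles",
    "ggo_blobs",
    "consolidation_clusters",
    "mixed_dild",
)

DEFAULT_SPACING_MM = 0.74


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom; spec + seed determine it bit-exactly.

    Background (normal_like and all pathological kinds):
      base_hu            centre of the parenchyma field, HU
      base_sigma_hu      amplitude (SD) of the correlated background noise, HU
      noise_kernel_px    Gaussian smoothing length of the background noise
      speckle_frac       fraction of pixels replaced by out-of-band speckle

    Pathological structures (counts are draw ranges, inclusive):
      n_bubbles / bubble_radius_px   air-density disks in the emphysema band
      n_blobs / blob_radius_px       irregular ground-glass blobs
      n_clusters / cluster_radius_px compact consolidation clusters
    """

    kind: str
    seed: int = 0
    size_px: int = 65
    pixel_spacing_mm: float = DEFAULT_SPACING_MM
    band_table: HUBandTable = field(default_factory=default_band_table)

    # uniform / checkerboard
    uniform_hu: int = -1000
    checker_hu: tuple[int, int] = (-1000, -500)

    # normal-parenchyma background
    base_hu: int = -850
    base_sigma_hu: float = 40.0
    noise_kernel_px: float = 2.0
    speckle_frac: float = 0.06

    # pathological structures
    n_bubbles: tuple[int, int] = (2, 4)
    bubble_radius_px: tuple[int, int] = (2, 5)
    bubble_hu: int = -1000
    n_blobs: tuple[int, int] = (2, 4)
    blob_radius_px: tuple[int, int] = (5, 9)
    blob_hu: int = -550
    blob_sigma_hu: float = 25.0
    n_clusters: tuple[int, int] = (1, 3)
    cluster_radius_px: tuple[int, int] = (2, 4)
    cluster_hu: int = -50

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ConfigurationError(f"unknown phantom kind {self.kind!r}")
        if self.size_px < 3:
            raise ConfigurationError("size_px must be at least 3")
        if not 0 <= self.speckle_frac < 1:
            raise ConfigurationError("speckle_frac must lie in [0, 1)")


def _smooth_unit_noise(rng: np.random.Generator, size: int,
                       kernel_px: float) -> np.ndarray:
    """Gaussian-smoothed white noise rescaled to unit SD."""
    raw = ndimage.gaussian_filter(rng.standard_normal((size, size)), kernel_px)
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def _normal_background(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Correlated parenchyma field clipped inside the normal band."""
    band = spec.band_table["normal_parenchyma"]
    hu = spec.base_hu + spec.base_sigma_hu * _smooth_unit_noise(
        rng, spec.size_px, spec.noise_kernel_px
    )
    # Keep strictly inside the band so rounding cannot cross a boundary.
    return np.clip(hu, band.low + 1, band.high - 2)


def _apply_speckle(hu: np.ndarray, rng: np.random.Generator,
                   spec: PhantomSpec) -> np.ndarray:
    """Replace a sparse pixel fraction with out-of-band speckle values.

    Split 70% GGO / 15% emphysema / 15% consolidation: scattered hazy and
    dense voxels dominate over air pockets in quiet parenchyma.
    """
    n = hu.size
    n_speckle = int(round(spec.speckle_frac * n))
    if n_speckle == 0:
        return hu
    table = spec.band_table
    idx = rng.choice(n, size=n_speckle, replace=False)
    kinds = rng.choice(3, size=n_speckle, p=[0.70, 0.15, 0.15])
    vals = np.empty(n_speckle)
    for code, band_name, centre, sd in (
        (0, "ggo", -550.0, 30.0),
        (1, "emphysema", -1000.0, 10.0),
        (2, "consolidation", -50.0, 15.0),
    ):
        band = table[band_name]
        sel = kinds == code
        vals[sel] = np.clip(rng.normal(centre, sd, size=sel.sum()),
                            band.low, band.high - 1)
    flat = hu.ravel().copy()
    flat[idx] = vals
    return flat.reshape(hu.shape)


def _disk_mask(size: int, centre: tuple[int, int], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[:size, :size]
    return (rr - centre[0]) ** 2 + (cc - centre[1]) ** 2 <= radius**2


def _paint_disks(
    hu: np.ndarray,
    rng: np.random.Generator,
    n_range: tuple[int, int],
    radius_range: tuple[int, int],
    centre_hu: float,
    sigma_hu: float,
    band,
    irregular: bool = False,
    kernel_px: float = 2.0,
) -> np.ndarray:
    """Seed disks (optionally irregularised) of band-interior HU values.

    Values inside a structure are a smooth field ``centre_hu ± sigma_hu``,
    clipped inside ``band``, so neighbouring pixels stay within the gradient
    tolerance of each other and every painted pixel classifies into the
    intended band.
    """
    size = hu.shape[0]
    out = hu.copy()
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    for _ in range(n):
        radius = int(rng.integers(radius_range[0], radius_range[1] + 1))
        centre = tuple(rng.integers(radius, size - radius, size=2))
        mask = _disk_mask(size, centre, radius)
        if irregular:
            wobble = _smooth_unit_noise(rng, size, kernel_px)
            rr, cc = np.ogrid[:size, :size]
            dist = np.sqrt((rr - centre[0]) ** 2 + (cc - centre[1]) ** 2)
            mask = (dist / radius + 0.35 * wobble) <= 1.0
        texture = np.clip(
            centre_hu + sigma_hu * _smooth_unit_noise(rng, size, kernel_px),
            band.low,
            band.high - 1,
        )
        out[mask] = texture[mask]
    return out


def make_phantom(spec: PhantomSpec) -> CropSample:
    """Generate the phantom described by ``spec`` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size_px

    if spec.kind == "uniform":
        hu = np.full((size, size), float(spec.uniform_hu))
    elif spec.kind == "checkerboard":
        a, b = spec.checker_hu
        rr, cc = np.indices((size, size))
        hu = np.where((rr + cc) % 2 == 0, float(a), float(b))
    else:
        hu = _normal_background(rng, spec)
        hu = _apply_speckle(hu, rng, spec)
        emph = spec.band_table["emphysema"]
        ggo = spec.band_table["ggo"]
        cons = spec.band_table["consolidation"]
        if spec.kind in ("emphysema_bubbles", "mixed_dild"):
            hu = _paint_disks(hu, rng, spec.n_bubbles, spec.bubble_radius_px,
                              spec.bubble_hu, 8.0, emph)
        if spec.kind in ("ggo_blobs", "mixed_dild"):
            hu = _paint_disks(hu, rng, spec.n_blobs, spec.blob_radius_px,
                              spec.blob_hu, spec.blob_sigma_hu, ggo,
                              irregular=True)
        if spec.kind in ("consolidation_clusters", "mixed_dild"):
            hu = _paint_disks(hu, rng, spec.n_clusters, spec.cluster_radius_px,
                              spec.cluster_hu, 15.0, cons)
        hu = np.clip(hu, HU_MIN, HU_MAX)

    hu = np.round(hu)
    return CropSample(
        hu=hu,
        size_px=size,
        origin=(0, 0),
        pixel_spacing_mm=spec.pixel_spacing_mm,
        source_id=f"phantom-{spec.kind}-seed{spec.seed}",
    )


def write_fixture_dicom(
    crop: CropSample,
    path: str | Path,
    slope: float = 1.0,
    intercept: float = -1024.0,
    spacing: float | None = None,
) -> Path:
    """Write the crop as a valid single-frame CT DICOM (synthetic fixture).

    The raw stored values are the inverse rescale ``(hu − intercept)/slope``
    and must come out as non-negative integers fitting unsigned 16-bit;
    otherwise an :class:`EncodingError` is raised.
    """
    path = Path(path)
    spacing = crop.pixel_spacing_mm if spacing is None else spacing
    raw = (crop.hu - intercept) / slope
    raw_int = np.round(raw)
    if not np.allclose(raw, raw_int, atol=1e-9):
        raise EncodingError("HU values are not representable as integers "
                            "under this slope/intercept")
    if raw_int.min() < 0 or raw_int.max() > np.iinfo(np.uint16).max:
        raise EncodingError("raw values fall outside unsigned 16-bit range")

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = CTImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.SeriesDescription = "synthetic phantom"
    ds.Rows, ds.Columns = crop.hu.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = intercept
    ds.PixelSpacing = [spacing, spacing]
    ds.PixelData = raw_int.astype(np.uint16).tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return path


def make_cohort(
    n_normal: int,
    n_dild: int,
    seed: int = 0,
) -> list[tuple[CropSample, str]]:
    """Seeded lot of normal-like and mixed-DILD phantoms.

    Per-sample variability comes from independent child seeds plus mild
    draws of the background noise amplitude (30–50 HU) and speckle fraction
    (5–8%), emulating patient-to-patient variation; DILD samples addition-
    ally vary in structure counts via their own seeds. Returns
    ``[(crop, "normal"), ..., (crop, "dild"), ...]``.
    """
    if n_normal < 0 or n_dild < 0 or n_normal + n_dild == 0:
        raise ConfigurationError("cohort needs at least one sample")
    master = np.random.default_rng(seed)
    out: list[tuple[CropSample, str]] = []
    for i in range(n_normal + n_dild):
        child_seed = int(master.integers(2**31))
        draw = np.random.default_rng(child_seed)
        sigma = float(draw.uniform(30.0, 50.0))
        speckle = float(draw.uniform(0.05, 0.08))
        kind = "normal_like" if i < n_normal else "mixed_dild"
        spec = PhantomSpec(
            kind=kind,
            seed=child_seed,
            base_sigma_hu=sigma,
            speckle_frac=speckle,
        )
        out.append((make_phantom(spec), "normal" if i < n_normal else "dild"))
    return out


def cohort_manifest(cohort: list[tuple[CropSample, str]]) -> "pd.DataFrame":
    """Manifest table (sample_id, group, source_id) for a generated cohort."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(len(cohort))],
            "group": [g for _, g in cohort],
            "source_id": [c.source_id for c, _ in cohort],
        }
    )
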