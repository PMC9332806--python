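"""Hounsfield-unit band classification and per-band layer masks.

Lung texture is read off the CT attenuation scale: air-filled destroyed
tissue (emphysema) sits near -1000 HU, aerated parenchyma around -850 HU,
ground-glass opacities (GGO) in a hazy mid range, and consolidations near
water density. Each crop pixel is assigned to exactly one half-open HU
interval, and the crop is split into one boolean mask per band so each band
can be analysed as its own network layer. The default intervals are
scanner-specific (calibrated on a GE Optima 520 protocol) and overridable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dicom_io import CropSample
from .errors import ConfigurationError, DomainError

# Canonical band names used throughout the package.
EMPHYSEMA = "emphysema"
NORMAL_PARENCHYMA = "normal_parenchyma"
GGO = "ggo"
CRAZY_PAVING = "others_crazy_paving"
CONSOLIDATION = "consolidation"
VESSELS = "others_vessels"

#: The three bands the method analyses as networks.
PATHOLOGICAL_BANDS = (EMPHYSEMA, GGO, CONSOLIDATION)


@dataclass(frozen=True)
class HUBand:
    """One half-open HU interval [low, high)."""

    name: str
    low: float
    high: float

    def contains(self, hu) -> bool | np.ndarray:
        return (np.asarray(hu) >= self.low) & (np.asarray(hu) < self.high)


@dataclass(frozen=True)
class HUBandTable:
    """An ordered, disjoint, total partition of the HU axis into named bands.

    All intervals are half-open [low, high); the last band is open-ended.
    A boundary value such as -977 therefore belongs to the band whose *low*
    bound it is. The table is total: every HU value from -1024 upward maps to
    exactly one band.
    """

    bands: tuple[HUBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError("band table must contain at least one band")
        lows = [b.low for b in self.bands]
        if lows != sorted(lows):
            raise ConfigurationError("bands must be ordered by low bound")
        for a, b in zip(self.bands, self.bands[1:]):
            if a.high != b.low:
                raise ConfigurationError(
                    f"bands {a.name!r} and {b.name!r} must abut: "
                    f"{a.high} != {b.low}"
                )
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ConfigurationError("band names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    def __getitem__(self, name: str) -> HUBand:
        for b in self.bands:
            if b.name == name:
                return b
        raise ConfigurationError(f"unknown band {name!r}")

    def edges(self) -> np.ndarray:
        """Interior bin edges, suitable for ``np.searchsorted``."""
        return np.array([b.low for b in self.bands[1:]], dtype=float)

    def classify(self, hu) -> np.ndarray:
        """Vectorised band-index lookup for an array of HU values."""
        hu = np.asarray(hu, dtype=float)
        if np.any(hu < self.bands[0].low):
            raise DomainError(
                f"HU below the table's lower bound {self.bands[0].low}"
            )
        return np.searchsorted(self.edges(), hu, side="right")


def default_band_table() -> HUBandTable:
    """The six-band partition used for DILD texture analysis.

    The final "vessels" band is open-ended; an HU of exactly 5 falls in it
    (a half-open [−100, 5) consolidation band keeps the partition total).
    """
    return HUBandTable(
        bands=(
            HUBand(EMPHYSEMA, -1024, -977),
            HUBand(NORMAL_PARENCHYMA, -977, -703),
            HUBand(GGO, -703, -368),
            HUBand(CRAZY_PAVING, -368, -100),
            HUBand(CONSOLIDATION, -100, 5),
            HUBand(VESSELS, 5, np.inf),
        )
    )


def classify_hu(hu: float, table: HUBandTable | None = None) -> str:
    """Name of the unique band containing ``hu``."""
    table = table or default_band_table()
    return table.bands[int(table.classify(hu))].name


@dataclass(frozen=True)
class LayerMask:
    """Boolean membership mask of one HU band over a crop.

    Carries the crop's HU grid alongside the mask so a layer is
    self-contained for graph construction.
    """

    band_name: str
    mask: np.ndarray
    hu: np.ndarray
    pixel_spacing_mm: float = 0.74

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        hu = np.asarray(self.hu, dtype=float)
        if mask.shape != hu.shape:
            raise DomainError("mask and HU grid shapes differ")
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "hu", hu)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def split_layers(
    crop: CropSample,
    table: HUBandTable | None = None,
    selected: Sequence[str] | Iterable[str] = PATHOLOGICAL_BANDS,
) -> list[LayerMask]:
    """Split a crop into one :class:`LayerMask` per selected band.

    By default only the three pathological bands (emphysema, GGO,
    consolidation) are produced; normal parenchyma and the two "others"
    bands can be requested explicitly. Masks of distinct bands are disjoint
    by construction.
    """
    table = table or default_band_table()
    selected = list(selected)
    unknown = set(selected) - set(table.names)
    if unknown:
        raise ConfigurationError(f"unknown band name(s): {sorted(unknown)}")
    idx = table.classify(crop.hu)
    name_to_index = {name: i for i, name in enumerate(table.names)}
    return [
        LayerMask(
            band_name=name,
            mask=idx == name_to_index[name],
            hu=crop.hu,
            pixel_spacing_mm=crop.pixel_spacing_mm,
        )
        for name in selected
    ]


def write_layer_csv(layer: LayerMask, path) -> None:
    """Write the mask as a 0/1 CSV grid."""
    np.savetxt(path, layer.mask.astype(int), fmt="%d", delimiter=",")


def composite_rgb(layers: Sequence[LayerMask]) -> np.ndarray:
    """RGB preview with up to three layers in distinct channels (uint8)."""
    if not layers:
        raise ConfigurationError("need at least one layer")
    shape = layers[0].mask.shape
    out = np.zeros((*shape, 3), dtype=np.uint8)
    for channel, layer in enumerate(layers[:3]):
        out[..., channel] = np.where(layer.mask, 255, 0)
    return out
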