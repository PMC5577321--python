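"""Core raster and measurement containers shared across the pipeline.

A :class:`StainImage` is a calibrated raster (RGB for brightfield stains,
single-channel float for fluorescence) tagged with the stain it carries.
A :class:`BinaryMask` is a boolean raster aligned to such an image and is
the carrier of every segmentation result.  Pressure-probe locations and
their readings travel as :class:`MeasurementSite` / :class:`PressureRecord`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "StainKind",
    "StainImage",
    "BinaryMask",
    "MeasurementSite",
    "PressureRecord",
]


class StainKind(str, Enum):
    """Stain/channel identity of a raster."""

    MT = "mt"  # Masson's Trichrome brightfield (collagen blue)
    HABP = "habp"  # hyaluronic-acid binding protein brightfield (HA brown)
    LECTIN = "lectin"  # fluorescent lectin perfusion (patent vessels)
    VERTEPORFIN = "verteporfin"  # fluorescent verteporfin uptake

    @property
    def is_rgb(self) -> bool:
        return self in (StainKind.MT, StainKind.HABP)


@dataclass(frozen=True)
class StainImage:
    """Calibrated stain raster.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 for brightfield stains (MT, HABP) or ``(H, W)``
        non-negative float for fluorescence channels (lectin, verteporfin).
    pixel_size_um
        Physical edge length of one pixel in microns; must be positive.
    stain
        Which stain the raster carries; dictates the expected layout.
    """

    pixels: np.ndarray
    pixel_size_um: float
    stain: StainKind

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        px = np.asarray(self.pixels)
        if self.stain.is_rgb:
            if px.ndim != 3 or px.shape[2] != 3:
                raise TypeError(
                    f"{self.stain.value} stain requires an RGB (H, W, 3) raster, "
                    f"got shape {px.shape}"
                )
        else:
            if px.ndim != 2:
                raise TypeError(
                    f"{self.stain.value} stain requires a single-channel (H, W) "
                    f"raster, got shape {px.shape}"
                )
            if np.any(px < 0):
                raise ValueError("fluorescence intensities must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class BinaryMask:
    """Boolean raster aligned to a :class:`StainImage`."""

    values: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise TypeError(f"mask must be 2-D, got shape {v.shape}")
        object.__setattr__(self, "values", v.astype(bool, copy=False))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def area_fraction(self, within: "BinaryMask | None" = None) -> float:
        """Fraction of true pixels, optionally restricted to ``within``."""
        if within is None:
            return float(self.values.mean())
        sel = within.values
        denom = int(sel.sum())
        if denom == 0:
            raise ValueError("restriction mask is empty")
        return float(self.values[sel].sum() / denom)

    def is_subset_of(self, other: "BinaryMask") -> bool:
        return bool(np.all(other.values[self.values]))


@dataclass(frozen=True)
class MeasurementSite:
    """A pressure-probe location marked on the section.

    ``center_px`` is ``(x, y)`` in pixel coordinates (x = column, y = row).
    ``needle_track_diameter_um`` is the diameter of the introducer-needle
    track excluded from all ROI statistics; 640 um is the nominal outer
    diameter of a 23-gauge needle.
    """

    site_id: str
    center_px: tuple[float, float]
    needle_track_diameter_um: float = 640.0

    def __post_init__(self) -> None:
        if self.needle_track_diameter_um < 0:
            raise ValueError("needle_track_diameter_um must be >= 0")


@dataclass(frozen=True)
class PressureRecord:
    """Pressure readings (mmHg) at one site; ``None`` marks an unmeasured
    quantity (IFP is typically probed at a single site per tumor)."""

    site_id: str
    ttp_mmHg: float | None = None
    ifp_mmHg: float | None = None

    def __post_init__(self) -> None:
        for name in ("ttp_mmHg", "ifp_mmHg"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                object.__setattr__(self, name, None)
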