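"""Square regions of interest around pressure-probe sites.

Each probe site gets a square ROI whose side is a small multiple of the
pressure-sensor diameter (0.47 mm); the introducer-needle track is excluded
from every statistic.  Area fractions are percentages of the analyzable ROI
pixels (window minus needle track, optionally restricted to the tumor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import BinaryMask, MeasurementSite, PressureRecord, StainImage

__all__ = [
    "ROI",
    "ROIQuant",
    "StainBundle",
    "define_roi",
    "area_fraction",
    "mean_intensity",
    "quantify_site",
    "DEFAULT_ROI_SIDES_MM",
    "SENSOR_DIAMETER_MM",
]

logger = logging.getLogger(__name__)

#: Piezoelectric sensor diameter; ROI sides of 0.5/1/1.5/2 mm are ~1-4x this.
SENSOR_DIAMETER_MM = 0.47

DEFAULT_ROI_SIDES_MM = (0.5, 1.0, 1.5, 2.0)


@dataclass(frozen=True)
class ROI:
    """A clipped square pixel window around a site, with the needle-track
    exclusion rasterized at the same clipping.

    ``rows``/``cols`` are half-open pixel bounds into the parent image;
    ``exclusion`` is a boolean array of the clipped window's shape.
    """

    site: MeasurementSite
    side_mm: float
    pixel_size_um: float
    rows: tuple[int, int]
    cols: tuple[int, int]
    exclusion: np.ndarray

    @property
    def window_shape(self) -> tuple[int, int]:
        return (self.rows[1] - self.rows[0], self.cols[1] - self.cols[0])

    def extract(self, raster: np.ndarray) -> np.ndarray:
        """Slice the ROI window out of a full-image raster."""
        return raster[self.rows[0] : self.rows[1], self.cols[0] : self.cols[1]]


@dataclass(frozen=True)
class ROIQuant:
    """Per-ROI readout: stromal area fractions (%), verteporfin mean
    intensity (A.U.), and the co-located pressure readings when present."""

    site_id: str
    side_mm: float
    collagen_frac_pct: float
    ha_frac_pct: float
    vessel_frac_pct: float
    verteporfin_mean: float
    ttp_mmHg: float | None = None
    ifp_mmHg: float | None = None

    def __post_init__(self) -> None:
        for name in ("collagen_frac_pct", "ha_frac_pct", "vessel_frac_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} out of [0, 100]: {v}")


@dataclass(frozen=True)
class StainBundle:
    """Co-registered masks and fluorescence channels for one section."""

    collagen: BinaryMask
    ha: BinaryMask
    vessels: BinaryMask
    verteporfin: StainImage
    tumor: BinaryMask | None = None

    def __post_init__(self) -> None:
        shapes = {self.collagen.shape, self.ha.shape, self.vessels.shape,
                  self.verteporfin.shape}
        if self.tumor is not None:
            shapes.add(self.tumor.shape)
        if len(shapes) != 1:
            raise ValueError(f"bundle rasters disagree in shape: {shapes}")


def window_size_px(side_mm: float, pixel_size_um: float) -> int:
    """Odd pixel size of a square ROI of physical side ``side_mm``.

    The nominal size round(side_mm * 1000 / pixel_size_um) is bumped to the
    next odd integer so the window centers exactly on the site pixel.
    """
    n = int(round(side_mm * 1000.0 / pixel_size_um))
    return n if n % 2 == 1 else n + 1


def define_roi(
    site: MeasurementSite,
    side_mm: float,
    pixel_size_um: float,
    image_shape: tuple[int, int],
) -> ROI:
    """Build the clipped square window and needle-track exclusion for a site.

    Raises ``ValueError`` if the window lies entirely outside the image;
    logs a warning when more than 10% of it is clipped at the image edge.
    """
    if side_mm <= 0:
        raise ValueError(f"side_mm must be > 0, got {side_mm}")
    n = window_size_px(side_mm, pixel_size_um)
    half = n // 2
    cx, cy = site.center_px
    r0, c0 = int(round(cy)) - half, int(round(cx)) - half
    r1, c1 = r0 + n, c0 + n
    H, W = image_shape
    rr0, rr1 = max(r0, 0), min(r1, H)
    cc0, cc1 = max(c0, 0), min(c1, W)
    if rr0 >= rr1 or cc0 >= cc1:
        raise ValueError(f"ROI for site {site.site_id!r} lies outside the image")
    clipped = 1.0 - (rr1 - rr0) * (cc1 - cc0) / (n * n)
    if clipped > 0.10:
        logger.warning(
            "ROI for site %s clipped by %.0f%% at the image edge",
            site.site_id, 100 * clipped,
        )
    radius_px = site.needle_track_diameter_um / 2.0 / pixel_size_um
    if radius_px > 0:
        yy, xx = np.mgrid[rr0:rr1, cc0:cc1]
        exclusion = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2
    else:
        exclusion = np.zeros((rr1 - rr0, cc1 - cc0), dtype=bool)
    return ROI(site, side_mm, pixel_size_um, (rr0, rr1), (cc0, cc1), exclusion)


def _analyzable(roi: ROI, within: BinaryMask | None) -> np.ndarray:
    sel = ~roi.exclusion
    if within is not None:
        sel &= roi.extract(within.values)
    return sel


def area_fraction(
    mask: BinaryMask, roi: ROI, within: BinaryMask | None = None
) -> float:
    """Percent of analyzable ROI pixels that are true in ``mask``.

    Analyzable pixels are the window minus the needle track, intersected
    with ``within`` (e.g. the tumor outline) when given.
    """
    sel = _analyzable(roi, within)
    denom = int(sel.sum())
    if denom == 0:
        raise ValueError("needle-track exclusion covers the entire ROI")
    return 100.0 * float(roi.extract(mask.values)[sel].sum()) / denom


def mean_intensity(
    image: StainImage, roi: ROI, within: BinaryMask | None = None
) -> float:
    """Arithmetic mean intensity over the analyzable ROI pixels."""
    if image.pixels.ndim != 2:
        raise TypeError("mean_intensity requires a single-channel image")
    sel = _analyzable(roi, within)
    if not sel.any():
        raise ValueError("needle-track exclusion covers the entire ROI")
    return float(roi.extract(image.pixels)[sel].mean())


def quantify_site(
    bundle: StainBundle,
    site: MeasurementSite,
    side_mm: float,
    record: PressureRecord | None = None,
) -> ROIQuant:
    """Assemble the full per-site readout for one ROI side length."""
    shape = bundle.collagen.shape
    roi = define_roi(site, side_mm, bundle.collagen.pixel_size_um, shape)
    return ROIQuant(
        site_id=site.site_id,
        side_mm=side_mm,
        collagen_frac_pct=area_fraction(bundle.collagen, roi, bundle.tumor),
        ha_frac_pct=area_fraction(bundle.ha, roi, bundle.tumor),
        vessel_frac_pct=area_fraction(bundle.vessels, roi, bundle.tumor),
        verteporfin_mean=mean_intensity(bundle.verteporfin, roi, bundle.tumor),
        ttp_mmHg=None if record is None else record.ttp_mmHg,
        ifp_mmHg=None if record is None else record.ifp_mmHg,
    )
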