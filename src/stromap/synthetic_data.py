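"""Synthetic multi-stain tumor phantoms with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes in a desmoplastic pancreatic tumor section: a spatially
heterogeneous collagen field with tunable irregularity, hyaluronan pools
optionally encapsulated by collagen rings, patent vessels whose placement
probability decays with the locally modelled total tissue pressure (TTP),
verteporfin uptake decaying with local TTP, and per-site pressure readings
drawn from the elastic model plus Gaussian noise.  Every raster is
co-registered by construction, and every run is bit-reproducible from the
config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image
from scipy import ndimage as _ndi
from skimage.color import hsv2rgb

from .core import BinaryMask, MeasurementSite, PressureRecord, StainImage, StainKind
from .pressure_model import ElasticModelParams, predict_ttp
from .roi_quantification import area_fraction, define_roi

__all__ = [
    "PhantomConfig",
    "Phantom",
    "generate_collagen_field",
    "generate_phantom",
    "render_mt_image",
    "render_habp_image",
    "render_fluorescence",
    "write_phantom",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one phantom tumor section.

    Defaults describe a ~4 mm desmoplastic section scanned at 2 um/px with
    three probe sites (one of which also reads IFP), a collagen-rich stroma
    (30% area fraction, 12% HA), and pressures generated from the elastic
    model at SS_swell = 170 mmHg over IFP = 10.9 mmHg with 5 mmHg reading
    noise.
    """

    image_size_px: tuple[int, int] = (2048, 2048)
    pixel_size_um: float = 2.0
    n_sites: int = 3
    collagen_target_fraction: float = 0.30
    complexity: float = 0.5
    encapsulation: float = 0.5
    vessel_density_base: float = 0.05
    model_params: ElasticModelParams = field(
        default_factory=lambda: ElasticModelParams(170.0, 10.9)
    )
    pressure_noise_sd_mmHg: float = 5.0
    seed: int = 0
    # generator internals, all physically interpretable and overridable
    ha_target_fraction: float = 0.12
    ha_pool_radius_um: float = 75.0
    ring_width_um: float = 40.0
    vessel_radius_um: float = 15.0
    vessel_ttp_scale_mmHg: float = 60.0
    verteporfin_i0: float = 100.0
    verteporfin_tau_mmHg: float = 40.0
    verteporfin_noise_sd: float = 1.0
    lectin_gain: float = 100.0
    min_site_separation_mm: float = 2.0
    roi_side_mm: float = 1.0
    needle_track_diameter_um: float = 640.0

    def __post_init__(self) -> None:
        h, w = self.image_size_px
        if h < 256 or w < 256:
            raise ValueError(f"image_size_px must be >= 256 each, got {(h, w)}")
        if not 0.1 < self.pixel_size_um <= 10:
            raise ValueError(f"pixel_size_um must be in (0.1, 10], got {self.pixel_size_um}")
        if self.n_sites < 1:
            raise ValueError(f"n_sites must be >= 1, got {self.n_sites}")
        for name in (
            "collagen_target_fraction", "complexity", "encapsulation",
            "vessel_density_base", "ha_target_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pressure_noise_sd_mmHg < 0:
            raise ValueError("pressure_noise_sd_mmHg must be >= 0")
        object.__setattr__(self, "image_size_px", (int(h), int(w)))


@dataclass(frozen=True)
class Phantom:
    """A generated section: four co-registered stain channels, the ground
    truth masks they were rendered from, and the simulated pressure data."""

    config: PhantomConfig
    mt_image: StainImage
    habp_image: StainImage
    lectin_image: StainImage
    verteporfin_image: StainImage
    truth_collagen: BinaryMask
    truth_ha: BinaryMask
    truth_vessels: BinaryMask
    tumor_mask: BinaryMask
    sites: tuple[MeasurementSite, ...]
    records: tuple[PressureRecord, ...]

    def truth_bundle(self):
        from .roi_quantification import StainBundle

        return StainBundle(
            collagen=self.truth_collagen,
            ha=self.truth_ha,
            vessels=self.truth_vessels,
            verteporfin=self.verteporfin_image,
            tumor=self.tumor_mask,
        )


# ---------------------------------------------------------------- geometry


def _tumor_mask(config: PhantomConfig, rng: np.random.Generator) -> BinaryMask:
    """Slightly irregular ellipse filling ~90% of the frame."""
    H, W = config.image_size_px
    yy, xx = np.mgrid[0:H, 0:W]
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    ry, rx = 0.45 * H, 0.45 * W
    ang = np.arctan2((yy - cy) / ry, (xx - cx) / rx)
    # low-order harmonic boundary perturbation for a non-circular outline
    amps = rng.uniform(-0.04, 0.04, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    wobble = 1.0 + sum(
        a * np.cos((k + 2) * ang + p) for k, (a, p) in enumerate(zip(amps, phases))
    )
    r = np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2)
    return BinaryMask(r <= wobble, config.pixel_size_um)


def _spectral_noise(
    shape: tuple[int, int], beta: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian random field with an isotropic power-law spectrum
    S(k) ~ k^-beta, min-max normalized to [0, 1].

    Smaller beta puts more power at fine scales, giving rougher, more
    perforated excursion sets; larger beta gives smooth blobby fields.
    """
    H, W = shape
    ky = np.fft.fftfreq(H)[:, None]
    kx = np.fft.rfftfreq(W)[None, :]
    k = np.sqrt(ky**2 + kx**2)
    k[0, 0] = np.inf  # zero the DC mode
    amp = k ** (-beta / 2.0)
    phase = rng.standard_normal((H, W // 2 + 1)) + 1j * rng.standard_normal(
        (H, W // 2 + 1)
    )
    f = np.fft.irfft2(amp * phase, s=shape)
    lo, hi = f.min(), f.max()
    return (f - lo) / (hi - lo) if hi > lo else np.zeros(shape)


def _threshold_for_fraction(
    field: np.ndarray, inside: np.ndarray, target: float, tol: float = 0.02
) -> float:
    """Bisection on the threshold so that mean(field >= t | inside) hits
    the target fraction within ``tol`` (absolute)."""
    vals = field[inside]
    lo, hi = float(vals.min()) - 1e-9, float(vals.max()) + 1e-9
    if target <= 0:
        return hi  # empty mask
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        frac = float((vals >= mid).mean())
        if frac > target:
            lo = mid
        else:
            hi = mid
    t = 0.5 * (lo + hi)
    achieved = float((vals >= t).mean())
    if abs(achieved - target) > tol:
        raise ValueError(
            f"cannot reach collagen fraction {target:.3f}: closest achievable "
            f"is {achieved:.3f}"
        )
    return t


def generate_collagen_field(
    config: PhantomConfig,
    tumor_mask: BinaryMask | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, BinaryMask]:
    """Continuous collagen density field in [0, 1] and its thresholded mask.

    The field is a Gaussian random field with power-law spectrum
    S(k) ~ k^-beta, where the spectral exponent is mapped from
    ``complexity`` (beta = 3.5 at complexity 0 down to 2.0 at complexity
    1).  Rougher spectra perforate the thresholded mask at all scales, so
    higher complexity yields higher entropy and higher box-counting
    fractal dimension of the mask, in expectation over seeds.  The
    threshold is found by bisection so the mask's area fraction inside the
    tumor matches ``collagen_target_fraction`` within 2 percentage points.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if tumor_mask is None:
        tumor_mask = _tumor_mask(config, rng)
    beta = 3.5 - 1.5 * config.complexity
    field = _spectral_noise(config.image_size_px, beta, rng)
    t = _threshold_for_fraction(
        field, tumor_mask.values, config.collagen_target_fraction
    )
    mask = BinaryMask((field >= t) & tumor_mask.values, config.pixel_size_um)
    return field, mask


def _disk(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return xx**2 + yy**2 <= radius_px**2


def _stamp(canvas: np.ndarray, stamp: np.ndarray, cy: int, cx: int) -> None:
    """OR a small boolean stamp into the canvas, clipped at the borders."""
    sh, sw = stamp.shape
    r0, c0 = cy - sh // 2, cx - sw // 2
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r0 + sh, canvas.shape[0]), min(c0 + sw, canvas.shape[1])
    if rr0 >= rr1 or cc0 >= cc1:
        return
    canvas[rr0:rr1, cc0:cc1] |= stamp[rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0]


def _place_ha_pools(
    config: PhantomConfig,
    tumor: np.ndarray,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """HA pools (disks) and the collagen rings encapsulating a fraction of
    them.  Returns (ha_mask, ring_mask)."""
    H, W = tumor.shape
    px = config.pixel_size_um
    r_px = config.ha_pool_radius_um / px
    pool_area = np.pi * r_px**2
    n_pools = int(round(config.ha_target_fraction * tumor.sum() / pool_area))
    ha = np.zeros((H, W), bool)
    rings = np.zeros((H, W), bool)
    inside = _ndi.distance_transform_edt(tumor) >= r_px
    ys, xs = np.nonzero(inside)
    if len(ys) == 0 or n_pools == 0:
        return ha, rings
    ring_w = config.ring_width_um / px
    for _ in range(n_pools):
        k = rng.integers(len(ys))
        cy, cx = int(ys[k]), int(xs[k])
        radius = r_px * rng.uniform(0.7, 1.3)
        pool = _disk(radius)
        _stamp(ha, pool, cy, cx)
        if rng.random() < config.encapsulation:
            ring = _disk(radius + ring_w) & ~_disk_padded(radius, int(np.ceil(radius + ring_w)))
            _stamp(rings, ring, cy, cx)
    return ha & tumor, rings & tumor


def _disk_padded(radius_px: float, half: int) -> np.ndarray:
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    return xx**2 + yy**2 <= radius_px**2


def _local_fraction(mask: np.ndarray, window_px: int) -> np.ndarray:
    return _ndi.uniform_filter(mask.astype(np.float64), size=window_px)


def _local_ttp_field(
    collagen: np.ndarray,
    ha: np.ndarray,
    config: PhantomConfig,
) -> np.ndarray:
    """Per-pixel modelled TTP from locally averaged area fractions."""
    win = max(4, int(round(250.0 / config.pixel_size_um)))  # ~0.25 mm support
    c_loc = np.maximum(_local_fraction(collagen, win), 0.01)
    ha_loc = _local_fraction(ha, win)
    p = config.model_params
    return p.ss_swell_mmHg / (1.0 + ha_loc / c_loc) + p.ifp_mmHg


def _place_vessels(
    config: PhantomConfig,
    tumor: np.ndarray,
    ttp_field: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Small ellipses accepted with probability exp(-(TTP-IFP)/scale):
    high local pressure suppresses patent vessels."""
    px = config.pixel_size_um
    r_px = config.vessel_radius_um / px
    vessel_area = np.pi * r_px**2
    n_candidates = int(round(config.vessel_density_base * tumor.sum() / vessel_area))
    vessels = np.zeros_like(tumor)
    ys, xs = np.nonzero(tumor)
    if len(ys) == 0 or n_candidates == 0:
        return vessels
    ifp = config.model_params.ifp_mmHg
    for _ in range(n_candidates):
        k = rng.integers(len(ys))
        cy, cx = int(ys[k]), int(xs[k])
        accept_p = np.exp(-(ttp_field[cy, cx] - ifp) / config.vessel_ttp_scale_mmHg)
        if rng.random() >= accept_p:
            continue
        a = r_px * rng.uniform(0.7, 1.3)
        b = a * rng.uniform(0.4, 1.0)
        th = rng.uniform(0, np.pi)
        half = int(np.ceil(a)) + 1
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
        u = xx * np.cos(th) + yy * np.sin(th)
        v = -xx * np.sin(th) + yy * np.cos(th)
        _stamp(vessels, (u / a) ** 2 + (v / b) ** 2 <= 1.0, cy, cx)
    return vessels & tumor


def _place_sites(
    config: PhantomConfig,
    tumor: np.ndarray,
    rng: np.random.Generator,
) -> tuple[MeasurementSite, ...]:
    """Rejection-sample site centers inside the tumor, pairwise separated
    by at least ``min_site_separation_mm``."""
    px = config.pixel_size_um
    margin_px = max(1, int(round(250.0 / px)))  # keep sensor clear of the edge
    inside = _ndi.distance_transform_edt(tumor) >= margin_px
    ys, xs = np.nonzero(inside)
    if len(ys) == 0:
        raise ValueError("tumor too small to place any measurement site")
    min_sep_px = config.min_site_separation_mm * 1000.0 / px
    centers: list[tuple[float, float]] = []
    # greedy sampling with full restarts: a badly placed first site must
    # not doom an otherwise feasible configuration
    for _ in range(200):
        centers = []
        for _ in range(500):
            k = rng.integers(len(ys))
            cand = (float(xs[k]), float(ys[k]))
            if all(
                (cand[0] - x) ** 2 + (cand[1] - y) ** 2 >= min_sep_px**2
                for x, y in centers
            ):
                centers.append(cand)
                if len(centers) == config.n_sites:
                    break
        if len(centers) == config.n_sites:
            break
    else:
        raise ValueError(
            f"cannot place {config.n_sites} sites "
            f">= {config.min_site_separation_mm} mm apart inside the tumor"
        )
    return tuple(
        MeasurementSite(
            site_id=f"site{i:02d}",
            center_px=c,
            needle_track_diameter_um=config.needle_track_diameter_um,
        )
        for i, c in enumerate(centers)
    )


# ---------------------------------------------------------------- rendering


def render_mt_image(
    truth_collagen: BinaryMask,
    tumor_mask: BinaryMask,
    rng: np.random.Generator | None = None,
) -> StainImage:
    """Render a Masson's-Trichrome-like RGB image from a collagen mask.

    Collagen pixels get HSV hue in [0.62, 0.68], saturation in
    [0.75, 0.95] and full value — safely inside the segmentation gate even
    after uint8 quantization.  Non-collagen tumor is rendered as pale pink
    tissue outside the gate; background is white.  Color variety comes
    from a 64-entry palette per tissue class (converted to RGB once) so
    whole-slide rendering stays cheap.
    """
    if truth_collagen.shape != tumor_mask.shape:
        raise ValueError("mask shapes disagree")
    rng = np.random.default_rng(0) if rng is None else rng
    n_pal = 64

    def _palette(h_lo, h_hi, s_lo, s_hi, v_lo, v_hi):
        hsv = np.stack(
            [
                rng.uniform(h_lo, h_hi, n_pal),
                rng.uniform(s_lo, s_hi, n_pal),
                rng.uniform(v_lo, v_hi, n_pal),
            ],
            axis=-1,
        )[np.newaxis]
        return np.clip(np.round(hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)[0]

    collagen_pal = _palette(0.62, 0.68, 0.75, 0.95, 1.0, 1.0)
    tissue_pal = _palette(0.93, 0.97, 0.20, 0.35, 0.85, 1.0)
    H, W = truth_collagen.shape
    rgb = np.full((H, W, 3), 255, dtype=np.uint8)
    tissue = tumor_mask.values & ~truth_collagen.values
    rgb[tissue] = tissue_pal[rng.integers(n_pal, size=int(tissue.sum()))]
    col = truth_collagen.values
    rgb[col] = collagen_pal[rng.integers(n_pal, size=int(col.sum()))]
    return StainImage(rgb, truth_collagen.pixel_size_um, StainKind.MT)


def render_habp_image(
    truth_ha: BinaryMask,
    tumor_mask: BinaryMask,
    rng: np.random.Generator | None = None,
) -> StainImage:
    """Render an HABP-1-like RGB image from an HA mask.

    HA pixels are brown with R strictly greater than twice G and B;
    non-HA tumor is pale pink failing the red-dominance rule; background
    is white (removed by white-background subtraction).
    """
    if truth_ha.shape != tumor_mask.shape:
        raise ValueError("mask shapes disagree")
    rng = np.random.default_rng(0) if rng is None else rng
    H, W = truth_ha.shape
    rgb = np.full((H, W, 3), 255, dtype=np.uint8)
    tissue = tumor_mask.values & ~truth_ha.values
    n_t = int(tissue.sum())
    rgb[..., 0][tissue] = rng.integers(190, 211, n_t)
    rgb[..., 1][tissue] = rng.integers(150, 171, n_t)
    rgb[..., 2][tissue] = rng.integers(140, 161, n_t)
    ha = truth_ha.values
    n_h = int(ha.sum())
    g = rng.integers(60, 81, n_h)
    b = rng.integers(50, 76, n_h)
    r = 2 * np.maximum(g, b) + rng.integers(10, 41, n_h)
    rgb[..., 0][ha] = np.clip(r, 0, 215).astype(np.uint8)
    rgb[..., 1][ha] = g.astype(np.uint8)
    rgb[..., 2][ha] = b.astype(np.uint8)
    return StainImage(rgb, truth_ha.pixel_size_um, StainKind.HABP)


def render_fluorescence(
    mask_or_field: BinaryMask | np.ndarray,
    gain: float,
    stain: StainKind = StainKind.LECTIN,
    pixel_size_um: float | None = None,
    rng: np.random.Generator | None = None,
    background_max: float = 5.0,
) -> StainImage:
    """Render a single-channel fluorescence image.

    A boolean mask renders as bright foreground (uniform in
    [0.6, 1.0] x gain) over dim background noise (uniform in
    [0, background_max]); a float field renders as field x gain plus the
    same background floor outside its support.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    if isinstance(mask_or_field, BinaryMask):
        m = mask_or_field.values
        px = mask_or_field.pixel_size_um
        img = rng.uniform(0.0, background_max, m.shape)
        img[m] = gain * rng.uniform(0.6, 1.0, int(m.sum()))
    else:
        f = np.asarray(mask_or_field, dtype=np.float64)
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required when passing a raw field")
        px = pixel_size_um
        img = gain * f + rng.uniform(0.0, background_max, f.shape) * (f <= 0)
    return StainImage(np.maximum(img, 0.0), px, stain)


# ---------------------------------------------------------------- assembly


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Generate one fully co-registered phantom from the config seed.

    The pressure records follow the elastic model applied to the ROI-local
    ground-truth area fractions at each site: TTP = model prediction plus
    Gaussian noise, IFP = model IFP plus the same noise (recorded at the
    first site only, as a single IFP probe per tumor).
    """
    rng = np.random.default_rng(config.seed)
    tumor = _tumor_mask(config, rng)
    _, collagen0 = generate_collagen_field(config, tumor, rng)
    ha_arr, rings = _place_ha_pools(config, tumor.values, rng)
    collagen_arr = (collagen0.values | rings) & ~ha_arr & tumor.values
    collagen = BinaryMask(collagen_arr, config.pixel_size_um)
    ha = BinaryMask(ha_arr & tumor.values, config.pixel_size_um)

    ttp_field = _local_ttp_field(collagen.values, ha.values, config)
    vessels = BinaryMask(
        _place_vessels(config, tumor.values, ttp_field, rng), config.pixel_size_um
    )

    verteporfin_field = np.zeros(config.image_size_px)
    inside = tumor.values
    verteporfin_field[inside] = config.verteporfin_i0 * np.exp(
        -ttp_field[inside] / config.verteporfin_tau_mmHg
    )
    verteporfin_field += rng.normal(
        0.0, config.verteporfin_noise_sd, config.image_size_px
    ) * inside
    verteporfin = StainImage(
        np.maximum(verteporfin_field, 0.0),
        config.pixel_size_um,
        StainKind.VERTEPORFIN,
    )

    sites = _place_sites(config, tumor.values, rng)
    records = []
    shape = config.image_size_px
    for i, site in enumerate(sites):
        roi = define_roi(site, config.roi_side_mm, config.pixel_size_um, shape)
        c_pct = area_fraction(collagen, roi, tumor)
        ha_pct = area_fraction(ha, roi, tumor)
        if c_pct > 0:
            ttp = predict_ttp(ha_pct, c_pct, config.model_params)
        else:  # ratio -> infinity limit: only fluid pressure remains
            ttp = config.model_params.ifp_mmHg
        ttp += rng.normal(0.0, config.pressure_noise_sd_mmHg) if config.pressure_noise_sd_mmHg else 0.0
        ifp = None
        if i == 0:
            ifp = config.model_params.ifp_mmHg + (
                rng.normal(0.0, config.pressure_noise_sd_mmHg)
                if config.pressure_noise_sd_mmHg
                else 0.0
            )
        records.append(PressureRecord(site.site_id, float(ttp), ifp))

    mt = render_mt_image(collagen, tumor, rng)
    habp = render_habp_image(ha, tumor, rng)
    lectin = render_fluorescence(
        vessels, config.lectin_gain, StainKind.LECTIN, rng=rng
    )
    return Phantom(
        config=config,
        mt_image=mt,
        habp_image=habp,
        lectin_image=lectin,
        verteporfin_image=verteporfin,
        truth_collagen=collagen,
        truth_ha=ha,
        truth_vessels=vessels,
        tumor_mask=tumor,
        sites=sites,
        records=tuple(records),
    )


# ---------------------------------------------------------------- file I/O


def write_phantom(phantom: Phantom, outdir: str | Path) -> dict[str, Path]:
    """Write stain channels as TIFF, masks as 0/255 PNG, and sites/records
    as CSV (site_id, x_px, y_px, ttp_mmHg, ifp_mmHg; empty = unmeasured)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, img in [
        ("mt", phantom.mt_image),
        ("habp", phantom.habp_image),
        ("lectin", phantom.lectin_image),
        ("verteporfin", phantom.verteporfin_image),
    ]:
        p = out / f"{name}.tif"
        data = img.pixels if img.stain.is_rgb else img.pixels.astype(np.float32)
        tifffile.imwrite(p, data)
        paths[name] = p
    for name, mask in [
        ("truth_collagen", phantom.truth_collagen),
        ("truth_ha", phantom.truth_ha),
        ("truth_vessels", phantom.truth_vessels),
        ("tumor_mask", phantom.tumor_mask),
    ]:
        p = out / f"{name}.png"
        Image.fromarray((mask.values * np.uint8(255))).save(p)
        paths[name] = p
    rec = {r.site_id: r for r in phantom.records}
    df = pd.DataFrame(
        {
            "site_id": [s.site_id for s in phantom.sites],
            "x_px": [s.center_px[0] for s in phantom.sites],
            "y_px": [s.center_px[1] for s in phantom.sites],
            "ttp_mmHg": [rec[s.site_id].ttp_mmHg for s in phantom.sites],
            "ifp_mmHg": [rec[s.site_id].ifp_mmHg for s in phantom.sites],
        }
    )
    p = out / "sites.csv"
    df.to_csv(p, index=False)
    paths["sites"] = p
    save_config(phantom.config, out / "phantom_config.yaml")
    paths["config"] = out / "phantom_config.yaml"
    return paths


def save_config(config: PhantomConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    d["image_size_px"] = list(d["image_size_px"])
    d["model_params"] = {
        "ss_swell_mmHg": config.model_params.ss_swell_mmHg,
        "ifp_mmHg": config.model_params.ifp_mmHg,
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_config(path: str | Path) -> PhantomConfig:
    d = yaml.safe_load(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(PhantomConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown phantom config keys: {sorted(unknown)}")
    if "image_size_px" in d:
        d["image_size_px"] = tuple(d["image_size_px"])
    if "model_params" in d:
        d["model_params"] = ElasticModelParams(**d["model_params"])
    return PhantomConfig(**d)
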