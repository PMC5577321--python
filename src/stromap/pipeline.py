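"""End-to-end orchestration: simulate -> segment -> quantify -> texture ->
fit -> map -> stats, with file artifacts at every stage and a manifest for
reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .core import BinaryMask, StainImage, StainKind
from .pressure_model import (
    TumorObservation,
    fit_ss_swell,
    fit_ttp_collagen_regression,
    ttp_map,
)
from .roi_quantification import StainBundle, define_roi, quantify_site
from .stain_segmentation import (
    DEFAULT_V_MIN,
    DEFAULT_WHITE_THRESHOLD,
    segment_collagen_mt,
    segment_ha_habp,
    segment_lectin,
)
from .stats_analysis import linear_regression, per_group_means, power_law_fit
from .synthetic_data import (
    Phantom,
    PhantomConfig,
    generate_phantom,
    write_phantom,
)
from .texture_metrics import DEFAULT_N_BINS, DEFAULT_TILE_PX, texture_profile

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    v_min: float = DEFAULT_V_MIN
    white_threshold: int = DEFAULT_WHITE_THRESHOLD
    lectin_threshold: float = 30.0
    roi_sides_mm: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0)
    texture_window_px: int = DEFAULT_TILE_PX
    texture_n_bins: int = DEFAULT_N_BINS
    ss_swell_bounds_mmHg: tuple[float, float] = (0.0, 1000.0)
    map_tile_size_um: float = 100.0
    pool_by_tumor: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lectin_threshold < 0:
            raise ValueError("lectin_threshold must be >= 0")
        if any(s <= 0 for s in self.roi_sides_mm):
            raise ValueError("roi_sides_mm must be positive")
        object.__setattr__(self, "roi_sides_mm", tuple(self.roi_sides_mm))
        object.__setattr__(
            self, "ss_swell_bounds_mmHg", tuple(self.ss_swell_bounds_mmHg)
        )


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML, rejecting unknown keys."""
    d = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    if "phantom" in d:
        from .synthetic_data import ElasticModelParams

        ph = dict(d["phantom"])
        if "image_size_px" in ph:
            ph["image_size_px"] = tuple(ph["image_size_px"])
        if "model_params" in ph:
            ph["model_params"] = ElasticModelParams(**ph["model_params"])
        d["phantom"] = PhantomConfig(**ph)
    return PipelineConfig(**d)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def segment_phantom(phantom: Phantom, config: PipelineConfig) -> StainBundle:
    """Run the three segmenters on the rendered channels of a phantom."""
    return StainBundle(
        collagen=segment_collagen_mt(phantom.mt_image, v_min=config.v_min),
        ha=segment_ha_habp(phantom.habp_image, white_threshold=config.white_threshold),
        vessels=segment_lectin(phantom.lectin_image, config.lectin_threshold),
        verteporfin=phantom.verteporfin_image,
        tumor=phantom.tumor_mask,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage on a simulated phantom and write all artifacts.

    Returns a results dict mirroring what is written to disk.  Reruns with
    the same config are numerically identical (all randomness flows from
    the phantom seed).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        phantom = generate_phantom(
            dataclasses.replace(config.phantom, seed=config.seed)
        )
        write_phantom(phantom, out / "phantom")

        stage = "segment"
        bundle = segment_phantom(phantom, config)

        stage = "quantify"
        rec = {r.site_id: r for r in phantom.records}
        rows = []
        for site in phantom.sites:
            for side in config.roi_sides_mm:
                q = quantify_site(bundle, site, side, rec[site.site_id])
                rows.append(dataclasses.asdict(q))
        quant = pd.DataFrame(rows)
        quant.to_csv(out / "roi_quant.csv", index=False)

        stage = "texture"
        trows = []
        shape = bundle.collagen.shape
        for site in phantom.sites:
            side = max(config.roi_sides_mm)
            roi = define_roi(site, side, bundle.collagen.pixel_size_um, shape)
            prof = texture_profile(
                bundle.collagen,
                roi,
                window_px=config.texture_window_px,
                n_bins=config.texture_n_bins,
            )
            trows.append(
                {
                    "site_id": site.site_id,
                    "side_mm": side,
                    "entropy_bits": prof.entropy_bits,
                    "uniformity": prof.uniformity,
                    "fractal_D": prof.fractal_D,
                    "fractal_fit_r2": prof.fractal_fit_r2,
                    "window_px": prof.window_px,
                    "n_bins": prof.n_bins,
                }
            )
        texture = pd.DataFrame(trows)
        texture.to_csv(out / "texture.csv", index=False)

        stage = "fit"
        # headline ROI side for model fitting
        side0 = config.phantom.roi_side_mm
        if side0 not in config.roi_sides_mm:
            side0 = config.roi_sides_mm[0]
        q0 = quant[quant.side_mm == side0]
        ifp_vals = q0.ifp_mmHg.dropna()
        mean_ifp = float(ifp_vals.mean()) if len(ifp_vals) else 0.0
        obs = [
            TumorObservation(row.ttp_mmHg, row.ha_frac_pct, row.collagen_frac_pct)
            for row in q0.itertuples()
            if row.collagen_frac_pct > 0 and row.ttp_mmHg is not None
        ]
        model_block = None
        if len(obs) >= 3:
            params, r2, _ = fit_ss_swell(
                obs, mean_ifp, bounds=config.ss_swell_bounds_mmHg
            )
            model_block = {
                "ss_swell_mmHg": params.ss_swell_mmHg,
                "ifp_mmHg": params.ifp_mmHg,
                "r2": r2,
                "n": len(obs),
            }
        reg = fit_ttp_collagen_regression(
            q0.ttp_mmHg.to_numpy(), q0.collagen_frac_pct.to_numpy()
        )
        reg_block = dataclasses.asdict(reg)
        (out / "model.json").write_text(
            json.dumps(
                {"elastic_model": model_block, "ttp_collagen_regression": reg_block},
                indent=2,
            )
        )

        stage = "map"
        tmap = ttp_map(
            bundle.collagen,
            phantom.tumor_mask,
            reg,
            tile_size_um=config.map_tile_size_um,
        )
        tifffile.imwrite(out / "ttp_map.tif", tmap.values.astype(np.float32))
        nh, nw = tmap.values.shape
        tile_px = tmap.tile_size_um / bundle.collagen.pixel_size_um
        centers_y, centers_x = np.mgrid[0:nh, 0:nw]
        pd.DataFrame(
            {
                "tile_x_px": (centers_x.ravel() + 0.5) * tile_px,
                "tile_y_px": (centers_y.ravel() + 0.5) * tile_px,
                "ttp_mmHg": tmap.values.ravel(),
            }
        ).to_csv(out / "ttp_map_tiles.csv", index=False)

        stage = "stats"
        stats_block: dict = {}
        vq = q0[(q0.vessel_frac_pct > 0) & (q0.ttp_mmHg > 0)]
        if len(vq) >= 3 and vq.vessel_frac_pct.nunique() > 1:
            pl = power_law_fit(vq.vessel_frac_pct.to_numpy(), vq.ttp_mmHg.to_numpy())
            stats_block["ttp_vs_vessel_power_law"] = dataclasses.asdict(pl)
        if q0.verteporfin_mean.nunique() > 1 and len(q0) >= 3:
            vr = linear_regression(
                q0.ttp_mmHg.to_numpy(), q0.verteporfin_mean.to_numpy()
            )
            stats_block["verteporfin_vs_ttp_regression"] = dataclasses.asdict(vr)
        (out / "stats.json").write_text(json.dumps(stats_block, indent=2))

        stage = "report"
        manifest = {
            "stromap_version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "numpy_version": np.__version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        report = [
            "# stromap run report",
            "",
            f"- seed: {config.seed}",
            f"- sites: {len(phantom.sites)}; ROI sides (mm): {list(config.roi_sides_mm)}",
            f"- TTP ~ collagen regression: slope={reg.slope:.3f} mmHg/%, "
            f"intercept={reg.intercept:.2f} mmHg, R2={reg.r2:.3f}, p={reg.p_value:.3g}",
        ]
        if model_block:
            report.append(
                f"- elastic model fit: SS_swell={model_block['ss_swell_mmHg']:.1f} mmHg "
                f"(IFP={model_block['ifp_mmHg']:.1f} mmHg), R2={model_block['r2']:.3f}"
            )
        (out / "report.md").write_text("\n".join(report) + "\n")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return {
        "quant": quant,
        "texture": texture,
        "model": model_block,
        "regression": reg_block,
        "stats": stats_block,
        "ttp_map": tmap,
        "outdir": out,
    }
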