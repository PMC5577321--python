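"""Elastic spring model linking stromal composition to total tissue pressure.

Total tissue pressure (TTP) is modelled as a constant hyaluronan swelling
stress transmitted through collagen confinement, sitting on top of the
interstitial fluid pressure (IFP):

    TTP = SS_swell / (1 + [HA]/[C]) + IFP

where [HA] and [C] are the hyaluronan and collagen area fractions of the
local ROI.  Only their ratio enters, so percent and proportion units are
interchangeable.  SS_swell is fit by a one-dimensional bounded search
maximizing the coefficient of determination against observed TTP, with IFP
held at its measured mean.  A calibrated TTP-versus-collagen regression
turns whole-section collagen maps into predicted TTP maps on a ~100 um
tile grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize as _optimize

from .core import BinaryMask
from .stats_analysis import RegressionResult, linear_regression

__all__ = [
    "ElasticModelParams",
    "TumorObservation",
    "TTPMap",
    "predict_ttp",
    "fit_ss_swell",
    "fit_ttp_collagen_regression",
    "ttp_map",
]


@dataclass(frozen=True)
class ElasticModelParams:
    """Fitted constants of the spring model: the hyaluronan swelling stress
    SS_swell and the fluid-pressure offset IFP, both in mmHg."""

    ss_swell_mmHg: float
    ifp_mmHg: float

    def __post_init__(self) -> None:
        if self.ss_swell_mmHg < 0:
            raise ValueError(f"ss_swell_mmHg must be >= 0, got {self.ss_swell_mmHg}")


@dataclass(frozen=True)
class TumorObservation:
    """One fitted data point: observed TTP with its ROI area fractions."""

    ttp_mmHg: float
    ha_frac_pct: float
    collagen_frac_pct: float

    def __post_init__(self) -> None:
        if self.collagen_frac_pct <= 0:
            raise ValueError("collagen fraction must be > 0 for the ratio model")
        if self.ha_frac_pct < 0:
            raise ValueError("HA fraction must be >= 0")


@dataclass(frozen=True)
class TTPMap:
    """Tile grid of predicted TTP (mmHg); NaN marks tiles outside the tumor
    (or with insufficient tumor coverage)."""

    values: np.ndarray
    tile_size_um: float
    regression: RegressionResult

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def predict_ttp(ha_frac, collagen_frac, params: ElasticModelParams):
    """Model TTP for given HA and collagen area fractions.

    Accepts scalars or arrays (broadcast).  Strictly decreasing in the
    ratio [HA]/[C]: the ratio -> 0 limit is SS_swell + IFP and the
    ratio -> infinity limit is IFP.  Zero collagen is rejected, as the
    ratio is then undefined.
    """
    ha = np.asarray(ha_frac, dtype=np.float64)
    c = np.asarray(collagen_frac, dtype=np.float64)
    if np.any(c <= 0):
        raise ValueError("collagen fraction must be > 0 (ratio undefined at 0)")
    if np.any(ha < 0):
        raise ValueError("HA fraction must be >= 0")
    out = params.ss_swell_mmHg / (1.0 + ha / c) + params.ifp_mmHg
    return float(out) if out.ndim == 0 else out


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(((observed - predicted) ** 2).sum())
    ss_tot = float(((observed - observed.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)


def fit_ss_swell(
    observations: list[TumorObservation],
    ifp_mmHg: float,
    bounds: tuple[float, float] = (0.0, 1000.0),
    tol_mmHg: float = 0.01,
) -> tuple[ElasticModelParams, float, list[tuple[float, float]]]:
    """Fit SS_swell by bounded 1-D search maximizing R^2 of predicted TTP.

    IFP is held fixed at the supplied (measured mean) value.  Returns the
    fitted parameters, the achieved R^2, and the search trace as a list of
    (ss_swell, r2) evaluations.  If the optimum lands at the upper bound
    the bracket is widened (doubled, a few times) before giving up.
    """
    if len(observations) < 3:
        raise ValueError(f"need >= 3 observations, got {len(observations)}")
    ttp = np.array([o.ttp_mmHg for o in observations])
    ratio = np.array([o.ha_frac_pct / o.collagen_frac_pct for o in observations])
    if np.ptp(ratio) == 0:
        raise ValueError("all HA/collagen ratios identical; fit is degenerate")
    confinement = 1.0 / (1.0 + ratio)
    trace: list[tuple[float, float]] = []

    def neg_r2(s: float) -> float:
        r2 = _r2(ttp, s * confinement + ifp_mmHg)
        trace.append((float(s), r2))
        return -r2

    lo, hi = bounds
    for _ in range(8):
        res = _optimize.minimize_scalar(
            neg_r2, bounds=(lo, hi), method="bounded",
            options={"xatol": tol_mmHg},
        )
        if hi - res.x > 2 * tol_mmHg:
            break
        hi *= 2  # optimum pinned at the bound: widen and retry
    params = ElasticModelParams(ss_swell_mmHg=float(res.x), ifp_mmHg=ifp_mmHg)
    return params, float(-res.fun), trace


def fit_ttp_collagen_regression(ttp_mmHg, collagen_frac_pct) -> RegressionResult:
    """Calibrate the linear TTP = a*[C] + b regression used for TTP maps."""
    return linear_regression(collagen_frac_pct, ttp_mmHg)


def ttp_map(
    collagen_mask: BinaryMask,
    tumor_mask: BinaryMask,
    regression: RegressionResult,
    tile_size_um: float = 100.0,
    min_tumor_coverage: float = 0.5,
) -> TTPMap:
    """Predict a whole-section TTP map from the collagen distribution.

    The section is divided into square tiles of ``tile_size_um``; each
    tile's collagen area fraction (percent of its tumor pixels) is pushed
    through the calibrated regression.  Tiles with less than
    ``min_tumor_coverage`` tumor coverage are NaN.
    """
    px = collagen_mask.pixel_size_um
    tile_px = int(round(tile_size_um / px))
    if tile_px < 4:
        raise ValueError(
            f"tile_size_um={tile_size_um} is {tile_px} px at {px} um/px; need >= 4"
        )
    col = collagen_mask.values
    tum = tumor_mask.values
    H, W = col.shape
    nh, nw = H // tile_px, W // tile_px
    if nh == 0 or nw == 0:
        raise ValueError("image smaller than one tile")
    shape4 = (nh, tile_px, nw, tile_px)
    tum_cnt = tum[: nh * tile_px, : nw * tile_px].reshape(shape4).sum(axis=(1, 3))
    col_cnt = (
        (col & tum)[: nh * tile_px, : nw * tile_px].reshape(shape4).sum(axis=(1, 3))
    )
    defined = tum_cnt >= min_tumor_coverage * tile_px * tile_px
    if not defined.any():
        raise ValueError("no tiles with sufficient tumor coverage")
    values = np.full((nh, nw), np.nan)
    frac_pct = np.zeros_like(values)
    np.divide(100.0 * col_cnt, tum_cnt, out=frac_pct, where=tum_cnt > 0)
    values[defined] = regression.predict(frac_pct[defined])
    return TTPMap(values=values, tile_size_um=tile_px * px, regression=regression)
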