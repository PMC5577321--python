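"""Texture statistics of collagen distribution: entropy, uniformity, and
box-counting fractal dimension.

Entropy and uniformity are computed from the histogram of local collagen
area fractions V, obtained by tiling the ROI into non-overlapping square
sub-windows:

    Entropy    = -sum_i P(V_i) log2 P(V_i)        (bits)
    Uniformity =  sum_i P(V_i)^2

The fractal dimension D is the slope of log N(e) versus log(1/e), where
N(e) is the number of boxes of side e containing at least one collagen
pixel, for e = 2, 4, 8, ... up to a quarter of the window side.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BinaryMask
from .roi_quantification import ROI

__all__ = [
    "FractionHistogram",
    "TextureProfile",
    "local_fraction_histogram",
    "entropy",
    "uniformity",
    "fractal_dimension",
    "texture_profile",
    "DEFAULT_TILE_PX",
    "DEFAULT_N_BINS",
]

DEFAULT_TILE_PX = 32
DEFAULT_N_BINS = 64

_MIN_TILES = 16


@dataclass(frozen=True)
class FractionHistogram:
    """Probability histogram of local collagen area fractions on [0, 1]."""

    probabilities: np.ndarray
    bin_edges: np.ndarray
    window_px: int
    n_bins: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probabilities", p)


@dataclass(frozen=True)
class TextureProfile:
    """The three texture statistics for one ROI, plus the box-count fit R2."""

    entropy_bits: float
    uniformity: float
    fractal_D: float
    fractal_fit_r2: float
    window_px: int
    n_bins: int


def _window(mask: BinaryMask, roi: ROI | None) -> np.ndarray:
    if roi is None:
        return mask.values
    return roi.extract(mask.values)


def local_fraction_histogram(
    mask: BinaryMask,
    roi: ROI | None = None,
    window_px: int = DEFAULT_TILE_PX,
    n_bins: int = DEFAULT_N_BINS,
) -> FractionHistogram:
    """Histogram of per-tile collagen fractions within an ROI.

    The ROI window is tiled into non-overlapping ``window_px`` squares
    (partial edge tiles are dropped), the collagen fraction V of each tile
    is histogrammed into ``n_bins`` equal bins on [0, 1], and counts are
    normalized to probabilities.  Fewer than 16 complete tiles raises, as
    the histogram is then too unstable to carry texture statistics.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    win = _window(mask, roi)
    H, W = win.shape
    nh, nw = H // window_px, W // window_px
    if nh * nw < _MIN_TILES:
        raise ValueError(
            f"only {nh * nw} complete {window_px}-px tiles fit in the "
            f"{H}x{W} ROI; need at least {_MIN_TILES}"
        )
    tiles = win[: nh * window_px, : nw * window_px].reshape(
        nh, window_px, nw, window_px
    )
    fractions = tiles.mean(axis=(1, 3)).ravel()
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(fractions, bins=edges)
    # np.histogram's last bin is closed, so V = 1 lands in the top bin
    probs = counts / counts.sum()
    return FractionHistogram(probs, edges, window_px, n_bins)


def entropy(h: FractionHistogram) -> float:
    """Shannon entropy (bits) of the fraction histogram; 0 log 0 := 0."""
    p = h.probabilities[h.probabilities > 0]
    return float(-(p * np.log2(p)).sum())


def uniformity(h: FractionHistogram) -> float:
    """Sum of squared bin probabilities (a.k.a. energy); 1 for a point mass,
    1/N for a flat histogram over N bins."""
    return float((h.probabilities**2).sum())


def _box_sizes(side: int) -> list[int]:
    sizes, e = [], 2
    while e <= side // 4:
        sizes.append(e)
        e *= 2
    return sizes


def fractal_dimension(
    mask: BinaryMask, roi: ROI | None = None
) -> tuple[float, float]:
    """Box-counting fractal dimension of the collagen set within an ROI.

    Returns ``(D, r2)`` where D is the least-squares slope of log N versus
    log(1/e) over box sides e = 2, 4, ..., side/4 and r2 is the fit quality.
    Requires a window of at least 64 px per side and a nonempty mask.
    """
    win = _window(mask, roi)
    side = min(win.shape)
    if side < 64:
        raise ValueError(f"ROI window must be >= 64 px per side, got {side}")
    if not win.any():
        raise ValueError("mask is empty in the ROI; fractal dimension undefined")
    log_n, log_inv_e = [], []
    for e in _box_sizes(side):
        nh, nw = win.shape[0] // e, win.shape[1] // e
        # grid anchored at the window origin; incomplete edge boxes are
        # dropped so every count covers the same full-box support
        occupied = int(
            win[: nh * e, : nw * e].reshape(nh, e, nw, e).any(axis=(1, 3)).sum()
        )
        if occupied == 0:
            continue
        log_n.append(np.log(occupied))
        log_inv_e.append(np.log(1.0 / e))
    x = np.asarray(log_inv_e)
    y = np.asarray(log_n)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return float(slope), r2


def texture_profile(
    mask: BinaryMask,
    roi: ROI | None = None,
    window_px: int = DEFAULT_TILE_PX,
    n_bins: int = DEFAULT_N_BINS,
) -> TextureProfile:
    """Entropy, uniformity and fractal dimension of one ROI in one call."""
    h = local_fraction_histogram(mask, roi, window_px=window_px, n_bins=n_bins)
    d, r2 = fractal_dimension(mask, roi)
    return TextureProfile(entropy(h), uniformity(h), d, r2, window_px, n_bins)
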