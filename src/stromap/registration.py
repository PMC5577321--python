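"""Control-point similarity registration of serial sections.

Serial histology sections are aligned by a conformal linear transform
(uniform scale + rotation + translation, no reflection) estimated in
least squares from 5-8 manually matched surface features, mirroring the
classic control-point workflow.  Masks are resampled nearest-neighbour so
downstream area fractions are not diluted by interpolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import transform as _sk_transform

from .core import BinaryMask

__all__ = [
    "ControlPointSet",
    "SimilarityTransform",
    "estimate_similarity",
    "warp_mask",
    "read_control_points",
    "write_transform",
    "read_transform",
]


@dataclass(frozen=True)
class ControlPointSet:
    """Matched ``(x, y)`` pixel coordinates on the moving (source) and
    fixed (target) sections."""

    source_points: np.ndarray
    target_points: np.ndarray

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.source_points, dtype=np.float64))
        dst = np.atleast_2d(np.asarray(self.target_points, dtype=np.float64))
        if src.shape != dst.shape or src.shape[1] != 2:
            raise ValueError("source and target must be equal-length (n, 2) arrays")
        if len(src) < 2:
            raise ValueError(f"at least 2 point pairs required, got {len(src)}")
        if len(np.unique(src, axis=0)) != len(src):
            raise ValueError("duplicated source points")
        object.__setattr__(self, "source_points", src)
        object.__setattr__(self, "target_points", dst)

    def __len__(self) -> int:
        return len(self.source_points)


@dataclass(frozen=True)
class SimilarityTransform:
    """Conformal map ``p -> s R(theta) p + t`` in (x, y) pixel coordinates."""

    scale: float
    rotation_rad: float
    tx: float
    ty: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation_rad), np.sin(self.rotation_rad)
        m = np.array(
            [
                [self.scale * c, -self.scale * s, self.tx],
                [self.scale * s, self.scale * c, self.ty],
                [0.0, 0.0, 1.0],
            ]
        )
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        homo = np.hstack([pts, np.ones((len(pts), 1))])
        return (self.matrix @ homo.T).T[:, :2]

    def inverse(self) -> "SimilarityTransform":
        s = 1.0 / self.scale
        th = -self.rotation_rad
        c, sn = np.cos(th), np.sin(th)
        tx = -s * (c * self.tx - sn * self.ty)
        ty = -s * (sn * self.tx + c * self.ty)
        return SimilarityTransform(s, th, tx, ty)


def estimate_similarity(points: ControlPointSet) -> tuple[SimilarityTransform, float]:
    """Least-squares conformal transform from matched control points.

    Returns the transform and the RMS of the target-space residuals.
    Uses the closed-form Umeyama solution constrained to a proper rotation
    (determinant +1), i.e. reflections are excluded.
    """
    src, dst = points.source_points, points.target_points
    if np.allclose(src, src[0]):
        raise ValueError("all source points coincide; similarity is undefined")
    est = _sk_transform.SimilarityTransform.from_estimate(src, dst)
    if not est:
        raise ValueError("similarity estimation failed for the given points")
    t = SimilarityTransform(
        scale=float(est.scale),
        rotation_rad=float(est.rotation),
        tx=float(est.translation[0]),
        ty=float(est.translation[1]),
    )
    resid = t.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return t, rms


def warp_mask(
    mask: BinaryMask, t: SimilarityTransform, out_shape: tuple[int, int] | None = None
) -> BinaryMask:
    """Apply a similarity transform to a mask with nearest-neighbour
    resampling; pixels mapping from outside the source are false."""
    if out_shape is None:
        out_shape = mask.shape
    sk = _sk_transform.SimilarityTransform(matrix=t.matrix)
    warped = _sk_transform.warp(
        mask.values.astype(np.float64),
        inverse_map=sk.inverse,
        output_shape=out_shape,
        order=0,
        mode="constant",
        cval=0.0,
        preserve_range=True,
    )
    return BinaryMask(warped > 0.5, mask.pixel_size_um)


def read_control_points(path: str | Path) -> ControlPointSet:
    """Read matched points from a CSV with columns x_src, y_src, x_dst, y_dst."""
    df = pd.read_csv(path)
    return ControlPointSet(
        df[["x_src", "y_src"]].to_numpy(), df[["x_dst", "y_dst"]].to_numpy()
    )


def write_transform(t: SimilarityTransform, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {"s": t.scale, "theta_rad": t.rotation_rad, "tx": t.tx, "ty": t.ty},
            indent=2,
        )
    )


def read_transform(path: str | Path) -> SimilarityTransform:
    d = json.loads(Path(path).read_text())
    return SimilarityTransform(d["s"], d["theta_rad"], d["tx"], d["ty"])
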