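"""Color-rule segmentation of histology stains into binary masks.

Collagen is extracted from Masson's-Trichrome RGB images by thresholding in
HSV space (blue collagen: hue 0.6-0.7, saturation 0.7-1, value up to 1).
Hyaluronan is extracted from HABP-1 images by a red-dominance rule (brown
pixels: R more than twice G and B) after white-background subtraction.
Patent vessels are extracted from lectin fluorescence by a fixed intensity
threshold.  All threshold interval endpoints are inclusive.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2hsv

from .core import BinaryMask, StainImage, StainKind

__all__ = [
    "segment_collagen_mt",
    "segment_ha_habp",
    "segment_lectin",
    "DEFAULT_WHITE_THRESHOLD",
    "DEFAULT_V_MIN",
]

#: All three RGB channels strictly above this value counts as white background.
DEFAULT_WHITE_THRESHOLD = 220

#: Lower bound of the HSV value gate for collagen.  The printed upper bound
#: is 1; a strict equality V == 1 would select almost nothing in real scans,
#: so the gate is [v_min, 1] with v_min surfaced as a parameter.
DEFAULT_V_MIN = 0.0


def _require(image: StainImage, kind: StainKind) -> np.ndarray:
    if image.stain is not kind:
        raise TypeError(f"expected a {kind.value} image, got {image.stain.value}")
    return image.pixels


def segment_collagen_mt(image: StainImage, v_min: float = DEFAULT_V_MIN) -> BinaryMask:
    """Segment collagen from a Masson's-Trichrome RGB image.

    A pixel is collagen iff its HSV coordinates satisfy hue in [0.6, 0.7],
    saturation in [0.7, 1] and value in [``v_min``, 1], with hue normalized
    to [0, 1).  Achromatic pixels get hue 0 and fail the saturation gate.

    Parameters
    ----------
    image
        MT-stained RGB image (uint8 or float in [0, 255]).
    v_min
        Lower bound of the value gate, default 0 (value effectively
        unconstrained below the inclusive upper bound of 1).
    """
    px = _require(image, StainKind.MT)
    hsv = rgb2hsv(np.asarray(px, dtype=np.float64) / 255.0)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    mask = (
        (h >= 0.6) & (h <= 0.7)
        & (s >= 0.7) & (s <= 1.0)
        & (v >= v_min) & (v <= 1.0)
    )
    return BinaryMask(mask, image.pixel_size_um)


def segment_ha_habp(
    image: StainImage, white_threshold: int = DEFAULT_WHITE_THRESHOLD
) -> BinaryMask:
    """Segment hyaluronan from an HABP-1 RGB image.

    A pixel is HA iff it is not white background (all three channels above
    ``white_threshold``) and its red intensity strictly exceeds twice both
    the green and the blue intensity.
    """
    px = _require(image, StainKind.HABP).astype(np.int32)
    r, g, b = px[..., 0], px[..., 1], px[..., 2]
    background = (r > white_threshold) & (g > white_threshold) & (b > white_threshold)
    mask = ~background & (r > 2 * g) & (r > 2 * b)
    return BinaryMask(mask, image.pixel_size_um)


def segment_lectin(image: StainImage, threshold: float) -> BinaryMask:
    """Threshold a lectin fluorescence channel into a patent-vessel mask.

    A pixel is vessel iff its intensity strictly exceeds ``threshold``.
    """
    if threshold < 0:
        raise ValueError(f"lectin threshold must be >= 0, got {threshold}")
    px = _require(image, StainKind.LECTIN)
    return BinaryMask(px > threshold, image.pixel_size_um)
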