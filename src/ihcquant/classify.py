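"""Intensity-binned positive-pixel classification of DAB/hematoxylin images.

The classifier works in an HSI parameterization: hexagonal hue in [0, 1)
with 0 at pure red, saturation ``1 - min(R,G,B)/I``, and intensity
``I = (R+G+B)/3`` on the 0-255 scale.  A pixel inside the region of
interest is *positive* when its hue falls inside a circular window around
the DAB-brown hue, its saturation clears a floor, and its intensity is
below an upper bound (very faint pixels do not count as stained).
Positive pixels are binned by intensity into weak, medium and strong
classes — darker means stronger, since chromogen absorbs light.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from skimage.color import rgb2hsv


class PixelLabel(IntEnum):
    """Per-pixel class codes used in label maps."""

    EXCLUDED = 0
    NEGATIVE = 1
    WEAK = 2
    MEDIUM = 3
    STRONG = 4


#: Markup palette, bit-exact: strong red, medium orange, weak yellow,
#: negative blue, excluded white.
MARKUP_PALETTE: dict[PixelLabel, tuple[int, int, int]] = {
    PixelLabel.STRONG: (255, 0, 0),
    PixelLabel.MEDIUM: (255, 165, 0),
    PixelLabel.WEAK: (255, 255, 0),
    PixelLabel.NEGATIVE: (0, 0, 255),
    PixelLabel.EXCLUDED: (255, 255, 255),
}


@dataclass(frozen=True)
class PixelClassParams:
    """Thresholds of the positive-pixel counting algorithm.

    Defaults follow the publicly documented defaults of the commercial
    "positive pixel count v9" algorithm widely used for DAB
    quantification: a brown hue window centered at 0.1 spanning +-0.25,
    a low saturation floor, and intensity bins
    strong [0, 100) < medium [100, 175) < weak [175, 220), with pixels
    at intensity >= 220 considered too faint to count as stained.

    Parameters
    ----------
    hue_center : float
        Center of the chromogen hue window, in [0, 1); 0.1 is DAB brown.
    hue_width : float
        Full width of the hue window (circular), in (0, 1].
    saturation_threshold : float
        Minimum saturation for a pixel to count as stained.
    iwp_high : float
        Upper intensity bound for weak positivity; brighter pixels are
        negative.
    iwp_low : float
        Weak/medium bin boundary.
    ip_low : float
        Medium/strong bin boundary.
    isp_low : float
        Lower intensity bound for strong positivity.
    """

    hue_center: float = 0.1
    hue_width: float = 0.5
    saturation_threshold: float = 0.04
    iwp_high: float = 220.0
    iwp_low: float = 175.0
    ip_low: float = 100.0
    isp_low: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hue_center < 1.0:
            raise ValueError("hue_center must lie in [0, 1)")
        if not 0.0 < self.hue_width <= 1.0:
            raise ValueError("hue_width must lie in (0, 1]")
        if not 0.0 <= self.saturation_threshold <= 1.0:
            raise ValueError("saturation_threshold must lie in [0, 1]")
        if not self.isp_low < self.ip_low < self.iwp_low < self.iwp_high:
            raise ValueError(
                "intensity bounds must satisfy isp_low < ip_low < iwp_low < iwp_high"
            )


@dataclass(frozen=True)
class PixelCounts:
    """Tally of one sample's ROI pixels by class.

    ``n_total`` counts included pixels only (positive + negative);
    excluded pixels contribute to no count.
    """

    n_weak: int
    n_medium: int
    n_strong: int
    n_negative: int
    n_total: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.n_total == -1:
            object.__setattr__(
                self,
                "n_total",
                self.n_weak + self.n_medium + self.n_strong + self.n_negative,
            )
        if min(self.n_weak, self.n_medium, self.n_strong, self.n_negative) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_total != self.n_weak + self.n_medium + self.n_strong + self.n_negative:
            raise ValueError("n_total must equal the sum of the four class counts")

    @property
    def n_positive(self) -> int:
        return self.n_weak + self.n_medium + self.n_strong


def _validate_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB image, got shape {image.shape}")
    if image.shape[0] < 1 or image.shape[1] < 1:
        raise ValueError("image must contain at least one pixel")
    return image


def rgb_to_hsi(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an 8-bit RGB image to per-pixel hue/saturation/intensity.

    Hue is the standard hexagonal hue normalized to [0, 1) with 0 at pure
    red (reported as 0 for achromatic pixels); saturation is
    ``1 - min(R,G,B)/I`` (0 when I = 0); intensity is the channel mean on
    the 0-255 scale.

    Returns
    -------
    (hue, saturation, intensity) : tuple of float64 arrays, shape HxW.
    """
    image = _validate_rgb(image)
    rgb = image.astype(np.float64)
    intensity = rgb.mean(axis=2)
    cmin = rgb.min(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        saturation = np.where(intensity > 0, 1.0 - cmin / intensity, 0.0)
    # hexagonal hue from the HSV model; V/S differ from ours, H is shared
    hue = rgb2hsv(image.astype(np.uint8))[..., 0]
    hue = np.where(hue >= 1.0, 0.0, hue)
    return hue, saturation, intensity


def _circular_hue_distance(hue: np.ndarray, center: float) -> np.ndarray:
    d = np.abs(hue - center)
    return np.minimum(d, 1.0 - d)


def classify_pixels(
    image: np.ndarray,
    mask: np.ndarray | None = None,
    params: PixelClassParams | None = None,
) -> tuple[np.ndarray, PixelCounts]:
    """Label every ROI pixel as negative or weak/medium/strong positive.

    A pixel is positive when its hue lies within ``hue_center +-
    hue_width/2`` (circular distance), its saturation is at least
    ``saturation_threshold`` and its intensity lies in
    ``[isp_low, iwp_high)``.  Positive pixels fall into half-open bins
    closed at the darker end: strong ``[isp_low, ip_low)``, medium
    ``[ip_low, iwp_low)``, weak ``[iwp_low, iwp_high)``.  All other
    included pixels are negative.

    Parameters
    ----------
    image : HxWx3 uint8 array.
    mask : HxW boolean (or nonzero) array, or None to include all pixels.
    params : classification thresholds; defaults used when None.

    Returns
    -------
    labels : HxW uint8 array of :class:`PixelLabel` codes.
    counts : :class:`PixelCounts` over included pixels.

    Raises
    ------
    ValueError
        If mask and image dimensions differ.
    """
    image = _validate_rgb(image)
    params = params or PixelClassParams()
    if mask is None:
        include = np.ones(image.shape[:2], dtype=bool)
    else:
        include = np.asarray(mask).astype(bool)
        if include.shape != image.shape[:2]:
            raise ValueError(
                f"mask shape {include.shape} does not match image shape {image.shape[:2]}"
            )

    hue, sat, inten = rgb_to_hsi(image)
    in_hue = _circular_hue_distance(hue, params.hue_center) <= params.hue_width / 2.0
    positive = (
        include
        & in_hue
        & (sat >= params.saturation_threshold)
        & (inten >= params.isp_low)
        & (inten < params.iwp_high)
    )

    labels = np.full(image.shape[:2], PixelLabel.EXCLUDED, dtype=np.uint8)
    labels[include] = PixelLabel.NEGATIVE
    labels[positive & (inten < params.ip_low)] = PixelLabel.STRONG
    labels[positive & (inten >= params.ip_low) & (inten < params.iwp_low)] = PixelLabel.MEDIUM
    labels[positive & (inten >= params.iwp_low)] = PixelLabel.WEAK

    counts = count_labels(labels)
    return labels, counts


def count_labels(labels: np.ndarray) -> PixelCounts:
    """Tally a label map into :class:`PixelCounts` (excluded pixels ignored)."""
    labels = np.asarray(labels)
    return PixelCounts(
        n_weak=int((labels == PixelLabel.WEAK).sum()),
        n_medium=int((labels == PixelLabel.MEDIUM).sum()),
        n_strong=int((labels == PixelLabel.STRONG).sum()),
        n_negative=int((labels == PixelLabel.NEGATIVE).sum()),
    )


def render_markup(labels: np.ndarray) -> np.ndarray:
    """Render a label map as the conventional markup image.

    Strong pixels are red, medium orange, weak yellow, negative blue and
    excluded white; the palette is bijective so the label map can be
    recovered from the markup.
    """
    labels = np.asarray(labels)
    out = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for label, rgb in MARKUP_PALETTE.items():
        out[labels == label] = rgb
    return out
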