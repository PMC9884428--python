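"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import colorsys

import numpy as np
import pytest

from ihcquant import PixelClassParams, PixelLabel


def brute_force_classify(image, mask, params: PixelClassParams) -> np.ndarray:
    """Scalar per-pixel reimplementation of the threshold rules.

    Uses colorsys (stdlib) for the hexagonal hue, so it shares no code
    with the vectorized classifier it checks.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    labels = np.empty((h, w), dtype=np.uint8)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                labels[y, x] = PixelLabel.EXCLUDED
                continue
            r, g, b = (int(v) for v in image[y, x])
            hue = colorsys.rgb_to_hsv(r / 255.0, g / 255.0, b / 255.0)[0]
            if hue >= 1.0:
                hue = 0.0
            intensity = (r + g + b) / 3.0
            sat = 1.0 - min(r, g, b) / intensity if intensity > 0 else 0.0
            d = abs(hue - params.hue_center)
            in_window = min(d, 1.0 - d) <= params.hue_width / 2.0
            positive = (
                in_window
                and sat >= params.saturation_threshold
                and params.isp_low <= intensity < params.iwp_high
            )
            if not positive:
                labels[y, x] = PixelLabel.NEGATIVE
            elif intensity < params.ip_low:
                labels[y, x] = PixelLabel.STRONG
            elif intensity < params.iwp_low:
                labels[y, x] = PixelLabel.MEDIUM
            else:
                labels[y, x] = PixelLabel.WEAK
    return labels


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t-test (two-sided)."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * t_dist.sf(abs(t), df=na + nb - 2)
    return t, p


def random_ihc_like_image(rng: np.random.Generator, height: int, width: int):
    """Random image mixing uniform-random pixels with brown/blue-ish ones,
    so every class and every threshold edge gets exercised."""
    kind = rng.integers(0, 3, size=(height, width))
    img = rng.integers(0, 256, size=(height, width, 3), dtype=np.int64)
    t = rng.uniform(0, 255, size=(height, width))
    brown = np.stack([t * 1.2, t, t * 0.8], axis=-1)
    blue = np.stack([t * 0.75, t * 0.85, t * 1.4], axis=-1)
    img = np.where(kind[..., None] == 1, brown, img)
    img = np.where(kind[..., None] == 2, blue, img)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@pytest.fixture
def rng():
    return np.random.default_rng(20221230)
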