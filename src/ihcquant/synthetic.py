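"""Synthetic IHC image generator with planted ground truth.

Real DAB/hematoxylin slides for this kind of analysis are rarely
deposited, so the pipeline is exercised on generated rasters instead:
positive pixels are rendered in a DAB-brown hue (inside the default
classifier hue window, saturation well above the floor) at intensities
drawn strictly inside the target weak/medium/strong bin; negative pixels
in a hematoxylin-blue hue far outside the window; non-ROI pixels in
background white.  Class assignments are planted in exactly the
requested proportions (largest-remainder rounding to whole pixels), so
the generator's bookkeeping is an exact oracle for the classifier at
zero noise.

The generator emulates the color logic of stained tissue, not its
texture: there are no nuclei, gradients or scanner artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import PixelClassParams, PixelLabel, count_labels
from .scoring import hscore_from_counts

#: Background color outside the ROI.
BACKGROUND_RGB = (255, 255, 255)

#: Channel multipliers for hematoxylin-blue negative pixels (mean 1.0,
#: hexagonal hue ~0.65 -- far outside the default DAB window).
_NEGATIVE_DIRECTION = np.array([0.75, 0.85, 1.40])

#: Intensity range for negative pixels (mid-range, like a counterstain).
_NEGATIVE_INTENSITY = (110.0, 170.0)

#: Mixture shape used to invert a target H-score into per-bin fractions.
HSCORE_MIXTURE_SHAPE = (0.5, 0.3, 0.2)  # weak, medium, strong


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for one generated image.

    ``frac_weak/medium/strong`` are the planted ROI pixel fractions
    (summing to at most 1; the remainder is negative).  ``noise_sd`` is
    the standard deviation of additive Gaussian noise applied per
    channel before clamping to [0, 255]; intensities are sampled at
    least ``max(1, 3*noise_sd)`` inside their bin so that low-noise
    recovery stays exact or near-exact.
    """

    width: int = 64
    height: int = 64
    frac_weak: float = 0.0
    frac_medium: float = 0.0
    frac_strong: float = 0.0
    roi_shape: str = "full"  # "full" or "disc"
    noise_sd: float = 0.0
    seed: int = 0
    params: PixelClassParams = field(default_factory=PixelClassParams)

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("image dimensions must be positive")
        fracs = (self.frac_weak, self.frac_medium, self.frac_strong)
        if any(f < 0 for f in fracs):
            raise ValueError("planted fractions must be non-negative")
        if sum(fracs) > 1.0 + 1e-12:
            raise ValueError(f"planted fractions sum to {sum(fracs)} > 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.roi_shape not in ("full", "disc"):
            raise ValueError(f"unknown roi_shape {self.roi_shape!r}")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Recipe for a two-group cohort with planted group-mean H-scores."""

    n_per_group: int = 8
    mean_hscore_a: float = 1.05
    mean_hscore_b: float = 0.11
    between_sample_sd: float = 0.0
    group_a: str = "N0"
    group_b: str = "N1"
    image_template: SyntheticImageSpec = field(default_factory=SyntheticImageSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        for name, m in (("mean_hscore_a", self.mean_hscore_a),
                        ("mean_hscore_b", self.mean_hscore_b)):
            if not 0.0 <= m <= 3.0:
                raise ValueError(f"{name} = {m} is not an attainable H-score in [0, 3]")
        if self.between_sample_sd < 0:
            raise ValueError("between_sample_sd must be non-negative")


@dataclass(frozen=True)
class CohortSample:
    sample_id: str
    group: str
    target_hscore: float
    spec: SyntheticImageSpec
    image: np.ndarray
    mask: np.ndarray
    truth_labels: np.ndarray
    planted_hscore: float  # after pixel quantization, from the truth labels


@dataclass(frozen=True)
class Cohort:
    samples: list[CohortSample]
    manifest: pd.DataFrame  # sample_id, group
    truth: pd.DataFrame  # per-sample targets and planted scores


def hscore_to_fractions(h: float) -> tuple[float, float, float]:
    """Invert a target H-score into (weak, medium, strong) fractions.

    The inversion is underdetermined, so the mixture shape is fixed:
    fractions proportional to ``HSCORE_MIXTURE_SHAPE`` scaled to hit the
    target.  That shape attains H-scores up to 1.7 (all ROI pixels
    positive); above it the generator falls back to a strong-only
    mixture, which covers the rest of [0, 3].
    """
    if not 0.0 <= h <= 3.0:
        raise ValueError(f"target H-score {h} outside [0, 3]")
    w, m, s = HSCORE_MIXTURE_SHAPE
    shape_h = w + 2 * m + 3 * s  # H-score when the whole ROI follows the shape
    if h <= shape_h:
        scale = h / shape_h
        return (w * scale, m * scale, s * scale)
    return (0.0, 0.0, h / 3.0)


def largest_remainder(fractions: tuple[float, ...], n: int) -> list[int]:
    """Apportion n items to classes in the given proportions.

    Floors each quota and hands the leftover items to the classes with
    the largest fractional remainders (ties broken by class order).
    Fractions must sum to 1 (so the quotas sum to n).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    quotas = [f * n for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    leftover = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:leftover]:
        counts[i] += 1
    return counts


def _roi_mask(spec: SyntheticImageSpec) -> np.ndarray:
    if spec.roi_shape == "full":
        return np.ones((spec.height, spec.width), dtype=bool)
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    radius = min(spec.height, spec.width) / 2.0 - 2.0
    if radius <= 0:
        raise ValueError("image too small for a disc ROI")
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _positive_rgb(intensities: np.ndarray) -> np.ndarray:
    """DAB-brown RGB rows at the requested mean intensities.

    Channels are ``t*(1+s), t, t*(1-s)`` with saturation ``s`` as large
    as 0.6 where headroom allows, shrinking near white so the red
    channel stays below 255.  The channel mean equals ``t`` exactly and
    the hexagonal hue is 1/12 for every ``t``.
    """
    t = np.asarray(intensities, dtype=float)
    with np.errstate(divide="ignore"):
        s = np.minimum(0.6, 0.98 * (255.0 / np.maximum(t, 1e-9) - 1.0))
    return np.stack([t * (1 + s), t, t * (1 - s)], axis=-1)


def _bin_intensity_range(
    label: PixelLabel, params: PixelClassParams, noise_sd: float
) -> tuple[float, float]:
    edges = {
        PixelLabel.STRONG: (params.isp_low, params.ip_low),
        PixelLabel.MEDIUM: (params.ip_low, params.iwp_low),
        PixelLabel.WEAK: (params.iwp_low, params.iwp_high),
    }
    lo, hi = edges[label]
    margin = max(1.0, 3.0 * noise_sd)
    if lo + margin >= hi - margin:
        raise ValueError(
            f"noise_sd {noise_sd} leaves no room inside the "
            f"{label.name.lower()} bin [{lo}, {hi})"
        )
    return lo + margin, hi - margin


def generate_image(
    spec: SyntheticImageSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate one synthetic IHC image with its ROI mask and truth labels.

    Returns
    -------
    image : HxWx3 uint8
    mask : HxW bool, the ROI
    truth_labels : HxW uint8 :class:`PixelLabel` codes -- the planted
        classes, which the classifier recovers exactly at zero noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    mask = _roi_mask(spec)
    n_roi = int(mask.sum())

    frac_negative = max(0.0, 1.0 - spec.frac_weak - spec.frac_medium - spec.frac_strong)
    n_weak, n_medium, n_strong, n_negative = largest_remainder(
        (spec.frac_weak, spec.frac_medium, spec.frac_strong, frac_negative), n_roi
    )

    flat_idx = np.flatnonzero(mask.ravel())
    rng.shuffle(flat_idx)
    assignment = np.concatenate(
        [
            np.full(n_weak, PixelLabel.WEAK, dtype=np.uint8),
            np.full(n_medium, PixelLabel.MEDIUM, dtype=np.uint8),
            np.full(n_strong, PixelLabel.STRONG, dtype=np.uint8),
            np.full(n_negative, PixelLabel.NEGATIVE, dtype=np.uint8),
        ]
    )
    truth = np.full(spec.height * spec.width, PixelLabel.EXCLUDED, dtype=np.uint8)
    truth[flat_idx] = assignment

    rgb = np.empty((spec.height * spec.width, 3), dtype=float)
    rgb[:] = BACKGROUND_RGB
    for label in (PixelLabel.WEAK, PixelLabel.MEDIUM, PixelLabel.STRONG):
        sel = np.flatnonzero(truth == label)
        if sel.size == 0:
            continue
        lo, hi = _bin_intensity_range(label, spec.params, spec.noise_sd)
        rgb[sel] = _positive_rgb(rng.uniform(lo, hi, size=sel.size))
    neg = np.flatnonzero(truth == PixelLabel.NEGATIVE)
    if neg.size:
        t = rng.uniform(*_NEGATIVE_INTENSITY, size=neg.size)
        rgb[neg] = t[:, None] * _NEGATIVE_DIRECTION

    if spec.noise_sd > 0:
        roi_rows = np.flatnonzero(truth != PixelLabel.EXCLUDED)
        rgb[roi_rows] += rng.normal(0.0, spec.noise_sd, size=(roi_rows.size, 3))

    image = np.rint(np.clip(rgb, 0, 255)).astype(np.uint8)
    return (
        image.reshape(spec.height, spec.width, 3),
        mask,
        truth.reshape(spec.height, spec.width),
    )


def generate_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Generate a two-group cohort of images with planted H-score targets.

    Per-sample target H-scores are drawn Normal(group mean,
    between_sample_sd), clipped to [0, 3], and converted to planted
    fractions via :func:`hscore_to_fractions`.  Sub-seeds derive
    deterministically from the cohort seed and sample index, so every
    image is reproducible on its own.
    """
    # the target-drawing stream is separate from the per-image streams
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xFFFF)))
    samples: list[CohortSample] = []
    rows = []
    idx = 0
    for group, mean in ((spec.group_a, spec.mean_hscore_a),
                        (spec.group_b, spec.mean_hscore_b)):
        for k in range(spec.n_per_group):
            target = float(np.clip(rng.normal(mean, spec.between_sample_sd), 0.0, 3.0))
            fw, fm, fs = hscore_to_fractions(target)
            sub_seed = np.random.SeedSequence((spec.seed, idx)).generate_state(1)[0]
            img_spec = replace(
                spec.image_template,
                frac_weak=fw,
                frac_medium=fm,
                frac_strong=fs,
                seed=int(sub_seed),
            )
            image, mask, truth = generate_image(img_spec)
            planted = hscore_from_counts(count_labels(truth)).h_score
            sample_id = f"{group}_{k + 1:02d}"
            samples.append(
                CohortSample(
                    sample_id=sample_id,
                    group=group,
                    target_hscore=target,
                    spec=img_spec,
                    image=image,
                    mask=mask,
                    truth_labels=truth,
                    planted_hscore=planted,
                )
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "group": group,
                    "target_hscore": target,
                    "frac_weak": fw,
                    "frac_medium": fm,
                    "frac_strong": fs,
                    "planted_hscore": planted,
                }
            )
            idx += 1
    truth_df = pd.DataFrame(rows)
    manifest = truth_df[["sample_id", "group"]].copy()
    return Cohort(samples=samples, manifest=manifest, truth=truth_df)
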