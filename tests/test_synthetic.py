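"""Synthetic image and cohort generation: planted truth, determinism, recovery."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from ihcquant import (
    PixelLabel,
    SyntheticCohortSpec,
    SyntheticImageSpec,
    classify_pixels,
    count_labels,
    generate_cohort,
    generate_image,
    hscore_from_counts,
    hscore_to_fractions,
    largest_remainder,
)


def test_hscore_inversion_round_trips():
    for h in np.linspace(0.0, 3.0, 61):
        fw, fm, fs = hscore_to_fractions(float(h))
        assert fw + fm + fs <= 1.0 + 1e-12
        assert fw + 2 * fm + 3 * fs == pytest.approx(h, abs=1e-12)
    # above the mixture shape's ceiling (1.7) the split is strong-only
    assert hscore_to_fractions(3.0) == (0.0, 0.0, 1.0)
    fw, fm, fs = hscore_to_fractions(2.4)
    assert fw == fm == 0.0 and fs == pytest.approx(0.8)
    with pytest.raises(ValueError):
        hscore_to_fractions(3.2)


def test_largest_remainder_apportionment():
    assert largest_remainder((0.5, 0.25, 0.25), 4) == [2, 1, 1]
    # remainder tie between classes 1 and 2 goes to the earlier class
    assert largest_remainder((0.4, 0.35, 0.25), 10) == [4, 4, 2]
    counts = largest_remainder((0.123, 0.456, 0.421), 997)
    assert sum(counts) == 997
    assert all(abs(c - f * 997) < 1 for c, f in zip(counts, (0.123, 0.456, 0.421)))


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="sum"):
        SyntheticImageSpec(frac_weak=0.6, frac_medium=0.5)
    with pytest.raises(ValueError, match="attainable"):
        SyntheticCohortSpec(mean_hscore_a=3.2)
    with pytest.raises(ValueError, match="n_per_group"):
        SyntheticCohortSpec(n_per_group=1)


def test_identical_seeds_give_identical_images():
    spec = SyntheticImageSpec(
        width=40, height=40, frac_weak=0.2, frac_medium=0.1, frac_strong=0.05,
        roi_shape="disc", noise_sd=3.0, seed=7,
    )
    img1, mask1, truth1 = generate_image(spec)
    img2, mask2, truth2 = generate_image(spec)
    assert np.array_equal(img1, img2)
    assert np.array_equal(mask1, mask2)
    assert np.array_equal(truth1, truth2)
    img3, _, _ = generate_image(dataclasses.replace(spec, seed=8))
    assert not np.array_equal(img1, img3)


def test_all_negative_spec_recovered():
    img, mask, _ = generate_image(SyntheticImageSpec(width=24, height=24))
    _, counts = classify_pixels(img, mask)
    assert counts.n_negative == counts.n_total == 576


def test_zero_noise_recovery_is_exact():
    """Classifier recovers the planted label map pixel-for-pixel at zero noise."""
    for seed in (0, 42, 99):
        spec = SyntheticImageSpec(
            width=48, height=48, frac_weak=0.20, frac_medium=0.30, frac_strong=0.10,
            roi_shape="disc", seed=seed,
        )
        img, mask, truth = generate_image(spec)
        labels, counts = classify_pixels(img, mask, spec.params)
        assert np.array_equal(labels, truth)
        assert counts == count_labels(truth)


def test_noisy_recovery_within_tolerance():
    planted = np.array([0.20, 0.30, 0.10])
    for seed in range(10):
        spec = SyntheticImageSpec(
            width=64, height=64, frac_weak=0.20, frac_medium=0.30, frac_strong=0.10,
            noise_sd=4.0, seed=seed,
        )
        img, mask, _ = generate_image(spec)
        _, c = classify_pixels(img, mask, spec.params)
        recovered = np.array([c.n_weak, c.n_medium, c.n_strong]) / c.n_total
        assert np.abs(recovered - planted).max() <= 0.02


def test_non_roi_pixels_are_background_white():
    spec = SyntheticImageSpec(width=32, height=32, roi_shape="disc", frac_strong=0.5)
    img, mask, truth = generate_image(spec)
    assert (img[~mask] == 255).all()
    assert (truth[~mask] == PixelLabel.EXCLUDED).all()


def test_cohort_structure_and_determinism():
    spec = SyntheticCohortSpec(
        n_per_group=3, mean_hscore_a=1.0, mean_hscore_b=0.2, between_sample_sd=0.1,
        image_template=SyntheticImageSpec(width=24, height=24), seed=5,
    )
    c1, c2 = generate_cohort(spec), generate_cohort(spec)
    assert c1.manifest.equals(c2.manifest)
    assert all(
        np.array_equal(s1.image, s2.image) for s1, s2 in zip(c1.samples, c2.samples)
    )
    assert sorted(c1.manifest["group"].unique()) == ["N0", "N1"]
    assert len(c1.samples) == 6
    assert ((c1.truth["target_hscore"] >= 0) & (c1.truth["target_hscore"] <= 3)).all()


def test_planted_hscore_within_quantization_of_target():
    """Pixel rounding moves the planted H-score < 3/n_roi off the target."""
    n_roi = 48 * 48
    spec = SyntheticCohortSpec(
        n_per_group=4, mean_hscore_a=1.05, mean_hscore_b=0.11, between_sample_sd=0.2,
        image_template=SyntheticImageSpec(width=48, height=48), seed=11,
    )
    cohort = generate_cohort(spec)
    for s in cohort.samples:
        assert abs(s.planted_hscore - s.target_hscore) <= 3.0 / n_roi
        # and the classified score equals the planted score exactly (no noise)
        _, counts = classify_pixels(s.image, s.mask, s.spec.params)
        assert hscore_from_counts(counts).h_score == pytest.approx(
            s.planted_hscore, abs=1e-12
        )


def test_recovered_group_means_unbiased():
    """Across replicate cohorts the recovered group means track the targets.

    Targets sit well inside (0, 3) so the [0, 3] clipping of per-sample
    draws never binds; near the boundary the truncation itself shifts
    the realized mean, which is expected behaviour, not bias.
    """
    tmpl = SyntheticImageSpec(width=32, height=32)
    bias_a, bias_b = [], []
    for rep in range(200):
        spec = SyntheticCohortSpec(
            n_per_group=8, mean_hscore_a=1.05, mean_hscore_b=0.50,
            between_sample_sd=0.15, image_template=tmpl, seed=rep,
        )
        cohort = generate_cohort(spec)
        rec = {"N0": [], "N1": []}
        for s in cohort.samples:
            _, c = classify_pixels(s.image, s.mask, s.spec.params)
            rec[s.group].append(hscore_from_counts(c).h_score)
        bias_a.append(np.mean(rec["N0"]) - 1.05)
        bias_b.append(np.mean(rec["N1"]) - 0.50)
    assert stats.ttest_1samp(bias_a, 0.0).pvalue > 0.01
    assert stats.ttest_1samp(bias_b, 0.0).pvalue > 0.01
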