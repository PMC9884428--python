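"""Simulate a two-group cohort and test for a difference in H-scores.

Generates 8 node-negative-like (high expression) and 8 node-positive-like
(low expression) samples with between-sample spread, runs every image
through classification and scoring, and compares the groups.
"""

from ihcquant import (
    SampleRecord,
    SyntheticCohortSpec,
    SyntheticImageSpec,
    classify_pixels,
    compare_groups,
    format_comparison,
    generate_cohort,
    hscore_from_counts,
)

spec = SyntheticCohortSpec(
    n_per_group=8,
    mean_hscore_a=1.05,   # group N0: retained marker expression
    mean_hscore_b=0.11,   # group N1: strong downregulation
    between_sample_sd=0.10,
    image_template=SyntheticImageSpec(width=64, height=64, roi_shape="disc"),
    seed=7,
)
cohort = generate_cohort(spec)

records = []
for sample in cohort.samples:
    _, counts = classify_pixels(sample.image, sample.mask, sample.spec.params)
    score = hscore_from_counts(counts, sample.sample_id)
    records.append(SampleRecord(sample.sample_id, sample.group, score.h_score))

comparison = compare_groups(records, "N0", "N1")
print(format_comparison(comparison))
# A fold-change near 9.5 with a small p-value: the pipeline detects the
# planted ~10x difference in marker expression between the groups.
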