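# Methods

## Pixel classification model

Each 8-bit RGB pixel is mapped to an HSI triple:

- intensity `I = (R+G+B)/3` on the 0–255 scale,
- saturation `S = 1 − min(R,G,B)/I` (defined as 0 when `I = 0`),
- hue: the standard hexagonal hue normalized to [0, 1) with 0 at pure
  red, reported as 0 for achromatic pixels. Hue comes from
  `skimage.color.rgb2hsv`; S and I are computed directly, because this
  mixed parameterization (hexagonal hue with intensity-based saturation)
  is what positive-pixel-count thresholds conventionally act on. It is
  deliberately *not* a color-deconvolution into optical-density stain
  channels; the thresholds act in HSI space.

A pixel inside the region of interest is **positive** when

```
circ_dist(hue, hue_center) <= hue_width / 2
AND  S  >= saturation_threshold
AND  isp_low <= I < iwp_high
```

and positive pixels fall into half-open intensity bins closed at the
darker end (a pixel exactly on a boundary is assigned once, to the
brighter bin):

| bin    | intensity range        | markup color |
|--------|------------------------|--------------|
| strong | `[isp_low, ip_low)`    | red (255,0,0) |
| medium | `[ip_low, iwp_low)`    | orange (255,165,0) |
| weak   | `[iwp_low, iwp_high)`  | yellow (255,255,0) |

Everything else in the ROI is negative (blue, (0,0,255)); non-ROI pixels
are excluded (white) and contribute to no count, so `n_total` is the ROI
pixel count. Pixels with `I >= iwp_high` are negative even when hue and
saturation match: an upper weak-intensity bound means "too faint to
count as stained". The gate also requires `I >= isp_low` so that every
positive pixel has a bin; at the default `isp_low = 0` this is vacuous.

### Defaults

`hue_center = 0.1` (DAB brown), `hue_width = 0.5`,
`saturation_threshold = 0.04`, `iwp_high = 220`, `iwp_low = 175`,
`ip_low = 100`, `isp_low = 0` — the publicly documented defaults of the
widely used commercial positive-pixel-count v9 algorithm. Published
studies using that algorithm rarely report non-default settings, so
these are the sensible reproduction defaults; all are overridable via
`PixelClassParams` or the YAML config (`params:` block).

Images are 8-bit RGB; 16-bit inputs are rescaled to 8-bit on read with a
logged warning and alpha channels are dropped. Masks are single-channel
PNGs, nonzero = include; an absent mask includes every pixel. An
all-excluded mask yields zero counts; scoring such a sample raises
`EmptyROIError` and the batch pipeline records it as an error row rather
than aborting the run.

## Scoring

Per-bin positivity fractions divide `n_weak/n_medium/n_strong` by
`n_total`; the H-score is `1·f_weak + 2·f_medium + 3·f_strong ∈ [0, 3]`.
Percentages are kept as fractions so reported group means land on the
0–3 scale (the pathology 0–300 convention is ×100). Values are exact
internally; CSV output rounds fractional columns to 4 decimals.

## Group statistics

`compare_groups` reports per-group n, mean, SEM (sample SD with the n−1
denominator over √n; undefined for n = 1), a two-sided unpaired t-test
and the fold-change `mean_a / mean_b` (group a is the reference;
undefined — reported as such, not infinity — when `mean_b = 0`). The
test defaults to the classical pooled-variance Student form because
"unpaired t-test" without a variance qualifier conventionally denotes
it; Welch is available via `equal_var=False` / config. When both groups
have exactly zero variance (possible with noiseless synthetic cohorts)
the pooled statistic is undefined; the package then reports t = 0,
p = 1 for equal means and t = ±inf, p = 0 otherwise. A single
comparison is reported unadjusted; `holm_adjust` is available when
several comparisons form a family (off by default).

Report rounding follows the field's granularity: means/SEM to 2
decimals, fold-change to 1 decimal, p to 4 significant figures.

## Synthetic data generator

The generator emulates the *color logic* of a DAB/hematoxylin slide,
not its histology: an ROI (full frame, or a disc on a white background
emulating a tissue-microarray core) in which each pixel is independently
a class, with classes planted in exactly the requested proportions via
largest-remainder rounding to whole pixels. Consequences:

- **what passing tests show** — the classifier applies its thresholds
  correctly, counts conserve, scores and statistics propagate exactly;
- **what they do not show** — robustness to real-slide phenomena
  (nuclear texture, stain colocalization, uneven illumination, scanner
  color profiles, blur), which the generator does not model.

Positive pixels are rendered as DAB-brown `(t(1+s), t, t(1−s))` with
channel mean exactly `t` and hexagonal hue 1/12 for every `t`; the
chroma `s` is 0.6 where headroom allows and shrinks near white so the
red channel stays ≤ 255. `t` is drawn uniformly from strictly inside
the target bin with a margin of `max(1, 3·noise_sd)`: at zero noise the
margin absorbs per-channel rounding so recovery is *exact*; at the
noise levels exercised (sd = 4) boundary crossings are >5σ events, so
recovery stays within ±0.02 with large headroom (observed worst error
~1.5e-4 over 50 images). Negative pixels use a hematoxylin-blue
direction (hue ≈ 0.65, far outside the default window) at mid-range
intensities. Gaussian channel noise (`noise_sd`, default 0) is added
inside the ROI, then values are clamped to [0, 255] and rounded.

Cohorts draw per-sample target H-scores from Normal(group mean,
`between_sample_sd`), clipped to [0, 3] (near the boundaries this
truncation shifts realized means — expected behaviour, tested only away
from the boundary). Targets convert to planted fractions through a
fixed mixture shape (weak:medium:strong = 0.5:0.3:0.2 scaled to the
target), since one H-score equation cannot determine three fractions;
the shape attains H ≤ 1.7, above which the generator falls back to a
strong-only mixture, covering all of [0, 3]. Pixel quantization keeps
each planted H-score within 3/(ROI pixels) of its target. Determinism:
every RNG stream is seeded; per-image sub-seeds derive from
`SeedSequence((cohort_seed, sample_index))`, so cohorts reproduce
image-by-image.

## Demo cohort and problem sizes

The built-in demo plants the canonical comparison: 8 samples per group,
group means 1.05 (N0) and 0.11 (N1), zero between-sample spread, zero
channel noise. Images are 256×256 discs (~50k ROI pixels) so that the
quantization error on the small group mean (≤ 3/n ≈ 6e-5, relative
~5e-4) sits an order of magnitude inside the 0.1-rounding margin of the
reported fold-change — the pipeline then reports means 1.05 and 0.11
and a 9.5-fold difference (1.05/0.11 = 9.545…). With zero spread the
demo's per-group variance is exactly zero, so its p-value is the
degenerate 0 described above; with any positive `between_sample_sd` the
ordinary t-test applies (see `examples/compare_two_groups.py`). Unit
tests use 24–96 px images; the calibration check uses 2,000 null
replicates at n = 8 per group, matching the cohort size the statistics
are meant for.

## Known limitations

- No whole-slide pyramid formats (SVS/NDPI), stitching, or automatic
  tumor/stroma segmentation — the ROI is an input, mirroring manual
  region selection.
- The HSI thresholds assume DAB + hematoxylin; other chromogens need a
  different `hue_center`/`hue_width`.
- Images are treated as unitless rasters; magnification and pixel size
  are not modeled.
- One record per input image: averaging multiple cores per patient, if
  wanted, belongs in the sample manifest upstream of the statistics.
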