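# ihcquant

Quantitative analysis of chromogenic immunohistochemistry (IHC) images:
positive-pixel counting, H-scores, and two-group biomarker comparison.

## The problem

Pathology studies often ask whether a protein marker is expressed
differently between two patient groups — for example, whether a tumor
suppressor is downregulated in primary tumors that have metastasized to
regional lymph nodes (nodal status N1) compared to those that have not
(N0). The raw evidence is a set of tissue sections stained with a brown
DAB chromogen where the marker is present, counterstained with blue
hematoxylin, and photographed. Manual grading of such slides is
subjective; positive-pixel counting replaces it with a deterministic
per-pixel rule.

`ihcquant` implements that workflow for anyone who has per-sample RGB
images (PNG/TIFF) and, optionally, region-of-interest masks delimiting
the tumor parenchyma:

1. **Pixel classification** — every ROI pixel is converted to
   hue/saturation/intensity (hue hexagonal in [0,1), S = 1 − min(R,G,B)/I,
   I = (R+G+B)/3) and called *positive* when its hue falls in a circular
   window around DAB brown, its saturation clears a floor, and its
   intensity is below an upper bound. Positive pixels are binned by
   intensity — weak (N_wp), medium (N_p), strong (N_sp); darker is
   stronger. A markup image paints them yellow/orange/red over blue
   negatives.
2. **Scoring** — per-bin positivity fractions are the bin counts over
   N_total (all ROI pixels), and the H-score is the weighted sum

   H = 1·(% weak) + 2·(% medium) + 3·(% strong),   H ∈ [0, 3]

   with percentages as fractions (the conventional pathology 0–300 scale
   is this value × 100).
3. **Group statistics** — per-group mean and SEM, a two-sided unpaired
   t-test (pooled Student by default, Welch optional), and the
   fold-change between group means.
4. **Synthetic data** — a generator that plants known per-bin pixel
   fractions (and whole cohorts with known group means) in IHC-like
   images, so every stage is testable against exact ground truth without
   slide data.

## Worked example

```bash
python examples/classify_and_score_one_image.py
```

builds a 64×64 synthetic image with 20% weak / 30% medium / 10% strong
DAB-positive pixels in a disc ROI and prints:

```
ROI pixels: 2828
weak/medium/strong/negative: 566/848/283/1131
fraction positive: 0.6001
H-score (0-3 scale): 1.1001
```

566/2828 ≈ 0.20, 848/2828 ≈ 0.30, 283/2828 ≈ 0.10: the classifier
recovers the planted fractions exactly (up to whole-pixel rounding), and
the H-score is 0.20·1 + 0.30·2 + 0.10·3 ≈ 1.10. The other examples
(`compare_two_groups.py`, `render_markup_image.py`) show the cohort
comparison and the markup overlay.

The same pipeline is available from the shell:

```bash
ihcquant demo --out demo_run                # built-in N0-vs-N1 cohort
ihcquant simulate --spec cohort.yaml --out sim
ihcquant quantify --images sim/images --masks sim/masks --out quant
ihcquant compare --scores quant/scores.csv --manifest sim/manifest.csv \
                 --group-a N0 --group-b N1 --out report
```

`demo` prints:

```
Group N0: n = 8, mean H-score = 1.05 (SEM 0.00)
Group N1: n = 8, mean H-score = 0.11 (SEM 0.00)
Fold-change: 9.5-fold (N0/N1)
```

i.e. a cohort planted at mean H-scores 1.05 and 0.11 comes back from the
full image pipeline with those means and a 9.5-fold difference.

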