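"""Render the classic markup overlay for a classified image.

Strong positive pixels are painted red, medium orange, weak yellow,
negative blue and excluded (non-ROI) pixels white -- the standard way to
eyeball what a positive-pixel count actually counted.
"""

from pathlib import Path

from ihcquant import SyntheticImageSpec, classify_pixels, generate_image, render_markup
from ihcquant.io import write_image

spec = SyntheticImageSpec(
    width=96, height=96, frac_weak=0.15, frac_medium=0.25, frac_strong=0.20,
    roi_shape="disc", noise_sd=2.0, seed=11,
)
image, mask, _ = generate_image(spec)
labels, counts = classify_pixels(image, mask, spec.params)
markup = render_markup(labels)

out = Path("scratch") if Path("scratch").exists() else Path(".")
write_image(out / "example_input.png", image)
write_image(out / "example_markup.png", markup)
print(f"wrote {out / 'example_input.png'} and {out / 'example_markup.png'}")
print(f"counts: weak={counts.n_weak} medium={counts.n_medium} "
      f"strong={counts.n_strong} negative={counts.n_negative}")
# Open the two PNGs side by side: every brown pixel in the input gets a
# red/orange/yellow color by intensity bin; counterstain turns blue.
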