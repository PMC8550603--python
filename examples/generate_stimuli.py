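"""Generate jittered lattice textures and check their displacement statistics.

Builds the tightest stimulus geometry (spacing level 1, size level 3) at the
largest jitter level, renders one texture to a 16-bit PNG, and compares the
measured element displacement of many layouts against the closed-form mean
for unconstrained uniform jitter -- showing how overlap rejection slightly
compresses the effective jitter.
"""

import numpy as np

from regtex import (apply_jitter, make_grid, measure_displacement,
                    mean_displacement_analytic, render_texture)
from regtex.stimuli import ELEMENT_DIAMETERS, JITTER_RANGES, save_texture

rng = np.random.default_rng(0)
grid = make_grid(1)                      # 9 x 9 lattice, 17.52 arcmin pitch
diameter = ELEMENT_DIAMETERS[3]          # 15.57 arcmin elements

layouts = [apply_jitter(grid, 5, diameter, seed=rng) for _ in range(184)]
summary = measure_displacement(layouts)
free = mean_displacement_analytic(JITTER_RANGES[5])

print(f"unconstrained mean displacement (analytic): {free:.2f} arcmin")
print(f"constrained mean over 184 layouts:          {summary.mean:.2f} "
      f"arcmin (SD {summary.sd:.2f})")
print("-> overlap rejection keeps elements apart, trimming the largest "
      "relative offsets, so the realised jitter is slightly below the "
      "nominal range.")

image = render_texture(layouts[0], size_level=3)
save_texture(image, "example_texture.png",
             metadata={"spacing_level": 1, "size_level": 3,
                       "jitter_level": 5, "seed": 0})
print(f"wrote example_texture.png ({image.size} px, "
      f"{image.pixel_pitch:.3f} arcmin/px, mean luminance "
      f"{image.pixels.mean():+.4f} on a zero background)")
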