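"""Contour curvature and the curvature-intensity correlation.

Generates a six-lobed puzzle cell, paints its margin so that signal
concentrates in indentations (coupling c = 0.6), measures signed
curvature by circle fitting and margin-band intensity, and reports the
curvature correlation coefficient: negative values mean the signal
sits in necks, as cortical microtubules do.
"""

import numpy as np

import pavecell as pc

contour, analytic = pc.make_puzzle_cell(5.0, 6, 0.3, vertex_spacing_um=0.2)
margin_img, texture_img, truth = pc.make_textured_cell(
    contour, coupling=0.6, texture_orientation_deg=30.0, noise_sd=0.1, seed=5
)

profile = pc.curvature_profile(contour, window_um=0.5)
err = np.abs(profile.curvature_um - analytic)
print(f"curvature: median |fit - analytic| = {np.median(err):.3f} 1/um "
      f"(range {analytic.min():.2f} to {analytic.max():.2f})")

profile.intensity = pc.margin_intensity(margin_img, contour, margin_um=1.0, window_um=0.5)
r = pc.curvature_correlation(profile)
print(f"curvature correlation r = {r:.3f} (planted coupling 0.6 -> expect ~ -0.6; "
      "negative = signal in indentations)")

nem = pc.nematic_tensor(texture_img, contour.polygon)
print(f"texture orientation {nem.orientation_deg:.1f} deg (truth 30), "
      f"anisotropy {nem.anisotropy:.2f}")
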