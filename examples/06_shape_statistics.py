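"""Pavement-cell shape statistics: lobeyness, growth regression, Welch test.

Lobeyness = perimeter / convex-hull perimeter (1 for convex outlines).
The rate of shape formation is the OLS slope of lobeyness on cell
area; two conditions are compared with Welch's unpaired two-tailed
t-test, the convention used for every comparison in this pipeline.
"""

import numpy as np

import pavecell as pc

puzzle, _ = pc.make_puzzle_cell(10.0, 6, 0.3)
m = pc.shape_metrics(puzzle)
print(f"puzzle cell: area {m.area_um2:.0f} um^2, perimeter {m.perimeter_um:.1f} um, "
      f"lobeyness {m.lobeyness:.3f}")

rng = np.random.default_rng(8)
area = rng.uniform(100, 600, 200)
wild_type = 1 + 0.002 * area + rng.normal(0, 0.08, 200)
mutant = 1 + 0.001 * area + rng.normal(0, 0.08, 200)
rw = pc.shape_rate_regression(area, wild_type)
rm = pc.shape_rate_regression(area, mutant)
print(f"shape-formation rate: {rw.slope:.5f} vs {rm.slope:.5f} lobeyness/um^2 "
      f"(planted 0.002 vs 0.001)")

res = pc.welch_t_test(wild_type, mutant)
print(f"Welch t = {res.t:.2f}, df = {res.df:.1f}, p = {res.p:.2e}; "
      f"means {res.mean1:.3f} [{res.ci1[0]:.3f}, {res.ci1[1]:.3f}] vs "
      f"{res.mean2:.3f} [{res.ci2[0]:.3f}, {res.ci2[1]:.3f}] (95% CI)")
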