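"""Object-based co-localization with a Costes significance test.

Builds channel pairs with known shared structure (mixing rho) and
reports Pearson r, Manders M1/M2 and the Costes block-randomization
p-value: p <= 0.001 flags significant co-localization at 999 shuffles.
"""

import pavecell as pc

for rho in (0.0, 0.5, 1.0):
    a, b, _ = pc.make_coloc_pair((80, 80), rho, seed=6)
    res = pc.pearson_manders(a, b)
    p = pc.costes_randomization(a, b, block_px=10, n_rand=999, seed=7)
    print(f"rho={rho:.1f}: Pearson r={res.pearson:+.3f}  "
          f"M1={res.manders_m1:.2f} M2={res.manders_m2:.2f}  Costes p={p:.3f}")
print("(r rises with the shared fraction; only truly co-localized pairs reach p <= 0.001)")
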