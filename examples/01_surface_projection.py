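"""Surface-manifold projection of a curved-cell z-stack.

Builds a two-channel synthetic stack (membrane band on a sinusoidal
surface, bright Golgi-like blobs 3 um deeper), recovers the surface
from the reference channel and compares a depth-3 surface MIP of the
target channel against a naive whole-stack MIP.
"""

import numpy as np

import pavecell as pc

spec = pc.SceneSpec(shape=(192, 192), n_z=40, read_noise_sd=200.0, seed=1)
ref, tgt, truth = pc.make_surface_scene(
    spec, lambda x, y: 20 + 5 * np.sin(2 * np.pi * x / 64), blob_count=8, n_puncta=30
)

manifold = pc.estimate_manifold(ref)
rms = np.sqrt(np.mean((manifold.heights - truth.manifold) ** 2))
print(f"manifold RMS error: {rms:.3f} z-steps ({rms * spec.z_step_nm:.0f} nm)")

mip3 = pc.project_surface_mip(tgt, manifold, depth=3).image
whole = tgt.data.max(axis=0)
by, bx = truth.blob_centers[:, 1].astype(int), truth.blob_centers[:, 2].astype(int)
print(f"deep-blob signal in surface MIP: {100 * np.mean(mip3[by, bx] / whole[by, bx]):.1f}% "
      "of whole-stack MIP (lower = better suppression of sub-surface structures)")
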