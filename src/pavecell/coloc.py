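"""Object-based co-localization of two channels.

Threshold-based co-localization is unreliable on raw CESA/microtubule
recordings because fluorescence fluctuates strongly across cells and
fields of view, so channels are first reduced to spot-rendered images
(see :mod:`pavecell.spots`) and then compared with Pearson's
correlation, the Manders overlap coefficients, and a Costes
block-randomization significance test of the Pearson value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ColocResult", "pearson_manders", "costes_randomization"]


@dataclass
class ColocResult:
    pearson: float
    manders_m1: float
    manders_m2: float
    costes_p: float | None = None
    n_randomizations: int | None = None
    block_px: int | None = None
    pearson_defined: bool = True


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(float)
    b = b.ravel().astype(float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def pearson_manders(
    image_a: np.ndarray,
    image_b: np.ndarray,
    mask: np.ndarray | None = None,
    thresholds: tuple[float, float] | str = (0.0, 0.0),
) -> ColocResult:
    """Pearson r and Manders M1/M2 over (optionally masked) pixels.

    ``M1 = sum(A over pixels where B > t_B) / sum(A)`` and
    symmetrically for M2.  The default thresholds are the classic
    Manders zero thresholds (so identical positive channels give
    M1 = M2 = 1); pass ``thresholds="otsu"`` for per-channel Otsu
    thresholds on strongly backgrounded data.  Pearson is flagged
    undefined (NaN) when either channel has zero variance.
    """
    from skimage.filters import threshold_otsu

    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        a, b = a[m], b[m]
    r = _pearson(a, b)
    if thresholds == "otsu":
        ta = threshold_otsu(a) if a.std() > 0 else a.max()
        tb = threshold_otsu(b) if b.std() > 0 else b.max()
    else:
        ta, tb = thresholds
    sa, sb = a.sum(), b.sum()
    m1 = float(a[b > tb].sum() / sa) if sa > 0 else 0.0
    m2 = float(b[a > ta].sum() / sb) if sb > 0 else 0.0
    return ColocResult(r, m1, m2, pearson_defined=np.isfinite(r))


def costes_randomization(
    image_a: np.ndarray,
    image_b: np.ndarray,
    block_px: int = 5,
    n_rand: int = 999,
    seed: int = 0,
) -> float:
    """Costes significance test of the observed Pearson correlation.

    Channel A is cut into non-overlapping ``block_px`` squares (at
    least the PSF width, so shuffling destroys true co-localization
    but preserves local texture), the blocks are shuffled ``n_rand``
    times and Pearson r against B recomputed each time.  The add-one
    p-value ``(1 + #{r_shuffled >= r_observed}) / (n_rand + 1)`` never
    reaches 0; with 999 randomizations the smallest attainable value
    is 0.001.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    ny, nx = a.shape
    if ny < block_px or nx < block_px:
        raise ValueError("image smaller than one randomization block")
    by, bx = ny // block_px, nx // block_px
    cy, cx = by * block_px, bx * block_px
    a_c = a[:cy, :cx]
    b_c = b[:cy, :cx]
    r_obs = _pearson(a_c, b_c)
    # (n_blocks, block, block) view for shuffling
    blocks = a_c.reshape(by, block_px, bx, block_px).swapaxes(1, 2).reshape(-1, block_px, block_px)
    rng = np.random.default_rng(seed)
    b_flat = b_c.ravel()
    b_std = b_flat.std()
    b_centred = b_flat - b_flat.mean()
    exceed = 0
    for _ in range(n_rand):
        perm = rng.permutation(len(blocks))
        shuffled = (
            blocks[perm].reshape(by, bx, block_px, block_px).swapaxes(1, 2).reshape(cy, cx)
        )
        s = shuffled.ravel()
        s_std = s.std()
        if s_std == 0 or b_std == 0:
            r_sh = 0.0
        else:
            r_sh = float(np.dot(s - s.mean(), b_centred) / (len(s) * s_std * b_std))
        if r_sh >= r_obs:
            exceed += 1
    return (1 + exceed) / (n_rand + 1)
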