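"""Seeded synthetic confocal scenes with exact ground truth.

Every downstream stage of the pipeline (surface projection, spot
detection, tracking, contour geometry, co-localization, shape
statistics) is validated against scenes built here, so each generator
records complete ground truth: manifold heights, per-frame particle
positions and motion classes, analytic contour curvature, texture
orientation/anisotropy and channel-coupling coefficients.

Conventions (shared by all modules): arrays are indexed ``[z, y, x]``
or ``[t, y, x]``; positions are ``(x, y)`` in pixels, 0-based, sampled
at pixel centres; contours are stored with positive shoelace area in
``(x, y)`` array coordinates (interior on the left of the traversal).
Physical scales (pixel size, z-step, frame interval) live in
:class:`SceneSpec` and are never hard-coded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .surface import ImageStack

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "make_surface_scene",
    "make_spot_movie",
    "make_puzzle_cell",
    "make_textured_cell",
    "make_coloc_pair",
    "observed_spots_from_truth",
]

MotionType = Literal["linear", "immobile", "erratic"]


@dataclass(frozen=True)
class SceneSpec:
    """Acquisition geometry and noise model of a synthetic recording.

    Defaults mirror a spinning-disk time lapse of cotyledon epidermis:
    16 one-minute frames, 0.3 um z-steps.  The camera pixel size is a
    required configuration value (110 nm/px is plausible for a x100
    NA 1.49 objective on an sCMOS camera) — physical outputs are always
    derived from it, never asserted as biology.
    """

    shape: tuple[int, int] = (256, 256)  # (ny, nx) lateral, px
    n_z: int = 40
    pixel_size_nm: float = 110.0
    z_step_nm: float = 300.0
    frame_interval_s: float = 60.0
    n_frames: int = 16
    read_noise_sd: float = 0.0  # Gaussian read noise, counts
    poisson_noise: bool = False  # shot noise on the clean signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.z_step_nm <= 0:
            raise ValueError("pixel size and z-step must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Exact truth records for one synthetic scene.

    Only the fields relevant to the generating call are populated;
    every rendered signal element appears in exactly one record.
    """

    manifold: np.ndarray | None = None  # (ny, nx) z-heights, z-step units
    blob_centers: np.ndarray | None = None  # (n, 3) as (z, y, x) px
    puncta: np.ndarray | None = None  # (n, 2) as (x, y) px, on-surface spots
    tracks: pd.DataFrame | None = None  # track_id, frame, x, y, speed_nm_min, motion
    contour: np.ndarray | None = None  # (n, 2) vertices (x, y) px
    curvature_um: np.ndarray | None = None  # analytic, per vertex, 1/um
    coupling: float | None = None
    texture_orientation_deg: float | None = None
    mixing: float | None = None
    extras: dict = field(default_factory=dict)


def _apply_noise(clean: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    out = clean.astype(np.float64)
    if spec.poisson_noise:
        out = rng.poisson(np.clip(out, 0, None)).astype(np.float64)
    if spec.read_noise_sd > 0:
        out = out + rng.normal(0.0, spec.read_noise_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# surface scenes


def make_surface_scene(
    spec: SceneSpec,
    manifold: Callable[[np.ndarray, np.ndarray], np.ndarray] | np.ndarray,
    blob_count: int = 0,
    *,
    surface_amplitude: float = 1000.0,
    surface_sigma_z: float = 0.8,
    n_puncta: int = 0,
    puncta_amplitude: float = 400.0,
    blob_amplitude: float = 5000.0,
    blob_depth_um: float = 3.0,
    blob_sigma_px: float = 2.5,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Render a two-channel z-stack of a curved cell surface.

    The reference channel carries a Gaussian band of membrane/cortex
    signal centred on the manifold ``z(x, y)``.  The target channel
    carries diffraction-limited puncta *on* the surface plus
    ``blob_count`` bright Golgi-like blobs placed at least 2 um below
    it (z increases into the cell interior), the classic confounders a
    surface projection must suppress.

    ``manifold`` is either a ``(ny, nx)`` height array in z-step units
    or a callable ``f(x, y)`` evaluated on the pixel grid.
    """
    ny, nx = spec.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    if callable(manifold):
        heights = np.asarray(manifold(xx.astype(float), yy.astype(float)), dtype=float)
    else:
        heights = np.asarray(manifold, dtype=float)
        if heights.shape != (ny, nx):
            heights = np.broadcast_to(heights, (ny, nx)).astype(float)
    if heights.min() < 0 or heights.max() > spec.n_z - 1:
        raise ValueError(
            f"manifold heights [{heights.min():.2f}, {heights.max():.2f}] exceed the "
            f"z-range [0, {spec.n_z - 1}] of the stack"
        )

    rng = spec.rng()
    z = np.arange(spec.n_z, dtype=float)[:, None, None]
    ref = surface_amplitude * np.exp(-0.5 * ((z - heights[None]) / surface_sigma_z) ** 2)

    tgt = 0.15 * ref  # faint membrane bleed-through so the channel is not empty
    puncta_xy = np.empty((0, 2))
    if n_puncta > 0:
        puncta_xy = np.column_stack(
            [rng.uniform(4, nx - 5, n_puncta), rng.uniform(4, ny - 5, n_puncta)]
        )
        sig = 1.6
        for px, py in puncta_xy:
            hz = heights[int(round(py)), int(round(px))]
            r2 = (xx - px) ** 2 + (yy - py) ** 2
            lateral = np.exp(-0.5 * r2 / sig**2)
            axial = np.exp(-0.5 * ((z - hz) / surface_sigma_z) ** 2)
            tgt = tgt + puncta_amplitude * axial * lateral[None]

    depth_steps = blob_depth_um * 1000.0 / spec.z_step_nm
    min_sep_steps = 2000.0 / spec.z_step_nm  # contract: blobs >= 2 um below surface
    if depth_steps < min_sep_steps:
        raise ValueError("blob depth must be at least 2 um below the manifold")
    blob_centers = np.empty((0, 3))
    if blob_count > 0:
        bx = rng.uniform(6, nx - 7, blob_count)
        by = rng.uniform(6, ny - 7, blob_count)
        bz = heights[by.astype(int), bx.astype(int)] + depth_steps
        bz = np.clip(bz, 0, spec.n_z - 1)
        blob_centers = np.column_stack([bz, by, bx])
        sigma_z_blob = blob_sigma_px * spec.pixel_size_nm / spec.z_step_nm
        for cz, cy, cx in blob_centers:
            lateral = np.exp(
                -0.5 * ((xx - cx) ** 2 + (yy - cy) ** 2) / blob_sigma_px**2
            )
            axial = np.exp(-0.5 * ((z - cz) / max(sigma_z_blob, 1.0)) ** 2)
            tgt = tgt + blob_amplitude * axial * lateral[None]

    ref = _apply_noise(ref, spec, rng)
    tgt = _apply_noise(tgt, spec, rng)

    truth = GroundTruth(manifold=heights, blob_centers=blob_centers, puncta=puncta_xy)
    mk = lambda a, ch: ImageStack(  # noqa: E731
        a,
        pixel_size_nm=spec.pixel_size_nm,
        z_step_nm=spec.z_step_nm,
        frame_interval_s=spec.frame_interval_s,
        channel=ch,
    )
    return mk(ref, "reference"), mk(tgt, "target"), truth


# ---------------------------------------------------------------------------
# moving puncta


def _integrated_gaussian_patch(x0: float, y0: float, sigma: float, photons: float,
                               shape: tuple[int, int]) -> np.ndarray:
    """Pixel-integrated symmetric Gaussian (the camera model a localization
    fitter assumes), rendered over a full frame."""
    from scipy.special import erf

    ny, nx = shape
    xe = np.arange(nx + 1) - 0.5  # pixel edges; centres at integers
    ye = np.arange(ny + 1) - 0.5
    s = sigma * np.sqrt(2.0)
    fx = 0.5 * (erf((xe[1:] - x0) / s) - erf((xe[:-1] - x0) / s))
    fy = 0.5 * (erf((ye[1:] - y0) / s) - erf((ye[:-1] - y0) / s))
    return photons * np.outer(fy, fx)


def _add_integrated_gaussian(frame: np.ndarray, x0: float, y0: float,
                             sigma: float, photons: float) -> None:
    """Accumulate a pixel-integrated Gaussian into ``frame`` over a
    local +-6 sigma window (in place)."""
    from scipy.special import erf

    ny, nx = frame.shape
    r = int(np.ceil(6 * sigma))
    xa, xb = max(int(x0) - r, 0), min(int(x0) + r + 2, nx)
    ya, yb = max(int(y0) - r, 0), min(int(y0) + r + 2, ny)
    if xa >= xb or ya >= yb:
        return
    s = sigma * np.sqrt(2.0)
    xe = np.arange(xa, xb + 1) - 0.5
    ye = np.arange(ya, yb + 1) - 0.5
    fx = 0.5 * (erf((xe[1:] - x0) / s) - erf((xe[:-1] - x0) / s))
    fy = 0.5 * (erf((ye[1:] - y0) / s) - erf((ye[:-1] - y0) / s))
    frame[ya:yb, xa:xb] += photons * np.outer(fy, fx)


def make_spot_movie(
    spec: SceneSpec,
    populations: Sequence[tuple[int, float, MotionType]],
    *,
    psf_sigma_px: float = 1.6,
    photons: float = 1000.0,
) -> tuple[ImageStack, GroundTruth]:
    """Render a time lapse of diffraction-limited puncta with known motion.

    ``populations`` is a list of ``(n, speed_nm_per_min, motion_type)``:
    ``linear`` movers keep one random heading, ``immobile`` particles do
    not move, and ``erratic`` walkers (SMACC-like) take a fixed-length
    step in a fresh random direction every frame.  Particles that leave
    the field keep their (truncated) truth track.
    """
    ny, nx = spec.shape
    rng = spec.rng()
    step_scale = spec.frame_interval_s / 60.0 / spec.pixel_size_nm  # nm/min -> px/frame
    frames = np.zeros((spec.n_frames, ny, nx))
    rows = []
    tid = 0
    for n, speed, motion in populations:
        if speed < 0:
            raise ValueError("speeds must be >= 0")
        step_px = speed * step_scale
        for _ in range(n):
            x = rng.uniform(6, nx - 7)
            y = rng.uniform(6, ny - 7)
            theta = rng.uniform(0, 2 * np.pi)
            for t in range(spec.n_frames):
                if not (0 <= x < nx and 0 <= y < ny):
                    break  # left the field: truncated track
                _add_integrated_gaussian(frames[t], x, y, psf_sigma_px, photons)
                rows.append((tid, t, x, y, speed, motion))
                if motion == "immobile":
                    continue
                if motion == "erratic":
                    theta = rng.uniform(0, 2 * np.pi)
                x += step_px * np.cos(theta)
                y += step_px * np.sin(theta)
            tid += 1
    frames = _apply_noise(frames, spec, rng)
    tracks = pd.DataFrame(
        rows, columns=["track_id", "frame", "x", "y", "speed_nm_min", "motion"]
    )
    stack = ImageStack(
        frames,
        pixel_size_nm=spec.pixel_size_nm,
        z_step_nm=spec.z_step_nm,
        frame_interval_s=spec.frame_interval_s,
        channel="target",
        time_lapse=True,
    )
    return stack, GroundTruth(tracks=tracks)


def observed_spots_from_truth(
    truth: GroundTruth, jitter_nm: float, pixel_size_nm: float, seed: int = 0
) -> pd.DataFrame:
    """Truth positions corrupted by localization noise, as a detector
    would report them — a frame/x/y table ready for track linking."""
    if truth.tracks is None:
        raise ValueError("truth carries no tracks")
    rng = np.random.default_rng(seed)
    df = truth.tracks[["frame", "x", "y"]].copy()
    df[["x", "y"]] += rng.normal(0.0, jitter_nm / pixel_size_nm, size=(len(df), 2))
    return df


# ---------------------------------------------------------------------------
# puzzle-cell contours


def make_puzzle_cell(
    base_radius_um: float,
    lobe_count: int,
    amplitude: float,
    *,
    pixel_size_nm: float = 110.0,
    vertex_spacing_um: float = 0.15,
    center_px: tuple[float, float] | None = None,
):
    """Pavement-cell-like closed contour with analytically known curvature.

    The outline is the polar curve ``r(theta) = R (1 + a cos k theta)``;
    its signed curvature is

        kappa = (r^2 + 2 r'^2 - r r'') / (r^2 + r'^2)^(3/2),

    positive on protrusions (lobes) and negative in indentations
    (necks), matching the centre-outside-is-negative circle-fit
    convention used for measured contours.

    Returns a :class:`~pavecell.contour.CellContour` and the analytic
    per-vertex curvature in 1/um.
    """
    from .contour import CellContour

    if not (0 <= amplitude < 1):
        raise ValueError("amplitude must be in [0, 1) to avoid self-intersection")
    R = base_radius_um
    k = lobe_count
    a = amplitude
    # perimeter upper bound for dense sampling
    approx_perim = 2 * np.pi * R * (1 + abs(a) * max(k, 1))
    n = max(int(np.ceil(approx_perim / vertex_spacing_um)), 64)
    theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    r = R * (1 + a * np.cos(k * theta))
    r1 = -R * a * k * np.sin(k * theta)
    r2 = -R * a * k * k * np.cos(k * theta)
    kappa = (r * r + 2 * r1 * r1 - r * r2) / (r * r + r1 * r1) ** 1.5  # 1/um

    px_per_um = 1000.0 / pixel_size_nm
    if center_px is None:
        c = R * (1 + abs(a)) * px_per_um + 8.0
        center_px = (c, c)
    x = center_px[0] + r * np.cos(theta) * px_per_um
    y = center_px[1] + r * np.sin(theta) * px_per_um
    contour = CellContour(np.column_stack([x, y]), pixel_size_nm=pixel_size_nm)
    return contour, kappa


# ---------------------------------------------------------------------------
# curvature-coupled textures


def make_textured_cell(
    contour,
    coupling: float,
    texture_orientation_deg: float = 0.0,
    *,
    margin_um: float = 1.8,
    base_intensity: float = 100.0,
    stripe_period_px: float = 8.0,
    noise_sd: float = 0.0,
    shape: tuple[int, int] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Paint a margin band whose intensity couples to contour curvature,
    plus an oriented filament texture filling the cell.

    The band weight at contour point ``i`` mixes standardized
    curvature with an independent smooth random profile ``u`` along
    the contour (biological patchiness):

        w_i = 1 + amp * (-c * khat_i + sqrt(1 - c^2) * u_i)

    so the expected Pearson correlation between curvature and margin
    intensity is ``-c`` exactly: ``c = +1`` makes intensity a perfect
    decreasing linear function of curvature (signal concentrated in
    indentations, the behaviour reported for cortical microtubules and
    CESA trajectories), ``c = 0`` decouples them, and ``|r|`` grows
    monotonically with ``|c|``.  Returns
    ``(margin_image, texture_image, truth)``.
    """
    from scipy.spatial import cKDTree

    from .contour import CellContour, curvature_profile

    if not (-1 <= coupling <= 1):
        raise ValueError("coupling must lie in [-1, 1]")
    assert isinstance(contour, CellContour)
    rng = np.random.default_rng(seed)
    verts = contour.vertices
    if shape is None:
        m = int(np.ceil(verts.max() + 8))
        shape = (m, m)
    ny, nx = shape

    prof = curvature_profile(contour, window_um=1.0)
    kappa = prof.curvature_um
    khat = (kappa - kappa.mean()) / (kappa.std() + 1e-12)
    # smooth independent profile along the (circular) contour, unit variance
    from scipy.ndimage import gaussian_filter1d

    n_vert = len(khat)
    perim_um = contour.perimeter_px() * contour.pixel_size_nm / 1000.0
    sigma_vert = max(1.0 * n_vert / perim_um, 2.0)  # ~1 um correlation length
    u = gaussian_filter1d(rng.normal(size=n_vert), sigma_vert, mode="wrap")
    u = (u - u.mean()) / (u.std() + 1e-12)
    mix = -coupling * khat + np.sqrt(1.0 - coupling**2) * u
    # scale so the painted weight stays positive: an affine rescale
    # leaves the curvature-intensity correlation untouched
    amp = min(0.35, 0.9 / (np.abs(mix).max() + 1e-12))
    weight = 1.0 + amp * mix

    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    tree = cKDTree(verts)
    dist, nearest = tree.query(pts)
    margin_px = margin_um * 1000.0 / contour.pixel_size_nm
    inside = contour.contains_points(pts)
    band = inside & (dist <= margin_px)

    margin_img = np.zeros((ny, nx))
    margin_img.ravel()[band] = base_intensity * weight[nearest[band]]

    theta = np.deg2rad(texture_orientation_deg)
    # stripes *along* orientation theta: intensity varies perpendicular to it
    phase = (-np.sin(theta) * xx + np.cos(theta) * yy) * 2 * np.pi / stripe_period_px
    texture = np.zeros((ny, nx))
    texture[inside.reshape(ny, nx)] = (
        base_intensity * 0.5 * (1 + np.sin(phase[inside.reshape(ny, nx)]))
    )

    if noise_sd > 0:
        margin_img += rng.normal(0, noise_sd * base_intensity, margin_img.shape)
        texture += rng.normal(0, noise_sd * base_intensity, texture.shape)

    truth = GroundTruth(
        contour=verts.copy(),
        coupling=coupling,
        texture_orientation_deg=texture_orientation_deg % 180.0,
        extras={"margin_weight": weight, "standardized_curvature": khat},
    )
    return margin_img, texture, truth


# ---------------------------------------------------------------------------
# co-localization pairs


def make_coloc_pair(
    shape: tuple[int, int],
    mixing: float,
    *,
    smooth_sigma: float = 2.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two positive random fields with tunable shared structure.

    ``B = rho * A + (1 - rho) * independent`` (both unit-scaled smooth
    fields); the expected Pearson correlation increases monotonically
    with ``rho``, reaching 1 at ``rho = 1`` and ~0 at ``rho = 0``.
    """
    from scipy.ndimage import gaussian_filter

    if not (0 <= mixing <= 1):
        raise ValueError("mixing must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    def unit_field() -> np.ndarray:
        f = gaussian_filter(rng.normal(size=shape), smooth_sigma)
        f -= f.min()
        return f / (f.max() + 1e-12)

    a = unit_field()
    b = mixing * a + (1 - mixing) * unit_field()
    b -= b.min()
    b /= b.max() + 1e-12
    return a, b, GroundTruth(mixing=mixing)
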