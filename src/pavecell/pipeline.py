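"""End-to-end orchestration of the analysis stages.

A :class:`PipelineConfig` (schema-validated, unknown keys rejected)
drives simulate -> project -> detect -> track -> contour -> coloc ->
stats on a synthetic scene, writing tidy CSV/JSON artifacts that all
carry the configuration hash, so a rerun with the same config and seed
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import coloc as coloc_mod
from . import scene as scene_mod
from . import spots as spots_mod
from . import stats as stats_mod
from . import surface as surface_mod
from . import tracking as tracking_mod
from .contour import curvature_correlation, curvature_profile, margin_intensity, nematic_tensor

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "write_report"]


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    output_dir: str = "pavecell_out"
    # acquisition geometry
    shape: tuple[int, int] = (192, 192)
    n_z: int = 30
    pixel_size_nm: float = Field(110.0, gt=0)
    z_step_nm: float = Field(300.0, gt=0)
    frame_interval_s: float = Field(60.0, gt=0)
    n_frames: int = Field(12, ge=1)
    read_noise_sd: float = Field(3.0, ge=0)
    poisson_noise: bool = True
    # scene content
    n_blobs: int = 8
    n_puncta: int = 40
    populations: list[tuple[int, float, str]] = [
        (30, 0.0, "immobile"),
        (30, 100.0, "linear"),
        (30, 300.0, "erratic"),
    ]
    cell_radius_um: float = 7.0
    lobe_count: int = 6
    lobe_amplitude: float = 0.3
    coupling: float = 0.6
    texture_orientation_deg: float = 30.0
    coloc_mixing: float = 0.7
    # stage parameters (defaults follow the published workflow)
    mip_depth_px: int = 3
    rolling_ball_radius_px: float = 10.0
    threshold_factor: float = 1.5
    fit_radius_px: int = 3
    initial_sigma_px: float = 1.6
    uncertainty_bounds_nm: tuple[float, float] = (5.0, 60.0)
    sigma_bounds_nm: tuple[float, float] = (50.0, 500.0)
    intensity_max: float = 500_000.0
    max_displacement_nm: float = 500.0
    min_track_length: int = 4
    stall_max_nm_min: float = 25.0
    csc_max_nm_min: float = 200.0
    margin_um: float = 1.8
    window_um: float = 1.8
    coloc_block_px: int = 5
    coloc_n_rand: int = 199

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pavecell config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a seeded synthetic scene; return the bundle.

    The bundle is a plain dict of stage results plus a ``counts`` log
    (spots detected/filtered, tracks kept, cells analysed); artifacts
    are written under ``config.output_dir``.
    """
    cfg = config
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    counts: dict[str, int | float] = {}

    spec = scene_mod.SceneSpec(
        shape=cfg.shape, n_z=cfg.n_z, pixel_size_nm=cfg.pixel_size_nm,
        z_step_nm=cfg.z_step_nm, frame_interval_s=cfg.frame_interval_s,
        n_frames=cfg.n_frames, read_noise_sd=cfg.read_noise_sd,
        poisson_noise=cfg.poisson_noise, seed=cfg.seed,
    )

    # --- surface stage ----------------------------------------------------
    ny, nx = cfg.shape
    manifold_fn = lambda x, y: (  # noqa: E731 gentle curved surface
        cfg.n_z / 2 + 4 * np.sin(2 * np.pi * x / nx) * np.cos(2 * np.pi * y / ny)
    )
    ref, tgt, surf_truth = scene_mod.make_surface_scene(
        spec, manifold_fn, blob_count=cfg.n_blobs, n_puncta=cfg.n_puncta
    )
    manifold = surface_mod.estimate_manifold(ref)
    proj = surface_mod.project_surface_mip(tgt, manifold, depth=cfg.mip_depth_px)
    proj_img = surface_mod.rolling_ball_subtract(proj.image, cfg.rolling_ball_radius_px)
    rms = float(np.sqrt(np.mean((manifold.heights - surf_truth.manifold) ** 2)))
    counts["manifold_rms_zsteps"] = rms

    # --- detection stage --------------------------------------------------
    movie, movie_truth = scene_mod.make_spot_movie(
        spec, [(n, v, m) for n, v, m in cfg.populations]  # type: ignore[misc]
    )
    bounds = spots_mod.FilterBounds(
        uncertainty_nm=cfg.uncertainty_bounds_nm,
        sigma_nm=cfg.sigma_bounds_nm,
        intensity_max=cfg.intensity_max,
    )
    all_spots = []
    for t in range(cfg.n_frames):
        frame = movie.data[t]
        cands = spots_mod.detect_candidates(frame, cfg.threshold_factor)
        recs = spots_mod.fit_spots(
            frame, cands, fit_radius=cfg.fit_radius_px,
            initial_sigma=cfg.initial_sigma_px,
            pixel_size_nm=cfg.pixel_size_nm, frame=t,
        )
        all_spots.extend(recs)
    counts["spots_detected"] = len(all_spots)
    kept, rejections = spots_mod.filter_spots(all_spots, bounds)
    counts["spots_kept"] = len(kept)
    counts.update({f"rejected_{k}": v for k, v in rejections.items()})
    spot_df = spots_mod.spots_to_frame(all_spots)
    _write_csv(spot_df, out / "spots.csv", cfg_hash)

    # --- tracking stage ---------------------------------------------------
    kept_df = spot_df[spot_df.kept][["frame", "x_px", "y_px"]].rename(
        columns={"x_px": "x", "y_px": "y"}
    )
    tracks = tracking_mod.link_tracks(
        kept_df, max_displacement_nm=cfg.max_displacement_nm,
        min_length=cfg.min_track_length, pixel_size_nm=cfg.pixel_size_nm,
    )
    counts["tracks_kept"] = len(tracks)
    cutoffs = tracking_mod.SpeedCutoffs(cfg.stall_max_nm_min, cfg.csc_max_nm_min)
    if tracks:
        tracks, fractions = tracking_mod.classify_and_fractions(
            tracks, cutoffs, pixel_size_nm=cfg.pixel_size_nm,
            interval_s=cfg.frame_interval_s,
        )
    else:
        fractions = {}
        log.warning("no tracks survived linking; fractions undefined")
    track_df = pd.DataFrame(
        [
            {
                "track_id": tr.track_id, "frame": int(f),
                "x_nm": x * cfg.pixel_size_nm, "y_nm": y * cfg.pixel_size_nm,
                "v_fit": tr.v_fit, "v_step": tr.v_step, "class": tr.motility_class,
            }
            for tr in tracks
            for f, x, y in zip(tr.frames, tr.x, tr.y)
        ]
    )
    _write_csv(track_df, out / "tracks.csv", cfg_hash)

    # --- contour stage ----------------------------------------------------
    contour, analytic_kappa = scene_mod.make_puzzle_cell(
        cfg.cell_radius_um, cfg.lobe_count, cfg.lobe_amplitude,
        pixel_size_nm=cfg.pixel_size_nm,
    )
    margin_img, texture_img, tex_truth = scene_mod.make_textured_cell(
        contour, cfg.coupling, cfg.texture_orientation_deg,
        margin_um=cfg.margin_um, noise_sd=0.05, seed=cfg.seed,
    )
    prof = curvature_profile(contour, window_um=cfg.window_um)
    prof.intensity = margin_intensity(
        margin_img, contour, margin_um=cfg.margin_um, window_um=cfg.window_um
    )
    corr = curvature_correlation(prof)
    nem = nematic_tensor(texture_img, contour.polygon)
    metrics = stats_mod.shape_metrics(contour)
    counts["cells_analysed"] = 1
    contour_df = pd.DataFrame(
        {
            "x_px": contour.vertices[:, 0], "y_px": contour.vertices[:, 1],
            "curvature_um": prof.curvature_um, "intensity": prof.intensity,
        }
    )
    _write_csv(contour_df, out / "contour.csv", cfg_hash)

    # --- co-localization stage --------------------------------------------
    a_img, b_img, coloc_truth = scene_mod.make_coloc_pair(
        cfg.shape, cfg.coloc_mixing, seed=cfg.seed
    )
    cres = coloc_mod.pearson_manders(a_img, b_img)
    cres.costes_p = coloc_mod.costes_randomization(
        a_img, b_img, block_px=cfg.coloc_block_px,
        n_rand=cfg.coloc_n_rand, seed=cfg.seed,
    )
    cres.n_randomizations = cfg.coloc_n_rand
    cres.block_px = cfg.coloc_block_px

    bundle = {
        "config_hash": cfg_hash,
        "config": cfg.model_dump(),
        "counts": counts,
        "manifold_rms_zsteps": rms,
        "projection_mean": float(proj_img.mean()),
        "density_per_um2_per_frame": None,
        "fractions": fractions,
        "mean_csc_speed_nm_min": (
            float(np.mean([t.v_fit for t in tracks if t.motility_class == "CSC"]))
            if any(t.motility_class == "CSC" for t in tracks) else None
        ),
        "curvature_correlation": corr,
        "true_coupling": tex_truth.coupling,
        "nematic_orientation_deg": nem.orientation_deg,
        "nematic_anisotropy": nem.anisotropy,
        "pearson": cres.pearson,
        "manders_m1": cres.manders_m1,
        "manders_m2": cres.manders_m2,
        "costes_p": cres.costes_p,
        "lobeyness": metrics.lobeyness,
        "area_um2": metrics.area_um2,
    }
    if len(kept) > 0:
        _, density = spots_mod.render_and_density(
            kept, cfg.shape, contour.vertices, cfg.n_frames,
            pixel_size_nm=cfg.pixel_size_nm,
        )
        bundle["density_per_um2_per_frame"] = density
    (out / "bundle.json").write_text(json.dumps(bundle, indent=2, default=float))
    return bundle


def write_report(bundle: dict, path: str | Path | None = None) -> str:
    """Machine-readable JSON plus a human-readable per-cell summary."""
    lines = ["pavecell run report", "===================", ""]
    if not bundle:
        text = "\n".join(lines + ["(empty bundle)"])
    else:
        counts = bundle.get("counts", {})
        lines.append(f"config hash: {bundle.get('config_hash', 'n/a')}")
        for k, v in counts.items():
            lines.append(f"  {k}: {v}")
        for key in (
            "density_per_um2_per_frame", "fractions", "mean_csc_speed_nm_min",
            "curvature_correlation", "nematic_anisotropy", "lobeyness",
            "pearson", "costes_p",
        ):
            if key in bundle:
                lines.append(f"{key}: {bundle[key]}")
        text = "\n".join(lines)
    if path is not None:
        p = Path(path)
        p.with_suffix(".json").write_text(json.dumps(bundle, indent=2, default=float))
        p.with_suffix(".txt").write_text(text + "\n")
    return text
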