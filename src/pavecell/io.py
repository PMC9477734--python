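"""Reading and writing pipeline artifacts (OME-TIFF, CSV, JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .scene import GroundTruth
from .surface import ImageStack

__all__ = ["write_stack", "read_stack", "write_truth_sidecar", "read_truth_sidecar"]


def write_stack(path: str | Path, stack: ImageStack) -> None:
    """OME-TIFF with physical calibration in the OME pixel metadata."""
    axes = "TYX" if (stack.time_lapse and stack.data.ndim == 3) else (
        "TZYX" if stack.data.ndim == 4 else "ZYX"
    )
    px_um = stack.pixel_size_nm / 1000.0
    meta = {
        "axes": axes,
        "PhysicalSizeX": px_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": px_um,
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeZ": stack.z_step_nm / 1000.0,
        "PhysicalSizeZUnit": "µm",
        "TimeIncrement": stack.frame_interval_s,
        "TimeIncrementUnit": "s",
        "Channel": {"Name": stack.channel or "unnamed"},
    }
    tifffile.imwrite(path, stack.data.astype(np.float32), ome=True, metadata=meta)


def read_stack(
    path: str | Path,
    *,
    pixel_size_nm: float | None = None,
    z_step_nm: float | None = None,
    frame_interval_s: float | None = None,
    time_lapse: bool = False,
    channel: str = "",
) -> ImageStack:
    """Load a stack; OME calibration is used unless overridden."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        ome = tf.ome_metadata
    px, zs, dt = 110.0, 300.0, 60.0
    if ome:
        import re

        def grab(attr: str) -> float | None:
            m = re.search(rf'{attr}="([\d.eE+-]+)"', ome)
            return float(m.group(1)) if m else None

        px = (grab("PhysicalSizeX") or 0.11) * 1000.0
        zs = (grab("PhysicalSizeZ") or 0.3) * 1000.0
        dt = grab("TimeIncrement") or 60.0
    return ImageStack(
        data,
        pixel_size_nm=pixel_size_nm or px,
        z_step_nm=z_step_nm or zs,
        frame_interval_s=frame_interval_s or dt,
        time_lapse=time_lapse or data.ndim == 3 and "T" in (channel or ""),
        channel=channel,
    )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_truth_sidecar(path: str | Path, truth: GroundTruth) -> None:
    """Ground truth as a JSON sidecar next to the rendered stacks."""
    payload = {
        "manifold": _jsonable(truth.manifold),
        "blob_centers": _jsonable(truth.blob_centers),
        "puncta": _jsonable(truth.puncta),
        "tracks": truth.tracks.to_dict(orient="list") if truth.tracks is not None else None,
        "contour": _jsonable(truth.contour),
        "curvature_um": _jsonable(truth.curvature_um),
        "coupling": truth.coupling,
        "texture_orientation_deg": truth.texture_orientation_deg,
        "mixing": truth.mixing,
        "extras": {k: _jsonable(v) for k, v in truth.extras.items()},
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_sidecar(path: str | Path) -> GroundTruth:
    import pandas as pd

    d = json.loads(Path(path).read_text())
    arr = lambda v: None if v is None else np.asarray(v)  # noqa: E731
    return GroundTruth(
        manifold=arr(d["manifold"]),
        blob_centers=arr(d["blob_centers"]),
        puncta=arr(d["puncta"]),
        tracks=None if d["tracks"] is None else pd.DataFrame(d["tracks"]),
        contour=arr(d["contour"]),
        curvature_um=arr(d["curvature_um"]),
        coupling=d["coupling"],
        texture_orientation_deg=d["texture_orientation_deg"],
        mixing=d["mixing"],
        extras=d.get("extras", {}),
    )
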