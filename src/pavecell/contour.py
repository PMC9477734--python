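"""Cell-contour geometry: curvature, margin intensity, texture nematics.

Pavement cells form interlocking lobes (convex protrusions) and necks
(concave indentations).  The quantities defined here follow the
contour-analysis workflow for such cells:

* signed local curvature by least-squares circle fitting over a fixed
  arc length (1.8 um for CSC-MT data, 1.2 um for membrane-MT data),
  with the sign read off a point-in-polygon test of the fitted centre
  — centre outside the cell means concave, negative;
* margin-band intensity: signal measured only within a band of the
  same width inward of the contour, attributed to the nearest contour
  arc position;
* the curvature-correlation coefficient: Pearson r between per-vertex
  curvature and margin intensity (negative = signal concentrates in
  indentations);
* FibrilTool-style nematic orientation/anisotropy from intensity
  gradients; and the acute co-alignment angle of a cell's texture
  orientation with the nearest edge of an ablation-site polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "CellContour",
    "CurvatureProfile",
    "NematicResult",
    "extract_contours",
    "curvature_profile",
    "margin_intensity",
    "curvature_correlation",
    "nematic_tensor",
    "ablation_co_alignment",
]


def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


@dataclass
class CellContour:
    """Closed, simple polygon outlining one cell.

    Vertices are ``(x, y)`` pixels stored with positive shoelace area
    (interior on the left of the traversal).  ``exclude`` optionally
    masks vertices to be ignored in correlations, e.g. walls shared
    with stomata.
    """

    vertices: np.ndarray
    pixel_size_nm: float = 110.0
    exclude: np.ndarray | None = None
    touches_border: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 20:
            raise ValueError("contour needs an (n >= 20, 2) vertex array")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if _shoelace(v) < 0:
            v = v[::-1].copy()
            if self.exclude is not None:
                self.exclude = np.asarray(self.exclude)[::-1].copy()
        self.vertices = v
        if not Polygon(v).is_valid:
            raise ValueError("contour polygon is self-intersecting")
        if self.exclude is not None:
            self.exclude = np.asarray(self.exclude, dtype=bool)
            if len(self.exclude) != len(v):
                raise ValueError("exclusion mask length mismatch")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def arc_lengths_px(self) -> np.ndarray:
        """Cumulative arc length at each vertex (closing edge excluded)."""
        steps = np.linalg.norm(np.diff(self.vertices, axis=0, append=self.vertices[:1]), axis=1)
        return np.concatenate([[0.0], np.cumsum(steps)[:-1]])

    def perimeter_px(self) -> float:
        return float(self.polygon.length)

    def contains_points(self, pts: np.ndarray) -> np.ndarray:
        from matplotlib.path import Path as _MplPath  # vectorized point-in-polygon

        try:
            return _MplPath(self.vertices).contains_points(pts)
        except ImportError:  # pragma: no cover
            poly = self.polygon
            return np.array([poly.contains(Point(p)) for p in pts])


@dataclass
class CurvatureProfile:
    """Per-vertex signed curvature (1/um) plus optional margin
    intensity and local texture fields for the same contour."""

    contour: CellContour
    curvature_um: np.ndarray
    radius_um: np.ndarray
    centers_px: np.ndarray
    intensity: np.ndarray | None = None
    orientation_deg: np.ndarray | None = None
    anisotropy: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class NematicResult:
    """Average texture orientation (deg, mod 180) and anisotropy score
    in [0, 1] (0 isotropic, 1 perfectly aligned)."""

    orientation_deg: float
    anisotropy: float
    defined: bool = True


# ---------------------------------------------------------------------------


def extract_contours(
    membrane_image: np.ndarray,
    *,
    pixel_size_nm: float = 110.0,
    smooth_sigma: float = 1.0,
    min_area_px: float = 200.0,
    h_minima: float | None = None,
) -> list[CellContour]:
    """Watershed cell segmentation of a membrane image.

    Cell borders are bright ridges; the watershed is flooded from the
    regional minima of the smoothed image (optionally h-minima
    suppressed), one contour per basin, traced as a closed polygon.
    Basins touching the image border are flagged.  A blank image
    yields an empty list.
    """
    from scipy import ndimage as ndi
    from skimage.measure import find_contours
    from skimage.morphology import local_minima
    from skimage.segmentation import watershed

    img = np.asarray(membrane_image, dtype=float)
    if img.std() == 0:
        return []
    smooth = ndi.gaussian_filter(img, smooth_sigma)
    if h_minima is not None:
        from skimage.morphology import h_minima as _hmin

        seeds = _hmin(smooth, h_minima)
    else:
        seeds = local_minima(smooth)
    markers, n = ndi.label(seeds)
    if n == 0:
        return []
    labels = watershed(smooth, markers)
    contours: list[CellContour] = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        if mask.sum() < min_area_px:
            continue
        border = (
            mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
        )
        found = find_contours(mask.astype(float), 0.5)
        if not found:
            continue
        ring = max(found, key=len)  # rows are (y, x)
        verts = ring[:, ::-1]
        if len(verts) < 21:
            continue
        try:
            contours.append(
                CellContour(verts, pixel_size_nm=pixel_size_nm, touches_border=border)
            )
        except ValueError:
            continue
    return contours


def _kasa_circle(pts: np.ndarray) -> tuple[float, float, float]:
    """Algebraic (Kasa) least-squares circle fit.

    Solves ``x^2 + y^2 = 2 a x + 2 b y + c`` linearly; returns centre
    (a, b) and radius.  Near-collinear arcs produce huge radii, which
    callers map to zero curvature.
    """
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(pts))])
    b = x * x + y * y
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3 or sv[-1] < 1e-9 * sv[0]:  # collinear arc: no finite circle
        return float("nan"), float("nan"), float("inf")
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    return float(cx), float(cy), float(np.sqrt(max(r2, 0.0)))


def curvature_profile(
    contour: CellContour,
    window_um: float = 1.8,
    *,
    max_radius_um: float = 1e4,
    sign_rule: str = "normal_side",
) -> CurvatureProfile:
    """Signed local curvature by circle fitting along the contour.

    For each vertex the arc of total length ``window_um`` centred on
    it is fitted to a circle; curvature is the reciprocal radius
    (1/um), negative in concave (indenting) regions and positive in
    convex (protruding) ones.  Nearly collinear arcs (radius beyond
    ``max_radius_um``) give curvature 0.

    The concavity convention is that the fitted centre lies outside
    the cell in indenting regions.  ``sign_rule="centre_in_polygon"``
    applies that test verbatim; the default ``"normal_side"`` reads
    the sign off which side of the contour the centre falls (inward
    normal means convex), which is identical whenever the fitted
    circle is small enough to sit inside the cell but remains correct
    for near-straight stretches, where an interior-side centre can lie
    beyond the far cell boundary and the literal point-in-polygon test
    would misclassify a flat convex run as concave.
    """
    v = contour.vertices
    n = len(v)
    px_per_um = 1000.0 / contour.pixel_size_nm
    window_px = window_um * px_per_um
    s = contour.arc_lengths_px()
    perim = contour.perimeter_px()
    if window_px < 3 * perim / n:
        raise ValueError("window must span at least 3 vertex spacings")
    half = window_px / 2.0

    if sign_rule not in ("normal_side", "centre_in_polygon"):
        raise ValueError(f"unknown sign_rule {sign_rule!r}")
    poly = contour.polygon
    kappa = np.zeros(n)
    radius = np.full(n, np.inf)
    centers = np.zeros((n, 2))
    tangent = np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)
    inward = np.column_stack([-tangent[:, 1], tangent[:, 0]])  # left of CCW traversal
    # arc selection on the circular contour via arc-length distance
    for i in range(n):
        ds = np.abs(s - s[i])
        ds = np.minimum(ds, perim - ds)
        idx = np.nonzero(ds <= half)[0]
        if len(idx) < 3:
            idx = np.array([(i - 1) % n, i, (i + 1) % n])
        cx, cy, r_px = _kasa_circle(v[idx])
        centers[i] = (cx, cy)
        r_um = r_px / px_per_um
        radius[i] = r_um
        if not np.isfinite(r_um) or r_um > max_radius_um or r_um == 0:
            kappa[i] = 0.0
            continue
        if sign_rule == "centre_in_polygon":
            sign = 1.0 if poly.contains(Point(cx, cy)) else -1.0
        else:
            sign = 1.0 if np.dot((cx - v[i, 0], cy - v[i, 1]), inward[i]) >= 0 else -1.0
        kappa[i] = sign / r_um
    return CurvatureProfile(
        contour, kappa, radius, centers, meta={"window_um": window_um}
    )


def margin_intensity(
    image: np.ndarray,
    contour: CellContour,
    margin_um: float = 1.8,
    window_um: float = 1.8,
) -> np.ndarray:
    """Mean signal in the inward margin band, per contour vertex.

    The band is the region within ``margin_um`` inward of the contour
    (clipped at the cell midline for narrow cells).  Each band pixel
    is attributed to its nearest contour vertex; a vertex's intensity
    is the mean over band pixels whose arc position lies within
    ``window_um / 2`` of it.  Excluded vertices return NaN.
    """
    from scipy.spatial import cKDTree

    img = np.asarray(image, dtype=float)
    v = contour.vertices
    n = len(v)
    px_per_um = 1000.0 / contour.pixel_size_nm
    margin_px = margin_um * px_per_um
    half_window_px = window_um * px_per_um / 2.0

    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    tree = cKDTree(v)
    dist, nearest = tree.query(pts)
    band = contour.contains_points(pts) & (dist <= margin_px)
    band_vals = img.ravel()[band]
    band_nearest = nearest[band]

    s = contour.arc_lengths_px()
    perim = contour.perimeter_px()
    # per-vertex sums, then circular arc-window average over vertices
    sums = np.bincount(band_nearest, weights=band_vals, minlength=n)
    counts = np.bincount(band_nearest, minlength=n)
    out = np.full(n, np.nan)
    for i in range(n):
        ds = np.abs(s - s[i])
        ds = np.minimum(ds, perim - ds)
        sel = ds <= half_window_px
        c = counts[sel].sum()
        if c > 0:
            out[i] = sums[sel].sum() / c
    if contour.exclude is not None:
        out[contour.exclude] = np.nan
    return out


def curvature_correlation(profile: CurvatureProfile) -> float:
    """Pearson correlation between per-vertex curvature and margin
    intensity over non-excluded vertices.

    Negative values mean the signal concentrates in indentations.
    Returns NaN (flagged undefined) if fewer than 10 usable vertices
    remain or either variable has zero variance.
    """
    if profile.intensity is None:
        raise ValueError("profile carries no margin intensity")
    k = profile.curvature_um
    inten = profile.intensity
    ok = np.isfinite(k) & np.isfinite(inten)
    if profile.contour.exclude is not None:
        ok &= ~profile.contour.exclude
    if ok.sum() < 10:
        return float("nan")
    k, inten = k[ok], inten[ok]
    if k.std() == 0 or inten.std() == 0:
        return float("nan")
    return float(np.corrcoef(k, inten)[0, 1])


def nematic_tensor(
    image: np.ndarray, region: np.ndarray | Polygon | None = None
) -> NematicResult:
    """Texture orientation and anisotropy from intensity gradients.

    Central-difference gradients are computed per pixel; for pixels
    with non-zero gradient the unit-gradient outer product is averaged
    over the region into a trace-1 tensor.  Fibrils run perpendicular
    to the intensity gradient, so the reported orientation is the
    eigenvector of the *smaller* eigenvalue (deg, mod 180; 0 = along
    +x, 90 = along +y); anisotropy is the eigenvalue difference
    (0 isotropic, 1 perfectly parallel).
    """
    img = np.asarray(image, dtype=float)
    gy, gx = np.gradient(img)
    if region is not None:
        if isinstance(region, Polygon):
            from matplotlib.path import Path as _MplPath

            ny, nx = img.shape
            yy, xx = np.mgrid[0:ny, 0:nx]
            mask = _MplPath(np.asarray(region.exterior.coords)).contains_points(
                np.column_stack([xx.ravel(), yy.ravel()])
            ).reshape(ny, nx)
        else:
            mask = np.asarray(region, dtype=bool)
        gx, gy = gx[mask], gy[mask]
    gx, gy = gx.ravel(), gy.ravel()
    mag2 = gx * gx + gy * gy
    nz = mag2 > 0
    if nz.sum() < 1:
        return NematicResult(float("nan"), 0.0, defined=False)
    ux, uy = gx[nz] / np.sqrt(mag2[nz]), gy[nz] / np.sqrt(mag2[nz])
    txx = float(np.mean(ux * ux))
    tyy = float(np.mean(uy * uy))
    txy = float(np.mean(ux * uy))
    tensor = np.array([[txx, txy], [txy, tyy]])
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    anisotropy = float(evals[1] - evals[0])
    minor = evecs[:, 0]  # eigenvector of the smaller eigenvalue
    angle = float(np.degrees(np.arctan2(minor[1], minor[0])) % 180.0)
    return NematicResult(angle, anisotropy)


def ablation_co_alignment(
    orientation_deg: float,
    centroid: tuple[float, float],
    ablation_polygon: np.ndarray,
) -> float:
    """Acute angle between a cell's texture orientation and the
    nearest stretch of an ablation-site polygon.

    The nearest edge is the polygon segment minimizing distance to the
    cell centroid; both orientations are axial (mod 180), and the
    difference is folded into [0, 90] — 0 is perfect co-alignment.
    """
    poly = np.asarray(ablation_polygon, dtype=float)
    if poly.ndim != 2 or len(poly) < 2:
        raise ValueError("ablation polygon needs at least 2 vertices")
    p = Point(centroid)
    closed = not np.allclose(poly[0], poly[-1]) and len(poly) > 2
    edges = list(zip(poly[:-1], poly[1:]))
    if closed:
        edges.append((poly[-1], poly[0]))
    best, best_d = None, np.inf
    for a, b in edges:
        if np.allclose(a, b):
            continue
        d = LineString([a, b]).distance(p)
        if d < best_d:
            best_d, best = d, (a, b)
    if best is None:
        raise ValueError("degenerate ablation polygon (all edges zero-length)")
    a, b = best
    edge_angle = np.degrees(np.arctan2(b[1] - a[1], b[0] - a[0])) % 180.0
    diff = abs(orientation_deg % 180.0 - edge_angle) % 180.0
    return float(min(diff, 180.0 - diff))
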