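"""Contour curvature, margin intensity, nematic texture, co-alignment."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

import pavecell as pc
from pavecell.contour import CellContour


def _extrema_mask(n, k, frac=0.1):
    """Vertices at least ``frac`` of a half lobe-period away from the
    analytic curvature extrema of r(theta) = R(1 + a cos k theta)."""
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    phase = (k * theta) % np.pi
    dist = np.minimum(phase, np.pi - phase)
    return dist > frac * (np.pi / 2)


class TestCurvature:
    def test_circle_curvature_positive_inverse_radius(self):
        contour, _ = pc.make_puzzle_cell(10.0, 1, 0.0)
        prof = pc.curvature_profile(contour, window_um=1.8)
        assert np.allclose(prof.curvature_um, 0.1, rtol=0.01)
        assert np.all(prof.curvature_um > 0)

    def test_straight_segment_zero_curvature(self):
        # long thin rectangle: the long sides are straight
        n = 200
        xs = np.linspace(0, 400, n)
        top = np.column_stack([xs, np.zeros(n)])
        bot = np.column_stack([xs[::-1], np.full(n, 40.0)])
        rect = CellContour(
            np.vstack([top, [[400.0, 20.0]], bot, [[0.0, 20.0]]]), pixel_size_nm=110
        )
        prof = pc.curvature_profile(rect, window_um=1.0)
        mid = np.abs(rect.vertices[:, 1]) < 1e-9
        mid &= (rect.vertices[:, 0] > 100) & (rect.vertices[:, 0] < 300)
        assert np.allclose(prof.curvature_um[mid], 0.0, atol=1e-9)

    def test_puzzle_matches_analytic_away_from_extrema(self, puzzle):
        contour, kappa = puzzle
        prof = pc.curvature_profile(contour, window_um=0.5)
        sel = _extrema_mask(len(kappa), 6) & (np.abs(kappa) > 0.2 * np.abs(kappa).max())
        rel = np.abs((prof.curvature_um[sel] - kappa[sel]) / kappa[sel])
        assert rel.mean() < 0.05

    def test_sign_convention_centre_outside_negative(self, puzzle):
        contour, kappa = puzzle
        prof = pc.curvature_profile(
            contour, window_um=0.5, sign_rule="centre_in_polygon"
        )
        poly = contour.polygon
        for i in range(0, len(contour.vertices), 37):
            inside = poly.contains(Point(prof.centers_px[i]))
            assert (prof.curvature_um[i] >= 0) == inside

    def test_sign_rules_agree_on_well_curved_regions(self, puzzle):
        # the robust normal-side rule reproduces the centre-in-polygon
        # convention wherever the fitted circle is smaller than the cell
        contour, _ = puzzle
        p1 = pc.curvature_profile(contour, window_um=0.5)
        p2 = pc.curvature_profile(contour, window_um=0.5, sign_rule="centre_in_polygon")
        small = p1.radius_um < 3.0
        assert small.sum() > 100
        assert np.array_equal(
            np.sign(p1.curvature_um[small]), np.sign(p2.curvature_um[small])
        )

    def test_convex_hull_vertices_nonnegative_curvature(self, puzzle):
        contour, _ = puzzle
        prof = pc.curvature_profile(contour, window_um=0.5)
        hull = contour.polygon.convex_hull.exterior
        on_hull = np.array(
            [hull.distance(Point(v)) < 0.5 for v in contour.vertices]
        )
        assert np.all(prof.curvature_um[on_hull] > -0.05)

    def test_total_turning_2pi(self, puzzle):
        contour, _ = puzzle
        prof = pc.curvature_profile(contour, window_um=0.5)
        ds_px = np.linalg.norm(
            np.diff(contour.vertices, axis=0, append=contour.vertices[:1]), axis=1
        )
        ds_um = ds_px * contour.pixel_size_nm / 1000.0
        total = np.sum(prof.curvature_um * ds_um)
        assert total == pytest.approx(2 * np.pi, rel=0.05)

    def test_window_too_small_raises(self, puzzle):
        contour, _ = puzzle
        with pytest.raises(ValueError):
            pc.curvature_profile(contour, window_um=0.01)


class TestMarginIntensity:
    def test_uniform_image_uniform_intensity(self, small_puzzle):
        contour, _ = small_puzzle
        m = int(np.ceil(contour.vertices.max() + 5))
        inten = pc.margin_intensity(np.full((m, m), 7.0), contour, 1.0, 0.5)
        assert np.allclose(inten[np.isfinite(inten)], 7.0)

    def test_indentation_painting_recovered(self, small_puzzle):
        contour, kappa = small_puzzle
        img, _, truth = pc.make_textured_cell(contour, 1.0, 0.0, noise_sd=0.0, seed=0)
        inten = pc.margin_intensity(img, contour, 1.0, 0.5)
        neck = kappa < np.percentile(kappa, 20)
        lobe = kappa > np.percentile(kappa, 80)
        assert np.nanmean(inten[neck]) > np.nanmean(inten[lobe])

    def test_strong_coupling_profile_tracks_truth(self, small_puzzle):
        contour, _ = small_puzzle
        img, _, truth = pc.make_textured_cell(contour, 0.8, 0.0, noise_sd=0.0, seed=1)
        inten = pc.margin_intensity(img, contour, 1.0, 0.5)
        w = truth.extras["margin_weight"]
        ok = np.isfinite(inten)
        assert np.corrcoef(inten[ok], w[ok])[0, 1] > 0.9

    def test_excluded_vertices_nan(self, small_puzzle):
        contour, _ = small_puzzle
        excl = np.zeros(len(contour.vertices), bool)
        excl[:50] = True
        masked = CellContour(
            contour.vertices.copy(), pixel_size_nm=contour.pixel_size_nm, exclude=excl
        )
        m = int(np.ceil(contour.vertices.max() + 5))
        inten = pc.margin_intensity(np.ones((m, m)), masked, 1.0, 0.5)
        assert np.all(np.isnan(inten[masked.exclude]))


class TestCurvatureCorrelation:
    def test_perfect_anticorrelation_and_correlation(self, small_puzzle):
        contour, _ = small_puzzle
        prof = pc.curvature_profile(contour, window_um=0.5)
        prof.intensity = -prof.curvature_um
        assert pc.curvature_correlation(prof) == pytest.approx(-1.0)
        prof.intensity = prof.curvature_um.copy()
        assert pc.curvature_correlation(prof) == pytest.approx(1.0)

    def test_zero_variance_flagged_nan(self, small_puzzle):
        contour, _ = small_puzzle
        prof = pc.curvature_profile(contour, window_um=0.5)
        prof.intensity = np.ones(len(contour.vertices))
        assert np.isnan(pc.curvature_correlation(prof))

    def test_construction_exactness_at_full_coupling(self, small_puzzle):
        contour, _ = small_puzzle
        for c, expected in ((1.0, -1.0), (-1.0, 1.0)):
            _, _, truth = pc.make_textured_cell(contour, c, 0.0, noise_sd=0.0, seed=2)
            r = np.corrcoef(
                truth.extras["standardized_curvature"], truth.extras["margin_weight"]
            )[0, 1]
            assert r == pytest.approx(expected, abs=1e-6)

    def test_reflection_invariance(self, small_puzzle):
        contour, _ = small_puzzle
        img, _, _ = pc.make_textured_cell(contour, 0.7, 0.0, noise_sd=0.05, seed=3)
        prof = pc.curvature_profile(contour, window_um=0.5)
        prof.intensity = pc.margin_intensity(img, contour, 1.0, 0.5)
        r = pc.curvature_correlation(prof)
        # mirror both contour and image about the y axis of the image
        w = img.shape[1]
        mv = contour.vertices.copy()
        mv[:, 0] = (w - 1) - mv[:, 0]
        mc = CellContour(mv, pixel_size_nm=contour.pixel_size_nm)
        mimg = img[:, ::-1]
        mprof = pc.curvature_profile(mc, window_um=0.5)
        mprof.intensity = pc.margin_intensity(mimg, mc, 1.0, 0.5)
        assert pc.curvature_correlation(mprof) == pytest.approx(r, abs=0.02)


def _stripes(deg, shape=(128, 128), period=8.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    th = np.deg2rad(deg)
    phase = (-np.sin(th) * xx + np.cos(th) * yy) * 2 * np.pi / period
    return 100 * (1 + np.sin(phase))


class TestNematic:
    @pytest.mark.parametrize("deg", [0, 45, 90, 135])
    def test_stripe_orientation_and_high_anisotropy(self, deg):
        res = pc.nematic_tensor(_stripes(deg))
        diff = abs(res.orientation_deg - deg) % 180
        assert min(diff, 180 - diff) < 2.0
        assert res.anisotropy > 0.95

    def test_isotropic_noise_low_anisotropy(self):
        vals = [
            pc.nematic_tensor(np.random.default_rng(s).normal(size=(128, 128))).anisotropy
            for s in range(10)
        ]
        assert max(vals) < 0.05

    def test_rotation_equivariance(self):
        from scipy.ndimage import rotate

        img = _stripes(20)
        base = pc.nematic_tensor(img[32:96, 32:96])
        rot = rotate(img, -30, reshape=False, order=3)  # image rotation by +30 deg axes
        res = pc.nematic_tensor(rot[32:96, 32:96])
        diff = abs(res.orientation_deg - (base.orientation_deg + 30)) % 180
        assert min(diff, 180 - diff) < 2.0
        assert abs(res.anisotropy - base.anisotropy) < 0.02

    def test_constant_region_flagged(self):
        res = pc.nematic_tensor(np.ones((32, 32)))
        assert not res.defined and res.anisotropy == 0.0


class TestCoAlignment:
    def test_parallel_and_perpendicular(self):
        edge = np.array([[0.0, 0.0], [10.0, 0.0]])
        assert pc.ablation_co_alignment(0.0, (5, 5), edge) == 0.0
        assert pc.ablation_co_alignment(90.0, (5, 5), edge) == 90.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            poly = rng.uniform(0, 100, (rng.integers(2, 8), 2))
            cen = tuple(rng.uniform(0, 100, 2))
            ori = float(rng.uniform(0, 180))
            got = pc.ablation_co_alignment(ori, cen, poly)
            best, bd = None, np.inf
            edges = list(zip(poly[:-1], poly[1:]))
            if len(poly) > 2:
                edges.append((poly[-1], poly[0]))
            for a, b in edges:
                d = LineString([a, b]).distance(Point(cen))
                if d < bd:
                    bd, best = d, (a, b)
            ea = np.degrees(np.arctan2(best[1][1] - best[0][1], best[1][0] - best[0][0])) % 180
            diff = abs(ori - ea) % 180
            assert got == pytest.approx(min(diff, 180 - diff), abs=1e-9)

    def test_degenerate_polygon_raises(self):
        with pytest.raises(ValueError):
            pc.ablation_co_alignment(0.0, (0, 0), np.array([[1.0, 1.0], [1.0, 1.0]]))


class TestWatershed:
    def test_grid_of_rectangular_cells(self):
        img = np.zeros((100, 100))
        img[::33, :] = 100.0
        img[:, ::33] = 100.0
        img[-1, :] = 100.0
        img[:, -1] = 100.0
        cells = pc.extract_contours(img, min_area_px=100)
        assert len(cells) == 9

    def test_rendered_puzzle_cell_boundary_recovered(self, small_puzzle):
        contour, _ = small_puzzle
        m = int(np.ceil(contour.vertices.max() + 10))
        yy, xx = np.mgrid[0:m, 0:m]
        pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        inside = contour.contains_points(pts).reshape(m, m)
        from scipy.ndimage import binary_dilation

        wall = binary_dilation(inside) & ~inside | (
            inside & ~np.roll(inside, 1, 0) | inside & ~np.roll(inside, 1, 1)
        )
        img = np.where(wall, 100.0, 0.0)
        img[0, :] = img[-1, :] = img[:, 0] = img[:, -1] = 100.0
        cells = pc.extract_contours(img, min_area_px=500)
        interior = [c for c in cells if not c.touches_border]
        assert len(interior) >= 1
        cell = max(interior, key=lambda c: c.polygon.area)
        # symmetric boundary distance below 2 px
        truth_ring = LineString(np.vstack([contour.vertices, contour.vertices[:1]]))
        got_ring = LineString(np.vstack([cell.vertices, cell.vertices[:1]]))
        d1 = max(truth_ring.distance(Point(p)) for p in cell.vertices[::7])
        d2 = max(got_ring.distance(Point(p)) for p in contour.vertices[::7])
        assert max(d1, d2) < 2.0

    def test_blank_image_empty(self):
        assert pc.extract_contours(np.zeros((64, 64))) == []
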