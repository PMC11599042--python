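"""Scaled three-point curvature, motif and BSCR mapping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bscrmap as b
from bscrmap.topography import (
    BSCR_CATEGORIES,
    MOTIF_FLAT,
    MOTIF_INVALID,
    bscr_category,
    direction_angles,
    maps_to_table,
    read_heightmap,
)

from conftest import circumradius_3pt, sphere_bowl_height


# ---------------------------------------------------------------------------
# The three-point primitive


class TestThreePointCurvature:
    def test_collinear_is_zero(self):
        assert b.three_point_curvature(0.0, 0.0, 0.0, 30.0) == 0.0
        assert b.three_point_curvature(1.0, 2.0, 0.0, 30.0) == 0.0  # on a ramp

    def test_circle_radius_32(self):
        """Chord points on a circle of radius 32 µm give kappa = 1000/32."""
        z = 32.0 - math.sqrt(32.0**2 - 30.0**2)
        assert b.three_point_curvature(0.0, z, z, 30.0) == pytest.approx(31.25, rel=1e-6)
        assert b.three_point_curvature(0.0, -z, -z, 30.0) == pytest.approx(-31.25, rel=1e-6)

    @given(
        zA=st.floats(-50, 50),
        zC=st.floats(-50, 50),
        zE=st.floats(-50, 50),
        s=st.floats(5.0, 60.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_circumcircle_oracle(self, zA, zC, zE, s):
        """|kappa| always equals 1000 / circumradius of (±s, z) and (0, zA),
        with the sign of the sagitta (independent linear-solve oracle)."""
        kappa = b.three_point_curvature(zA, zC, zE, s)
        d = zC + zE - 2 * zA
        if abs(d) < 1e-9:
            assert kappa == 0.0
        else:
            r = circumradius_3pt((-s, zE), (0.0, zA), (s, zC))
            assert abs(kappa) == pytest.approx(1000.0 / r, rel=1e-9)
            assert math.copysign(1.0, kappa) == math.copysign(1.0, d)

    @given(
        zA=st.floats(-50, 50), zC=st.floats(-50, 50), zE=st.floats(-50, 50),
        c=st.floats(-20, 20),
    )
    @settings(max_examples=100, deadline=None)
    def test_height_offset_invariance_and_negation(self, zA, zC, zE, c):
        k1 = b.three_point_curvature(zA, zC, zE, 30.0)
        k2 = b.three_point_curvature(zA + c, zC + c, zE + c, 30.0)
        # offset invariance up to rounding of the shifted inputs
        assert k2 == pytest.approx(k1, rel=1e-12, abs=1e-9)
        # negation is an exact floating-point operation
        assert b.three_point_curvature(-zA, -zC, -zE, 30.0) == -k1

    @pytest.mark.parametrize("radius", [16.0, 24.0, 32.0, 48.0, 80.0])
    def test_sphere_exactness_uninterpolated(self, radius):
        """Exact sphere samples recover 1000/R to < 1e-9 relative in every
        direction (the chord plane always cuts the sphere in a great or
        small... here through the bottom point: a circle of radius R)."""
        s = min(30.0, 0.75 * radius)
        z = radius - math.sqrt(radius**2 - s**2)
        for _ in direction_angles(18):
            kappa = b.three_point_curvature(0.0, z, z, s)
            assert abs(kappa * radius / 1000.0 - 1.0) < 1e-9


# ---------------------------------------------------------------------------
# Height-map construction and sampling


class TestHeightmapFromVoxels:
    def test_column_height(self):
        vol = np.zeros((12, 2, 2), dtype=np.uint8)
        vol[0:10, 0, 0] = 1  # occupied for z-indices 0..9
        vol[0:3, 0, 1] = 1
        hm = b.heightmap_from_voxels(vol, voxel_size=1.0)
        assert hm.heights[0, 0] == pytest.approx(10.0)
        assert hm.heights[0, 1] == pytest.approx(3.0)
        assert not hm.valid[1, 1]  # empty column -> invalid

    def test_non_binary_rejected(self):
        with pytest.raises(b.ValidationError):
            b.heightmap_from_voxels(np.full((2, 2, 2), 2), voxel_size=1.0)

    def test_hemisphere_raster_matches_analytic_cap(self):
        """A dome rasterized at 0.5 µm voxels reproduces the analytic
        spherical-cap height within one voxel everywhere."""
        R, vox, base = 20.0, 0.5, 2.0
        n = int(50.0 / vox) + 1
        x = np.arange(n) * vox
        X, Y = np.meshgrid(x, x)
        rho = np.hypot(X - 25.0, Y - 25.0)
        analytic = base + np.where(rho < R, np.sqrt(np.maximum(R**2 - rho**2, 0.0)), 0.0)
        nz = int(np.ceil(analytic.max() / vox)) + 2
        zidx = np.arange(nz)[:, None, None] * vox
        vol = (zidx < analytic[None, :, :]).astype(np.uint8)
        hm = b.heightmap_from_voxels(vol, voxel_size=vox)
        assert hm.valid.all()
        assert np.max(np.abs(hm.heights - analytic)) <= vox + 1e-9


class TestSampleHeight:
    def test_grid_node(self):
        hm = b.HeightMap(np.arange(9, dtype=float).reshape(3, 3), pixel_size=2.0)
        assert b.sample_height(hm, 2.0, 4.0) == pytest.approx(7.0)  # col 1, row 2

    def test_centre_of_four_pixels(self):
        hm = b.HeightMap(np.array([[0.0, 0.0], [4.0, 4.0]]), pixel_size=1.0)
        assert b.sample_height(hm, 0.5, 0.5) == pytest.approx(2.0)

    def test_exact_on_planar_ramp(self):
        hm = b.HeightMap(0.3 * np.arange(11, dtype=float)[None, :].repeat(11, axis=0),
                         pixel_size=1.0)
        for xq in (0.25, 3.7, 9.99):
            assert b.sample_height(hm, xq, 5.3) == pytest.approx(0.3 * xq, rel=1e-12)

    def test_out_of_extent_and_invalid_neighbour(self):
        z = np.zeros((4, 4))
        valid = np.ones((4, 4), bool)
        valid[1, 1] = False
        hm = b.HeightMap(z, 1.0, valid=valid)
        with pytest.raises(b.SamplingError):
            b.sample_height(hm, -0.1, 0.0)
        with pytest.raises(b.SamplingError):
            b.sample_height(hm, 1.5, 1.5)
        # on-node query adjacent to the invalid pixel is fine (zero weight)
        assert b.sample_height(hm, 2.0, 1.0) == 0.0


# ---------------------------------------------------------------------------
# Directional curvature


class TestDirectionalCurvatures:
    def test_flat_map_all_zero(self, flat_map):
        dc = b.directional_curvatures(flat_map, 250.0, 250.0)
        assert np.all(dc.kappas == 0.0)
        assert dc.mean_kappa == 0.0

    def test_bowl_centre_all_directions_in_bscr(self, bowl_surface):
        """At the centre of a sphere-radius-32 bowl every direction reads
        ~31.25 mm^-1: exactly on grid-aligned axes, within 1% with bilinear
        interpolation elsewhere."""
        hm, info = bowl_surface
        dc = b.directional_curvatures(hm, 100.0, 100.0)
        assert dc.kappas.shape == (18,)
        nominal = info["nominal_kappa_mm1"]
        assert nominal == pytest.approx(31.25)
        # axis-aligned chords sample grid nodes exactly
        assert dc.kappas[0] == pytest.approx(nominal, rel=1e-9)
        assert dc.kappas[9] == pytest.approx(nominal, rel=1e-9)
        assert np.all(np.abs(dc.kappas / nominal - 1.0) < 0.01)
        positive, count, cat = b.bscr_flags(dc.kappas)
        assert (positive, count, cat) == (True, 18, "hi")

    def test_rotational_invariance_at_bowl_centre(self, bowl_surface):
        """Radially symmetric surface: spread of the 18 directional values
        at the symmetry centre stays below 0.1 mm^-1 on a 1 µm grid."""
        hm, _ = bowl_surface
        dc = b.directional_curvatures(hm, 100.0, 100.0)
        assert dc.kappas.max() - dc.kappas.min() < 0.1

    @pytest.mark.parametrize("radius", [16.0, 32.0, 48.0, 80.0])
    def test_sphere_bilinear_within_one_percent(self, radius):
        """Bilinear sampling on a 1 µm grid keeps every directional estimate
        within 1% of 1000/R across bowl radii 16-80 µm."""
        s = min(30.0, 0.7 * radius)
        a = min(0.95 * radius, 1.4 * s)  # aperture half-width: fits the chords
        n = 161
        x = np.arange(n, dtype=float)
        X, Y = np.meshgrid(x, x)
        rho = np.hypot(X - 80.0, Y - 80.0)
        hm = b.HeightMap(sphere_bowl_height(rho, radius, a), pixel_size=1.0)
        params = b.CurvatureParams(scale_length=2 * s)
        dc = b.directional_curvatures(hm, 80.0, 80.0, params)
        assert np.all(np.abs(dc.kappas * radius / 1000.0 - 1.0) < 0.01)

    def test_unsampleable_endpoint_invalidates_point(self, flat_map):
        with pytest.raises(b.SamplingError):
            b.directional_curvatures(flat_map, 10.0, 250.0)  # chord leaves raster


class TestCylinderAnisotropy:
    # axis angles are multiples of the 10° direction step so that both the
    # along-axis and across-axis orientations are in the sampled set
    @pytest.mark.parametrize("radius", [20.0, 28.0, 32.0, 40.0, 60.0])
    @pytest.mark.parametrize("axis_deg", [0.0, 30.0, 90.0, 140.0])
    def test_groove_floor_against_analytic_chords(self, radius, axis_deg):
        """At a cylindrical groove floor the directional curvature is 0 along
        the axis, 1000/R across it, and matches the brute-force circumcircle
        through analytically placed chord points to < 1e-6 relative."""
        s = min(30.0, 0.75 * radius)
        phi = math.radians(axis_deg)
        kappas = []
        for theta in direction_angles(18):
            # transverse offset of the chord endpoint on the cylinder
            d_perp = abs(s * math.sin(theta - phi))
            z = radius - math.sqrt(radius**2 - d_perp**2)
            kappa = b.three_point_curvature(0.0, z, z, s)
            kappas.append(kappa)
            if z > 1e-9:
                r_oracle = circumradius_3pt((-s, z), (0.0, 0.0), (s, z))
                assert kappa == pytest.approx(1000.0 / r_oracle, rel=1e-6)
        kappas = np.asarray(kappas)
        along = np.argmin(np.abs((np.degrees(direction_angles(18)) - axis_deg + 90) % 180 - 90))
        assert kappas[along] == pytest.approx(0.0, abs=1e-6)
        assert kappas.max() == pytest.approx(1000.0 / radius, rel=1e-3)
        # strictly monotone in the angular distance to the axis
        ang_dist = np.abs((np.degrees(direction_angles(18)) - axis_deg + 90) % 180 - 90)
        order = np.argsort(ang_dist)
        diffs = np.diff(kappas[order])
        grouped = ang_dist[order]
        same = np.isclose(np.diff(grouped), 0.0)
        assert np.all(diffs[~same] > 0)

    def test_groove_surface_on_grid(self):
        """Grid-rasterized groove (R=32 µm): across-axis curvature ~31.25,
        along-axis ~0 at the floor."""
        hm, info = b.make_surface(
            b.SurfaceSpec(kind="microgroove_array", extent=(200, 200), pixel_size=1.0,
                          radius=32.0, aperture=62.0, pitch=200.0, axis_angle=0.0)
        )
        # grooves run along x (axis_angle 0): floor at y = pitch/2 = 100
        dc = b.directional_curvatures(hm, 100.0, 100.0)
        assert dc.kappas[0] == pytest.approx(0.0, abs=1e-9)  # along axis
        assert dc.kappas[9] == pytest.approx(31.25, rel=1e-6)  # across axis


# ---------------------------------------------------------------------------
# Classification


class TestClassification:
    @pytest.mark.parametrize(
        "mk,expected",
        [
            (0.0, "flat"), (2.4999, "flat"), (-2.4999, "flat"),
            (2.5, "concave"), (-2.5, "convex"),
            (10.0, "concave"), (-10.0, "convex"),
            (float("nan"), "invalid"),
        ],
    )
    def test_motif_boundaries(self, mk, expected):
        assert b.classify_motif(mk, 2.5) == expected

    @given(mk=st.floats(-100, 100))
    @settings(max_examples=100, deadline=None)
    def test_classes_partition_the_line(self, mk):
        assert b.classify_motif(mk, 2.5) in ("convex", "flat", "concave")

    def test_bscr_strict_interior(self):
        positive, count, cat = b.bscr_flags(np.full(18, 15.0))
        assert (positive, count, cat) == (False, 0, "none")
        positive, count, cat = b.bscr_flags(np.full(18, 62.0))
        assert (positive, count, cat) == (False, 0, "none")

    def test_single_direction_in_range(self):
        kappas = np.zeros(18)
        kappas[0] = 20.0
        assert b.bscr_flags(kappas) == (True, 1, "low")

    @pytest.mark.parametrize(
        "count,cat", [(0, "none"), (1, "low"), (6, "low"), (7, "med"),
                      (12, "med"), (13, "hi"), (18, "hi")]
    )
    def test_count_bands(self, count, cat):
        assert bscr_category(count, 18) == cat


# ---------------------------------------------------------------------------
# Whole-map evaluation


class TestMapSurface:
    def test_flat_map_summary(self, flat_map):
        motif, bscr, summary = b.map_surface(flat_map)
        assert summary["frac_flat"] == 1.0
        assert summary["frac_bscr_positive"] == 0.0
        assert summary["count_hist"][0] == summary["n_valid"]
        inner = motif.labels[20:-20, 20:-20]
        assert np.all(inner == MOTIF_FLAT)
        # border margin (half-span 30 µm = 15 px) is invalid
        assert np.all(motif.labels[0:14, :] == MOTIF_INVALID)

    def test_negation_swaps_convex_concave(self, bowl_array_maps):
        hm, motif, bscr, summary = bowl_array_maps
        neg = b.HeightMap(-hm.heights, hm.pixel_size, valid=hm.valid)
        motif_n, _, summary_n = b.map_surface(neg, b.CurvatureParams())
        f, fn = motif.fractions(), motif_n.fractions()
        assert fn["convex"] == f["concave"]
        assert fn["concave"] == f["convex"]
        assert fn["flat"] == f["flat"]

    def test_constant_offset_changes_nothing(self, bowl_array_maps):
        hm, motif, bscr, _ = bowl_array_maps
        shifted = b.HeightMap(hm.heights + 17.3, hm.pixel_size, valid=hm.valid)
        motif2, bscr2, _ = b.map_surface(shifted, b.CurvatureParams())
        assert np.array_equal(motif2.labels, motif.labels)
        assert np.array_equal(bscr2.count, bscr.count)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0.0, 3.0, (120, 120))
        from scipy.ndimage import gaussian_filter

        base = gaussian_filter(base, 4.0)
        hm = b.HeightMap(base, pixel_size=1.0)
        params = b.CurvatureParams()
        motif, bscr, _ = b.map_surface(hm, params)
        shift = 7
        hm_s = b.HeightMap(np.roll(base, shift, axis=1), pixel_size=1.0)
        motif_s, bscr_s, _ = b.map_surface(hm_s, params)
        # columns computable in both frames: margin 30 px on each raster,
        # mapped through the shift (shifted col c holds original col c-shift)
        lo, hi = 30 + shift, 90
        assert np.array_equal(
            motif_s.labels[:, lo:hi], motif.labels[:, lo - shift : hi - shift]
        )
        assert np.array_equal(
            bscr_s.count[:, lo:hi], bscr.count[:, lo - shift : hi - shift]
        )

    def test_partition_and_flag_consistency(self, bowl_array_maps):
        _, motif, bscr, summary = bowl_array_maps
        total = summary["frac_convex"] + summary["frac_flat"] + summary["frac_concave"]
        assert total == pytest.approx(1.0, abs=1e-12)
        valid = bscr.count >= 0
        assert np.array_equal(bscr.positive[valid], bscr.count[valid] >= 1)
        assert (motif.labels != MOTIF_INVALID).sum() == valid.sum()

    def test_matches_pointwise_evaluation(self, bowl_array_maps):
        """The vectorized whole-map path agrees with the per-point API."""
        hm, motif, bscr, _ = bowl_array_maps
        params = b.CurvatureParams()
        rng = np.random.default_rng(0)
        rr, cc = np.nonzero(bscr.count >= 0)
        for i in rng.choice(rr.size, 25, replace=False):
            x, y = cc[i] * hm.pixel_size, rr[i] * hm.pixel_size
            dc = b.directional_curvatures(hm, x, y, params)
            _, count, _ = b.bscr_flags(dc.kappas, params.bscr)
            assert count == bscr.count[rr[i], cc[i]]
            assert b.classify_motif(dc.mean_kappa, params.flat_band) == \
                   {1: "convex", 2: "flat", 3: "concave"}[motif.labels[rr[i], cc[i]]]

    def test_resolution_refinement(self):
        """BSCR+ area fraction of a bowl tiling is stable (within 10%
        relative) under 2x grid refinement."""
        fracs = {}
        for px in (1.0, 0.5):
            hm, _ = b.make_surface(
                b.SurfaceSpec(kind="microbowl_array", extent=(300, 300), pixel_size=px,
                              radius=32.0, aperture=60.0, pitch=100.0)
            )
            _, _, summary = b.map_surface(hm, b.CurvatureParams())
            fracs[px] = summary["frac_bscr_positive"]
        assert abs(fracs[1.0] - fracs[0.5]) / fracs[0.5] < 0.10

    def test_raster_too_small(self):
        with pytest.raises(b.ValidationError):
            b.map_surface(b.HeightMap(np.zeros((20, 20)), 1.0))


class TestRasterIO:
    def test_csv_and_tiff_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        z = rng.uniform(0, 10, (40, 30))
        np.savetxt(tmp_path / "hm.csv", z, delimiter=",")
        hm = read_heightmap(tmp_path / "hm.csv", pixel_size=2.0)
        assert np.allclose(hm.heights, z)
        import tifffile

        tifffile.imwrite(tmp_path / "hm.tif", z.astype(np.float32))
        hm2 = read_heightmap(tmp_path / "hm.tif", pixel_size=2.0, height_scale=0.5)
        assert np.allclose(hm2.heights, 0.5 * z, atol=1e-5)

    def test_map_table(self, bowl_array_maps):
        _, motif, bscr, summary = bowl_array_maps
        table = maps_to_table(motif, bscr)
        assert len(table) == summary["n_valid"]
        assert set(table["bscr_category"]).issubset(set(BSCR_CATEGORIES))
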