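"""LV coordinate frame, wall depth, and compartment/AHA aggregation."""

import math

import numpy as np
import pytest

import ecvatlas as ea
from ecvatlas.geometry import (
    GeometryError,
    MaskWallModel,
    LVGeometry,
    aha_segment_ids,
    sector_index,
)

GEOM = ea.capsule_geometry(70.0, 50.0, 10.0)


class TestWallDepth:
    @pytest.mark.parametrize(
        "point,expected",
        [
            ((15.0, 0.0, 20.0), 0.0),  # endocardial surface, barrel
            ((25.0, 0.0, 20.0), 1.0),  # epicardial surface, barrel
            ((0.0, 20.0, 30.0), 0.5),  # mid-wall, barrel
            ((0.0, 0.0, 65.0), 0.5),  # mid-wall on the axis, apex cap
            ((0.0, 20.0 / math.sqrt(2), 45.0 + 20.0 / math.sqrt(2)), 0.5),  # oblique cap ray
        ],
    )
    def test_analytic_values(self, point, expected):
        assert ea.wall_depth(point, GEOM) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("point", [(5.0, 0.0, 20.0), (30.0, 0.0, 20.0), (20.0, 0.0, -5.0)])
    def test_outside_shell_raises(self, point):
        with pytest.raises(GeometryError):
            ea.wall_depth(point, GEOM)

    def test_mask_derived_depth_matches_analytic(self, coarse_phantom):
        """Depth from distance transforms of the mask agrees with the analytic
        shell to within one voxel spacing of wall depth."""
        _, _, truth = coarse_phantom
        mask = truth["myocardium_mask"]
        geom = truth["geometry"]
        mask_geom = LVGeometry(
            geom.long_axis, geom.base_point, geom.axis_length, geom.anterior,
            MaskWallModel(mask),
        )
        idx = np.argwhere(mask.values > 0)
        pts = mask.world_coordinates(idx)
        _, _, d_analytic, _ = geom.coordinates(pts)
        _, _, d_mask, _ = mask_geom.coordinates(pts)
        # one voxel spacing (0.8 mm) over a 10 mm wall = 0.08 depth units
        assert np.abs(d_analytic - d_mask).max() <= 0.08 + 1e-6


def test_degenerate_axis_rejected():
    with pytest.raises(GeometryError):
        ea.capsule_geometry(20.0, 50.0, 10.0)  # shorter than the apex cap
    with pytest.raises(GeometryError):
        LVGeometry((0, 0, 1), (0, 0, 0), 0.0, (1, 0, 0), GEOM.wall)
    with pytest.raises(GeometryError):
        LVGeometry((0, 0, 1), (0, 0, 0), 70.0, (0, 0, 2), GEOM.wall)  # anterior || axis


def test_anterior_is_orthogonalized():
    g = LVGeometry((0, 0, 1), (0, 0, 0), 70.0, (1, 0, 0.5), GEOM.wall)
    assert abs(np.dot(g.anterior, g.long_axis)) < 1e-12


class TestCompartments:
    def test_uniform_field_means_exact(self, coarse_phantom, coarse_ecv):
        spec, _, truth = coarse_phantom
        grid = ea.build_compartments(coarse_ecv, truth["myocardium_mask"], truth["geometry"])
        assert grid.mean_ecv.shape == (3, 34, 72)
        nonempty = grid.voxel_count > 0
        assert np.allclose(grid.mean_ecv[nonempty], spec.background_ecv, atol=1e-12)
        assert np.isnan(grid.mean_ecv[~nonempty]).all()

    def test_partition_conservation_against_brute_force(self):
        """Independent per-voxel scalar reassignment reproduces every cell count."""
        spec = ea.PhantomSpec(voxel_spacing=(1.6, 1.6, 2.0))
        iodine, truth = ea.generate_phantom(spec)
        ecv = ea.compute_ecv(ea.IodineStudy(iodine, spec.blood_iodine, spec.hematocrit))
        mask = truth["myocardium_mask"]
        grid = ea.build_compartments(ecv, mask, truth["geometry"])

        counts = {}
        n_in_band = 0
        epi, endo, cyl = 25.0, 15.0, 45.0
        xs, ys, zs = mask.axis_coords()
        for i, j, k in np.argwhere(mask.values > 0):
            x, y, z = xs[i], ys[j], zs[k]
            r = math.hypot(x, y)
            if r < max(spec.voxel_spacing):
                continue  # unstable azimuth near the long axis
            s_dist = math.hypot(r, z - cyl) if z > cyl else r
            depth = (s_dist - endo) / (epi - endo)
            if not 0.10 <= depth <= 0.90:
                continue
            n_in_band += 1
            theta = math.atan2(y, x) % (2 * math.pi)
            d = min(int((depth - 0.10) / 0.80 * 3), 2)
            l = min(int(z / 70.0 * 34), 33)
            s = min(int(theta / (2 * math.pi) * 72), 71)
            counts[(d, l, s)] = counts.get((d, l, s), 0) + 1

        assert grid.voxel_count.sum() == n_in_band
        brute = np.zeros((3, 34, 72), int)
        for (d, l, s), c in counts.items():
            brute[d, l, s] = c
        assert np.array_equal(grid.voxel_count, brute)

    def test_count_sum_matches_independent_band_count(self, coarse_phantom, coarse_ecv):
        spec, _, truth = coarse_phantom
        mask, geom = truth["myocardium_mask"], truth["geometry"]
        grid = ea.build_compartments(coarse_ecv, mask, geom)
        idx = np.argwhere(mask.values > 0)
        pts = mask.world_coordinates(idx)
        t, _, depth, r_perp = geom.coordinates(pts)
        in_band = (depth >= 0.10) & (depth <= 0.90) & (r_perp >= max(spec.voxel_spacing))
        assert grid.voxel_count.sum() == int(in_band.sum())
        assert grid.mean_ecv.size == 7344

    def test_empty_mask_rejected(self, coarse_ecv):
        empty = ea.VoxelVolume(np.zeros(coarse_ecv.shape, np.uint8), coarse_ecv.spacing,
                               coarse_ecv.origin)
        with pytest.raises(GeometryError):
            ea.build_compartments(coarse_ecv, empty, GEOM)

    def test_grid_mismatch_rejected(self, coarse_phantom, coarse_ecv):
        _, _, truth = coarse_phantom
        bad = ea.VoxelVolume(np.ones((4, 4, 4), np.uint8), (1, 1, 1))
        with pytest.raises(GeometryError):
            ea.build_compartments(coarse_ecv, bad, truth["geometry"])

    def test_subendocardial_lesion_lands_in_predicted_cells(self, study_factory):
        """A 20-degree x 10 mm lesion confined to the inner wall elevates only
        subendocardial-depth cells at the predicted layer/sector indices."""
        _, ecv, truth = study_factory(
            lesions=[
                dict(center=(0.0, 20.0, 35.0), angular_extent=20.0,
                     longitudinal_extent=10.0, transmural_range=(0.10, 0.33),
                     lesion_ecv=0.55)
            ]
        )
        grid = ea.build_compartments(ecv, truth["myocardium_mask"], truth["geometry"])
        with np.errstate(invalid="ignore"):
            supra = grid.mean_ecv > 0.40
        assert supra[0].any()
        assert not supra[1].any() and not supra[2].any()
        layers, sectors = np.nonzero(supra[0])
        # axial span [30, 40] mm -> layers 15..20 (1-based); azimuth 90 +/- 10
        # degrees -> sectors 17..20 (1-based)
        assert set(layers + 1) <= set(range(15, 21))
        assert set(sectors + 1) <= set(range(17, 21))

    def test_sector_assignment_rotation_equivariant(self):
        """Rotating points about the long axis by k*5 degrees shifts their
        sector index by exactly k (mod 72)."""
        rng = np.random.default_rng(5)
        n = 500
        r = rng.uniform(16, 24, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        # keep azimuths away from sector boundaries
        phi = (np.floor(phi / np.deg2rad(5)) + 0.5) * np.deg2rad(5)
        z = rng.uniform(5, 40, n)
        pts = np.c_[r * np.cos(phi), r * np.sin(phi), z]
        _, theta0, _, _ = GEOM.coordinates(pts)
        s0 = sector_index(theta0)
        for k in (1, 7, 35):
            a = np.deg2rad(5.0 * k)
            rot = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
            _, theta, _, _ = GEOM.coordinates(pts @ rot.T)
            assert np.array_equal(sector_index(theta), (s0 + k) % 72)


class TestAHA16:
    def test_uniform_field(self, coarse_phantom, coarse_ecv):
        spec, _, truth = coarse_phantom
        aha = ea.aha16_aggregate(coarse_ecv, truth["myocardium_mask"], truth["geometry"])
        assert aha.mean_ecv.shape == (16, 2)
        assert np.allclose(aha.mean_ecv, spec.background_ecv, atol=1e-12)
        assert (aha.voxel_count > 0).all()

    def test_band_totals_match_direct_depth_count(self, coarse_phantom, coarse_ecv):
        spec, _, truth = coarse_phantom
        mask, geom = truth["myocardium_mask"], truth["geometry"]
        aha = ea.aha16_aggregate(coarse_ecv, mask, geom)
        idx = np.argwhere(mask.values > 0)
        pts = mask.world_coordinates(idx)
        _, _, depth, r_perp = geom.coordinates(pts)
        ok = r_perp >= max(spec.voxel_spacing)
        n_endo = int(((depth >= 0.10) & (depth < 0.50) & ok).sum())
        n_epi = int(((depth >= 0.50) & (depth <= 0.90) & ok).sum())
        assert aha.voxel_count[:, 0].sum() == n_endo
        assert aha.voxel_count[:, 1].sum() == n_epi

    def test_basal_anterior_lesion_localizes_to_segment_1(self, study_factory):
        spec, ecv, truth = study_factory(
            lesions=[
                dict(center=(20.0, 0.0, 11.0), angular_extent=40.0,
                     longitudinal_extent=18.0, lesion_ecv=0.60)
            ]
        )
        aha = ea.aha16_aggregate(ecv, truth["myocardium_mask"], truth["geometry"])
        assert aha.value(1, "subendo") > 0.40
        assert aha.value(1, "subepi") > 0.40
        for seg in (3, 4, 5, 9, 10, 11, 15):  # segments away from the lesion
            assert aha.value(seg, "subendo") == pytest.approx(spec.background_ecv, abs=1e-9)

    def test_aha_segment_numbering_layout(self):
        """Ring and sector layout of the standard 16-segment scheme."""
        t = np.array([5.0, 5.0, 30.0, 60.0, 60.0])
        theta = np.deg2rad([0.0, 70.0, 180.0, 0.0, 180.0])
        assert aha_segment_ids(t, theta, 70.0).tolist() == [1, 2, 10, 13, 15]

    def test_refinement_consistency_with_compartments(self, study_factory):
        """AHA16 band means equal the count-weighted means of matched-band
        atlas compartments when layers/sectors align with segment borders."""
        _, ecv, truth = study_factory(
            lesions=[
                dict(center=(17, 36), angular_extent=35.0, longitudinal_extent=20.0,
                     lesion_ecv=0.55)
            ]
        )
        mask, geom = truth["myocardium_mask"], truth["geometry"]
        aha = ea.aha16_aggregate(ecv, mask, geom)
        grid = ea.build_compartments(ecv, mask, geom, n_layers=33, depth_bands=2)

        ring_of_layer = np.repeat([0, 1, 2], 11)
        centers = (np.arange(72) + 0.5) * 5.0
        six = np.floor(((centers + 30.0) % 360.0) / 60.0).astype(int)
        four = np.floor(((centers + 45.0) % 360.0) / 90.0).astype(int)
        for seg in range(1, 17):
            if seg <= 6:
                ring, sectors = 0, np.flatnonzero(six == seg - 1)
            elif seg <= 12:
                ring, sectors = 1, np.flatnonzero(six == seg - 7)
            else:
                ring, sectors = 2, np.flatnonzero(four == seg - 13)
            layers = np.flatnonzero(ring_of_layer == ring)
            for band in range(2):
                cells_mean = grid.mean_ecv[band][np.ix_(layers, sectors)]
                cells_count = grid.voxel_count[band][np.ix_(layers, sectors)]
                total = cells_count.sum()
                assert total == aha.voxel_count[seg - 1, band]
                weighted = np.nansum(cells_mean * cells_count) / total
                assert weighted == pytest.approx(aha.mean_ecv[seg - 1, band], rel=1e-9)


def test_atlas_cell_surface_span_defaults():
    longitudinal, circumferential = ea.atlas_cell_surface_span(70.0, 50.0)
    assert longitudinal == pytest.approx(70.0 / 34.0)
    assert circumferential == pytest.approx(np.pi * 50.0 / 72.0)


def test_compartment_csv_layout(tmp_path, coarse_phantom, coarse_ecv):
    _, _, truth = coarse_phantom
    grid = ea.build_compartments(coarse_ecv, truth["myocardium_mask"], truth["geometry"])
    out = tmp_path / "compartments.csv"
    grid.to_csv(out)
    raw = out.read_bytes()
    assert raw.count(b"\r\n") == 7345  # header + 7344 cells, RFC-4180 endings
    header = raw.split(b"\r\n", 1)[0].decode()
    assert header == "depth_layer,layer,sector,mean_ecv_percent,voxel_count"
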