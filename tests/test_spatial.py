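"""Zone partitioning, clustering, band densities, heatmaps and summaries."""
import numpy as np
import pandas as pd
import pytest

import ledscan as ls
from ledscan.chromatin import LABEL_EUCHROMATIN, ChromatinMap
from ledscan.errors import ValidationError
from ledscan.records import ParticleRecord
from ledscan.spatial import (
    ZONE_BORDER,
    ZONE_INSIDE,
    ZONE_OUTSIDE,
    ClusterAssignment,
    SpatialTable,
    brute_force_clusters,
    cluster_category,
    cluster_zone_percentages,
    find_clusters,
    summarize_sections,
)

from conftest import square_ledd_region


def _records(xy):
    return [
        ParticleRecord(i, (float(x), float(y)), 6.0, 0.9, 0.1, "6nm")
        for i, (x, y) in enumerate(xy)
    ]


def _flat_cmap(shape, scale=1.0):
    return ChromatinMap(
        labels=np.full(shape, LABEL_EUCHROMATIN, dtype=np.uint8),
        thresholds_used=(0.4, 0.7), smoothing_scale_nm=30.0, scale_nm_per_px=scale,
    )


class TestBuildPartition:
    def test_square_ledd_zone_areas_match_minkowski(self):
        """Inside/border areas of a square LEDD match the analytic dilation/erosion."""
        shape = (1024, 1024)
        side, h = 400, 100.0
        region = square_ledd_region(shape, 312, 312, side)
        part = ls.build_partition([region], shape, 1.0, border_halfwidth_nm=h)
        inside = (part.zone_labels == ZONE_INSIDE).sum()
        border = (part.zone_labels == ZONE_BORDER).sum()
        inside_analytic = (side - 2 * h) ** 2
        dilated = (side + 2 * h) ** 2 - (4 - np.pi) * h**2
        border_analytic = dilated - inside_analytic
        assert inside == pytest.approx(inside_analytic, rel=0.02)
        assert border == pytest.approx(border_analytic, rel=0.02)

    def test_zero_ledds_all_outside_flagged(self):
        part = ls.build_partition([], (64, 64), 1.0)
        assert part.no_ledds
        assert (part.zone_labels == ZONE_OUTSIDE).all()
        assert np.isinf(part.signed_distance_nm).all()
        with pytest.raises(ValidationError):
            ls.band_density_profile(pd.DataFrame(), part)

    def test_border_closed_at_exact_halfwidth(self):
        """A pixel exactly 300 nm from the boundary lies in the border zone."""
        shape = (32, 32)
        region = square_ledd_region(shape, 0, 0, 16, scale=100.0)
        part = ls.build_partition([region], shape, 100.0, border_halfwidth_nm=300.0)
        # column 18 is 3 px = 300 nm beyond the last LEDD column (15)
        assert part.signed_distance_nm[8, 18] == pytest.approx(300.0)
        assert part.zone_labels[8, 18] == ZONE_BORDER
        assert part.zone_labels[8, 19] == ZONE_OUTSIDE

    def test_zone_area_conservation(self, default_scene):
        img, _ = default_scene
        cmap = ls.classify_chromatin(img)
        ledds = ls.segment_ledds(cmap, img)
        part = ls.build_partition(ledds, img.shape, 1.0,
                                  analysis_mask=img.analysis_mask())
        n_zone = sum(
            (part.zone_labels == z).sum() for z in (ZONE_INSIDE, ZONE_BORDER, ZONE_OUTSIDE)
        )
        assert n_zone == img.analysis_mask().sum()

    def test_signed_distance_matches_brute_force(self):
        """EDT field equals the O(N·M) nearest-boundary-pixel scan within 1 px."""
        rng = np.random.default_rng(5)
        shape = (128, 128)
        mask = np.zeros(shape, dtype=bool)
        yy, xx = np.mgrid[0:128, 0:128]
        for _ in range(3):
            r0, c0 = rng.integers(20, 108, 2)
            rad = rng.integers(8, 20)
            mask |= np.hypot(yy - r0, xx - c0) <= rad
        region = ls.LEDDRegion(0, np.array([[0.0, 0.0]]), mask.sum() * 1e-6,
                               (0.0, 0.0), mask=mask)
        part = ls.build_partition([region], shape, 1.0)
        inside_px = np.argwhere(mask)
        outside_px = np.argwhere(~mask)
        # brute force: for each pixel, min distance to any opposite-phase pixel
        for pts, pool in ((inside_px[::13], outside_px), (outside_px[::37], inside_px)):
            for r, c in pts:
                d = np.hypot(pool[:, 0] - r, pool[:, 1] - c).min()
                assert abs(abs(part.signed_distance_nm[r, c]) - d) <= 1.0


class TestAssignParticles:
    @pytest.fixture()
    def geometry(self):
        shape = (1200, 1200)
        region = square_ledd_region(shape, 200, 200, 800)
        part = ls.build_partition([region], shape, 1.0)
        return shape, region, part

    def test_center_particle_inside(self, geometry):
        shape, region, part = geometry
        df = ls.assign_particles(_records([(600, 600)]), part, _flat_cmap(shape))
        assert df.iloc[0].zone == "inside"
        assert df.iloc[0].band == ""

    def test_150nm_outside_is_border_and_second_band(self, geometry):
        """150 nm beyond the boundary: border zone, 101-200 nm band."""
        shape, region, part = geometry
        df = ls.assign_particles(_records([(600, 1149.2)]), part, _flat_cmap(shape))
        assert df.iloc[0].zone == "border"
        assert df.iloc[0].band == "101-200 nm"

    def test_row_order_invariant_to_particle_order(self, geometry):
        shape, _, part = geometry
        xy = [(600, 600), (30, 30), (600, 1149), (1100, 80)]
        recs = _records(xy)
        rng = np.random.default_rng(3)
        shuffled = [recs[i] for i in rng.permutation(len(recs))]
        a = ls.assign_particles(recs, part, _flat_cmap(shape))
        b = ls.assign_particles(shuffled, part, _flat_cmap(shape))
        pd.testing.assert_frame_equal(a, b)

    def test_every_particle_exactly_one_row(self, geometry):
        shape, _, part = geometry
        recs = _records([(i * 37 % 1100 + 10, i * 53 % 1100 + 10) for i in range(40)])
        df = ls.assign_particles(recs, part, _flat_cmap(shape))
        assert sorted(df["id"]) == list(range(40))


class TestFindClusters:
    def test_empty_input(self):
        assert find_clusters([]) == []

    def test_pair_plus_singleton(self):
        """Two beads 30 nm apart and one 200 nm away: clusters of size 2 and 1."""
        clusters = find_clusters(_records([(0, 0), (30, 0), (230, 0)]), linkage_nm=50)
        sizes = sorted(c.size for c in clusters)
        assert sizes == [1, 2]
        assert all(c.category == "1-2" for c in clusters)

    def test_nonpositive_linkage_rejected(self):
        with pytest.raises(ValidationError):
            find_clusters(_records([(0, 0)]), linkage_nm=0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_transitive_closure(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 150))
        xy = rng.uniform(0, 800, size=(n, 2))
        clusters = find_clusters(_records(xy), linkage_nm=50.0)
        expected = brute_force_clusters(xy, 50.0)
        got = sorted(tuple(c.member_ids) for c in clusters)
        assert got == expected
        # clusters partition the particle set
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == list(range(n))

    def test_cluster_ids_deterministic_minimum_member(self):
        clusters = find_clusters(_records([(100, 100), (110, 100), (0, 0)]))
        by_size = {c.size: c for c in clusters}
        assert by_size[2].cluster_id == 0  # min member id
        assert by_size[1].cluster_id == 2

    def test_category_bins(self):
        assert [cluster_category(s) for s in (1, 2, 3, 4, 5, 9)] == [
            "1-2", "1-2", "3-4", "3-4", ">4", ">4"
        ]


class TestZonePercentages:
    def _cluster(self, size, zone, cid=0):
        return ClusterAssignment(cid, tuple(range(size)), size,
                                 cluster_category(size), (0.0, 0.0), zone=zone)

    def test_all_inside(self):
        out = cluster_zone_percentages([self._cluster(3, "inside")])
        assert (out["inside"], out["border"], out["outside"]) == (100.0, 0.0, 0.0)

    def test_mixed_percentages(self):
        clusters = (
            [self._cluster(3, "inside", i) for i in range(2)]
            + [self._cluster(4, "border", 10 + i) for i in range(2)]
            + [self._cluster(5, "outside", 20 + i) for i in range(4)]
        )
        out = cluster_zone_percentages(clusters)
        assert (out["inside"], out["border"], out["outside"]) == (25.0, 25.0, 50.0)
        assert out["inside"] + out["border"] + out["outside"] == pytest.approx(100.0, abs=1e-6)

    def test_small_clusters_do_not_qualify(self):
        out = cluster_zone_percentages([self._cluster(2, "inside")])
        assert out["empty"] and out["n_clusters"] == 0

    def test_empty_flagged_zeros(self):
        out = cluster_zone_percentages([])
        assert out["empty"]
        assert out["inside"] == out["border"] == out["outside"] == 0.0


class TestBandDensities:
    def test_no_particles_zero_density_nonzero_area(self):
        shape = (1200, 1200)
        part = ls.build_partition([square_ledd_region(shape, 200, 200, 400)], shape, 1.0)
        prof = ls.band_density_profile(
            pd.DataFrame(columns=["signed_distance_nm"]), part
        )
        assert (prof["count"] == 0).all()
        assert (prof["area_um2"] > 0).all()
        assert (prof["density_per_um2"] == 0).all()

    def test_uniform_placement_is_flat_within_poisson_error(self):
        shape = (1400, 1400)
        part = ls.build_partition([square_ledd_region(shape, 500, 500, 400)], shape, 1.0)
        rng = np.random.default_rng(11)
        sd = part.signed_distance_nm
        valid = (sd > 0) & (sd <= 400)
        pts = np.argwhere(valid)
        sel = pts[rng.choice(len(pts), 4000, replace=False)]
        df = pd.DataFrame({"signed_distance_nm": sd[sel[:, 0], sel[:, 1]]})
        prof = ls.band_density_profile(df, part)
        dens = prof["density_per_um2"].to_numpy()
        # all bands share one uniform density; 3 SE Poisson tolerance per band
        pooled = 4000 / prof["area_um2"].sum()
        for cnt, area in zip(prof["count"], prof["area_um2"]):
            se = np.sqrt(pooled / area)
            assert abs(cnt / area - pooled) <= 3 * se


class TestDensityHeatmap:
    def test_single_particle_peak_at_its_cell(self):
        recs = _records([(520, 730)])
        dm = ls.density_heatmap(recs, (1000, 1000), 1.0, grid_nm=100.0)
        iy, ix = np.unravel_index(np.argmax(dm.values), dm.values.shape)
        assert (iy, ix) == (7, 5)

    def test_two_distant_particles_equal_modes(self):
        recs = _records([(200, 200), (800, 800)])
        dm = ls.density_heatmap(recs, (1000, 1000), 1.0, grid_nm=100.0,
                                kernel_bandwidth_nm=100.0)
        v = dm.values
        assert v[2, 2] == pytest.approx(v[8, 8], rel=1e-9)

    def test_integral_equals_particle_count(self):
        rng = np.random.default_rng(2)
        recs = _records(rng.uniform(0, 999, size=(500, 2)))
        dm = ls.density_heatmap(recs, (1000, 1000), 1.0)
        assert dm.integral() == pytest.approx(500, rel=0.01)


class TestSummaries:
    def _table(self, n_particles, condition="hi", time_point="0.5h"):
        df = pd.DataFrame({
            "id": range(n_particles),
            "x_nm": np.zeros(n_particles),
            "y_nm": np.zeros(n_particles),
            "size_class": ["6nm"] * n_particles,
            "zone": ["outside"] * n_particles,
            "band": [""] * n_particles,
            "chromatin": ["euchromatin"] * n_particles,
            "signed_distance_nm": np.full(n_particles, 500.0),
        })
        return SpatialTable(
            particles=df, clusters=[], zone_percentages=cluster_zone_percentages([]),
            band_profile=None, condition=condition, time_point=time_point,
        )

    def test_hand_computed_mean_and_se(self):
        out = summarize_sections([self._table(10), self._table(20), self._table(30)])
        row = out[(out.metric == "n_particles")].iloc[0]
        assert row["mean"] == pytest.approx(20.0)
        assert row["se"] == pytest.approx(5.7735, abs=1e-3)
        assert row["n_sections"] == 3

    def test_identical_sections_zero_se(self):
        out = summarize_sections([self._table(7), self._table(7)])
        row = out[(out.metric == "n_particles")].iloc[0]
        assert row["se"] == 0.0

    def test_groups_kept_separate(self):
        out = summarize_sections([
            self._table(5, time_point="0.5h"), self._table(9, time_point="5h"),
        ])
        means = out[out.metric == "n_particles"].set_index("time_point")["mean"]
        assert means["0.5h"] == 5 and means["5h"] == 9
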