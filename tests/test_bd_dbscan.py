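import numpy as np
import pytest
from shapely.geometry import Polygon, box

from dermoseg import bd_dbscan as bdd
from dermoseg.synthetic import CloudSpec, make_point_cloud


def block(ox, oy, w, h):
    return [(ox + x, oy + y) for x in range(w) for y in range(h)]


def core_partition(ps, labels, R, MP):
    """Partition of core points as frozenset of frozensets (label-free)."""
    cores = [
        i
        for i in range(len(ps))
        if len(ps.query_indices(ps.points[i], R)) >= MP
    ]
    groups = {}
    for i in cores:
        groups.setdefault(labels[i], set()).add(tuple(ps.points[i]))
    return frozenset(frozenset(g) for g in groups.values())


class TestRegionQuery:
    def setup_method(self):
        self.grid = bdd.PointSet([(x, y) for x in (-1, 0, 1) for y in (-1, 0, 1)])

    def test_unit_radius_cross_neighborhood(self):
        pts = bdd.region_query(self.grid, (0, 0), 1.0)
        assert len(pts) == 5  # center + 4-neighbors, diagonals at sqrt(2) excluded
        assert (np.abs(pts).sum(axis=1) <= 1).all()

    def test_radius_1_5_includes_diagonals(self):
        assert len(bdd.region_query(self.grid, (0, 0), 1.5)) == 9

    def test_isolated_point_returns_itself(self):
        ps = bdd.PointSet([(5, 5)])
        np.testing.assert_array_equal(bdd.region_query(ps, (5, 5), 10.0), [[5, 5]])

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            bdd.region_query(self.grid, (0, 0), 0.0)

    def test_result_lex_ordered_by_y_then_x(self):
        pts = bdd.region_query(self.grid, (0, 0), 5.0)
        order = np.lexsort((pts[:, 0], pts[:, 1]))
        np.testing.assert_array_equal(order, np.arange(len(pts)))

    def test_matches_linear_scan(self, rng):
        pts = rng.integers(0, 40, size=(300, 2))
        ps = bdd.PointSet(pts)
        for _ in range(20):
            q = rng.integers(-5, 45, size=2)
            R = float(rng.choice([1, 2, 3.5, 5]))
            got = bdd.region_query(ps, q, R)
            d2 = ((ps.points - q) ** 2).sum(axis=1)
            expected = ps.points[d2 <= R * R]
            np.testing.assert_array_equal(got, expected)


class TestPrimitiveCluster:
    def test_hull_contains_all_points(self, rng):
        pts = rng.integers(0, 30, size=(10, 2))
        c = bdd.init_primitive_cluster(pts, mp=10)
        assert c is not None
        for p in pts:
            assert c.covers_point(p)

    def test_below_mp_rejected(self, rng):
        assert bdd.init_primitive_cluster(rng.integers(0, 9, (5, 2)), mp=60) is None

    def test_collinear_points_keep_zero_area_hull(self):
        c = bdd.init_primitive_cluster(np.array([(0, 0), (2, 2), (4, 4)]), mp=3)
        assert c is not None
        assert c.area == 0.0
        assert c.boundary_distance((2, 2)) == 0.0  # every point is boundary

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bdd.init_primitive_cluster(np.empty((0, 2)), mp=1)


class TestLeadingPoints:
    def test_deep_interior_point_skipped(self):
        c = bdd.ClusterBoundary(box(0, 0, 20, 20))
        assert bdd.select_leading_points(c, [(10, 10)], R=5.0) == []

    def test_near_boundary_point_leading(self):
        c = bdd.ClusterBoundary(box(0, 0, 20, 20))
        [p] = bdd.select_leading_points(c, [(2, 10)], R=5.0)
        np.testing.assert_array_equal(p, (2, 10))

    def test_point_on_boundary_leading(self):
        c = bdd.ClusterBoundary(box(0, 0, 20, 20))
        assert len(bdd.select_leading_points(c, [(0, 10)], R=5.0)) == 1

    def test_point_near_hole_boundary_leading(self):
        holey = Polygon(box(0, 0, 30, 30).exterior, [box(12, 12, 18, 18).exterior.coords])
        c = bdd.ClusterBoundary(holey)
        # (10, 15) is 2 from the hole wall: its query could fill the hole
        assert len(bdd.select_leading_points(c, [(10, 15)], R=5.0)) == 1
        # (6, 6) is 6 from both outer and hole boundary
        assert bdd.select_leading_points(c, [(6, 6)], R=5.0) == []


class TestMergeHull:
    def test_hole_absorbed_by_covering_hull(self):
        holey = Polygon(box(0, 0, 10, 10).exterior, [box(4, 4, 6, 6).exterior.coords])
        c = bdd.ClusterBoundary(holey)
        merged = bdd.merge_hull(c, box(3, 3, 7, 7))
        assert merged.holes == []
        assert merged.area == pytest.approx(100.0)

    def test_contained_hull_is_absorbing(self):
        c = bdd.ClusterBoundary(box(0, 0, 10, 10))
        merged = bdd.merge_hull(c, box(2, 2, 5, 5))
        assert merged.area == pytest.approx(100.0)
        assert merged.geom.equals(c.geom)

    def test_rectangle_union_extends_outer(self):
        c = bdd.ClusterBoundary(box(0, 0, 10, 4))
        merged = bdd.merge_hull(c, box(8, 0, 18, 4))
        assert merged.geom.equals(box(0, 0, 18, 4))

    def test_encircling_union_creates_hole(self):
        # four slabs forming a picture frame around an uncovered center
        c = bdd.ClusterBoundary(box(0, 0, 30, 5))
        for piece in [box(25, 0, 30, 30), box(0, 25, 30, 30), box(0, 0, 5, 30)]:
            c = bdd.merge_hull(c, piece)
        assert len(c.holes) == 1
        assert not c.covers_point((15, 15))

    def test_area_monotone_over_random_merges(self, rng):
        c = bdd.ClusterBoundary(box(0, 0, 4, 4))
        area = c.area
        for _ in range(30):
            x, y = rng.uniform(0, 40, size=2)
            c = bdd.merge_hull(c, box(x, y, x + rng.uniform(1, 8), y + rng.uniform(1, 8)))
            assert c.area >= area - 1e-9
            area = c.area

    def test_point_array_coerced_to_hull(self):
        c = bdd.ClusterBoundary(box(0, 0, 4, 4))
        merged = bdd.merge_hull(c, np.array([(3, 0), (8, 0), (8, 4), (3, 4)]))
        assert merged.area == pytest.approx(32.0)


class TestRunBdDbscan:
    def test_two_blocks_two_clusters(self):
        ps = bdd.PointSet(block(0, 0, 5, 5) + block(25, 0, 5, 5))
        params = bdd.DBSCANParams(R=3, MP=10)
        res = bdd.run_bd_dbscan(ps, params, check_pruning=True)
        oracle = bdd.run_dbscan_oracle(ps, params)
        assert res.n_clusters == 2
        np.testing.assert_array_equal(np.sort(res.cluster_sizes()), [25, 25])
        assert (res.labels != bdd.NOISE).all()
        np.testing.assert_array_equal(res.labels, oracle.labels)

    def test_isolated_point_is_noise(self):
        ps = bdd.PointSet([(0, 0), (50, 50)])
        res = bdd.run_bd_dbscan(ps, bdd.DBSCANParams(R=3, MP=2))
        assert (res.labels == bdd.NOISE).all()

    def test_solid_block_single_cluster_with_query_savings(self):
        ps = bdd.PointSet(block(0, 0, 40, 40))
        params = bdd.DBSCANParams(R=5, MP=60)
        res = bdd.run_bd_dbscan(ps, params, check_pruning=True)
        oracle = bdd.run_dbscan_oracle(ps, params)
        assert res.n_clusters == 1
        assert res.cluster_sizes()[0] == 1600
        assert res.queries_fired < 1600
        assert oracle.queries_fired == 1600
        np.testing.assert_array_equal(res.labels, oracle.labels)

    def test_empty_point_set(self):
        res = bdd.run_bd_dbscan(bdd.PointSet([]), bdd.DBSCANParams(R=2, MP=4))
        assert len(res.labels) == 0 and res.n_clusters == 0

    def test_mutual_neighborhood_single_cluster(self):
        ps = bdd.PointSet([(0, 0), (1, 0), (0, 1), (1, 1)])
        res = bdd.run_bd_dbscan(ps, bdd.DBSCANParams(R=2, MP=4))
        assert res.n_clusters == 1 and (res.labels == 1).all()

    def test_matches_sklearn_core_partition(self, rng):
        """Core-point partition agrees with the independent sklearn DBSCAN."""
        from sklearn.cluster import DBSCAN

        ps, _ = make_point_cloud(
            CloudSpec(
                blobs=((20, 20, 8, 0.9), (60, 50, 10, 0.8)),
                n_noise=60,
                extent=(90, 90),
                seed=5,
            )
        )
        R, MP = 3.0, 10
        res = bdd.run_bd_dbscan(ps, bdd.DBSCANParams(R=R, MP=MP))
        sk = DBSCAN(eps=R, min_samples=MP).fit(ps.points)
        assert core_partition(ps, res.labels, R, MP) == core_partition(
            ps, sk.labels_, R, MP
        )


class TestLabelingToMask:
    def test_largest_cluster_wins(self):
        ps = bdd.PointSet(block(0, 0, 5, 5) + block(30, 0, 6, 4))
        res = bdd.run_bd_dbscan(ps, bdd.DBSCANParams(R=3, MP=10))
        assert sorted(res.cluster_sizes()) == [24, 25]
        mask = bdd.labeling_to_mask(res, ps, nc=40, nr=10)
        assert mask.sum() == 25
        assert mask[:5, :5].all()

    def test_all_noise_empty_mask(self):
        ps = bdd.PointSet([(0, 0), (30, 30)])
        res = bdd.run_bd_dbscan(ps, bdd.DBSCANParams(R=2, MP=5))
        assert bdd.labeling_to_mask(res, ps, nc=40, nr=40).sum() == 0


class TestEstimator:
    def test_sklearn_api_and_agreement(self):
        X = np.array(block(0, 0, 6, 6) + [(40, 40)])
        est = bdd.BoundaryDrivenDBSCAN(radius=2.0, min_points=5)
        labels = est.fit_predict(X)
        assert est.get_params() == {"radius": 2.0, "min_points": 5}
        assert labels.shape == (len(X),)
        assert labels[-1] == -1  # sklearn noise convention
        assert est.n_clusters_ == 1
        assert set(labels[:-1]) == {0}

    def test_set_params_roundtrip(self):
        est = bdd.BoundaryDrivenDBSCAN().set_params(radius=3.0, min_points=4)
        assert est.radius == 3.0 and est.min_points == 4


class TestDonut:
    def test_ring_cluster_boundary_gets_hole(self):
        ps, _ = make_point_cloud(
            CloudSpec(rings=((30, 30, 12, 18),), extent=(60, 60), seed=2)
        )
        res = bdd.run_bd_dbscan(ps, bdd.DBSCANParams(R=2, MP=8), check_pruning=True)
        assert res.n_clusters == 1
        final = res.clusters[0]
        assert len(final.holes) == 1
        assert not final.covers_point((30, 30))
        oracle = bdd.run_dbscan_oracle(ps, bdd.DBSCANParams(R=2, MP=8))
        np.testing.assert_array_equal(res.labels, oracle.labels)
        assert res.queries_fired <= oracle.queries_fired
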