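"""Substrate features: arithmetic examples, oracles, invariances, recovery."""

import numpy as np
import pytest

from eamrisk import (
    EamExport,
    MapPoint,
    extract_features,
    gradient_value,
    late_extent,
    regional_impedance,
    scar_extent,
    vlt_extent,
)
from eamrisk.features import FeatureParams, FeatureVector, _face_clusters
from eamrisk.sphere import FaceValueMap, project_points
from eamrisk.synthetic import (
    Isthmus,
    NoiseSd,
    ScarPatch,
    SubstrateScenario,
    VltPatch,
    generate_map,
    region_center_direction,
)

from conftest import brute_force_components, make_export, random_rotation


def face_map_from(sphere, faces, *, bip=None, uni=None, lat=None, imp=None):
    """Hand-built FaceValueMap for arithmetic examples."""
    faces = np.asarray(faces, dtype=int)
    n = len(faces)
    default = lambda v, fill: np.broadcast_to(
        np.asarray(fill if v is None else v, dtype=float), (n,)
    ).copy()
    return FaceValueMap(
        faces=faces,
        point_index=np.arange(n),
        values={
            "bip_v": default(bip, 3.0),
            "uni_v": default(uni, 10.0),
            "lat": default(lat, 0.0),
            "imp": default(imp, 100.0),
        },
        point_faces=faces.copy(),
    )


class TestGradient:
    def test_two_point_arithmetic(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        res = gradient_value(pos, np.array([0.0, 10.0]), radius=7.0)
        np.testing.assert_allclose(res.per_point, [2.0, 2.0])
        assert res.scalar == pytest.approx(2.0)

    def test_uniform_lat_gives_zero(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(-10, 10, (50, 3))
        res = gradient_value(pos, np.full(50, 42.0), radius=7.0)
        assert np.all(res.per_point == 0)

    def test_coincident_points_skipped(self):
        pos = np.array([[0.0, 0, 0], [0.0, 0, 0], [5.0, 0, 0]])
        res = gradient_value(pos, np.array([0.0, 100.0, 10.0]), radius=7.0)
        assert np.isfinite(res.per_point).all()
        # the coincident pair contributes nothing; each sees only the far point
        assert res.per_point[0] == pytest.approx(abs(0.0 - 10.0) / 5.0)
        assert res.per_point[1] == pytest.approx(abs(100.0 - 10.0) / 5.0)

    def test_matches_quadratic_oracle(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(-20, 20, (200, 3))
        lat = rng.uniform(0, 100, 200)
        radius = 9.0
        res = gradient_value(pos, lat, radius=radius)
        diff = pos[:, None, :] - pos[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        g = np.abs(lat[:, None] - lat[None, :]) / np.where(dist > 0, dist, np.inf)
        g[(dist > radius) | (dist < 0.1)] = 0.0
        np.testing.assert_allclose(res.per_point, g.max(axis=1))

    def test_regional_is_per_region_max(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0], [100.0, 0, 0], [104.0, 0, 0]])
        lat = np.array([0.0, 10.0, 0.0, 40.0])
        regions = np.array([1, 1, 2, 2])
        res = gradient_value(pos, lat, radius=7.0, regions=regions)
        assert res.regional[0] == pytest.approx(2.0)
        assert res.regional[1] == pytest.approx(10.0)
        assert np.isnan(res.regional[2:]).all()


class TestClusteredExtents:
    def test_vlt_zero_when_differences_equal(self, sphere):
        fm = face_map_from(sphere, np.arange(0, 100, 10), bip=3.0, uni=10.0)
        scalar, regional = vlt_extent(fm, sphere)
        assert scalar == 0.0

    def test_vlt_two_adjacent_critical_faces(self, sphere):
        # 10 occupied faces; two edge-adjacent ones carry a high bip-uni difference
        f0 = 60 * sphere.n_lon + 10
        faces = np.array(sorted([f0, f0 + 1, *(3 * sphere.n_lon + 12 * k for k in range(8))]))
        uni = np.where(np.isin(faces, [f0, f0 + 1]), 2.0, 10.0)
        fm = face_map_from(sphere, faces, bip=3.0, uni=uni)
        scalar, _ = vlt_extent(fm, sphere, min_cluster=2, cluster_angle_deg=None)
        assert scalar == pytest.approx(20.0)

    def test_late_extent_range_rule(self, sphere):
        # LAT 0..90 on 10 faces; cut = 72 so two faces are late; adjacent pair
        f0 = 60 * sphere.n_lon + 40
        faces = np.array([f0, f0 + 1, *(10 * sphere.n_lon + 9 * k for k in range(8))])
        order = np.argsort(faces)
        lat = np.array([80.0, 90.0, *np.arange(0.0, 80.0, 10.0)])[order]
        fm = face_map_from(sphere, faces[order], lat=lat)
        scalar, _ = late_extent(fm, sphere, min_cluster=2, cluster_angle_deg=None)
        assert scalar == pytest.approx(100.0 * 2 / 8)

    def test_late_uniform_is_zero(self, sphere):
        fm = face_map_from(sphere, np.arange(0, 50, 5), lat=12.0)
        scalar, _ = late_extent(fm, sphere)
        assert scalar == 0.0

    def test_late_total_denominator(self, sphere):
        f0 = 60 * sphere.n_lon + 40
        faces = np.array([f0, f0 + 1, *(10 * sphere.n_lon + 9 * k for k in range(8))])
        order = np.argsort(faces)
        lat = np.array([80.0, 90.0, *np.arange(0.0, 80.0, 10.0)])[order]
        fm = face_map_from(sphere, faces[order], lat=lat)
        scalar, _ = late_extent(fm, sphere, min_cluster=2, cluster_angle_deg=None,
                                denominator="total")
        assert scalar == pytest.approx(20.0)

    def test_scar_single_face(self, sphere):
        fm = face_map_from(sphere, [10, 5000, 9000], bip=[0.3, 0.6, 1.6])
        scalar, _ = scar_extent(fm, sphere, min_cluster=1)
        assert scalar == pytest.approx(100.0 / 3)

    def test_scar_zero_when_all_above_cutoff(self, sphere):
        fm = face_map_from(sphere, np.arange(0, 40, 4), bip=1.7)
        scalar, _ = scar_extent(fm, sphere)
        assert scalar == 0.0

    def test_undefined_below_two_faces(self, sphere):
        fm = face_map_from(sphere, [7])
        with pytest.warns(UserWarning, match="undefined"):
            scalar, regional = scar_extent(fm, sphere)
        assert np.isnan(scalar) and np.isnan(regional).all()

    def test_cluster_membership_matches_graph_oracle(self, sphere):
        rng = np.random.default_rng(2)
        faces = np.unique(rng.integers(0, sphere.n_faces, 300))
        ours = {frozenset(c) for c in _face_clusters(sphere, faces, angle_deg=8.0)}
        oracle = set(brute_force_components(sphere, faces, angle_deg=8.0))
        assert ours == oracle

    def test_edge_adjacency_clusters_match_oracle(self, small_sphere):
        import networkx as nx

        rng = np.random.default_rng(3)
        faces = np.unique(rng.integers(0, small_sphere.n_faces, 60))
        g = nx.Graph()
        g.add_nodes_from(int(f) for f in faces)
        fs = set(int(f) for f in faces)
        for f in fs:
            for nb in small_sphere.neighbors(f):
                if nb in fs:
                    g.add_edge(f, nb)
        oracle = {frozenset(c) for c in nx.connected_components(g)}
        ours = {frozenset(c) for c in _face_clusters(small_sphere, faces, angle_deg=None)}
        assert ours == oracle


class TestRegionalImpedance:
    def test_uniform_map(self, sphere):
        rng = np.random.default_rng(4)
        faces = np.unique(rng.integers(0, sphere.n_faces, 400))
        fm = face_map_from(sphere, faces, imp=100.0)
        imp = regional_impedance(fm, sphere)
        occupied_regions = np.unique(sphere.region_of_face[faces])
        for r in occupied_regions:
            assert imp[r - 1] == pytest.approx(100.0)

    def test_two_face_mean(self, sphere):
        # two faces in the same octant
        f = int(sphere.face_of_directions(np.array([[1.0, 1.0, 1.0]]))[0])
        fm = face_map_from(sphere, [f, f + 1], imp=[90.0, 110.0])
        imp = regional_impedance(fm, sphere)
        r = sphere.region_of_face[f]
        assert imp[r - 1] == pytest.approx(100.0)

    def test_matches_brute_force_mean(self, sphere):
        rng = np.random.default_rng(5)
        faces = np.unique(rng.integers(0, sphere.n_faces, 500))
        vals = rng.uniform(80, 140, len(faces))
        fm = face_map_from(sphere, faces, imp=vals)
        imp = regional_impedance(fm, sphere)
        regions = sphere.region_of_face[faces]
        for r in range(1, 9):
            m = regions == r
            expected = vals[m].mean() if m.any() else np.nan
            if np.isnan(expected):
                assert np.isnan(imp[r - 1])
            else:
                assert imp[r - 1] == pytest.approx(expected)


class TestExtractFeatures:
    def test_healthy_noise_free_map_is_silent(self, sphere):
        scenario = SubstrateScenario(n_points=600, noise_sd=NoiseSd.zero(), seed=0)
        fv = extract_features(generate_map(scenario), sphere)
        assert fv.gr == 0.0
        assert fv.vlt == 0.0
        assert fv.lat == 0.0
        assert fv.scar == 0.0

    def test_rigid_motion_and_scaling_invariance(self, sphere):
        scenario = SubstrateScenario(
            n_points=500,
            scar_patches=(ScarPatch(2, 18.0, 0.2),),
            vlt_patches=(VltPatch(6, 15.0, 6.0),),
            isthmus=Isthmus(4, 3.0, 60.0),
            seed=11,
        )
        export = generate_map(scenario)
        ref = extract_features(export, sphere).as_array()
        rng = np.random.default_rng(12)
        for _ in range(3):
            R = random_rotation(rng)
            s = rng.uniform(0.5, 2.0)
            pos = export.positions() @ R.T * s + rng.uniform(-50, 50, 3)
            moved = EamExport(
                "M-1",
                [
                    MapPoint(pos[i, 0], pos[i, 1], pos[i, 2], p.alpha, p.beta, p.gamma,
                             p.uni_v, p.bip_v, p.lat, p.imp)
                    for i, p in enumerate(export.points)
                ],
            )
            np.testing.assert_allclose(
                extract_features(moved, sphere).as_array(), ref, atol=1e-6
            )

    def test_scar_cutoff_monotonicity(self, sphere):
        scenario = SubstrateScenario(
            n_points=700, scar_patches=(ScarPatch(3, 25.0, 0.4),), seed=13
        )
        export = generate_map(scenario)
        fm = project_points(export, sphere)
        extents = [
            scar_extent(fm, sphere, threshold=t, min_cluster=1)[0]
            for t in (0.2, 0.5, 1.0, 2.0)
        ]
        assert extents == sorted(extents)

    def test_min_cluster_monotonicity(self, sphere):
        scenario = SubstrateScenario(
            n_points=700, scar_patches=(ScarPatch(3, 25.0, 0.2),), seed=14
        )
        fm = project_points(generate_map(scenario), sphere)
        extents = [scar_extent(fm, sphere, min_cluster=k)[0] for k in (1, 3, 10, 50)]
        assert extents == sorted(extents, reverse=True)

    def test_extents_bounded(self, sphere):
        rng = np.random.default_rng(15)
        export = make_export(rng, n=400)
        fm = project_points(export, sphere)
        for scalar, regional in (
            vlt_extent(fm, sphere),
            scar_extent(fm, sphere),
            late_extent(fm, sphere, denominator="total"),
        ):
            assert 0.0 <= scalar <= 100.0
            ok = ~np.isnan(regional)
            assert np.all(regional[ok] >= 0.0) and np.all(regional[ok] <= 100.0)

    def test_feature_vector_column_order_stable(self):
        cols = FeatureVector.columns()
        assert cols[:4] == ["GR", "VLT", "LAT", "ScarAreas"]
        assert len(cols) == 4 + 5 * 8
        assert cols[-1] == "IMP8"
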