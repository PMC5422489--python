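import numpy as np
import pytest

from ssamfe._proximity import Surface
from ssamfe.mesh import TetMesh, element_volumes, surface_facets
from ssamfe.reference_data import (EXPERIMENTAL_STRENGTH, paired_strengths)
from ssamfe.validate import (DICCloud, icp_register, neck_volume_diff,
                             pair_strains, robust_regression, shape_error,
                             slab_volume, strength_error_metrics)

from conftest import structured_box


def _rot(axis, deg):
    axis = np.asarray(axis, float)
    axis /= np.linalg.norm(axis)
    a = np.deg2rad(deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


@pytest.fixture(scope="module")
def femur_surface(femur_member):
    mesh, _ = femur_member
    return Surface.from_tetmesh(mesh)


@pytest.fixture(scope="module")
def surface_cloud(femur_member, femur_surface):
    """Points sampled on the femur surface with synthetic strains."""
    mesh, _ = femur_member
    facets, _, _ = surface_facets(mesh)
    rng = np.random.default_rng(8)
    tri = mesh.nodes[facets]
    w = rng.dirichlet(np.ones(3), 4 * len(facets))
    idx = rng.integers(0, len(facets), len(w))
    pts = np.einsum("pk,pki->pi", w, tri[idx])
    major = rng.uniform(100, 2000, len(pts))
    minor = major - rng.uniform(500, 3000, len(pts))
    return DICCloud(pts, major, minor)


class TestICP:
    def test_identity_cloud(self, surface_cloud, femur_surface):
        res = icp_register(surface_cloud, femur_surface)
        assert res.residuals[-1] < 1e-6
        assert res.rotation == pytest.approx(np.eye(3), abs=1e-4)

    def test_known_transform_recovered(self, surface_cloud, femur_surface):
        r = _rot([0.3, 1.0, 0.2], 10.0)
        t = np.array([5.0, 3.0, -2.0])
        moved = DICCloud(surface_cloud.points @ r.T + t,
                         surface_cloud.major, surface_cloud.minor)
        res = icp_register(moved, femur_surface)
        recovered = res.rotation @ r
        angle = np.rad2deg(
            np.arccos(np.clip((np.trace(recovered) - 1) / 2, -1, 1))
        )
        assert angle < 0.1
        back = res.points
        assert np.abs(back - surface_cloud.points).max() < 0.05

    def test_outliers_handled_by_trimming(self, surface_cloud, femur_surface):
        rng = np.random.default_rng(12)
        pts = surface_cloud.points.copy()
        n_out = max(1, len(pts) // 100)  # 1 % gross outliers
        out_idx = rng.choice(len(pts), n_out, replace=False)
        pts[out_idx] += rng.normal(0, 30, (n_out, 3))
        r = _rot([0, 0, 1.0], 5.0)
        moved = DICCloud(pts @ r.T, surface_cloud.major, surface_cloud.minor)
        res = icp_register(moved, femur_surface, trim_fraction=0.95)
        recovered = res.rotation @ r
        angle = np.rad2deg(
            np.arccos(np.clip((np.trace(recovered) - 1) / 2, -1, 1))
        )
        assert angle < 0.5


class TestPairStrains:
    def test_mean_within_sphere(self):
        mesh = TetMesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
            np.array([[0, 1, 2, 3]]),
        )
        cloud = DICCloud(
            np.array([[0.2, 0.2, 0.2], [0.3, 0.2, 0.1], [0.25, 0.25, 0.25]]),
            np.array([100.0, 200.0, 300.0]),
            np.array([-100.0, -200.0, -300.0]),
        )
        ps = np.array([[500.0, 0.0, -700.0]])
        pairs = pair_strains(mesh, np.array([0]), ps, cloud)
        assert pairs["exp_major"] == pytest.approx([200.0])
        assert pairs["exp_minor"] == pytest.approx([-200.0])
        assert pairs["fe_major"] == pytest.approx([500.0])
        assert pairs["fe_minor"] == pytest.approx([-700.0])

    def test_boundary_point_included(self):
        from ssamfe.mesh import circumscribing_sphere

        mesh = TetMesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
            np.array([[0, 1, 2, 3]]),
        )
        sph = circumscribing_sphere(mesh.nodes)
        boundary_pt = sph.center + np.array([sph.radius, 0.0, 0.0])
        cloud = DICCloud(boundary_pt[None], [50.0], [-50.0])
        pairs = pair_strains(mesh, np.array([0]),
                             np.array([[1.0, 0.0, -1.0]]), cloud)
        assert pairs["exp_major"] == pytest.approx([50.0])

    def test_empty_pairing_raises(self):
        mesh = TetMesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
            np.array([[0, 1, 2, 3]]),
        )
        cloud = DICCloud(np.array([[100.0, 100, 100]]), [1.0], [0.0])
        with pytest.raises(ValueError, match="no surface element"):
            pair_strains(mesh, np.array([0]), np.zeros((1, 3)), cloud)

    def test_self_consistency_regression(self, femur_member, femur_surface):
        # cloud fabricated from the FE solution itself: identity regression
        mesh, dens = femur_member
        from ssamfe.fe import stance_strain_case
        from ssamfe.material import density_to_modulus, surface_compensation

        elast = surface_compensation(mesh, density_to_modulus(dens))
        res = stance_strain_case(mesh, elast, 75.0)
        _, surf, _ = surface_facets(mesh)
        from ssamfe.mesh import circumscribing_sphere

        # one cloud point per element, on elements spaced so that each
        # point falls in exactly one pairing sphere: the regression is then
        # an exact identity
        cent = mesh.nodes[mesh.elements].mean(axis=1)
        radii = np.array([
            circumscribing_sphere(mesh.nodes[mesh.elements[e]]).radius
            for e in surf
        ])
        sep = 2.1 * radii.max()
        chosen = []
        for e, c in zip(surf, cent[surf]):
            if all(np.linalg.norm(c - cent[f]) > sep for f in chosen):
                chosen.append(e)
        chosen = np.array(chosen)
        assert len(chosen) >= 10
        ps = res.principal_strains * 1e6
        cloud = DICCloud(cent[chosen], ps[chosen, 0], ps[chosen, 2])
        pairs = pair_strains(mesh, chosen, ps, cloud)
        rep = robust_regression(pairs["exp_major"], pairs["fe_major"])
        assert rep.slope == pytest.approx(1.0, abs=1e-6)
        assert rep.r2 == pytest.approx(1.0, abs=1e-6)


class TestRobustRegression:
    def test_exact_identity(self):
        x = np.linspace(100, 2000, 50)
        rep = robust_regression(x, x)
        assert rep.slope == pytest.approx(1.0, abs=1e-10)
        assert rep.intercept == pytest.approx(0.0, abs=1e-7)
        assert rep.r2 == pytest.approx(1.0, abs=1e-12)
        assert rep.nrmse_pct == pytest.approx(0.0, abs=1e-8)
        assert rep.max_error_pct == pytest.approx(0.0, abs=1e-8)

    def test_exact_affine_line(self):
        x = np.linspace(100, 2000, 50)
        rep = robust_regression(x, 2 * x + 100)
        assert rep.slope == pytest.approx(2.0, abs=1e-8)
        assert rep.intercept == pytest.approx(100.0, abs=1e-5)
        assert rep.r2 == pytest.approx(1.0, abs=1e-12)

    def test_resists_gross_outliers(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(100, 3000, 100)
        y = x.copy()
        y[:5] += rng.uniform(5000, 10000, 5)  # 5 gross outliers
        rep = robust_regression(x, y)
        assert abs(rep.slope - 1.0) < 0.02
        ols = np.polyfit(x, y, 1)[0]
        assert abs(ols - 1.0) > abs(rep.slope - 1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            robust_regression(np.full(10, 5.0), np.arange(10.0))


class TestStrengthErrorMetrics:
    def test_single_prediction_relative_error(self):
        out = strength_error_metrics([13106.0], [13383.0])
        assert out["relative_errors_rounded"][0] == -2

    def test_pooled_see(self):
        pred, exp = paired_strengths("ssam_bmd")
        out = strength_error_metrics(pred, exp)
        assert round(out["see"]) == 2267

    def test_perfect_prediction(self):
        out = strength_error_metrics([1000.0, 2000.0], [1000.0, 2000.0])
        assert out["relative_errors_pct"] == pytest.approx([0.0, 0.0])
        assert out["see"] == 0.0

    def test_zero_experimental_rejected(self):
        with pytest.raises(ValueError):
            strength_error_metrics([1.0], [0.0])


class TestShapeError:
    def test_identical_mesh_zero(self, femur_member, femur_surface):
        mesh, _ = femur_member
        _, _, bnodes = surface_facets(mesh)
        dist, stats = shape_error(mesh.nodes[bnodes], femur_surface)
        assert stats["max"] < 1e-9

    def test_translated_plane(self):
        verts = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [10, 10, 0]])
        surf = Surface(verts, np.array([[0, 1, 2], [1, 3, 2]]))
        pts = np.array([[2.0, 2, 1], [5.0, 5, 1], [8.0, 3, 1]])
        dist, _ = shape_error(pts, surf)
        assert dist == pytest.approx(1.0, abs=1e-12)

    def test_matches_exhaustive_oracle(self, femur_member, femur_surface):
        mesh, _ = femur_member
        rng = np.random.default_rng(23)
        pts = mesh.nodes.mean(axis=0) + rng.normal(0, 25, (40, 3))
        dist, _ = shape_error(pts, femur_surface)
        tri = femur_surface._tri
        from ssamfe._proximity import _closest_on_triangles

        for p, d in zip(pts, dist):
            pp = np.broadcast_to(p, (len(tri), 3))
            cp = _closest_on_triangles(np.ascontiguousarray(pp), tri)
            brute = np.linalg.norm(pp - cp, axis=1).min()
            assert d == pytest.approx(brute, abs=1e-9)


class TestNeckVolume:
    AXIS = (0.0, 0.0, 1.0)

    def test_identical_is_zero(self, femur_member):
        mesh, _ = femur_member
        diff = neck_volume_diff(mesh, mesh, (0, 0, 0), self.AXIS, (20, 50))
        assert diff == pytest.approx(0.0, abs=1e-9)

    def test_uniform_scaling_cubic_law(self):
        # slab containing the whole scaled region: cubic scaling closed form
        mesh = structured_box(3, 3, 3, size=(10, 10, 10))
        center = mesh.nodes.mean(axis=0)
        scaled = TetMesh(center + 1.01 * (mesh.nodes - center),
                         mesh.elements.copy())
        diff = neck_volume_diff(scaled, mesh, center, self.AXIS, (-8.0, 8.0))
        assert diff == pytest.approx((1.01 ** 3 - 1) * 100, abs=1e-6)

    def test_sign_flips_when_swapped(self, femur_member):
        mesh, _ = femur_member
        center = mesh.nodes.mean(axis=0)
        bigger = TetMesh(center + 1.05 * (mesh.nodes - center),
                         mesh.elements.copy())
        d1 = neck_volume_diff(bigger, mesh, (0, 0, 0), self.AXIS, (20, 50))
        d2 = neck_volume_diff(mesh, bigger, (0, 0, 0), self.AXIS, (20, 50))
        assert d1 > 0 > d2

    def test_empty_slab_raises(self, femur_member):
        mesh, _ = femur_member
        with pytest.raises(ValueError, match="empty neck slab"):
            neck_volume_diff(mesh, mesh, (0, 0, 0), self.AXIS, (-500, -400))

    def test_slab_volume_against_monte_carlo(self):
        mesh = structured_box(2, 2, 2, size=(7, 5, 9))
        axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        vol = slab_volume(mesh, (0, 0, 0), axis, 2.0, 8.0)
        rng = np.random.default_rng(31)
        pts = rng.uniform([0, 0, 0], [7, 5, 9], (200000, 3))
        d = pts @ axis
        frac = ((d >= 2.0) & (d <= 8.0)).mean()
        assert vol == pytest.approx(7 * 5 * 9 * frac, rel=0.01)

    def test_total_volume_recovered(self, femur_member):
        mesh, _ = femur_member
        total = slab_volume(mesh, (0, 0, 0), self.AXIS, -1e4, 1e4)
        assert total == pytest.approx(element_volumes(mesh).sum(), rel=1e-9)
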