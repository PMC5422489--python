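import numpy as np
import pytest

from ssamfe.fe import (FEModel, G_ACCEL, MaterialParams, assemble_and_solve,
                       rate_modulus, simulate_strength, stance_strain_case,
                       superior_head_nodes)
from ssamfe.material import ElasticityField, density_to_modulus, \
    surface_compensation
from ssamfe.mesh import surface_facets

from conftest import structured_box, uniform_density


def _bar(nx=2, ny=2, nz=8, length=40.0, a=4.0):
    return structured_box(nx, ny, nz, size=(a, a, length))


def _tributary_loads(mesh, nodes, total_force):
    """Consistent nodal forces for uniform traction on the z-max face."""
    facets, _, _ = surface_facets(mesh)
    zmax = mesh.nodes[:, 2].max()
    top = facets[np.isin(facets, nodes).all(axis=1)]
    tri = mesh.nodes[top]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    w = np.zeros(mesh.n_nodes)
    for t, ar in zip(top, areas):
        w[t] += ar / 3.0
    w /= w.sum()
    return {int(n): np.array([0.0, 0.0, total_force * w[n]]) for n in nodes}


class TestLinearSolve:
    def test_patch_test_affine_displacement(self):
        # affine boundary displacement on a single-material block must give
        # the exact uniform strain field (CST completeness)
        mesh = structured_box(2, 2, 2, size=(2.0, 2.0, 2.0))
        rng = np.random.default_rng(1)
        grad = rng.normal(0, 1e-3, (3, 3))
        _, _, bnodes = surface_facets(mesh)
        prescribed = {int(n): grad @ mesh.nodes[n] for n in bnodes}
        model = FEModel(
            mesh, ElasticityField(np.full(mesh.n_elements, 5000.0), 0.3),
            fixed_nodes=np.array([], dtype=int), prescribed=prescribed,
        )
        res = assemble_and_solve(model)
        sym = 0.5 * (grad + grad.T)
        expected = np.array([sym[0, 0], sym[1, 1], sym[2, 2],
                             2 * sym[0, 1], 2 * sym[1, 2], 2 * sym[0, 2]])
        assert np.abs(res.strain_voigt - expected).max() < 1e-10

    def test_rigid_translation_zero_strain(self):
        mesh = structured_box(2, 2, 2)
        _, _, bnodes = surface_facets(mesh)
        shift = np.array([0.3, -0.2, 0.5])
        model = FEModel(
            mesh, ElasticityField(np.full(mesh.n_elements, 5000.0), 0.3),
            fixed_nodes=np.array([], dtype=int),
            prescribed={int(n): shift for n in bnodes},
        )
        res = assemble_and_solve(model)
        assert np.abs(res.strain_voigt).max() < 1e-12

    def test_axial_bar_closed_form(self):
        mesh = _bar()
        e_mod, length, area, force = 10000.0, 40.0, 16.0, 100.0
        elast = ElasticityField(np.full(mesh.n_elements, e_mod), 0.0)
        bottom = np.flatnonzero(mesh.nodes[:, 2] < 1e-9)
        top = np.flatnonzero(mesh.nodes[:, 2] > length - 1e-9)
        model = FEModel(mesh, elast, bottom,
                        loads=_tributary_loads(mesh, top, force))
        res = assemble_and_solve(model)
        expected = force * length / (e_mod * area)
        assert res.displacements[top, 2] == pytest.approx(expected, rel=1e-8)
        # equilibrium: reactions balance applied load
        assert res.reactions[:, 2].sum() == pytest.approx(-force, rel=1e-8)

    def test_energy_consistency(self):
        mesh = _bar(nz=4)
        elast = ElasticityField(np.full(mesh.n_elements, 8000.0), 0.3)
        bottom = np.flatnonzero(mesh.nodes[:, 2] < 1e-9)
        top = np.flatnonzero(mesh.nodes[:, 2] > 40 - 1e-9)
        loads = _tributary_loads(mesh, top, 50.0)
        model = FEModel(mesh, elast, bottom, loads=loads)
        res = assemble_and_solve(model)
        ext_work = sum(
            0.5 * np.dot(f, res.displacements[n]) for n, f in loads.items()
        )
        from ssamfe.fe import _assemble

        k, _ = _assemble(mesh, elast)
        u = res.displacements.ravel()
        strain_energy = 0.5 * u @ (k @ u)
        assert ext_work == pytest.approx(strain_energy, rel=1e-8)

    def test_underconstrained_raises(self):
        mesh = _bar(nz=2)
        elast = ElasticityField(np.full(mesh.n_elements, 8000.0), 0.3)
        one_node = np.array([0])  # leaves rotational rigid-body modes
        model = FEModel(mesh, elast, one_node,
                        loads={int(mesh.n_nodes - 1): np.array([0, 0, 1.0])})
        with pytest.raises(np.linalg.LinAlgError):
            assemble_and_solve(model)


class TestStanceCase:
    def test_total_applied_force(self, femur_member):
        mesh, dens = femur_member
        elast = surface_compensation(mesh, density_to_modulus(dens))
        head = superior_head_nodes(mesh, 10)
        assert len(head) == 10
        bw = 82.0
        res = stance_strain_case(mesh, elast, bw)
        applied = 4 * bw * G_ACCEL
        assert res.reactions[:, 2].sum() == pytest.approx(applied, rel=1e-8)

    def test_linearity_in_body_weight(self, femur_member):
        mesh, dens = femur_member
        elast = surface_compensation(mesh, density_to_modulus(dens))
        r1 = stance_strain_case(mesh, elast, 40.0)
        r2 = stance_strain_case(mesh, elast, 80.0)
        assert r2.strain_voigt == pytest.approx(2 * r1.strain_voigt, rel=1e-8)

    def test_stance_bending_sign_pattern(self, femur_member):
        # head offset medially (+x): tension on the lateral (-x) shaft
        # surface, compression on the medial (+x) side
        mesh, dens = femur_member
        elast = surface_compensation(mesh, density_to_modulus(dens))
        res = stance_strain_case(mesh, elast, 75.0)
        _, surf, _ = surface_facets(mesh)
        ps = res.principal_strains[surf]
        cent = mesh.nodes[mesh.elements].mean(axis=1)[surf]
        shaft = cent[:, 2] < 0.75 * mesh.nodes[:, 2].max() / 2 + 20
        tens = np.argsort(ps[shaft, 0])[-15:]
        comp = np.argsort(ps[shaft, 2])[:15]
        assert cent[shaft][tens, 0].mean() < 0
        assert cent[shaft][comp, 0].mean() > 0


class TestRateModulus:
    def test_reference_rate_identity(self):
        p = MaterialParams()
        assert rate_modulus(1234.0, p.ref_strain_rate, p) == pytest.approx(
            1234.0
        )

    def test_power_law_decade(self):
        p = MaterialParams(rate_exponent=0.06)
        got = rate_modulus(1000.0, 10 * p.ref_strain_rate, p)
        assert got == pytest.approx(1000.0 * 10 ** 0.06, rel=1e-12)

    def test_rate_independent_when_k_zero(self):
        p = MaterialParams(rate_exponent=0.0)
        rates = np.array([1.0, 100.0, 5000.0, 1e6])
        assert rate_modulus(777.0, rates, p) == pytest.approx(777.0)

    def test_monotone_in_rate(self):
        p = MaterialParams()
        rates = np.logspace(0, 7, 50)
        e = rate_modulus(1000.0, rates, p)
        assert (np.diff(e) >= 0).all()


class TestStrength:
    def _tension_setup(self):
        mesh = _bar(nz=6)
        elast = ElasticityField(np.full(mesh.n_elements, 10000.0), 0.0)
        bottom = np.flatnonzero(mesh.nodes[:, 2] < 1e-9)
        top = np.flatnonzero(mesh.nodes[:, 2] > 40 - 1e-9)
        return mesh, elast, bottom, top

    def test_bar_strength_closed_form(self):
        # elastic to failure (yield set just below the failure strain):
        # strength = E * eps_f * A within one increment's force step
        mesh, elast, bottom, top = self._tension_setup()
        params = MaterialParams(rate_exponent=0.0, yield_tension=0.015499,
                                fail_tension=0.0155, failure_scope="any")
        res = simulate_strength(mesh, elast, params, fixed_nodes=bottom,
                                driven_nodes=top, direction=(0, 0, 1.0),
                                max_increments=40)
        expected = 10000.0 * 0.0155 * 16.0
        force_step = 10000.0 * 16.0 / 40.0 * 0.05
        assert not res.unfractured
        assert abs(res.strength - expected) <= force_step

    def test_post_yield_stiffness_is_softened(self):
        mesh, elast, bottom, top = self._tension_setup()
        params = MaterialParams(rate_exponent=0.0, yield_tension=0.004,
                                fail_tension=0.020, failure_scope="any")
        res = simulate_strength(mesh, elast, params, fixed_nodes=bottom,
                                driven_nodes=top, direction=(0, 0, 1.0),
                                max_increments=40)
        df = np.diff(res.force)
        pre = df[0]
        post = df[-1]  # fully yielded bar
        assert post == pytest.approx(0.55 * pre, rel=1e-6)

    def test_strength_monotone_in_failure_strain(self):
        mesh, elast, bottom, top = self._tension_setup()
        strengths = []
        for eps_f in (0.012, 0.016, 0.020):
            params = MaterialParams(rate_exponent=0.0, yield_tension=0.004,
                                    fail_tension=eps_f, failure_scope="any")
            res = simulate_strength(mesh, elast, params, fixed_nodes=bottom,
                                    driven_nodes=top, direction=(0, 0, 1.0),
                                    max_increments=60)
            strengths.append(res.strength)
        assert strengths[0] <= strengths[1] <= strengths[2]

    def test_increment_halving_consistent(self):
        mesh, elast, bottom, top = self._tension_setup()
        params = MaterialParams(rate_exponent=0.0, yield_tension=0.015499,
                                fail_tension=0.0155, failure_scope="any")
        coarse = simulate_strength(mesh, elast, params, fixed_nodes=bottom,
                                   driven_nodes=top, direction=(0, 0, 1.0),
                                   increment=0.05, max_increments=40)
        fine = simulate_strength(mesh, elast, params, fixed_nodes=bottom,
                                 driven_nodes=top, direction=(0, 0, 1.0),
                                 increment=0.025, max_increments=80)
        force_step = 10000.0 * 16.0 / 40.0 * 0.05
        assert abs(coarse.strength - fine.strength) <= force_step

    def test_yield_state_irreversible(self):
        mesh, elast, bottom, top = self._tension_setup()
        params = MaterialParams(rate_exponent=0.0, yield_tension=0.004,
                                fail_tension=0.020, failure_scope="any")
        res = simulate_strength(mesh, elast, params, fixed_nodes=bottom,
                                driven_nodes=top, direction=(0, 0, 1.0),
                                max_increments=40)
        assert (res.element_state >= 1).all()  # all yielded before failure

    def test_unfractured_flagged(self):
        mesh, elast, bottom, top = self._tension_setup()
        params = MaterialParams(rate_exponent=0.0)
        res = simulate_strength(mesh, elast, params, fixed_nodes=bottom,
                                driven_nodes=top, direction=(0, 0, 1.0),
                                max_increments=3)
        assert res.unfractured
        assert np.isnan(res.strength)

    def test_rate_dependence_raises_strength(self):
        mesh, elast, bottom, top = self._tension_setup()
        kwargs = dict(fixed_nodes=bottom, driven_nodes=top,
                      direction=(0, 0, 1.0), max_increments=60)
        base = MaterialParams(rate_exponent=0.0, yield_tension=0.015499,
                              fail_tension=0.0155, failure_scope="any")
        # driving at 15 mm/s over a 40 mm bar gives ~3.75e5 ue/s >> 5000
        rated = MaterialParams(rate_exponent=0.06, yield_tension=0.015499,
                               fail_tension=0.0155, failure_scope="any")
        s0 = simulate_strength(mesh, elast, base, **kwargs).strength
        s1 = simulate_strength(mesh, elast, rated, **kwargs).strength
        assert s1 > s0
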