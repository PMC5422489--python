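"""Linear-tetrahedron finite element solver.

Static strain prediction under a single-leg-stance load (4x body weight on
the femoral head, equally split over the 10 most superior surface nodes) and
displacement-controlled strength simulation with a strain-rate-dependent
material and separate tension/compression yield and failure strain limits.

Strength procedure: consecutive 0.05 mm increments at a 15 mm/s displacement
rate; per increment each element's modulus is evaluated at its current strain
rate, yielded elements carry a 0.55 softening factor, and the run stops when
the first surface element exceeds a failure strain. The accumulated reaction
force on the driven nodes at that increment is the predicted strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .material import ElasticityField
from .mesh import TetMesh, surface_facets

logger = logging.getLogger(__name__)

__all__ = ["FEModel", "FEResult", "MaterialParams", "StrengthResult",
           "assemble_and_solve", "stance_strain_case", "rate_modulus",
           "simulate_strength", "superior_head_nodes", "distal_cut_nodes"]

G_ACCEL = 9.81  # m/s^2, body weight kg -> N


@dataclass
class FEModel:
    """Mesh + moduli + boundary conditions for a single solve."""

    mesh: TetMesh
    elasticity: ElasticityField
    fixed_nodes: np.ndarray
    loads: dict = field(default_factory=dict)   # node -> (3,) force N
    prescribed: dict = field(default_factory=dict)  # node -> (3,) displacement mm

    def __post_init__(self):
        self.fixed_nodes = np.asarray(self.fixed_nodes, dtype=np.int64)
        if len(self.fixed_nodes) == 0 and not self.prescribed:
            raise ValueError("constrained node set must be non-empty")
        overlap = set(self.loads) & set(self.prescribed)
        if overlap:
            raise ValueError(f"nodes both driven and loaded: {sorted(overlap)[:5]}")


@dataclass
class FEResult:
    displacements: np.ndarray        # (N, 3) mm
    strain_voigt: np.ndarray         # (M, 6) [xx yy zz gxy gyz gxz]
    principal_strains: np.ndarray    # (M, 3) sorted eps1 >= eps2 >= eps3
    reactions: np.ndarray            # (N, 3) N at constrained nodes (else 0)


def _element_b_matrices(mesh: TetMesh):
    """Shape-function gradient matrices; returns (B (M,6,12), volumes)."""
    verts = mesh.nodes[mesh.elements]
    t = np.transpose(verts[:, 1:] - verts[:, :1], (0, 2, 1))  # (M,3,3) columns
    tinv = np.linalg.inv(t)
    # gradients of N1..N3 are rows of tinv; N0 = -(sum)
    g = np.empty((len(verts), 4, 3))
    g[:, 1:] = tinv
    g[:, 0] = -tinv.sum(axis=1)
    vols = np.abs(np.linalg.det(t)) / 6.0
    m = len(verts)
    b = np.zeros((m, 6, 12))
    for a in range(4):
        gx, gy, gz = g[:, a, 0], g[:, a, 1], g[:, a, 2]
        c = 3 * a
        b[:, 0, c] = gx
        b[:, 1, c + 1] = gy
        b[:, 2, c + 2] = gz
        b[:, 3, c] = gy
        b[:, 3, c + 1] = gx
        b[:, 4, c + 1] = gz
        b[:, 4, c + 2] = gy
        b[:, 5, c] = gz
        b[:, 5, c + 2] = gx
    return b, vols


def _d_matrices(e_values: np.ndarray, nu: float) -> np.ndarray:
    lam = e_values * nu / ((1 + nu) * (1 - 2 * nu))
    mu = e_values / (2 * (1 + nu))
    m = len(e_values)
    d = np.zeros((m, 6, 6))
    for i in range(3):
        for j in range(3):
            d[:, i, j] = lam
        d[:, i, i] += 2 * mu
        d[:, 3 + i, 3 + i] = mu
    return d


def _assemble(mesh: TetMesh, elasticity: ElasticityField):
    b, vols = _element_b_matrices(mesh)
    d = _d_matrices(np.maximum(elasticity.values, 1e-9), elasticity.poisson)
    ke = np.einsum("mji,mjk,mkl->mil", b, d, b) * vols[:, None, None]
    dof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(len(ke), 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsc()
    return k, b


def _solve_dirichlet(k, f, fixed_dofs, fixed_vals):
    n = k.shape[0]
    free = np.setdiff1d(np.arange(n), fixed_dofs)
    u = np.zeros(n)
    u[fixed_dofs] = fixed_vals
    kff = k[free][:, free]
    rhs = f[free] - k[free][:, fixed_dofs] @ fixed_vals
    try:
        uf = spla.spsolve(kff, rhs)
    except Exception as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(f"singular stiffness matrix: {exc}")
    resid = np.linalg.norm(kff @ uf - rhs) if np.all(np.isfinite(uf)) else np.inf
    if resid > 1e-6 * max(np.linalg.norm(rhs), 1e-12):
        nz = _null_space_dim(kff)
        raise np.linalg.LinAlgError(
            f"singular system (under-constrained): null-space dimension ~{nz}"
        )
    u[free] = uf
    reactions = k @ u - f
    r = np.zeros(n)
    r[fixed_dofs] = reactions[fixed_dofs]
    return u, r


def _null_space_dim(kff) -> int:
    try:
        w = spla.eigsh(kff, k=min(6, kff.shape[0] - 1), sigma=0,
                       return_eigenvectors=False)
        scale = abs(w).max() + 1e-30
        return int((abs(w) / scale < 1e-8).sum())
    except Exception:  # pragma: no cover
        return -1


def _principal(strain_voigt: np.ndarray) -> np.ndarray:
    """Principal strains sorted descending from Voigt engineering strain."""
    m = len(strain_voigt)
    t = np.zeros((m, 3, 3))
    t[:, 0, 0] = strain_voigt[:, 0]
    t[:, 1, 1] = strain_voigt[:, 1]
    t[:, 2, 2] = strain_voigt[:, 2]
    t[:, 0, 1] = t[:, 1, 0] = strain_voigt[:, 3] / 2
    t[:, 1, 2] = t[:, 2, 1] = strain_voigt[:, 4] / 2
    t[:, 0, 2] = t[:, 2, 0] = strain_voigt[:, 5] / 2
    return np.linalg.eigvalsh(t)[:, ::-1]


def assemble_and_solve(model: FEModel) -> FEResult:
    """Static solve; returns displacements, element strains, principal
    strains (sorted eps1 >= eps3) and reaction forces.

    Equilibrium holds to solver precision: the reactions at constrained
    nodes balance the applied loads.
    """
    k, b = _assemble(model.mesh, model.elasticity)
    n = 3 * model.mesh.n_nodes
    f = np.zeros(n)
    for node, force in model.loads.items():
        f[3 * node : 3 * node + 3] += np.asarray(force, dtype=float)
    fixed_dofs = (3 * model.fixed_nodes[:, None] + np.arange(3)).ravel()
    fixed_vals = np.zeros(len(fixed_dofs))
    if model.prescribed:
        pn = np.array(sorted(model.prescribed), dtype=np.int64)
        pdofs = (3 * pn[:, None] + np.arange(3)).ravel()
        pvals = np.concatenate([np.asarray(model.prescribed[i], dtype=float)
                                for i in sorted(model.prescribed)])
        fixed_dofs = np.concatenate([fixed_dofs, pdofs])
        fixed_vals = np.concatenate([fixed_vals, pvals])
    u, r = _solve_dirichlet(k, f, fixed_dofs, fixed_vals)
    ue = u.reshape(-1, 3)[model.mesh.elements].reshape(-1, 12)
    strain = np.einsum("mij,mj->mi", b, ue)
    return FEResult(u.reshape(-1, 3), strain, _principal(strain),
                    r.reshape(-1, 3))


def superior_head_nodes(mesh: TetMesh, n: int = 10) -> np.ndarray:
    """The n most superior (largest z) surface nodes — the femoral head top."""
    _, _, snodes = surface_facets(mesh)
    if len(snodes) < n:
        raise ValueError(f"mesh has only {len(snodes)} surface nodes, need {n}")
    order = np.argsort(mesh.nodes[snodes, 2])[::-1]
    return snodes[order[:n]]


def distal_cut_nodes(mesh: TetMesh, tol: float = 1e-6) -> np.ndarray:
    """Nodes of the distal cut plane: the tagged set if present, else all
    nodes within ``tol`` of the minimum z coordinate."""
    if "distal_cut" in mesh.node_sets:
        return np.asarray(mesh.node_sets["distal_cut"], dtype=np.int64)
    zmin = mesh.nodes[:, 2].min()
    return np.flatnonzero(mesh.nodes[:, 2] <= zmin + tol)


def stance_strain_case(
    mesh: TetMesh,
    elasticity: ElasticityField,
    body_weight: float,
    fixed_nodes: np.ndarray | None = None,
) -> FEResult:
    """Single-leg-stance strain case: total force 4 * BW * g applied downward
    (-z), equally distributed over the 10 most superior surface nodes; the
    distal cut plane is fully fixed."""
    head = superior_head_nodes(mesh, 10)
    fixed = fixed_nodes if fixed_nodes is not None else distal_cut_nodes(mesh)
    total = 4.0 * body_weight * G_ACCEL
    per_node = np.array([0.0, 0.0, -total / len(head)])
    model = FEModel(mesh, elasticity, fixed,
                    loads={int(nd): per_node for nd in head})
    return assemble_and_solve(model)


@dataclass(frozen=True)
class MaterialParams:
    """Rate-dependent yield/failure material parameters.

    Strains are absolute (dimensionless); the reference strain rate is in
    microstrain per second. ``rate_exponent`` = 0 gives a rate-independent
    material. Yielded elements keep ``softening`` x E(rate) thereafter.
    """

    ref_strain_rate: float = 5000.0        # microstrain / s
    rate_exponent: float = 0.06
    yield_tension: float = 0.0073
    yield_compression: float = 0.0104
    fail_tension: float = 0.0155
    fail_compression: float = 0.025
    softening: float = 0.55
    failure_scope: str = "surface"         # "surface" | "any"

    def __post_init__(self):
        if not (0 < self.yield_tension < self.fail_tension):
            raise ValueError("need 0 < yield < failure strain (tension)")
        if not (0 < self.yield_compression < self.fail_compression):
            raise ValueError("need 0 < yield < failure strain (compression)")
        if self.ref_strain_rate <= 0:
            raise ValueError("reference strain rate must be > 0")
        if not (0 < self.softening <= 1):
            raise ValueError("softening factor must be in (0, 1]")


def rate_modulus(e_ref, strain_rate, params: MaterialParams):
    """Strain-rate-scaled modulus E(rate) = E_ref (rate / ref_rate)^k.

    ``E(ref_rate) = E_ref`` exactly; monotone non-decreasing in rate; the
    rate is floored at a small positive value.
    """
    rate = np.maximum(np.asarray(strain_rate, dtype=float), 1e-3)
    return np.asarray(e_ref) * (rate / params.ref_strain_rate) ** params.rate_exponent


@dataclass
class StrengthResult:
    displacement: np.ndarray     # (n_inc,) mm, applied magnitude
    force: np.ndarray            # (n_inc,) N, accumulated reaction on driven set
    strength: float              # N, force at first failure (NaN if unfractured)
    failing_element: int         # -1 if unfractured
    increment_index: int
    element_state: np.ndarray    # (M,) 0 intact, 1 yielded, 2 failed
    unfractured: bool


def simulate_strength(
    mesh: TetMesh,
    elasticity: ElasticityField,
    params: MaterialParams = MaterialParams(),
    fixed_nodes: np.ndarray | None = None,
    driven_nodes: np.ndarray | None = None,
    direction=(0.0, 0.0, -1.0),
    increment: float = 0.05,
    rate: float = 15.0,
    max_increments: int = 200,
) -> StrengthResult:
    """Displacement-controlled strength simulation.

    Each increment applies a further ``increment`` mm of displacement to the
    driven nodes along ``direction`` (default: the 10 most superior surface
    nodes pushed down) against the fixed distal cut plane, assembling the
    tangent stiffness from the current per-element moduli. Strains and
    reaction forces are accumulated; strain rates come from the change of the
    largest-magnitude principal strain over dt = increment / rate.
    """
    if driven_nodes is None:
        driven_nodes = superior_head_nodes(mesh, 10)
    if fixed_nodes is None:
        fixed_nodes = distal_cut_nodes(mesh)
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    dt = increment / rate
    _, surf_elems, _ = surface_facets(mesh)
    in_scope = np.zeros(mesh.n_elements, dtype=bool)
    if params.failure_scope == "surface":
        in_scope[surf_elems] = True
    elif params.failure_scope == "any":
        in_scope[:] = True
    else:
        raise ValueError("failure_scope must be 'surface' or 'any'")

    e_ref = elasticity.values.copy()
    state = np.zeros(mesh.n_elements, dtype=np.int8)     # 0/1/2
    strain = np.zeros((mesh.n_elements, 6))
    prev_peak = np.zeros(mesh.n_elements)
    strain_rate = np.full(mesh.n_elements, params.ref_strain_rate)
    disp_hist, force_hist = [], []
    total_force = 0.0
    dstep = {int(nd): direction * increment for nd in driven_nodes}
    ddofs = (3 * np.asarray(driven_nodes)[:, None] + np.arange(3)).ravel()

    for inc in range(1, max_increments + 1):
        e_now = rate_modulus(e_ref, strain_rate, params)
        e_now = np.where(state >= 1, params.softening * e_now, e_now)
        model = FEModel(
            mesh, ElasticityField(e_now, elasticity.poisson),
            fixed_nodes, prescribed=dstep,
        )
        k, b = _assemble(model.mesh, model.elasticity)
        f = np.zeros(3 * mesh.n_nodes)
        fixed_dofs = (3 * np.asarray(fixed_nodes)[:, None] + np.arange(3)).ravel()
        fixed_vals = np.zeros(len(fixed_dofs))
        pvals = np.tile(direction * increment, len(driven_nodes))
        u, r = _solve_dirichlet(
            k, f,
            np.concatenate([fixed_dofs, ddofs]),
            np.concatenate([fixed_vals, pvals]),
        )
        ue = u.reshape(-1, 3)[mesh.elements].reshape(-1, 12)
        dstrain = np.einsum("mij,mj->mi", b, ue)
        strain += dstrain
        total_force += abs(float((r[ddofs].reshape(-1, 3) @ direction).sum()))
        disp_hist.append(inc * increment)
        force_hist.append(total_force)

        princ = _principal(strain)
        peak = np.where(np.abs(princ[:, 0]) >= np.abs(princ[:, 2]),
                        princ[:, 0], princ[:, 2])
        strain_rate = np.abs(peak - prev_peak) / dt * 1e6
        prev_peak = peak

        newly_yielded = (princ[:, 0] > params.yield_tension) | (
            princ[:, 2] < -params.yield_compression
        )
        state = np.maximum(state, newly_yielded.astype(np.int8))
        failed = (princ[:, 0] > params.fail_tension) | (
            princ[:, 2] < -params.fail_compression
        )
        state = np.where(failed, 2, state).astype(np.int8)
        trigger = failed & in_scope
        if trigger.any():
            over = np.where(
                trigger,
                np.maximum(princ[:, 0] / params.fail_tension,
                           -princ[:, 2] / params.fail_compression),
                -np.inf,
            )
            failing = int(np.argmax(over))
            return StrengthResult(
                np.array(disp_hist), np.array(force_hist), total_force,
                failing, inc, state, False,
            )

    logger.warning("no failure within %d increments: unfractured", max_increments)
    return StrengthResult(
        np.array(disp_hist), np.array(force_hist), float("nan"),
        -1, max_increments, state, True,
    )
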