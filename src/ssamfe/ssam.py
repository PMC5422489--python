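"""Statistical shape-and-appearance model (SSAM) of the proximal femur.

The model is a principal-component decomposition, via SVD, of a data matrix
whose columns stack the nodal coordinates of corresponded tetrahedral meshes
followed by the per-element densities. Instances are generated from mode
weights expressed in standard scores (unit variance per mode), so bounds of
a few units are anatomically meaningful.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._proximity import Surface
from .mesh import DensityField, TetMesh, surface_facets

logger = logging.getLogger(__name__)

__all__ = ["SSAModel", "build_ssam", "instantiate", "morph_template",
           "save_model", "load_model", "project_member"]


@dataclass
class SSAModel:
    """SVD shape-and-appearance model over stacked [coordinates; densities].

    ``mean`` and the columns of ``modes`` live in block-scaled units: the
    coordinate block (mm) and the density block (g/cm^3) are each divided by
    ``coord_scale`` / ``density_scale`` so that both blocks carry unit total
    variance in the training set. Scaling is inverted on instantiation.
    """

    connectivity: np.ndarray
    n_nodes: int
    mean: np.ndarray
    modes: np.ndarray           # (D, m), orthonormal columns
    singular_values: np.ndarray  # (m,)
    n_samples: int
    coord_scale: float
    density_scale: float
    density_kind: str = "rho_app"

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def n_elements(self) -> int:
        return len(self.connectivity)

    def connectivity_hash(self) -> str:
        return hashlib.sha256(
            np.ascontiguousarray(self.connectivity, dtype=np.int64).tobytes()
        ).hexdigest()[:16]


def _stack(mesh: TetMesh, density: DensityField) -> np.ndarray:
    return np.concatenate([mesh.nodes.ravel(), density.values])


def _procrustes_rigid(moving: np.ndarray, fixed: np.ndarray):
    """Rotation R and translation t minimizing ||R @ moving + t - fixed||."""
    mu_m, mu_f = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - mu_m).T @ (fixed - mu_f)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = mu_f - r @ mu_m
    return r, t


def build_ssam(
    instances: list[tuple[TetMesh, DensityField]],
    block_scaling: bool = True,
    align: bool = False,
    n_modes: int | None = None,
) -> SSAModel:
    """Build an SSAM from corresponded training instances.

    Parameters
    ----------
    instances : list of (TetMesh, DensityField)
        All instances must share the template connectivity.
    block_scaling : bool
        Scale the coordinate and density blocks to unit total variance before
        the SVD (they carry different units); inverted on instantiation.
    align : bool
        Rigidly pre-align every instance to the first by Procrustes on nodes.
        Off by default: corresponded families are normally already in a
        common frame.
    n_modes : int, optional
        Retain this many modes (default: all ``n_samples - 1``).
    """
    if len(instances) < 2:
        raise ValueError("need at least 2 training instances")
    conn = instances[0][0].elements
    for mesh, dens in instances[1:]:
        if mesh.elements.shape != conn.shape or (mesh.elements != conn).any():
            raise ValueError("training instances have mismatched connectivity")
    kind = instances[0][1].kind
    meshes = [m for m, _ in instances]
    if align:
        ref = meshes[0].nodes
        aligned = [meshes[0]]
        for m in meshes[1:]:
            r, t = _procrustes_rigid(m.nodes, ref)
            aligned.append(TetMesh((r @ m.nodes.T).T + t, conn))
        meshes = aligned
    cols = [np.concatenate([m.nodes.ravel(), d.values])
            for m, (_, d) in zip(meshes, instances)]
    x = np.column_stack(cols)
    n = x.shape[1]
    mu = x.mean(axis=1)
    xc = x - mu[:, None]
    nc = 3 * instances[0][0].n_nodes
    if block_scaling:
        var_c = (xc[:nc] ** 2).sum() / (n - 1)
        var_d = (xc[nc:] ** 2).sum() / (n - 1)
        cs = np.sqrt(var_c) if var_c > 0 else 1.0
        ds = np.sqrt(var_d) if var_d > 0 else 1.0
    else:
        cs = ds = 1.0
    xc[:nc] /= cs
    xc[nc:] /= ds
    mu_scaled = mu.copy()
    mu_scaled[:nc] /= cs
    mu_scaled[nc:] /= ds
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    keep = min(n - 1, n_modes) if n_modes is not None else n - 1
    return SSAModel(
        connectivity=conn.copy(),
        n_nodes=instances[0][0].n_nodes,
        mean=mu_scaled,
        modes=u[:, :keep],
        singular_values=s[:keep],
        n_samples=n,
        coord_scale=float(cs),
        density_scale=float(ds),
        density_kind=kind,
    )


def instantiate(model: SSAModel, b: np.ndarray) -> tuple[TetMesh, DensityField]:
    """Generate a (mesh, density) instance from mode weights ``b``.

    ``x = mu + U diag(s / sqrt(n-1)) b`` in scaled units, then each block is
    unscaled. ``b`` is in standard scores. Negative densities are clamped to 0
    (count logged).
    """
    b = np.asarray(b, dtype=float).ravel()
    if len(b) != model.n_modes:
        raise ValueError(f"expected {model.n_modes} mode weights, got {len(b)}")
    amp = model.singular_values / np.sqrt(max(model.n_samples - 1, 1))
    x = model.mean + model.modes @ (amp * b)
    nc = 3 * model.n_nodes
    coords = (x[:nc] * model.coord_scale).reshape(-1, 3)
    dens = x[nc:] * model.density_scale
    n_clamped = int((dens < 0).sum())
    if n_clamped:
        logger.info("clamped %d negative densities to 0", n_clamped)
        dens = np.maximum(dens, 0.0)
    return TetMesh(coords, model.connectivity.copy()), DensityField(
        dens, kind=model.density_kind
    )


def project_member(
    model: SSAModel, mesh: TetMesh, density: DensityField
) -> np.ndarray:
    """Mode weights (standard scores) of a given instance."""
    x = _stack(mesh, density)
    nc = 3 * model.n_nodes
    xs = x.copy()
    xs[:nc] /= model.coord_scale
    xs[nc:] /= model.density_scale
    amp = model.singular_values / np.sqrt(max(model.n_samples - 1, 1))
    coeffs = model.modes.T @ (xs - model.mean)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(amp > 1e-12 * amp.max(initial=1.0), coeffs / amp, 0.0)
    return b


# ----------------------------------------------------------------- morphing --


def _tet_edges(elements: np.ndarray) -> np.ndarray:
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    e = np.vstack([elements[:, [a, b]] for a, b in pairs])
    return np.unique(np.sort(e, axis=1), axis=0)


def morph_template(
    template: TetMesh,
    target_surface: Surface,
    n_iter: int = 8,
    allow_inverted: bool = False,
) -> TetMesh:
    """Fit the template mesh to a target triangle surface, keeping connectivity.

    Stage 1: similarity pre-alignment — uniform scale from the RMS-radius
    ratio of the target vertices to the template boundary, centroids matched,
    then a few rigid ICP iterations (scale-free, avoiding ICP shrinkage).
    Stage 2: iterate closest-point-on-surface projection of the boundary nodes
    with harmonic (graph-Laplacian) interpolation of the interior displacement.
    """
    _, _, bnodes = surface_facets(template)
    nodes = template.nodes.copy()
    prox = target_surface

    tverts = target_surface.referenced_vertices
    mu_s = nodes[bnodes].mean(axis=0)
    mu_t = tverts.mean(axis=0)
    rms_s = np.sqrt(((nodes[bnodes] - mu_s) ** 2).sum(axis=1).mean())
    rms_t = np.sqrt(((tverts - mu_t) ** 2).sum(axis=1).mean())
    nodes = (rms_t / rms_s) * (nodes - mu_s) + mu_t
    for _ in range(5):  # rigid refinement
        closest, _, _ = prox.on_surface(nodes[bnodes])
        r, t = _procrustes_rigid(nodes[bnodes], closest)
        nodes = nodes @ r.T + t

    # graph Laplacian with umbrella weights, interior rows only
    n = len(nodes)
    interior = np.setdiff1d(np.arange(n), bnodes)
    edges = _tet_edges(template.elements)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])
    w = np.ones(len(i))
    adj = sp.csr_matrix((w, (i, j)), shape=(n, n))
    deg = sp.diags(np.asarray(adj.sum(axis=1)).ravel())
    lap = (deg - adj).tocsr()
    l_ii = lap[interior][:, interior].tocsc()
    l_ib = lap[interior][:, bnodes]
    solver = spla.factorized(l_ii) if len(interior) else None

    for _ in range(n_iter):
        closest, _, _ = prox.on_surface(nodes[bnodes])
        disp_b = closest - nodes[bnodes]
        nodes[bnodes] = closest
        if solver is not None:
            rhs = -l_ib @ disp_b
            disp_i = np.column_stack([solver(rhs[:, k]) for k in range(3)])
            nodes[interior] += disp_i

    p = nodes[template.elements]
    vols = np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0
    inverted = np.flatnonzero(vols <= 0)
    if len(inverted) and not allow_inverted:
        raise ValueError(
            f"morph produced {len(inverted)} inverted elements: "
            f"{inverted[:20].tolist()}"
        )
    return TetMesh(nodes, template.elements.copy())


# ------------------------------------------------------------- persistence --


def save_model(model: SSAModel, path) -> None:
    """Serialize an SSAM as a single .npz archive with JSON metadata."""
    meta = {
        "n_nodes": model.n_nodes,
        "n_samples": model.n_samples,
        "coord_scale": model.coord_scale,
        "density_scale": model.density_scale,
        "density_kind": model.density_kind,
        "connectivity_hash": model.connectivity_hash(),
    }
    np.savez_compressed(
        path,
        connectivity=model.connectivity,
        mean=model.mean,
        modes=model.modes,
        singular_values=model.singular_values,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path) -> SSAModel:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["meta"]).decode())
        model = SSAModel(
            connectivity=z["connectivity"],
            n_nodes=int(meta["n_nodes"]),
            mean=z["mean"],
            modes=z["modes"],
            singular_values=z["singular_values"],
            n_samples=int(meta["n_samples"]),
            coord_scale=float(meta["coord_scale"]),
            density_scale=float(meta["density_scale"]),
            density_kind=meta["density_kind"],
        )
    if model.connectivity_hash() != meta["connectivity_hash"]:
        raise ValueError("connectivity hash mismatch in model archive")
    return model
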