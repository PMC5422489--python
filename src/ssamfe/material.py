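"""Density calibration, density-elasticity laws, inter-mesh density transfer
and the two-step surface modulus compensation.

Calibration chain (all constants configurable, recorded in output metadata):
rho_ash = 0.877 * rho_qct + 0.079, rho_app = rho_ash / 0.6 (g/cm^3), and the
density-elasticity power law E = 6850 * rho_app^1.49 MPa, the empirical
relationship standard in femoral FE modelling. The model-wide modulus cap is
22 GPa; thin-cortex surface elements are floored at 5 GPa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import (DensityField, TetMesh, face_adjacency, surface_facets)

logger = logging.getLogger(__name__)

__all__ = [
    "Calibration", "DensityLaw", "ElasticityField", "VoxelGrid",
    "convert_density", "density_to_modulus", "map_density",
    "map_density_from_grid", "surface_compensation", "DEFAULT_LAW",
    "DEFAULT_CALIBRATION",
]


@dataclass(frozen=True)
class Calibration:
    """Linear rho_qct -> rho_ash map and ash/apparent ratio."""

    ash_slope: float = 0.877
    ash_intercept: float = 0.079
    ash_app_ratio: float = 0.6


DEFAULT_CALIBRATION = Calibration()


def convert_density(
    density: DensityField, to_kind: str, calib: Calibration = DEFAULT_CALIBRATION
) -> DensityField:
    """Convert a density field between rho_qct / rho_ash / rho_app."""
    if to_kind == density.kind:
        return DensityField(density.values.copy(), kind=density.kind)
    v = density.values
    # to ash first
    if density.kind == "rho_qct":
        ash = calib.ash_slope * v + calib.ash_intercept
    elif density.kind == "rho_app":
        ash = v * calib.ash_app_ratio
    else:
        ash = v
    if to_kind == "rho_ash":
        out = ash
    elif to_kind == "rho_app":
        out = ash / calib.ash_app_ratio
    elif to_kind == "rho_qct":
        out = (ash - calib.ash_intercept) / calib.ash_slope
    else:
        raise ValueError(f"unknown density kind {to_kind!r}")
    return DensityField(np.maximum(out, 0.0), kind=to_kind)


@dataclass(frozen=True)
class DensityLaw:
    """Piecewise power law E = a + b * rho^c (MPa) over density segments.

    ``segments`` is a list of (rho_lo, rho_hi, a, b, c); the law must be
    monotone non-decreasing over rho >= 0 and have E(0) >= 0.
    """

    name: str = "power_1p49"
    kind: str = "rho_app"
    segments: tuple = ((0.0, np.inf, 0.0, 6850.0, 1.49),)

    def __post_init__(self):
        grid = np.linspace(0.0, 3.0, 301)
        e = self.evaluate(grid)
        if e[0] < 0 or (np.diff(e) < -1e-9).any():
            raise ValueError("density law must be non-decreasing with E(0) >= 0")

    def evaluate(self, rho: np.ndarray) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        if (rho < 0).any():
            raise ValueError("negative density passed to density law")
        e = np.zeros_like(rho)
        for lo, hi, a, b, c in self.segments:
            sel = (rho >= lo) & (rho < hi)
            e[sel] = a + b * rho[sel] ** c
        return e


DEFAULT_LAW = DensityLaw()


@dataclass
class ElasticityField:
    """Per-element Young's modulus (MPa) and a uniform Poisson ratio."""

    values: np.ndarray
    poisson: float = 0.3

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if (self.values < 0).any():
            raise ValueError("moduli must be non-negative")
        if not (0.0 <= self.poisson < 0.5):
            raise ValueError("Poisson ratio must be in [0, 0.5)")


def density_to_modulus(
    density: DensityField,
    law: DensityLaw = DEFAULT_LAW,
    calib: Calibration = DEFAULT_CALIBRATION,
    poisson: float = 0.3,
) -> ElasticityField:
    """Elementwise density -> Young's modulus through ``law``.

    The density is converted to the law's calibration kind first.
    """
    rho = convert_density(density, law.kind, calib).values
    return ElasticityField(law.evaluate(rho), poisson=poisson)


# ---------------------------------------------------------- density mapping --


def _tet_sample_points(mesh: TetMesh, n_samples: int) -> np.ndarray:
    """(M, S, 3) deterministic stratified interior sample points per element."""
    from .drr import _cube_to_tet_barycentric

    n = max(1, round(n_samples ** (1.0 / 3.0)))
    bary = _cube_to_tet_barycentric(n)
    return np.einsum("sk,mki->msi", bary, mesh.nodes[mesh.elements])


class _TetLocator:
    """Point-in-tet lookup via centroid KD-tree + barycentric membership."""

    def __init__(self, mesh: TetMesh, k: int = 32):
        self.mesh = mesh
        verts = mesh.nodes[mesh.elements]
        self.v0 = verts[:, 0]
        t = np.transpose(verts[:, 1:] - verts[:, :1], (0, 2, 1))  # (M,3,3) cols
        self.tinv = np.linalg.inv(t)
        self.tree = cKDTree(verts.mean(axis=1))
        self.k = min(k, mesh.n_elements)

    def locate(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Element index containing each point, or -1."""
        pts = np.atleast_2d(points)
        _, cand = self.tree.query(pts, k=self.k)
        cand = np.atleast_2d(cand)
        out = np.full(len(pts), -1, dtype=np.int64)
        pending = np.arange(len(pts))
        for rank in range(cand.shape[1]):
            if not len(pending):
                break
            e = cand[pending, rank]
            local = np.einsum(
                "pij,pj->pi", self.tinv[e], pts[pending] - self.v0[e]
            )
            ok = (local >= -tol).all(axis=1) & (local.sum(axis=1) <= 1 + tol)
            out[pending[ok]] = e[ok]
            pending = pending[~ok]
        return out


def map_density(
    source_mesh: TetMesh,
    source_density: DensityField,
    target: TetMesh,
    n_samples: int = 64,
) -> DensityField:
    """Transfer per-element density from one tet mesh onto another.

    Treats the source density as a 3D step function and estimates, for each
    target element, the intersection-volume-weighted average of the source
    densities via deterministic stratified sampling (``n_samples`` interior
    points per target element). Target elements with no overlap get 0 and are
    counted in a warning.
    """
    pts = _tet_sample_points(target, n_samples)
    loc = _TetLocator(source_mesh)
    owners = loc.locate(pts.reshape(-1, 3)).reshape(pts.shape[:2])
    matched = owners >= 0
    vals = np.where(matched, source_density.values[np.maximum(owners, 0)], 0.0)
    n_in = matched.sum(axis=1)
    with np.errstate(invalid="ignore"):
        rho = np.where(n_in > 0, vals.sum(axis=1) / np.maximum(n_in, 1), 0.0)
    n_empty = int((n_in == 0).sum())
    if n_empty == target.n_elements:
        logger.warning("meshes are disjoint: all-zero density field")
    elif n_empty:
        logger.warning("%d target elements have no overlap with source", n_empty)
    return DensityField(rho, kind=source_density.kind)


@dataclass
class VoxelGrid:
    """Axis-aligned voxel grid of density values (step function per voxel).

    ``values`` indexed [ix, iy, iz]; ``origin`` is the corner of voxel
    (0,0,0); ``spacing`` the voxel edge lengths in mm.
    """

    values: np.ndarray
    origin: tuple
    spacing: tuple
    kind: str = "rho_app"

    def lookup(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-voxel values and an in-grid mask."""
        idx = np.floor(
            (points - np.asarray(self.origin)) / np.asarray(self.spacing)
        ).astype(np.int64)
        shape = np.asarray(self.values.shape)
        inside = ((idx >= 0) & (idx < shape)).all(axis=1)
        idx = np.clip(idx, 0, shape - 1)
        return self.values[idx[:, 0], idx[:, 1], idx[:, 2]], inside


def map_density_from_grid(
    grid: VoxelGrid, target: TetMesh, n_samples: int = 64
) -> DensityField:
    """Bonemat-style element integration of a voxelized density field."""
    pts = _tet_sample_points(target, n_samples)
    vals, inside = grid.lookup(pts.reshape(-1, 3))
    vals = vals.reshape(pts.shape[:2])
    inside = inside.reshape(pts.shape[:2])
    n_in = inside.sum(axis=1)
    rho = np.where(
        n_in > 0, (vals * inside).sum(axis=1) / np.maximum(n_in, 1), 0.0
    )
    n_out = int((n_in == 0).sum())
    if n_out:
        logger.warning("%d elements fall outside the voxel grid", n_out)
    return DensityField(np.maximum(rho, 0.0), kind=grid.kind)


# ---------------------------------------------------- surface compensation --


def surface_compensation(
    mesh: TetMesh,
    elasticity: ElasticityField,
    e_max: float = 22000.0,
    e_surface_min: float = 5000.0,
) -> ElasticityField:
    """Two-step modulus compensation after density mapping.

    Step 1: each surface element's modulus becomes the maximum of its mapped
    value and the moduli of its face-adjacent non-surface neighbours.
    Step 2: every modulus is capped at ``e_max`` (22 GPa); surface elements
    are additionally floored at ``e_surface_min`` (5 GPa, thin-cortex
    assumption). Idempotent.
    """
    e = elasticity.values.copy()
    _, surf_elems, _ = surface_facets(mesh)
    is_surf = np.zeros(mesh.n_elements, dtype=bool)
    is_surf[surf_elems] = True
    nbrs = face_adjacency(mesh)
    e1 = e.copy()
    for s in surf_elems:
        interior_nb = [n for n in nbrs[s] if not is_surf[n]]
        if interior_nb:
            e1[s] = max(e[s], max(e[n] for n in interior_nb))
    e1 = np.minimum(e1, e_max)
    e1[is_surf] = np.maximum(e1[is_surf], e_surface_min)
    return ElasticityField(e1, poisson=elasticity.poisson)
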