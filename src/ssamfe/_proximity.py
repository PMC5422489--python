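"""Point-to-triangle-surface proximity queries.

Exact closest-point computation on a candidate set of triangles found via a
KD-tree over triangle centroids (with a conservative candidate count). Used
for template morphing, ICP registration and shape-error metrics.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["Surface"]


def _closest_on_triangles(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each point (vectorized, Ericson).

    p: (n, 3); tri: (n, 3, 3) one triangle per point.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)                                # vertex A
    assign((d3 >= 0) & (d4 <= d3), b)                               # vertex B
    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[:, None] * ab)
    assign((d6 >= 0) & (d5 <= d6), c)                               # vertex C
    vb = d5 * d2 - d1 * d6
    with np.errstate(divide="ignore", invalid="ignore"):
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[:, None] * ac)
    va = d3 * d6 - d5 * d4
    with np.errstate(divide="ignore", invalid="ignore"):
        w_bc = np.where((d4 - d3) + (d5 - d6) != 0,
                        (d4 - d3) / ((d4 - d3) + (d5 - d6)), 0.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + w_bc[:, None] * (c - b))
    denom = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(denom != 0, vb / denom, 0.0)
        w = np.where(denom != 0, vc / denom, 0.0)
    assign(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)
    return out


class Surface:
    """Triangle surface with closest-point queries.

    Parameters: ``vertices`` (V, 3), ``faces`` (F, 3) vertex indices.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.ascontiguousarray(vertices, dtype=float)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        self._tri = self.vertices[self.faces]
        centroids = self._tri.mean(axis=1)
        self._tree = cKDTree(centroids)
        self.referenced_vertices = self.vertices[np.unique(self.faces)]
        self._k = min(8, len(self.faces))
        # centroid-to-vertex radius bounds the centroid-ordering error
        self._radius = np.linalg.norm(
            self._tri - centroids[:, None, :], axis=2
        ).max()

    @classmethod
    def from_tetmesh(cls, mesh) -> "Surface":
        from .mesh import surface_facets

        facets, _, _ = surface_facets(mesh)
        return cls(mesh.nodes, facets)

    def on_surface(self, points: np.ndarray):
        """Exact closest surface points; returns (closest (n,3),
        distance (n,), triangle index (n,)).

        A k-nearest-centroid pass yields an upper bound on each distance;
        every triangle whose centroid lies within that bound plus the
        largest centroid-to-vertex radius is then checked exactly.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        _, cand = self._tree.query(pts, k=self._k)
        cand = np.atleast_2d(cand)
        best_d = np.full(len(pts), np.inf)
        best_p = np.zeros_like(pts)
        best_t = np.zeros(len(pts), dtype=np.int64)

        def update(p_idx, t_idx):
            cp = _closest_on_triangles(pts[p_idx], self._tri[t_idx])
            d = np.linalg.norm(pts[p_idx] - cp, axis=1)
            order = np.lexsort((d, p_idx))
            p_s, d_s, cp_s, t_s = p_idx[order], d[order], cp[order], t_idx[order]
            first = np.ones(len(p_s), dtype=bool)
            first[1:] = p_s[1:] != p_s[:-1]
            better = first & (d_s < best_d[p_s])
            best_d[p_s[better]] = d_s[better]
            best_p[p_s[better]] = cp_s[better]
            best_t[p_s[better]] = t_s[better]

        for rank in range(cand.shape[1]):
            t = cand[:, rank]
            update(np.arange(len(pts)), t)
        balls = self._tree.query_ball_point(pts, best_d + self._radius + 1e-9)
        counts = np.array([len(b) for b in balls])
        if counts.sum():
            p_idx = np.repeat(np.arange(len(pts)), counts)
            t_idx = np.concatenate([np.asarray(b, dtype=np.int64)
                                    for b in balls if len(b)])
            update(p_idx, t_idx)
        return best_p, best_d, best_t
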