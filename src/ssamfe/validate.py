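"""Validation machinery: DIC-cloud registration and strain pairing, robust
regression accuracy metrics, strength-error metrics, and shape / neck-volume
reconstruction error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.spatial import ConvexHull, cKDTree

from ._proximity import Surface
from .mesh import TetMesh, circumscribing_sphere, element_volumes

logger = logging.getLogger(__name__)

__all__ = ["DICCloud", "RegressionReport", "ICPResult", "icp_register",
           "pair_strains", "robust_regression", "strength_error_metrics",
           "shape_error", "neck_volume_diff", "slab_volume"]


@dataclass
class DICCloud:
    """Surface strain point cloud: positions (mm) with major and minor
    principal strains (microstrain) per point."""

    points: np.ndarray
    major: np.ndarray
    minor: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.major = np.asarray(self.major, dtype=float).ravel()
        self.minor = np.asarray(self.minor, dtype=float).ravel()
        if not (np.isfinite(self.major).all() and np.isfinite(self.minor).all()):
            raise ValueError("strains must be finite")
        if (self.major < self.minor).any():
            raise ValueError("major principal strain must be >= minor")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray):
        return DICCloud(self.points @ rotation.T + translation,
                        self.major.copy(), self.minor.copy())

    @classmethod
    def read_csv(cls, path):
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(data[:, :3], data[:, 3], data[:, 4])

    def write_csv(self, path):
        header = "x_mm,y_mm,z_mm,eps_major_ue,eps_minor_ue"
        np.savetxt(path, np.column_stack([self.points, self.major, self.minor]),
                   delimiter=",", header=header, comments="")


@dataclass
class RegressionReport:
    r2: float
    slope: float
    intercept: float          # microstrain
    nrmse_pct: float
    max_error_pct: float
    n: int


@dataclass
class ICPResult:
    rotation: np.ndarray
    translation: np.ndarray
    residuals: np.ndarray       # mean point-to-surface distance per iteration
    points: np.ndarray          # transformed cloud points


def _kabsch(src: np.ndarray, dst: np.ndarray, weights=None):
    w = np.ones(len(src)) if weights is None else weights
    w = w / w.sum()
    mu_s = (src * w[:, None]).sum(axis=0)
    mu_d = (dst * w[:, None]).sum(axis=0)
    h = (src - mu_s).T @ ((dst - mu_d) * w[:, None])
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, mu_d - r @ mu_s


def icp_register(
    cloud: DICCloud,
    surface: Surface,
    seed: int = 0,
    max_iter: int = 60,
    tol: float = 1e-6,
    trim_fraction: float = 1.0,
) -> ICPResult:
    """Register a DIC cloud onto a triangle surface by iterative closest
    point, with coarse pre-alignment by centroid + principal axes.

    ``trim_fraction`` < 1 keeps only the best correspondences each iteration
    (robustness to outlier points). Raises if the mean residual increases for
    5 consecutive iterations (divergence).
    """
    prox = surface
    pts0 = cloud.points

    # centroid + principal-axes pre-alignment; resolve axis-sign ambiguity by
    # trying the four proper sign combinations and keeping the best residual
    def principal_frame(p):
        c = p.mean(axis=0)
        _, _, vt = np.linalg.svd(p - c, full_matrices=False)
        if np.linalg.det(vt) < 0:
            vt[2] *= -1
        return c, vt

    c_c, f_c = principal_frame(pts0)
    c_s, f_s = principal_frame(surface.referenced_vertices)
    # the incoming pose itself is a candidate: do not disturb an already
    # good registration
    _, d0, _ = prox.on_surface(pts0)
    best = (d0.mean(), np.eye(3), np.zeros(3))
    for s1, s2 in [(1, 1), (1, -1), (-1, 1), (-1, -1)]:
        f = f_c.copy()
        f[0] *= s1
        f[1] *= s2
        f[2] = np.cross(f[0], f[1])
        r0 = f_s.T @ f
        t0 = c_s - r0 @ c_c
        p = pts0 @ r0.T + t0
        _, d, _ = prox.on_surface(p)
        if d.mean() < best[0]:
            best = (d.mean(), r0, t0)
    _, r_tot, t_tot = best
    pts = pts0 @ r_tot.T + t_tot

    residuals = []
    rising = 0
    for _ in range(max_iter):
        closest, dist, _ = prox.on_surface(pts)
        if trim_fraction < 1.0:
            k = max(3, int(np.ceil(trim_fraction * len(pts))))
            keep = np.argsort(dist)[:k]
        else:
            keep = slice(None)
        r, t = _kabsch(pts[keep], closest[keep])
        pts = pts @ r.T + t
        r_tot = r @ r_tot
        t_tot = r @ t_tot + t
        _, dist, _ = prox.on_surface(pts)
        residuals.append(dist.mean())
        if residuals[-1] < tol:
            break
        if len(residuals) > 1:
            if residuals[-1] > residuals[-2] + 1e-9:
                rising += 1
                if rising >= 5:
                    raise RuntimeError(
                        f"ICP diverging; residual trace: {residuals}"
                    )
            else:
                rising = 0
            if abs(residuals[-2] - residuals[-1]) < tol:
                break
    return ICPResult(r_tot, t_tot, np.array(residuals), pts)


def pair_strains(
    mesh: TetMesh,
    surface_elements: np.ndarray,
    principal_strains: np.ndarray,
    cloud: DICCloud,
    project_to_surface: bool = False,
    surface: Surface | None = None,
):
    """Pair experimental DIC strains with FE surface-element strains.

    For each surface element the smallest sphere circumscribing its 4 nodes
    is computed; all DIC points inside the closed sphere are averaged, giving
    one (experimental, FE) pair per retained element for each of the major
    and minor principal strains. Elements whose sphere contains no points are
    excluded. Optionally the cloud is first projected point-to-surface (used
    when the FE geometry is itself a reconstruction).

    Returns a dict with keys ``exp_major, fe_major, exp_minor, fe_minor,
    elements``.
    """
    pts = cloud.points
    if project_to_surface:
        if surface is None:
            raise ValueError("surface required for point-to-surface projection")
        pts, _, _ = surface.on_surface(pts)
    tree = cKDTree(pts)
    exp_ma, exp_mi, fe_ma, fe_mi, kept = [], [], [], [], []
    for e in np.asarray(surface_elements):
        sph = circumscribing_sphere(mesh.nodes[mesh.elements[e]])
        idx = tree.query_ball_point(sph.center, sph.radius * (1 + 1e-12) + 1e-9)
        if not idx:
            continue
        exp_ma.append(cloud.major[idx].mean())
        exp_mi.append(cloud.minor[idx].mean())
        fe_ma.append(principal_strains[e, 0])
        fe_mi.append(principal_strains[e, 2])
        kept.append(int(e))
    if not kept:
        raise ValueError("no surface element paired with any DIC point")
    return {
        "exp_major": np.array(exp_ma), "fe_major": np.array(fe_ma),
        "exp_minor": np.array(exp_mi), "fe_minor": np.array(fe_mi),
        "elements": np.array(kept, dtype=np.int64),
    }


def robust_regression(x: np.ndarray, y: np.ndarray,
                      rel_error_floor: float = 0.1) -> RegressionReport:
    """Robust linear regression of predicted on experimental strains.

    Iteratively reweighted least squares with the Tukey bisquare weight
    (tuning constant 4.685, MAD scale). R^2 is computed on the final
    weighted fit. NRMSE is the RMS residual about the fit normalized by the
    range of x (percent). The maximum error is the largest |y - x| relative
    to |x|, over points with |x| above ``rel_error_floor`` times max |x|.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need n >= 3 paired samples")
    if np.ptp(x) < 1e-12:
        raise ValueError("zero variance in x")
    exog = sm.add_constant(x)
    fit = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=4.685)).fit(
        conv="coefs", tol=1e-10, maxiter=200
    )
    intercept, slope = fit.params
    w = fit.weights
    resid = y - fit.fittedvalues
    ybar = (w * y).sum() / w.sum()
    ss_res = (w * resid ** 2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    nrmse = 100.0 * np.sqrt((resid ** 2).mean()) / np.ptp(x)
    big = np.abs(x) >= rel_error_floor * np.abs(x).max()
    max_err = 100.0 * np.max(np.abs((y - x))[big] / np.abs(x)[big])
    return RegressionReport(float(r2), float(slope), float(intercept),
                            float(nrmse), float(max_err), len(x))


def strength_error_metrics(predicted, experimental) -> dict:
    """Relative prediction errors (percent) and the standard error of the
    estimate, SEE = sqrt(mean of squared residuals (pred - exp)), in N.

    Relative errors are also reported rounded to the nearest integer percent.
    SEE requires at least 2 pairs.
    """
    p = np.asarray(predicted, dtype=float).ravel()
    e = np.asarray(experimental, dtype=float).ravel()
    if len(p) != len(e) or len(p) < 1:
        raise ValueError("predicted and experimental must have equal length >= 1")
    if (e == 0).any():
        raise ValueError("experimental strength of 0 N")
    rel = (p - e) / e * 100.0
    out = {
        "relative_errors_pct": rel,
        "relative_errors_rounded": np.round(rel).astype(int),
    }
    if len(p) >= 2:
        out["see"] = float(np.sqrt(((p - e) ** 2).mean()))
    return out


def shape_error(nodes: np.ndarray, surface: Surface):
    """Unsigned point-to-surface distances with mean / 95th percentile / max."""
    _, dist, _ = surface.on_surface(np.atleast_2d(nodes))
    return dist, {
        "mean": float(dist.mean()),
        "p95": float(np.percentile(dist, 95)),
        "max": float(dist.max()),
    }


def _tet_volume_below(verts: np.ndarray, s: np.ndarray) -> float:
    """Volume of the part of a tet where the signed distance s <= 0."""
    v = abs(np.linalg.det(verts[1:] - verts[0])) / 6.0
    neg = s <= 0
    if neg.all():
        return v
    if not neg.any():
        return 0.0
    pts = [verts[i] for i in range(4) if neg[i]]
    for i in range(4):
        for j in range(i + 1, 4):
            if neg[i] != neg[j]:
                t = s[i] / (s[i] - s[j])
                pts.append(verts[i] + t * (verts[j] - verts[i]))
    try:
        return float(ConvexHull(np.array(pts)).volume)
    except Exception:  # degenerate sliver
        return 0.0


def slab_volume(mesh: TetMesh, origin, axis, lo: float, hi: float) -> float:
    """Exact mesh volume between two parallel planes perpendicular to
    ``axis`` at offsets lo and hi (mm) from ``origin``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    d = (mesh.nodes - np.asarray(origin)) @ axis
    ds = d[mesh.elements]
    vols = element_volumes(mesh)
    total = 0.0
    inside_hi = ds <= hi
    inside_lo = ds <= lo
    full = inside_hi.all(axis=1) & ~inside_lo.any(axis=1)
    total += vols[full].sum()
    straddle = np.flatnonzero(~full & inside_hi.any(axis=1) & ~inside_lo.all(axis=1))
    for e in straddle:
        verts = mesh.nodes[mesh.elements[e]]
        v_hi = _tet_volume_below(verts, ds[e] - hi)
        v_lo = _tet_volume_below(verts, ds[e] - lo)
        total += v_hi - v_lo
    return float(total)


def neck_volume_diff(mesh_a: TetMesh, mesh_b: TetMesh, origin, axis,
                     span: tuple) -> float:
    """Percent volume change of mesh A relative to mesh B inside the neck
    slab delimited by two planes perpendicular to the neck axis.

    Positive values mean A (the reconstruction) is bigger.
    """
    lo, hi = span
    va = slab_volume(mesh_a, origin, axis, lo, hi)
    vb = slab_volume(mesh_b, origin, axis, lo, hi)
    if vb <= 0:
        raise ValueError("empty neck slab in reference mesh")
    return 100.0 * (va - vb) / vb
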