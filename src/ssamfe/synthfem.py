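"""Deterministic synthetic proximal-femur family.

A femur-like solid — cylindrical shaft, frustum-like neck at a configurable
neck-shaft angle, spherical head — is swept as a generalized cylinder along a
smoothly bent centerline and tet-meshed once; family members are produced by
re-evaluating the same parametric map at different latent parameters, so all
members share the template connectivity and node correspondence is exact by
construction. Densities follow a cortical-shell / trabecular-interior
structure with a smooth radial blend.

Seven latent parameters drive the family: head radius, neck length,
neck-shaft angle, shaft radius, cortical thickness, trabecular density level
and cortical density level.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .drr import ArealBMDImage, GridSpec, Pose, project_areal_bmd, write_image
from .mesh import DensityField, TetMesh, write_mesh

logger = logging.getLogger(__name__)

__all__ = ["FamilySpec", "DeviceProfile", "FemurParams", "PRODIGY", "IDXA",
           "generate_femur", "generate_family", "synth_dxa",
           "make_fixture_suite"]


@dataclass(frozen=True)
class FemurParams:
    """Latent geometric and density parameters of one synthetic femur."""

    head_radius: float = 22.0          # mm
    neck_length: float = 30.0          # mm
    neck_shaft_angle: float = 125.0    # deg
    shaft_radius: float = 14.0         # mm
    cortical_thickness: float = 4.0    # mm
    trabecular_density: float = 0.30   # g/cm^3 apparent
    cortical_density: float = 1.70     # g/cm^3 apparent
    shaft_length: float = 70.0         # mm, fixed across the family


@dataclass
class FamilySpec:
    """Family definition: member count, latent ranges, resolution, seed."""

    n_members: int = 10
    seed: int = 0
    head_radius: tuple = (19.0, 25.0)
    neck_length: tuple = (25.0, 35.0)
    neck_shaft_angle: tuple = (118.0, 132.0)
    shaft_radius: tuple = (12.0, 16.0)
    cortical_thickness: tuple = (2.5, 5.5)
    trabecular_density: tuple = (0.20, 0.40)
    cortical_density: tuple = (1.55, 1.85)
    n_axial: int = 22
    n_ring: int = 3
    n_theta: int = 12

    def __post_init__(self):
        for name in ("head_radius", "neck_length", "neck_shaft_angle",
                     "shaft_radius", "cortical_thickness",
                     "trabecular_density", "cortical_density"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range for {name}")


@dataclass(frozen=True)
class DeviceProfile:
    """DXA-device emulation: pixel geometry and additive image noise."""

    name: str
    pixel_size: tuple
    noise_sd: float = 0.0   # g/cm^2

    def __post_init__(self):
        if min(self.pixel_size) <= 0 or self.noise_sd < 0:
            raise ValueError("pixel sizes must be > 0 and noise >= 0")


PRODIGY = DeviceProfile("prodigy", (1.05, 0.60), 0.015)
IDXA = DeviceProfile("idxa", (0.25, 0.30), 0.025)


# ---------------------------------------------------------------- geometry --


def _disk_triangulation(n_ring: int, n_theta: int):
    """Node layout and triangles of the cross-section disk.

    Node 0 is the center; ring j (1..n_ring) holds n_theta nodes at radial
    fraction j / n_ring. Returns (radial fractions, angles, triangles).
    """
    frac = [0.0]
    theta = [0.0]
    for j in range(1, n_ring + 1):
        for k in range(n_theta):
            frac.append(j / n_ring)
            theta.append(2 * np.pi * k / n_theta)
    tri = []
    ring = lambda j, k: 1 + (j - 1) * n_theta + (k % n_theta)
    for k in range(n_theta):
        tri.append((0, ring(1, k), ring(1, k + 1)))
    for j in range(1, n_ring):
        for k in range(n_theta):
            a, b = ring(j, k), ring(j, k + 1)
            c, d = ring(j + 1, k), ring(j + 1, k + 1)
            tri.append((a, d, b))
            tri.append((a, c, d))
    return np.array(frac), np.array(theta), np.array(tri, dtype=np.int64)


def _split_prism(bottom, top):
    """Dompierre's consistent prism-to-3-tets split (min-vertex rule)."""
    v = list(bottom) + list(top)
    rotations = [
        (0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4),
        (3, 5, 4, 0, 2, 1), (4, 3, 5, 1, 0, 2), (5, 4, 3, 2, 1, 0),
    ]
    for perm in rotations:
        if v[perm[0]] == min(v):
            w = [v[i] for i in perm]
            break
    if min(w[1], w[5]) < min(w[2], w[4]):
        return [(w[0], w[1], w[2], w[5]), (w[0], w[1], w[5], w[4]),
                (w[0], w[4], w[5], w[3])]
    return [(w[0], w[1], w[2], w[4]), (w[0], w[4], w[2], w[5]),
            (w[0], w[4], w[5], w[3])]


def _centerline(params: FemurParams, n_axial: int, blend: float = 12.0):
    """Stations along the bent centerline.

    Returns positions (S,3), tangents, in-plane normals e1, out-of-plane e2
    (the +y axis), arc-length u per station and total neck-axis geometry.
    """
    beta = np.deg2rad(180.0 - params.neck_shaft_angle)   # tilt from +z
    d_shaft = np.array([0.0, 0.0, 1.0])
    d_neck = np.array([np.sin(beta), 0.0, np.cos(beta)])
    rn = 0.65 * params.head_radius                       # neck radius
    head_extra = np.sqrt(max(params.head_radius ** 2 - rn ** 2, 0.0)) \
        + params.head_radius
    total = params.shaft_length + params.neck_length + head_extra
    u = np.linspace(0.0, total, n_axial)
    pos = np.zeros((n_axial, 3))
    tan = np.zeros((n_axial, 3))
    p = np.zeros(3)
    prev_u = 0.0
    for i, ui in enumerate(u):
        # integrate direction over [prev_u, ui] in small steps
        steps = max(1, int(np.ceil((ui - prev_u) / 0.5)))
        for t in np.linspace(prev_u, ui, steps + 1)[1:]:
            frac = np.clip(
                (t - (params.shaft_length - blend)) / (2 * blend), 0.0, 1.0
            )
            ang = frac * beta
            d = np.array([np.sin(ang), 0.0, np.cos(ang)])
            p = p + d * (ui - prev_u) / steps
        frac = np.clip(
            (ui - (params.shaft_length - blend)) / (2 * blend), 0.0, 1.0
        )
        ang = frac * beta
        pos[i] = p
        tan[i] = [np.sin(ang), 0.0, np.cos(ang)]
        prev_u = ui
    e2 = np.tile([0.0, 1.0, 0.0], (n_axial, 1))
    e1 = np.cross(e2, tan)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    return pos, tan, e1, e2, u, total, d_neck, rn


def _radius_profile(params: FemurParams, u: np.ndarray, total: float,
                    rn: float) -> np.ndarray:
    """Local cross-section radius along arc length."""
    ls, ln = params.shaft_length, params.neck_length
    rh = params.head_radius
    c = ls + ln + np.sqrt(max(rh ** 2 - rn ** 2, 0.0))   # head sphere center
    r = np.empty_like(u)
    taper = 12.0                                         # shaft->neck blend mm
    for i, ui in enumerate(u):
        if ui <= ls - taper:
            r[i] = params.shaft_radius
        elif ui <= ls:
            t = (ui - (ls - taper)) / taper
            s = t * t * (3 - 2 * t)                      # smoothstep
            r[i] = (1 - s) * params.shaft_radius + s * rn
        elif ui <= ls + ln:
            r[i] = rn
        else:
            r[i] = np.sqrt(max(rh ** 2 - (ui - c) ** 2, 0.25))
    return np.maximum(r, 0.5)


def generate_femur(params: FemurParams, n_axial: int = 22, n_ring: int = 3,
                   n_theta: int = 12):
    """Build one synthetic femur: ``(TetMesh, DensityField)``.

    The mesh carries node set ``distal_cut`` (the flat distal cross-section)
    and element sets ``neck`` and ``head``. Connectivity depends only on the
    resolution, so members built at the same resolution correspond exactly.
    """
    frac, theta, tris = _disk_triangulation(n_ring, n_theta)
    pos, tan, e1, e2, u, total, d_neck, rn = _centerline(params, n_axial)
    radius = _radius_profile(params, u, total, rn)
    npd = len(frac)                                     # nodes per disk
    nodes = np.empty((n_axial * npd, 3))
    node_frac = np.empty(n_axial * npd)
    node_station = np.empty(n_axial * npd, dtype=np.int64)
    for i in range(n_axial):
        offs = (frac * radius[i])[:, None] * (
            np.cos(theta)[:, None] * e1[i] + np.sin(theta)[:, None] * e2[i]
        )
        nodes[i * npd : (i + 1) * npd] = pos[i] + offs
        node_frac[i * npd : (i + 1) * npd] = frac
        node_station[i * npd : (i + 1) * npd] = i

    elements = []
    for i in range(n_axial - 1):
        lo, hi = i * npd, (i + 1) * npd
        for t in tris:
            elements.extend(_split_prism([lo + a for a in t],
                                         [hi + a for a in t]))
    elements = np.array(elements, dtype=np.int64)

    # density: cortical shell over trabecular interior, smooth radial blend
    ef = node_frac[elements].mean(axis=1)
    est = node_station[elements].mean(axis=1)
    er = np.interp(est, np.arange(n_axial), radius)
    if params.cortical_thickness <= 0:
        rho = np.full(len(elements), params.trabecular_density)
    else:
        shell_frac = 1.0 - params.cortical_thickness / er
        w = np.clip((ef - shell_frac) / np.maximum(1.0 - shell_frac, 1e-9),
                    0.0, 1.0)
        w = w * w * (3 - 2 * w)
        rho = params.trabecular_density + w * (
            params.cortical_density - params.trabecular_density
        )

    eu = np.interp(est, np.arange(n_axial), u)
    ls, ln = params.shaft_length, params.neck_length
    esets = {
        "neck": np.flatnonzero((eu > ls) & (eu <= ls + ln)),
        "head": np.flatnonzero(eu > ls + ln),
    }
    nsets = {"distal_cut": np.arange(npd, dtype=np.int64)}
    mesh = TetMesh(nodes, elements, node_sets=nsets, element_sets=esets)
    return mesh, DensityField(rho, kind="rho_app")


def _sample_params(spec: FamilySpec, rng: np.random.Generator) -> FemurParams:
    draw = lambda rg: float(rng.uniform(*rg))
    return FemurParams(
        head_radius=draw(spec.head_radius),
        neck_length=draw(spec.neck_length),
        neck_shaft_angle=draw(spec.neck_shaft_angle),
        shaft_radius=draw(spec.shaft_radius),
        cortical_thickness=draw(spec.cortical_thickness),
        trabecular_density=draw(spec.trabecular_density),
        cortical_density=draw(spec.cortical_density),
    )


def generate_family(spec: FamilySpec):
    """Generate the corresponded synthetic family.

    Returns ``(members, latents)``: a list of ``(TetMesh, DensityField)``
    sharing connectivity, and the :class:`FemurParams` of each member.
    Deterministic in the seed. Raises if a parameter combination produces
    inverted elements (checked after canonical orientation: element count
    mismatch would indicate construction failure).
    """
    rng = np.random.default_rng(spec.seed)
    members, latents = [], []
    conn = None
    for m in range(spec.n_members):
        params = _sample_params(spec, rng)
        mesh, dens = generate_femur(params, spec.n_axial, spec.n_ring,
                                    spec.n_theta)
        from .mesh import element_volumes

        if (element_volumes(mesh) <= 0).any():
            raise ValueError(f"family member {m} has degenerate elements "
                             f"(params {params})")
        if conn is None:
            conn = mesh.elements
        members.append((mesh, dens))
        latents.append(params)
    return members, latents


def neck_axis(params: FemurParams):
    """Origin, direction and along-axis span of the neck region of a member
    (used to place the neck-slab cutting planes)."""
    beta = np.deg2rad(180.0 - params.neck_shaft_angle)
    d = np.array([np.sin(beta), 0.0, np.cos(beta)])
    # neck starts roughly where the centerline leaves the shaft
    origin = np.array([0.0, 0.0, params.shaft_length])
    return origin, d, (2.0, params.neck_length - 2.0)


# ------------------------------------------------------------------ images --


def synth_dxa(
    member: tuple,
    profile: DeviceProfile,
    pose: Pose | None = None,
    seed: int = 0,
    margin: float = 4.0,
) -> ArealBMDImage:
    """Synthetic DXA-like reference image of a family member: DRR on the
    device's pixel grid plus seeded additive Gaussian noise, clipped at 0."""
    mesh, dens = member
    nodes = pose.apply(mesh.nodes) if pose else mesh.nodes
    grid = GridSpec.covering(nodes[mesh.elements.ravel()][:, [0, 2]],
                             profile.pixel_size, margin=margin)
    img = project_areal_bmd(mesh, dens, pose=pose, grid=grid)
    if profile.noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = img.values + rng.normal(0.0, profile.noise_sd, img.values.shape)
        img = ArealBMDImage(np.maximum(noisy, 0.0), img.grid, img.axis)
    return img


def make_fixture_suite(out_dir, seed: int = 0, spec: FamilySpec | None = None):
    """Write a complete on-disk input set: training family, one held-out
    target, reference images at both device profiles, config and a manifest
    with content hashes. Returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec or FamilySpec(n_members=11, seed=seed)
    members, latents = generate_family(spec)
    train, target = members[:-1], members[-1]
    files = {}

    for i, (mesh, dens) in enumerate(train):
        p = out / f"train_{i:02d}.vtk"
        write_mesh(mesh, p, density=dens)
        files[p.name] = p
    p = out / "target.vtk"
    write_mesh(target[0], p, density=target[1])
    files[p.name] = p

    for profile in (PRODIGY, IDXA):
        img = synth_dxa(target, profile, seed=seed + 1)
        p = out / f"reference_{profile.name}.tiff"
        write_image(img, p)
        files[p.name] = p
        files[p.name + ".json"] = p.with_suffix(".tiff.json")

    origin, direction, span = neck_axis(latents[-1])
    config = {
        "seed": seed,
        "body_weight_kg": 75.0,
        "n_train": len(train),
        "held_out": "target.vtk",
        "neck_region": {
            "origin_mm": origin.tolist(),
            "axis": direction.tolist(),
            "span_mm": list(span),
        },
        "device_profiles": {
            pr.name: {"pixel_size_mm": list(pr.pixel_size),
                      "noise_sd_g_cm2": pr.noise_sd}
            for pr in (PRODIGY, IDXA)
        },
    }
    cfg_path = out / "config.json"
    cfg_path.write_text(json.dumps(config, indent=1))
    files[cfg_path.name] = cfg_path

    manifest = {
        name: hashlib.sha256(Path(path).read_bytes()).hexdigest()
        for name, path in sorted(files.items())
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
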