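"""2D-3D reconstruction: register the SSAM to a reference areal-BMD image
with a genetic algorithm.

The cost is the sum of three components: the sum of absolute differences
(SAD) of areal BMD between the instance's DRR and the reference image, a
mesh-quality term (mean-ratio metric), and an anatomical-positioning term.
Each term is normalized by its value at the mean-shape / identity-pose
initialization so the terms start comparable; default weights (1, 0.1, 0.1).

The positioning term is a stand-in for the one used with clinical images
(defined only in prior work): squared in-image tilt of the shaft axis away
from vertical plus squared in-plane offset of the mass centroid from the
reference image's mass centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .drr import ArealBMDImage, Pose, image_sad, project_areal_bmd
from .mesh import element_volumes, mean_ratio_quality
from .ssam import SSAModel, instantiate

logger = logging.getLogger(__name__)

__all__ = ["ReconstructionParams", "CostBreakdown", "GAConfig", "cost",
           "reconstruct_ga", "term_normalizers"]

INVERTED_PENALTY = 1.0e3


@dataclass
class ReconstructionParams:
    """Mode weights (standard scores) + rigid pose + optional uniform scale."""

    b: np.ndarray
    rotation: tuple = (0.0, 0.0, 0.0)
    translation: tuple = (0.0, 0.0, 0.0)
    scale: float = 1.0

    def pose(self) -> Pose:
        return Pose(tuple(self.rotation), tuple(self.translation), self.scale)


@dataclass
class CostBreakdown:
    sad: float
    quality: float
    positioning: float
    weights: tuple = (1.0, 0.1, 0.1)

    @property
    def total(self) -> float:
        w = self.weights
        return w[0] * self.sad + w[1] * self.quality + w[2] * self.positioning


@dataclass
class GAConfig:
    """Generational GA: tournament selection (size 3), SBX crossover,
    per-gene Gaussian mutation, elitism 1."""

    population: int = 60
    generations: int = 80
    crossover_rate: float = 0.9
    sbx_eta: float = 10.0
    mutation_rate: float = 0.15
    mutation_sigma: float = 0.15      # fraction of each gene's range (initial)
    mutation_sigma_final: float = 0.01  # annealed to this by the last generation
    tournament: int = 3
    elitism: int = 1
    mode_bound: float = 3.0           # |b| <= 3 standard scores
    rotation_bound: float = 0.35      # rad
    translation_bound: float = 20.0   # mm
    scale_bounds: tuple = (0.9, 1.1)
    fit_pose: bool = True
    fit_scale: bool = False
    drr_nsub: int = 3


def _quality_penalty(mesh) -> float:
    p = mesh.nodes[mesh.elements]
    v = np.linalg.det(p[:, 1:] - p[:, :1]) / 6.0
    frac_inverted = float((v <= 0).mean())
    eta = mean_ratio_quality(mesh)
    return float((1.0 - eta).mean()) + INVERTED_PENALTY * frac_inverted


def _image_mass_centroid(ref: ArealBMDImage) -> np.ndarray:
    u, v = ref.pixel_centers()
    w = ref.values
    total = w.sum()
    if total <= 0:
        return np.array([u.mean(), v.mean()])
    cu = (w.sum(axis=0) * u).sum() / total
    cv = (w.sum(axis=1) * v).sum() / total
    return np.array([cu, cv])


def _positioning_penalty(mesh, density, ref: ArealBMDImage) -> float:
    nodes = mesh.nodes
    c = nodes.mean(axis=0)
    _, _, vt = np.linalg.svd(nodes - c, full_matrices=False)
    axis = vt[0]
    tilt = np.arctan2(abs(axis[0]), abs(axis[2]))  # in-image tilt from vertical
    vols = element_volumes(mesh)
    w = density.values * vols
    cen = (
        (mesh.nodes[mesh.elements].mean(axis=1) * w[:, None]).sum(axis=0)
        / max(w.sum(), 1e-12)
    )
    d = np.array([cen[0], cen[2]]) - _image_mass_centroid(ref)
    return float(tilt ** 2 + (d @ d) / 100.0)


def cost(
    params: ReconstructionParams,
    model: SSAModel,
    ref: ArealBMDImage,
    weights: tuple = (1.0, 0.1, 0.1),
    normalizers: tuple = (1.0, 1.0, 1.0),
    nsub: int = 3,
) -> CostBreakdown:
    """Evaluate the three-term registration cost (deterministic).

    Instances with inverted elements receive a large finite quality penalty,
    never an exception, so GA ranking stays consistent.
    """
    mesh, dens = instantiate(model, params.b)
    pose = params.pose()
    posed = mesh.copy()
    posed.nodes = pose.apply(mesh.nodes)
    drr = project_areal_bmd(mesh, dens, pose=pose, grid=ref.grid, nsub=nsub,
                            warn_clip=False)
    sad = image_sad(ref, drr) / normalizers[0]
    q = _quality_penalty(posed) / normalizers[1]
    pos = _positioning_penalty(posed, dens, ref) / normalizers[2]
    return CostBreakdown(sad, q, pos, weights)


def term_normalizers(model: SSAModel, ref: ArealBMDImage, nsub: int = 3) -> tuple:
    """Term scales: the raw cost terms at mean shape / identity pose (terms
    that vanish there keep scale 1)."""
    raw = cost(
        ReconstructionParams(np.zeros(model.n_modes)), model, ref, nsub=nsub
    )
    return tuple(t if t > 1e-12 else 1.0 for t in (raw.sad, raw.quality,
                                                   raw.positioning))


def _bounds(model: SSAModel, cfg: GAConfig):
    lo = [-cfg.mode_bound] * model.n_modes
    hi = [cfg.mode_bound] * model.n_modes
    if cfg.fit_pose:
        lo += [-cfg.rotation_bound] * 3 + [-cfg.translation_bound] * 3
        hi += [cfg.rotation_bound] * 3 + [cfg.translation_bound] * 3
    if cfg.fit_scale:
        lo.append(cfg.scale_bounds[0])
        hi.append(cfg.scale_bounds[1])
    return np.array(lo), np.array(hi)


def _decode(x: np.ndarray, model: SSAModel, cfg: GAConfig) -> ReconstructionParams:
    m = model.n_modes
    b = x[:m]
    rot = (0.0, 0.0, 0.0)
    trans = (0.0, 0.0, 0.0)
    scale = 1.0
    i = m
    if cfg.fit_pose:
        rot = tuple(x[i : i + 3])
        trans = tuple(x[i + 3 : i + 6])
        i += 6
    if cfg.fit_scale:
        scale = float(x[i])
    return ReconstructionParams(b, rot, trans, scale)


def _sbx(rng, p1, p2, lo, hi, eta):
    u = rng.random(len(p1))
    beta = np.where(
        u <= 0.5,
        (2 * u) ** (1.0 / (eta + 1)),
        (1.0 / (2 * (1 - u))) ** (1.0 / (eta + 1)),
    )
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def reconstruct_ga(
    model: SSAModel,
    ref: ArealBMDImage,
    ga_config: GAConfig = GAConfig(),
    seed: int = 0,
    weights: tuple = (1.0, 0.1, 0.1),
):
    """Genetic-algorithm registration of the SSAM to a reference image.

    Returns ``(best_params, best_cost_breakdown, trace)`` where ``trace`` is
    the best total cost after each generation (non-increasing). Identical
    seed and config give identical results.
    """
    if ga_config.population < 2 or ga_config.generations < 1:
        raise ValueError("population >= 2 and generations >= 1 required")
    rng = np.random.default_rng(seed)
    lo, hi = _bounds(model, ga_config)
    norms = term_normalizers(model, ref, nsub=ga_config.drr_nsub)

    def evaluate(x):
        return cost(_decode(x, model, ga_config), model, ref, weights, norms,
                    nsub=ga_config.drr_nsub)

    pop = rng.uniform(lo, hi, size=(ga_config.population, len(lo)))
    # informed initialization: the mean shape plus +-1 standard-score
    # single-mode perturbations, then random fill
    seeds = [np.zeros(len(lo))]
    for i in range(model.n_modes):
        for s in (1.0, -1.0):
            e = np.zeros(len(lo))
            e[i] = s
            seeds.append(e)
    for i, s in enumerate(seeds[: ga_config.population]):
        pop[i] = np.clip(s, lo, hi)
    costs = [evaluate(x) for x in pop]
    totals = np.array([c.total for c in costs])
    best_i = int(np.argmin(totals))
    best_x, best_c = pop[best_i].copy(), costs[best_i]
    trace = [best_c.total]

    for gen in range(ga_config.generations):
        # geometric annealing of the mutation scale: explore early, then polish
        frac = gen / max(ga_config.generations - 1, 1)
        sigma = ga_config.mutation_sigma * (
            ga_config.mutation_sigma_final / ga_config.mutation_sigma
        ) ** frac
        order = np.arange(ga_config.population)
        new_pop = [best_x.copy() for _ in range(ga_config.elitism)]
        while len(new_pop) < ga_config.population:
            idx1 = rng.choice(order, size=ga_config.tournament, replace=False)
            idx2 = rng.choice(order, size=ga_config.tournament, replace=False)
            p1 = pop[idx1[np.argmin(totals[idx1])]]
            p2 = pop[idx2[np.argmin(totals[idx2])]]
            if rng.random() < ga_config.crossover_rate:
                c1, c2 = _sbx(rng, p1, p2, lo, hi, ga_config.sbx_eta)
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                mut = rng.random(len(child)) < ga_config.mutation_rate
                noise = rng.normal(0.0, sigma, len(child))
                child[mut] += (noise * (hi - lo))[mut]
                np.clip(child, lo, hi, out=child)
                if len(new_pop) < ga_config.population:
                    new_pop.append(child)
        pop = np.array(new_pop)
        costs = [evaluate(x) for x in pop]
        totals = np.array([c.total for c in costs])
        gen_best = int(np.argmin(totals))
        if totals[gen_best] < best_c.total:
            best_x, best_c = pop[gen_best].copy(), costs[gen_best]
        trace.append(best_c.total)

    return _decode(best_x, model, ga_config), best_c, trace
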