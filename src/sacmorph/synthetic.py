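"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of its parameters (seed included), so all
downstream stages are testable without imaging or recording data:

* :func:`gen_arbor` — radially symmetric SAC-like dendritic trees, with a
  control phenotype calibrated to ~115 branch points / ~4-5 mm total cable,
  and a *Pten*-KO phenotype with ~1.7x the branching and one hypertrophic
  primary dendrite, at unchanged field radius.
* :func:`gen_mosaic` — homogeneous Poisson vs hard-core (sequential
  inhibition) soma mosaics.
* :func:`gen_depth_profile` — two-band (S2/S4-like) IPL fluorescence depth
  profiles.
* :func:`gen_unit_responses` — Poisson spike counts over the 12-direction
  grating protocol, mixing von Mises-tuned and untuned units.
* :func:`gen_puncta` — synaptic puncta confined to the outer portion of an
  arbor, plus optional off-mask / undersized decoys.

Arbors grow in a plane (z jitter <= 1 um): SACs are planar and every
morphometric downstream is computed en face; the small z spread exercises the
self-crossing z-slab logic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .types import (
    DENDRITE,
    DIRECTION_GRID_DEG,
    SOMA,
    NeuriteTree,
    PointPattern,
    PunctaRecord,
    UnitResponse,
)


# ---------------------------------------------------------------------------
# dendritic arbors
# ---------------------------------------------------------------------------

@dataclass
class ArborParams:
    """Growth parameters for a synthetic SAC arbor.

    Growth combines per-segment stochastic bifurcation
    (``branch_prob_per_segment``) with space competition: a tip that extends
    into territory already occupied by other dendrites (foreign nodes within
    ``self_avoid_radius``) terminates with a crowding-dependent probability.
    Space competition saturates total cable at a tiling density set by the
    avoidance radius, so the branch-point count scales close to linearly
    with the bifurcation probability while total dendrite length moves only
    weakly — reproducing the dissociation in which doubled branching
    coexists with near-normal cable length and an unchanged field radius.
    Control defaults are calibrated to ~115 branch points and ~4-5 mm of
    total dendrite, typical of mouse SACs.
    """

    phenotype: str = "control"  # "control" | "pten_ko"
    n_primary: int = 4  # 3-5 primary dendrites
    field_radius: float = 120.0  # um
    mean_segment_length: float = 16.0  # um
    branch_prob_per_segment: float = 0.77  # calibrated; see class docstring
    ko_branch_multiplier: float = 1.7
    self_avoid_radius: float = 8.75  # um; crowding scale of dendrite tiling
    crowding_kill_prob: float = 0.6  # per nearby foreign node per segment
    crowded_branch_factor: float = 0.2  # branch prob multiplier per neighbour
    base_caliber: float = 0.6  # um diameter
    ko_hypertrophic_caliber: float = 1.4  # um diameter
    z_jitter: float = 1.0  # um; arbors are planar to within this
    angle_noise_sd: float = 0.20  # rad per segment
    branch_angle_mean: float = 0.55  # rad half-angle at bifurcations
    radial_bias: float = 0.30  # pull of growth direction toward outward radial
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_primary < 1:
            raise ValueError("n_primary must be >= 1")
        if self.field_radius <= 0:
            raise ValueError("field_radius must be > 0")
        if not 0 <= self.branch_prob_per_segment <= 1:
            raise ValueError("branch_prob_per_segment must be in [0, 1]")
        if not 0 <= self.crowding_kill_prob <= 1:
            raise ValueError("crowding_kill_prob must be in [0, 1]")
        if self.ko_branch_multiplier < 1:
            raise ValueError("ko_branch_multiplier must be >= 1")
        if self.phenotype not in ("control", "pten_ko"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


def _rot2(v: np.ndarray, ang: float) -> np.ndarray:
    c, s = math.cos(ang), math.sin(ang)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def gen_arbor(params: ArborParams) -> NeuriteTree:
    """Grow a radially symmetric SAC-like tree; deterministic given the seed.

    ``n_primary`` trunks leave the soma at evenly spaced angles (plus
    jitter); segments extend outward with angular noise and a mild radial
    bias, bifurcating stochastically until they pass ``field_radius``.  Node
    radii taper distally from ``base_caliber``.  The ``pten_ko`` phenotype
    multiplies the bifurcation probability by ``ko_branch_multiplier`` and
    makes one primary trunk hypertrophic (``ko_hypertrophic_caliber``),
    leaving the field radius unchanged.
    """
    rng = np.random.default_rng(params.seed)
    ko = params.phenotype == "pten_ko"
    p0 = params.branch_prob_per_segment * (params.ko_branch_multiplier if ko else 1.0)
    hyper_trunk = int(rng.integers(params.n_primary)) if ko else -1

    ids = [1]
    parents = [-1]
    xyz = [(0.0, 0.0, 0.0)]
    radii = [4.0]  # soma equivalent-circle radius, um
    kinds = [SOMA]
    next_id = 2

    base_r = params.base_caliber / 2.0
    hyper_r = params.ko_hypertrophic_caliber / 2.0

    def add_node(parent_id, pos, r):
        nonlocal next_id
        nid = next_id
        next_id += 1
        ids.append(nid)
        parents.append(parent_id)
        xyz.append(tuple(pos))
        radii.append(r)
        kinds.append(DENDRITE)
        return nid

    # tips: (parent_node_id, pos(3,), dir(2,), hypertrophic?, ancestry ids)
    tips = []
    base_ang = rng.uniform(0, 2 * math.pi)
    for k in range(params.n_primary):
        ang = base_ang + 2 * math.pi * k / params.n_primary + rng.normal(0, 0.10)
        d = np.array([math.cos(ang), math.sin(ang)])
        tips.append((1, np.zeros(3), d, k == hyper_trunk, (1,)))

    # uniform grid over node positions for crowding queries
    cell = max(params.self_avoid_radius, 1e-6)
    grid: dict[tuple[int, int], list[int]] = {}  # cell -> node indices

    def neighbours(xy: np.ndarray, exclude: set[int]) -> int:
        """Count foreign nodes within self_avoid_radius of a position."""
        gx, gy = int(xy[0] // cell), int(xy[1] // cell)
        r2 = params.self_avoid_radius**2
        n = 0
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for idx in grid.get((gx + dx, gy + dy), ()):
                    if ids[idx] in exclude:
                        continue
                    p = xyz[idx]
                    if (p[0] - xy[0]) ** 2 + (p[1] - xy[1]) ** 2 < r2:
                        n += 1
        return n

    max_nodes = 200_000
    while tips:
        new_tips = []
        for parent_id, pos, dvec, hyper, ancestry in tips:
            seg = rng.normal(params.mean_segment_length, 0.15 * params.mean_segment_length)
            seg = float(np.clip(seg, 0.4 * params.mean_segment_length,
                                1.6 * params.mean_segment_length))
            d = _rot2(dvec, rng.normal(0, params.angle_noise_sd))
            rho = math.hypot(pos[0], pos[1])
            if rho > 1e-9:
                radial = np.array([pos[0], pos[1]]) / rho
                d = (1 - params.radial_bias) * d + params.radial_bias * radial
                d = d / np.linalg.norm(d)
            new_xy = pos[:2] + seg * d
            new_z = float(np.clip(pos[2] + rng.normal(0, 0.25),
                                  -params.z_jitter, params.z_jitter))
            new_pos = np.array([new_xy[0], new_xy[1], new_z])
            new_rho = math.hypot(new_pos[0], new_pos[1])
            if hyper:
                r = hyper_r
            else:
                r = max(0.05, base_r * (1.0 - 0.5 * min(new_rho, params.field_radius)
                                        / params.field_radius))
            nid = add_node(parent_id, new_pos, r)
            idx = len(ids) - 1
            grid.setdefault((int(new_pos[0] // cell), int(new_pos[1] // cell)),
                            []).append(idx)
            if len(ids) > max_nodes:
                raise RuntimeError("arbor growth runaway: too many nodes")
            if new_rho >= params.field_radius:
                continue  # tip reached the dendritic field edge
            # space competition: crowded territory terminates the tip
            recent = set(ancestry[-4:]) | {nid}
            n_close = neighbours(new_pos[:2], recent)
            if n_close and rng.random() < 1 - (1 - params.crowding_kill_prob) ** n_close:
                continue
            lineage = ancestry + (nid,)
            # contact inhibition: branching is suppressed in crowded territory
            p_branch = p0 * params.crowded_branch_factor**n_close
            if rng.random() < p_branch:
                half = abs(rng.normal(params.branch_angle_mean, 0.12))
                for sgn in (+1, -1):
                    # hypertrophy is a property of the primary trunk only
                    new_tips.append(
                        (nid, new_pos, _rot2(d, sgn * half), False, lineage)
                    )
            else:
                new_tips.append((nid, new_pos, d, hyper, lineage))
        tips = new_tips

    return NeuriteTree(
        ids=np.array(ids),
        parent=np.array(parents),
        xyz=np.array(xyz),
        radius=np.array(radii),
        kind=np.array(kinds),
        metadata={"phenotype": params.phenotype, "seed": params.seed},
    )


# ---------------------------------------------------------------------------
# soma mosaics
# ---------------------------------------------------------------------------

@dataclass
class MosaicParams:
    """Parameters for synthetic soma point patterns."""

    mode: str = "exclusion"  # "random" | "exclusion"
    intensity: float = 700.0  # cells per mm^2
    exclusion_radius: float = 25.0  # um (hard-core distance, exclusion mode)
    window: tuple[float, float, float, float] = (0.0, 1000.0, 0.0, 1000.0)  # um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("intensity must be > 0")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be >= 0")
        if self.mode not in ("random", "exclusion"):
            raise ValueError(f"unknown mode {self.mode!r}")


def gen_mosaic(params: MosaicParams) -> PointPattern:
    """Generate a soma mosaic; deterministic given the seed.

    ``random`` draws a homogeneous Poisson realization; ``exclusion`` runs
    simple sequential inhibition (hard-core): candidates falling within
    ``exclusion_radius`` of an accepted point are rejected until the target
    count is reached.  Raises ``RuntimeError`` if the requested intensity
    cannot be packed after a bounded number of attempts.
    """
    rng = np.random.default_rng(params.seed)
    xmin, xmax, ymin, ymax = params.window
    area_mm2 = (xmax - xmin) * (ymax - ymin) / 1e6
    n_target = rng.poisson(params.intensity * area_mm2)
    if params.mode == "random" or params.exclusion_radius == 0:
        pts = np.column_stack([
            rng.uniform(xmin, xmax, n_target),
            rng.uniform(ymin, ymax, n_target),
        ])
        return PointPattern(points=pts, window=params.window)

    accepted: list[np.ndarray] = []
    r2 = params.exclusion_radius**2
    max_attempts = max(10_000, 200 * n_target)
    attempts = 0
    # coarse grid for neighbour lookup
    cell = max(params.exclusion_radius, 1e-6)
    grid: dict[tuple[int, int], list[int]] = {}
    while len(accepted) < n_target:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"exclusion packing infeasible: placed {len(accepted)}/{n_target} "
                f"after {attempts} attempts"
            )
        cand = np.array([rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)])
        gx, gy = int(cand[0] // cell), int(cand[1] // cell)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for idx in grid.get((gx + dx, gy + dy), ()):
                    if np.sum((accepted[idx] - cand) ** 2) < r2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((gx, gy), []).append(len(accepted))
            accepted.append(cand)
    return PointPattern(points=np.array(accepted), window=params.window)


# ---------------------------------------------------------------------------
# IPL depth profiles
# ---------------------------------------------------------------------------

def gen_depth_profile(
    band_centers: tuple[float, float] = (0.27, 0.62),
    band_sigma: float = 0.05,
    noise_sd: float = 0.02,
    amplitude: float = 1.0,
    n_samples: int = 400,
    ipl_bounds: tuple[float, float] = (0.0, 50.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Dense fluorescence-vs-position samples for a two-band IPL profile.

    Returns ``(positions, intensities, ipl_bounds)`` where positions run in
    source coordinates across the IPL span and intensity is a sum of Gaussian
    bands centred at the given normalized depths plus non-negative noise.
    Pass a single-element tuple for a unimodal profile.
    """
    for c in band_centers:
        if not 0 < c < 1:
            raise ValueError("band centers must lie in (0, 1)")
    if band_sigma <= 0:
        raise ValueError("band_sigma must be > 0")
    rng = np.random.default_rng(seed)
    lo, hi = ipl_bounds
    pos = np.linspace(lo, hi, n_samples)
    depth = (pos - lo) / (hi - lo)
    intensity = np.zeros_like(depth)
    for c in band_centers:
        intensity += amplitude * np.exp(-0.5 * ((depth - c) / band_sigma) ** 2)
    if noise_sd > 0:
        intensity = np.maximum(0.0, intensity + rng.normal(0, noise_sd, n_samples))
    return pos, intensity, ipl_bounds


# ---------------------------------------------------------------------------
# MEA unit responses
# ---------------------------------------------------------------------------

@dataclass
class UnitSimParams:
    """Mixture of von Mises-tuned and untuned Poisson units."""

    n_units: int = 100
    ds_fraction: float = 0.15
    kappa: float = 2.0
    preferred_deg: float | str = "uniform"  # fixed angle or "uniform"
    mean_preferred_spikes: float = 20.0  # spikes/epoch at preferred direction
    baseline_spikes: float = 2.0  # spikes/epoch far from preferred
    nonds_spikes: float = 5.0  # spikes/epoch of untuned units
    n_epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if min(self.mean_preferred_spikes, self.baseline_spikes, self.nonds_spikes) < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.ds_fraction <= 1:
            raise ValueError("ds_fraction must be in [0, 1]")


def vm_rate(theta_deg: np.ndarray, preferred_deg: float, kappa: float,
            peak: float, baseline: float) -> np.ndarray:
    """Von Mises tuning law: baseline + (peak-baseline) exp(kappa(cos d - 1))."""
    d = np.deg2rad(np.asarray(theta_deg, dtype=float) - preferred_deg)
    return baseline + (peak - baseline) * np.exp(kappa * (np.cos(d) - 1.0))


def gen_unit_responses(params: UnitSimParams) -> list[UnitResponse]:
    """Simulate per-unit spike-count tables; deterministic given the seed.

    DS units: counts ~ Poisson with the :func:`vm_rate` mean per epoch.
    Non-DS units: Poisson at a direction-independent rate.  Ground truth is
    stored in each unit's id (``ds`` / ``nds`` prefix) and returned order is
    DS first.
    """
    rng = np.random.default_rng(params.seed)
    n_ds = int(round(params.ds_fraction * params.n_units))
    units: list[UnitResponse] = []
    for i in range(params.n_units):
        is_ds = i < n_ds
        if is_ds:
            if params.preferred_deg == "uniform":
                mu = float(rng.uniform(0, 360))
            else:
                mu = float(params.preferred_deg)
            rates = vm_rate(DIRECTION_GRID_DEG, mu, params.kappa,
                            params.mean_preferred_spikes, params.baseline_spikes)
            uid = f"ds{i:03d}_mu{mu:.1f}"
        else:
            rates = np.full(12, params.nonds_spikes)
            uid = f"nds{i:03d}"
        counts = rng.poisson(rates, size=(params.n_epochs, 12))
        units.append(UnitResponse(unit_id=uid,
                                  directions=DIRECTION_GRID_DEG.astype(float),
                                  counts=counts))
    return units


# ---------------------------------------------------------------------------
# synaptic puncta
# ---------------------------------------------------------------------------

def gen_puncta(
    tree: NeuriteTree,
    n: int,
    inner_exclusion_fraction: float = 2.0 / 3.0,
    size_mean: float = 1.0,
    size_sd: float = 0.2,
    decoy_fraction: float = 0.0,
    seed: int = 0,
) -> list[PunctaRecord]:
    """Place puncta on the arbor beyond a normalized-radius exclusion zone.

    ``round(decoy_fraction * n)`` of the ``n`` records are decoys meant to be
    removed by downstream filtering: alternately off-mask (``in_mask=False``)
    or undersized (< 0.5 um); decoys are placed anywhere on the arbor.
    """
    if not 0 <= inner_exclusion_fraction < 1:
        raise ValueError("inner_exclusion_fraction must be in [0, 1)")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    edges = tree.edges()
    if len(edges) == 0:
        raise ValueError("tree has no dendritic edges to place puncta on")
    soma = tree.soma_xyz
    radial = tree.radial_distance()
    arbor_radius = float(radial.max())
    if arbor_radius <= 0:
        raise ValueError("degenerate tree: zero arbor radius")

    p0 = tree.xyz[edges[:, 0]]
    p1 = tree.xyz[edges[:, 1]]
    lengths = np.linalg.norm(p1 - p0, axis=1)
    w = lengths / lengths.sum()

    def sample_point(outer_only: bool) -> np.ndarray:
        for _ in range(5_000):
            e = rng.choice(len(edges), p=w)
            t = rng.random()
            pt = p0[e] + t * (p1[e] - p0[e])
            rho = np.linalg.norm(pt[:2] - soma[:2])
            if not outer_only or rho > inner_exclusion_fraction * arbor_radius:
                return pt
        raise ValueError(
            "no arbor points beyond the inner exclusion fraction"
        )
    # fail fast when the whole arbor is inside the exclusion zone
    if inner_exclusion_fraction > 0:
        rho1 = np.linalg.norm(p1[:, :2] - soma[:2], axis=1)
        if (rho1 <= inner_exclusion_fraction * arbor_radius).all():
            raise ValueError("no arbor points beyond the inner exclusion fraction")

    n_decoy = int(round(decoy_fraction * n))
    out: list[PunctaRecord] = []
    for i in range(n):
        decoy = i < n_decoy
        pt = sample_point(outer_only=not decoy)
        if decoy and i % 2 == 0:
            size = float(rng.uniform(0.1, 0.45))  # undersized, still in mask
            in_mask = True
        elif decoy:
            size = max(0.05, float(rng.normal(size_mean, size_sd)))
            in_mask = False
        else:
            size = max(0.5, float(rng.normal(size_mean, size_sd)))
            in_mask = True
        out.append(PunctaRecord(x=pt[0], y=pt[1], z=pt[2], size=size,
                                in_mask=in_mask))
    return out
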