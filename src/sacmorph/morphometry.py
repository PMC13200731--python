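"""Single-cell dendritic morphometrics for planar (en-face) reconstructions.

Conventions, chosen to match flat-mount confocal practice:

* Sholl circles are evaluated in the xy projection, not as 3D spheres, and
  an edge that re-enters a circle counts once per sign change of its radial
  distance.
* A *branch* is a maximal unbranched path between the soma, a branch point,
  or a tip; its *level* is 1 + the number of branch points strictly between
  it and the soma (primary dendrites are level 1).  The soma never counts
  as a branch point, however many trunks it bears.
* Branch caliber is the median node diameter along the branch — robust to
  tapering tips, and analogous to measuring one perpendicular line per
  dendrite.
* Self-crossings are edge pairs that properly intersect in xy while lying
  within a z tolerance of each other, emulating counts made in single
  z-planes of a stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .types import NeuriteTree


@dataclass
class Branch:
    """A maximal unbranched path; identified by its distal node id."""

    branch_id: int  # id of the distal endpoint (branch point or tip)
    node_indices: list[int]  # path nodes, proximal junction excluded
    level: int

    def caliber(self, tree: NeuriteTree) -> float:
        """Median node diameter (2 x radius) along the branch, um."""
        return float(np.median(2.0 * tree.radius[self.node_indices]))


@dataclass
class MorphometryReport:
    total_length: float
    n_branch_points: int
    branch_level_histogram: dict[int, int]
    sholl_radii: np.ndarray
    sholl_raw: np.ndarray
    sholl_normalized: np.ndarray  # 10 values
    field_area: float
    n_self_crossings: int
    hypertrophic: bool
    hypertrophic_branch_ids: list[int] = field(default_factory=list)
    soma_area: float | None = None

    def to_dict(self) -> dict:
        return {
            "total_length_um": self.total_length,
            "n_branch_points": self.n_branch_points,
            "branch_level_histogram": {
                str(k): v for k, v in sorted(self.branch_level_histogram.items())
            },
            "sholl_radii_um": self.sholl_radii.tolist(),
            "sholl_raw": self.sholl_raw.tolist(),
            "sholl_normalized": self.sholl_normalized.tolist(),
            "field_area_um2": self.field_area,
            "n_self_crossings": self.n_self_crossings,
            "hypertrophic": self.hypertrophic,
            "hypertrophic_branch_ids": self.hypertrophic_branch_ids,
            "soma_area_um2": self.soma_area,
        }


# ---------------------------------------------------------------------------
# basic morphometrics
# ---------------------------------------------------------------------------

def total_dendrite_length(tree: NeuriteTree) -> float:
    """Sum of Euclidean lengths of all parent-child edges, in micrometres."""
    e = tree.edges()
    if len(e) == 0:
        return 0.0
    return float(np.linalg.norm(tree.xyz[e[:, 0]] - tree.xyz[e[:, 1]], axis=1).sum())


def count_branch_points(tree: NeuriteTree) -> int:
    """Non-soma nodes with >= 2 children.

    The soma is excluded regardless of how many primary dendrites it bears:
    trunks leaving the soma do not create a branch point.
    """
    children = tree.children_map()
    root = tree.root_index
    return sum(1 for k, ch in children.items() if k != root and len(ch) >= 2)


def decompose_branches(tree: NeuriteTree) -> list[Branch]:
    """Split the tree into maximal unbranched paths with Imaris-style levels."""
    children = tree.children_map()
    root = tree.root_index
    is_bp = {k for k, ch in children.items() if k != root and len(ch) >= 2}
    branches: list[Branch] = []
    # walk from every junction (root or branch point) child-wards
    stack = [(c, 1) for c in children[root]]
    while stack:
        node, level = stack.pop()
        path = [node]
        while node not in is_bp and len(children[node]) == 1:
            node = children[node][0]
            path.append(node)
        branches.append(
            Branch(branch_id=int(tree.ids[node]), node_indices=path, level=level)
        )
        for c in children[node]:
            stack.append((c, level + 1))
    return branches


def branch_level_histogram(tree: NeuriteTree) -> dict[int, int]:
    """Count of branches per branch level (primary dendrites = level 1)."""
    hist: dict[int, int] = {}
    for b in decompose_branches(tree):
        hist[b.level] = hist.get(b.level, 0) + 1
    return hist


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------

def _edge_circle_crossings(p0: np.ndarray, p1: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Crossing counts of edges with circles of radii ``r`` about the origin.

    ``p0``, ``p1``: (m, 2) xy endpoints relative to the soma.  Returns an
    (m, len(r)) integer array.  A crossing is a sign change of the radial
    distance along the edge (inside -> outside or back); tangencies do not
    count.
    """
    d0 = np.linalg.norm(p0, axis=1)[:, None]  # (m, 1)
    d1 = np.linalg.norm(p1, axis=1)[:, None]
    seg = p1 - p0
    a = np.einsum("ij,ij->i", seg, seg)[:, None]  # |seg|^2
    b = 2.0 * np.einsum("ij,ij->i", p0, seg)[:, None]
    tstar = np.where(a > 0, -b / (2 * np.maximum(a, 1e-300)), 0.0)
    interior = (tstar > 0) & (tstar < 1)
    dmin_sq = np.where(
        interior,
        np.einsum("ij,ij->i", p0, p0)[:, None] - b**2 / (4 * np.maximum(a, 1e-300)),
        np.minimum(d0, d1) ** 2,
    )
    dmin = np.sqrt(np.maximum(dmin_sq, 0.0))
    r = np.asarray(r, dtype=float)[None, :]  # (1, k)
    # the circle itself belongs to the inside, so a node exactly on a circle
    # yields one crossing for the node's in/out edge pair, not zero or two
    in0, in1 = d0 <= r, d1 <= r
    one = in0 != in1
    two = ~in0 & ~in1 & (dmin < r)
    return one.astype(np.int64) + 2 * two.astype(np.int64)


def sholl_analysis(
    tree: NeuriteTree, step: float = 1.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sholl intersection counts at concentric circles about the soma.

    Circles are spaced ``step`` micrometres apart in the en-face (xy)
    projection.  Returns ``(radii, raw, normalized)`` where ``normalized``
    holds the mean raw count over each 10%-of-radial-distance bin
    (half-open intervals ``((k-1)R/10, kR/10]``; empty bins are 0), with
    the radial distance R taken as the maximum node distance from the soma.
    """
    rad = tree.radial_distance()
    R = float(rad.max())
    if R <= 0:
        raise ValueError("degenerate tree: zero radial extent")
    radii = np.arange(step, R + 1e-9, step)
    e = tree.edges()
    p0 = tree.xyz[e[:, 0], :2] - tree.soma_xyz[:2]
    p1 = tree.xyz[e[:, 1], :2] - tree.soma_xyz[:2]
    raw = _edge_circle_crossings(p0, p1, radii).sum(axis=0)
    normalized = np.zeros(10)
    for k in range(1, 11):
        lo, hi = (k - 1) * R / 10.0, k * R / 10.0
        sel = (radii > lo) & (radii <= hi)
        if sel.any():
            normalized[k - 1] = raw[sel].mean()
    return radii, raw, normalized


# ---------------------------------------------------------------------------
# field area, self-crossings, caliber, soma
# ---------------------------------------------------------------------------

def field_area_convex_hull(tree: NeuriteTree) -> float:
    """Area (um^2) of the 2D convex hull of all node xy positions."""
    pts = tree.xyz[:, :2]
    if len(pts) < 3:
        raise ValueError("need at least 3 nodes for a hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise ValueError(f"degenerate (collinear) node set: {e}") from None
    return float(hull.volume)  # 2D ConvexHull: volume == area


def count_self_crossings(tree: NeuriteTree, z_tolerance: float = 1.0) -> int:
    """Edge pairs that properly cross in xy within a z tolerance.

    Pairs sharing a node (parent/child or siblings at a branch point) are
    excluded; the crossing must be a proper interior intersection of the xy
    projections, and the two edges' interpolated z values at the crossing
    must differ by at most ``z_tolerance`` micrometres.
    """
    e = tree.edges()
    m = len(e)
    if m < 2:
        return 0
    P0 = tree.xyz[e[:, 0], :2]
    P1 = tree.xyz[e[:, 1], :2]
    Z0 = tree.xyz[e[:, 0], 2]
    Z1 = tree.xyz[e[:, 1], 2]
    ii, jj = np.triu_indices(m, k=1)
    # exclude pairs sharing any node
    share = (
        (e[ii, 0] == e[jj, 0]) | (e[ii, 0] == e[jj, 1])
        | (e[ii, 1] == e[jj, 0]) | (e[ii, 1] == e[jj, 1])
    )
    ii, jj = ii[~share], jj[~share]
    a0, a1 = P0[ii], P1[ii]
    b0, b1 = P0[jj], P1[jj]
    da = a1 - a0
    db = b1 - b0

    def cross(u, v):
        return u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]

    o1 = cross(da, b0 - a0)
    o2 = cross(da, b1 - a0)
    o3 = cross(db, a0 - b0)
    o4 = cross(db, a1 - b0)
    proper = (o1 * o2 < 0) & (o3 * o4 < 0)
    if not proper.any():
        return 0
    ii, jj = ii[proper], jj[proper]
    a0, da, b0, db = a0[proper], da[proper], b0[proper], db[proper]
    denom = cross(da, db)
    t = cross(b0 - a0, db) / denom
    u = cross(b0 - a0, da) / denom
    za = Z0[ii] + t * (Z1[ii] - Z0[ii])
    zb = Z0[jj] + u * (Z1[jj] - Z0[jj])
    return int(np.sum(np.abs(za - zb) <= z_tolerance))


def classify_hypertrophic(
    tree: NeuriteTree, caliber_threshold: float = 1.0
) -> tuple[bool, list[int]]:
    """Flag the cell if any branch caliber strictly exceeds the threshold.

    Returns ``(is_hypertrophic, flagged_branch_ids)``; the default 1 um
    threshold defines a hypertrophic dendrite.
    """
    flagged = [
        b.branch_id
        for b in decompose_branches(tree)
        if b.caliber(tree) > caliber_threshold
    ]
    return bool(flagged), flagged


def soma_area(polygon: np.ndarray) -> float:
    """Absolute shoelace area of a simple polygon (vertex order irrelevant)."""
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon must be (n>=3, 2) vertices")
    from shapely.geometry import Polygon

    if not Polygon(poly).is_valid:
        raise ValueError("self-intersecting polygon")
    x, y = poly[:, 0], poly[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def compute_report(
    tree: NeuriteTree,
    sholl_step: float = 1.0,
    z_tolerance: float = 1.0,
    caliber_threshold: float = 1.0,
) -> MorphometryReport:
    """Run the full per-cell morphometric battery."""
    radii, raw, norm = sholl_analysis(tree, step=sholl_step)
    hyper, hyper_ids = classify_hypertrophic(tree, caliber_threshold)
    return MorphometryReport(
        total_length=total_dendrite_length(tree),
        n_branch_points=count_branch_points(tree),
        branch_level_histogram=branch_level_histogram(tree),
        sholl_radii=radii,
        sholl_raw=raw,
        sholl_normalized=norm,
        field_area=field_area_convex_hull(tree),
        n_self_crossings=count_self_crossings(tree, z_tolerance),
        hypertrophic=hyper,
        hypertrophic_branch_ids=hyper_ids,
    )
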