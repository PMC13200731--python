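"""Shared domain containers for SAC population and single-cell analyses.

All coordinates are micrometres in a continuous, 0-based frame; nothing
downstream carries pixel or voxel semantics.  Trees follow SWC conventions:
a single soma root node and dendrite nodes, each with an equivalent-circle
radius.  Stimulus directions are motion directions in degrees,
counter-clockwise with 0 deg = +x, on the fixed 12 x 30 deg grid used by the
moving-grating protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

SOMA = 1
DENDRITE = 3

#: The 12 stimulus motion directions (degrees) of the grating protocol.
DIRECTION_GRID_DEG = np.arange(0, 360, 30)


class StructureError(ValueError):
    """Raised when a reconstruction violates tree invariants."""


class FormatError(ValueError):
    """Raised when a table or file does not match the expected layout."""


@dataclass
class NeuriteTree:
    """Rooted 3D dendritic reconstruction with per-node radii.

    Parameters
    ----------
    ids : (n,) int array of SWC node ids (need not be contiguous).
    parent : (n,) int array of parent ids, ``-1`` for the root.
    xyz : (n, 3) float array of node positions in micrometres.
    radius : (n,) float array of node radii in micrometres.
    kind : (n,) int array of SWC type codes (1 = soma, 3 = dendrite).
    metadata : free-form annotations (cell label, layer GCL|INL, genotype).
    """

    ids: np.ndarray
    parent: np.ndarray
    xyz: np.ndarray
    radius: np.ndarray
    kind: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.kind = np.asarray(self.kind, dtype=np.int64)
        self._index = {int(i): k for k, i in enumerate(self.ids)}

    # -- structural helpers -------------------------------------------------

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, node_id: int) -> int:
        return self._index[int(node_id)]

    @property
    def root_index(self) -> int:
        roots = np.flatnonzero(self.parent == -1)
        if len(roots) != 1:
            raise StructureError(f"expected exactly one root, found {len(roots)}")
        return int(roots[0])

    @property
    def soma_id(self) -> int:
        return int(self.ids[self.root_index])

    @property
    def soma_xyz(self) -> np.ndarray:
        return self.xyz[self.root_index]

    def parent_index(self) -> np.ndarray:
        """Per-node index of the parent node; -1 for the root."""
        out = np.full(len(self.ids), -1, dtype=np.int64)
        for k, p in enumerate(self.parent):
            if p != -1:
                out[k] = self._index[int(p)]
        return out

    def edges(self) -> np.ndarray:
        """(m, 2) array of (parent_index, child_index) for every non-root node."""
        pidx = self.parent_index()
        child = np.flatnonzero(pidx >= 0)
        return np.column_stack([pidx[child], child])

    def children_map(self) -> dict[int, list[int]]:
        """Node index -> list of child node indices."""
        out: dict[int, list[int]] = {k: [] for k in range(len(self.ids))}
        pidx = self.parent_index()
        for k, p in enumerate(pidx):
            if p >= 0:
                out[int(p)].append(k)
        return out

    def radial_distance(self, use_z: bool = False) -> np.ndarray:
        """Distance of every node from the soma (en-face xy by default)."""
        d = self.xyz - self.soma_xyz
        if not use_z:
            d = d[:, :2]
        return np.linalg.norm(d, axis=1)


def validate_tree(tree: NeuriteTree) -> list[str]:
    """Check all NeuriteTree invariants; return human-readable violations.

    An empty list means the tree is valid.  Violations name the node ids
    involved.  Nothing is raised: callers decide severity.
    """
    v: list[str] = []
    ids = tree.ids
    if len(ids) == 0:
        return ["tree has no nodes"]
    if len(set(ids.tolist())) != len(ids):
        v.append("duplicate node ids present")
    known = set(ids.tolist())
    roots = [int(i) for i, p in zip(ids, tree.parent) if p == -1]
    if len(roots) != 1:
        v.append(f"expected exactly one root, found {len(roots)}: {roots}")
    else:
        root_kind = tree.kind[tree._index[roots[0]]]
        if root_kind != SOMA:
            v.append(f"root node {roots[0]} is not a soma (type {int(root_kind)})")
    for i, p in zip(ids, tree.parent):
        if p != -1 and int(p) not in known:
            v.append(f"node {int(i)} references missing parent {int(p)}")
        if p == i:
            v.append(f"node {int(i)} is its own parent")
    for i, r in zip(ids, tree.radius):
        if not (r >= 0):
            v.append(f"node {int(i)} has negative radius {r}")
    if not np.all(np.isfinite(tree.xyz)):
        bad = ids[~np.all(np.isfinite(tree.xyz), axis=1)]
        v.append(f"non-finite coordinates at nodes {bad.tolist()}")
    # cycle / connectivity check by walking parent pointers
    if len(roots) == 1 and not any("missing parent" in s or "own parent" in s for s in v):
        for i in ids:
            seen = set()
            cur = int(i)
            while cur != -1:
                if cur in seen:
                    v.append(f"cycle detected through node {int(i)}: {sorted(seen)}")
                    return v
                seen.add(cur)
                cur = int(tree.parent[tree._index[cur]])
    return v


@dataclass
class PointPattern:
    """Soma centroids in a rectangular observation window (micrometres)."""

    points: np.ndarray  # (n, 2)
    window: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        xmin, xmax, ymin, ymax = self.window
        if not (xmax > xmin and ymax > ymin):
            raise ValueError("window must have positive area")
        if len(self.points):
            x, y = self.points[:, 0], self.points[:, 1]
            if (x < xmin).any() or (x > xmax).any() or (y < ymin).any() or (y > ymax).any():
                raise ValueError("points outside window")
            # duplicate check within 1e-9 um
            key = np.round(self.points / 1e-9).astype(np.int64)
            if len(np.unique(key, axis=0)) != len(key):
                raise ValueError("duplicate points within 1e-9 um")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def area_um2(self) -> float:
        xmin, xmax, ymin, ymax = self.window
        return (xmax - xmin) * (ymax - ymin)

    @property
    def area_mm2(self) -> float:
        return self.area_um2 / 1e6


@dataclass
class UnitResponse:
    """Per-unit spike counts across the 12-direction grating protocol."""

    unit_id: str
    directions: np.ndarray  # (12,) degrees, ascending from 0 in 30 deg steps
    counts: np.ndarray  # (n_epochs, 12) non-negative integers
    epoch_duration: float = 3.0  # seconds per direction presentation

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.directions.shape != (12,) or not np.array_equal(
            self.directions, DIRECTION_GRID_DEG
        ):
            raise FormatError(
                f"unit {self.unit_id}: directions must be 0,30,...,330"
            )
        if self.counts.ndim != 2 or self.counts.shape[1] != 12:
            raise FormatError(f"unit {self.unit_id}: counts must be (n_epochs, 12)")
        if self.counts.shape[0] < 1:
            raise FormatError(f"unit {self.unit_id}: need at least one epoch")
        if (self.counts < 0).any() or not np.issubdtype(self.counts.dtype, np.integer):
            ints = np.asarray(self.counts, dtype=float)
            if (ints < 0).any() or not np.allclose(ints, np.round(ints)):
                raise FormatError(
                    f"unit {self.unit_id}: counts must be non-negative integers"
                )
            self.counts = np.round(ints).astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)

    @property
    def n_epochs(self) -> int:
        return self.counts.shape[0]


@dataclass
class PunctaRecord:
    """A single synaptophysin punctum (Imaris surface centroid + size)."""

    x: float
    y: float
    z: float
    size: float  # largest surface diameter, micrometres
    in_mask: bool  # passed the membrane-GFP mask filter

    def __post_init__(self) -> None:
        if not self.size > 0:
            raise ValueError(f"punctum size must be > 0, got {self.size}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def volume(self) -> float:
        """Sphere-equivalent volume (um^3) from the diameter-like size field."""
        return math.pi / 6.0 * self.size**3
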