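"""Readers and writers for the plain-text carriers used across the pipeline.

SWC carries reconstructions (7 whitespace-separated columns:
``id type x y z radius parent``), RFC-4180 CSV carries unit spike tables,
soma point patterns and puncta tables, and JSON carries analysis reports.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .types import (
    DENDRITE,
    DIRECTION_GRID_DEG,
    SOMA,
    FormatError,
    NeuriteTree,
    PointPattern,
    PunctaRecord,
    StructureError,
    UnitResponse,
    validate_tree,
)

log = logging.getLogger("sacmorph.io")


def read_swc(path: str | Path) -> NeuriteTree:
    """Read a 7-column SWC reconstruction into a validated :class:`NeuriteTree`.

    Comment lines starting with ``#`` are ignored and node ids need not be
    contiguous.  Type codes other than 1 (soma) and 3 (dendrite) are accepted
    but mapped to dendrite with a logged warning — SACs are axonless, and all
    neurites are treated as dendrites throughout.
    """
    path = Path(path)
    ids, parents, xyzs, radii, kinds = [], [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise FormatError(
                    f"{path}:{lineno}: expected 7 columns, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                kind = int(parts[1])
                x, y, z, r = (float(p) for p in parts[2:6])
                parent = int(parts[6])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: malformed value ({e})") from None
            if kind not in (SOMA, DENDRITE):
                log.warning(
                    "%s:%d: SWC type %d mapped to dendrite", path, lineno, kind
                )
                kind = DENDRITE
            ids.append(nid)
            parents.append(parent)
            xyzs.append((x, y, z))
            radii.append(r)
            kinds.append(kind)
    if not ids:
        raise FormatError(f"{path}: no nodes")
    tree = NeuriteTree(
        ids=np.array(ids),
        parent=np.array(parents),
        xyz=np.array(xyzs),
        radius=np.array(radii),
        kind=np.array(kinds),
        metadata={"source": str(path)},
    )
    violations = validate_tree(tree)
    if violations:
        raise StructureError(f"{path}: " + "; ".join(violations))
    return tree


def write_swc(tree: NeuriteTree, path: str | Path) -> None:
    """Write a tree as standard 7-column SWC."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for i in range(len(tree)):
            fh.write(
                f"{int(tree.ids[i])} {int(tree.kind[i])} "
                f"{tree.xyz[i, 0]:.6f} {tree.xyz[i, 1]:.6f} {tree.xyz[i, 2]:.6f} "
                f"{tree.radius[i]:.6f} {int(tree.parent[i])}\n"
            )


def read_unit_table(path: str | Path) -> list[UnitResponse]:
    """Read a long-format CSV of spike counts into per-unit responses.

    Expected columns: ``unit_id, direction_deg, epoch, n_spikes``.  Every unit
    must cover the full 12 x 30-degree direction grid for every epoch; missing
    cells, off-grid directions, negative counts or ragged epochs raise
    :class:`FormatError`.
    """
    df = pd.read_csv(path)
    required = {"unit_id", "direction_deg", "epoch", "n_spikes"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    if (df["n_spikes"] < 0).any():
        raise FormatError(f"{path}: negative spike counts")
    if (df["direction_deg"] % 30 != 0).any() or (df["direction_deg"] >= 360).any() or (
        df["direction_deg"] < 0
    ).any():
        raise FormatError(f"{path}: directions must lie on the 0..330 30-degree grid")
    units: list[UnitResponse] = []
    for unit_id, g in df.groupby("unit_id", sort=False):
        pivot = g.pivot_table(
            index="epoch", columns="direction_deg", values="n_spikes", aggfunc="first"
        )
        if pivot.isna().any().any() or set(pivot.columns) != set(
            DIRECTION_GRID_DEG.tolist()
        ):
            raise FormatError(
                f"{path}: unit {unit_id} has missing (direction, epoch) cells"
            )
        pivot = pivot.sort_index(axis=0).reindex(columns=sorted(pivot.columns))
        units.append(
            UnitResponse(
                unit_id=str(unit_id),
                directions=DIRECTION_GRID_DEG.astype(float),
                counts=pivot.to_numpy(),
            )
        )
    return units


def write_unit_table(units: Iterable[UnitResponse], path: str | Path) -> None:
    rows = []
    for u in units:
        for e in range(u.n_epochs):
            for d in range(12):
                rows.append(
                    {
                        "unit_id": u.unit_id,
                        "direction_deg": int(u.directions[d]),
                        "epoch": e,
                        "n_spikes": int(u.counts[e, d]),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_points(path: str | Path) -> PointPattern:
    """Read soma xy coordinates with the sampling window in header comments.

    Layout: ``# window xmin xmax ymin ymax`` comment line followed by a CSV
    with columns ``x_um, y_um``.
    """
    path = Path(path)
    window = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "window":
                    window = tuple(float(v) for v in parts[1:5])
            else:
                break
    if window is None:
        raise FormatError(f"{path}: missing '# window xmin xmax ymin ymax' header")
    df = pd.read_csv(path, comment="#")
    if not {"x_um", "y_um"}.issubset(df.columns):
        raise FormatError(f"{path}: need columns x_um, y_um")
    return PointPattern(points=df[["x_um", "y_um"]].to_numpy(), window=window)


def write_points(pattern: PointPattern, path: str | Path) -> None:
    with open(path, "w") as fh:
        xmin, xmax, ymin, ymax = pattern.window
        fh.write(f"# window {xmin} {xmax} {ymin} {ymax}\n")
        fh.write("x_um,y_um\n")
        for x, y in pattern.points:
            fh.write(f"{x:.6f},{y:.6f}\n")


def read_puncta(path: str | Path) -> list[PunctaRecord]:
    """Read a puncta table (columns x_um, y_um, z_um, size_um, in_mask)."""
    df = pd.read_csv(path)
    required = {"x_um", "y_um", "z_um", "size_um", "in_mask"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    return [
        PunctaRecord(
            x=row.x_um, y=row.y_um, z=row.z_um, size=row.size_um,
            in_mask=bool(row.in_mask),
        )
        for row in df.itertuples()
    ]


def write_puncta(puncta: Iterable[PunctaRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"x_um": p.x, "y_um": p.y, "z_um": p.z, "size_um": p.size,
             "in_mask": p.in_mask}
            for p in puncta
        ]
    ).to_csv(path, index=False)


def write_report(report: dict, path: str | Path) -> None:
    """Write an analysis report as JSON (numpy scalars/arrays coerced)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=default)
        fh.write("\n")
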