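"""The coupling plane spanned by cQ and cTew.

Trajectories are projected onto the plane spanned by the dominant
quaternary mode (cQ) and the ensemble-weighted tertiary coupling mode
(cTew), anchored at the T-state reference.  The span of the projections
is divided equidistantly into ``n`` parts per axis (20 by default,
yielding a 20 x 20 = 400 cell grid covering all projected frames); each
cell centre is backprojected to a full structure

    x(a, b) = origin + a * cQ + b * cTew.

The L-shaped path from the T-state cell to the R-state cell — first
varying the cQ coordinate, then the cTew coordinate — artificially
separates motions that occur simultaneously in the data and is the path
along which contacts are profiled and classified.

Backprojection uses the linearised modes; the curvature of finite
rigid-body rotations is deliberately ignored (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .geometry import StructureFrame, Trajectory
from .modes import CollectiveMode, mode_overlap, project

__all__ = [
    "PlaneProjection",
    "CouplingGrid",
    "GridPath",
    "project_plane",
    "build_grid",
    "backproject",
    "make_path",
    "path_from_anchors",
]


@dataclass
class PlaneProjection:
    """Per-frame (a, b) plane coordinates in nm along (cQ, cTew)."""

    points: np.ndarray  # (F, 2)
    mode_a: CollectiveMode
    mode_b: CollectiveMode
    origin: np.ndarray  # (3N,) flattened origin structure
    anchors: dict[str, np.ndarray] | None = None  # e.g. {"T": (a,b), "R": (a,b)}

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if not np.all(np.isfinite(self.points)):
            raise DataError("plane projections contain non-finite values")


@dataclass
class CouplingGrid:
    """Equidistant n x n grid of cell centres covering the projections."""

    n_per_axis: int
    cell_centers: np.ndarray  # (n, n, 2); [i, j] -> (a_i, b_j)
    bounds: np.ndarray  # (2, 2); [axis, (min, max)]
    mode_a: CollectiveMode
    mode_b: CollectiveMode
    origin: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.n_per_axis**2

    def cell_of(self, point: np.ndarray) -> tuple[int, int]:
        """Grid cell containing a plane point (clipped to the grid)."""
        point = np.asarray(point, dtype=np.float64).reshape(2)
        out = []
        for ax in range(2):
            lo, hi = self.bounds[ax]
            step = (hi - lo) / self.n_per_axis
            i = int(np.floor((point[ax] - lo) / step))
            out.append(int(np.clip(i, 0, self.n_per_axis - 1)))
        return out[0], out[1]


@dataclass
class GridPath:
    """Ordered cells of the L-shaped cQ -> cTew path plus structures."""

    cells: list[tuple[int, int]]
    cell_coords: np.ndarray  # (L, 2)
    structures: list[StructureFrame]
    corner_index: int

    def __len__(self) -> int:
        return len(self.cells)


def project_plane(
    traj: Trajectory | np.ndarray,
    cq: CollectiveMode,
    ctew: CollectiveMode,
    origin: StructureFrame | np.ndarray,
    anchors: dict[str, StructureFrame] | None = None,
) -> PlaneProjection:
    """Project a trajectory onto the (cQ, cTew) plane.

    The two modes must be near-orthogonal; an overlap >= 0.5 leaves the
    plane ill-defined and raises.
    """
    ov = mode_overlap(cq, ctew)
    if ov >= 0.5:
        raise DataError(f"cQ/cTew overlap {ov:.2f} >= 0.5: plane ill-defined")
    origin_flat = origin.flat if isinstance(origin, StructureFrame) else np.asarray(origin).reshape(-1)
    cq_a = CollectiveMode(cq.vector, role=cq.role, origin=origin_flat)
    ctew_a = CollectiveMode(ctew.vector, role=ctew.role, origin=origin_flat)
    a = project(traj, cq_a).values
    b = project(traj, ctew_a).values
    anchor_points = None
    if anchors is not None:
        anchor_points = {
            name: np.array(
                [project(f, cq_a).values[0], project(f, ctew_a).values[0]]
            )
            for name, f in anchors.items()
        }
    return PlaneProjection(
        points=np.column_stack([a, b]),
        mode_a=cq_a,
        mode_b=ctew_a,
        origin=origin_flat,
        anchors=anchor_points,
    )


def build_grid(projection: PlaneProjection, n_per_axis: int = 20) -> CouplingGrid:
    """Divide the span of the projections into ``n_per_axis`` equal parts.

    Cell centres are the midpoints of the ``n_per_axis`` equal intervals
    between the minimal and maximal projection per axis, so every
    projected frame falls inside the bounds by construction.
    """
    if n_per_axis < 1:
        raise ConfigError("n_per_axis must be >= 1")
    pts = projection.points
    bounds = np.stack([pts.min(axis=0), pts.max(axis=0)], axis=1)  # (2, 2)
    if np.any(bounds[:, 1] - bounds[:, 0] <= 0):
        raise DataError("degenerate axis: projections have zero range")
    centers = np.empty((n_per_axis, n_per_axis, 2))
    axes = []
    for ax in range(2):
        lo, hi = bounds[ax]
        step = (hi - lo) / n_per_axis
        axes.append(lo + (np.arange(n_per_axis) + 0.5) * step)
    centers[..., 0] = axes[0][:, None]
    centers[..., 1] = axes[1][None, :]
    return CouplingGrid(
        n_per_axis=n_per_axis,
        cell_centers=centers,
        bounds=bounds,
        mode_a=projection.mode_a,
        mode_b=projection.mode_b,
        origin=projection.origin,
    )


def backproject(
    cell: np.ndarray | tuple[float, float],
    origin: StructureFrame,
    cq: CollectiveMode,
    ctew: CollectiveMode,
) -> StructureFrame:
    """Map a plane coordinate back to a full structure.

    ``coords = origin + a * cQ + b * cTew`` with the modes as unit
    3N-vectors; the result carries provenance ``backprojected``.
    """
    a, b = np.asarray(cell, dtype=np.float64).reshape(2)
    flat = origin.flat + a * cq.vector + b * ctew.vector
    return origin.with_coords(flat.reshape(-1, 3), provenance="backprojected")


def grid_structures(grid: CouplingGrid, template: StructureFrame) -> list[list[StructureFrame]]:
    """Backprojected structure for every grid cell ([i][j] indexing)."""
    return [
        [
            backproject(grid.cell_centers[i, j], template, grid.mode_a, grid.mode_b)
            for j in range(grid.n_per_axis)
        ]
        for i in range(grid.n_per_axis)
    ]


def make_path(
    grid: CouplingGrid,
    start_cell: tuple[int, int],
    end_cell: tuple[int, int],
    template: StructureFrame,
) -> GridPath:
    """L-shaped path from ``start_cell`` to ``end_cell``.

    The first leg varies the cQ index at constant cTew index, the second
    leg varies the cTew index; the corner cell is visited exactly once.
    The path visits ``|Δi| + |Δj| + 1`` cells, each backprojected to a
    full structure.
    """
    (i0, j0), (i1, j1) = start_cell, end_cell
    n = grid.n_per_axis
    for i, j in (start_cell, end_cell):
        if not (0 <= i < n and 0 <= j < n):
            raise DataError(f"cell ({i}, {j}) outside the {n} x {n} grid")
    cells: list[tuple[int, int]] = []
    step_i = 1 if i1 >= i0 else -1
    for i in range(i0, i1 + step_i, step_i):
        cells.append((i, j0))
    if j1 != j0:
        step_j = 1 if j1 > j0 else -1
        for j in range(j0 + step_j, j1 + step_j, step_j):
            cells.append((i1, j))
    corner_index = abs(i1 - i0)
    coords = np.array([grid.cell_centers[i, j] for i, j in cells])
    structures = [
        backproject(c, template, grid.mode_a, grid.mode_b) for c in coords
    ]
    return GridPath(
        cells=cells, cell_coords=coords, structures=structures,
        corner_index=corner_index,
    )


def path_from_anchors(
    grid: CouplingGrid,
    projection: PlaneProjection,
    template: StructureFrame,
    start: str = "T",
    end: str = "R",
) -> GridPath:
    """Path between the cells containing two anchor structures (T and R)."""
    if projection.anchors is None or start not in projection.anchors or end not in projection.anchors:
        raise DataError(f"projection lacks anchors {start!r} and {end!r}")
    return make_path(
        grid,
        grid.cell_of(projection.anchors[start]),
        grid.cell_of(projection.anchors[end]),
        template,
    )
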