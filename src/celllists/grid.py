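"""Sparse cell-list grids over particle point clouds.

A cell grid partitions the axis-aligned bounding box of a point cloud into
cubic cells whose edge length equals the interaction cutoff ``rc``.  Every
particle pair closer than ``rc`` then lies in the same cell or in two
Chebyshev-adjacent cells, which is what makes approximately linear-time pair
enumeration possible at bounded density (see :mod:`celllists.neighbors`).

Storage is sparse: only non-empty cells are recorded, in a hash map from the
linearised cell index to an ``(offset, length)`` segment of one shared,
contiguous storage array.  Construction follows a counting-sort pattern —
count particles per cell, reserve one segment per non-empty cell, then place
each particle's index into its segment in input order.  A single allocation
keeps spatially close particles close in memory, and the hash map keeps the
footprint proportional to the number of occupied cells (at most ``n``) rather
than to the bounding-box volume, which matters for sparsely populated or
coarse-grained systems with dynamic boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

__all__ = [
    "CellListError",
    "ValidationError",
    "EmptyCloudError",
    "OutOfBoundsError",
    "ConsistencyError",
    "PointCloud",
    "GridShape",
    "CellIndex",
    "CellGrid",
    "linearize",
    "delinearize",
    "compute_bounding_box",
    "cell_index",
    "build_grid",
    "rebuild",
    "grid_statistics",
]


# ---------------------------------------------------------------------------
# Errors

class CellListError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(CellListError, ValueError):
    """Invalid user input: bad coordinates, parameters, or file contents."""


class EmptyCloudError(ValidationError):
    """An operation that needs at least one particle received none."""


class OutOfBoundsError(CellListError):
    """A point lies outside the grid's bounding box.

    Cell grids are derived from the data they index; callers holding a point
    outside the box must rebuild the grid rather than force an index.
    """


class ConsistencyError(CellListError):
    """A grid and a point cloud passed together do not belong together."""


# ---------------------------------------------------------------------------
# Point clouds

@dataclass
class PointCloud:
    """``n`` particle positions in Å with optional element/radius annotations.

    Parameters
    ----------
    coords:
        ``(n, d)`` array of coordinates with ``d`` in ``{2, 3}``.  The dtype
        is preserved if floating (float32 is supported for memory-bound
        workloads); anything else is promoted to float64.
    elements:
        Optional length-``n`` sequence of chemical element symbols.
    radii:
        Optional length-``n`` array of positive atom radii sigma_p (Å).

    Particle identity is positional: particle ``i`` is row ``i`` of
    ``coords``, and every index reported elsewhere in the package refers to
    that row.  Duplicate coordinates are permitted (they simply form pairs at
    distance zero).
    """

    coords: np.ndarray
    elements: list[str] | None = None
    radii: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords)
        if not np.issubdtype(coords.dtype, np.floating):
            coords = coords.astype(np.float64)
        if coords.ndim != 2:
            raise ValidationError(
                f"coordinates must be a 2-D (n, d) array, got shape {coords.shape}"
            )
        if coords.shape[1] not in (2, 3):
            raise ValidationError(
                f"only 2-D and 3-D point clouds are supported, got d={coords.shape[1]}"
            )
        finite = np.isfinite(coords).all(axis=1)
        if not finite.all():
            raise ValidationError(
                f"non-finite coordinate for particle {int(np.argmin(finite))}"
            )
        self.coords = coords
        if self.elements is not None:
            self.elements = list(self.elements)
            if len(self.elements) != len(coords):
                raise ValidationError(
                    f"{len(self.elements)} element symbols for {len(coords)} particles"
                )
        if self.radii is not None:
            radii = np.asarray(self.radii, dtype=np.float64)
            if radii.shape != (len(coords),):
                raise ValidationError(
                    f"radii shape {radii.shape} does not match {len(coords)} particles"
                )
            if not np.isfinite(radii).all() or not (radii > 0).all():
                raise ValidationError("atom radii must be finite and positive")
            self.radii = radii

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    def __len__(self) -> int:
        return self.n


# ---------------------------------------------------------------------------
# Grid geometry

@dataclass(frozen=True)
class GridShape:
    """Geometry of a cell grid: box origin, cell edge, and cells per axis."""

    origin: np.ndarray
    edge: float
    dims: tuple[int, ...]

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=np.float64)
        origin.setflags(write=False)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "edge", float(self.edge))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        if self.edge <= 0 or not math.isfinite(self.edge):
            raise ValidationError(f"cell edge must be positive and finite, got {self.edge}")
        if len(self.dims) != origin.shape[0]:
            raise ValidationError("origin and dims dimensionality mismatch")
        if any(d < 1 for d in self.dims):
            raise ValidationError(f"dims must all be >= 1, got {self.dims}")

    @property
    def ndim(self) -> int:
        return len(self.dims)

    @property
    def ncells(self) -> int:
        return int(np.prod(self.dims))

    @property
    def upper(self) -> np.ndarray:
        """Maximum corner of the box covered by the grid."""
        return self.origin + self.edge * np.asarray(self.dims, dtype=np.float64)

    def contains(self, point: np.ndarray) -> bool:
        x = np.asarray(point, dtype=np.float64)
        return bool(np.all(x >= self.origin) and np.all(x <= self.upper))

    def cell_center(self, ijk: Sequence[int]) -> np.ndarray:
        return self.origin + self.edge * (np.asarray(ijk, dtype=np.float64) + 0.5)


class CellIndex(NamedTuple):
    """A cell's per-axis index tuple and its linearised integer form."""

    ijk: tuple[int, ...]
    linear: int


def linearize(ijk: Sequence[int], dims: Sequence[int]) -> int:
    """Linearise a cell tuple, first axis fastest.

    ``linear = i_1 + dims_1 * (i_2 + dims_2 * i_3)`` — a fixed convention so
    cell identifiers are reproducible across runs and platforms.
    """
    lin = 0
    for i, d in zip(reversed(ijk), reversed(tuple(dims))):
        lin = lin * d + i
    return int(lin)


def delinearize(linear: int, dims: Sequence[int]) -> tuple[int, ...]:
    """Inverse of :func:`linearize` on valid linear indices."""
    out = []
    lin = int(linear)
    for d in dims:
        out.append(lin % d)
        lin //= d
    return tuple(out)


def compute_bounding_box(points: PointCloud, rc: float) -> GridShape:
    """Tight axis-aligned bounding box of ``points`` cut into cells of edge ``rc``.

    The cell edge is set to exactly ``rc`` (the smallest admissible value),
    which maximises grid sparsity while preserving the guarantee that any two
    particles within ``rc`` occupy the same or adjacent cells.  Points lying
    exactly on the upper box face belong to the last cell along that axis.
    """
    if not (math.isfinite(rc) and rc > 0):
        raise ValidationError(f"cutoff must be positive and finite, got {rc}")
    if len(points) == 0:
        raise EmptyCloudError("cannot compute a bounding box for an empty point cloud")
    mins = points.coords.min(axis=0).astype(np.float64)
    maxs = points.coords.max(axis=0).astype(np.float64)
    dims = tuple(max(1, math.ceil((hi - lo) / rc)) for lo, hi in zip(mins, maxs))
    return GridShape(origin=mins, edge=float(rc), dims=dims)


def _cell_tuples(coords: np.ndarray, shape: GridShape) -> np.ndarray:
    """Vectorised per-axis binning with upper-face clamping; assumes containment."""
    rel = (np.asarray(coords, dtype=np.float64) - shape.origin) / shape.edge
    ijk = np.floor(rel).astype(np.int64)
    np.clip(ijk, 0, np.asarray(shape.dims, dtype=np.int64) - 1, out=ijk)
    return ijk


def _linearize_array(ijk: np.ndarray, dims: Sequence[int]) -> np.ndarray:
    lin = np.zeros(ijk.shape[0], dtype=np.int64)
    for axis in range(len(dims) - 1, -1, -1):
        lin = lin * int(dims[axis]) + ijk[:, axis]
    return lin


def cell_index(point: Sequence[float], shape: GridShape) -> CellIndex:
    """Index of the cell containing ``point``; the point must lie in the box."""
    x = np.asarray(point, dtype=np.float64)
    if x.shape != (shape.ndim,):
        raise ValidationError(f"point shape {x.shape} does not match grid dimension {shape.ndim}")
    if not shape.contains(x):
        raise OutOfBoundsError(
            f"point {x.tolist()} lies outside the grid box "
            f"[{shape.origin.tolist()}, {shape.upper.tolist()}]; rebuild the grid"
        )
    ijk = tuple(int(v) for v in _cell_tuples(x[None, :], shape)[0])
    return CellIndex(ijk=ijk, linear=linearize(ijk, shape.dims))


# ---------------------------------------------------------------------------
# Grid construction

@dataclass
class CellGrid:
    """Sparse cell decomposition of a point cloud at cutoff ``rc``.

    Attributes
    ----------
    shape:
        Grid geometry (box origin, cell edge ``= rc``, cells per axis).
    cutoff:
        The cutoff radius the grid was built for (Å); equals ``shape.edge``.
    particle_cells:
        Length-``n`` array mapping each particle to its linear cell index.
    storage:
        Length-``n`` array of particle indices, grouped per cell in one
        contiguous block; within a cell, indices keep input order.
    cells:
        Hash map ``linear cell index -> (offset, length)`` into ``storage``;
        contains only non-empty cells, so ``len(cells) <= n``.
    """

    shape: GridShape
    cutoff: float
    particle_cells: np.ndarray
    storage: np.ndarray
    cells: dict[int, tuple[int, int]] = field(repr=False)

    @property
    def n(self) -> int:
        return int(self.storage.shape[0])

    @property
    def n_occupied(self) -> int:
        return len(self.cells)

    def segment(self, linear: int) -> np.ndarray:
        """Particle indices stored for cell ``linear`` (empty if unoccupied)."""
        entry = self.cells.get(int(linear))
        if entry is None:
            return np.empty(0, dtype=np.int64)
        off, length = entry
        return self.storage[off : off + length]


def build_grid(points: PointCloud, rc: float) -> CellGrid:
    """Build a sparse cell grid over ``points`` with cell edge ``rc``.

    Counting-sort construction: a first pass bins every particle and counts
    occupants per (hashed) cell index; segments of one shared storage array
    are then reserved per non-empty cell and filled in input order.  The
    vectorised form below realises exactly that via a stable argsort on the
    linear cell indices.  An empty cloud yields an empty grid with no cells.
    """
    if len(points) == 0:
        d = points.dim
        shape = GridShape(origin=np.zeros(d), edge=float(rc), dims=(1,) * d)
        empty = np.empty(0, dtype=np.int64)
        return CellGrid(shape=shape, cutoff=float(rc), particle_cells=empty,
                        storage=empty.copy(), cells={})
    shape = compute_bounding_box(points, rc)
    lin = _linearize_array(_cell_tuples(points.coords, shape), shape.dims)
    # Stable sort groups particles by cell while preserving input order within
    # each cell (the counting-sort placement order).
    order = np.argsort(lin, kind="stable").astype(np.int64)
    uniq, starts = np.unique(lin[order], return_index=True)
    lengths = np.diff(np.append(starts, lin.shape[0]))
    cells = {
        int(c): (int(o), int(l)) for c, o, l in zip(uniq.tolist(), starts.tolist(), lengths.tolist())
    }
    return CellGrid(shape=shape, cutoff=float(rc), particle_cells=lin,
                    storage=order, cells=cells)


def rebuild(grid: CellGrid, points: PointCloud) -> CellGrid:
    """Re-index ``points`` at the grid's cutoff after coordinates changed.

    Behaviourally identical to ``build_grid(points, grid.cutoff)``: the
    bounding box is recomputed from the new coordinates, so the grid tracks
    dynamic simulation boundaries.
    """
    return build_grid(points, grid.cutoff)


def grid_statistics(grid: CellGrid) -> dict[str, object]:
    """Summary statistics used for logging: size, dims, occupancy spread."""
    if grid.cells:
        lengths = np.fromiter((l for _, l in grid.cells.values()), dtype=np.int64)
        occ_min, occ_mean, occ_max = int(lengths.min()), float(lengths.mean()), int(lengths.max())
    else:
        occ_min = occ_max = 0
        occ_mean = 0.0
    return {
        "n_particles": grid.n,
        "dims": grid.shape.dims,
        "n_cells_total": grid.shape.ncells,
        "n_cells_occupied": grid.n_occupied,
        "occupancy_min": occ_min,
        "occupancy_mean": occ_mean,
        "occupancy_max": occ_max,
    }
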