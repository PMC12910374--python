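"""Pair enumeration and point neighbourhood queries on a cell grid.

Pair enumeration visits, for every occupied cell, the 2-combinations of its
own particles and the Cartesian products with each occupied *half-Moore*
neighbour.  The half-Moore neighbourhood is an antisymmetric half of the
3^d - 1 Moore offsets (13 in 3D, 4 in 2D) chosen so that, summed over all
cells, each unordered pair of adjacent cells is traversed exactly once.
Candidate pairs are then filtered by Euclidean distance with an *inclusive*
cutoff (``dist <= rc``).

Grid boundaries are aperiodic: cells on a box face simply have fewer
neighbours, and offsets leaving the grid are dropped.

Point queries ``N_x^rc = {p : rc >= ||x - p||}`` scan the full Moore
neighbourhood of the cell containing ``x`` (clamped into the grid when ``x``
is outside the box, which the surface sampler needs).  Since the box is tight
around the data and the cell edge equals ``rc``, this is exact for any query
within ``rc`` of the box; farther out no particle can be in range at all,
which a cheap box-distance guard short-circuits.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Iterator, NamedTuple

import numpy as np

from .grid import (
    CellGrid,
    CellIndex,
    ConsistencyError,
    GridShape,
    PointCloud,
    ValidationError,
    delinearize,
    linearize,
)

__all__ = [
    "ParticlePair",
    "Neighborhood",
    "half_moore_neighbors",
    "candidate_pairs",
    "count_candidate_pairs",
    "pairs_within_cutoff",
    "pairs_within_cutoff_arrays",
    "neighbors_of_point",
]


class ParticlePair(NamedTuple):
    """An unordered pair of original particle indices.

    ``i`` comes from the cell being iterated (or the earlier segment slot for
    an intra-cell pair) and ``j`` from the half-Moore partner; semantically
    the pair is unordered and each unordered pair is emitted at most once.
    ``dist`` is the Euclidean distance in Å when the producing operation
    computed it, else ``None``.
    """

    i: int
    j: int
    dist: float | None = None


@dataclass
class Neighborhood:
    """Result of a point query: particles within ``rc`` of ``query`` (inclusive)."""

    query: np.ndarray
    indices: np.ndarray
    distances: np.ndarray

    @property
    def members(self) -> list[tuple[int, float]]:
        return [(int(i), float(d)) for i, d in zip(self.indices, self.distances)]

    def __len__(self) -> int:
        return int(self.indices.shape[0])


@lru_cache(maxsize=None)
def _moore_offsets(ndim: int) -> tuple[tuple[int, ...], ...]:
    return tuple(off for off in product((-1, 0, 1), repeat=ndim) if any(off))


@lru_cache(maxsize=None)
def _half_moore_offsets(ndim: int) -> tuple[tuple[int, ...], ...]:
    # Lexicographically positive offsets: an antisymmetric half, so summing
    # over all cells visits each unordered adjacent cell pair exactly once.
    zero = (0,) * ndim
    return tuple(off for off in _moore_offsets(ndim) if off > zero)


def half_moore_neighbors(cell: CellIndex | tuple[int, ...], shape: GridShape) -> list[int]:
    """In-bounds half-Moore neighbour cells of ``cell`` as linear indices.

    Offsets whose per-axis tuple is lexicographically positive are kept
    (13 of the 26 Moore offsets in 3D, 4 of 8 in 2D); out-of-bounds offsets
    are dropped silently (aperiodic boundaries).  The returned order follows
    the fixed offset enumeration order and is deterministic.
    """
    ijk = cell.ijk if isinstance(cell, CellIndex) else tuple(int(v) for v in cell)
    dims = shape.dims
    out: list[int] = []
    for off in _half_moore_offsets(len(dims)):
        nb = tuple(i + o for i, o in zip(ijk, off))
        if all(0 <= v < d for v, d in zip(nb, dims)):
            out.append(linearize(nb, dims))
    return out


def _check_consistent(grid: CellGrid, points: PointCloud) -> None:
    if grid.n != len(points):
        raise ConsistencyError(
            f"grid indexes {grid.n} particles but the point cloud has {len(points)}"
        )
    if grid.shape.ndim != points.dim:
        raise ConsistencyError(
            f"grid dimension {grid.shape.ndim} does not match cloud dimension {points.dim}"
        )


def _pair_blocks(grid: CellGrid) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (i-indices, j-indices) blocks per cell/neighbour combination.

    Cells are visited in increasing linear index so enumeration order is
    reproducible regardless of hash-map iteration order.
    """
    dims = grid.shape.dims
    for lin in sorted(grid.cells):
        off, length = grid.cells[lin]
        seg = grid.storage[off : off + length]
        if length > 1:
            a, b = np.triu_indices(length, k=1)
            yield seg[a], seg[b]
        for nb in half_moore_neighbors(delinearize(lin, dims), grid.shape):
            entry = grid.cells.get(nb)
            if entry is None:
                continue
            noff, nlen = entry
            nseg = grid.storage[noff : noff + nlen]
            yield np.repeat(seg, nlen), np.tile(nseg, length)


def candidate_pairs(grid: CellGrid, points: PointCloud) -> Iterator[ParticlePair]:
    """Stream every unordered pair of particles in equal or Moore-adjacent cells.

    Per occupied cell: its 2-combinations first, then Cartesian products with
    each occupied half-Moore neighbour.  Because the cell edge equals the
    cutoff, this candidate set is a superset of all pairs within ``rc``;
    particles more than two cell edges apart on any axis never appear.
    """
    _check_consistent(grid, points)
    for ii, jj in _pair_blocks(grid):
        for i, j in zip(ii.tolist(), jj.tolist()):
            yield ParticlePair(i, j)


def count_candidate_pairs(grid: CellGrid) -> int:
    """Number of candidate pairs, from cell occupancies alone (no enumeration).

    ``sum_c C(l_c, 2) + sum_{adjacent occupied (c, c')} l_c * l_c'`` — the
    quantity whose boundedness per particle at fixed density underpins the
    linear-time complexity of cell-list pair iteration.
    """
    dims = grid.shape.dims
    total = 0
    for lin, (_, length) in grid.cells.items():
        total += length * (length - 1) // 2
        for nb in half_moore_neighbors(delinearize(lin, dims), grid.shape):
            entry = grid.cells.get(nb)
            if entry is not None:
                total += length * entry[1]
    return total


def pairs_within_cutoff(grid: CellGrid, points: PointCloud) -> Iterator[ParticlePair]:
    """Stream candidate pairs filtered to ``||p_i - p_j|| <= rc``, with distances.

    The cutoff test is inclusive: a pair at exactly ``rc`` is emitted.  As a
    set of unordered index pairs the result equals the brute-force set
    ``{(i, j) : i < j, ||p_i - p_j|| <= rc}``.
    """
    _check_consistent(grid, points)
    coords = points.coords
    rc = grid.cutoff
    for ii, jj in _pair_blocks(grid):
        diff = coords[ii] - coords[jj]
        dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        keep = dist <= rc
        for i, j, d in zip(ii[keep].tolist(), jj[keep].tolist(), dist[keep].tolist()):
            yield ParticlePair(i, j, d)


def pairs_within_cutoff_arrays(
    grid: CellGrid, points: PointCloud
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised form of :func:`pairs_within_cutoff`.

    Returns ``(i, j, dist)`` arrays in the same deterministic emission order
    as the generator; preferred for large inputs (CLI, batch analysis).
    """
    _check_consistent(grid, points)
    coords = points.coords
    rc = grid.cutoff
    out_i: list[np.ndarray] = []
    out_j: list[np.ndarray] = []
    out_d: list[np.ndarray] = []
    for ii, jj in _pair_blocks(grid):
        diff = coords[ii] - coords[jj]
        dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
        keep = dist <= rc
        if keep.any():
            out_i.append(ii[keep])
            out_j.append(jj[keep])
            out_d.append(dist[keep])
    if not out_i:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty.copy(), np.empty(0, dtype=np.float64)
    return np.concatenate(out_i), np.concatenate(out_j), np.concatenate(out_d)


def neighbors_of_point(
    grid: CellGrid, points: PointCloud, x: np.ndarray
) -> Neighborhood:
    """All particles within ``rc`` (inclusive) of an arbitrary query point ``x``.

    ``x`` may lie outside the grid's bounding box; its cell tuple is clamped
    into the grid and the full Moore neighbourhood of the clamped cell is
    scanned.  A preliminary guard returns an empty neighbourhood when ``x``
    is farther than ``rc`` from the box, where no particle can be in range.
    Members are sorted by particle index.
    """
    _check_consistent(grid, points)
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (points.dim,):
        raise ValidationError(f"query shape {x.shape} does not match dimension {points.dim}")
    if not np.isfinite(x).all():
        raise ValidationError(f"non-finite query point {x.tolist()}")
    empty = Neighborhood(query=x, indices=np.empty(0, dtype=np.int64),
                         distances=np.empty(0, dtype=np.float64))
    if not grid.cells:
        return empty
    shape = grid.shape
    rc = grid.cutoff
    gap = np.maximum(np.maximum(shape.origin - x, x - shape.upper), 0.0)
    if float(np.sqrt(gap @ gap)) > rc:
        return empty
    dims = np.asarray(shape.dims, dtype=np.int64)
    center = np.floor((x - shape.origin) / shape.edge).astype(np.int64)
    np.clip(center, 0, dims - 1, out=center)
    segments: list[np.ndarray] = []
    for off in product((-1, 0, 1), repeat=shape.ndim):
        nb = center + np.asarray(off, dtype=np.int64)
        if np.any(nb < 0) or np.any(nb >= dims):
            continue
        seg = grid.segment(linearize(tuple(int(v) for v in nb), shape.dims))
        if seg.shape[0]:
            segments.append(seg)
    if not segments:
        return empty
    idx = np.concatenate(segments)
    diff = points.coords[idx].astype(np.float64) - x
    dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    keep = dist <= rc
    idx, dist = idx[keep], dist[keep]
    order = np.argsort(idx, kind="stable")
    return Neighborhood(query=x, indices=idx[order], distances=dist[order])
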