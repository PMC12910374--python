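"""Independent oracles used by the test suite.

Everything here deliberately avoids the package's grid machinery: pair sets
come from dense distance matrices, cell membership from per-axis floor
division in plain Python, smooth distances from direct summation over an
all-atom scan.  Tests compare the package against these.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_pairs(coords: np.ndarray, rc: float) -> set[tuple[int, int]]:
    """All unordered index pairs with inclusive Euclidean distance <= rc."""
    coords = np.asarray(coords, dtype=np.float64)
    d = cdist(coords, coords)
    i, j = np.where(np.triu(d <= rc, k=1))
    return {(int(a), int(b)) for a, b in zip(i, j)}


def brute_force_pair_distances(coords: np.ndarray, rc: float) -> dict[tuple[int, int], float]:
    coords = np.asarray(coords, dtype=np.float64)
    d = cdist(coords, coords)
    i, j = np.where(np.triu(d <= rc, k=1))
    return {(int(a), int(b)): float(d[a, b]) for a, b in zip(i, j)}


def brute_force_neighbors(coords: np.ndarray, x: np.ndarray, rc: float):
    """Sorted (indices, distances) of all particles within rc of x (inclusive)."""
    diff = np.asarray(coords, dtype=np.float64) - np.asarray(x, dtype=np.float64)
    dist = np.sqrt((diff * diff).sum(axis=1))
    idx = np.where(dist <= rc)[0]
    return idx, dist[idx]


def cell_tuple_oracle(point, origin, edge, dims) -> tuple[int, ...]:
    """Per-axis floor-division binning with upper-face clamping, in plain Python."""
    out = []
    for x, o, d in zip(point, origin, dims):
        k = math.floor((x - o) / edge)
        out.append(min(max(k, 0), d - 1))
    return tuple(out)


def chebyshev_adjacent_cell_pairs(dims) -> set[frozenset]:
    """All unordered pairs of distinct cells at Chebyshev distance 1."""
    cells = list(product(*[range(d) for d in dims]))
    pairs = set()
    for a in cells:
        for b in cells:
            if a != b and max(abs(x - y) for x, y in zip(a, b)) == 1:
                pairs.add(frozenset((a, b)))
    return pairs


def linearize_oracle(ijk, dims) -> int:
    lin = 0
    for i, d in zip(reversed(ijk), reversed(tuple(dims))):
        lin = lin * d + i
    return lin


def direct_sigma_tilde(x, atom_coords, radii, rc) -> float:
    """Weighted-mean radius over an all-atom scan, plain loops, no shifting."""
    num = den = 0.0
    for p, s in zip(atom_coords, radii):
        r = math.dist(tuple(x), tuple(p))
        if r <= rc:
            w = math.exp(-r)
            num += w * s
            den += w
    return num / den


def direct_smooth_distance(x, atom_coords, radii, rc) -> float:
    """Soft-min distance over an all-atom scan: direct summation, no grid."""
    total = 0.0
    hit = False
    for p, s in zip(atom_coords, radii):
        r = math.dist(tuple(x), tuple(p))
        if r <= rc:
            total += math.exp(-r / s)
            hit = True
    assert hit, "oracle query has an empty neighborhood"
    return -direct_sigma_tilde(x, atom_coords, radii, rc) * math.log(total)


def radial_target_mean(stiffness: float, level: float) -> float:
    """Mean of r under p(r) proportional to r^2 exp(-k/2 (r - level)^2) on (0, inf).

    This is the exact expected smooth distance of a correctly sampled chain
    on the single-atom toy, where SDF(x) = ||x||.
    """
    from scipy.integrate import quad

    dens = lambda r: r * r * math.exp(-0.5 * stiffness * (r - level) ** 2)
    z, _ = quad(dens, 0, level + 20.0 / math.sqrt(stiffness))
    m, _ = quad(lambda r: r * dens(r), 0, level + 20.0 / math.sqrt(stiffness))
    return m / z


def batch_se(values: np.ndarray, n_batches: int = 20) -> float:
    """Batch-means standard error of the mean for a correlated chain."""
    values = np.asarray(values, dtype=np.float64)
    usable = (len(values) // n_batches) * n_batches
    means = values[:usable].reshape(n_batches, -1).mean(axis=1)
    return float(means.std(ddof=1) / math.sqrt(n_batches))
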