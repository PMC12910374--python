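# celllists

Sparse cell lists for fixed-radius neighbour search in particle systems,
with a smooth-distance-function surface sampler for molecular structures.

## What problem this solves

Enumerating all particle pairs closer than a cutoff `rc` is the inner loop of
most particle-based simulation and analysis — molecular dynamics force loops,
contact maps, coarse-grained polymer models.  Done naively it costs O(n²).
The *cell lists* algorithm cuts the bounding box of the data into cubic cells
of edge ≥ `rc`; every pair within the cutoff then lies in the same cell or in
two Chebyshev-adjacent cells, and enumeration becomes O(n) at bounded
density.

This package implements a sparse variant aimed at coarse-grained or sparsely
populated systems with dynamic boundaries, where a dense 3-D array of cells
wastes memory:

- **Counting-sort storage** — particles are counted per cell, then placed
  into per-cell segments of a *single* contiguous allocation, preserving
  input order within each cell.  Spatially (and, for biomolecules, usually
  sequentially) close particles end up close in memory.
- **Hash map over non-empty cells** — only occupied cells are stored
  (`linear cell index → (offset, length)`), so memory scales with the number
  of occupied cells (≤ n), not with box volume.
- **Half-Moore pair iteration** — per cell, the 2-combinations of its own
  particles plus Cartesian products with each occupied half-Moore neighbour
  (13 of the 26 Moore offsets in 3D), so every unordered pair of adjacent
  cells is visited exactly once.  Boundaries are aperiodic.  The distance
  filter is inclusive (`dist ≤ rc`).
- **Point queries** — `N_x^rc = {p : rc ≥ ‖x − p‖}` for arbitrary query
  points, including points outside the bounding box.

On top of the queries sits a probabilistic molecular-surface representation.
For atoms `P` with radii σ_p, the **smooth distance function**

    SDF(x) = −σ̃(x) · log Σ_{p ∈ N_x^rc} exp(−‖x − p‖ / σ_p),
    σ̃(x)  = Σ_p exp(−‖x − p‖) σ_p / Σ_p exp(−‖x − p‖)

is a soft minimum of atom distances (exactly the Euclidean distance when one
atom is in range).  A fixed level set — 1.05 Å by default — stands in for
the protein surface, and point clouds on it are drawn by running the
No-U-Turn sampler (NUTS) on the harmonic potential
`U(x) = k/2 (SDF(x) − d0)²` using the exact analytic gradient.

## Worked example

```python
import numpy as np
from celllists import (BenchmarkSpec, SamplerConfig, benchmark_cloud, build_grid,
                       grid_statistics, pairs_within_cutoff_arrays, sample_surface,
                       toy_structure)

# a uniform cloud at ~10 particles per cubic cell, rc = 10 A
cloud = benchmark_cloud(BenchmarkSpec(n=2000, rc=10.0, density=10.0, seed=7))
grid = build_grid(cloud, 10.0)
print("grid:", grid_statistics(grid))
i, j, d = pairs_within_cutoff_arrays(grid, cloud)
print(f"{len(i)} pairs within 10 A; first: ({i[0]}, {j[0]}) at {d[0]:.3f} A")

# sample the 1.05 A level set of a two-atom toy structure
atoms = toy_structure("dumbbell", separation=4.0)
result = sample_surface(atoms, rc=10.0,
                        config=SamplerConfig(n_samples=2000, warmup=500, seed=1))
print(f"sampled {len(result)} surface points; mean SDF = {np.nanmean(result.sdf):.3f} A, "
      f"spread = {np.nanstd(result.sdf):.3f} A, divergences = {result.trace.divergences}")
```

prints

```
grid: {'n_particles': 2000, 'dims': (10, 10, 2), 'n_cells_total': 200, 'n_cells_occupied': 200, 'occupancy_min': 3, 'occupancy_mean': 10.0, 'occupancy_max': 21}
31433 pairs within 10 A; first: (166, 233) at 7.605 A
sampled 2000 surface points; mean SDF = 1.070 A, spread = 0.143 A, divergences = 0
```

The grid statistics show the cloud hit its target mean occupancy of 10
particles per cell.  The sampled smooth-distance values cluster around the
1.05 Å level with spread ≈ k^(−1/2) = 0.14 Å at the default stiffness
k = 50 Å⁻²; the small upward shift of the mean is the expected geometric
effect of sampling a thin shell in 3-D (see `docs/methods.md`).

## Command line

```sh
celllists generate --n 10000 --cutoff 10 --seed 1 -o cloud.xyz
celllists pairs cloud.xyz --cutoff 10 -o pairs.tsv          # i<TAB>j<TAB>dist
celllists query cloud.xyz --cutoff 10 --point 50,50,20 -o nb.tsv
celllists sample-surface protein.pdb --chain A --seed 1 -o surface.csv
```

All outputs are deterministic for a fixed argument list and seed; indices
are 0-based.

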