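# Methods

## Cell grid model

A point cloud of `n` particles in `d ∈ {2, 3}` dimensions (coordinates in Å)
is decomposed over its tight axis-aligned bounding box into cubic cells of
edge `h`.  Correctness of neighbour search only needs `h ≥ rc`; we fix
`h = rc` exactly, which maximises grid sparsity and makes the half-Moore
adjacency argument tight: two particles within `rc` can differ by at most
one cell index per axis.

Cell tuples are `i_k = min(⌊(x_k − origin_k)/h⌋, dims_k − 1)`.  Because the
box is derived from the data, the per-axis maxima are attained; points on
the upper face are clamped into the last cell (the `min`).  Tuples are
linearised first-axis-fastest, `linear = i_1 + dims_1(i_2 + dims_2 i_3)`.
Neither the linearisation order nor the upper-face rule affects which pairs
are found; they are fixed solely so cell identifiers and output order are
reproducible across runs and platforms.  Degenerate axes (all points
sharing one coordinate) get `dims_k = 1` and need no special casing.

Construction is a counting sort: bin all particles (one vectorised pass),
count occupants per linear index, reserve one contiguous segment per
non-empty cell inside a single length-`n` storage array, and place each
particle's index into its segment in input order.  In code the
count-and-place is realised by a stable argsort of the linear indices,
which produces the identical grouping.  Only non-empty cells enter the hash
map (`linear → (offset, length)`), so the memory footprint follows the
number of occupied cells (≤ n) rather than the box volume — the property
that makes the structure usable for sparse, coarse-grained, or
dynamically-bounded systems.  `rebuild` is defined behaviourally: it equals
a fresh construction at the same cutoff (allocation reuse is an
implementation concern the contract deliberately omits).

Invariants maintained (and property-tested): cell lengths sum to `n`;
storage is a permutation of `0..n−1`; within-cell input order is preserved;
groupings are invariant under rigid translation (tested with
exactly-representable translations, since a generic floating translation
can legitimately flip a particle sitting within one ulp of a cell face).

## Pair enumeration and queries

The half-Moore stencil is the set of Moore offsets whose tuple is
lexicographically positive — 13 of 26 in 3D, 4 of 8 in 2D.  Any
antisymmetric half works; lexicographic positivity is canonical and easy to
verify exhaustively (over all cells, each unordered Chebyshev-adjacent cell
pair is produced exactly once; boundary cells simply produce fewer —
boundaries are aperiodic).  Enumeration iterates cells in increasing linear
index (never raw hash order, which would not be reproducible), yielding
intra-cell 2-combinations and then inter-cell Cartesian products.  The
distance filter is inclusive, `dist ≤ rc`, in both pair enumeration and
point queries; a pair at exactly the cutoff is reported.

Point queries clamp the query's cell tuple into the grid and scan the full
3^d Moore block around the clamped cell.  For a query within `rc` outside
the box this is still exact: any in-range particle is within `rc` of the
crossed box face, hence (with `h = rc`) in the last or second-to-last cell
layer, both of which the clamped Moore block covers.  Farther than `rc`
from the box no particle can be in range; a box-distance guard returns an
empty neighbourhood immediately.

## Smooth distance function

For atoms `P` with radii σ_p and neighbourhood `N_x^rc`:

    σ̃(x)  = Σ_p exp(−‖x−p‖) σ_p / Σ_p exp(−‖x−p‖)          (convex combination)
    SDF(x) = −σ̃(x) · log Σ_p exp(−‖x−p‖/σ_p)

Both sums run over `N_x^rc` only.  The exponent of the σ̃ weights treats
the distance in Å as dimensionless; that is the function as defined and is
implemented verbatim.  Numerics: the log-sum-exp is computed in shifted
form (subtracting the max exponent), and the σ̃ weights are shifted by the
minimum distance — otherwise queries near the cutoff fringe with small
radii underflow to `−σ̃·log 0` or `0/0`.  With a single atom in range the
expression collapses to the exact Euclidean distance (the basis of the
closed-form tests); with uniform radii it is a soft minimum bounded above
by the true minimum distance.  Restricting the sums to `N_x^rc` makes the
function discontinuous when atoms cross the cutoff sphere; this is the
accepted approximation trade-off and no smoothing window is added.

The gradient is analytic (product rule over σ̃ and the log-sum-exp; with
`u_p = (x−p)/‖x−p‖`, `w` the σ̃ weights and `s` the softmax of `−‖x−p‖/σ_p`:
`∇σ̃ = Σ w_p(σ̃−σ_p)u_p / Σ w_p`, `∇lse = −Σ s_p u_p/σ_p`), validated
against central finite differences at `h = 1e−5` Å.  At an atom centre the
gradient of `‖x−p‖` is undefined and a dedicated error is raised; the
sampler's initialisation can never start there.

Default radii are a small van der Waals table (C 1.70, N 1.55, O 1.52,
S 1.80, H 1.10, P 1.80 Å; fallback 1.70 Å, logged) in `celllists.io`,
overridable wherever radii are assigned.

## Level-set sampling

The surface is the `d0 = 1.05` Å level set of the SDF.  Points on it are
drawn from `exp(−U)` with `U(x) = k/2 (SDF(x) − d0)²` using a
self-contained No-U-Turn sampler: standard doubling trajectories with a
slice variable, unit mass matrix, dual-averaging step-size adaptation
(target acceptance 0.8, warmup 1000, max tree depth 10), and a
counter-based Philox RNG so a given seed yields a bit-identical chain.
Divergent trajectories (energy error > 1000) are counted and reported.

The stiffness default `k = 50 Å⁻²` is a design choice (no canonical value
exists): it puts the stationary spread `≈ k^{−1/2} = 0.14` Å well under the
1.05 Å level while keeping the target mild enough for large, stable steps.
Where no atom is within `rc` the SDF is undefined; the potential falls back
to a large finite confinement energy (10⁴) plus a unit-slope pull toward
the nearest occupied cell (found by expanding Chebyshev shells), so a chain
that steps outside all neighbourhoods recovers instead of crashing.  The
chain starts at a random atom centre displaced by `max σ_p + d0` in a
uniform random direction.

A geometric point that matters when validating the sampler: the target
density `exp(−U)` lives on ℝ³, so along the "radial" coordinate `s = SDF`
it carries the surface-area measure of the level sets.  For the single-atom
toy (`SDF(x) = ‖x‖`, level sets are spheres) the marginal is exactly
`p(r) ∝ r² exp(−k/2 (r−d0)²)`, whose mean is `d0 + 2/(k d0) + O(k⁻²)`
≈ 1.088 Å at the defaults — *above* the level by construction, for any
correct sampler.  Calibration tests therefore compare the sampled mean
against the exact target mean obtained by quadrature of that marginal (and
against analytic N(0, I) moments for the Gaussian check), with batch-means
standard errors to account for chain autocorrelation.  The same tilt, of
order `2/(k d0)`, bounds the tolerance used for the dumbbell check.

## Synthetic data

`benchmark_cloud` reproduces the unstructured stress-test construction:
`n` points uniform in a box with fixed x/y edges (default `10·rc`) and a
z-extent derived so the grid at cutoff `rc` averages `density` particles
per cubic cell (default 10).  Box surface and volume then both grow
linearly in `n`, keeping boundary effects from dominating measurements, and
at density 10 essentially every neighbour lookup hits an occupied cell.
The presorted variant sorts the same points by z (a pure permutation),
emulating spatially coherent input.  `toy_structure` provides the
deterministic single-atom / dumbbell / ring / Fibonacci-shell
configurations used by the closed-form surface tests.

The generator emulates density and scaling structure only: real molecular
data has correlated, clustered coordinates, excluded volume, and element
heterogeneity, none of which affect the exactness guarantees tested here
(pair sets are compared against oracles point-for-point) but which do mean
the benchmark clouds say nothing about cache behaviour or constants on
real structures.

### Problem sizes

Correctness tests compare against O(n²)/O(n) brute-force oracles, which
caps cloud sizes at n ≤ 2000 (pairs) and 500 (queries) — ample, since the
comparisons are exact set equalities.  The candidate-pairs-per-particle
scaling measurement runs at n = 10³, 10⁴, 10⁵ with five seeds per size.
For that measurement the box keeps a one-cell cross-section
(`base_edge = rc`) so that the boundary-cell fraction is essentially
constant across the whole range (end effects ∝ 1/z ≤ 1%): with the default
`10·rc` base, n = 10³ at density 10 would collapse to a single z-layer and
the comparison would measure box geometry rather than enumeration
structure.  Sampler calibration uses 5000 post-warmup draws.

## Known limitations

- No periodic boundary conditions; no Verlet lists, larger stencils,
  particle reordering, or parallel iteration.
- No k-nearest-neighbour queries or bonded-pair exclusion lists.
- The SDF is unsigned and discontinuous at the cutoff sphere; the sampler
  covers the surface stochastically and is not a mesh extractor.
- Sampling disjoint surfaces in one chain is out of scope (it would need
  multiple interacting particles).
- PDB input reads the first model only, keeps altloc blank/'A', and by
  default drops HETATM records and hydrogens (flag-controlled).
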