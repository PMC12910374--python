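"""Synthetic particle clouds and toy atom configurations.

Two kinds of fixtures are produced here.  ``benchmark_cloud`` follows the
construction used to stress cell grids in an unfavourable, unstructured
setting: ``n`` positions sampled uniformly in a box whose x- and y-extents
are fixed while the z-extent grows with ``n`` so that a grid at cutoff
``rc`` holds a prescribed mean number of particles per cubic cell (10 by
default).  Box surface and volume then both scale linearly with ``n``, so
measurements on such clouds are not dominated by boundary artefacts, and
every interior cell has occupied Moore neighbours.  An optional variant
returns the same points sorted by their z-components, emulating the spatial
coherence of structured (e.g. polymer) data.

``toy_structure`` builds tiny deterministic atom arrangements with uniform
radii — single atoms, dumbbells, rings and spherical shells — whose smooth
distance functions have closed forms or symmetries that tests can check
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import PointCloud, ValidationError

__all__ = ["BenchmarkSpec", "benchmark_cloud", "toy_structure"]


@dataclass
class BenchmarkSpec:
    """Parameters of a uniform benchmark cloud.

    ``base_edge`` (default ``10 * rc``) fixes the x/y box extents; the
    z-extent is derived so that ``n / (total cells) = density``.
    """

    n: int
    rc: float = 10.0
    density: float = 10.0
    base_edge: float | None = None
    presorted: bool = False
    seed: int = 0


def benchmark_cloud(spec: BenchmarkSpec) -> PointCloud:
    """Sample ``spec.n`` positions uniformly in the benchmark box.

    Deterministic for a given seed (counter-based Philox stream).  Raises
    when the derived z-extent would be smaller than one cell; increase ``n``
    or decrease ``density`` in that case.
    """
    if spec.n < 1:
        raise ValidationError(f"n must be >= 1, got {spec.n}")
    if spec.rc <= 0 or spec.density <= 0:
        raise ValidationError("rc and density must be positive")
    base = 10.0 * spec.rc if spec.base_edge is None else float(spec.base_edge)
    if base < spec.rc:
        raise ValidationError("base_edge must be at least one cell (rc)")
    total_cells = spec.n / spec.density
    z_extent = total_cells * spec.rc**3 / base**2
    if z_extent < spec.rc:
        raise ValidationError(
            f"derived z-extent {z_extent:.3g} A is smaller than one cell "
            f"({spec.rc} A); increase n or decrease density"
        )
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(spec.seed)))
    coords = rng.uniform(size=(spec.n, 3)) * np.array([base, base, z_extent])
    if spec.presorted:
        coords = coords[np.argsort(coords[:, 2], kind="stable")]
    return PointCloud(coords=coords)


def toy_structure(
    kind: str,
    separation: float = 4.0,
    m: int = 16,
    ring_radius: float = 5.0,
    shell_radius: float = 10.0,
    radius: float = 1.7,
) -> PointCloud:
    """Deterministic toy atom configurations with uniform radii.

    Kinds: ``single_atom`` (one atom at the origin), ``dumbbell`` (two atoms
    at +-separation/2 on x), ``ring`` (``m`` atoms on a circle in the xy
    plane), ``shell`` (``m`` atoms on a Fibonacci sphere).
    """
    if kind == "single_atom":
        coords = np.zeros((1, 3))
    elif kind == "dumbbell":
        half = separation / 2.0
        coords = np.array([[-half, 0.0, 0.0], [half, 0.0, 0.0]])
    elif kind == "ring":
        if m < 1:
            raise ValidationError(f"ring needs m >= 1 atoms, got {m}")
        angles = 2.0 * np.pi * np.arange(m) / m
        coords = ring_radius * np.stack(
            [np.cos(angles), np.sin(angles), np.zeros(m)], axis=1
        )
    elif kind == "shell":
        if m < 1:
            raise ValidationError(f"shell needs m >= 1 atoms, got {m}")
        # Fibonacci sphere: near-even deterministic coverage.
        k = np.arange(m, dtype=np.float64)
        z = 1.0 - (2.0 * k + 1.0) / m
        phi = np.pi * (1.0 + np.sqrt(5.0)) * k
        rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
        coords = shell_radius * np.stack(
            [rho * np.cos(phi), rho * np.sin(phi), z], axis=1
        )
    else:
        raise ValidationError(f"unknown toy structure kind {kind!r}")
    n = coords.shape[0]
    return PointCloud(
        coords=coords, elements=["C"] * n, radii=np.full(n, float(radius))
    )
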