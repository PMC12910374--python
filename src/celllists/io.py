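"""Readers and writers for the structure and point-cloud formats the tool touches.

PDB reading goes through :mod:`gemmi` (fixed-column parsing, element
inference from atom names when columns 77-78 are absent); XYZ, CSV and the
TSV pair-list format are plain text.  All particle indices written by this
package are 0-based; PDB serial numbers are not preserved as identifiers.

The element -> van der Waals radius table used to assign sigma_p lives here
and is deliberately small and configurable: callers may pass their own
mapping wherever radii are assigned.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .grid import EmptyCloudError, PointCloud, ValidationError
from .neighbors import ParticlePair

__all__ = [
    "VDW_RADII",
    "DEFAULT_RADIUS",
    "radii_for_elements",
    "read_pdb",
    "read_xyz",
    "write_xyz",
    "read_csv",
    "write_csv",
    "read_points",
    "write_pairs",
    "write_pseudo_pdb",
]

logger = logging.getLogger(__name__)

#: Van der Waals radii in Å for the elements dominating protein structures.
VDW_RADII: dict[str, float] = {
    "H": 1.10,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
}

#: Fallback radius (Å) for elements missing from the table; its use is logged.
DEFAULT_RADIUS: float = 1.70


def radii_for_elements(
    elements: Sequence[str], table: Mapping[str, float] | None = None
) -> np.ndarray:
    """Map element symbols to radii via ``table`` (default :data:`VDW_RADII`)."""
    table = VDW_RADII if table is None else table
    radii = np.empty(len(elements), dtype=np.float64)
    missing: set[str] = set()
    for k, el in enumerate(elements):
        key = el.strip().capitalize()
        try:
            radii[k] = table[key]
        except KeyError:
            radii[k] = DEFAULT_RADIUS
            missing.add(key or "?")
    if missing:
        logger.warning(
            "no van der Waals radius for element(s) %s; using fallback %.2f A",
            ", ".join(sorted(missing)), DEFAULT_RADIUS,
        )
    return radii


def read_pdb(
    path: str | Path,
    chains: Sequence[str] | None = None,
    include_hetatm: bool = False,
    include_hydrogens: bool = False,
    radius_table: Mapping[str, float] | None = None,
) -> PointCloud:
    """Read ATOM records of a PDB file into a :class:`PointCloud` with radii.

    Parameters
    ----------
    chains:
        Optional chain identifiers to keep; ``None`` keeps every chain.
    include_hetatm:
        Also keep HETATM records (waters, ligands).  Off by default: the
        polymer surface is usually what is wanted.
    include_hydrogens:
        Keep hydrogen atoms.  Off by default.
    radius_table:
        Element -> radius mapping overriding :data:`VDW_RADII`.

    Only the first model is read, and only atoms with blank or ``'A'``
    alternate-location indicators.  Raises an error naming the file when no
    atom survives the filters.
    """
    import gemmi

    path = Path(path)
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValidationError(f"malformed PDB file {path}: {exc}") from exc
    wanted = None if chains is None else {c.strip() for c in chains}
    coords: list[tuple[float, float, float]] = []
    elements: list[str] = []
    for model in structure:
        for chain in model:
            if wanted is not None and chain.name.strip() not in wanted:
                continue
            for residue in chain:
                if residue.het_flag == "H" and not include_hetatm:
                    continue
                for atom in residue:
                    if atom.altloc not in ("\0", "", "A"):
                        continue
                    if atom.is_hydrogen() and not include_hydrogens:
                        continue
                    coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    elements.append(atom.element.name)
        break  # first model only
    if not coords:
        raise EmptyCloudError(f"no atoms selected from {path} (chains={chains!r})")
    arr = np.asarray(coords, dtype=np.float64)
    return PointCloud(coords=arr, elements=elements,
                      radii=radii_for_elements(elements, radius_table))


def read_xyz(path: str | Path) -> PointCloud:
    """Read a standard XYZ file (count line, comment line, ``El x y z`` rows)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty XYZ file")
    try:
        count = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ValidationError(f"{path}: first line must be the atom count") from exc
    rows = [ln for ln in lines[2 : 2 + count]]
    if len(rows) < count:
        raise ValidationError(
            f"{path}: count line promises {count} atoms but only {len(rows)} rows present"
        )
    coords = np.empty((count, 3), dtype=np.float64)
    elements: list[str] = []
    for k, row in enumerate(rows):
        parts = row.split()
        if len(parts) < 4:
            raise ValidationError(f"{path}: malformed XYZ row {k + 3}: {row!r}")
        elements.append(parts[0])
        coords[k] = [float(v) for v in parts[1:4]]
    if count == 0:
        return PointCloud(coords=np.empty((0, 3)), elements=[])
    return PointCloud(coords=coords, elements=elements)


def write_xyz(points: PointCloud, path: str | Path, comment: str = "") -> None:
    """Write ``points`` as XYZ with 6-decimal fixed notation."""
    path = Path(path)
    elements = points.elements or ["X"] * len(points)
    with path.open("w") as fh:
        fh.write(f"{len(points)}\n{comment}\n")
        for el, row in zip(elements, points.coords):
            fh.write(f"{el} " + " ".join(f"{v:.6f}" for v in row) + "\n")


def read_csv(path: str | Path) -> PointCloud:
    """Read a CSV of coordinates; a non-numeric first line is treated as a header."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise EmptyCloudError(f"{path}: empty CSV file")
    start = 0
    try:
        [float(v) for v in lines[0].split(",")[:3]]
    except ValueError:
        start = 1
    rows = []
    for k, ln in enumerate(lines[start:]):
        parts = ln.split(",")
        if len(parts) < 2:
            raise ValidationError(f"{path}: malformed CSV row {start + k + 1}: {ln!r}")
        rows.append([float(v) for v in parts[:3]] if len(parts) >= 3 else
                    [float(v) for v in parts[:2]])
    return PointCloud(coords=np.asarray(rows, dtype=np.float64))


def write_csv(
    points: PointCloud, path: str | Path, values: np.ndarray | None = None,
    value_name: str = "sdf",
) -> None:
    """Write coordinates as CSV ``x,y,z[,value]`` with 6-decimal precision."""
    path = Path(path)
    header = ",".join("xyz"[: points.dim]) + (f",{value_name}" if values is not None else "")
    with path.open("w") as fh:
        fh.write(header + "\n")
        for k, row in enumerate(points.coords):
            line = ",".join(f"{v:.6f}" for v in row)
            if values is not None:
                line += f",{values[k]:.6f}"
            fh.write(line + "\n")


def read_points(path: str | Path, fmt: str | None = None) -> PointCloud:
    """Dispatch to a reader by ``fmt`` or file extension (pdb/ent, xyz, csv)."""
    path = Path(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt in ("pdb", "ent"):
        return read_pdb(path)
    if fmt == "xyz":
        return read_xyz(path)
    if fmt == "csv":
        return read_csv(path)
    raise ValidationError(f"unsupported input format {fmt!r} for {path}")


def write_pairs(pairs: Iterable[ParticlePair], path: str | Path) -> int:
    """Write a pair stream as TSV ``i<TAB>j<TAB>dist`` (6 decimals); returns row count.

    Pairs are written in the order received (producers emit cells by
    increasing linear index, so output is deterministic).
    """
    path = Path(path)
    count = 0
    try:
        with path.open("w") as fh:
            fh.write("i\tj\tdist\n")
            for p in pairs:
                dist = "" if p.dist is None else f"{p.dist:.6f}"
                fh.write(f"{p.i}\t{p.j}\t{dist}\n")
                count += 1
    except OSError as exc:
        raise CellListIOError(f"cannot write pair list to {path}: {exc}") from exc
    return count


class CellListIOError(ValidationError):
    """File could not be read or written."""


def write_pseudo_pdb(points: PointCloud, path: str | Path,
                     values: np.ndarray | None = None) -> None:
    """Write points as HETATM pseudo-atoms (element C), ``values`` in the B-factor."""
    path = Path(path)
    if points.dim != 3:
        raise ValidationError("PDB output requires 3-D points")
    with path.open("w") as fh:
        for k, (x, y, z) in enumerate(points.coords):
            b = 0.0 if values is None else float(values[k])
            serial = (k % 99999) + 1
            resnum = (k % 9999) + 1
            fh.write(
                f"HETATM{serial:5d}  C   SUR A{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00{b:6.2f}           C\n"
            )
        fh.write("END\n")
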