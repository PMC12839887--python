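"""Readers and writers: Gaussian cube, XYZ, and the descriptor CSV schema.

Cube files are kept in the conventional layout (two comment lines; atom
count + origin; three axis records; one line per atom; values with the
last axis fastest) and are always interpreted in bohr.  XYZ files are in
angstrom and converted on read.  Descriptor tables are CSV with explicit
``NaN`` for missing labels -- missingness is never encoded as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ELEMENT_NUMBERS, AtomSpec, MolecularGrid

__all__ = [
    "ANGSTROM_TO_BOHR",
    "ITA_COLUMNS",
    "FEATURE_COLUMNS",
    "TARGET_COLUMNS",
    "TABLE_COLUMNS",
    "CubeData",
    "read_cube",
    "write_cube",
    "read_xyz",
    "read_table",
    "write_table",
]

ANGSTROM_TO_BOHR = 1.8897259886
_SYMBOL_OF_Z = {z: el for el, z in ELEMENT_NUMBERS.items()}

ITA_COLUMNS = ["S_S", "I_F", "S_GBP", "E2", "E3", "rR2", "rR3", "I_G", "G1", "G2", "G3"]
FEATURE_COLUMNS = ITA_COLUMNS + ["homo", "lumo"]
TARGET_COLUMNS = ["q1_mv", "q2_mv", "sigma_p"]
TABLE_COLUMNS = (
    ["molecule_id", "family"]
    + ITA_COLUMNS
    + ["homo", "lumo", "mep_o1", "mep_o2", "sum_nao_o"]
    + TARGET_COLUMNS
)


class ParseError(ValueError):
    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


@dataclass
class CubeData:
    """A scalar field on a regular lattice plus the molecular geometry."""

    atoms: list[AtomSpec]
    origin: np.ndarray          # (3,), bohr
    axes: np.ndarray            # (3, 3), rows are voxel steps, bohr
    shape: tuple[int, int, int]
    values: np.ndarray          # (nx, ny, nz)
    comments: tuple[str, str] = ("", "")
    metadata: dict = field(default_factory=dict)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.axes)))

    def integrate(self) -> float:
        """Lattice-sum integral using the voxel volume as uniform weight."""
        return float(self.values.sum() * self.voxel_volume)

    def as_grid(self) -> MolecularGrid:
        idx = np.indices(self.shape).reshape(3, -1).T
        pts = self.origin + idx @ self.axes
        w = np.full(pts.shape[0], self.voxel_volume)
        return MolecularGrid(points=pts, weights=w)


def _parse_metadata(comment: str) -> dict:
    meta = {}
    for token in comment.replace(",", " ").split():
        if "=" in token:
            key, _, val = token.partition("=")
            try:
                meta[key.strip().lower()] = float(val)
            except ValueError:
                pass
    return meta


def read_cube(path) -> CubeData:
    """Parse a Gaussian cube file (bohr units).

    ``HOMO=<hartree> LUMO=<hartree>`` tokens on either comment line are
    collected into ``metadata``.
    """
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 6:
        raise ParseError(path, len(lines), "truncated cube header")
    c1, c2 = lines[0].rstrip("\n"), lines[1].rstrip("\n")
    try:
        head = lines[2].split()
        natoms = int(head[0])
        origin = np.array(head[1:4], dtype=float)
    except (IndexError, ValueError) as exc:
        raise ParseError(path, 3, f"bad atom-count/origin record: {exc}") from exc
    if natoms < 0:
        raise ParseError(path, 3, "cube files with DSET ids are not supported")
    shape = []
    axes = []
    for i in range(3):
        try:
            rec = lines[3 + i].split()
            shape.append(int(rec[0]))
            axes.append([float(x) for x in rec[1:4]])
        except (IndexError, ValueError) as exc:
            raise ParseError(path, 4 + i, f"bad axis record: {exc}") from exc
    atoms = []
    for i in range(natoms):
        try:
            rec = lines[6 + i].split()
            z = int(rec[0])
            pos = np.array(rec[2:5], dtype=float)
        except (IndexError, ValueError) as exc:
            raise ParseError(path, 7 + i, f"bad atom record: {exc}") from exc
        atoms.append(AtomSpec(element=_SYMBOL_OF_Z.get(z, f"Z{z}"), position=pos, nuclear_charge=z))
    raw = []
    for ln, line in enumerate(lines[6 + natoms:], start=7 + natoms):
        try:
            raw.extend(float(x) for x in line.split())
        except ValueError as exc:
            raise ParseError(path, ln, f"bad value record: {exc}") from exc
    n_expected = shape[0] * shape[1] * shape[2]
    if len(raw) != n_expected:
        raise ParseError(path, len(lines), f"expected {n_expected} values, found {len(raw)}")
    values = np.array(raw).reshape(shape)
    meta = {**_parse_metadata(c1), **_parse_metadata(c2)}
    return CubeData(atoms=atoms, origin=origin, axes=np.array(axes),
                    shape=tuple(shape), values=values, comments=(c1, c2), metadata=meta)


def write_cube(path, cube: CubeData) -> None:
    with open(path, "w") as fh:
        fh.write((cube.comments[0] or "cube") + "\n")
        fh.write((cube.comments[1] or "") + "\n")
        fh.write(f"{len(cube.atoms):5d} {cube.origin[0]:13.6e} {cube.origin[1]:13.6e} {cube.origin[2]:13.6e}\n")
        for n, ax in zip(cube.shape, cube.axes):
            fh.write(f"{n:5d} {ax[0]:13.6e} {ax[1]:13.6e} {ax[2]:13.6e}\n")
        for a in cube.atoms:
            fh.write(
                f"{a.nuclear_charge:5d} {float(a.nuclear_charge):13.6e} "
                f"{a.position[0]:13.6e} {a.position[1]:13.6e} {a.position[2]:13.6e}\n"
            )
        flat = cube.values.reshape(-1)
        for start in range(0, flat.size, 6):
            fh.write(" ".join(f"{v: .12e}" for v in flat[start:start + 6]) + "\n")


def read_xyz(path) -> list[AtomSpec]:
    """Read an XYZ file (angstrom) into :class:`AtomSpec` positions in bohr."""
    with open(path) as fh:
        lines = fh.readlines()
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(path, 1, f"bad atom count: {exc}") from exc
    atoms = []
    for i in range(n):
        try:
            rec = lines[2 + i].split()
            el = rec[0]
            pos = np.array(rec[1:4], dtype=float) * ANGSTROM_TO_BOHR
        except (IndexError, ValueError) as exc:
            raise ParseError(path, 3 + i, f"bad coordinate record: {exc}") from exc
        atoms.append(AtomSpec(element=el, position=pos))
    return atoms


def read_table(path) -> pd.DataFrame:
    """Read a descriptor/label CSV; missing labels stay ``NaN``."""
    df = pd.read_csv(path, dtype={"molecule_id": str})
    missing = [c for c in ("molecule_id",) if c not in df.columns]
    if missing:
        raise ValueError(f"table lacks required columns: {missing}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")
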