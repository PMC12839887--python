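"""Electrostatic-potential descriptors and dataset curation.

The molecular electrostatic potential at a nucleus (MEP@atom),

    V(R_A) = sum_{B != A} Z_B / |R_A - R_B| - int rho(r) / |r - R_A| dr,

with the self-nucleus term excluded, is a proven predictor of acidity and
redox behaviour; for quinones it is evaluated at the two carbonyl oxygens
O1/O2 and averaged.  The electronic integral is done on the molecular
quadrature grid -- the atom-centered radial shells resolve the integrable
1/r singularity at the probe nucleus.

Curation implements the fixed exclusion rules for the 350-molecule quinone
reduction-potential compilation (indices 000-349): index 116 (structure
indeterminable from its name) and the duplicate pair 209/210 are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fields import DensityField, ScalarFieldSample
from .grids import AtomSpec, MolecularGrid, integrate

__all__ = [
    "mep_at_nucleus",
    "identify_carbonyl_oxygens",
    "curate_dataset",
    "CurationReport",
    "EXCLUDED_INDICES",
    "COVALENT_RADII_A",
]

# Covalent radii (angstrom), Cordero et al. values for the elements handled.
COVALENT_RADII_A = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_ANGSTROM_TO_BOHR = 1.8897259886
_BOND_SCALE = 1.15

#: 116: structure not determinable from its name; 209/210 duplicate 192/193.
EXCLUDED_INDICES = frozenset({116, 209, 210})


class CarbonylIdentificationError(ValueError):
    pass


def mep_at_nucleus(
    atoms: list[AtomSpec],
    field,
    grid: MolecularGrid,
    target_atom_index: int,
) -> float:
    """Molecular electrostatic potential at nucleus ``target_atom_index`` (a.u.)."""
    if not 0 <= target_atom_index < len(atoms):
        raise IndexError(f"target_atom_index {target_atom_index} out of range")
    target = atoms[target_atom_index]

    nuclear = 0.0
    for i, atom in enumerate(atoms):
        if i == target_atom_index:
            continue
        nuclear += atom.nuclear_charge / np.linalg.norm(atom.position - target.position)

    if isinstance(field, ScalarFieldSample):
        rho = field.rho
    elif isinstance(field, DensityField):
        rho = field.density(grid.points)
    else:
        rho = np.asarray(field, dtype=float)

    r = np.linalg.norm(grid.points - target.position, axis=1)
    if r.min() > 0.1:
        warnings.warn(
            "no grid point within 0.1 bohr of the probe nucleus; "
            "the electronic MEP integral may be inaccurate",
            RuntimeWarning,
            stacklevel=2,
        )
    electronic = integrate(rho / np.maximum(r, 1e-12), grid)
    return float(nuclear - electronic)


def _bond_matrix(atoms: list[AtomSpec], distance_matrix: np.ndarray | None) -> np.ndarray:
    pos = np.stack([a.position for a in atoms])
    d = distance_matrix if distance_matrix is not None else np.linalg.norm(
        pos[:, None, :] - pos[None, :, :], axis=2
    )
    radii = np.array([
        COVALENT_RADII_A.get(a.element, 0.77) * _ANGSTROM_TO_BOHR for a in atoms
    ])
    cutoff = _BOND_SCALE * (radii[:, None] + radii[None, :])
    bonded = (d < cutoff) & ~np.eye(len(atoms), dtype=bool)
    return bonded


def identify_carbonyl_oxygens(
    atoms: list[AtomSpec],
    distance_matrix: np.ndarray | None = None,
) -> tuple[int, int]:
    """Locate the two carbonyl (C=O) oxygens of a quinone scaffold.

    Bonds come from a covalent-radius distance criterion (scale 1.15);
    a candidate oxygen is bonded to exactly one atom, and that atom is a
    carbon.  If more than two candidates exist, the two with the shortest
    C-O distances are taken.  ``O1`` is the lower atom index.
    """
    bonded = _bond_matrix(atoms, distance_matrix)
    pos = np.stack([a.position for a in atoms])
    candidates = []
    oxygens = [i for i, a in enumerate(atoms) if a.element == "O"]
    for i in oxygens:
        nbrs = np.flatnonzero(bonded[i])
        if len(nbrs) == 1 and atoms[nbrs[0]].element == "C":
            candidates.append((float(np.linalg.norm(pos[i] - pos[nbrs[0]])), i))
    if len(candidates) < 2:
        raise CarbonylIdentificationError(
            f"found {len(candidates)} carbonyl-like oxygens among oxygens at "
            f"indices {oxygens}; need two"
        )
    candidates.sort()
    picked = sorted(i for _, i in candidates[:2])
    return picked[0], picked[1]


def carbonyl_mep_descriptors(atoms, field, grid) -> dict:
    """MEP at the two carbonyl oxygens and their average (a.u.).

    ``mep_o_avg`` is exactly the arithmetic mean of the two single-oxygen
    values; O1 is the lower atom index.
    """
    i1, i2 = identify_carbonyl_oxygens(atoms)
    v1 = mep_at_nucleus(atoms, field, grid, i1)
    v2 = mep_at_nucleus(atoms, field, grid, i2)
    return {"mep_o1": v1, "mep_o2": v2, "mep_o_avg": (v1 + v2) / 2.0}


@dataclass
class CurationReport:
    n_input: int
    excluded_ids: list[str]
    n_retained: int
    n_q1: int
    n_q2: int
    n_sigma_p: int


def curate_dataset(records) -> tuple[pd.DataFrame, CurationReport]:
    """Apply the fixed exclusion rules and count usable labels.

    ``records`` is a DataFrame (or coercible) with at least ``molecule_id``;
    label columns ``q1_mv``/``q2_mv``/``sigma_p`` may be absent or ``NaN``.
    Raises on duplicated ``molecule_id``.
    """
    df = pd.DataFrame(records)
    if df.empty:
        report = CurationReport(0, [], 0, 0, 0, 0)
        return df, report
    if "molecule_id" not in df.columns:
        raise ValueError("records lack a molecule_id column")
    ids = df["molecule_id"].astype(str)
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate molecule_id values: {dupes}")

    def _as_int(s):
        try:
            return int(s)
        except ValueError:
            return None

    drop = ids.map(lambda s: _as_int(s) in EXCLUDED_INDICES)
    curated = df.loc[~drop].reset_index(drop=True)

    def _count(col):
        if col not in curated.columns:
            return 0
        return int(curated[col].notna().sum())

    report = CurationReport(
        n_input=len(df),
        excluded_ids=sorted(ids[drop].tolist()),
        n_retained=len(curated),
        n_q1=_count("q1_mv"),
        n_q2=_count("q2_mv"),
        n_sigma_p=_count("sigma_p"),
    )
    return curated, report
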