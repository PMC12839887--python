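"""Analytic model densities and promolecular (free-atom) references.

Every field evaluator exposes ``density``, ``gradient`` and ``laplacian``
on arbitrary point sets and can be sampled onto a grid as a
:class:`ScalarFieldSample`.  These closed-form fields are the oracles for
the information-theoretic functionals: Gaussians and Slater 1s densities
have exact entropies, Fisher informations and divergences.

The bundled free-atom reference densities are single-zeta Slater-type
shell fits (exponents from Slater's screening rules), normalised to the
element's electron count.  They define the promolecule used by the
stockholder partition.  Users with their own spherically averaged atomic
densities (e.g. from a DFT code) can load them from two-column text
tables via :meth:`PromolecularReference.from_tables`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import gammaln

from .grids import AtomSpec, MolecularGrid, integrate

__all__ = [
    "ScalarFieldSample",
    "DensityField",
    "gaussian_density",
    "slater_1s_density",
    "SuperpositionField",
    "PromolecularReference",
    "build_promolecule",
    "normalize_reference",
]


@dataclass
class ScalarFieldSample:
    """Density, gradient and Laplacian of one field evaluated on a point set.

    ``orbital_rho`` optionally carries occupation-weighted orbital densities
    ``rho_i`` with their gradients; they must sum pointwise to ``rho``.
    """

    rho: np.ndarray                 # (n,)
    grad: np.ndarray                # (n, 3)
    laplacian: np.ndarray           # (n,)
    orbital_rho: list[tuple[np.ndarray, np.ndarray]] | None = None
    orbital_occupations: np.ndarray | None = None

    def __post_init__(self):
        if np.any(self.rho < -1e-10):
            raise ValueError("density must be non-negative")
        self.rho = np.maximum(self.rho, 0.0)
        if self.orbital_rho is not None:
            total = sum(r for r, _ in self.orbital_rho)
            if not np.allclose(total, self.rho, atol=1e-8):
                raise ValueError("orbital densities must sum to the total density")


class DensityField:
    """Base class for analytic fields; subclasses fill in the radial parts."""

    electron_count: float = 0.0

    def density(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def gradient(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def laplacian(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def orbitals(self, points: np.ndarray):
        """Occupation-weighted orbital densities; default: one orbital."""
        return [(self.density(points), self.gradient(points))]

    def sample(self, grid: MolecularGrid | np.ndarray, with_orbitals: bool = False) -> ScalarFieldSample:
        pts = grid.points if isinstance(grid, MolecularGrid) else np.asarray(grid)
        orb = self.orbitals(pts) if with_orbitals else None
        return ScalarFieldSample(
            rho=self.density(pts),
            grad=self.gradient(pts),
            laplacian=self.laplacian(pts),
            orbital_rho=orb,
        )


class GaussianDensity(DensityField):
    """``rho = N (a/pi)^{3/2} exp(-a |r-c|^2)`` with exact derivatives."""

    def __init__(self, n_electrons: float, alpha: float, center=(0.0, 0.0, 0.0)):
        if alpha <= 0:
            raise ValueError(f"alpha must be positive, got {alpha}")
        if n_electrons <= 0:
            raise ValueError("n_electrons must be positive")
        self.alpha = float(alpha)
        self.center = np.asarray(center, dtype=float)
        self.electron_count = float(n_electrons)
        self._norm = n_electrons * (alpha / math.pi) ** 1.5

    def density(self, points):
        d = points - self.center
        return self._norm * np.exp(-self.alpha * np.einsum("ij,ij->i", d, d))

    def gradient(self, points):
        d = points - self.center
        return -2.0 * self.alpha * self.density(points)[:, None] * d

    def laplacian(self, points):
        d = points - self.center
        r2 = np.einsum("ij,ij->i", d, d)
        return self.density(points) * (4.0 * self.alpha**2 * r2 - 6.0 * self.alpha)


class Slater1sDensity(DensityField):
    """``rho = N (Z^3/pi) exp(-2 Z |r-c|)``: cusped hydrogen-like density."""

    def __init__(self, Z: float, center=(0.0, 0.0, 0.0), n_electrons: float = 1.0):
        if Z <= 0:
            raise ValueError(f"Z must be positive, got {Z}")
        self.Z = float(Z)
        self.center = np.asarray(center, dtype=float)
        self.electron_count = float(n_electrons)
        self._norm = n_electrons * Z**3 / math.pi

    def _r(self, points):
        return np.linalg.norm(points - self.center, axis=1)

    def density(self, points):
        return self._norm * np.exp(-2.0 * self.Z * self._r(points))

    def gradient(self, points):
        d = points - self.center
        r = self._r(points)
        safe = np.maximum(r, 1e-300)
        return (-2.0 * self.Z * self.density(points) / safe)[:, None] * d

    def laplacian(self, points):
        r = np.maximum(self._r(points), 1e-300)
        rho = self.density(points)
        return rho * (4.0 * self.Z**2 - 4.0 * self.Z / r)


def gaussian_density(n_electrons: float, alpha: float, center=(0.0, 0.0, 0.0)) -> GaussianDensity:
    """Normalised Gaussian model density (see :class:`GaussianDensity`)."""
    return GaussianDensity(n_electrons, alpha, center)


def slater_1s_density(Z: float, center=(0.0, 0.0, 0.0)) -> Slater1sDensity:
    """Hydrogen-like 1s density with a nuclear cusp at ``center``."""
    return Slater1sDensity(Z, center)


class SuperpositionField(DensityField):
    """Sum of component fields; each component is one 'orbital' shell."""

    def __init__(self, components: list[DensityField]):
        if not components:
            raise ValueError("need at least one component")
        self.components = list(components)
        self.electron_count = float(sum(c.electron_count for c in components))

    def density(self, points):
        return np.sum([c.density(points) for c in self.components], axis=0)

    def gradient(self, points):
        return np.sum([c.gradient(points) for c in self.components], axis=0)

    def laplacian(self, points):
        return np.sum([c.laplacian(points) for c in self.components], axis=0)

    def orbitals(self, points):
        return [(c.density(points), c.gradient(points)) for c in self.components]


class ScaledField(DensityField):
    def __init__(self, base: DensityField, factor: float):
        self.base = base
        self.factor = float(factor)
        self.electron_count = base.electron_count * factor

    def density(self, points):
        return self.factor * self.base.density(points)

    def gradient(self, points):
        return self.factor * self.base.gradient(points)

    def laplacian(self, points):
        return self.factor * self.base.laplacian(points)

    def orbitals(self, points):
        return [(self.factor * r, self.factor * g) for r, g in self.base.orbitals(points)]


# ---------------------------------------------------------------------------
# Free-atom radial densities
# ---------------------------------------------------------------------------

class RadialDensity:
    """Interface: spherically averaged atomic density and radial derivatives."""

    electron_count: float = 0.0

    def rho(self, r: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def drho(self, r: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def d2rho(self, r: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# Slater-rule shells: (principal n, effective n*, occupation, zeta).
# zeta = (Z - s)/n* with the standard screening constants.
def _slater_shells(Z: int) -> list[tuple[int, float, float, float]]:
    shells = []  # (n, occ)
    remaining = Z
    for n, cap in ((1, 2), (2, 8), (3, 8)):
        occ = min(remaining, cap)
        if occ > 0:
            shells.append((n, occ))
            remaining -= occ
    if remaining > 0:  # 3d then 4s4p (enough for Z <= 36)
        occ_d = min(remaining, 10)
        shells.append((3.5, occ_d))  # marker for the d group
        remaining -= occ_d
    if remaining > 0:
        shells.append((4, remaining))

    out = []
    nstar = {1: 1.0, 2: 2.0, 3: 3.0, 4: 3.7}
    for idx, (n, occ) in enumerate(shells):
        is_d = n == 3.5
        n_eff = 3 if is_d else int(n)
        same = 0.35 if n_eff > 1 else 0.30
        s = (occ - 1) * same
        for n2, occ2 in shells[:idx]:
            n2_eff = 3 if n2 == 3.5 else int(n2)
            if is_d:
                s += occ2  # d electrons: all inner groups screen fully
            elif n2_eff == n_eff - 1:
                s += 0.85 * occ2
            elif n2_eff <= n_eff - 2:
                s += 1.00 * occ2
            else:
                s += 0.35 * occ2  # same-n s,p group reached via d marker
        zeta = (Z - s) / nstar[n_eff]
        out.append((n_eff, nstar[n_eff], float(occ), max(zeta, 0.3)))
    return out


class SlaterAtomDensity(RadialDensity):
    """Single-zeta Slater-shell fit: ``rho = sum_k c_k r^{2n_k-2} e^{-2 z_k r}``.

    Each shell is normalised so that ``4 pi \\int rho_k r^2 dr = occ_k``.
    """

    def __init__(self, Z: int):
        self.Z = Z
        self.electron_count = float(Z)
        self._terms = []  # (coef, power, 2*zeta)
        for n, _, occ, zeta in _slater_shells(Z):
            p = 2 * n - 2
            # int r^(p+2) e^(-2 zeta r) dr = (p+2)! / (2 zeta)^(p+3)
            lognorm = math.log(occ) + (p + 3) * math.log(2 * zeta) \
                - math.log(4 * math.pi) - gammaln(p + 3)
            self._terms.append((math.exp(lognorm), p, 2.0 * zeta))

    def rho(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for c, p, tz in self._terms:
            out += c * r**p * np.exp(-tz * r)
        return out

    def drho(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for c, p, tz in self._terms:
            e = np.exp(-tz * r)
            term = -tz * c * r**p * e
            if p > 0:
                term = term + c * p * r ** (p - 1) * e
            out += term
        return out

    def d2rho(self, r):
        r = np.asarray(r, dtype=float)
        out = np.zeros_like(r)
        for c, p, tz in self._terms:
            e = np.exp(-tz * r)
            term = tz**2 * c * r**p * e
            if p > 0:
                term = term - 2.0 * tz * c * p * r ** (p - 1) * e
            if p > 1:
                term = term + c * p * (p - 1) * r ** (p - 2) * e
            out += term
        return out


class TabulatedRadialDensity(RadialDensity):
    """Radial density from an (r, rho) table.

    Interpolation is a cubic spline in ``log rho`` versus ``r`` (guaranteeing
    positivity and smooth derivatives), with linear-in-log (exponential) tail
    extrapolation beyond the last tabulated radius.
    """

    def __init__(self, r: np.ndarray, rho: np.ndarray, electron_count: float):
        r = np.asarray(r, dtype=float)
        rho = np.asarray(rho, dtype=float)
        if np.any(rho <= 0):
            raise ValueError("tabulated densities must be strictly positive")
        order = np.argsort(r)
        self._rmin, self._rmax = r[order][0], r[order][-1]
        self._spl = CubicSpline(r[order], np.log(rho[order]))
        self._tail_slope = float(self._spl(self._rmax, 1))
        self._tail_log = float(self._spl(self._rmax))
        self.electron_count = float(electron_count)

    def _logrho(self, r, der=0):
        r = np.asarray(r, dtype=float)
        rc = np.clip(r, self._rmin, self._rmax)
        val = self._spl(rc, der)
        tail = r > self._rmax
        if np.any(tail):
            if der == 0:
                val = np.where(tail, self._tail_log + self._tail_slope * (r - self._rmax), val)
            elif der == 1:
                val = np.where(tail, self._tail_slope, val)
            else:
                val = np.where(tail, 0.0, val)
        return val

    def rho(self, r):
        return np.exp(self._logrho(r))

    def drho(self, r):
        return self.rho(r) * self._logrho(r, 1)

    def d2rho(self, r):
        l1 = self._logrho(r, 1)
        return self.rho(r) * (l1**2 + self._logrho(r, 2))


_DEFAULT_ELEMENTS = ("H", "C", "N", "O", "F", "S", "Cl", "Br")


@dataclass
class PromolecularReference:
    """Per-element spherically averaged free-atom densities rho_A^0."""

    atoms: dict[str, RadialDensity] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "PromolecularReference":
        """Bundled Slater-shell fits for H, C, N, O, F, S, Cl, Br."""
        from .grids import ELEMENT_NUMBERS
        return cls({el: SlaterAtomDensity(ELEMENT_NUMBERS[el]) for el in _DEFAULT_ELEMENTS})

    @classmethod
    def from_tables(cls, tables: dict[str, str], electron_counts: dict[str, float]) -> "PromolecularReference":
        """Load per-element two-column (r_bohr, density) text tables."""
        atoms = {}
        for el, path in tables.items():
            data = np.loadtxt(path)
            atoms[el] = TabulatedRadialDensity(data[:, 0], data[:, 1], electron_counts[el])
        return cls(atoms)

    def __contains__(self, element: str) -> bool:
        return element in self.atoms

    def __getitem__(self, element: str) -> RadialDensity:
        if element not in self.atoms:
            raise KeyError(f"no reference atomic density for element {element!r}")
        return self.atoms[element]


class _CenteredRadialField(DensityField):
    """A radial atomic density placed at a nucleus."""

    def __init__(self, radial: RadialDensity, center: np.ndarray):
        self.radial = radial
        self.center = np.asarray(center, dtype=float)
        self.electron_count = radial.electron_count

    def _r(self, points):
        return np.maximum(np.linalg.norm(points - self.center, axis=1), 1e-300)

    def density(self, points):
        return self.radial.rho(self._r(points))

    def gradient(self, points):
        r = self._r(points)
        return (self.radial.drho(r) / r)[:, None] * (points - self.center)

    def laplacian(self, points):
        r = self._r(points)
        return self.radial.d2rho(r) + 2.0 / r * self.radial.drho(r)


class PromoleculeField(SuperpositionField):
    """Superposition of free-atom densities at the molecular geometry."""

    def __init__(self, atoms: list[AtomSpec], ref: PromolecularReference):
        missing = sorted({a.element for a in atoms if a.element not in ref})
        if missing:
            raise KeyError(f"reference lacks atomic densities for: {', '.join(missing)}")
        super().__init__([_CenteredRadialField(ref[a.element], a.position) for a in atoms])
        self.atoms = list(atoms)

    def atomic_terms(self, points: np.ndarray) -> np.ndarray:
        """Per-atom reference densities rho_A^0(|r - R_A|), shape (A, n)."""
        return np.stack([c.density(points) for c in self.components])


def build_promolecule(atoms: list[AtomSpec], ref: PromolecularReference) -> PromoleculeField:
    """Superpose spherically averaged free atoms at the molecular geometry."""
    return PromoleculeField(atoms, ref)


def normalize_reference(ref_field: DensityField, target_N: float, grid: MolecularGrid) -> ScaledField:
    """Uniformly rescale a field so its grid integral equals ``target_N``."""
    total = integrate(ref_field.density(grid.points), grid)
    if total <= 0:
        raise ValueError("cannot normalize a field with non-positive integral")
    return ScaledField(ref_field, target_N / total)
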