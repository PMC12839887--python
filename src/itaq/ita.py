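"""The eleven information-theoretic (ITA) density functionals.

All quantities are functionals of the molecular electron density rho(r),
its gradient and Laplacian, evaluated by multicenter quadrature in atomic
units:

* Shannon entropy        S_S   = -int rho ln rho dr
* Fisher information     I_F   =  int |grad rho|^2 / rho dr
* GBP entropy            S_GBP = -int (3/2) k rho [c + ln(t/t_TF)] dr
* Onicescu energies      E_n   = 1/(n-1) int rho^n dr            (n = 2, 3)
* relative Renyi         rR_n  = 1/(1-n) log10 int rho^n/rho0^(n-1) dr
* information gain       I_G   =  int rho ln(rho/rho0) dr
* relative-Fisher G1/G2/G3 over Hirshfeld atoms (see :func:`g_functions`)

The reference density rho0 for the relative quantities is the promolecule,
rescaled to the molecular electron count; the G functions use the raw
free-atom references, whose definition imposes no normalization.

The GBP (Ghosh-Berkowitz-Parr) entropy needs the non-interacting kinetic
energy density built from occupation-weighted orbital densities,

    t = sum_i (1/8) |grad rho_i|^2 / rho_i - (1/8) lap rho,

compared against the Thomas-Fermi form t_TF = c_K rho^{5/3}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .fields import (
    DensityField,
    PromolecularReference,
    ScalarFieldSample,
    build_promolecule,
    normalize_reference,
)
from .grids import AtomSpec, MolecularGrid, integrate
from .hirshfeld import AtomicPartition, hirshfeld_partition

__all__ = [
    "ITAVector",
    "KineticDensities",
    "C_K",
    "GBP_C",
    "DENSITY_FLOOR",
    "shannon_entropy",
    "fisher_information",
    "kinetic_energy_densities",
    "gbp_entropy",
    "onicescu_energy",
    "relative_renyi",
    "information_gain",
    "g_functions",
    "compute_ita_vector",
]

#: Thomas-Fermi constant (3/10) (3 pi^2)^(2/3).
C_K = 0.3 * (3.0 * math.pi**2) ** (2.0 / 3.0)
#: GBP constant c = 5/3 + ln(4 pi c_K / 3).
GBP_C = 5.0 / 3.0 + math.log(4.0 * math.pi * C_K / 3.0)
#: Densities below this (e/bohr^3) contribute nothing to logarithmic integrands.
DENSITY_FLOOR = 1e-12
_SIGNIFICANT = 1e-8


class ITADataError(ValueError):
    pass


class ITANumericalError(RuntimeError):
    pass


@dataclass(frozen=True)
class ITAVector:
    """The 11 ITA quantities of one molecule, canonical order, atomic units."""

    S_S: float
    I_F: float
    S_GBP: float
    E2: float
    E3: float
    rR2: float
    rR3: float
    I_G: float
    G1: float
    G2: float
    G3: float

    NAMES = ("S_S", "I_F", "S_GBP", "E2", "E3", "rR2", "rR3", "I_G", "G1", "G2", "G3")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.NAMES], dtype=float)

    def __len__(self) -> int:
        return len(self.NAMES)


@dataclass
class KineticDensities:
    """Pointwise kinetic-energy densities and the total kinetic energy."""

    t: np.ndarray        # non-interacting KE density
    t_TF: np.ndarray     # Thomas-Fermi KE density
    T_S: float           # int t dr, hartree


def _as_sample(field, grid: MolecularGrid, with_orbitals: bool = False) -> ScalarFieldSample:
    if isinstance(field, ScalarFieldSample):
        return field
    if isinstance(field, DensityField):
        return field.sample(grid, with_orbitals=with_orbitals)
    raise TypeError(f"expected ScalarFieldSample or DensityField, got {type(field)!r}")


def _check_rho(rho: np.ndarray) -> np.ndarray:
    if np.any(rho < -1e-10):
        raise ITADataError(f"density dips to {rho.min():.3e}; negative beyond tolerance")
    return np.maximum(rho, 0.0)


def shannon_entropy(field, grid: MolecularGrid) -> float:
    """S_S = -int rho ln rho dr; the integrand vanishes below the floor."""
    s = _as_sample(field, grid)
    rho = _check_rho(s.rho)
    mask = rho > DENSITY_FLOOR
    integrand = np.zeros_like(rho)
    integrand[mask] = -rho[mask] * np.log(rho[mask])
    return integrate(integrand, grid)


def fisher_information(field, grid: MolecularGrid) -> float:
    """I_F = int |grad rho|^2 / rho dr (non-negative by construction)."""
    s = _as_sample(field, grid)
    rho = _check_rho(s.rho)
    g2 = np.einsum("ij,ij->i", s.grad, s.grad)
    mask = rho > DENSITY_FLOOR
    integrand = np.zeros_like(rho)
    integrand[mask] = g2[mask] / rho[mask]
    return integrate(integrand, grid)


def kinetic_energy_densities(field, grid: MolecularGrid) -> KineticDensities:
    """Orbital-resolved t(r), Thomas-Fermi t_TF(r) and T_S = int t dr."""
    s = _as_sample(field, grid, with_orbitals=True)
    if s.orbital_rho is None:
        raise ITADataError("kinetic energy density requires orbital densities")
    rho = _check_rho(s.rho)
    t = -0.125 * s.laplacian
    for orb_rho, orb_grad in s.orbital_rho:
        g2 = np.einsum("ij,ij->i", orb_grad, orb_grad)
        mask = orb_rho > DENSITY_FLOOR
        contrib = np.zeros_like(rho)
        contrib[mask] = 0.125 * g2[mask] / orb_rho[mask]
        t = t + contrib
    t_tf = C_K * rho ** (5.0 / 3.0)
    return KineticDensities(t=t, t_TF=t_tf, T_S=integrate(t, grid))


def gbp_entropy(field, kd: KineticDensities, grid: MolecularGrid, k: float = 1.0) -> float:
    """Ghosh-Berkowitz-Parr entropy -int (3/2) k rho [c + ln(t/t_TF)] dr.

    ``k`` is the Boltzmann constant, 1 in atomic units.
    """
    s = _as_sample(field, grid)
    rho = _check_rho(s.rho)
    mask = rho > DENSITY_FLOOR
    bad = mask & (rho > _SIGNIFICANT) & ((kd.t <= 0.0) | (kd.t_TF <= 0.0))
    if np.any(bad):
        raise ITANumericalError(
            f"non-positive kinetic energy density on {int(bad.sum())} points "
            "carrying significant density"
        )
    ok = mask & (kd.t > 0.0) & (kd.t_TF > 0.0)
    integrand = np.zeros_like(rho)
    integrand[ok] = -1.5 * k * rho[ok] * (GBP_C + np.log(kd.t[ok] / kd.t_TF[ok]))
    return integrate(integrand, grid)


def onicescu_energy(field, grid: MolecularGrid, order: int, prefactor: float | None = None) -> float:
    """Onicescu information energy E_n = 1/(n-1) int rho^n dr, n in {2, 3}."""
    if order not in (2, 3):
        raise ValueError(f"Onicescu order must be 2 or 3, got {order}")
    s = _as_sample(field, grid)
    rho = _check_rho(s.rho)
    pref = 1.0 / (order - 1) if prefactor is None else prefactor
    return pref * integrate(rho**order, grid)


def _clamped_reference(rho: np.ndarray, rho0: np.ndarray, what: str) -> np.ndarray:
    starved = (rho > DENSITY_FLOOR) & (rho0 < DENSITY_FLOOR)
    if np.any(starved):
        warnings.warn(
            f"{what}: reference density below floor on {int(starved.sum())} points "
            "with molecular density present; floor applied",
            RuntimeWarning,
            stacklevel=3,
        )
    return np.maximum(rho0, DENSITY_FLOOR)


def relative_renyi(field, ref_field, grid: MolecularGrid, order: int) -> float:
    """Relative Renyi entropy 1/(1-n) log10 int rho^n / rho0^(n-1) dr.

    ``rho`` and ``rho0`` are expected to share one normalization.
    """
    if order not in (2, 3):
        raise ValueError(f"Renyi order must be 2 or 3, got {order}")
    s = _as_sample(field, grid)
    r = _as_sample(ref_field, grid)
    rho = _check_rho(s.rho)
    rho0 = _clamped_reference(rho, r.rho, "relative_renyi")
    mask = rho > DENSITY_FLOOR
    integrand = np.zeros_like(rho)
    integrand[mask] = rho[mask] ** order / rho0[mask] ** (order - 1)
    return (1.0 / (1.0 - order)) * math.log10(integrate(integrand, grid))


def information_gain(field, ref_field, grid: MolecularGrid) -> float:
    """Kullback-Leibler divergence int rho ln(rho/rho0) dr."""
    s = _as_sample(field, grid)
    r = _as_sample(ref_field, grid)
    rho = _check_rho(s.rho)
    rho0 = _clamped_reference(rho, r.rho, "information_gain")
    mask = rho > DENSITY_FLOOR
    integrand = np.zeros_like(rho)
    integrand[mask] = rho[mask] * np.log(rho[mask] / rho0[mask])
    return integrate(integrand, grid)


def g_functions(partition: AtomicPartition, grid: MolecularGrid) -> tuple[float, float, float]:
    """Relative-Fisher deformation functionals (G1, G2, G3) over Hirshfeld atoms.

    For stockholder weights the per-atom ratio rho_A/rho_A^0 equals
    rho/rho_promol at every point, so the atomic sums collapse to molecular
    integrals weighted by the total density:

        G3 = int rho |grad ln(rho/rho0)|^2 dr
        G1 = int (lap rho) (rho/rho0) dr
        G2 = int [lap rho - (rho/rho0) lap rho0] dr

    with rho0 the (raw, unnormalized) promolecular density.
    """
    f = partition.field
    if f.laplacian is None or partition.promolecule_lap is None:
        raise ITADataError("G functions require Laplacians of density and promolecule")
    rho = _check_rho(f.rho)
    rho0 = np.maximum(partition.promolecule_rho, DENSITY_FLOOR)
    mask = rho > DENSITY_FLOOR

    ratio = np.zeros_like(rho)
    ratio[mask] = rho[mask] / rho0[mask]

    # grad ln(rho/rho0) = grad rho / rho - grad rho0 / rho0
    v = np.zeros_like(f.grad)
    v[mask] = f.grad[mask] / rho[mask, None] - partition.promolecule_grad[mask] / rho0[mask, None]
    g3 = integrate(rho * np.einsum("ij,ij->i", v, v), grid)
    g1 = integrate(f.laplacian * ratio, grid)
    g2 = integrate(np.where(mask, f.laplacian - ratio * partition.promolecule_lap, 0.0), grid)
    return g1, g2, g3


def compute_ita_vector(
    field,
    atoms: list[AtomSpec],
    ref: PromolecularReference,
    grid: MolecularGrid,
) -> ITAVector:
    """Evaluate all 11 ITA quantities for one molecule on one grid.

    The promolecular reference is rescaled to the molecular electron count
    (as measured on the grid) before the relative Renyi entropies and the
    information gain; the G functions see the raw free-atom reference.
    """
    s = _as_sample(field, grid, with_orbitals=True)
    promol = build_promolecule(atoms, ref)
    n_mol = integrate(_check_rho(s.rho), grid)
    promol_scaled = normalize_reference(promol, n_mol, grid).sample(grid)
    partition = hirshfeld_partition(s, atoms, promol, grid)

    values: dict[str, float] = {}

    def step(name: str, fn):
        try:
            values[name] = fn()
        except Exception as exc:  # label which quantity failed
            raise type(exc)(f"{name}: {exc}") from exc

    step("S_S", lambda: shannon_entropy(s, grid))
    step("I_F", lambda: fisher_information(s, grid))
    step("S_GBP", lambda: gbp_entropy(s, kinetic_energy_densities(s, grid), grid))
    step("E2", lambda: onicescu_energy(s, grid, 2))
    step("E3", lambda: onicescu_energy(s, grid, 3))
    step("rR2", lambda: relative_renyi(s, promol_scaled, grid, 2))
    step("rR3", lambda: relative_renyi(s, promol_scaled, grid, 3))
    step("I_G", lambda: information_gain(s, promol_scaled, grid))

    def _g():
        return g_functions(partition, grid)

    try:
        g1, g2, g3 = _g()
    except Exception as exc:
        raise type(exc)(f"G1/G2/G3: {exc}") from exc
    values.update(G1=g1, G2=g2, G3=g3)

    return ITAVector(**values)
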