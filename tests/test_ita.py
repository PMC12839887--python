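import math

import numpy as np
import pytest

from itaq import (
    AtomSpec,
    PromolecularReference,
    build_molecular_grid,
    compute_ita_vector,
    fisher_information,
    g_functions,
    gaussian_density,
    gbp_entropy,
    hirshfeld_partition,
    information_gain,
    integrate,
    kinetic_energy_densities,
    normalize_reference,
    onicescu_energy,
    relative_renyi,
    shannon_entropy,
    slater_1s_density,
)
from itaq.ita import C_K, GBP_C, ITANumericalError, ITAVector, KineticDensities
from itaq.fields import SuperpositionField
from itaq.synth import GaussianRadial, _CenteredGaussian

from oracles import radial_integral

GAUSS_S = 1.5 * (1.0 + math.log(math.pi))  # Shannon entropy of the unit Gaussian


class TestShannon:
    def test_unit_gaussian_closed_form(self, grid_h_default):
        f = gaussian_density(1.0, 1.0)
        assert shannon_entropy(f, grid_h_default) == pytest.approx(GAUSS_S, rel=1e-6)

    def test_slater_closed_form(self, grid_h_default):
        f = slater_1s_density(1.0)
        assert shannon_entropy(f, grid_h_default) == pytest.approx(
            3.0 + math.log(math.pi), rel=1e-5
        )

    def test_scaling_law(self, grid_h_default):
        """rho_lambda(r) = lambda^3 rho(lambda r) lowers S by 3 ln lambda."""
        s1 = shannon_entropy(gaussian_density(1.0, 1.0), grid_h_default)
        s2 = shannon_entropy(gaussian_density(1.0, 4.0), grid_h_default)
        assert s2 - s1 == pytest.approx(-3.0 * math.log(2.0), abs=1e-6)


class TestFisher:
    def test_unit_gaussian(self, grid_h_default):
        assert fisher_information(gaussian_density(1.0, 1.0), grid_h_default) == pytest.approx(
            6.0, rel=1e-6
        )

    def test_slater_4z2_identity(self, grid_h_default):
        assert fisher_information(slater_1s_density(2.0), grid_h_default) == pytest.approx(
            16.0, rel=1e-6
        )

    def test_positive_on_random_fields(self, grid_h_coarse):
        rng = np.random.default_rng(0)
        for _ in range(5):
            f = gaussian_density(rng.uniform(0.5, 4.0), rng.uniform(0.3, 3.0))
            assert fisher_information(f, grid_h_coarse) > 0


class TestKineticDensities:
    def test_ck_constant(self):
        assert C_K == pytest.approx(2.8712, abs=1e-4)

    def test_doubly_occupied_gaussian_orbital(self, grid_h_default):
        """One Gaussian orbital with two electrons: T_S = 2 * (3 alpha / 4)."""
        alpha = 1.3
        f = gaussian_density(2.0, alpha)
        kd = kinetic_energy_densities(f, grid_h_default)
        assert kd.T_S == pytest.approx(2.0 * 0.75 * alpha, rel=1e-6)

    def test_thomas_fermi_pointwise(self, grid_h_coarse):
        f = gaussian_density(1.0, 1.0)
        kd = kinetic_energy_densities(f, grid_h_coarse)
        rho = f.density(grid_h_coarse.points)
        assert np.allclose(kd.t_TF, C_K * rho ** (5.0 / 3.0), rtol=1e-12)

    def test_missing_orbitals_rejected(self, grid_h_coarse):
        f = gaussian_density(1.0, 1.0)
        sample = f.sample(grid_h_coarse, with_orbitals=False)
        with pytest.raises(ValueError, match="orbital"):
            kinetic_energy_densities(sample, grid_h_coarse)


class TestGBP:
    def test_thomas_fermi_limit(self, grid_h_default):
        """t == t_TF collapses the log; S_GBP = -(3/2) c N."""
        f = gaussian_density(1.0, 1.0)
        rho = f.density(grid_h_default.points)
        ttf = C_K * rho ** (5.0 / 3.0)
        kd = KineticDensities(t=ttf.copy(), t_TF=ttf, T_S=0.0)
        expected = -1.5 * GBP_C * 1.0
        assert gbp_entropy(f, kd, grid_h_default) == pytest.approx(expected, abs=1e-6)

    def test_gaussian_against_radial_oracle(self, grid_h_default):
        alpha = 1.0
        f = gaussian_density(1.0, alpha)
        kd = kinetic_energy_densities(f, grid_h_default)
        value = gbp_entropy(f, kd, grid_h_default)

        def integrand(r):
            rho = (alpha / math.pi) ** 1.5 * np.exp(-alpha * r**2)
            t = 0.75 * alpha * rho
            ttf = C_K * rho ** (5.0 / 3.0)
            return -1.5 * rho * (GBP_C + np.log(t / ttf))

        # rmax bounded: the analytic integrand underflows to 0/0 beyond ~r=12
        assert value == pytest.approx(radial_integral(integrand, rmax=12.0), rel=1e-5)

    def test_negative_t_reported_with_count(self, grid_h_coarse):
        f = gaussian_density(1.0, 1.0)
        rho = f.density(grid_h_coarse.points)
        t = rho.copy()
        t[np.argsort(rho)[-10:]] = -1.0  # corrupt points carrying real density
        kd = KineticDensities(t=t, t_TF=C_K * rho ** (5 / 3), T_S=0.0)
        with pytest.raises(ITANumericalError, match="10 points"):
            gbp_entropy(f, kd, grid_h_coarse)


class TestOnicescu:
    def test_order2_closed_form(self, grid_h_default):
        f = gaussian_density(1.0, 1.0)
        assert onicescu_energy(f, grid_h_default, 2) == pytest.approx(
            (1.0 / (2.0 * math.pi)) ** 1.5, rel=1e-6
        )

    def test_order3_closed_form(self, grid_h_default):
        alpha = 1.0
        f = gaussian_density(1.0, alpha)
        expected = 0.5 * (alpha**2 / (3.0 * math.pi**2)) ** 1.5
        assert onicescu_energy(f, grid_h_default, 3) == pytest.approx(expected, rel=1e-6)

    def test_homogeneity_in_electron_count(self, grid_h_default):
        one = onicescu_energy(gaussian_density(1.0, 1.0), grid_h_default, 2)
        two = onicescu_energy(gaussian_density(2.0, 1.0), grid_h_default, 2)
        assert two == pytest.approx(4.0 * one, rel=1e-10)

    def test_unsupported_order(self, grid_h_coarse):
        with pytest.raises(ValueError, match="order"):
            onicescu_energy(gaussian_density(1.0, 1.0), grid_h_coarse, 4)


class TestRelativeRenyi:
    def test_self_reference_unit_norm(self, grid_h_default):
        f = gaussian_density(1.0, 1.0)
        assert relative_renyi(f, f, grid_h_default, 2) == pytest.approx(0.0, abs=1e-9)

    def test_self_reference_ten_electrons(self, grid_h_default):
        f = gaussian_density(10.0, 1.0)
        assert relative_renyi(f, f, grid_h_default, 2) == pytest.approx(-1.0, abs=1e-9)

    @pytest.mark.parametrize("order", [2, 3])
    def test_gaussian_pair_against_radial_oracle(self, order, grid_h_default):
        # convergence of int rho^n / rho0^(n-1) needs a0 < n a / (n-1)
        a, a0 = 1.0, 1.2
        f = gaussian_density(1.0, a)
        ref = gaussian_density(1.0, a0)

        def integrand(r):
            rho = (a / math.pi) ** 1.5 * np.exp(-a * r**2)
            rho0 = (a0 / math.pi) ** 1.5 * np.exp(-a0 * r**2)
            return rho**order / rho0 ** (order - 1)

        expected = (1.0 / (1.0 - order)) * math.log10(radial_integral(integrand, rmax=15.0))
        # the density floor truncates the slowly converging ratio tail, so
        # agreement is at the default-grid band (1e-4), not machine precision
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                got = relative_renyi(f, ref, grid_h_default, order)
        assert got == pytest.approx(expected, rel=1e-4, abs=1e-6)


class TestInformationGain:
    def test_self_reference_zero(self, grid_h_default):
        f = gaussian_density(1.0, 1.0)
        assert information_gain(f, f, grid_h_default) == pytest.approx(0.0, abs=1e-10)

    def test_gaussian_kl_closed_form(self, grid_h_default):
        f = gaussian_density(1.0, 2.0)
        ref = gaussian_density(1.0, 1.0)
        expected = 1.5 * (math.log(2.0) - 0.5)
        assert information_gain(f, ref, grid_h_default) == pytest.approx(expected, rel=1e-6)

    def test_starved_reference_warns(self, grid_h_coarse):
        f = gaussian_density(1.0, 0.5)
        ref = gaussian_density(1.0, 20.0)  # collapses to nothing in the tails
        with pytest.warns(RuntimeWarning, match="floor"):
            information_gain(f, ref, grid_h_coarse)


class TestGFunctions:
    @staticmethod
    def _one_atom_partition(alpha, alpha0, grid):
        atoms = [AtomSpec("O", [0.0, 0.0, 0.0])]
        ref = PromolecularReference({"O": GaussianRadial(1.0, alpha0)})
        field = SuperpositionField([_CenteredGaussian(1.0, alpha, (0, 0, 0))])
        s = field.sample(grid, with_orbitals=True)
        return hirshfeld_partition(s, atoms, ref, grid)

    def test_self_reference_all_zero(self, grid_h_default):
        part = self._one_atom_partition(1.0, 1.0, grid_h_default)
        g1, g2, g3 = g_functions(part, grid_h_default)
        assert abs(g3) < 1e-10
        assert abs(g2) < 1e-10
        assert abs(g1) < 1e-5  # bounded by the Laplacian quadrature residual

    def test_g3_analytic_and_nonnegative(self, grid_h_default):
        a, a0 = 2.0, 1.0
        part = self._one_atom_partition(a, a0, grid_h_default)
        _, _, g3 = g_functions(part, grid_h_default)
        assert g3 == pytest.approx(6.0 * (a - a0) ** 2 / a, rel=1e-6)
        assert g3 >= 0.0

    def test_g1_g2_against_radial_oracle(self, grid_h_default):
        a, a0 = 2.0, 1.0
        part = self._one_atom_partition(a, a0, grid_h_default)
        g1, g2, _ = g_functions(part, grid_h_default)

        def rho(r, al):
            return (al / math.pi) ** 1.5 * np.exp(-al * r**2)

        def lap(r, al):
            return (4 * al**2 * r**2 - 6 * al) * rho(r, al)

        g1_oracle = radial_integral(lambda r: lap(r, a) * rho(r, a) / rho(r, a0), rmax=20.0)
        g2_oracle = radial_integral(
            lambda r: lap(r, a) - rho(r, a) / rho(r, a0) * lap(r, a0), rmax=20.0
        )
        assert g1 == pytest.approx(g1_oracle, rel=1e-4, abs=1e-4)
        assert g2 == pytest.approx(g2_oracle, rel=1e-4, abs=1e-4)


class TestITAVector:
    @staticmethod
    def _single_atom_toy():
        atoms = [AtomSpec("O", [0.0, 0.0, 0.0])]
        ref = PromolecularReference({"O": GaussianRadial(8.0, 1.1)})
        field = SuperpositionField([_CenteredGaussian(8.0, 1.1, (0, 0, 0))])
        return atoms, ref, field

    def test_self_reference_limits(self, grid_h_default):
        atoms, ref, field = self._single_atom_toy()
        vec = compute_ita_vector(field, atoms, ref, grid_h_default)
        n = 8.0
        assert vec.rR2 == pytest.approx(-math.log10(n), abs=1e-7)
        assert vec.rR3 == pytest.approx(-0.5 * math.log10(n), abs=1e-7)
        assert abs(vec.I_G) < 1e-8
        assert abs(vec.G2) < 1e-8
        assert abs(vec.G3) < 1e-10
        assert abs(vec.G1) < 1e-4

    def test_canonical_order_stable(self, grid_h_coarse):
        atoms, ref, field = self._single_atom_toy()
        v1 = compute_ita_vector(field, atoms, ref, grid_h_coarse)
        v2 = compute_ita_vector(field, atoms, ref, grid_h_coarse)
        assert len(v1) == 11
        assert ITAVector.NAMES == ("S_S", "I_F", "S_GBP", "E2", "E3",
                                   "rR2", "rR3", "I_G", "G1", "G2", "G3")
        assert np.array_equal(v1.to_array(), v2.to_array())

    def test_componentwise_consistency(self, toy_quinone):
        toy = toy_quinone
        vec = compute_ita_vector(toy.field, toy.atoms, toy.ref, toy.grid)
        s = toy.field.sample(toy.grid, with_orbitals=True)
        assert vec.S_S == pytest.approx(shannon_entropy(s, toy.grid), rel=1e-12)
        assert vec.I_F == pytest.approx(fisher_information(s, toy.grid), rel=1e-12)
        assert vec.E2 == pytest.approx(onicescu_energy(s, toy.grid, 2), rel=1e-12)
        kd = kinetic_energy_densities(s, toy.grid)
        assert vec.S_GBP == pytest.approx(gbp_entropy(s, kd, toy.grid), rel=1e-12)
        from itaq import build_promolecule

        n_mol = integrate(s.rho, toy.grid)
        promol = build_promolecule(toy.atoms, toy.ref)
        scaled = normalize_reference(promol, n_mol, toy.grid)
        assert vec.I_G == pytest.approx(information_gain(s, scaled, toy.grid), rel=1e-10)

    def test_collinearity_smoke(self, grid_h_coarse):
        """A one-parameter Gaussian family reproduces the strong pairwise
        correlations among ITA quantities (qualitative, not numeric)."""
        ref = PromolecularReference({"O": GaussianRadial(8.0, 1.0)})
        atoms = [AtomSpec("O", [0.0, 0.0, 0.0])]
        rows = []
        for alpha in np.linspace(0.7, 1.5, 7):
            field = SuperpositionField([_CenteredGaussian(8.0, alpha, (0, 0, 0))])
            rows.append(compute_ita_vector(field, atoms, ref, grid_h_coarse).to_array())
        arr = np.array(rows)
        names = list(ITAVector.NAMES)
        for a, b in [("rR2", "rR3"), ("S_S", "I_F"), ("I_G", "G3")]:
            r = np.corrcoef(arr[:, names.index(a)], arr[:, names.index(b)])[0, 1]
            assert abs(r) > 0.9
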