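"""Free-energy functional terms, gradients, minimization, corrections."""

import numpy as np
import pytest

import mdft_et as m
from mdft_et.constants import COULOMB, KB, XI_EWALD
from mdft_et.functional import total_free_energy
from oracles import dense_quadratic_solution


def bulk_field(grid, quad, solvent):
    return m.DensityField.bulk(grid, quad, solvent.n_bulk)


def random_density(rng, grid, quad, solvent, amp=0.4):
    rho_b = solvent.rho_bulk(quad)
    vals = rho_b * np.exp(rng.normal(scale=amp, size=grid.shape + (quad.n_orientations,)))
    return m.DensityField(vals, grid, quad, rho_b)


class TestIdealTerm:
    def test_bulk_is_zero_in_both_modes(self, small_grid, quad8, toy_solvent):
        f = bulk_field(small_grid, quad8, toy_solvent)
        for mode in ("exact", "quadratic"):
            F, g = m.ideal_free_energy(f, toy_solvent.temperature, mode)
            assert F == pytest.approx(0.0, abs=1e-14)
            assert np.allclose(g, 0.0)

    def test_doubled_density_closed_forms(self, small_grid, quad8, toy_solvent):
        """ρ ≡ 2ρ_H: exact gives kT·n_H·V·(2ln2 − 1), quadratic kT·n_H·V/2."""
        f = bulk_field(small_grid, quad8, toy_solvent)
        f2 = f.copy_with(2.0 * f.values)
        kT = KB * toy_solvent.temperature
        nV = toy_solvent.n_bulk * small_grid.volume
        F_ex, _ = m.ideal_free_energy(f2, toy_solvent.temperature, "exact")
        F_q, _ = m.ideal_free_energy(f2, toy_solvent.temperature, "quadratic")
        assert F_ex == pytest.approx(kT * nV * (2 * np.log(2.0) - 1.0), rel=1e-12)
        assert F_q == pytest.approx(kT * nV / 2.0, rel=1e-12)

    def test_quadratic_is_second_order_expansion(self, small_grid, quad8, toy_solvent, rng):
        """The two modes agree to O(Δρ³): their gap shrinks cubically with
        the perturbation amplitude."""
        # one-sided perturbation: keeps the leading (cubic) error term alive
        pert = np.abs(np.clip(rng.normal(size=small_grid.shape + (quad8.n_orientations,)), -0.9, 0.9))
        f = bulk_field(small_grid, quad8, toy_solvent)
        gaps = []
        for amp in (0.2, 0.1):
            vals = f.rho_bulk * (1.0 + amp * pert)
            fa = f.copy_with(vals)
            F_ex, _ = m.ideal_free_energy(fa, toy_solvent.temperature, "exact")
            F_q, _ = m.ideal_free_energy(fa, toy_solvent.temperature, "quadratic")
            gaps.append(abs(F_ex - F_q))
        assert gaps[0] / gaps[1] == pytest.approx(8.0, rel=0.25)

    def test_negative_density_rejected_in_exact_mode(self, small_grid, quad8, toy_solvent):
        f = bulk_field(small_grid, quad8, toy_solvent)
        bad = f.copy_with(f.values - 2 * f.rho_bulk, validate=False)
        with pytest.raises(ValueError):
            m.ideal_free_energy(bad, toy_solvent.temperature, "exact")
        m.ideal_free_energy(bad, toy_solvent.temperature, "quadratic")  # fine


class TestExternalTerm:
    def test_zero_potential(self, small_grid, quad8, toy_solvent):
        f = bulk_field(small_grid, quad8, toy_solvent)
        V = m.PotentialField(np.zeros_like(f.values), small_grid, quad8, 1.0)
        F, _ = m.external_free_energy(f, V)
        assert F == 0.0

    def test_constant_potential_on_bulk(self, small_grid, quad8, toy_solvent):
        f = bulk_field(small_grid, quad8, toy_solvent)
        V = m.PotentialField(np.full_like(f.values, 2.5), small_grid, quad8, 1e3)
        F, _ = m.external_free_energy(f, V)
        assert F == pytest.approx(2.5 * toy_solvent.n_bulk * small_grid.volume, rel=1e-12)

    def test_against_direct_summation(self, small_grid, quad8, toy_solvent, rng):
        f = random_density(rng, small_grid, quad8, toy_solvent)
        V = m.PotentialField(
            rng.normal(size=f.values.shape), small_grid, quad8, 1e3
        )
        F, _ = m.external_free_energy(f, V)
        oracle = sum(
            f.values[ix] * V.values[ix] * small_grid.voxel_volume * quad8.weights[ix[-1]]
            for ix in np.ndindex(f.values.shape)
        )
        assert F == pytest.approx(oracle, rel=1e-12)


class TestExcessTerm:
    def test_zero_kernel(self, small_grid, quad8, toy_solvent, zero_kernel, rng):
        f = random_density(rng, small_grid, quad8, toy_solvent)
        F, g = m.excess_free_energy(f, zero_kernel, toy_solvent.temperature)
        assert F == 0.0 and np.all(g == 0.0)

    def test_inner_product_identity(self, small_grid, quad8, toy_solvent, weak_kernel, rng):
        f = random_density(rng, small_grid, quad8, toy_solvent)
        kT = KB * toy_solvent.temperature
        F, g = m.excess_free_energy(f, weak_kernel, toy_solvent.temperature)
        gamma = -g / kT
        ip = m.integrate_field(f.delta() * gamma, small_grid, quad8)
        assert F == pytest.approx(-0.5 * kT * ip, rel=1e-12)

    def test_against_quadruple_sum_oracle(self, small_grid, quad8, toy_solvent, weak_kernel, rng):
        from oracles import brute_force_gamma

        f = random_density(rng, small_grid, quad8, toy_solvent)
        kT = KB * toy_solvent.temperature
        F, _ = m.excess_free_energy(f, weak_kernel, toy_solvent.temperature)
        gamma = brute_force_gamma(weak_kernel, f.delta(), small_grid, quad8)
        F_oracle = -0.5 * kT * m.integrate_field(f.delta() * gamma, small_grid, quad8)
        assert F == pytest.approx(F_oracle, rel=1e-8)


class TestGradients:
    @pytest.mark.parametrize("ideal_mode", ["exact", "quadratic"])
    def test_central_differences_match_analytic(self, toy_solvent, weak_kernel, rng, ideal_mode):
        """FD check of ∂F/∂u at 50 random nodes for all three terms.

        A small grid keeps the total F comparable to individual node
        contributions, so central differences are not drowned by the
        cancellation of a large sum.
        """
        grid = m.build_spatial_grid((4.0, 4.0, 4.0), (4, 4, 4))
        quad = m.build_orientation_quadrature(2, 2, 1, 1)
        V = m.PotentialField(
            rng.normal(scale=1.0, size=grid.shape + (quad.n_orientations,)),
            grid, quad, 1e6,
        )
        spec = m.FunctionalSpec(toy_solvent, weak_kernel, V, ideal_mode)
        rho_b = toy_solvent.rho_bulk(quad)
        mvec = grid.voxel_volume * quad.weights
        u = rng.normal(scale=0.2, size=V.values.shape)

        def F_of_u(uu):
            rho = rho_b * np.exp(uu)
            f = m.DensityField(rho, grid, quad, rho_b)
            Ftot, _, dFdrho = total_free_energy(spec, f)
            return Ftot, dFdrho * rho * mvec

        F0, g = F_of_u(u)
        h = 1e-5
        gscale = np.abs(g).max()
        nodes = [tuple(rng.integers(0, s) for s in u.shape) for _ in range(50)]
        worst = 0.0
        for ix in nodes:
            up, um = u.copy(), u.copy()
            up[ix] += h
            um[ix] -= h
            fd = (F_of_u(up)[0] - F_of_u(um)[0]) / (2 * h)
            worst = max(worst, abs(fd - g[ix]) / max(abs(fd), 1e-3 * gscale))
        assert worst < 1e-6


class TestMinimization:
    def test_bulk_is_fixed_point_without_potential(
        self, small_grid, quad8, toy_solvent, weak_kernel
    ):
        V = m.PotentialField(
            np.zeros(small_grid.shape + (quad8.n_orientations,)), small_grid, quad8, 1.0
        )
        spec = m.FunctionalSpec(toy_solvent, weak_kernel, V, "exact")
        f = bulk_field(small_grid, quad8, toy_solvent)
        _, _, grad = total_free_energy(spec, f)
        assert np.all(grad == 0.0)  # first gradient evaluation identically zero
        res = m.minimize_functional(spec)
        assert res.converged
        assert abs(res.free_energy) <= 1e-8
        assert np.allclose(res.density.values, f.values, rtol=1e-10)

    def test_zero_kernel_boltzmann_solution(self, small_grid, quad8, toy_solvent, zero_kernel, rng):
        """With c = 0 the minimizer is ρ_H e^{−βV} and F has a closed form."""
        kT = KB * toy_solvent.temperature
        Vv = np.abs(rng.normal(scale=2.0, size=small_grid.shape + (quad8.n_orientations,)))
        V = m.PotentialField(Vv, small_grid, quad8, 1e6)
        spec = m.FunctionalSpec(toy_solvent, zero_kernel, V, "exact")
        res = m.minimize_functional(spec)
        rho_b = toy_solvent.rho_bulk(quad8)
        expected_rho = rho_b * np.exp(-V.values / kT)
        assert np.allclose(res.density.values, expected_rho, rtol=1e-8)
        F_closed = -kT * m.integrate_field(
            rho_b * (np.exp(-V.values / kT) - 1.0), small_grid, quad8
        )
        assert res.free_energy == pytest.approx(F_closed, rel=1e-10)

    def test_hard_core_solvation_limit(self, quad8, toy_solvent, zero_kernel):
        from mdft_et.systems import hard_core_potential

        grid = m.build_spatial_grid((12.0, 12.0, 12.0), (24, 24, 24))
        V = hard_core_potential(grid, quad8, (6.0, 6.0, 6.0), 3.0, toy_solvent.kT)
        res = m.minimize_functional(m.FunctionalSpec(toy_solvent, zero_kernel, V, "exact"))
        analytic = toy_solvent.kT * toy_solvent.n_bulk * 4.0 / 3.0 * np.pi * 27.0
        assert res.free_energy == pytest.approx(analytic, rel=0.01)

    def test_quadratic_mode_equals_linear_solve(
        self, small_grid, quad8, toy_solvent, weak_kernel, rng
    ):
        V = m.PotentialField(
            rng.normal(scale=1.5, size=small_grid.shape + (quad8.n_orientations,)),
            small_grid, quad8, 1e6,
        )
        spec = m.FunctionalSpec(toy_solvent, weak_kernel, V, "quadratic")
        res = m.minimize_functional(spec)
        d = dense_quadratic_solution(weak_kernel, V, toy_solvent, small_grid, quad8)
        rho_b = toy_solvent.rho_bulk(quad8)
        f = m.DensityField(rho_b + d, small_grid, quad8, rho_b, validate=False)
        F_oracle, _, _ = total_free_energy(spec, f)
        assert abs(res.free_energy - F_oracle) / abs(F_oracle) < 1e-9

    def test_monotone_descent_and_bookkeeping(self, small_grid, quad8, toy_solvent, weak_kernel, rng):
        V = m.PotentialField(
            np.abs(rng.normal(scale=3.0, size=small_grid.shape + (quad8.n_orientations,))),
            small_grid, quad8, 1e6,
        )
        spec = m.FunctionalSpec(toy_solvent, weak_kernel, V, "exact")
        res = m.minimize_functional(spec)
        hist = np.array(res.f_history)
        assert np.all(np.diff(hist) <= 1e-10 * np.maximum(np.abs(hist[:-1]), 1.0))
        assert res.free_energy == sum(res.terms.values())  # bit-exact bookkeeping

    def test_deterministic_reruns(self, small_grid, quad8, toy_solvent, weak_kernel, rng):
        V = m.PotentialField(
            np.abs(rng.normal(scale=2.0, size=small_grid.shape + (quad8.n_orientations,))),
            small_grid, quad8, 1e6,
        )
        spec = m.FunctionalSpec(toy_solvent, weak_kernel, V, "exact")
        r1 = m.minimize_functional(spec)
        r2 = m.minimize_functional(spec)
        assert r1.free_energy == r2.free_energy
        assert np.array_equal(r1.density.values, r2.density.values)


class TestEvaluateAtDensity:
    def test_consistent_with_minimizer(self, small_grid, quad8, toy_solvent, weak_kernel, rng):
        V = m.PotentialField(
            np.abs(rng.normal(size=small_grid.shape + (quad8.n_orientations,))),
            small_grid, quad8, 1e6,
        )
        spec = m.FunctionalSpec(toy_solvent, weak_kernel, V, "exact")
        res = m.minimize_functional(spec)
        F, terms = m.evaluate_at_density(res.density, V, weak_kernel, toy_solvent, "exact")
        assert F == pytest.approx(res.free_energy, rel=1e-12)

    def test_external_difference_is_gap(self, small_grid, quad8, toy_solvent, weak_kernel, rng):
        """F_1[ρ] − F_0[ρ] = ∫∫ρ(V_1 − V_0) for any ρ whatsoever."""
        f = random_density(rng, small_grid, quad8, toy_solvent)
        shape = f.values.shape
        V0 = m.PotentialField(rng.normal(size=shape), small_grid, quad8, 1e6)
        V1 = m.PotentialField(rng.normal(size=shape), small_grid, quad8, 1e6)
        F0, _ = m.evaluate_at_density(f, V0, weak_kernel, toy_solvent)
        F1, _ = m.evaluate_at_density(f, V1, weak_kernel, toy_solvent)
        gap = m.integrate_field(f.values * (V1.values - V0.values), small_grid, quad8)
        assert F1 - F0 == pytest.approx(gap, rel=1e-9)

    def test_variational_optimality(self, small_grid, quad8, toy_solvent, weak_kernel, rng):
        """Cross evaluation: F_0[ρ*_1] ≥ F_0[ρ*_0]."""
        shape = small_grid.shape + (quad8.n_orientations,)
        V0 = m.PotentialField(np.abs(rng.normal(scale=2.0, size=shape)), small_grid, quad8, 1e6)
        V1 = m.PotentialField(np.abs(rng.normal(scale=2.0, size=shape)), small_grid, quad8, 1e6)
        r0 = m.minimize_functional(m.FunctionalSpec(toy_solvent, weak_kernel, V0, "exact"))
        r1 = m.minimize_functional(m.FunctionalSpec(toy_solvent, weak_kernel, V1, "exact"))
        F0_rho1, _ = m.evaluate_at_density(r1.density, V0, weak_kernel, toy_solvent)
        assert F0_rho1 >= r0.free_energy - 1e-9


class TestCorrections:
    def test_neutral_solute_no_finite_size_term(self):
        assert m.finite_size_correction(0.0, (20.0, 20.0, 20.0), 71.0) == 0.0

    def test_inverse_box_length_scaling(self):
        c1 = m.finite_size_correction(1.0, (20.0,) * 3, 71.0)
        c2 = m.finite_size_correction(1.0, (40.0,) * 3, 71.0)
        assert c1 == pytest.approx(2.0 * c2, rel=1e-12)

    def test_closed_form_value(self):
        """q = 1 e, L = 24.83 Å, ε_s = 71."""
        got = m.finite_size_correction(1.0, (24.83,) * 3, 71.0)
        expected = -XI_EWALD * COULOMB * (1.0 - 1.0 / 71.0) / (2.0 * 24.83)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(78.26, rel=1e-3)

    def test_non_cubic_box_rejected(self):
        with pytest.raises(ValueError):
            m.finite_size_correction(1.0, (20.0, 20.0, 30.0), 71.0)

    def test_pressure_correction_sign_and_linearity(self):
        assert m.pressure_correction(0.0, 0.5) == 0.0
        assert m.pressure_correction(10.0, 0.5) < 0.0
        assert m.pressure_correction(20.0, 0.5) == pytest.approx(
            2.0 * m.pressure_correction(10.0, 0.5), rel=1e-12
        )
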