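"""Cycle assembly, identities, difference profiles and unfolding thermodynamics."""

import numpy as np
import pytest

from pmfdecomp.constants import kt
from pmfdecomp.decompose import (
    DecomposedProfiles,
    ThermoSummary,
    add_intramolecular_split,
    add_nonpolar_split,
    assemble_cycle,
    delta_P_profile,
    delta_T_profile,
    delta_T_unfolding,
    intramolecular_energy_profile,
    partial_molar_volume,
    unfolding_free_energy,
)
from pmfdecomp.wham import FreeEnergyProfile


def make_profile(values, r=None, errors=None, T=298.0, component=""):
    values = np.asarray(values, dtype=float)
    if r is None:
        r = 0.5 + 0.1 * np.arange(len(values))
    errors = np.zeros_like(values) if errors is None else np.asarray(errors, float)
    return FreeEnergyProfile(r, values, errors, r_ref=float(r[0]),
                             temperature=T, component=component)


def random_decomposition(rng, T=298.0, n=12):
    f_gb = make_profile(rng.normal(0, 2, n), T=T)
    mu = make_profile(rng.normal(0, 2, n), T=T)
    dmu = make_profile(rng.normal(0, 1, n), T=T)
    dec = assemble_cycle(f_gb, mu, dmu)
    add_nonpolar_split(dec, make_profile(rng.normal(0, 1, n), T=T))
    add_intramolecular_split(dec, make_profile(rng.normal(0, 1, n), T=T))
    return dec


class TestAssembleCycle:
    def test_gb_self_consistency(self, rng):
        n = 10
        f_gb = make_profile(rng.normal(0, 2, n))
        mu = make_profile(rng.normal(0, 2, n))
        zero = make_profile(np.zeros(n))
        dec = assemble_cycle(f_gb, mu, zero)
        np.testing.assert_array_equal(dec["F"].values, f_gb.values)
        np.testing.assert_array_equal(dec["mu_ex"].values, mu.values)

    def test_zero_ladder_means_vacuum_equals_gb(self, rng):
        n = 10
        f_gb = make_profile(rng.normal(0, 2, n))
        dec = assemble_cycle(f_gb, make_profile(np.zeros(n)), make_profile(rng.normal(0, 1, n)))
        np.testing.assert_array_equal(dec["F_vac"].values, f_gb.values)

    def test_closure_identities_machine_precision(self, rng):
        dec = random_decomposition(rng)
        for name, resid in dec.identity_residuals().items():
            assert resid < 1e-10, f"{name} violated: {resid}"

    def test_grid_mismatch_rejected(self, rng):
        a = make_profile(rng.normal(0, 1, 8))
        b = make_profile(rng.normal(0, 1, 8), r=0.6 + 0.1 * np.arange(8))
        with pytest.raises(ValueError, match="grid"):
            assemble_cycle(a, b, a)

    def test_errors_combine_in_quadrature(self):
        n = 5
        f_gb = make_profile(np.zeros(n), errors=np.full(n, 0.3))
        mu = make_profile(np.zeros(n), errors=np.full(n, 0.4))
        dec = assemble_cycle(f_gb, mu, make_profile(np.zeros(n)))
        np.testing.assert_allclose(dec["F_vac"].errors, 0.5)


class TestDifferenceProfiles:
    def test_equal_temperatures_give_zero(self, rng):
        dec = random_decomposition(rng)
        d = delta_T_profile(dec, dec)
        for v in d.values():
            np.testing.assert_array_equal(v, 0.0)

    def test_delta_T_additivity(self, rng):
        d1 = random_decomposition(rng, T=298.0)
        d2 = random_decomposition(rng, T=373.0)
        # align the grids (same construction) and zero refs
        d2p = DecomposedProfiles(
            {k: make_profile(d2[k].values, T=373.0) for k in d2.profiles},
            temperature=373.0, r_ref=d1.r_ref,
        )
        d = delta_T_profile(d1, d2p)
        np.testing.assert_allclose(d["F"], d["F_vac"] + d["mu_ex"], atol=1e-10)
        np.testing.assert_allclose(d["mu_ex"], d["mu_nonpol"] + d["mu_pol"], atol=1e-10)

    def test_delta_P_identity_and_zero_case(self, rng):
        dec1 = random_decomposition(rng)
        d0 = delta_P_profile(dec1, dec1)
        np.testing.assert_array_equal(d0["F"], 0.0)
        # second pressure: same F_vac (only dmu changes)
        n = len(dec1.r)
        dmu2 = make_profile(dec1["dmu_ref_GB"].values + rng.normal(0, 1, n))
        dec2 = assemble_cycle(dec1["F_GB"], dec1["mu_ex_GB"], dmu2, pressure=8000.0)
        d = delta_P_profile(dec1, dec2)
        np.testing.assert_allclose(d["F"], d["mu_ex"], atol=1e-12)

    def test_delta_P_rejects_pressure_dependent_vacuum(self, rng):
        dec1 = random_decomposition(rng)
        n = len(dec1.r)
        other = assemble_cycle(
            make_profile(dec1["F_GB"].values + 1e-3 * rng.normal(size=n)),
            dec1["mu_ex_GB"], dec1["dmu_ref_GB"], pressure=8000.0,
        )
        with pytest.raises(ValueError, match="F_vac"):
            delta_P_profile(dec1, other)


class TestIntramolecularProfiles:
    def test_rigid_molecule_entropy_constant(self):
        """A rigid system has no conformational entropy differences: the
        entropy term is exactly zero after shifting."""
        r = np.array([0.5, 0.6, 0.7])
        u = np.array([1.0, 2.0, 4.0])  # rigid: F_vac/kT = βU exactly
        f_vac = make_profile(u - u[0], r=r, component="F_vac")
        energies = {ri: np.full(50, ui * kt(298.0)) for ri, ui in zip(r, u)}
        e_prof = intramolecular_energy_profile(energies, 298.0, r_ref=0.5)
        dec = assemble_cycle(f_vac, make_profile(np.zeros(3), r=r),
                             make_profile(np.zeros(3), r=r))
        # F_vac here is constructed as F_GB with zero ladder → F_vac = F_GB
        add_intramolecular_split(dec, e_prof)
        np.testing.assert_allclose(dec["minus_TS_intra"].values, 0.0, atol=1e-12)

    def test_dumbbell_jacobian_oracle(self, dumbbell, vacuum):
        """For the dumbbell: E_intra(R) = βU(R) and −TS/k_BT = −2 ln R + const."""
        from pmfdecomp.pipeline import vacuum_energy_profile
        from pmfdecomp.sampler import SamplingProtocol

        r = np.array([0.45, 0.5, 0.55, 0.6])
        proto = SamplingProtocol(n_equilibration=10, n_production=100, stride=2, seed=3)
        e_prof = vacuum_energy_profile(dumbbell.topology, r, proto, 298.0, r_ref=0.5)
        beta_u = 0.5 * 1000.0 * (r - 0.5) ** 2 / kt(298.0)
        np.testing.assert_allclose(e_prof.values, beta_u - beta_u[1], atol=1e-9)
        # analytic F_vac = βU − 2 ln R ⇒ −TS = F_vac − E = −2 ln R + const
        f_vac = make_profile(dumbbell.f_exact(r) - dumbbell.f_exact(np.array([0.5]))[0], r=r)
        dec = assemble_cycle(f_vac, make_profile(np.zeros(4), r=r),
                             make_profile(np.zeros(4), r=r))
        add_intramolecular_split(dec, e_prof)
        th = -2 * np.log(r) + 2 * np.log(0.5)
        np.testing.assert_allclose(dec["minus_TS_intra"].values, th, atol=1e-9)

    def test_missing_ensemble_rejected(self):
        with pytest.raises(ValueError, match="missing|no vacuum"):
            intramolecular_energy_profile({0.5: []}, 298.0, 0.5)


class TestUnfoldingFreeEnergy:
    def test_three_point_enumeration(self):
        """Flat profile on {0.5, 0.6, 1.8} with folded = {0.5, 0.6} → ln 2."""
        prof = make_profile([0.0, 0.0, 0.0], r=np.array([0.5, 0.6, 1.8]))
        dfu, err = unfolding_free_energy(prof, [0.5, 0.6], n_boot=0)
        assert dfu == pytest.approx(np.log(2.0), abs=1e-12)

    def test_sign_convention_folded_more_stable_is_positive(self):
        prof = make_profile([-3.0, 0.0, 0.0], r=np.array([0.5, 1.0, 1.5]))
        dfu, _ = unfolding_free_energy(prof, [0.5], n_boot=0)
        assert dfu > 0

    def test_degenerate_profile_guarded(self):
        prof = make_profile([0.0, 800.0, 900.0], r=np.array([0.5, 1.0, 1.5]))
        with pytest.raises(ValueError, match="degenerate"):
            unfolding_free_energy(prof, [0.5], n_boot=0)

    def test_printed_pair_difference(self):
        """ΔF_u/k_BT of 2.7 at 298 K and −0.1 at 373 K give Δ_T F_u = −2.8."""
        assert delta_T_unfolding(-0.1, 2.7) == pytest.approx(-2.8, abs=1e-12)

    def test_bootstrap_error_reproducible(self):
        prof = make_profile([0.0, 1.0, 2.0], r=np.array([0.5, 1.0, 1.5]),
                            errors=[0.1, 0.1, 0.1])
        a = unfolding_free_energy(prof, [0.5], n_boot=100, seed=3)
        b = unfolding_free_energy(prof, [0.5], n_boot=100, seed=3)
        assert a == b
        assert a[1] > 0


class TestPartialMolarVolume:
    def test_flat_is_zero(self):
        assert partial_molar_volume(
            [1.0, 4000.0, 8000.0], [2.0, 2.0, 2.0], 298.0
        ) == pytest.approx(0.0, abs=1e-12)

    def test_linear_drop_unit_conversion(self):
        """2.7 → 1.0 k_BT between 1 and 8000 bar at 298 K ⇒ ≈ −5.27 cm³/mol."""
        dv = partial_molar_volume([1.0, 8000.0], [2.7, 1.0], 298.0)
        expected = (1.0 - 2.7) * kt(298.0) * 1000.0 / 7999.0 * 10.0
        assert dv == pytest.approx(expected, rel=1e-12)
        assert dv == pytest.approx(-5.27, abs=0.01)

    def test_quadratic_local_slope_matches_derivative(self):
        """Least squares over a tight pressure pair approximates the analytic
        local derivative of a quadratic ΔF_u(P)."""
        a, b = 3.0, -2e-4
        c = -1e-8

        def dfu(p):
            return a + b * p + c * p * p

        p0 = 2000.0
        dv = partial_molar_volume([p0 - 50, p0 + 50], [dfu(p0 - 50), dfu(p0 + 50)], 298.0)
        analytic = (b + 2 * c * p0) * kt(298.0) * 1000.0 * 10.0
        assert dv == pytest.approx(analytic, rel=1e-6)

    def test_single_pressure_rejected(self):
        with pytest.raises(ValueError, match="two pressures"):
            partial_molar_volume([1.0], [2.0], 298.0)


class TestThermoSummary:
    def test_empty_folded_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            ThermoSummary(dfu={}, folded_r=())
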