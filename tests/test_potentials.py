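"""Unit tests for the analytic potentials, forces and the dielectric model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eecsim.errors import ParameterError
from eecsim.potentials import (
    Electrostatics,
    HarmonicBond,
    HydrophobicTail,
    MiePair,
    bond_energy,
    bond_force,
    dielectric,
    dlnEps_dlnT,
    hydrophobic_tail_energy,
    hydrophobic_tail_force,
    lambda_of_T,
    mie_prefactor,
    pair_force,
    screened_coulomb_energy,
    screened_coulomb_force,
    tabulate_potential,
    wca_energy,
    wca_force,
)
from eecsim.units import SIGMA_ANGSTROM


class TestWCA:
    def test_cutoff_is_mie_minimum(self):
        p = MiePair()
        assert p.r_cut == pytest.approx(50.0 / 49.0)
        # derivative vanishes at the cutoff: force -> 0 continuously
        assert wca_force(p.r_cut - 1e-9, p) == pytest.approx(0.0, abs=1e-5)

    def test_zero_at_and_beyond_cutoff(self):
        p = MiePair()
        assert wca_energy(p.r_cut, p) == 0.0
        assert wca_energy(5.0, p) == 0.0

    def test_value_at_sigma_is_epsilon(self):
        # the Mie term cancels exactly at r = sigma, leaving the shift
        assert wca_energy(1.0, MiePair()) == pytest.approx(1.0)
        assert wca_energy(1.0, MiePair(epsilon=2.5)) == pytest.approx(2.5)

    def test_strictly_decreasing_and_repulsive(self):
        p = MiePair()
        r = np.linspace(0.8, p.r_cut - 1e-6, 200)
        u = wca_energy(r, p)
        assert np.all(np.diff(u) < 0)
        assert np.all(wca_force(r, p) >= 0)

    def test_prefactor_closed_form(self):
        assert mie_prefactor(50, 49) == pytest.approx(50 * (50 / 49) ** 49)

    def test_invalid_exponents_and_domain(self):
        with pytest.raises(ParameterError):
            MiePair(lambda_r=6, lambda_a=12)
        with pytest.raises(ParameterError):
            wca_energy(-1.0, MiePair())


class TestHydrophobicTail:
    def test_zero_coupling_kills_potential(self):
        h = HydrophobicTail(lambda0=0.0, alpha=0.0)
        r = np.linspace(0.5, 4.0, 50)
        assert np.all(hydrophobic_tail_energy(r, 300.0, h) == 0.0)

    def test_lambda_at_theta_is_lambda0(self):
        h = HydrophobicTail(lambda0=0.95, alpha=0.007, theta=320.0)
        assert lambda_of_T(320.0, h) == 0.95

    def test_linear_in_lambda(self):
        h1 = HydrophobicTail(lambda0=0.4)
        h2 = HydrophobicTail(lambda0=0.8)
        r = np.linspace(0.9, 2.9, 20)
        np.testing.assert_allclose(
            hydrophobic_tail_energy(r, 300.0, h2), 2 * hydrophobic_tail_energy(r, 300.0, h1)
        )

    def test_lambda_arithmetic(self):
        h = HydrophobicTail(lambda0=0.95, alpha=-0.005, theta=300.0)
        assert lambda_of_T(400.0, h) == pytest.approx(0.45)

    def test_lcst_direction(self):
        # alpha > 0: heating strengthens the attraction
        h = HydrophobicTail(lambda0=0.95, alpha=0.005, theta=300.0)
        assert lambda_of_T(350.0, h) > h.lambda0

    def test_nonpositive_everywhere_beyond_sigma(self):
        h = HydrophobicTail()
        r = np.linspace(1.0, 5.0, 100)
        assert np.all(hydrophobic_tail_energy(r, 300.0, h) <= 0.0)
        assert hydrophobic_tail_energy(3.0, 300.0, h) == 0.0

    def test_negative_lambda_rejected(self):
        h = HydrophobicTail(lambda0=0.1, alpha=-0.005, theta=300.0)
        with pytest.raises(ParameterError):
            hydrophobic_tail_energy(1.5, 400.0, h)

    @given(
        t1=st.floats(250, 350),
        t2=st.floats(250, 350),
        alpha=st.floats(-0.009, 0.009),
    )
    @settings(max_examples=50, deadline=None)
    def test_lambda_linearity_identity(self, t1, t2, alpha):
        h = HydrophobicTail(lambda0=0.95, alpha=alpha, theta=300.0)
        lhs = lambda_of_T(t1, h) + lambda_of_T(t2, h) - h.lambda0
        rhs = lambda_of_T(t1 + t2 - h.theta, h)
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)


class TestElectrostatics:
    def test_bjerrum_definition(self):
        es = Electrostatics(bjerrum_length=1.19, kappa=0.0)
        assert screened_coulomb_energy(1.19, 1.0, 1.0, es) == pytest.approx(1.0)

    def test_bjerrum_length_at_room_conditions(self):
        es = Electrostatics.from_conditions(eps_r=78.0, T=300.0)
        assert es.bjerrum_length * SIGMA_ANGSTROM == pytest.approx(7.1, abs=0.1)
        assert es.bjerrum_length == pytest.approx(1.19, abs=0.01)

    def test_debye_length_at_100mM(self):
        es = Electrostatics.from_conditions(salt_molar=0.1)
        assert es.debye_length * SIGMA_ANGSTROM == pytest.approx(9.6, abs=0.15)
        assert es.debye_length == pytest.approx(1.60, abs=0.03)

    def test_kappa_zero_recovers_coulomb_pointwise(self):
        lb = 1.19
        bare = Electrostatics(bjerrum_length=lb, kappa=0.0)
        r = np.linspace(0.5, 10.0, 50)
        for kappa in (1e-3, 1e-5):
            scr = Electrostatics(bjerrum_length=lb, kappa=kappa)
            diff = screened_coulomb_energy(r, 1, -1, scr) - screened_coulomb_energy(r, 1, -1, bare)
            assert np.max(np.abs(diff)) < 2 * kappa * lb

    def test_shifted_form_is_continuous_and_truncated(self):
        es = Electrostatics.from_conditions(shifted=True)
        rc = es.r_cut_el
        assert screened_coulomb_energy(rc - 1e-9, 1, -1, es) == pytest.approx(0.0, abs=1e-6)
        assert screened_coulomb_energy(rc + 0.1, 1, -1, es) == 0.0

    def test_negative_kappa_rejected(self):
        with pytest.raises(ParameterError):
            Electrostatics(kappa=-0.1)


class TestDielectric:
    def test_room_temperature_value(self):
        assert dielectric(300.0) == pytest.approx(78.0, abs=0.5)

    def test_log_derivative_at_300K(self):
        assert dlnEps_dlnT(300.0) == pytest.approx(-1.36, abs=0.01)

    def test_monotonically_decreasing(self):
        temps = np.linspace(273.5, 373.0, 40)
        eps = [dielectric(t) for t in temps]
        assert np.all(np.diff(eps) < 0)
        assert dielectric(350.0) < dielectric(300.0)
        assert all(dlnEps_dlnT(t) < 0 for t in temps)

    def test_out_of_range_rejected(self):
        for T in (250.0, 400.0):
            with pytest.raises(ParameterError):
                dielectric(T)


class TestHarmonicBond:
    def test_zero_at_rest_length_and_symmetry(self):
        b = HarmonicBond()
        assert bond_energy(0.7, b) == 0.0
        assert bond_energy(0.6, b) == pytest.approx(bond_energy(0.8, b))

    def test_no_half_convention(self):
        # u = K (r - r0)^2: K = 100, displacement 0.1 sigma -> exactly 1 kT
        assert bond_energy(0.8, HarmonicBond(k_bond=100.0, r0=0.7)) == pytest.approx(1.0)
        # consistent force: -dU/dr = -2K(r-r0)
        assert bond_force(0.8, HarmonicBond()) == pytest.approx(-20.0)


class TestForceConsistency:
    """force = -dU/dr for every family, against a central-difference oracle."""

    @pytest.mark.parametrize(
        "name,u,f,lo,hi",
        [
            ("wca", lambda r: wca_energy(r, MiePair()), lambda r: wca_force(r, MiePair()), 0.9, 1.015),
            (
                "tail",
                lambda r: hydrophobic_tail_energy(r, 300.0, HydrophobicTail()),
                lambda r: hydrophobic_tail_force(r, 300.0, HydrophobicTail()),
                0.8,
                2.9,
            ),
            (
                "coulomb",
                lambda r: screened_coulomb_energy(r, 1.0, -1.0, Electrostatics.from_conditions(shifted=True)),
                lambda r: screened_coulomb_force(r, 1.0, -1.0, Electrostatics.from_conditions(shifted=True)),
                0.5,
                7.9,
            ),
            ("bond", lambda r: bond_energy(r, HarmonicBond()), lambda r: bond_force(r, HarmonicBond()), 0.3, 1.5),
        ],
    )
    def test_force_equals_negative_gradient(self, name, u, f, lo, hi):
        rng = np.random.default_rng(42)
        r = rng.uniform(lo, hi, size=100)
        h = 1e-7 * np.maximum(r, 1.0)
        numeric = -(u(r + h) - u(r - h)) / (2 * h)
        analytic = f(r)
        scale = np.maximum(np.abs(numeric), 1e-8)
        assert np.max(np.abs(analytic - numeric) / scale) < 1e-5

    def test_force_zero_at_cutoffs(self):
        assert wca_force(MiePair().r_cut, MiePair()) == 0.0
        assert hydrophobic_tail_force(3.0, 300.0, HydrophobicTail()) == 0.0

    def test_dispatch(self):
        assert pair_force(1.0, MiePair()) == wca_force(1.0, MiePair())
        assert pair_force(0.8, HarmonicBond()) == bond_force(0.8, HarmonicBond())
        with pytest.raises(TypeError):
            pair_force(1.0, object())


def test_wca_energy_continuous_at_cutoff():
    p = MiePair()
    assert wca_energy(p.r_cut - 1e-10, p) == pytest.approx(0.0, abs=1e-9)
    h = HydrophobicTail()
    assert hydrophobic_tail_energy(3.0 - 1e-10, 300.0, h) == pytest.approx(0.0, abs=1e-9)


def test_tabulated_export(tmp_path):
    path = tmp_path / "wca.tsv"
    r = np.linspace(0.9, 1.1, 11)
    tabulate_potential(r, lambda x: wca_energy(x, MiePair()), lambda x: wca_force(x, MiePair()), path)
    data = np.loadtxt(path)
    assert data.shape == (11, 3)
    np.testing.assert_allclose(data[:, 1], wca_energy(r, MiePair()))
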