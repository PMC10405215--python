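"""Engine tests: force correctness against a brute-force oracle, integrator
conservation/thermostat properties, determinism, Boltzmann sampling."""

import numpy as np
import pytest
from scipy.integrate import quad

from eecsim import ForceField, build_pair, compute_forces, fixture_dimer
from eecsim.engine import block_stats, langevin_step, run
from eecsim.pmf import abf_window
from eecsim.potentials import (
    bond_energy,
    bond_force,
    hydrophobic_tail_energy,
    hydrophobic_tail_force,
    screened_coulomb_energy,
    screened_coulomb_force,
    wca_energy,
    wca_force,
)
from eecsim.system import ChainSystem


def brute_force_reference(system, ff):
    """O(N^2) double-loop oracle using the analytic potential functions
    directly (independent of the kernel code path)."""
    n = system.n_total
    pos, box = system.positions, system.box
    bonded = set(map(tuple, np.sort(system.bonds, axis=1)))
    f = np.zeros((n, 3))
    u = dict.fromkeys(("wca", "hp", "el", "bond"), 0.0)
    for i in range(n - 1):
        for j in range(i + 1, n):
            if (i, j) in bonded:
                continue
            d = pos[i] - pos[j]
            d -= box * np.round(d / box)
            r = np.linalg.norm(d)
            rhat = d / r
            u["wca"] += wca_energy(r, ff.mie)
            u["hp"] += hydrophobic_tail_energy(r, ff.temperature, ff.tail)
            fr = wca_force(r, ff.mie) + hydrophobic_tail_force(r, ff.temperature, ff.tail)
            qq = system.charges[i] * system.charges[j]
            if qq != 0.0:
                u["el"] += screened_coulomb_energy(r, system.charges[i], system.charges[j], ff.elec)
                fr += screened_coulomb_force(r, system.charges[i], system.charges[j], ff.elec)
            f[i] += fr * rhat
            f[j] -= fr * rhat
    for i, j in system.bonds:
        d = pos[i] - pos[j]
        d -= box * np.round(d / box)
        r = np.linalg.norm(d)
        u["bond"] += bond_energy(r, ff.bond)
        fr = bond_force(r, ff.bond)
        f[i] += fr * d / r
        f[j] -= fr * d / r
    return f, u


@pytest.fixture(scope="module")
def ff_shifted():
    return ForceField()


class TestForces:
    def test_neighbor_list_matches_direct_sum(self, ff_shifted):
        """Kernel forces with the Verlet list equal the O(N^2) brute-force
        oracle on random overlapping two-chain configurations."""
        rng = np.random.default_rng(0)
        for trial in range(3):
            sys_ = build_pair(0.5, seed=trial, n_beads_per_chain=25, separation=3.0)
            sys_.positions += rng.normal(scale=0.05, size=sys_.positions.shape)
            f_kernel, eb = compute_forces(sys_, ff_shifted)
            f_ref, u_ref = brute_force_reference(sys_, ff_shifted)
            # overlapping random configurations can reach huge core forces;
            # agreement is to relative machine-level accuracy
            fscale = max(1.0, float(np.max(np.abs(f_ref))))
            assert np.max(np.abs(f_kernel - f_ref)) < 1e-8 * fscale
            assert eb.U_wca == pytest.approx(u_ref["wca"], rel=1e-10, abs=1e-9)
            assert eb.U_hp == pytest.approx(u_ref["hp"], rel=1e-10, abs=1e-9)
            assert eb.U_el == pytest.approx(u_ref["el"], rel=1e-10, abs=1e-9)
            assert eb.U_bond == pytest.approx(u_ref["bond"], rel=1e-10, abs=1e-9)

    def test_newtons_third_law(self, ff_shifted):
        sys_ = build_pair(0.3, seed=4, separation=3.5)
        f, _ = compute_forces(sys_, ff_shifted)
        assert np.max(np.abs(f.sum(axis=0))) < 1e-12 * np.abs(f).sum()

    def test_isolated_dimer_equals_analytic_pair_force(self, ff_shifted):
        r = 1.3
        s = fixture_dimer(r, 1.0, -1.0)
        f, _ = compute_forces(s, ff_shifted)
        fr = (
            wca_force(r, ff_shifted.mie)
            + hydrophobic_tail_force(r, ff_shifted.temperature, ff_shifted.tail)
            + screened_coulomb_force(r, 1.0, -1.0, ff_shifted.elec)
        )
        # bead 0 sits at smaller x; positive radial force pushes it to -x
        assert f[0, 0] == pytest.approx(-fr, rel=1e-12)
        assert f[1, 0] == pytest.approx(fr, rel=1e-12)

    def test_breakdown_sums_to_total(self, ff_shifted):
        sys_ = build_pair(0.5, seed=9, separation=2.5)
        _, eb = compute_forces(sys_, ff_shifted)
        assert eb.total == pytest.approx(eb.U_wca + eb.U_hp + eb.U_el + eb.U_bond, rel=1e-12)


class TestIntegrator:
    def test_nve_energy_conservation(self, ff_shifted):
        """gamma = 0 reduces BAOAB to velocity Verlet: total energy drift of
        a stretched harmonic dimer over 1e4 steps stays below 1e-3 kT per
        bead (smooth potential, so the symplectic integrator conserves a
        shadow Hamiltonian)."""
        s = fixture_dimer(0.85, bonded=True)
        rng = np.random.default_rng(8)
        s.velocities = rng.normal(scale=0.5, size=s.positions.shape)
        _, eb0 = compute_forces(s, ff_shifted)
        e0 = eb0.total + 0.5 * np.sum(s.velocities**2)
        run(s, ff_shifted, n_steps=10_000, seed=1, gamma=0.0, sample_every=0)
        _, eb1 = compute_forces(s, ff_shifted)
        e1 = eb1.total + 0.5 * np.sum(s.velocities**2)
        assert abs(e1 - e0) / s.n_total < 1e-3

    def test_free_particle_velocity_autocorrelation(self, ff_shifted):
        """Ornstein-Uhlenbeck velocities: VACF decays as exp(-gamma t)."""
        gamma, dt = 1.0, 0.002
        s = ChainSystem(
            positions=np.array([[50.0, 50.0, 50.0]]),
            charges=np.zeros(1),
            bonds=np.zeros((0, 2), dtype=int),
            n_chain1=1,
        )
        traj = run(s, ff_shifted, n_steps=400_000, seed=12, gamma=gamma, dt=dt,
                   sample_every=0, save_every=50, save_velocities=True)
        v = traj.velocities[:, 0, :]
        v = v - v.mean(axis=0)
        var = (v * v).mean()
        for lag in (5, 10, 20):  # frames -> t = lag*50*dt
            acf = (v[:-lag] * v[lag:]).mean() / var
            expected = np.exp(-gamma * lag * 50 * dt)
            assert acf == pytest.approx(expected, abs=0.05)

    def test_harmonic_dimer_equipartition(self, ff_shifted):
        """<u_bond> matches the exact radial-measure average (about kT/2
        plus the small Jacobian correction) within 3 block standard errors."""
        s = fixture_dimer(0.7, bonded=True)
        traj = run(s, ff_shifted, n_steps=400_000, seed=3, sample_every=20)
        mean, se = block_stats(traj.energies[:, 3], n_blocks=10)
        k, r0 = ff_shifted.bond.k_bond, ff_shifted.bond.r0
        z = quad(lambda r: r * r * np.exp(-k * (r - r0) ** 2), 0.3, 1.2)[0]
        expected = quad(lambda r: k * (r - r0) ** 2 * r * r * np.exp(-k * (r - r0) ** 2), 0.3, 1.2)[0] / z
        assert mean == pytest.approx(expected, abs=max(3 * se, 0.02))

    def test_zero_steps_leaves_state_unchanged(self, ff_shifted):
        sys_ = build_pair(0.5, seed=2)
        before = sys_.positions.copy()
        run(sys_, ff_shifted, n_steps=0, seed=5, sample_every=0)
        np.testing.assert_array_equal(sys_.positions, before)

    def test_bitwise_determinism_under_seed(self, ff_shifted):
        outs = []
        for _ in range(2):
            sys_ = build_pair(0.3, seed=7, separation=5.0)
            traj = run(sys_, ff_shifted, n_steps=2_000, seed=99, sample_every=100)
            outs.append((sys_.positions.copy(), traj.energies.copy()))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        np.testing.assert_array_equal(outs[0][1], outs[1][1])

    def test_langevin_step_advances_time(self, ff_shifted):
        s = fixture_dimer(1.5, bonded=True)
        state = langevin_step(s, ff_shifted, seed=4)
        assert state.time == pytest.approx(0.002)
        assert np.all(np.isfinite(state.positions))


class TestBoltzmannSampling:
    def test_charged_dimer_radial_distribution(self, ff_shifted):
        """Unbiased sampling of a screened charged dimer reproduces the
        analytic pair density p(r) ~ exp(-u(r)) r^2 (chi-squared on
        decorrelated effective samples)."""
        s = fixture_dimer(1.5, 1.0, -1.0)
        profile = abf_window(
            s, ff_shifted, (1.0, 3.0), n_steps=2_000_000, seed=21,
            bin_width=0.25, apply_bias=False, wall_k=200.0,
        )
        counts = profile.counts
        r = profile.bin_centers

        def dens(x):
            return np.exp(-ff_shifted.pair_energy(x, 1.0, -1.0)) * x * x

        expected = np.array([quad(dens, lo, lo + 0.25)[0] for lo in np.arange(1.0, 3.0, 0.25)])
        expected *= counts.sum() / expected.sum()
        decorr = 400  # steps between effectively independent samples
        chi2_eff = np.sum((counts - expected) ** 2 / expected) / decorr
        dof = len(counts) - 1
        # generous gate: effective chi2 within 3x dof
        assert chi2_eff < 3 * dof
        # per-bin multinomial z-scores on the effective sample size
        n_eff = counts.sum() / decorr
        p = expected / expected.sum()
        z = (counts / decorr - n_eff * p) / np.sqrt(n_eff * p * (1 - p))
        assert np.max(np.abs(z)) < 4.0
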