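"""Langevin dynamics driver with per-channel energy bookkeeping.

Thin object layer over the numba kernels in :mod:`eecsim._kernels`.
Defaults follow the model's operating state: time step dt = 0.002 tau,
thermostat at the operating temperature (kT = 1 in reduced units), friction
gamma = 1/tau, Verlet list skin 0.3 sigma.  Nonbonded interactions between
directly bonded neighbours are excluded (the usual bead-spring convention;
the bond length 0.7 sigma sits well inside the repulsive core).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import NumericalError
from .forcefield import ForceField
from .system import ChainSystem

__all__ = ["EnergyBreakdown", "SimulationState", "Trajectory", "compute_forces", "langevin_step", "run", "block_stats"]

DEFAULT_DT = 0.002
DEFAULT_GAMMA = 1.0
DEFAULT_SKIN = 0.3


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-channel potential energies in k_B*T."""

    U_wca: float
    U_hp: float
    U_el: float
    U_bond: float

    @property
    def total(self) -> float:
        return self.U_wca + self.U_hp + self.U_el + self.U_bond

    def as_array(self) -> np.ndarray:
        return np.array([self.U_wca, self.U_hp, self.U_el, self.U_bond])


@dataclass
class SimulationState:
    """Coordinates, velocities and bookkeeping for a running simulation."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    energy_breakdown: EnergyBreakdown | None = None


@dataclass
class Trajectory:
    """Output of :func:`run`: saved frames plus sampled channel energies."""

    frames: np.ndarray  # (n_frames, n, 3)
    velocities: np.ndarray  # (n_frames, n, 3) or empty
    energies: np.ndarray  # (n_samples, 4): U_wca, U_hp, U_el, U_bond
    final_state: SimulationState = field(default=None)  # type: ignore[assignment]

    def mean_energies(self) -> EnergyBreakdown:
        m = self.energies.mean(axis=0)
        return EnergyBreakdown(*m)

    def energy_stderr(self, n_blocks: int = 10) -> np.ndarray:
        return np.array([block_stats(self.energies[:, k], n_blocks)[1] for k in range(4)])


def block_stats(series: np.ndarray, n_blocks: int = 10) -> tuple[float, float]:
    """Block-averaged mean and standard error (guards against correlated
    samples)."""
    series = np.asarray(series, dtype=float)
    n = len(series) // n_blocks
    if n < 1:
        return float(series.mean()), float(series.std(ddof=1) / np.sqrt(max(len(series) - 1, 1)))
    blocks = series[: n * n_blocks].reshape(n_blocks, n).mean(axis=1)
    return float(blocks.mean()), float(blocks.std(ddof=1) / np.sqrt(n_blocks))


def _exclusions(system: ChainSystem) -> np.ndarray:
    n = system.n_total
    excl = np.zeros((n, n), dtype=np.bool_)
    for i, j in system.bonds:
        excl[i, j] = excl[j, i] = True
    return excl


def _check_status(status: int) -> None:
    if status == _kernels.STATUS_OVERLAP:
        raise NumericalError("pair overlap below 1e-6 sigma")
    if status == _kernels.STATUS_NONFINITE:
        raise NumericalError("non-finite coordinates during integration")


def compute_forces(system: ChainSystem, ff: ForceField) -> tuple[np.ndarray, EnergyBreakdown]:
    """Minimum-image pairwise forces and channel energies for a
    configuration (neighbor list covering every in-range pair)."""
    n = system.n_total
    pos = np.ascontiguousarray(system.positions)
    excl = _exclusions(system)
    max_pairs = n * (n - 1) // 2
    pi = np.empty(max_pairs, dtype=np.int64)
    pj = np.empty(max_pairs, dtype=np.int64)
    n_pairs = _kernels.build_pairs(pos, system.box, ff.max_cutoff + DEFAULT_SKIN, excl, pi, pj)
    f = np.zeros((n, 3))
    uw, uh, ue, ub, status = _kernels.compute_forces(
        pos, system.box, system.charges, pi, pj, n_pairs, system.bonds, ff.kernel_params(), f
    )
    _check_status(status)
    return f, EnergyBreakdown(uw, uh, ue, ub)


def _init_velocities(system: ChainSystem, kT: float, seed: int) -> np.ndarray:
    if system.velocities is not None:
        return np.array(system.velocities, dtype=float)
    rng = np.random.default_rng(seed)
    return rng.normal(scale=np.sqrt(kT), size=(system.n_total, 3))


def run(
    system: ChainSystem,
    ff: ForceField,
    n_steps: int,
    seed: int,
    dt: float = DEFAULT_DT,
    gamma: float = DEFAULT_GAMMA,
    kT: float = 1.0,
    sample_every: int = 100,
    save_every: int = 0,
    save_velocities: bool = False,
) -> Trajectory:
    """Run plain Langevin dynamics; deterministic under ``seed``.  The
    system's positions/velocities are updated in place and also returned in
    ``final_state``."""
    pos = np.ascontiguousarray(system.positions, dtype=np.float64)
    vel = np.ascontiguousarray(_init_velocities(system, kT, seed + 7919))
    n = system.n_total
    n_samples = n_steps // sample_every if sample_every > 0 else 0
    energy_out = np.zeros((n_samples, 4))
    n_frames = n_steps // save_every if save_every > 0 else 0
    traj = np.zeros((n_frames, n, 3))
    vels = np.zeros((n_frames, n, 3)) if (save_velocities and n_frames) else np.zeros((0, n, 3))
    if n_steps > 0:
        status = _kernels.run_md(
            pos,
            vel,
            system.charges,
            system.bonds,
            _exclusions(system),
            system.box,
            ff.kernel_params(),
            dt,
            gamma,
            kT,
            n_steps,
            seed % 2**31,
            ff.max_cutoff + DEFAULT_SKIN,
            DEFAULT_SKIN,
            sample_every,
            energy_out,
            save_every,
            traj,
            vels,
        )
        _check_status(status)
    system.positions = pos
    system.velocities = vel
    _, breakdown = compute_forces(system, ff)
    state = SimulationState(positions=pos, velocities=vel, time=n_steps * dt, energy_breakdown=breakdown)
    return Trajectory(frames=traj, velocities=vels, energies=energy_out, final_state=state)


def langevin_step(
    system: ChainSystem,
    ff: ForceField,
    seed: int,
    dt: float = DEFAULT_DT,
    gamma: float = DEFAULT_GAMMA,
    kT: float = 1.0,
) -> SimulationState:
    """Advance one BAOAB step (convenience wrapper around :func:`run`)."""
    traj = run(system, ff, n_steps=1, seed=seed, dt=dt, gamma=gamma, kT=kT, sample_every=0)
    return traj.final_state
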