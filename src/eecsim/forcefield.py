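"""Force-field container: all pair/bond parameters and the temperature map.

The operating state is a simulation at 300 K; sweeping the solvent condition
means varying theta (equivalently dT = T - theta) and the sensitivity alpha
of the hydrophobic attraction, while the electrostatics stay fixed at the
0.1 M monovalent-salt, eps_r = 78 reference state the model is built around.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .potentials import (
    Electrostatics,
    HarmonicBond,
    HydrophobicTail,
    MiePair,
    bond_energy,
    hydrophobic_tail_energy,
    lambda_of_T,
    screened_coulomb_energy,
    wca_energy,
)
from .units import T_ROOM

__all__ = ["ForceField"]


@dataclass(frozen=True)
class ForceField:
    """All interaction parameters plus the operating temperature."""

    mie: MiePair = field(default_factory=MiePair)
    tail: HydrophobicTail = field(default_factory=HydrophobicTail)
    elec: Electrostatics = field(
        default_factory=lambda: Electrostatics.from_conditions(shifted=True)
    )
    bond: HarmonicBond = field(default_factory=HarmonicBond)
    temperature: float = T_ROOM

    @property
    def lam(self) -> float:
        """lambda(T) at the operating temperature."""
        return lambda_of_T(self.temperature, self.tail)

    def with_hydrophobicity(self, alpha: float, dT: float, lambda0: float | None = None) -> "ForceField":
        """Return a copy with tail parameters (alpha, T - theta) set; the
        simulation temperature stays fixed, so varying dT varies theta."""
        lam0 = self.tail.lambda0 if lambda0 is None else lambda0
        tail = replace(self.tail, alpha=alpha, theta=self.temperature - dT, lambda0=lam0)
        return replace(self, tail=tail)

    def with_lambda(self, lam: float) -> "ForceField":
        """Copy with lambda(T) pinned to ``lam`` at the operating temperature
        (alpha = 0, lambda0 = lam)."""
        tail = replace(self.tail, alpha=0.0, lambda0=lam, theta=self.temperature)
        return replace(self, tail=tail)

    # -- analytic evaluations ------------------------------------------------

    def nonionic_energy(self, r, lam: float | None = None):
        """WCA + hydrophobic tail at coupling ``lam`` (default: lambda(T)),
        in k_B*T units; the integrand potential of the second virial
        coefficient."""
        ff = self if lam is None else self.with_lambda(lam)
        return wca_energy(r, ff.mie) + hydrophobic_tail_energy(r, ff.temperature, ff.tail)

    def pair_energy(self, r, qi: float = 0.0, qj: float = 0.0):
        """Full nonbonded pair energy between two beads with charges qi, qj,
        using the engine (truncated/shifted) electrostatics convention."""
        u = self.nonionic_energy(r)
        if qi * qj != 0.0:
            u = u + screened_coulomb_energy(r, qi, qj, self.elec)
        return u

    def bond_pair_energy(self, r):
        return bond_energy(r, self.bond)

    # -- kernel export -------------------------------------------------------

    def kernel_params(self) -> np.ndarray:
        """Flat float64 parameter vector consumed by the numba kernels:
        [C_mie, eps_wca, lambda_r, lambda_a, rc_wca, lam, eps_tail, rc_tail,
        tail_shift, lB, kappa, rc_el, el_shift, k_bond, r0]."""
        m, t, e, b = self.mie, self.tail, self.elec, self.bond
        el_shift = np.exp(-e.kappa * e.r_cut_el) / e.r_cut_el * e.bjerrum_length
        return np.array(
            [
                m.prefactor,
                m.epsilon,
                m.lambda_r,
                m.lambda_a,
                m.r_cut,
                self.lam,
                t.epsilon,
                t.r_cut_tail,
                t.tail_shift,
                e.bjerrum_length,
                e.kappa,
                e.r_cut_el,
                el_shift,
                b.k_bond,
                b.r0,
            ],
            dtype=np.float64,
        )

    @property
    def max_cutoff(self) -> float:
        return max(self.mie.r_cut, self.tail.r_cut_tail, self.elec.r_cut_el)
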