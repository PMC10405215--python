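"""Reduced-unit system and physical constants.

The simulation works in reduced units: lengths in units of the bead size
sigma (mapped to 6.0 A, the generic size of a protein residue), energies in
units of k_B*T at the operating temperature T0 = 300 K, bead mass m = 1, and
time in tau = sigma*sqrt(m/epsilon).  The single conversion constant needed
to report results in experimental units is k_B*T(300 K) = 0.596 kcal/mol.
"""

from __future__ import annotations

#: Operating (room) temperature, K.  All dynamics run at this temperature.
T_ROOM: float = 300.0

#: Physical map of the reduced length unit, Angstrom per sigma.
SIGMA_ANGSTROM: float = 6.0

#: k_B*T at 300 K in kcal/mol (k_B*N_A = 1.9872e-3 kcal/mol/K).
KT300_KCAL_PER_MOL: float = 0.596

#: e^2/(4*pi*eps0*k_B) in Angstrom*Kelvin; sets the Bjerrum length
#: l_B = ELEC_PREFACTOR_AK / (eps_r * T).
ELEC_PREFACTOR_AK: float = 1.6710e5

#: Avogadro-based conversion: number density (A^-3) per mol/L.
DENSITY_PER_MOLAR: float = 6.02214076e-4  # = 6.022e23 / 1e27


def kt_to_kcal_per_mol(energy_kt: float) -> float:
    """Convert an energy from k_B*T(300 K) units to kcal/mol."""
    return energy_kt * KT300_KCAL_PER_MOL


def per_residue(energy_kt: float, n_residues: int = 60) -> float:
    """Energy in kcal/mol per residue (divide the pair total by chain length)."""
    return kt_to_kcal_per_mol(energy_kt) / n_residues
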