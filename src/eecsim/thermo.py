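"""Closed-form entropy/enthalpy decomposition of the binding free energy.

The implicit-solvent pair potentials are potentials of mean force over the
water degrees of freedom, so their explicit temperature dependence encodes
water reorganization: for a channel with average energy change dU whose
potential scales as w(r; T), the entropy and enthalpy changes follow from
T*ds = -T*(d dW/dT) and dh = dW - T*(d dW/dT).

Channel coefficients (evaluated at the operating temperature T):

* electrostatics, w ~ 1/eps_r(T) with kappa held constant:
  T*dS_el = x * dU_el and dH_el = (1 + x) * dU_el, x = dln(eps_r)/dln(T)
  (about -1.36 at 300 K -- electrostatic attraction in water is
  entropy-driven and enthalpy-penalized);
* hydrophobic tail, w = -lambda(T)*eps0*phi(r) with fixed energy scale eps0:
  T*dS_hp = -(alpha*T/lambda) * dU_hp, dH_hp = (1 - alpha*T/lambda) * dU_hp;
* channels whose energy scale is proportional to k_B*T (WCA repulsion and
  harmonic bonds): fully entropic, T*dS = -dU and dH = 0.

Totals: T*dS_total = sum(dH_channels) - PMF(0);  the conformational entropy
is the remainder after subtracting every potential-derived channel entropy
(chain translational entropy excluded by convention).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import pandas as pd

from .errors import ParameterError
from .potentials import dlnEps_dlnT
from .units import KT300_KCAL_PER_MOL, T_ROOM

__all__ = [
    "ThermoDecomposition",
    "decompose_el",
    "decompose_hp",
    "decompose_entropic_channels",
    "total_and_conformational",
    "decompose",
]


def decompose_el(dU_el: float, T: float = T_ROOM) -> tuple[float, float]:
    """(T*dS_el, dH_el) from the dielectric-fit logarithmic derivative."""
    x = dlnEps_dlnT(T)
    return x * dU_el, (1.0 + x) * dU_el


def decompose_hp(
    dU_hp: float,
    T: float = T_ROOM,
    alpha: float = 0.0,
    theta: float = T_ROOM,
    lambda0: float = 0.95,
) -> tuple[float, float]:
    """(T*dS_hp, dH_hp) for the temperature-dependent hydrophobic channel."""
    lam = lambda0 + alpha * (T - theta)
    if lam <= 0.0:
        raise ParameterError(f"lambda(T) = {lam:.4g} <= 0: decomposition undefined")
    c = alpha * T / lam
    return -c * dU_hp, (1.0 - c) * dU_hp


def decompose_entropic_channels(dU_wca: float, dU_bond: float) -> tuple[float, float]:
    """(T*dS_wca, T*dS_bond); dH is identically zero for channels whose
    energy scale is proportional to k_B*T."""
    return -dU_wca, -dU_bond


def total_and_conformational(
    dG: float,
    dH_el: float,
    dH_hp: float,
    dH_wca: float,
    dH_bond: float,
    TdS_el: float,
    TdS_hp: float,
    TdS_wca: float,
    TdS_bond: float,
) -> tuple[float, float]:
    """T*dS_total from the PMF and all known enthalpies, and the
    conformational-entropy remainder."""
    TdS_total = dH_el + dH_hp + dH_wca + dH_bond - dG
    TdS_conf = TdS_total - TdS_el - TdS_hp - TdS_wca - TdS_bond
    return TdS_total, TdS_conf


@dataclass(frozen=True)
class ThermoDecomposition:
    """All decomposition fields in k_B*T(300 K) for the chain pair.

    ``to_kcal_per_mol``/``per_residue`` convert with k_B*T(300 K) =
    0.596 kcal/mol.  Identities holding by construction: per channel
    dH_x - TdS_x = dU_x, and dH_total - TdS_total = dG.
    """

    dG: float
    TdS_el: float
    dH_el: float
    TdS_hp: float
    dH_hp: float
    TdS_wca: float
    dH_wca: float
    TdS_bond: float
    dH_bond: float
    TdS_total: float
    dH_total: float
    TdS_conf: float

    def to_kcal_per_mol(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) * KT300_KCAL_PER_MOL for f in fields(self)}

    def per_residue(self, n_residues: int = 60) -> dict[str, float]:
        return {k: v / n_residues for k, v in self.to_kcal_per_mol().items()}

    def summary(self, n_residues: int = 60) -> pd.DataFrame:
        """Tabulate dG / TdS / dH per channel in k_B*T, kcal/mol per chain
        pair, and kcal/mol per residue."""
        kt = {f.name: getattr(self, f.name) for f in fields(self)}
        kcal = self.to_kcal_per_mol()
        res = self.per_residue(n_residues)
        return pd.DataFrame(
            {"kT": kt, "kcal/mol": kcal, "kcal/mol/residue": res}
        )


def decompose(
    dG: float,
    dU_el: float,
    dU_hp: float,
    dU_wca: float,
    dU_bond: float,
    alpha: float = 0.0,
    dT: float = 0.0,
    lambda0: float = 0.95,
    T: float = T_ROOM,
) -> ThermoDecomposition:
    """Assemble the full decomposition from PMF(0) and the channel energy
    changes.  ``dT = T - theta`` parameterizes the solvent condition."""
    TdS_el, dH_el = decompose_el(dU_el, T)
    TdS_hp, dH_hp = decompose_hp(dU_hp, T, alpha=alpha, theta=T - dT, lambda0=lambda0)
    TdS_wca, TdS_bond = decompose_entropic_channels(dU_wca, dU_bond)
    dH_wca = dH_bond = 0.0
    TdS_total, TdS_conf = total_and_conformational(
        dG, dH_el, dH_hp, dH_wca, dH_bond, TdS_el, TdS_hp, TdS_wca, TdS_bond
    )
    return ThermoDecomposition(
        dG=dG,
        TdS_el=TdS_el,
        dH_el=dH_el,
        TdS_hp=TdS_hp,
        dH_hp=dH_hp,
        TdS_wca=TdS_wca,
        dH_wca=dH_wca,
        TdS_bond=TdS_bond,
        dH_bond=dH_bond,
        TdS_total=TdS_total,
        dH_total=dH_el + dH_hp + dH_wca + dH_bond,
        TdS_conf=TdS_conf,
    )
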