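"""Analytic pair and bond potentials, forces, and temperature derivatives.

All energies are in reduced units of k_B*T at the operating temperature
(300 K) and lengths in units of the bead size sigma, unless noted.

Four interaction channels are modelled:

* a generalized Weeks-Chandler-Andersen repulsion built from the
  Mie(lambda_r, lambda_a) potential, truncated and shifted at its minimum
  (``MiePair``); with its energy scale set to k_B*T it is athermal in
  reduced units and therefore purely entropic;
* a temperature-dependent hydrophobic attraction
  u_T(r) = -lambda(T) * eps * (sigma/r)^6, truncated and shifted at
  ``r_cut_tail`` (``HydrophobicTail``), with lambda(T) = lambda0 +
  alpha*(T - theta) carrying all of the temperature dependence -- the
  phenomenological imprint of water reorganization around nonpolar groups;
* a Debye-Hueckel screened Coulomb interaction (``Electrostatics``), whose
  temperature dependence enters through the dielectric constant of water;
* a harmonic bond u(r) = K*(r - r0)^2 (``HarmonicBond``; note the
  MD-engine convention without the 1/2 factor).

Because these implicit-solvent potentials are potentials of mean force over
the water degrees of freedom, their explicit temperature dependence encodes
water-reorganization entropy: s = -dw/dT and h = w - T*dw/dT.  The
closed-form decomposition coefficients derived from these forms live in
:mod:`eecsim.thermo`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .units import DENSITY_PER_MOLAR, ELEC_PREFACTOR_AK, SIGMA_ANGSTROM, T_ROOM

__all__ = [
    "MiePair",
    "HydrophobicTail",
    "Electrostatics",
    "HarmonicBond",
    "mie_prefactor",
    "wca_energy",
    "wca_force",
    "lambda_of_T",
    "hydrophobic_tail_energy",
    "hydrophobic_tail_force",
    "screened_coulomb_energy",
    "screened_coulomb_force",
    "bond_energy",
    "bond_force",
    "pair_force",
    "dielectric",
    "dlnEps_dlnT",
    "tabulate_potential",
]


# --------------------------------------------------------------------------
# dielectric model (Malmberg & Maryott / CRC empirical fit, liquid water)

_MM_COEFFS = (87.740, -0.40008, 9.398e-4, -1.410e-6)  # cubic in Celsius
_T_MIN, _T_MAX = 273.0, 373.15


def dielectric(T: float) -> float:
    """Static dielectric constant of water from the empirical cubic-in-Celsius
    fit (valid 273-373 K).  Decreases monotonically with temperature, which
    is the source of the water-reorganization entropy in the electrostatic
    channel."""
    T = float(T)
    if not (_T_MIN <= T <= _T_MAX):
        raise ParameterError(f"dielectric fit valid for {_T_MIN}-{_T_MAX} K, got {T}")
    t = T - 273.15
    a0, a1, a2, a3 = _MM_COEFFS
    return a0 + a1 * t + a2 * t * t + a3 * t * t * t


def dlnEps_dlnT(T: float) -> float:
    """Logarithmic temperature derivative (T/eps_r)*d(eps_r)/dT of the
    dielectric fit; about -1.36 at 300 K."""
    T = float(T)
    eps = dielectric(T)
    t = T - 273.15
    _, a1, a2, a3 = _MM_COEFFS
    deps_dT = a1 + 2.0 * a2 * t + 3.0 * a3 * t * t
    return T * deps_dT / eps


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class MiePair:
    """Generalized WCA repulsion: Mie(lambda_r, lambda_a) + eps, cut at the
    potential minimum r_cut = (lambda_r/lambda_a)^(1/(lambda_r-lambda_a))."""

    sigma: float = 1.0
    epsilon: float = 1.0  # k_B*T at the operating temperature
    lambda_r: float = 50.0
    lambda_a: float = 49.0

    def __post_init__(self) -> None:
        if not (self.lambda_r > self.lambda_a > 3.0):
            raise ParameterError("require lambda_r > lambda_a > 3")

    @property
    def r_cut(self) -> float:
        return (self.lambda_r / self.lambda_a) ** (1.0 / (self.lambda_r - self.lambda_a)) * self.sigma

    @property
    def prefactor(self) -> float:
        return mie_prefactor(self.lambda_r, self.lambda_a)


def mie_prefactor(lambda_r: float, lambda_a: float) -> float:
    """C = (lr/(lr-la)) * (lr/la)^(la/(lr-la)), the Mie normalization that
    makes the well depth equal to epsilon."""
    return (lambda_r / (lambda_r - lambda_a)) * (lambda_r / lambda_a) ** (
        lambda_a / (lambda_r - lambda_a)
    )


@dataclass(frozen=True)
class HydrophobicTail:
    """Temperature-dependent attraction u_T(r) = -lambda(T)*eps*(sigma/r)^6,
    truncated and shifted to zero at ``r_cut_tail``.

    ``lambda0`` is fixed by requiring the second virial coefficient of the
    non-ionic interaction to vanish at T = theta; ``alpha`` (1/K) sets the
    temperature sensitivity and its sign selects LCST (alpha > 0) versus
    UCST (alpha < 0) behaviour.  ``eps`` is a fixed energy scale equal to
    k_B*T at the operating temperature; only lambda(T) depends on T.
    """

    lambda0: float = 0.95
    alpha: float = 0.0  # 1/K
    theta: float = T_ROOM  # K
    r_cut_tail: float = 3.0
    epsilon: float = 1.0
    sigma: float = 1.0

    @property
    def tail_shift(self) -> float:
        """(sigma/r_cut)^6, subtracted so the energy is continuous at cutoff."""
        return (self.sigma / self.r_cut_tail) ** 6


@dataclass(frozen=True)
class Electrostatics:
    """Debye-Hueckel screened Coulomb channel in reduced units.

    ``bjerrum_length`` (sigma units) is derived from eps_r(T); ``kappa``
    (1/sigma) from the monovalent salt concentration via
    kappa = sqrt(8*pi*l_B*C).  kappa is held temperature-independent.
    ``shifted`` controls whether the energy is shifted to zero at
    ``r_cut_el`` (the engine convention); the bare analytic form keeps
    shifted=False so that kappa=0 recovers the Coulomb potential exactly.
    """

    bjerrum_length: float = field(default=ELEC_PREFACTOR_AK / (78.0 * T_ROOM) / SIGMA_ANGSTROM)
    kappa: float = 0.0
    r_cut_el: float = 8.0
    shifted: bool = False

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ParameterError("kappa must be >= 0")

    @classmethod
    def from_conditions(
        cls,
        eps_r: float = 78.0,
        T: float = T_ROOM,
        salt_molar: float = 0.1,
        sigma_angstrom: float = SIGMA_ANGSTROM,
        r_cut_el: float = 8.0,
        shifted: bool = False,
    ) -> "Electrostatics":
        """Build from experimental conditions: dielectric constant, T, and
        monovalent salt concentration (mol/L)."""
        lb_A = ELEC_PREFACTOR_AK / (eps_r * T)
        n_A3 = salt_molar * DENSITY_PER_MOLAR
        kappa_A = np.sqrt(8.0 * np.pi * lb_A * n_A3)
        return cls(
            bjerrum_length=lb_A / sigma_angstrom,
            kappa=kappa_A * sigma_angstrom,
            r_cut_el=r_cut_el,
            shifted=shifted,
        )

    @property
    def debye_length(self) -> float:
        if self.kappa == 0.0:
            return np.inf
        return 1.0 / self.kappa


@dataclass(frozen=True)
class HarmonicBond:
    """u(r) = k_bond*(r - r0)^2 -- MD-engine convention, no 1/2 factor."""

    k_bond: float = 100.0  # k_B*T / sigma^2
    r0: float = 0.7  # sigma


# --------------------------------------------------------------------------
# energies and forces


def _check_positive_r(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0.0):
        raise ParameterError("pair separation must be positive")
    return r


def wca_energy(r, p: MiePair = MiePair()):
    """Truncated-and-shifted Mie(lr, la) repulsion; 0 at and beyond r_cut."""
    r = _check_positive_r(r)
    x = p.sigma / r
    # factored form x^la * (x^(lr-la) - 1) avoids inf - inf deep in the core
    u = p.prefactor * p.epsilon * x**p.lambda_a * (x ** (p.lambda_r - p.lambda_a) - 1.0) + p.epsilon
    out = np.where(r < p.r_cut, u, 0.0)
    return out if out.ndim else float(out)


def wca_force(r, p: MiePair = MiePair()):
    """-d(wca_energy)/dr; repulsive (positive) wherever nonzero."""
    r = _check_positive_r(r)
    x = p.sigma / r
    f = (p.prefactor * p.epsilon / r) * x**p.lambda_a * (
        p.lambda_r * x ** (p.lambda_r - p.lambda_a) - p.lambda_a
    )
    out = np.where(r < p.r_cut, f, 0.0)
    return out if out.ndim else float(out)


def lambda_of_T(T: float, h: HydrophobicTail) -> float:
    """lambda(T) = lambda0 + alpha*(T - theta).  alpha > 0 -> LCST-type
    (attraction strengthens on heating); alpha < 0 -> UCST-type."""
    return h.lambda0 + h.alpha * (T - h.theta)


def hydrophobic_tail_energy(r, T: float, h: HydrophobicTail):
    """u_T(r) = -lambda(T)*eps*[(sigma/r)^6 - (sigma/r_cut)^6] for r < r_cut,
    0 beyond.  Raises if lambda(T) < 0 (outside the admissible region)."""
    lam = lambda_of_T(T, h)
    if lam < 0.0:
        raise ParameterError(f"lambda(T) = {lam:.4g} < 0: outside admissible region")
    r = _check_positive_r(r)
    u = -lam * h.epsilon * ((h.sigma / r) ** 6 - h.tail_shift)
    out = np.where(r < h.r_cut_tail, u, 0.0)
    return out if out.ndim else float(out)


def hydrophobic_tail_force(r, T: float, h: HydrophobicTail):
    """-d(u_T)/dr (attractive, negative, for r < r_cut_tail)."""
    lam = lambda_of_T(T, h)
    if lam < 0.0:
        raise ParameterError(f"lambda(T) = {lam:.4g} < 0: outside admissible region")
    r = _check_positive_r(r)
    f = -6.0 * lam * h.epsilon * h.sigma**6 / r**7
    out = np.where(r < h.r_cut_tail, f, 0.0)
    return out if out.ndim else float(out)


def screened_coulomb_energy(r, qi: float, qj: float, es: Electrostatics):
    """u(r) = qi*qj*l_B*exp(-kappa*r)/r in k_B*T units; kappa = 0 recovers the
    bare Coulomb potential.  If ``es.shifted`` the energy is shifted to zero
    at ``r_cut_el`` and truncated there."""
    r = _check_positive_r(r)
    u = qi * qj * es.bjerrum_length * np.exp(-es.kappa * r) / r
    if es.shifted:
        rc = es.r_cut_el
        u = np.where(r < rc, u - qi * qj * es.bjerrum_length * np.exp(-es.kappa * rc) / rc, 0.0)
    return u if np.ndim(u) else float(u)


def screened_coulomb_force(r, qi: float, qj: float, es: Electrostatics):
    """-d(u)/dr of the (possibly truncated) screened Coulomb energy."""
    r = _check_positive_r(r)
    f = qi * qj * es.bjerrum_length * np.exp(-es.kappa * r) * (1.0 / r**2 + es.kappa / r)
    if es.shifted:
        f = np.where(r < es.r_cut_el, f, 0.0)
    return f if np.ndim(f) else float(f)


def bond_energy(r, b: HarmonicBond = HarmonicBond()):
    """u(r) = k_bond*(r - r0)^2; zero exactly at r0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0.0):
        raise ParameterError("bond length must be >= 0")
    u = b.k_bond * (r - b.r0) ** 2
    return u if u.ndim else float(u)


def bond_force(r, b: HarmonicBond = HarmonicBond()):
    """-d(u_bond)/dr = -2*k_bond*(r - r0)."""
    r = np.asarray(r, dtype=float)
    f = -2.0 * b.k_bond * (r - b.r0)
    return f if f.ndim else float(f)


def pair_force(r, potential, **kwargs):
    """Dispatch -dU/dr for any of the potential families."""
    if isinstance(potential, MiePair):
        return wca_force(r, potential)
    if isinstance(potential, HydrophobicTail):
        return hydrophobic_tail_force(r, kwargs.get("T", T_ROOM), potential)
    if isinstance(potential, Electrostatics):
        return screened_coulomb_force(r, kwargs.get("qi", 1.0), kwargs.get("qj", 1.0), potential)
    if isinstance(potential, HarmonicBond):
        return bond_force(r, potential)
    raise TypeError(f"unknown potential type {type(potential).__name__}")


def tabulate_potential(r_values, energy_fn, force_fn, path) -> None:
    """Export a two-column-per-block TSV (r, energy, force) for cross-checking
    against external MD engines."""
    r = np.asarray(r_values, dtype=float)
    u = np.asarray(energy_fn(r), dtype=float)
    f = np.asarray(force_fn(r), dtype=float)
    with open(path, "w") as fh:
        fh.write("# r\tenergy\tforce\n")
        for ri, ui, fi in zip(r, u, f):
            fh.write(f"{ri:.10g}\t{ui:.10g}\t{fi:.10g}\n")
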