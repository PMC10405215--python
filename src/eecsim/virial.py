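"""Second virial coefficient of the non-ionic interaction and lambda0
calibration.

B2 = 2*pi * Integral_0^inf [1 - exp(-u(r)/kT)] r^2 dr over
u = u_wca + u_T.  The solvent condition is characterized by the theta
temperature, at which B2 vanishes; the calibration constant lambda0 is the
root of B2(lambda; T = theta) = 0.  B2(T - theta) curves and the admissible
(alpha, T - theta) region drive the compensation sweep.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .errors import ConfigurationError, NumericalError
from .forcefield import ForceField
from .potentials import lambda_of_T

__all__ = [
    "B2Result",
    "AdmissibleRegion",
    "b2_of_lambda",
    "second_virial",
    "calibrate_lambda0",
    "b2_curve",
    "admissible_region",
    "sample_parameters",
]

#: absolute quadrature tolerance, sigma^3
QUAD_TOL = 1e-6


@dataclass(frozen=True)
class B2Result:
    """Second virial coefficient in sigma^3 with quadrature diagnostics."""

    value: float
    temperature: float
    lambda_used: float
    quadrature_error: float


@dataclass(frozen=True)
class AdmissibleRegion:
    """Parameter region for the compensation sweep: |alpha| < alpha_max,
    T - theta in dT_range, and B2 within b2_bounds (sigma^3)."""

    alpha_max: float = 0.01
    dT_range: tuple[float, float] = (-100.0, 100.0)
    b2_bounds: tuple[float, float] = (-1.1, 0.1)
    # lambda interval equivalent to b2_bounds (filled by admissible_region)
    lambda_bounds: tuple[float, float] = (0.0, np.inf)


def b2_of_lambda(lam: float, ff: ForceField) -> B2Result:
    """B2 of u_wca + u_T at hydrophobic coupling ``lam`` (dimensionless
    reduced form: energies already in k_B*T).  The integrand vanishes
    identically beyond the largest non-ionic cutoff, which therefore serves
    as the upper quadrature limit."""
    mie = ff.mie
    rc1 = mie.r_cut
    rc2 = ff.tail.r_cut_tail
    ffl = ff.with_lambda(lam)

    def integrand(r: float) -> float:
        return (1.0 - np.exp(-ffl.nonionic_energy(r))) * r * r

    total, err = 0.0, 0.0
    for a, b in ((1e-12, rc1), (rc1, max(rc1, rc2))):
        if b <= a:
            continue
        v, e = quad(integrand, a, b, epsabs=QUAD_TOL / (2.0 * np.pi), limit=200)
        total += v
        err += e
    value = 2.0 * np.pi * total
    err *= 2.0 * np.pi
    if not np.isfinite(value):
        raise NumericalError(f"B2 quadrature diverged at lambda={lam}")
    return B2Result(value=value, temperature=ff.temperature, lambda_used=lam, quadrature_error=err)


def second_virial(T: float, ff: ForceField) -> B2Result:
    """B2 at temperature T, using lambda(T) from the force field's tail."""
    lam = lambda_of_T(T, ff.tail)
    res = b2_of_lambda(lam, ff)
    return B2Result(value=res.value, temperature=T, lambda_used=lam, quadrature_error=res.quadrature_error)


def calibrate_lambda0(ff: ForceField | None = None, bracket: tuple[float, float] = (0.3, 2.0)) -> float:
    """Root-solve B2(lambda0) = 0 to fix the attraction strength at the
    theta point.  Raises if the bracket shows no sign change, which flags a
    wrong functional form for the temperature-dependent tail."""
    ff = ff or ForceField()
    lo, hi = bracket
    f_lo = b2_of_lambda(lo, ff).value
    f_hi = b2_of_lambda(hi, ff).value
    if f_lo * f_hi > 0:
        raise NumericalError(
            f"no sign change of B2 in lambda bracket {bracket}: "
            f"B2({lo})={f_lo:.4g}, B2({hi})={f_hi:.4g}; wrong u_T form?"
        )
    return float(brentq(lambda lam: b2_of_lambda(lam, ff).value, lo, hi, xtol=1e-6))


def b2_curve(dT_values: Sequence[float], alpha: float, ff: ForceField | None = None) -> list[B2Result]:
    """B2 versus T - theta at fixed alpha.  Near the theta point the curve is
    approximately linear; the sign of its slope follows the sign of alpha
    (LCST: B2 decreases with T - theta; UCST: increases)."""
    ff = ff or ForceField()
    out = []
    for dT in dT_values:
        ffd = ff.with_hydrophobicity(alpha=alpha, dT=float(dT))
        out.append(second_virial(ff.temperature, ffd))
    return out


def admissible_region(ff: ForceField | None = None) -> AdmissibleRegion:
    """Translate the B2 bounds into a lambda interval (B2 is strictly
    decreasing in lambda) and return the full constrained region."""
    ff = ff or ForceField()
    region = AdmissibleRegion()
    b2_lo, b2_hi = region.b2_bounds  # (-1.1, 0.1)

    def g(lam, target):
        return b2_of_lambda(lam, ff).value - target

    lam_min = brentq(g, 0.0, 3.0, args=(b2_hi,), xtol=1e-8)  # B2 = +0.1
    lam_max = brentq(g, 0.0, 3.0, args=(b2_lo,), xtol=1e-8)  # B2 = -1.1
    if lam_max <= lam_min:
        raise ConfigurationError("empty admissible lambda interval")
    return AdmissibleRegion(lambda_bounds=(lam_min, lam_max))


def sample_parameters(
    n: int,
    seed: int,
    ff: ForceField | None = None,
    region: AdmissibleRegion | None = None,
) -> list[tuple[float, float]]:
    """Draw ``n`` (alpha, dT) pairs uniformly over the admissible region by
    rejection against the B2 bounds.  Deterministic under ``seed``."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    ff = ff or ForceField()
    region = region or admissible_region(ff)
    lam0 = ff.tail.lambda0
    lam_min, lam_max = region.lambda_bounds
    rng = np.random.default_rng(seed)
    samples: list[tuple[float, float]] = []
    while len(samples) < n:
        alpha = rng.uniform(-region.alpha_max, region.alpha_max)
        dT = rng.uniform(*region.dT_range)
        lam = lam0 + alpha * dT
        if lam_min <= lam <= lam_max:
            samples.append((float(alpha), float(dT)))
    return samples
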