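"""Numba kernels: pairwise forces with a Verlet neighbor list, BAOAB
Langevin integration, and the ABF inner loop.

Everything here works on flat float64/int64 arrays in reduced units; the
parameter vector layout is produced by ``ForceField.kernel_params``:

  [0] C_mie  [1] eps_wca  [2] lambda_r  [3] lambda_a  [4] rc_wca
  [5] lam    [6] eps_tail [7] rc_tail   [8] tail_shift
  [9] lB    [10] kappa   [11] rc_el    [12] el_shift (per unit charge product)
  [13] k_bond [14] r0

Minimum-image convention throughout; positions are never wrapped (runs are
short and the chains stay within half a box length of each other).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the run kernels
STATUS_OK = 0
STATUS_OVERLAP = 1
STATUS_NONFINITE = 2

_OVERLAP_R2 = 1e-12  # (1e-6 sigma)^2


@njit(cache=True, fastmath=True)
def build_pairs(pos, box, rlist, excluded, pairs_i, pairs_j):
    """Fill the Verlet pair list with all non-excluded pairs within
    ``rlist``; O(N^2) scan (N is small).  Returns the number of pairs."""
    n = pos.shape[0]
    rl2 = rlist * rlist
    np_count = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            if excluded[i, j]:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            hbox = 0.5 * box
            if dx > hbox:
                dx -= box
            elif dx < -hbox:
                dx += box
            if dy > hbox:
                dy -= box
            elif dy < -hbox:
                dy += box
            if dz > hbox:
                dz -= box
            elif dz < -hbox:
                dz += box
            if dx * dx + dy * dy + dz * dz < rl2:
                pairs_i[np_count] = i
                pairs_j[np_count] = j
                np_count += 1
    return np_count


@njit(cache=True, fastmath=True)
def compute_forces(pos, box, charges, pairs_i, pairs_j, n_pairs, bonds, params, f):
    """Channel-resolved forces and energies over the given pair list plus
    the bond list.  Returns (u_wca, u_hp, u_el, u_bond, status)."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    C = params[0]
    eps_w = params[1]
    lr = params[2]
    la = params[3]
    rc_w = params[4]
    lam = params[5]
    eps_t = params[6]
    rc_t = params[7]
    t_shift = params[8]
    lB = params[9]
    kappa = params[10]
    rc_e = params[11]
    e_shift = params[12]
    kb = params[13]
    r0 = params[14]
    rc_w2 = rc_w * rc_w
    rc_t2 = rc_t * rc_t
    rc_e2 = rc_e * rc_e

    u_wca = 0.0
    u_hp = 0.0
    u_el = 0.0
    u_bond = 0.0
    status = STATUS_OK

    for p in range(n_pairs):
        i = pairs_i[p]
        j = pairs_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        hbox = 0.5 * box
        if dx > hbox:
            dx -= box
        elif dx < -hbox:
            dx += box
        if dy > hbox:
            dy -= box
        elif dy < -hbox:
            dy += box
        if dz > hbox:
            dz -= box
        elif dz < -hbox:
            dz += box
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc_e2 and r2 >= rc_t2:
            continue
        if r2 < _OVERLAP_R2:
            status = STATUS_OVERLAP
            continue
        r = np.sqrt(r2)
        inv_r = 1.0 / r
        fscal = 0.0
        if r2 < rc_t2:
            inv_r2 = inv_r * inv_r
            x6 = inv_r2 * inv_r2 * inv_r2
            if r2 < rc_w2:
                # generalized WCA via exp/log powers (exponents may be large)
                xlr = np.exp(-lr * np.log(r))
                xla = np.exp(-la * np.log(r))
                u_wca += C * eps_w * (xlr - xla) + eps_w
                fscal += C * eps_w * (lr * xlr - la * xla) * inv_r2
            u_hp += -lam * eps_t * (x6 - t_shift)
            fscal += -6.0 * lam * eps_t * x6 * inv_r2
        qq = charges[i] * charges[j]
        if qq != 0.0 and r2 < rc_e2:
            ue = qq * lB * np.exp(-kappa * r) * inv_r
            u_el += ue - qq * e_shift
            fscal += (ue * (inv_r + kappa)) * inv_r
        f[i, 0] += fscal * dx
        f[i, 1] += fscal * dy
        f[i, 2] += fscal * dz
        f[j, 0] -= fscal * dx
        f[j, 1] -= fscal * dy
        f[j, 2] -= fscal * dz

    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        hbox = 0.5 * box
        if dx > hbox:
            dx -= box
        elif dx < -hbox:
            dx += box
        if dy > hbox:
            dy -= box
        elif dy < -hbox:
            dy += box
        if dz > hbox:
            dz -= box
        elif dz < -hbox:
            dz += box
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-6:
            status = STATUS_OVERLAP
            continue
        u_bond += kb * (r - r0) * (r - r0)
        fscal = -2.0 * kb * (r - r0) / r
        f[i, 0] += fscal * dx
        f[i, 1] += fscal * dy
        f[i, 2] += fscal * dz
        f[j, 0] -= fscal * dx
        f[j, 1] -= fscal * dy
        f[j, 2] -= fscal * dz

    return u_wca, u_hp, u_el, u_bond, status


@njit(cache=True)
def _max_disp2(pos, pos_ref):
    n = pos.shape[0]
    m = 0.0
    for i in range(n):
        d = 0.0
        for k in range(3):
            dd = pos[i, k] - pos_ref[i, k]
            d += dd * dd
        if d > m:
            m = d
    return m


@njit(cache=True)
def run_md(
    pos,
    vel,
    charges,
    bonds,
    excluded,
    box,
    params,
    dt,
    gamma,
    kT,
    n_steps,
    seed,
    rlist,
    skin,
    sample_every,
    energy_out,
    save_every,
    traj_out,
    vel_out,
):
    """Plain Langevin (BAOAB) run with channel-energy sampling.

    ``energy_out`` is (n_samples, 4); ``traj_out``/``vel_out`` are
    (n_frames, n, 3) (pass size-0 arrays to skip saving).  Returns status.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    max_pairs = n * (n - 1) // 2
    pairs_i = np.empty(max_pairs, dtype=np.int64)
    pairs_j = np.empty(max_pairs, dtype=np.int64)
    pos_ref = pos.copy()
    n_pairs = build_pairs(pos, box, rlist, excluded, pairs_i, pairs_j)
    f = np.zeros((n, 3))
    uw, uh, ue, ub, status = compute_forces(
        pos, box, charges, pairs_i, pairs_j, n_pairs, bonds, params, f
    )
    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(kT * (1.0 - c1 * c1))
    else:
        c1 = 1.0
        c2 = 0.0
    half_dt = 0.5 * dt
    isample = 0
    iframe = 0
    for step in range(n_steps):
        for i in range(n):
            for k in range(3):
                vel[i, k] += half_dt * f[i, k]
                pos[i, k] += half_dt * vel[i, k]
        if c2 > 0.0:
            for i in range(n):
                for k in range(3):
                    vel[i, k] = c1 * vel[i, k] + c2 * np.random.standard_normal()
        elif c1 != 1.0:
            for i in range(n):
                for k in range(3):
                    vel[i, k] = c1 * vel[i, k]
        for i in range(n):
            for k in range(3):
                pos[i, k] += half_dt * vel[i, k]
        if _max_disp2(pos, pos_ref) > 0.25 * skin * skin:
            n_pairs = build_pairs(pos, box, rlist, excluded, pairs_i, pairs_j)
            pos_ref[:, :] = pos
        uw, uh, ue, ub, st = compute_forces(
            pos, box, charges, pairs_i, pairs_j, n_pairs, bonds, params, f
        )
        if st != STATUS_OK:
            status = st
        for i in range(n):
            for k in range(3):
                vel[i, k] += half_dt * f[i, k]
        if sample_every > 0 and (step + 1) % sample_every == 0 and isample < energy_out.shape[0]:
            energy_out[isample, 0] = uw
            energy_out[isample, 1] = uh
            energy_out[isample, 2] = ue
            energy_out[isample, 3] = ub
            isample += 1
        if save_every > 0 and (step + 1) % save_every == 0 and iframe < traj_out.shape[0]:
            traj_out[iframe, :, :] = pos
            if vel_out.shape[0] > iframe:
                vel_out[iframe, :, :] = vel
            iframe += 1
    if not np.all(np.isfinite(pos)):
        status = STATUS_NONFINITE
    return status


@njit(cache=True)
def run_abf(
    pos,
    vel,
    charges,
    bonds,
    excluded,
    box,
    params,
    n1,
    dt,
    gamma,
    kT,
    n_steps,
    seed,
    rlist,
    skin,
    r_lo,
    r_hi,
    nbins,
    ramp_n,
    wall_k,
    apply_bias,
    sample_every,
    bias_count,
    bias_fsum,
    comp_sums,
    comp_counts,
):
    """ABF along the center-of-mass distance between beads [0, n1) and
    [n1, n).

    The instantaneous force conjugate to the separation is
    F = mu*(F1/M1 - F2/M2).rhat computed from *physical* forces only; its
    running bin average is applied as a counter-bias (after a linear ramp of
    ``ramp_n`` samples per bin) distributed over the beads.  Harmonic walls
    of stiffness ``wall_k`` confine the coordinate to [r_lo, r_hi].

    ``bias_count``/``bias_fsum`` (nbins,) and ``comp_sums`` (4, nbins) /
    ``comp_counts`` (nbins,) accumulate in place so windows can be extended.
    Returns status.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    n2 = n - n1
    mu = n1 * n2 / (n1 + n2)
    max_pairs = n * (n - 1) // 2
    pairs_i = np.empty(max_pairs, dtype=np.int64)
    pairs_j = np.empty(max_pairs, dtype=np.int64)
    pos_ref = pos.copy()
    n_pairs = build_pairs(pos, box, rlist, excluded, pairs_i, pairs_j)
    f = np.zeros((n, 3))
    dbin = (r_hi - r_lo) / nbins
    if gamma > 0.0:
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(kT * (1.0 - c1 * c1))
    else:
        c1 = 1.0
        c2 = 0.0
    half_dt = 0.5 * dt
    status = STATUS_OK

    # initial force evaluation (physical only; bias added in the loop)
    uw, uh, ue, ub, st = compute_forces(
        pos, box, charges, pairs_i, pairs_j, n_pairs, bonds, params, f
    )

    for step in range(n_steps):
        for i in range(n):
            for k in range(3):
                vel[i, k] += half_dt * f[i, k]
                pos[i, k] += half_dt * vel[i, k]
        if c2 > 0.0:
            for i in range(n):
                for k in range(3):
                    vel[i, k] = c1 * vel[i, k] + c2 * np.random.standard_normal()
        for i in range(n):
            for k in range(3):
                pos[i, k] += half_dt * vel[i, k]
        if _max_disp2(pos, pos_ref) > 0.25 * skin * skin:
            n_pairs = build_pairs(pos, box, rlist, excluded, pairs_i, pairs_j)
            pos_ref[:, :] = pos
        uw, uh, ue, ub, st = compute_forces(
            pos, box, charges, pairs_i, pairs_j, n_pairs, bonds, params, f
        )
        if st != STATUS_OK:
            status = st

        # reaction coordinate and instantaneous radial force
        r1x = 0.0
        r1y = 0.0
        r1z = 0.0
        f1x = 0.0
        f1y = 0.0
        f1z = 0.0
        for i in range(n1):
            r1x += pos[i, 0]
            r1y += pos[i, 1]
            r1z += pos[i, 2]
            f1x += f[i, 0]
            f1y += f[i, 1]
            f1z += f[i, 2]
        r2x = 0.0
        r2y = 0.0
        r2z = 0.0
        f2x = 0.0
        f2y = 0.0
        f2z = 0.0
        for i in range(n1, n):
            r2x += pos[i, 0]
            r2y += pos[i, 1]
            r2z += pos[i, 2]
            f2x += f[i, 0]
            f2y += f[i, 1]
            f2z += f[i, 2]
        dx = r1x / n1 - r2x / n2
        dy = r1y / n1 - r2y / n2
        dz = r1z / n1 - r2z / n2
        xi = np.sqrt(dx * dx + dy * dy + dz * dz)
        if xi < 1e-10:
            xi = 1e-10
        ux = dx / xi
        uy = dy / xi
        uz = dz / xi
        f_inst = mu * (
            (f1x / n1 - f2x / n2) * ux
            + (f1y / n1 - f2y / n2) * uy
            + (f1z / n1 - f2z / n2) * uz
        )

        fc = 0.0  # total force applied to the coordinate (bias + walls)
        if r_lo <= xi < r_hi:
            b = int((xi - r_lo) / dbin)
            if b >= nbins:
                b = nbins - 1
            bias_count[b] += 1.0
            bias_fsum[b] += f_inst
            if apply_bias:
                ramp = bias_count[b] / ramp_n
                if ramp > 1.0:
                    ramp = 1.0
                fc -= ramp * bias_fsum[b] / bias_count[b]
            if sample_every > 0 and (step + 1) % sample_every == 0:
                comp_sums[0, b] += uw
                comp_sums[1, b] += uh
                comp_sums[2, b] += ue
                comp_sums[3, b] += ub
                comp_counts[b] += 1.0
        elif xi >= r_hi:
            fc -= wall_k * (xi - r_hi)
        else:
            fc -= wall_k * (xi - r_lo)

        if fc != 0.0:
            g1 = fc / n1
            g2 = fc / n2
            for i in range(n1):
                f[i, 0] += g1 * ux
                f[i, 1] += g1 * uy
                f[i, 2] += g1 * uz
            for i in range(n1, n):
                f[i, 0] -= g2 * ux
                f[i, 1] -= g2 * uy
                f[i, 2] -= g2 * uz

        for i in range(n):
            for k in range(3):
                vel[i, k] += half_dt * f[i, k]

    if not np.all(np.isfinite(pos)):
        status = STATUS_NONFINITE
    return status
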