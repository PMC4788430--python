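"""Optional numba-accelerated pair kernels for the coarse-grained force field.

The numpy path in :mod:`tailensemble.energetics` is the reference
implementation; these kernels reproduce it bit-for-bit at the level of
summed energies/forces (same formulas, scalar accumulation) and are used
automatically when numba imports cleanly.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in the supported env
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap(args[0]) if args and callable(args[0]) else wrap


@njit(cache=False, fastmath=False)
def pair_forces(pos, ii, jj, sigma, qq, scale, kappa_inv, cutoff, shift_per_qq,
                wca_epsilon, coulomb_over_eps, forces):
    """WCA + screened-Coulomb energy over pair lists; accumulates scaled forces.

    Returns the (unscaled) energy sum; ``forces`` receives ``scale`` times
    the pair forces (both members).
    """
    e_total = 0.0
    wca_factor = 2.0 ** (1.0 / 6.0)
    for k in range(len(ii)):
        i = ii[k]
        j = jj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            return np.nan
        r = np.sqrt(r2)
        f_over_r = 0.0
        s = sigma[k]
        if r < s * wca_factor:
            sr6 = (s / r) ** 6
            e_total += 4.0 * wca_epsilon * (sr6 * sr6 - sr6) + wca_epsilon
            f_over_r += 4.0 * wca_epsilon * (12.0 * sr6 * sr6 - 6.0 * sr6) / r2
        q = qq[k]
        if q != 0.0 and r < cutoff:
            pref = coulomb_over_eps * q
            ex = np.exp(-r / kappa_inv)
            e_total += pref * ex / r - shift_per_qq * q
            f_over_r += pref * ex * (1.0 / r + 1.0 / kappa_inv) / r2
        fs = scale * f_over_r
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz
    return e_total


@njit(cache=False, fastmath=False)
def _pchip_eval(x, bias_x, bias_c):
    """Piecewise-cubic value and derivative from scipy PPoly coefficients.

    Linear continuation with the boundary slope outside the knot range
    (must mirror BiasEstimate.value/derivative exactly).
    """
    n = len(bias_x)
    lo = bias_x[0]
    hi = bias_x[n - 1]
    if x < lo:
        # value and slope at the left edge of interval 0
        c0, c1_, c2, c3 = bias_c[0, 0], bias_c[1, 0], bias_c[2, 0], bias_c[3, 0]
        v = c3
        d = c2
        return v + d * (x - lo), d
    if x > hi:
        i = n - 2
        t = hi - bias_x[i]
        c0, c1_, c2, c3 = bias_c[0, i], bias_c[1, i], bias_c[2, i], bias_c[3, i]
        v = ((c0 * t + c1_) * t + c2) * t + c3
        d = (3.0 * c0 * t + 2.0 * c1_) * t + c2
        return v + d * (x - hi), d
    # binary search for the interval
    i0 = 0
    i1 = n - 1
    while i1 - i0 > 1:
        mid = (i0 + i1) // 2
        if bias_x[mid] <= x:
            i0 = mid
        else:
            i1 = mid
    t = x - bias_x[i0]
    c0, c1_, c2, c3 = bias_c[0, i0], bias_c[1, i0], bias_c[2, i0], bias_c[3, i0]
    v = ((c0 * t + c1_) * t + c2) * t + c3
    d = (3.0 * c0 * t + 2.0 * c1_) * t + c2
    return v, d


@njit(cache=False, fastmath=False)
def integrate_chunk(pos, vel, lam_arr, lamv_arr, noise_v, noise_l,
                    dt, c1, c2v, c1l, c2l, inv_m, mobile,
                    tt_ii, tt_jj, tt_sigma, tt_qq,
                    tr_ii, tr_jj, tr_sigma, tr_qq,
                    bi, bj, r0, cat,
                    kappa_inv, cutoff, shift_per_qq, wca_epsilon,
                    coulomb_over_eps, bond_k, e_rest_const,
                    bias_x, bias_c, rt_, m_lambda, lambda_min, lambda_max,
                    wall_k, wall_tol, frozen,
                    lam_out, etail_out, etr_out, forces, e_by_cat):
    """BAOAB chunk for a rigid-scaffold CG system; returns (status, step).

    status: 0 ok, 1 coincident beads / non-finite, 3 lambda escaped the
    wall region.  Per-step lambda and unscaled tail energies are written
    to the output arrays.  ``forces`` and ``e_by_cat`` are scratch.
    """
    n_steps = len(lam_out)
    n_beads = pos.shape[0]
    lam = lam_arr[0]
    lamv = lamv_arr[0]
    half = 0.5 * dt

    # initial force evaluation
    forces[:] = 0.0
    e_tt = pair_forces(pos, tt_ii, tt_jj, tt_sigma, tt_qq, lam * lam,
                       kappa_inv, cutoff, shift_per_qq, wca_epsilon,
                       coulomb_over_eps, forces)
    e_tr = pair_forces(pos, tr_ii, tr_jj, tr_sigma, tr_qq, lam,
                       kappa_inv, cutoff, shift_per_qq, wca_epsilon,
                       coulomb_over_eps, forces)
    if np.isnan(e_tt) or np.isnan(e_tr):
        return 1, 0
    e_by_cat[:] = 0.0
    e_tail_b = 0.0
    e_tr_b = 0.0
    e_rest_b = 0.0
    for k in range(len(bi)):
        i = bi[k]
        j = bj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[k]
        e_b = 0.5 * bond_k * dr * dr
        if cat[k] == 0:
            scale = lam * lam
            e_tail_b += e_b
        elif cat[k] == 1:
            scale = lam
            e_tr_b += e_b
        else:
            scale = 1.0
            e_rest_b += e_b
        fmag = -bond_k * dr / max(r, 1e-12)
        fs = scale * fmag
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz
    e_tail = e_tt + e_tail_b
    e_trest = e_tr + e_tr_b
    for i in range(n_beads):
        if not mobile[i]:
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
    if frozen:
        fl = 0.0
    else:
        _, bd = _pchip_eval(lam, bias_x, bias_c)
        wall_d = 0.0
        if lam > lambda_max:
            wall_d = 2.0 * wall_k * (lam - lambda_max)
        elif lam < lambda_min:
            wall_d = -2.0 * wall_k * (lambda_min - lam)
        fl = -(2.0 * lam * e_tail + e_trest + rt_ * bd + wall_d)

    for step in range(n_steps):
        # B half kick
        for i in range(n_beads):
            if mobile[i]:
                vel[i, 0] += half * forces[i, 0] * inv_m[i]
                vel[i, 1] += half * forces[i, 1] * inv_m[i]
                vel[i, 2] += half * forces[i, 2] * inv_m[i]
        if not frozen:
            lamv += half * fl / m_lambda
        # A half drift
        for i in range(n_beads):
            if mobile[i]:
                pos[i, 0] += half * vel[i, 0]
                pos[i, 1] += half * vel[i, 1]
                pos[i, 2] += half * vel[i, 2]
        if not frozen:
            lam += half * lamv
        # O
        for i in range(n_beads):
            if mobile[i]:
                vel[i, 0] = c1 * vel[i, 0] + c2v[i] * noise_v[step, i, 0]
                vel[i, 1] = c1 * vel[i, 1] + c2v[i] * noise_v[step, i, 1]
                vel[i, 2] = c1 * vel[i, 2] + c2v[i] * noise_v[step, i, 2]
        if not frozen:
            lamv = c1l * lamv + c2l * noise_l[step]
        # A half drift
        for i in range(n_beads):
            if mobile[i]:
                pos[i, 0] += half * vel[i, 0]
                pos[i, 1] += half * vel[i, 1]
                pos[i, 2] += half * vel[i, 2]
        if not frozen:
            lam += half * lamv
            if lam > lambda_max + wall_tol or lam < lambda_min - wall_tol:
                return 3, step
        # force refresh
        forces[:] = 0.0
        e_tt = pair_forces(pos, tt_ii, tt_jj, tt_sigma, tt_qq, lam * lam,
                           kappa_inv, cutoff, shift_per_qq, wca_epsilon,
                           coulomb_over_eps, forces)
        e_tr = pair_forces(pos, tr_ii, tr_jj, tr_sigma, tr_qq, lam,
                           kappa_inv, cutoff, shift_per_qq, wca_epsilon,
                           coulomb_over_eps, forces)
        if np.isnan(e_tt) or np.isnan(e_tr):
            return 1, step
        e_tail_b = 0.0
        e_tr_b = 0.0
        for k in range(len(bi)):
            i = bi[k]
            j = bj[k]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            dr = r - r0[k]
            e_b = 0.5 * bond_k * dr * dr
            if cat[k] == 0:
                scale = lam * lam
                e_tail_b += e_b
            elif cat[k] == 1:
                scale = lam
                e_tr_b += e_b
            else:
                scale = 1.0
            fmag = -bond_k * dr / max(r, 1e-12)
            fs = scale * fmag
            forces[i, 0] += fs * dx
            forces[i, 1] += fs * dy
            forces[i, 2] += fs * dz
            forces[j, 0] -= fs * dx
            forces[j, 1] -= fs * dy
            forces[j, 2] -= fs * dz
        e_tail = e_tt + e_tail_b
        e_trest = e_tr + e_tr_b
        if not (np.isfinite(e_tail) and np.isfinite(e_trest)):
            return 1, step
        for i in range(n_beads):
            if not mobile[i]:
                forces[i, 0] = 0.0
                forces[i, 1] = 0.0
                forces[i, 2] = 0.0
        if not frozen:
            _, bd = _pchip_eval(lam, bias_x, bias_c)
            wall_d = 0.0
            if lam > lambda_max:
                wall_d = 2.0 * wall_k * (lam - lambda_max)
            elif lam < lambda_min:
                wall_d = -2.0 * wall_k * (lambda_min - lam)
            fl = -(2.0 * lam * e_tail + e_trest + rt_ * bd + wall_d)
        # B half kick
        for i in range(n_beads):
            if mobile[i]:
                vel[i, 0] += half * forces[i, 0] * inv_m[i]
                vel[i, 1] += half * forces[i, 1] * inv_m[i]
                vel[i, 2] += half * forces[i, 2] * inv_m[i]
        if not frozen:
            lamv += half * fl / m_lambda
        lam_out[step] = lam
        etail_out[step] = e_tail
        etr_out[step] = e_trest
    lam_arr[0] = lam
    lamv_arr[0] = lamv
    return 0, n_steps


@njit(cache=False, fastmath=False)
def bond_forces(pos, bi, bj, r0, bond_scale, bond_k, e_by_cat, cat, forces):
    """Harmonic bond energies by category; accumulates scaled forces."""
    for k in range(len(bi)):
        i = bi[k]
        j = bj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[k]
        e_by_cat[cat[k]] += 0.5 * bond_k * dr * dr
        fmag = -bond_k * dr / max(r, 1e-12)
        fs = bond_scale[k] * fmag
        forces[i, 0] += fs * dx
        forces[i, 1] += fs * dy
        forces[i, 2] += fs * dz
        forces[j, 0] -= fs * dx
        forces[j, 1] -= fs * dy
        forces[j, 2] -= fs * dz
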