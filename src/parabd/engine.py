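"""Fused numba kernel: forces + Brownian step + stochastic chemistry.

The kernel advances the system in chunks.  It returns to Python whenever a
topology-changing chemistry event fires (depolymerization or severing), so
chain bookkeeping stays in plain Python while the inner loop runs compiled.
Hydrolysis only flips a nucleotide flag and is handled entirely in-kernel.

The interaction mathematics mirrors :mod:`parabd.forcefield` exactly; the
test suite checks the two paths against each other.

Two Verlet lists (all-pairs excluded volume; eligible ParA-ParB binding
pairs) are rebuilt together whenever any subunit has moved more than half
the skin since the last build.  Thermal kicks are pre-generated per chunk by
the caller (numpy's vectorized Gaussian sampler) and scaled in-kernel; the
chemistry Bernoulli draws use numba's own seeded uniform stream.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# float-parameter vector layout
PF_A, PF_K_EV, PF_K_BOND, PF_K_XL, PF_D0, PF_K_ALIGN, PF_EPS_B, PF_R_B, \
    PF_RANGE_B, PF_KAP1, PF_KAP2, PF_KAP3, PF_DT, PF_KT, PF_G0, PF_GROT, \
    PF_KH, PF_KD, PF_EPSTH, PF_BOUNDCUT, PF_SKIN, PF_MAXDISP, PF_EXTFX, \
    PF_CONF_R, PF_CONF_X0, PF_CONF_X1, PF_KWALL = range(27)
PF_N = 27

# counters layout
CT_NSAMP, CT_NFRAME, CT_NHYD, CT_NREBUILD, CT_NWARN, CT_LIST_VALID, \
    CT_NPAIRS, CT_NBINDPAIRS = range(8)
CT_N = 8

CODE_DONE = 0
CODE_EVENT = 1
CODE_NAN = 2
CODE_OVERFLOW = 3

EV_HYDROLYSIS = 0
EV_DEPOLYMERIZATION = 1
EV_SEVER = 2


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _ang_factor(c, kappa):
    h = np.exp(-((1.0 - c) ** 2) / (2.0 * kappa * kappa))
    return h, h * (1.0 - c) / (kappa * kappa)


@njit(cache=True)
def _rebuild_pairs(pos, active, species, bind_elig, cut_ev, cut_bind,
                   pair_i, pair_j, bind_i, bind_j, counts, ref_pos):
    """Two Verlet lists: all-pairs excluded volume and ParA-ParB binding.

    ``bind_i`` entries are the ParA partner, ``bind_j`` the ParB partner.
    Returns 0, or -1 on capacity overflow; counts -> (n_ev, n_bind).
    """
    n = pos.shape[0]
    cut_ev2 = cut_ev * cut_ev
    cut_bind2 = cut_bind * cut_bind
    big2 = max(cut_ev2, cut_bind2)
    cap_ev = pair_i.shape[0]
    cap_b = bind_i.shape[0]
    cnt = 0
    cntb = 0
    for i in range(n - 1):
        if not active[i]:
            continue
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        for j in range(i + 1, n):
            if not active[j]:
                continue
            dx = xi - pos[j, 0]
            dy = yi - pos[j, 1]
            dz = zi - pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 >= big2:
                continue
            if d2 < cut_ev2:
                if cnt >= cap_ev:
                    return -1
                pair_i[cnt] = i
                pair_j[cnt] = j
                cnt += 1
            if d2 < cut_bind2:
                ia = -1
                ib = -1
                if bind_elig[i] and species[j] == 1:
                    ia = i
                    ib = j
                elif bind_elig[j] and species[i] == 1:
                    ia = j
                    ib = i
                if ia >= 0:
                    if cntb >= cap_b:
                        return -1
                    bind_i[cntb] = ia
                    bind_j[cntb] = ib
                    cntb += 1
    for i in range(n):
        ref_pos[i, 0] = pos[i, 0]
        ref_pos[i, 1] = pos[i, 1]
        ref_pos[i, 2] = pos[i, 2]
    counts[0] = cnt
    counts[1] = cntb
    return 0


@njit(cache=True)
def _eval_forces(pos, pol, bonds, xlinks, angles, angle_k, aligns, align_c0,
                 hpairs, hk, hc0, in_bundle, pf, oriented,
                 pair_i, pair_j, n_pairs, bind_i, bind_j, n_bind,
                 forces, pgrad, maxb, maxb_bun):
    """Accumulate forces and dU/dp for the current configuration.

    Also fills ``maxb`` with each subunit's strongest |binding energy|.
    Returns the total potential energy.
    """
    n = pos.shape[0]
    for i in range(n):
        forces[i, 0] = 0.0
        forces[i, 1] = 0.0
        forces[i, 2] = 0.0
        pgrad[i, 0] = 0.0
        pgrad[i, 1] = 0.0
        pgrad[i, 2] = 0.0
        maxb[i] = 0.0
        maxb_bun[i] = 0.0
    energy = 0.0
    a = pf[PF_A]
    k_ev = pf[PF_K_EV]
    a2 = a * a

    # --- excluded volume -------------------------------------------------
    for q in range(n_pairs):
        i = pair_i[q]
        j = pair_j[q]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= a2 or r2 == 0.0:
            continue
        r = np.sqrt(r2)
        energy += 0.5 * k_ev * (r - a) ** 2
        fmag = -k_ev * (r - a) / r
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz

    # --- ParA-ParB binding ----------------------------------------------
    eps_b = pf[PF_EPS_B]
    r_b = pf[PF_R_B]
    range_b = pf[PF_RANGE_B]
    delta_b = range_b - r_b
    kap1, kap2, kap3 = pf[PF_KAP1], pf[PF_KAP2], pf[PF_KAP3]
    for q in range(n_bind):
        ia = bind_i[q]
        ib = bind_j[q]
        dx = pos[ia, 0] - pos[ib, 0]
        dy = pos[ia, 1] - pos[ib, 1]
        dz = pos[ia, 2] - pos[ib, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= range_b * range_b or r2 == 0.0:
            continue
        r = np.sqrt(r2)
        s = (r - r_b) / delta_b
        if np.abs(s) >= 1.0:
            continue
        one = 1.0 - s * s
        f = one * one
        dfdr = -4.0 * s * one / delta_b
        # u_hat: from ParA towards ParB
        ux = -dx / r
        uy = -dy / r
        uz = -dz / r
        c1 = pol[ia, 0] * ux + pol[ia, 1] * uy + pol[ia, 2] * uz
        h1, dh1 = _ang_factor(c1, kap1)
        if oriented == 1:
            pjd = pol[ib, 0] * ux + pol[ib, 1] * uy + pol[ib, 2] * uz
            c2 = -pjd
            c3 = -(pol[ia, 0] * pol[ib, 0] + pol[ia, 1] * pol[ib, 1]
                   + pol[ia, 2] * pol[ib, 2])
            h2, dh2 = _ang_factor(c2, kap2)
            h3, dh3 = _ang_factor(c3, kap3)
        else:
            pjd = 0.0
            h2 = 1.0
            h3 = 1.0
            dh2 = 0.0
            dh3 = 0.0
        u = -eps_b * f * h1 * h2 * h3
        energy += u
        au = -u
        if au > maxb[ia]:
            maxb[ia] = au
        if au > maxb[ib]:
            maxb[ib] = au
        if in_bundle[ia] and au > maxb_bun[ib]:
            maxb_bun[ib] = au
        du_dr = -eps_b * dfdr * h1 * h2 * h3
        du_dc1 = -eps_b * f * dh1 * h2 * h3
        # grad wrt r_ia; r_ia - r_ib = (dx,dy,dz) = -u*r
        gx = du_dr * dx / r + du_dc1 * (-(pol[ia, 0] - c1 * ux) / r)
        gy = du_dr * dy / r + du_dc1 * (-(pol[ia, 1] - c1 * uy) / r)
        gz = du_dr * dz / r + du_dc1 * (-(pol[ia, 2] - c1 * uz) / r)
        pgrad[ia, 0] += du_dc1 * ux
        pgrad[ia, 1] += du_dc1 * uy
        pgrad[ia, 2] += du_dc1 * uz
        if oriented == 1:
            du_dc2 = -eps_b * f * h1 * dh2 * h3
            du_dc3 = -eps_b * f * h1 * h2 * dh3
            gx += du_dc2 * ((pol[ib, 0] - pjd * ux) / r)
            gy += du_dc2 * ((pol[ib, 1] - pjd * uy) / r)
            gz += du_dc2 * ((pol[ib, 2] - pjd * uz) / r)
            pgrad[ia, 0] += du_dc3 * (-pol[ib, 0])
            pgrad[ia, 1] += du_dc3 * (-pol[ib, 1])
            pgrad[ia, 2] += du_dc3 * (-pol[ib, 2])
            pgrad[ib, 0] += du_dc2 * (-ux) + du_dc3 * (-pol[ia, 0])
            pgrad[ib, 1] += du_dc2 * (-uy) + du_dc3 * (-pol[ia, 1])
            pgrad[ib, 2] += du_dc2 * (-uz) + du_dc3 * (-pol[ia, 2])
        forces[ia, 0] -= gx
        forces[ia, 1] -= gy
        forces[ia, 2] -= gz
        forces[ib, 0] += gx
        forces[ib, 1] += gy
        forces[ib, 2] += gz

    # --- bonds -----------------------------------------------------------
    kb = pf[PF_K_BOND]
    for q in range(bonds.shape[0]):
        i = bonds[q, 0]
        j = bonds[q, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        energy += 0.5 * kb * (r - a) ** 2
        fmag = -kb * (r - a) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # --- crosslinks ------------------------------------------------------
    kx = pf[PF_K_XL]
    d0 = pf[PF_D0]
    for q in range(xlinks.shape[0]):
        i = xlinks[q, 0]
        j = xlinks[q, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        energy += 0.5 * kx * (r - d0) ** 2
        fmag = -kx * (r - d0) / r
        forces[i, 0] += fmag * dx
        forces[i, 1] += fmag * dy
        forces[i, 2] += fmag * dz
        forces[j, 0] -= fmag * dx
        forces[j, 1] -= fmag * dy
        forces[j, 2] -= fmag * dz

    # --- bending ---------------------------------------------------------
    for q in range(angles.shape[0]):
        ip = angles[q, 0]
        im = angles[q, 1]
        iq = angles[q, 2]
        kang = angle_k[q]
        b1x = pos[im, 0] - pos[ip, 0]
        b1y = pos[im, 1] - pos[ip, 1]
        b1z = pos[im, 2] - pos[ip, 2]
        b2x = pos[iq, 0] - pos[im, 0]
        b2y = pos[iq, 1] - pos[im, 1]
        b2z = pos[iq, 2] - pos[im, 2]
        l1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        l2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        b1x /= l1
        b1y /= l1
        b1z /= l1
        b2x /= l2
        b2y /= l2
        b2z /= l2
        c = b1x * b2x + b1y * b2y + b1z * b2z
        energy += kang * (1.0 - c)
        fpx = -kang * (b2x - c * b1x) / l1
        fpy = -kang * (b2y - c * b1y) / l1
        fpz = -kang * (b2z - c * b1z) / l1
        fnx = kang * (b1x - c * b2x) / l2
        fny = kang * (b1y - c * b2y) / l2
        fnz = kang * (b1z - c * b2z) / l2
        forces[ip, 0] += fpx
        forces[ip, 1] += fpy
        forces[ip, 2] += fpz
        forces[iq, 0] += fnx
        forces[iq, 1] += fny
        forces[iq, 2] += fnz
        forces[im, 0] -= fpx + fnx
        forces[im, 1] -= fpy + fny
        forces[im, 2] -= fpz + fnz

    # --- polarization alignment -----------------------------------------
    ka = pf[PF_K_ALIGN]
    for q in range(aligns.shape[0]):
        i = aligns[q, 0]   # subunit owning the polarization
        j = aligns[q, 1]   # bonded neighbour
        c0 = align_c0[q]
        bx = pos[j, 0] - pos[i, 0]
        by = pos[j, 1] - pos[i, 1]
        bz = pos[j, 2] - pos[i, 2]
        l = np.sqrt(bx * bx + by * by + bz * bz)
        bx /= l
        by /= l
        bz /= l
        c = pol[i, 0] * bx + pol[i, 1] * by + pol[i, 2] * bz
        energy += 0.5 * ka * (c - c0) ** 2
        g = ka * (c - c0)
        pgrad[i, 0] += g * bx
        pgrad[i, 1] += g * by
        pgrad[i, 2] += g * bz
        # dU/db = g (p - c b_hat)/l ; force on tip j = -dU/db, on i = +dU/db
        tx = g * (pol[i, 0] - c * bx) / l
        ty = g * (pol[i, 1] - c * by) / l
        tz = g * (pol[i, 2] - c * bz) / l
        forces[j, 0] -= tx
        forces[j, 1] -= ty
        forces[j, 2] -= tz
        forces[i, 0] += tx
        forces[i, 1] += ty
        forces[i, 2] += tz

    # --- helical couplings ----------------------------------------------
    for q in range(hpairs.shape[0]):
        i = hpairs[q, 0]
        j = hpairs[q, 1]
        kh_q = hk[q]
        c0 = hc0[q]
        c = pol[i, 0] * pol[j, 0] + pol[i, 1] * pol[j, 1] + pol[i, 2] * pol[j, 2]
        energy += 0.5 * kh_q * (c - c0) ** 2
        g = kh_q * (c - c0)
        pgrad[i, 0] += g * pol[j, 0]
        pgrad[i, 1] += g * pol[j, 1]
        pgrad[i, 2] += g * pol[j, 2]
        pgrad[j, 0] += g * pol[i, 0]
        pgrad[j, 1] += g * pol[i, 1]
        pgrad[j, 2] += g * pol[i, 2]
    return energy


@njit(cache=True)
def _confinement(pos, active, pf, forces):
    n = pos.shape[0]
    kw = pf[PF_KWALL]
    cr = pf[PF_CONF_R]
    x0 = pf[PF_CONF_X0]
    x1 = pf[PF_CONF_X1]
    e = 0.0
    for i in range(n):
        if not active[i]:
            continue
        rho = np.sqrt(pos[i, 1] * pos[i, 1] + pos[i, 2] * pos[i, 2])
        if rho > cr:
            fmag = -kw * (rho - cr) / rho
            forces[i, 1] += fmag * pos[i, 1]
            forces[i, 2] += fmag * pos[i, 2]
            e += 0.5 * kw * (rho - cr) ** 2
        if x1 > x0:
            if pos[i, 0] < x0:
                forces[i, 0] += kw * (x0 - pos[i, 0])
                e += 0.5 * kw * (x0 - pos[i, 0]) ** 2
            elif pos[i, 0] > x1:
                forces[i, 0] -= kw * (pos[i, 0] - x1)
                e += 0.5 * kw * (pos[i, 0] - x1) ** 2
    return e


@njit(cache=True)
def _sample(pos, species, polymerized, active, is_tip, in_bundle, maxb,
            maxb_bun, boundcut, scratch,
            k, t_comb, t_coma, t_gyr, t_nbound, t_nboundb, t_tipx, t_q90,
            t_mind, t_mindb, t_npoly):
    n = pos.shape[0]
    cbx = 0.0
    cby = 0.0
    cbz = 0.0
    nb = 0
    cax = 0.0
    cay = 0.0
    caz = 0.0
    na = 0
    ntip = 0
    tipx = 0.0
    for i in range(n):
        if species[i] != 0:
            cbx += pos[i, 0]
            cby += pos[i, 1]
            cbz += pos[i, 2]
            nb += 1
        elif polymerized[i]:
            cax += pos[i, 0]
            cay += pos[i, 1]
            caz += pos[i, 2]
            na += 1
            if is_tip[i] and in_bundle[i]:
                tipx += pos[i, 0]
                ntip += 1
    if nb > 0:
        cbx /= nb
        cby /= nb
        cbz /= nb
    if na > 0:
        cax /= na
        cay /= na
        caz /= na
    t_comb[k, 0] = cbx
    t_comb[k, 1] = cby
    t_comb[k, 2] = cbz
    t_coma[k, 0] = cax
    t_coma[k, 1] = cay
    t_coma[k, 2] = caz
    t_npoly[k] = na
    t_tipx[k] = tipx / ntip if ntip > 0 else np.nan
    gxx = 0.0
    gyy = 0.0
    gzz = 0.0
    gxy = 0.0
    gxz = 0.0
    gyz = 0.0
    for i in range(n):
        if species[i] != 0:
            dx = pos[i, 0] - cbx
            dy = pos[i, 1] - cby
            dz = pos[i, 2] - cbz
            gxx += dx * dx
            gyy += dy * dy
            gzz += dz * dz
            gxy += dx * dy
            gxz += dx * dz
            gyz += dy * dz
    if nb > 0:
        gxx /= nb
        gyy /= nb
        gzz /= nb
        gxy /= nb
        gxz /= nb
        gyz /= nb
    t_gyr[k, 0] = gxx
    t_gyr[k, 1] = gyy
    t_gyr[k, 2] = gzz
    t_gyr[k, 3] = gxy
    t_gyr[k, 4] = gxz
    t_gyr[k, 5] = gyz
    m = 0
    mall = 0
    for i in range(n):
        if species[i] == 1:
            if maxb[i] >= boundcut:
                mall += 1
            if maxb_bun[i] >= boundcut:
                scratch[m] = pos[i, 0]
                m += 1
    t_nbound[k] = mall
    t_nboundb[k] = m
    if m > 0:
        sub = np.sort(scratch[:m])
        idx = int(np.ceil(0.9 * m)) - 1
        if idx < 0:
            idx = 0
        t_q90[k] = sub[idx]
    else:
        t_q90[k] = np.nan
    best = np.inf
    bestb = np.inf
    for i in range(n):
        if species[i] == 0 and polymerized[i]:
            dx = pos[i, 0] - cbx
            dy = pos[i, 1] - cby
            dz = pos[i, 2] - cbz
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < best:
                best = d2
            if in_bundle[i] and d2 < bestb:
                bestb = d2
    t_mind[k] = np.sqrt(best) if best < np.inf else np.inf
    t_mindb[k] = np.sqrt(bestb) if bestb < np.inf else np.inf


@njit(cache=True)
def run_chunk(pos, pol, species, nucleotide, alpha, anchored, polymerized,
              active, has_pol,
              bonds, xlinks, angles, angle_k, aligns, align_c0,
              hpairs, hk, hc0, bind_elig, is_tip, in_bundle, ext_ids,
              pf, oriented, sever_mode,
              pair_i, pair_j, bind_i, bind_j, ref_pos,
              forces, pgrad, maxb, maxb_bun, scratch, noise, noise_rot,
              mob, std_t,
              rot_stride, n_steps, step_offset, sample_stride, traj_stride,
              t_times, t_comb, t_coma, t_gyr, t_nbound, t_nboundb, t_tipx,
              t_q90, t_mind, t_mindb, t_npoly,
              hyd_steps, hyd_ids, frames, frame_steps, counters):
    """Advance up to ``n_steps`` steps; return early on a topology event.

    ``noise`` (>= n_steps, n, 3) and ``noise_rot`` are standard normals
    supplied by the caller.  Polarization vectors are rotated every
    ``rot_stride``-th global step with a correspondingly larger rotational
    time step (their relaxation times are far longer than a few dt, and the
    rotational diffusion coefficient is preserved exactly).
    Returns ``(code, steps_done, ev_id, ev_kind)``.
    """
    n = pos.shape[0]
    dt = pf[PF_DT]
    kT = pf[PF_KT]
    g0 = pf[PF_G0]
    grot = pf[PF_GROT]
    cut_ev = pf[PF_A] + pf[PF_SKIN]
    cut_bind = pf[PF_RANGE_B] + pf[PF_SKIN]
    half_skin2 = (0.5 * pf[PF_SKIN]) ** 2
    p_h = 1.0 - np.exp(-pf[PF_KH] * dt)
    p_d = 1.0 - np.exp(-pf[PF_KD] * dt)
    maxdisp = pf[PF_MAXDISP]
    dt_rot = dt * rot_stride
    sqrt_rot = np.sqrt(2.0 * kT * dt_rot / grot)
    rrow = 0
    counts = np.empty(2, np.int64)
    counts[0] = counters[CT_NPAIRS]
    counts[1] = counters[CT_NBINDPAIRS]

    for s in range(n_steps):
        gstep = step_offset + s
        # --- pair-list maintenance (displacement check every 4 steps) ----
        need = counters[CT_LIST_VALID] == 0
        if not need and (s & 3) == 0:
            for i in range(n):
                dx = pos[i, 0] - ref_pos[i, 0]
                dy = pos[i, 1] - ref_pos[i, 1]
                dz = pos[i, 2] - ref_pos[i, 2]
                if dx * dx + dy * dy + dz * dz > half_skin2:
                    need = True
                    break
        if need:
            for i in range(n):
                if np.isnan(pos[i, 0]) or np.isnan(pos[i, 1]) or np.isnan(pos[i, 2]):
                    return CODE_NAN, s, i, -1
            ok = _rebuild_pairs(pos, active, species, bind_elig, cut_ev,
                                cut_bind, pair_i, pair_j, bind_i, bind_j,
                                counts, ref_pos)
            if ok < 0:
                return CODE_OVERFLOW, s, -1, -1
            counters[CT_NPAIRS] = counts[0]
            counters[CT_NBINDPAIRS] = counts[1]
            counters[CT_LIST_VALID] = 1
            counters[CT_NREBUILD] += 1

        _eval_forces(pos, pol, bonds, xlinks, angles, angle_k, aligns,
                     align_c0, hpairs, hk, hc0, in_bundle, pf, oriented,
                     pair_i, pair_j, counts[0], bind_i, bind_j, counts[1],
                     forces, pgrad, maxb, maxb_bun)
        if pf[PF_CONF_R] > 0.0:
            _confinement(pos, active, pf, forces)

        # external force on the ParB polymer ends (x component)
        for q in range(ext_ids.shape[0]):
            forces[ext_ids[q], 0] += pf[PF_EXTFX]

        # --- chemistry ---------------------------------------------------
        ev_id = -1
        ev_kind = -1
        eps_th = pf[PF_EPSTH]
        if p_h > 0.0:
            for i in range(n):
                if species[i] == 0 and polymerized[i] and nucleotide[i] == 0 \
                        and maxb[i] >= eps_th:
                    if np.random.random() < p_h:
                        nucleotide[i] = 1
                        hcount = counters[CT_NHYD]
                        if hcount < hyd_steps.shape[0]:
                            hyd_steps[hcount] = gstep
                            hyd_ids[hcount] = i
                            counters[CT_NHYD] = hcount + 1
        if p_d > 0.0:
            for i in range(n):
                if species[i] == 0 and polymerized[i] and nucleotide[i] == 1 \
                        and not anchored[i]:
                    if is_tip[i]:
                        if np.random.random() < p_d:
                            ev_id = i
                            ev_kind = EV_DEPOLYMERIZATION
                            break
                    elif sever_mode == 1:
                        if np.random.random() < p_d:
                            ev_id = i
                            ev_kind = EV_SEVER
                            break

        # --- sampling ----------------------------------------------------
        if sample_stride > 0 and gstep % sample_stride == 0:
            k = counters[CT_NSAMP]
            if k < t_times.shape[0]:
                t_times[k] = gstep * dt
                _sample(pos, species, polymerized, active, is_tip, in_bundle,
                        maxb, maxb_bun, pf[PF_BOUNDCUT], scratch, k, t_comb,
                        t_coma, t_gyr, t_nbound, t_nboundb, t_tipx, t_q90,
                        t_mind, t_mindb, t_npoly)
                counters[CT_NSAMP] = k + 1
        if traj_stride > 0 and gstep % traj_stride == 0:
            k = counters[CT_NFRAME]
            if k < frame_steps.shape[0]:
                for i in range(n):
                    frames[k, i, 0] = pos[i, 0]
                    frames[k, i, 1] = pos[i, 1]
                    frames[k, i, 2] = pos[i, 2]
                frame_steps[k] = gstep
                counters[CT_NFRAME] = k + 1

        # --- integration --------------------------------------------------
        do_rot = (gstep % rot_stride) == 0
        for i in range(n):
            if not active[i] or anchored[i]:
                continue
            m_i = mob[i]
            std = std_t[i]
            ddx = forces[i, 0] * m_i
            ddy = forces[i, 1] * m_i
            ddz = forces[i, 2] * m_i
            if np.abs(ddx) > maxdisp or np.abs(ddy) > maxdisp or np.abs(ddz) > maxdisp:
                counters[CT_NWARN] += 1
            pos[i, 0] += ddx + std * noise[s, i, 0]
            pos[i, 1] += ddy + std * noise[s, i, 1]
            pos[i, 2] += ddz + std * noise[s, i, 2]
            if do_rot and has_pol[i]:
                # torque T = -p x g; rotation vector w = T dt_rot/grot + noise
                gx = pgrad[i, 0]
                gy = pgrad[i, 1]
                gz = pgrad[i, 2]
                px = pol[i, 0]
                py = pol[i, 1]
                pz = pol[i, 2]
                tx = -(py * gz - pz * gy)
                ty = -(pz * gx - px * gz)
                tz = -(px * gy - py * gx)
                wx = tx * dt_rot / grot + sqrt_rot * noise_rot[rrow, i, 0]
                wy = ty * dt_rot / grot + sqrt_rot * noise_rot[rrow, i, 1]
                wz = tz * dt_rot / grot + sqrt_rot * noise_rot[rrow, i, 2]
                nx = px + (wy * pz - wz * py)
                ny = py + (wz * px - wx * pz)
                nz = pz + (wx * py - wy * px)
                norm = np.sqrt(nx * nx + ny * ny + nz * nz)
                pol[i, 0] = nx / norm
                pol[i, 1] = ny / norm
                pol[i, 2] = nz / norm
        if do_rot:
            rrow += 1

        if ev_id >= 0:
            return CODE_EVENT, s + 1, ev_id, ev_kind

    return CODE_DONE, n_steps, -1, -1


# ---------------------------------------------------------------------------
# one-shot force evaluation (fast path of forcefield.total_forces)
# ---------------------------------------------------------------------------

def evaluate_forces(state, ff, use_neighbor_list: bool = True, skin: float = 1.0):
    """Forces, torques and binding-energy table via the compiled kernel.

    Returns ``(energy, forces, torques, bind_table)`` matching
    :func:`parabd.forcefield.total_forces_reference`.
    """
    from .forcefield import BindingForm

    n = state.n
    if np.isnan(state.pos).any():
        bad = int(np.argwhere(np.isnan(state.pos))[0][0])
        raise FloatingPointError(f"NaN coordinate on subunit {bad}: integration blow-up")
    pf = np.zeros(PF_N)
    pf[PF_A] = ff.subunit_diameter_a
    pf[PF_K_EV] = ff.k_ev
    pf[PF_K_BOND] = ff.k_bond
    pf[PF_K_XL] = ff.k_crosslink
    pf[PF_D0] = ff.d0
    pf[PF_K_ALIGN] = ff.k_align
    pf[PF_EPS_B] = ff.eps_b
    pf[PF_R_B] = ff.r_b
    pf[PF_RANGE_B] = ff.range_b
    pf[PF_KAP1], pf[PF_KAP2], pf[PF_KAP3] = ff.ang_widths
    pf[PF_SKIN] = skin if use_neighbor_list else 0.0
    oriented = 1 if ff.binding_form is BindingForm.ORIENTED else 0

    cap = max(64, n * (n - 1) // 2)
    pair_i = np.empty(cap, np.int32)
    pair_j = np.empty(cap, np.int32)
    bind_i = np.empty(cap, np.int32)
    bind_j = np.empty(cap, np.int32)
    counts = np.empty(2, np.int64)
    ref_pos = np.empty_like(state.pos)
    _rebuild_pairs(state.pos, state.active, state.species, state.bind_eligible,
                   ff.subunit_diameter_a + pf[PF_SKIN],
                   ff.range_b + pf[PF_SKIN],
                   pair_i, pair_j, bind_i, bind_j, counts, ref_pos)
    forces = np.zeros((n, 3))
    pgrad = np.zeros((n, 3))
    maxb = np.zeros(n)
    maxb_bun = np.zeros(n)
    energy = _eval_forces(
        state.pos, state.pol, state.bonds, state.crosslinks, state.angles,
        state.angle_k, state.align_pairs, state.align_c0, state.helix_pairs,
        state.helix_k, state.helix_c0, state.in_bundle, pf, oriented,
        pair_i, pair_j, counts[0], bind_i, bind_j, counts[1],
        forces, pgrad, maxb, maxb_bun)
    torques = -np.cross(state.pol, pgrad)
    torques[~state.has_pol] = 0.0

    bind_table = _bind_table(state, ff)
    return energy, forces, torques, bind_table


def _bind_table(state, ff):
    """Python-side binding-energy table (pairs are few; clarity over speed)."""
    from .forcefield import binding

    table = {}
    pos = state.pos
    parb = np.flatnonzero(state.species == 1)
    for i in np.flatnonzero(state.bind_eligible):
        d = np.linalg.norm(pos[parb] - pos[i], axis=1)
        for j, r in zip(parb[d < ff.range_b], d[d < ff.range_b]):
            res = binding(pos[i] - pos[j], state.pol[i], state.pol[j], ff)
            if res.energy != 0.0:
                table[(int(i), int(j))] = res.energy
    return table
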