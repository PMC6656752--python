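"""Numba force kernels: switched LJ, Ewald electrostatics, bonded terms.

Conventions: positions in nm, energies kcal/mol, forces kcal/mol/nm.
All pair interactions use the minimum-image convention in an orthorhombic
box.  The pairwise virial is accumulated on molecule-COM separations
(``dcm`` holds r_i - R_cm(mol_i)), which makes the rigid-water constraint
forces drop out of the pressure.
"""

import math

import numpy as np
from numba import njit

SQRT_PI = math.sqrt(math.pi)


@njit(cache=True, fastmath=True, inline="always")
def _erfc_and_deriv(x):
    """(erfc(x), d erfc/dx) from the Abramowitz-Stegun 7.1.26 rational
    approximation (|abs error| < 1.5e-7).

    The derivative is the exact analytic derivative OF THE APPROXIMATION, so
    real-space Coulomb forces are the exact negative gradient of the
    implemented energy (finite differences agree to machine precision) while
    the approximation error versus the true erfc stays below 1.5e-7.
    """
    e = math.exp(-x * x)
    c = 0.3275911
    t = 1.0 / (1.0 + c * x)
    a1 = 0.254829592
    a2 = -0.284496736
    a3 = 1.421413741
    a4 = -1.453152027
    a5 = 1.061405429
    poly = t * (a1 + t * (a2 + t * (a3 + t * (a4 + t * a5))))
    dpoly = a1 + t * (2.0 * a2 + t * (3.0 * a3 + t * (4.0 * a4 + t * 5.0 * a5)))
    # d/dx [poly(t(x)) e^{-x^2}],  dt/dx = -c t^2
    deriv = (-c * t * t * dpoly - 2.0 * x * poly) * e
    return poly * e, deriv


@njit(cache=True, fastmath=True)
def build_pairs(pos, box, rlist2, excl_ptr, excl_j):
    """All non-excluded pairs with minimum-image separation < sqrt(rlist2)."""
    n = pos.shape[0]
    cap = n * (n - 1) // 2
    pairs = np.empty((cap, 2), dtype=np.int32)
    m = 0
    for i in range(n):
        p = excl_ptr[i]
        pend = excl_ptr[i + 1]
        for j in range(i + 1, n):
            while p < pend and excl_j[p] < j:
                p += 1
            if p < pend and excl_j[p] == j:
                continue
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= box[0] * round(dx / box[0])
            dy -= box[1] * round(dy / box[1])
            dz -= box[2] * round(dz / box[2])
            if dx * dx + dy * dy + dz * dz < rlist2:
                pairs[m, 0] = i
                pairs[m, 1] = j
                m += 1
    return pairs[:m].copy()


@njit(cache=True, fastmath=True)
def pair_forces(pos, box, pairs, tind, eps_t, sig_t, q, dcm,
                rc, rs, alpha, kcoul, do_coul, forces):
    """Switched LJ + real-space Ewald over a pair list.

    Returns (e_lj, e_coul_real, w_mol): energies and the molecular pairwise
    virial sum_{ij} f_ij . (r_ij - d_i + d_j).  The C1 switching function
    S(r) multiplies the LJ energy between rs and rc.
    """
    rc2 = rc * rc
    rs2 = rs * rs
    inv_denom = 1.0 / (rc2 - rs2) ** 3
    e_lj = 0.0
    e_cr = 0.0
    w = 0.0
    for m in range(pairs.shape[0]):
        i = pairs[m, 0]
        j = pairs[m, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * round(dx / box[0])
        dy -= box[1] * round(dy / box[1])
        dz -= box[2] * round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        r = math.sqrt(r2)
        fr = 0.0  # scalar -dU/dr
        eps = eps_t[tind[i], tind[j]]
        if eps > 0.0:
            sig = sig_t[tind[i], tind[j]]
            sr2 = sig * sig / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            u = 4.0 * eps * (sr12 - sr6)
            dudr = -24.0 * eps * (2.0 * sr12 - sr6) / r
            if r2 > rs2:
                a = rc2 - r2
                s = a * a * (rc2 + 2.0 * r2 - 3.0 * rs2) * inv_denom
                dsdr = 12.0 * r * a * (rs2 - r2) * inv_denom
                e_lj += s * u
                fr += -(s * dudr + u * dsdr)
            else:
                e_lj += u
                fr += -dudr
        if do_coul:
            qq = q[i] * q[j]
            if qq != 0.0:
                x = alpha * r
                erfc_x, derfc_x = _erfc_and_deriv(x)
                pref = kcoul * qq
                e_cr += pref * erfc_x / r
                fr += pref * (erfc_x / r2 - alpha * derfc_x / r)
        if fr != 0.0:
            g = fr / r
            fx = g * dx
            fy = g * dy
            fz = g * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            # molecular virial: f_ij . (r_ij - d_i + d_j)
            w += (fx * (dx - dcm[i, 0] + dcm[j, 0])
                  + fy * (dy - dcm[i, 1] + dcm[j, 1])
                  + fz * (dz - dcm[i, 2] + dcm[j, 2]))
    return e_lj, e_cr, w


@njit(cache=True, fastmath=True)
def ewald_recip(pos, q, box, kint, alpha, kcoul, forces):
    """Reciprocal-space Ewald sum over the half k-space listed in ``kint``.

    Returns (energy, atomic virial trace, per-site forces added in place,
    sum_i f_i . r_i is NOT needed -- the caller converts the atomic virial to
    the molecular one by subtracting sum_i f_recip_i . d_i).
    Forces are also accumulated into ``frec`` which the caller passes as the
    same array used for d_i bookkeeping.
    """
    n = pos.shape[0]
    nk = kint.shape[0]
    volume = box[0] * box[1] * box[2]
    two_pi = 2.0 * math.pi
    nmax = 0
    for m in range(nk):
        for ax in range(3):
            a = abs(kint[m, ax])
            if a > nmax:
                nmax = a
    # per-axis phase tables e^{i 2 pi n x / L}, n = 0..nmax
    cx = np.empty((n, 3, nmax + 1))
    sx = np.empty((n, 3, nmax + 1))
    for i in range(n):
        for ax in range(3):
            cx[i, ax, 0] = 1.0
            sx[i, ax, 0] = 0.0
            ang = two_pi * pos[i, ax] / box[ax]
            c1 = math.cos(ang)
            s1 = math.sin(ang)
            for p in range(1, nmax + 1):
                cx[i, ax, p] = cx[i, ax, p - 1] * c1 - sx[i, ax, p - 1] * s1
                sx[i, ax, p] = sx[i, ax, p - 1] * c1 + cx[i, ax, p - 1] * s1
    eik_re = np.empty(n)
    eik_im = np.empty(n)
    energy = 0.0
    w_trace = 0.0
    inv4a2 = 1.0 / (4.0 * alpha * alpha)
    for m in range(nk):
        nx = kint[m, 0]
        ny = kint[m, 1]
        nz = kint[m, 2]
        kx = two_pi * nx / box[0]
        ky = two_pi * ny / box[1]
        kz = two_pi * nz / box[2]
        k2 = kx * kx + ky * ky + kz * kz
        # weight 2 for the half space
        a_k = 2.0 * (2.0 * math.pi * kcoul / volume) * math.exp(-k2 * inv4a2) / k2
        s_re = 0.0
        s_im = 0.0
        for i in range(n):
            axp = abs(nx)
            cre = cx[i, 0, axp]
            cim = sx[i, 0, axp] if nx >= 0 else -sx[i, 0, axp]
            ayp = abs(ny)
            cyre = cx[i, 1, ayp]
            cyim = sx[i, 1, ayp] if ny >= 0 else -sx[i, 1, ayp]
            tre = cre * cyre - cim * cyim
            tim = cre * cyim + cim * cyre
            azp = abs(nz)
            czre = cx[i, 2, azp]
            czim = sx[i, 2, azp] if nz >= 0 else -sx[i, 2, azp]
            re = tre * czre - tim * czim
            im = tre * czim + tim * czre
            eik_re[i] = re
            eik_im[i] = im
            s_re += q[i] * re
            s_im += q[i] * im
        s2 = s_re * s_re + s_im * s_im
        energy += a_k * s2
        w_trace += a_k * s2 * (1.0 - k2 * 2.0 * inv4a2)
        for i in range(n):
            # f_i = 2 a_k q_i k * Im(S^* e^{i k r_i})
            im_part = s_re * eik_im[i] - s_im * eik_re[i]
            c = 2.0 * a_k * q[i] * im_part
            forces[i, 0] += c * kx
            forces[i, 1] += c * ky
            forces[i, 2] += c * kz
    return energy, w_trace


@njit(cache=True, fastmath=True)
def excluded_coulomb(pos, excl_pairs, q, alpha, kcoul, forces):
    """Remove the reciprocal-space contribution of excluded intramolecular
    pairs: subtracts q_i q_j erf(alpha r)/r (energy and forces).  These forces
    are intramolecular, so they carry no molecular virial."""
    e = 0.0
    for m in range(excl_pairs.shape[0]):
        i = excl_pairs[m, 0]
        j = excl_pairs[m, 1]
        qq = q[i] * q[j]
        if qq == 0.0:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        r = math.sqrt(r2)
        x = alpha * r
        erfc_x, derfc_x = _erfc_and_deriv(x)
        erf_x = 1.0 - erfc_x
        pref = kcoul * qq
        e -= pref * erf_x / r
        # fr = -dU/dr with U = -pref erf(x)/r; d erf/dx = -d erfc/dx
        fr = pref * (-derfc_x * alpha / r - erf_x / r2)
        g = fr / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz
    return e


@njit(cache=True, fastmath=True)
def bond_forces(pos, idx, kb, b0, forces):
    """Harmonic bonds U = k (b - b0)^2 (no minimum image: molecules whole)."""
    e = 0.0
    for m in range(idx.shape[0]):
        i = idx[m, 0]
        j = idx[m, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        db = r - b0[m]
        e += kb[m] * db * db
        g = -2.0 * kb[m] * db / r
        forces[i, 0] += g * dx
        forces[i, 1] += g * dy
        forces[i, 2] += g * dz
        forces[j, 0] -= g * dx
        forces[j, 1] -= g * dy
        forces[j, 2] -= g * dz
    return e


@njit(cache=True, fastmath=True)
def angle_forces(pos, idx, kt, t0, forces):
    """Harmonic angles U = k (theta - theta0)^2."""
    e = 0.0
    for m in range(idx.shape[0]):
        i = idx[m, 0]
        j = idx[m, 1]
        k = idx[m, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        ra = math.sqrt(ax * ax + ay * ay + az * az)
        rb = math.sqrt(bx * bx + by * by + bz * bz)
        cosv = (ax * bx + ay * by + az * bz) / (ra * rb)
        if cosv > 1.0:
            cosv = 1.0
        elif cosv < -1.0:
            cosv = -1.0
        th = math.acos(cosv)
        dth = th - t0[m]
        e += kt[m] * dth * dth
        sinv = math.sqrt(1.0 - cosv * cosv)
        if sinv < 1e-8:
            sinv = 1e-8
        dedth = 2.0 * kt[m] * dth
        coef = -dedth / sinv
        # dcos/dr_i = (b/(ra rb) - cos * a/ra^2), etc.
        fia = coef * (bx / (ra * rb) - cosv * ax / (ra * ra))
        fib = coef * (by / (ra * rb) - cosv * ay / (ra * ra))
        fic = coef * (bz / (ra * rb) - cosv * az / (ra * ra))
        fka = coef * (ax / (ra * rb) - cosv * bx / (rb * rb))
        fkb = coef * (ay / (ra * rb) - cosv * by / (rb * rb))
        fkc = coef * (az / (ra * rb) - cosv * bz / (rb * rb))
        forces[i, 0] -= fia
        forces[i, 1] -= fib
        forces[i, 2] -= fic
        forces[k, 0] -= fka
        forces[k, 1] -= fkb
        forces[k, 2] -= fkc
        forces[j, 0] += fia + fka
        forces[j, 1] += fib + fkb
        forces[j, 2] += fic + fkc
    return e


@njit(cache=True, fastmath=True)
def dihedral_forces(pos, idx, kp, mult, delta, forces):
    """Cosine dihedrals U = k (1 + cos(n phi - delta)), standard torsion forces."""
    e = 0.0
    for m in range(idx.shape[0]):
        i = idx[m, 0]
        j = idx[m, 1]
        k = idx[m, 2]
        l = idx[m, 3]
        # bond vectors
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        b3x = pos[l, 0] - pos[k, 0]
        b3y = pos[l, 1] - pos[k, 1]
        b3z = pos[l, 2] - pos[k, 2]
        # normals
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue
        b2n = math.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        cosphi = (n1x * n2x + n1y * n2y + n1z * n2z) / math.sqrt(n1sq * n2sq)
        if cosphi > 1.0:
            cosphi = 1.0
        elif cosphi < -1.0:
            cosphi = -1.0
        sinphi = (n1x * b3x + n1y * b3y + n1z * b3z) * b2n / math.sqrt(n1sq * n2sq)
        phi = math.atan2(sinphi, cosphi)
        n = mult[m]
        e += kp[m] * (1.0 + math.cos(n * phi - delta[m]))
        dedphi = -kp[m] * n * math.sin(n * phi - delta[m])
        # forces (standard formulation, e.g. Allen & Tildesley)
        fix = -dedphi * b2n / n1sq * n1x
        fiy = -dedphi * b2n / n1sq * n1y
        fiz = -dedphi * b2n / n1sq * n1z
        flx = dedphi * b2n / n2sq * n2x
        fly = dedphi * b2n / n2sq * n2y
        flz = dedphi * b2n / n2sq * n2z
        dot12 = b1x * b2x + b1y * b2y + b1z * b2z
        dot32 = b3x * b2x + b3y * b2y + b3z * b2z
        sx = (dot12 / (b2n * b2n)) * fix - (dot32 / (b2n * b2n)) * flx
        sy = (dot12 / (b2n * b2n)) * fiy - (dot32 / (b2n * b2n)) * fly
        sz = (dot12 / (b2n * b2n)) * fiz - (dot32 / (b2n * b2n)) * flz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[j, 0] += -fix + sx
        forces[j, 1] += -fiy + sy
        forces[j, 2] += -fiz + sz
        forces[k, 0] += -flx - sx
        forces[k, 1] += -fly - sy
        forces[k, 2] += -flz - sz
        forces[l, 0] += flx
        forces[l, 1] += fly
        forces[l, 2] += flz
    return e


@njit(cache=True, fastmath=True)
def max_displacement2(pos, ref, box):
    """Largest squared displacement since the last neighbour-list build."""
    n = pos.shape[0]
    worst = 0.0
    for i in range(n):
        d2 = 0.0
        for ax in range(3):
            d = pos[i, ax] - ref[i, ax]
            d2 += d * d
        if d2 > worst:
            worst = d2
    return worst
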