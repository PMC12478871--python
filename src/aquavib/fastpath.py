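"""Optional numba acceleration of the per-step water-cluster evaluation.

The DMC hot loop needs, for every walker at every step, the potential and
(for guided runs) log psi_g, grad log psi_g and the kinetic part of the
guide's local energy.  The numpy implementations in :mod:`aquavib.pes` are
the reference; the fused kernels here compute the same quantities in a
single pass per walker — including, for guided runs, the whole
drift/Metropolis update — and are used automatically when numba imports.
Equivalence of the two paths is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _potential_kernel(x, bonds, bends, oo, coul, qprod,
                      k_oh, l_eq, k_a, th_eq, eps, sigma, rmin):
    nb = x.shape[0]
    v = np.zeros(nb)
    for b in range(nb):
        acc = 0.0
        for p in range(bonds.shape[0]):
            i, j = bonds[p, 0], bonds[p, 1]
            dx = x[b, i, 0] - x[b, j, 0]
            dy = x[b, i, 1] - x[b, j, 1]
            dz = x[b, i, 2] - x[b, j, 2]
            dl = np.sqrt(dx * dx + dy * dy + dz * dz) - l_eq
            acc += 0.5 * k_oh * dl * dl
        for t in range(bends.shape[0]):
            i, j, k = bends[t, 0], bends[t, 1], bends[t, 2]
            ux = x[b, i, 0] - x[b, j, 0]
            uy = x[b, i, 1] - x[b, j, 1]
            uz = x[b, i, 2] - x[b, j, 2]
            wx = x[b, k, 0] - x[b, j, 0]
            wy = x[b, k, 1] - x[b, j, 1]
            wz = x[b, k, 2] - x[b, j, 2]
            r1 = np.sqrt(ux * ux + uy * uy + uz * uz)
            r2 = np.sqrt(wx * wx + wy * wy + wz * wz)
            c = (ux * wx + uy * wy + uz * wz) / (r1 * r2)
            if c > 1.0:
                c = 1.0
            elif c < -1.0:
                c = -1.0
            dth = np.arccos(c) - th_eq
            acc += 0.5 * k_a * dth * dth
        for p in range(oo.shape[0]):
            i, j = oo[p, 0], oo[p, 1]
            dx = x[b, i, 0] - x[b, j, 0]
            dy = x[b, i, 1] - x[b, j, 1]
            dz = x[b, i, 2] - x[b, j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            sr6 = (sigma / r) ** 6
            acc += 4.0 * eps * (sr6 * sr6 - sr6)
        for p in range(coul.shape[0]):
            i, j = coul[p, 0], coul[p, 1]
            dx = x[b, i, 0] - x[b, j, 0]
            dy = x[b, i, 1] - x[b, j, 1]
            dz = x[b, i, 2] - x[b, j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < rmin:
                r = rmin
            acc += qprod[p] / r
        v[b] = acc
    return v


@njit(cache=True)
def _eval_walker(xb, grad_out, lap_buf, bonds, bends, oo, coul, qprod,
                 k_oh, l_eq, k_a, th_eq, eps, sigma, rmin,
                 a_l, a_th, inv2m, sin_floor):
    """One walker: fill grad_out with grad log psi_g; return (V, log_g, kin)."""
    na = xb.shape[0]
    for a in range(na):
        lap_buf[a] = 0.0
        grad_out[a, 0] = 0.0
        grad_out[a, 1] = 0.0
        grad_out[a, 2] = 0.0
    acc = 0.0
    s_val = 0.0
    for p in range(bonds.shape[0]):
        i, j = bonds[p, 0], bonds[p, 1]
        dx = xb[i, 0] - xb[j, 0]
        dy = xb[i, 1] - xb[j, 1]
        dz = xb[i, 2] - xb[j, 2]
        l = np.sqrt(dx * dx + dy * dy + dz * dz)
        dl = l - l_eq
        acc += 0.5 * k_oh * dl * dl
        s_val += 0.5 * a_l * dl * dl
        f = a_l * dl / l
        grad_out[i, 0] += f * dx
        grad_out[i, 1] += f * dy
        grad_out[i, 2] += f * dz
        grad_out[j, 0] -= f * dx
        grad_out[j, 1] -= f * dy
        grad_out[j, 2] -= f * dz
        lap = a_l * (1.0 + dl * 2.0 / l)
        lap_buf[i] += lap
        lap_buf[j] += lap
    for t in range(bends.shape[0]):
        i, j, k = bends[t, 0], bends[t, 1], bends[t, 2]
        ux = xb[i, 0] - xb[j, 0]
        uy = xb[i, 1] - xb[j, 1]
        uz = xb[i, 2] - xb[j, 2]
        wx = xb[k, 0] - xb[j, 0]
        wy = xb[k, 1] - xb[j, 1]
        wz = xb[k, 2] - xb[j, 2]
        r1 = np.sqrt(ux * ux + uy * uy + uz * uz)
        r2 = np.sqrt(wx * wx + wy * wy + wz * wz)
        ux /= r1
        uy /= r1
        uz /= r1
        wx /= r2
        wy /= r2
        wz /= r2
        c = ux * wx + uy * wy + uz * wz
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        s2 = 1.0 - c * c
        if s2 < sin_floor * sin_floor:
            s2 = sin_floor * sin_floor
        s = np.sqrt(s2)
        dth = th - th_eq
        acc += 0.5 * k_a * dth * dth
        s_val += 0.5 * a_th * dth * dth
        gix = (c * ux - wx) / (r1 * s)
        giy = (c * uy - wy) / (r1 * s)
        giz = (c * uz - wz) / (r1 * s)
        gkx = (c * wx - ux) / (r2 * s)
        gky = (c * wy - uy) / (r2 * s)
        gkz = (c * wz - uz) / (r2 * s)
        gjx = -gix - gkx
        gjy = -giy - gky
        gjz = -giz - gkz
        f = a_th * dth
        grad_out[i, 0] += f * gix
        grad_out[i, 1] += f * giy
        grad_out[i, 2] += f * giz
        grad_out[j, 0] += f * gjx
        grad_out[j, 1] += f * gjy
        grad_out[j, 2] += f * gjz
        grad_out[k, 0] += f * gkx
        grad_out[k, 1] += f * gky
        grad_out[k, 2] += f * gkz
        gi2 = gix * gix + giy * giy + giz * giz
        gj2 = gjx * gjx + gjy * gjy + gjz * gjz
        gk2 = gkx * gkx + gky * gky + gkz * gkz
        cot = c / s
        lap_buf[i] += a_th * (gi2 + dth * cot / (r1 * r1))
        lap_buf[k] += a_th * (gk2 + dth * cot / (r2 * r2))
        lap_buf[j] += a_th * (gj2 + dth * (cot * (1.0 / (r1 * r1)
                                                 + 1.0 / (r2 * r2))
                                           - 2.0 / (r1 * r2 * s)))
    for p in range(oo.shape[0]):
        i, j = oo[p, 0], oo[p, 1]
        dx = xb[i, 0] - xb[j, 0]
        dy = xb[i, 1] - xb[j, 1]
        dz = xb[i, 2] - xb[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        sr6 = (sigma / r) ** 6
        acc += 4.0 * eps * (sr6 * sr6 - sr6)
    for p in range(coul.shape[0]):
        i, j = coul[p, 0], coul[p, 1]
        dx = xb[i, 0] - xb[j, 0]
        dy = xb[i, 1] - xb[j, 1]
        dz = xb[i, 2] - xb[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < rmin:
            r = rmin
        acc += qprod[p] / r
    k_acc = 0.0
    for a in range(na):
        g2 = grad_out[a, 0] ** 2 + grad_out[a, 1] ** 2 + grad_out[a, 2] ** 2
        k_acc += inv2m[a] * (lap_buf[a] - g2)
        grad_out[a, 0] = -grad_out[a, 0]
        grad_out[a, 1] = -grad_out[a, 1]
        grad_out[a, 2] = -grad_out[a, 2]
    return acc, -s_val, k_acc


@njit(cache=True)
def _guided_kernel(x, bonds, bends, oo, coul, qprod,
                   k_oh, l_eq, k_a, th_eq, eps, sigma, rmin,
                   a_l, a_th, inv2m, sin_floor):
    nb, na = x.shape[0], x.shape[1]
    v = np.zeros(nb)
    log_g = np.zeros(nb)
    kin = np.zeros(nb)
    grad = np.zeros((nb, na, 3))
    lap = np.zeros(na)
    for b in range(nb):
        v[b], log_g[b], kin[b] = _eval_walker(
            x[b], grad[b], lap, bonds, bends, oo, coul, qprod,
            k_oh, l_eq, k_a, th_eq, eps, sigma, rmin,
            a_l, a_th, inv2m, sin_floor)
    return v, log_g, grad, kin


@njit(cache=True)
def _guided_step_kernel(x, v, log_g, grad, kin, noise, log_u,
                        var_dof, sqrt_var_dof,
                        bonds, bends, oo, coul, qprod,
                        k_oh, l_eq, k_a, th_eq, eps, sigma, rmin,
                        a_l, a_th, inv2m, sin_floor):
    """One full drift-Metropolis step, in place.

    ``x`` (nb, na, 3) and the cached state arrays are updated for accepted
    walkers; returns the number of accepted moves.  ``var_dof`` is
    2 D dtau per atom; noise and log-uniforms are supplied by the caller's
    generator so the stream is reproducible.
    """
    nb, na = x.shape[0], x.shape[1]
    prop = np.empty((na, 3))
    gbuf = np.empty((na, 3))
    lap = np.empty(na)
    n_acc = 0
    for b in range(nb):
        fwd = 0.0
        for a in range(na):
            for d in range(3):
                nz = noise[b, a, d]
                prop[a, d] = (x[b, a, d] + var_dof[a] * grad[b, a, d]
                              + sqrt_var_dof[a] * nz)
                fwd += 0.5 * nz * nz
        v1, l1, k1 = _eval_walker(
            prop, gbuf, lap, bonds, bends, oo, coul, qprod,
            k_oh, l_eq, k_a, th_eq, eps, sigma, rmin,
            a_l, a_th, inv2m, sin_floor)
        bwd = 0.0
        for a in range(na):
            inv2v = 0.5 / var_dof[a]
            for d in range(3):
                diff = x[b, a, d] - prop[a, d] - var_dof[a] * gbuf[a, d]
                bwd += diff * diff * inv2v
        if log_u[b] < 2.0 * (l1 - log_g[b]) - bwd + fwd:
            n_acc += 1
            v[b] = v1
            log_g[b] = l1
            kin[b] = k1
            for a in range(na):
                for d in range(3):
                    x[b, a, d] = prop[a, d]
                    grad[b, a, d] = gbuf[a, d]
    return n_acc
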