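"""Numba kernels for force assembly and damped dynamic relaxation.

Single-threaded and free of fastmath reassociation so that runs with the
same seed are bit-reproducible on a given platform.

The volumetric strain-energy term is evaluated at a cluster-averaged
dilatation: ``cluster`` maps each tet to an averaging cluster and the
pressure is K (Jbar - 1) with Jbar the reference-volume-weighted mean of
J over the cluster.  With one tet per cluster this reduces exactly to the
pointwise K (J - 1) form; with the six tets of a lattice hex per cluster
it is the standard mean-dilatation treatment that avoids volumetric
locking of linear tetrahedra near incompressibility.
"""

from __future__ import annotations

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_INVERTED = 1
STATUS_NAN = 2


@njit(cache=True, fastmath=False, inline="always")
def _deformation(x, tets, invGA, e):
    """F of tet e at positions x (flattened 3x3 components + edges)."""
    i0 = tets[e, 0]
    i1 = tets[e, 1]
    i2 = tets[e, 2]
    i3 = tets[e, 3]
    e1x = x[i1, 0] - x[i0, 0]
    e1y = x[i1, 1] - x[i0, 1]
    e1z = x[i1, 2] - x[i0, 2]
    e2x = x[i2, 0] - x[i0, 0]
    e2y = x[i2, 1] - x[i0, 1]
    e2z = x[i2, 2] - x[i0, 2]
    e3x = x[i3, 0] - x[i0, 0]
    e3y = x[i3, 1] - x[i0, 1]
    e3z = x[i3, 2] - x[i0, 2]
    D = invGA[e]
    F00 = e1x * D[0, 0] + e2x * D[1, 0] + e3x * D[2, 0]
    F01 = e1x * D[0, 1] + e2x * D[1, 1] + e3x * D[2, 1]
    F02 = e1x * D[0, 2] + e2x * D[1, 2] + e3x * D[2, 2]
    F10 = e1y * D[0, 0] + e2y * D[1, 0] + e3y * D[2, 0]
    F11 = e1y * D[0, 1] + e2y * D[1, 1] + e3y * D[2, 1]
    F12 = e1y * D[0, 2] + e2y * D[1, 2] + e3y * D[2, 2]
    F20 = e1z * D[0, 0] + e2z * D[1, 0] + e3z * D[2, 0]
    F21 = e1z * D[0, 1] + e2z * D[1, 1] + e3z * D[2, 1]
    F22 = e1z * D[0, 2] + e2z * D[1, 2] + e3z * D[2, 2]
    return (
        F00, F01, F02, F10, F11, F12, F20, F21, F22,
        e1x, e1y, e1z, e2x, e2y, e2z, e3x, e3y, e3z,
    )


@njit(cache=True, fastmath=False)
def assemble_forces(
    x, tets, invGA, volG, mu_el, K_el, cluster, jbar_num, jbar_den, f
):
    """Nodal forces from per-element Cauchy stress via face tractions.

    For each tetrahedron the elastic deformation gradient is
    F = A_def (G A_hat)^-1; the traction -sigma.n of each deformed face
    (n = outward normal scaled by area) is distributed equally to the
    three face vertices, which for a constant-stress element reduces to
    f_k = sigma . n_opp(k) / 3.

    Returns (total_energy, status, bad_tet).
    """
    n = x.shape[0]
    m = tets.shape[0]
    nc = jbar_num.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0
    for c in range(nc):
        jbar_num[c] = 0.0
        jbar_den[c] = 0.0
    # pass 1: cluster-averaged dilatation
    for e in range(m):
        (F00, F01, F02, F10, F11, F12, F20, F21, F22,
         _, _, _, _, _, _, _, _, _) = _deformation(x, tets, invGA, e)
        J = (
            F00 * (F11 * F22 - F12 * F21)
            - F01 * (F10 * F22 - F12 * F20)
            + F02 * (F10 * F21 - F11 * F20)
        )
        if not np.isfinite(J):
            return 0.0, STATUS_NAN, e
        if J <= 0.0:
            return 0.0, STATUS_INVERTED, e
        c = cluster[e]
        jbar_num[c] += J * volG[e]
        jbar_den[c] += volG[e]

    energy = 0.0
    # volumetric energy per cluster (K is uniform within a cluster)
    for e in range(m):
        c = cluster[e]
        if jbar_den[c] > 0.0:
            jb = jbar_num[c] / jbar_den[c]
            energy += 0.5 * K_el[e] * (jb - 1.0) * (jb - 1.0) * volG[e]

    # pass 2: stresses and face tractions
    for e in range(m):
        (F00, F01, F02, F10, F11, F12, F20, F21, F22,
         e1x, e1y, e1z, e2x, e2y, e2z, e3x, e3y, e3z) = _deformation(
            x, tets, invGA, e
        )
        J = (
            F00 * (F11 * F22 - F12 * F21)
            - F01 * (F10 * F22 - F12 * F20)
            + F02 * (F10 * F21 - F11 * F20)
        )
        B00 = F00 * F00 + F01 * F01 + F02 * F02
        B11 = F10 * F10 + F11 * F11 + F12 * F12
        B22 = F20 * F20 + F21 * F21 + F22 * F22
        B01 = F00 * F10 + F01 * F11 + F02 * F12
        B02 = F00 * F20 + F01 * F21 + F02 * F22
        B12 = F10 * F20 + F11 * F21 + F12 * F22
        trB = B00 + B11 + B22
        mu = mu_el[e]
        Jm23 = J ** (-2.0 / 3.0)
        energy += 0.5 * mu * (trB * Jm23 - 3.0) * volG[e]
        cc = cluster[e]
        jb = jbar_num[cc] / jbar_den[cc]
        # Cauchy stress: mu J^(-5/3) dev(B) + K (Jbar - 1) I
        coef = mu * Jm23 / J
        p = K_el[e] * (jb - 1.0) - coef * trB / 3.0
        s00 = coef * B00 + p
        s11 = coef * B11 + p
        s22 = coef * B22 + p
        s01 = coef * B01
        s02 = coef * B02
        s12 = coef * B12
        # outward area normals of faces opposite each vertex
        n1x = 0.5 * (e3y * e2z - e3z * e2y)
        n1y = 0.5 * (e3z * e2x - e3x * e2z)
        n1z = 0.5 * (e3x * e2y - e3y * e2x)
        n2x = 0.5 * (e1y * e3z - e1z * e3y)
        n2y = 0.5 * (e1z * e3x - e1x * e3z)
        n2z = 0.5 * (e1x * e3y - e1y * e3x)
        n3x = 0.5 * (e2y * e1z - e2z * e1y)
        n3y = 0.5 * (e2z * e1x - e2x * e1z)
        n3z = 0.5 * (e2x * e1y - e2y * e1x)
        n0x = -(n1x + n2x + n3x)
        n0y = -(n1y + n2y + n3y)
        n0z = -(n1z + n2z + n3z)
        third = 1.0 / 3.0
        i0 = tets[e, 0]
        i1 = tets[e, 1]
        i2 = tets[e, 2]
        i3 = tets[e, 3]
        f[i0, 0] += third * (s00 * n0x + s01 * n0y + s02 * n0z)
        f[i0, 1] += third * (s01 * n0x + s11 * n0y + s12 * n0z)
        f[i0, 2] += third * (s02 * n0x + s12 * n0y + s22 * n0z)
        f[i1, 0] += third * (s00 * n1x + s01 * n1y + s02 * n1z)
        f[i1, 1] += third * (s01 * n1x + s11 * n1y + s12 * n1z)
        f[i1, 2] += third * (s02 * n1x + s12 * n1y + s22 * n1z)
        f[i2, 0] += third * (s00 * n2x + s01 * n2y + s02 * n2z)
        f[i2, 1] += third * (s01 * n2x + s11 * n2y + s12 * n2z)
        f[i2, 2] += third * (s02 * n2x + s12 * n2y + s22 * n2z)
        f[i3, 0] += third * (s00 * n3x + s01 * n3y + s02 * n3z)
        f[i3, 1] += third * (s01 * n3x + s11 * n3y + s12 * n3z)
        f[i3, 2] += third * (s02 * n3x + s12 * n3y + s22 * n3z)
    return energy, STATUS_OK, -1


@njit(cache=True, fastmath=False)
def relax_chunk(
    x, v, f, tets, invGA, volG, mu_el, K_el, cluster, jbar_num, jbar_den,
    ctype, cdir, inv_m, dt, gamma_over_m, n_steps,
):
    """Run ``n_steps`` of damped second-order dynamics.

    v(t+dt) = v + ((f - gamma v)/m) dt ;  x(t+dt) = x + v(t+dt) dt

    ``ctype`` encodes nodal constraints: 0 free, 1 fixed, 2 move only
    along ``cdir`` (single-sheet crease), 3 zero motion along ``cdir``
    (crease-plane normal in multi-layer runs).  ``inv_m`` is the per-node
    inverse mass.

    Returns (energy, max_step_displacement, status, bad_tet).
    """
    n = x.shape[0]
    energy = 0.0
    max_disp = 0.0
    status = STATUS_OK
    bad = -1
    for step in range(n_steps):
        energy, status, bad = assemble_forces(
            x, tets, invGA, volG, mu_el, K_el, cluster, jbar_num, jbar_den, f
        )
        if status != STATUS_OK:
            return energy, max_disp, status, bad
        max_disp = 0.0
        decay = 1.0 - gamma_over_m * dt
        for i in range(n):
            ct = ctype[i]
            if ct == 1:
                v[i, 0] = 0.0
                v[i, 1] = 0.0
                v[i, 2] = 0.0
                continue
            im = inv_m[i]
            vx = v[i, 0] * decay + f[i, 0] * im * dt
            vy = v[i, 1] * decay + f[i, 1] * im * dt
            vz = v[i, 2] * decay + f[i, 2] * im * dt
            if ct == 2:
                proj = vx * cdir[0] + vy * cdir[1] + vz * cdir[2]
                vx = proj * cdir[0]
                vy = proj * cdir[1]
                vz = proj * cdir[2]
            elif ct == 3:
                proj = vx * cdir[0] + vy * cdir[1] + vz * cdir[2]
                vx -= proj * cdir[0]
                vy -= proj * cdir[1]
                vz -= proj * cdir[2]
            v[i, 0] = vx
            v[i, 1] = vy
            v[i, 2] = vz
            x[i, 0] += vx * dt
            x[i, 1] += vy * dt
            x[i, 2] += vz * dt
            d = abs(vx)
            if abs(vy) > d:
                d = abs(vy)
            if abs(vz) > d:
                d = abs(vz)
            d *= dt
            if d > max_disp:
                max_disp = d
    return energy, max_disp, status, bad
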