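"""Numba kernels for the axisymmetric explicit solver.

Element technology: 4-node axisymmetric quadrilateral with one-point
(reduced) integration and Flanagan-Belytschko stiffness hourglass control,
mirroring the behaviour of reduced-integration brick elements commonly used
for this problem.  The constitutive update splits the response into an
elastic volumetric part and a deviatoric part carrying a three-branch Prony
shear relaxation evaluated with the exact exponential recurrence for a
piecewise-linear strain history.  Stress and strain tensors co-rotate with
the element spin (Jaumann increment), which keeps the small-strain update
objective under the moderate rotations seen during deep indentation.

All quantities are SI.  Tensor component order: (rr, zz, rz, theta-theta);
the rz component stores the *tensor* shear strain.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def element_pass(X, V, elems, dt, G0, K, ginf, a1, a2, a3, t1, t2, t3,
                 hg_alpha, e_dev, g1, g2, g3, eps_v, q_hg, F):
    """One strain/stress update + internal-force scatter over all elements.

    Returns 0 on success, ``1 + element_index`` when an element Jacobian is
    non-positive (inverted element).
    """
    ne = elems.shape[0]
    for e in range(ne):
        n0 = elems[e, 0]
        n1 = elems[e, 1]
        n2 = elems[e, 2]
        n3 = elems[e, 3]
        x0 = X[n0, 0]; y0 = X[n0, 1]
        x1 = X[n1, 0]; y1 = X[n1, 1]
        x2 = X[n2, 0]; y2 = X[n2, 1]
        x3 = X[n3, 0]; y3 = X[n3, 1]

        A = 0.5 * ((x2 - x0) * (y3 - y1) - (x3 - x1) * (y2 - y0))
        if A <= 0.0:
            return 1 + e
        rc = 0.25 * (x0 + x1 + x2 + x3)
        c = 0.5 / A
        bx0 = (y1 - y3) * c; bx1 = (y2 - y0) * c
        bx2 = (y3 - y1) * c; bx3 = (y0 - y2) * c
        by0 = (x3 - x1) * c; by1 = (x0 - x2) * c
        by2 = (x1 - x3) * c; by3 = (x2 - x0) * c

        vx0 = V[n0, 0]; vy0 = V[n0, 1]
        vx1 = V[n1, 0]; vy1 = V[n1, 1]
        vx2 = V[n2, 0]; vy2 = V[n2, 1]
        vx3 = V[n3, 0]; vy3 = V[n3, 1]

        dvxdx = bx0 * vx0 + bx1 * vx1 + bx2 * vx2 + bx3 * vx3
        dvydy = by0 * vy0 + by1 * vy1 + by2 * vy2 + by3 * vy3
        dvxdy = by0 * vx0 + by1 * vx1 + by2 * vx2 + by3 * vx3
        dvydx = bx0 * vy0 + bx1 * vy1 + bx2 * vy2 + bx3 * vy3
        vbar = 0.25 * (vx0 + vx1 + vx2 + vx3)

        # strain-rate components and spin at the element centre
        drr = dvxdx
        dzz = dvydy
        drz = 0.5 * (dvxdy + dvydx)
        dtt = vbar / rc
        dth = 0.5 * (dvxdy - dvydx) * dt   # Jaumann rotation increment

        # co-rotate stored tensors (theta-theta component is invariant)
        if dth != 0.0:
            trr = e_dev[e, 0]; tzz = e_dev[e, 1]; trz = e_dev[e, 2]
            e_dev[e, 0] = trr + 2.0 * dth * trz
            e_dev[e, 1] = tzz - 2.0 * dth * trz
            e_dev[e, 2] = trz + dth * (tzz - trr)
            trr = g1[e, 0]; tzz = g1[e, 1]; trz = g1[e, 2]
            g1[e, 0] = trr + 2.0 * dth * trz
            g1[e, 1] = tzz - 2.0 * dth * trz
            g1[e, 2] = trz + dth * (tzz - trr)
            trr = g2[e, 0]; tzz = g2[e, 1]; trz = g2[e, 2]
            g2[e, 0] = trr + 2.0 * dth * trz
            g2[e, 1] = tzz - 2.0 * dth * trz
            g2[e, 2] = trz + dth * (tzz - trr)
            trr = g3[e, 0]; tzz = g3[e, 1]; trz = g3[e, 2]
            g3[e, 0] = trr + 2.0 * dth * trz
            g3[e, 1] = tzz - 2.0 * dth * trz
            g3[e, 2] = trz + dth * (tzz - trr)

        dv = (drr + dzz + dtt) * dt
        eps_v[e] += dv
        third = dv / 3.0
        de0 = drr * dt - third
        de1 = dzz * dt - third
        de2 = drz * dt
        de3 = dtt * dt - third
        e_dev[e, 0] += de0
        e_dev[e, 1] += de1
        e_dev[e, 2] += de2
        e_dev[e, 3] += de3

        # Prony branches: g_i <- a_i * exp-integrator recurrence
        if a1 > 0.0:
            al = np.exp(-dt / t1)
            be = a1 * (t1 / dt) * (1.0 - al)
            g1[e, 0] = al * g1[e, 0] + be * de0
            g1[e, 1] = al * g1[e, 1] + be * de1
            g1[e, 2] = al * g1[e, 2] + be * de2
            g1[e, 3] = al * g1[e, 3] + be * de3
        if a2 > 0.0:
            al = np.exp(-dt / t2)
            be = a2 * (t2 / dt) * (1.0 - al)
            g2[e, 0] = al * g2[e, 0] + be * de0
            g2[e, 1] = al * g2[e, 1] + be * de1
            g2[e, 2] = al * g2[e, 2] + be * de2
            g2[e, 3] = al * g2[e, 3] + be * de3
        if a3 > 0.0:
            al = np.exp(-dt / t3)
            be = a3 * (t3 / dt) * (1.0 - al)
            g3[e, 0] = al * g3[e, 0] + be * de0
            g3[e, 1] = al * g3[e, 1] + be * de1
            g3[e, 2] = al * g3[e, 2] + be * de2
            g3[e, 3] = al * g3[e, 3] + be * de3

        two_g = 2.0 * G0
        srr = two_g * (ginf * e_dev[e, 0] + g1[e, 0] + g2[e, 0] + g3[e, 0])
        szz = two_g * (ginf * e_dev[e, 1] + g1[e, 1] + g2[e, 1] + g3[e, 1])
        srz = two_g * (ginf * e_dev[e, 2] + g1[e, 2] + g2[e, 2] + g3[e, 2])
        stt = two_g * (ginf * e_dev[e, 3] + g1[e, 3] + g2[e, 3] + g3[e, 3])
        pr = K * eps_v[e]
        sigrr = srr + pr
        sigzz = szz + pr
        sigtt = stt + pr
        sigrz = srz

        Ve = TWO_PI * rc * A
        hoop = TWO_PI * A * 0.25 * sigtt
        F[n0, 0] -= Ve * (bx0 * sigrr + by0 * sigrz) + hoop
        F[n0, 1] -= Ve * (by0 * sigzz + bx0 * sigrz)
        F[n1, 0] -= Ve * (bx1 * sigrr + by1 * sigrz) + hoop
        F[n1, 1] -= Ve * (by1 * sigzz + bx1 * sigrz)
        F[n2, 0] -= Ve * (bx2 * sigrr + by2 * sigrz) + hoop
        F[n2, 1] -= Ve * (by2 * sigzz + bx2 * sigrz)
        F[n3, 0] -= Ve * (bx3 * sigrr + by3 * sigrz) + hoop
        F[n3, 1] -= Ve * (by3 * sigzz + bx3 * sigrz)

        # hourglass control (stiffness form)
        hx = x0 - x1 + x2 - x3
        hy = y0 - y1 + y2 - y3
        G0c = 1.0 - hx * bx0 - hy * by0
        G1c = -1.0 - hx * bx1 - hy * by1
        G2c = 1.0 - hx * bx2 - hy * by2
        G3c = -1.0 - hx * bx3 - hy * by3
        qdx = G0c * vx0 + G1c * vx1 + G2c * vx2 + G3c * vx3
        qdy = G0c * vy0 + G1c * vy1 + G2c * vy2 + G3c * vy3
        q_hg[e, 0] += qdx * dt
        q_hg[e, 1] += qdy * dt
        bb = (bx0 * bx0 + bx1 * bx1 + bx2 * bx2 + bx3 * bx3
              + by0 * by0 + by1 * by1 + by2 * by2 + by3 * by3)
        khg = hg_alpha * G0 * Ve * bb
        fhx = khg * q_hg[e, 0]
        fhy = khg * q_hg[e, 1]
        F[n0, 0] -= fhx * G0c
        F[n0, 1] -= fhy * G0c
        F[n1, 0] -= fhx * G1c
        F[n1, 1] -= fhy * G1c
        F[n2, 0] -= fhx * G2c
        F[n2, 1] -= fhy * G2c
        F[n3, 0] -= fhx * G3c
        F[n3, 1] -= fhy * G3c
    return 0


@njit(cache=True)
def follower_pressure(X, edges, pval, F):
    """Constant follower pressure on surface edges (consistent nodal loads).

    Edges are ordered with x ascending along a surface traversed so that the
    rotated tangent ``(-dy, dx)`` points away from the solid interior; a
    positive ``pval`` pushes in that direction.
    """
    for k in range(edges.shape[0]):
        i = edges[k, 0]
        j = edges[k, 1]
        xa = X[i, 0]; ya = X[i, 1]
        xb = X[j, 0]; yb = X[j, 1]
        dx = xb - xa
        dy = yb - ya
        wa = (2.0 * xa + xb) / 6.0
        wb = (xa + 2.0 * xb) / 6.0
        F[i, 0] += pval * TWO_PI * wa * (-dy)
        F[i, 1] += pval * TWO_PI * wa * dx
        F[j, 0] += pval * TWO_PI * wb * (-dy)
        F[j, 1] += pval * TWO_PI * wb * dx


@njit(cache=True)
def axial_puff(X, edges, amp, xs_m, offset, F):
    """Fixed-axis air-puff traction on the anterior face.

    ``amp`` is the instantaneous peak pressure (Pa); the spatial Gaussian
    ``exp(-(x/xs)^2) + offset`` is evaluated at the current radial midpoint
    of each edge and the load acts along -y over the projected annulus.
    """
    for k in range(edges.shape[0]):
        i = edges[k, 0]
        j = edges[k, 1]
        xa = X[i, 0]
        xb = X[j, 0]
        mid = 0.5 * (xa + xb)
        shape = np.exp(-(mid / xs_m) ** 2) + offset
        p = amp * shape
        dr = xb - xa
        if dr < 0.0:
            dr = -dr
        wa = (2.0 * xa + xb) / 6.0
        wb = (xa + 2.0 * xb) / 6.0
        F[i, 1] -= p * TWO_PI * wa * dr
        F[j, 1] -= p * TWO_PI * wb * dr


@njit(cache=True)
def run_dynamic(X, V, minv, mass, elems, ant_edges, post_edges,
                dt, n_steps, out_every,
                G0, K, ginf, a1, a2, a3, t1, t2, t3,
                hg_alpha, mass_damp,
                iop_pa, pmax_pa, tpk, tsig, xs_m, soff,
                e_dev, g1, g2, g3, eps_v, q_hg,
                ant_nodes, frames_out, times_out):
    """Central-difference explicit integration of the air-puff transient.

    Frame 0 of the outputs is the initial (IOP-inflated) state.  Returns
    (status, n_frames): status 0 ok, 1 NaN/instability, 2 inverted element.
    """
    nn = X.shape[0]
    F = np.zeros((nn, 2))
    na = ant_nodes.shape[0]
    for q in range(na):
        frames_out[0, q, 0] = X[ant_nodes[q], 0]
        frames_out[0, q, 1] = X[ant_nodes[q], 1]
    times_out[0] = 0.0
    nfr = 1
    t = 0.0
    damp = 1.0 - mass_damp * dt
    for step in range(n_steps):
        for n in range(nn):
            F[n, 0] = 0.0
            F[n, 1] = 0.0
        status = element_pass(X, V, elems, dt, G0, K, ginf, a1, a2, a3,
                              t1, t2, t3, hg_alpha, e_dev, g1, g2, g3,
                              eps_v, q_hg, F)
        if status != 0:
            return 2, nfr
        follower_pressure(X, post_edges, iop_pa, F)
        ft = np.exp(-((t - tpk) / tsig) ** 2)
        axial_puff(X, ant_edges, pmax_pa * ft, xs_m, soff, F)
        for n in range(nn):
            V[n, 0] = (V[n, 0] + dt * F[n, 0] * minv[n, 0]) * damp
            V[n, 1] = (V[n, 1] + dt * F[n, 1] * minv[n, 1]) * damp
            X[n, 0] += dt * V[n, 0]
            X[n, 1] += dt * V[n, 1]
        t += dt
        if (step + 1) % out_every == 0 and nfr < frames_out.shape[0]:
            for q in range(na):
                frames_out[nfr, q, 0] = X[ant_nodes[q], 0]
                frames_out[nfr, q, 1] = X[ant_nodes[q], 1]
            times_out[nfr] = t
            nfr += 1
        if (step + 1) % 200 == 0:
            if not np.isfinite(X[ant_nodes[0], 1]):
                return 1, nfr
    return 0, nfr


@njit(cache=True)
def run_relax(X, V, minv, mass, elems, post_edges,
              dt, max_steps, tol, check_every, ramp_steps,
              G0, K, hg_alpha, iop_pa,
              e_dev, g1, g2, g3, eps_v, q_hg,
              free_mask, res_hist):
    """Dynamic relaxation to static equilibrium under posterior pressure.

    Kinetic damping: velocities are zeroed whenever the kinetic energy
    peaks.  The pressure ramps linearly over ``ramp_steps`` to avoid the
    load-shock overshoot that can transiently invert thin elements.  The
    material behaves elastically (pass the long-time shear modulus as
    ``G0``).  Returns (status, rel_residual, n_checks): status 0 converged,
    1 not converged, 2 inverted element.
    """
    nn = X.shape[0]
    F = np.zeros((nn, 2))
    Fe = np.zeros((nn, 2))
    ke_prev = 0.0
    n_checks = 0
    rel = 1.0e30
    best_rel = 1.0e30
    best_check = 0
    for step in range(max_steps):
        for n in range(nn):
            F[n, 0] = 0.0
            F[n, 1] = 0.0
            Fe[n, 0] = 0.0
            Fe[n, 1] = 0.0
        status = element_pass(X, V, elems, dt, G0, K, 1.0, 0.0, 0.0, 0.0,
                              1.0, 1.0, 1.0, hg_alpha, e_dev, g1, g2, g3,
                              eps_v, q_hg, F)
        if status != 0:
            return 2, rel, n_checks
        factor = 1.0
        if step < ramp_steps:
            factor = (step + 1.0) / ramp_steps
        follower_pressure(X, post_edges, iop_pa * factor, Fe)
        if step % check_every == 0 and step >= ramp_steps:
            res2 = 0.0
            load2 = 0.0
            for n in range(nn):
                for d in range(2):
                    if free_mask[n, d]:
                        ftot = F[n, d] + Fe[n, d]
                        res2 += ftot * ftot
                        load2 += Fe[n, d] * Fe[n, d]
            rel = np.sqrt(res2) / max(np.sqrt(load2), 1e-300)
            if n_checks < res_hist.shape[0]:
                res_hist[n_checks] = rel
            n_checks += 1
            if rel < tol:
                return 0, rel, n_checks
            if rel < 0.95 * best_rel:
                best_rel = rel
                best_check = n_checks
            elif n_checks - best_check > 60:
                return 1, rel, n_checks   # stalled: no sustained progress
        ke = 0.0
        for n in range(nn):
            vx = V[n, 0] + dt * (F[n, 0] + Fe[n, 0]) * minv[n, 0]
            vy = V[n, 1] + dt * (F[n, 1] + Fe[n, 1]) * minv[n, 1]
            V[n, 0] = vx
            V[n, 1] = vy
            ke += mass[n] * (vx * vx + vy * vy)
        if ke < ke_prev:
            for n in range(nn):
                V[n, 0] = 0.0
                V[n, 1] = 0.0
            ke = 0.0
        ke_prev = ke
        for n in range(nn):
            X[n, 0] += dt * V[n, 0]
            X[n, 1] += dt * V[n, 1]
    return 1, rel, n_checks
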