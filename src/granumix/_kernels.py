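"""Numba kernels for the soft-sphere DEM engine.

Hertz-Mindlin contact with a nonlinear dashpot calibrated to the coefficient
of restitution, a tangential Mindlin spring with per-contact history capped
by the Coulomb limit, and simplified-JKR cohesion F = gamma * pi * delta * R*.
Walls (floor, cylindrical shell, rotating flat blades) use the same law with
the rigid-wall effective moduli and per-particle per-wall tangential history.

The force routine is one monolithic jitted function: the contact law is
written out inline at each contact site because function-call boundaries
dominate the cost at these problem sizes.  All loops run in fixed order so
trajectories are bitwise deterministic.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: maximum tracked contacts per particle (monodisperse kissing number is 12)
MAXC = 16
_SQ56 = math.sqrt(5.0 / 6.0)


@njit(cache=True)
def compute_forces(pos, vel, omg, rad, mass,
                   ct_p_old, ct_x_old, ct_n_old,
                   ct_p_new, ct_x_new, ct_n_new,
                   wall_xi, force, torque,
                   estar, gstar, beta, mu, gamma_coh, gravity,
                   vessel_radius, blade_height, n_blades,
                   blade_angle, blade_omega, walls_on, dt):
    n = pos.shape[0]
    for i in range(n):
        force[i, 0] = 0.0
        force[i, 1] = 0.0
        force[i, 2] = -mass[i] * gravity
        torque[i, 0] = 0.0
        torque[i, 1] = 0.0
        torque[i, 2] = 0.0
        ct_n_new[i] = 0

    two_sq56_beta = 2.0 * _SQ56 * beta

    # ---- pairwise contacts via a uniform cell list (brute force for tiny n)
    rmax = 0.0
    for i in range(n):
        if rad[i] > rmax:
            rmax = rad[i]
    cell = 2.0 * rmax * 1.05
    ncx = 1
    ncy = 1
    ncz = 1
    xmin = 0.0
    ymin = 0.0
    zmin = 0.0
    use_cells = n > 64
    if use_cells:
        xmin = pos[0, 0]
        xmax = pos[0, 0]
        ymin = pos[0, 1]
        ymax = pos[0, 1]
        zmin = pos[0, 2]
        zmax = pos[0, 2]
        for i in range(n):
            if pos[i, 0] < xmin:
                xmin = pos[i, 0]
            if pos[i, 0] > xmax:
                xmax = pos[i, 0]
            if pos[i, 1] < ymin:
                ymin = pos[i, 1]
            if pos[i, 1] > ymax:
                ymax = pos[i, 1]
            if pos[i, 2] < zmin:
                zmin = pos[i, 2]
            if pos[i, 2] > zmax:
                zmax = pos[i, 2]
        ncx = int((xmax - xmin) / cell) + 1
        ncy = int((ymax - ymin) / cell) + 1
        ncz = int((zmax - zmin) / cell) + 1
        # cap the grid: coarser cells stay correct (cell >= 2 rmax), they
        # just admit more candidates, so widen rather than go O(n^2)
        cap = 8 * n + 1024
        while ncx * ncy * ncz > cap:
            cell *= 1.5
            ncx = int((xmax - xmin) / cell) + 1
            ncy = int((ymax - ymin) / cell) + 1
            ncz = int((zmax - zmin) / cell) + 1
    if use_cells:
        ncell = ncx * ncy * ncz
        head = np.full(ncell, -1, np.int64)
        nxt = np.empty(n, np.int64)
        cix = np.empty(n, np.int64)
        ciy = np.empty(n, np.int64)
        ciz = np.empty(n, np.int64)
        for i in range(n):
            cx = int((pos[i, 0] - xmin) / cell)
            cy = int((pos[i, 1] - ymin) / cell)
            cz = int((pos[i, 2] - zmin) / cell)
            cix[i] = cx
            ciy[i] = cy
            ciz[i] = cz
            c = cx + ncx * (cy + ncy * cz)
            nxt[i] = head[c]
            head[c] = i

    for i in range(n):
        # enumerate candidate partners j > i
        if use_cells:
            cx0 = cix[i]
            cy0 = ciy[i]
            cz0 = ciz[i]
        for ox in range(-1, 2):
            if use_cells:
                cx = cx0 + ox
                if cx < 0 or cx >= ncx:
                    continue
            elif ox != 0:
                continue
            for oy in range(-1, 2):
                if use_cells:
                    cy = cy0 + oy
                    if cy < 0 or cy >= ncy:
                        continue
                elif oy != 0:
                    continue
                for oz in range(-1, 2):
                    if use_cells:
                        cz = cz0 + oz
                        if cz < 0 or cz >= ncz:
                            continue
                        j = head[cx + ncx * (cy + ncy * cz)]
                    elif oz != 0:
                        continue
                    else:
                        j = i + 1  # brute force: walk the tail directly
                    while True:
                        if use_cells:
                            if j == -1:
                                break
                            jj = j
                            j = nxt[j]
                            if jj <= i:
                                continue
                        else:
                            if j >= n:
                                break
                            jj = j
                            j += 1
                        dx = pos[jj, 0] - pos[i, 0]
                        dy = pos[jj, 1] - pos[i, 1]
                        dz = pos[jj, 2] - pos[i, 2]
                        rsum = rad[i] + rad[jj]
                        d2 = dx * dx + dy * dy + dz * dz
                        if d2 >= rsum * rsum or d2 < 1e-24:
                            continue
                        d = math.sqrt(d2)
                        nx = dx / d
                        ny = dy / d
                        nz = dz / d
                        delta = rsum - d
                        ai = rad[i] - 0.5 * delta
                        aj = rad[jj] - 0.5 * delta
                        vrx = (vel[i, 0] - vel[jj, 0]
                               + ai * (omg[i, 1] * nz - omg[i, 2] * ny)
                               + aj * (omg[jj, 1] * nz - omg[jj, 2] * ny))
                        vry = (vel[i, 1] - vel[jj, 1]
                               + ai * (omg[i, 2] * nx - omg[i, 0] * nz)
                               + aj * (omg[jj, 2] * nx - omg[jj, 0] * nz))
                        vrz = (vel[i, 2] - vel[jj, 2]
                               + ai * (omg[i, 0] * ny - omg[i, 1] * nx)
                               + aj * (omg[jj, 0] * ny - omg[jj, 1] * nx))
                        # tangential history lives on the lower-index particle
                        xix = 0.0
                        xiy = 0.0
                        xiz = 0.0
                        for k in range(ct_n_old[i]):
                            if ct_p_old[i, k] == jj:
                                xix = ct_x_old[i, k, 0]
                                xiy = ct_x_old[i, k, 1]
                                xiz = ct_x_old[i, k, 2]
                                break
                        rstar = rad[i] * rad[jj] / rsum
                        mstar = (mass[i] * mass[jj]
                                 / (mass[i] + mass[jj]))
                        sq = math.sqrt(rstar * delta)
                        fn_el = (4.0 / 3.0) * estar * sq * delta
                        gam_n = -two_sq56_beta * math.sqrt(2.0 * estar * sq * mstar)
                        vn = vrx * nx + vry * ny + vrz * nz
                        f_coh = gamma_coh * math.pi * delta * rstar
                        fn_tot = fn_el + gam_n * vn - f_coh
                        fx = -fn_tot * nx
                        fy = -fn_tot * ny
                        fz = -fn_tot * nz
                        ftx = 0.0
                        fty = 0.0
                        ftz = 0.0
                        if mu > 0.0 and fn_el > 0.0:
                            vtx = vrx - vn * nx
                            vty = vry - vn * ny
                            vtz = vrz - vn * nz
                            xix += vtx * dt
                            xiy += vty * dt
                            xiz += vtz * dt
                            dot = xix * nx + xiy * ny + xiz * nz
                            xix -= dot * nx
                            xiy -= dot * ny
                            xiz -= dot * nz
                            k_t = 8.0 * gstar * sq
                            gam_t = -two_sq56_beta * math.sqrt(k_t * mstar)
                            ftx = -k_t * xix - gam_t * vtx
                            fty = -k_t * xiy - gam_t * vty
                            ftz = -k_t * xiz - gam_t * vtz
                            fmag = math.sqrt(ftx * ftx + fty * fty + ftz * ftz)
                            fmax = mu * fn_el
                            if fmag > fmax and fmag > 0.0:
                                scale = fmax / fmag
                                ftx *= scale
                                fty *= scale
                                ftz *= scale
                                # slip: spring stores exactly the capped force
                                xix = -(ftx + gam_t * vtx) / k_t
                                xiy = -(fty + gam_t * vty) / k_t
                                xiz = -(ftz + gam_t * vtz) / k_t
                            fx += ftx
                            fy += fty
                            fz += ftz
                        else:
                            xix = 0.0
                            xiy = 0.0
                            xiz = 0.0
                        force[i, 0] += fx
                        force[i, 1] += fy
                        force[i, 2] += fz
                        force[jj, 0] -= fx
                        force[jj, 1] -= fy
                        force[jj, 2] -= fz
                        # torque = lever x F_t; same sense n x F_t on both
                        tx = ny * ftz - nz * fty
                        ty = nz * ftx - nx * ftz
                        tz = nx * fty - ny * ftx
                        torque[i, 0] += ai * tx
                        torque[i, 1] += ai * ty
                        torque[i, 2] += ai * tz
                        torque[jj, 0] += aj * tx
                        torque[jj, 1] += aj * ty
                        torque[jj, 2] += aj * tz
                        k = ct_n_new[i]
                        if k < MAXC:
                            ct_p_new[i, k] = jj
                            ct_x_new[i, k, 0] = xix
                            ct_x_new[i, k, 1] = xiy
                            ct_x_new[i, k, 2] = xiz
                            ct_n_new[i] = k + 1

    # ---- walls: rigid-wall effective moduli (E_wall -> infinity)
    if walls_on:
        estar_w = 2.0 * estar
        gstar_w = 2.0 * gstar
        nwall = 2 + n_blades
        for i in range(n):
            for w in range(nwall):
                # contact test per wall entity; n points into the wall
                delta = -1.0
                nx = 0.0
                ny = 0.0
                nz = 0.0
                vwx = 0.0
                vwy = 0.0
                vwz = 0.0
                if w == 0:  # floor z = 0
                    delta = rad[i] - pos[i, 2]
                    nz = -1.0
                elif w == 1:  # cylindrical shell
                    rho = math.sqrt(pos[i, 0] * pos[i, 0]
                                    + pos[i, 1] * pos[i, 1])
                    if rho > 1e-12:
                        delta = rad[i] - (vessel_radius - rho)
                        nx = pos[i, 0] / rho
                        ny = pos[i, 1] / rho
                else:  # flat vertical blade rotating about the axis
                    b = w - 2
                    theta = blade_angle + 2.0 * math.pi * b / n_blades
                    ux = -math.sin(theta)
                    uy = math.cos(theta)
                    s = pos[i, 0] * ux + pos[i, 1] * uy
                    proj = (pos[i, 0] * math.cos(theta)
                            + pos[i, 1] * math.sin(theta))
                    if (abs(s) > 1e-12 and 0.0 <= proj <= vessel_radius
                            and pos[i, 2] <= blade_height):
                        delta = rad[i] - abs(s)
                        sgn = 1.0 if s > 0.0 else -1.0
                        nx = -sgn * ux
                        ny = -sgn * uy
                        vwx = -blade_omega * pos[i, 1]
                        vwy = blade_omega * pos[i, 0]
                if delta <= 0.0:
                    wall_xi[i, w, 0] = 0.0
                    wall_xi[i, w, 1] = 0.0
                    wall_xi[i, w, 2] = 0.0
                    continue
                a = rad[i] - 0.5 * delta
                vrx = vel[i, 0] - vwx + a * (omg[i, 1] * nz - omg[i, 2] * ny)
                vry = vel[i, 1] - vwy + a * (omg[i, 2] * nx - omg[i, 0] * nz)
                vrz = vel[i, 2] - vwz + a * (omg[i, 0] * ny - omg[i, 1] * nx)
                xix = wall_xi[i, w, 0]
                xiy = wall_xi[i, w, 1]
                xiz = wall_xi[i, w, 2]
                sq = math.sqrt(rad[i] * delta)
                fn_el = (4.0 / 3.0) * estar_w * sq * delta
                gam_n = -two_sq56_beta * math.sqrt(2.0 * estar_w * sq * mass[i])
                vn = vrx * nx + vry * ny + vrz * nz
                fn_tot = fn_el + gam_n * vn
                fx = -fn_tot * nx
                fy = -fn_tot * ny
                fz = -fn_tot * nz
                ftx = 0.0
                fty = 0.0
                ftz = 0.0
                if mu > 0.0 and fn_el > 0.0:
                    vtx = vrx - vn * nx
                    vty = vry - vn * ny
                    vtz = vrz - vn * nz
                    xix += vtx * dt
                    xiy += vty * dt
                    xiz += vtz * dt
                    dot = xix * nx + xiy * ny + xiz * nz
                    xix -= dot * nx
                    xiy -= dot * ny
                    xiz -= dot * nz
                    k_t = 8.0 * gstar_w * sq
                    gam_t = -two_sq56_beta * math.sqrt(k_t * mass[i])
                    ftx = -k_t * xix - gam_t * vtx
                    fty = -k_t * xiy - gam_t * vty
                    ftz = -k_t * xiz - gam_t * vtz
                    fmag = math.sqrt(ftx * ftx + fty * fty + ftz * ftz)
                    fmax = mu * fn_el
                    if fmag > fmax and fmag > 0.0:
                        scale = fmax / fmag
                        ftx *= scale
                        fty *= scale
                        ftz *= scale
                        xix = -(ftx + gam_t * vtx) / k_t
                        xiy = -(fty + gam_t * vty) / k_t
                        xiz = -(ftz + gam_t * vtz) / k_t
                    fx += ftx
                    fy += fty
                    fz += ftz
                else:
                    xix = 0.0
                    xiy = 0.0
                    xiz = 0.0
                force[i, 0] += fx
                force[i, 1] += fy
                force[i, 2] += fz
                tx = ny * ftz - nz * fty
                ty = nz * ftx - nx * ftz
                tz = nx * fty - ny * ftx
                torque[i, 0] += a * tx
                torque[i, 1] += a * ty
                torque[i, 2] += a * tz
                wall_xi[i, w, 0] = xix
                wall_xi[i, w, 1] = xiy
                wall_xi[i, w, 2] = xiz


@njit(cache=True)
def vv_kick_drift(pos, vel, omg, force, torque, mass, inertia, dt):
    n = pos.shape[0]
    for i in range(n):
        hm = 0.5 * dt / mass[i]
        hi = 0.5 * dt / inertia[i]
        for k in range(3):
            vel[i, k] += force[i, k] * hm
            pos[i, k] += vel[i, k] * dt
            omg[i, k] += torque[i, k] * hi


@njit(cache=True)
def vv_kick(vel, omg, force, torque, mass, inertia, dt):
    n = vel.shape[0]
    for i in range(n):
        hm = 0.5 * dt / mass[i]
        hi = 0.5 * dt / inertia[i]
        for k in range(3):
            vel[i, k] += force[i, k] * hm
            omg[i, k] += torque[i, k] * hi
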