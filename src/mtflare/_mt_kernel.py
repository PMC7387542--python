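"""Compiled Brownian-dynamics kernel for the 13-protofilament lattice.

Each PF n lives in the radial plane at azimuth 2*pi*n/13 that contains
the MT axis; a monomer carries plane coordinates {z axial (plus-end
positive), x radial deviation from the wall} and a rotation angle tau
(tau = 0 points along +z, positive tau tilts outward).  The wall
radius rho0 = r_tub * cot(pi/13) makes the lateral interaction sites
of resting neighbours coincide, so a perfect straight lattice has
every lateral bond at its well bottom.

Longitudinal terms act inside each plane exactly as in the single-PF
kernel (intra-dimer Hookean spring, breakable inter-dimer bond,
harmonic bending about theta0).  Lateral bonds connect monomers of
equal index k in adjacent PFs through the 3D distance between surface
sites placed at +-r_tub along the azimuthal tangent.

Monomers below mstart[n] are the frozen lattice boundary: their
coordinates never change, but bonds crossing the boundary act on the
mobile side.  Optional couplers: a Dam1 ring (one subunit per PF
plane, neighbour springs, linkers, shared axial load, ring centre
constrained to the axis) and a large spherical obstacle restricted to
axial motion.

Noise layout per step: 3 columns per mobile monomer in PF-major
order, then 2 per ring subunit (z, x), then 1 for the obstacle.
Status: 0 ok, >0 instability at step status-1.
"""

import math

import numpy as np
from numba import njit


def make_bond_tables(a_lat, r_lat, a_long, b_long, r_long,
                     h=0.005, d_max=24.0):
    """Tabulated bond energies/force factors for the stepping kernel.

    Lateral bonds split into an a-part (barrier, already scaled by
    a_lat) and a per-unit-b well part because the effective well depth
    varies per bond with nucleotide state; the longitudinal bond is a
    single table.  G tables hold E'(d)/d (smooth at 0); beyond d_max
    all entries vanish.  Linear interpolation error at h = 5 pm is
    far below thermal forces.
    """
    d = np.arange(int(d_max / h) + 2) * h
    xl = d / r_lat
    ebl = np.exp(-xl)
    ewl = np.exp(-xl * xl)
    lat_Ea = 2.0 * a_lat * xl * xl * ebl
    lat_Eb = -ewl
    lat_Ga = 2.0 * a_lat / r_lat ** 2 * ebl * (2.0 - xl)
    lat_Gb = 2.0 / r_lat ** 2 * ewl
    xg = d / r_long
    ebg = np.exp(-xg)
    ewg = np.exp(-xg * xg)
    lon_E = 2.0 * a_long * xg * xg * ebg - b_long * ewg
    lon_G = (2.0 * a_long / r_long ** 2 * ebg * (2.0 - xg)
             + 2.0 * b_long / r_long ** 2 * ewg)
    for t in (lat_Ea, lat_Eb, lat_Ga, lat_Gb, lon_E, lon_G):
        t[-1] = 0.0
    return (lat_Ea, lat_Eb, lat_Ga, lat_Gb, lon_E, lon_G,
            1.0 / h, d.size - 1)


@njit(cache=True, fastmath=True)
def mt_forces(z, x, tau, ct, st, K, mstart, npf, rho0, cosD, sinD,
              rt, k_intra, Bm, theta0, blat_m,
              lat_Ea, lat_Eb, lat_Ga, lat_Gb, lon_E, lon_G, inv_h, ntab,
              fz, fx, ftau):
    """Fill force arrays with dU/dq over the whole lattice; return U."""
    U = 0.0
    for n in range(npf):
        kn = K[n]
        for k in range(kn):
            fz[n, k] = 0.0
            fx[n, k] = 0.0
            ftau[n, k] = 0.0
    for n in range(npf):
        kn = K[n]
        k0 = max(1, mstart[n])
        for k in range(k0, kn):
            # longitudinal link (k-1, k): site_minus(k) - site_plus(k-1)
            dz = (z[n, k] - rt * ct[n, k]) - (z[n, k - 1] + rt * ct[n, k - 1])
            dx = (x[n, k] - rt * st[n, k]) - (x[n, k - 1] + rt * st[n, k - 1])
            d2 = dz * dz + dx * dx
            if (k - 1) % 2 == 0:
                g = k_intra
                U += 0.5 * k_intra * d2
            else:
                d = math.sqrt(d2)
                p = d * inv_h
                i = int(p)
                if i >= ntab:
                    g = 0.0
                else:
                    f = p - i
                    U += lon_E[i] + f * (lon_E[i + 1] - lon_E[i])
                    g = lon_G[i] + f * (lon_G[i + 1] - lon_G[i])
            gz = g * dz
            gx = g * dx
            fz[n, k] += gz
            fx[n, k] += gx
            fz[n, k - 1] -= gz
            fx[n, k - 1] -= gx
            # d(site)/dtau = -+ rt * u'(tau); u = (cos, sin), u' = (-sin, cos)
            ftau[n, k] += -rt * (-gz * st[n, k] + gx * ct[n, k])
            ftau[n, k - 1] += -rt * (-gz * st[n, k - 1] + gx * ct[n, k - 1])
            # bending hinge (k-1, k)
            Bh = 0.5 * (Bm[n, k - 1] + Bm[n, k])
            th = tau[n, k] - tau[n, k - 1] - theta0
            U += 0.5 * Bh * th * th
            t = Bh * th
            ftau[n, k] += t
            ftau[n, k - 1] -= t
    # lateral bonds between PF n and m = n+1 (wrap closes only a full ring)
    for n in range(npf):
        if n + 1 < npf:
            m = n + 1
        elif npf == 13:
            m = 0
        else:
            continue
        kmin = min(mstart[n], mstart[m])
        kmax = min(K[n], K[m])
        for k in range(kmin, kmax):
            r1 = rho0 + x[n, k]
            r2 = rho0 + x[m, k]
            ax = r1 - r2 * cosD - rt * sinD
            ay = rt - r2 * sinD + rt * cosD
            az = z[n, k] - z[m, k]
            d = math.sqrt(ax * ax + ay * ay + az * az)
            b = 0.5 * (blat_m[n, k] + blat_m[m, k])
            p = d * inv_h
            i = int(p)
            if i >= ntab:
                continue
            f = p - i
            U += (lat_Ea[i] + f * (lat_Ea[i + 1] - lat_Ea[i])
                  + b * (lat_Eb[i] + f * (lat_Eb[i + 1] - lat_Eb[i])))
            g = (lat_Ga[i] + f * (lat_Ga[i + 1] - lat_Ga[i])
                 + b * (lat_Gb[i] + f * (lat_Gb[i + 1] - lat_Gb[i])))
            fx[n, k] += g * ax
            fz[n, k] += g * az
            fx[m, k] += g * (-cosD * ax - sinD * ay)
            fz[m, k] -= g * az
    return U


@njit(cache=True, fastmath=True)
def _ring_forces(z, x, K, npf, rho0, rt, k_rep,
                 ring_z, ring_x, bound,
                 R_dam1, l0, l_max, k_linker, E_depth,
                 k_ring, ring_d0, cosD, f_sub,
                 frz, frx):
    """Dam1 ring terms: tubulin repulsion, linkers, neighbour springs,
    per-subunit axial load.  Handles linker rupture and rebinding
    (most minus-end-proximal reachable monomer).  Returns U."""
    U = 0.0
    contact = R_dam1 + rt
    for n in range(npf):
        frz[n] = -f_sub  # dU/dz of the load potential -f_sub*z
        frx[n] = 0.0
    for n in range(npf):
        rzn = ring_z[n]
        rxn = ring_x[n]
        # repulsion against PF n monomers
        for k in range(K[n]):
            dz = rzn - z[n, k]
            if dz > contact or dz < -contact:
                continue
            dx = rxn - (rho0 + x[n, k])
            d = math.sqrt(dz * dz + dx * dx)
            if d < contact:
                ov = contact - d
                U += k_rep * ov * ov
                if d > 1e-12:
                    g = -2.0 * k_rep * ov / d
                    frz[n] += g * dz
                    frx[n] += g * dx
        # linker
        kb = bound[n]
        if kb >= 0:
            if kb >= K[n]:
                bound[n] = -1
            else:
                dz = rzn - z[n, kb]
                dx = rxn - (rho0 + x[n, kb])
                d = math.sqrt(dz * dz + dx * dx)
                if d > l_max:
                    bound[n] = -1  # ruptured by stretch
                else:
                    if d >= l0:
                        U += -E_depth + 0.5 * k_linker * (l0 - d) ** 2
                        if d > 1e-12:
                            g = k_linker * (d - l0) / d
                            frz[n] += g * dz
                            frx[n] += g * dx
                    else:
                        U += -E_depth
        if bound[n] < 0:
            # rebind the most minus-end-proximal reachable monomer
            best = -1
            bestz = 1e30
            for k in range(K[n]):
                dz = rzn - z[n, k]
                if dz > l_max or dz < -l_max:
                    continue
                dx = rxn - (rho0 + x[n, k])
                if math.sqrt(dz * dz + dx * dx) <= l_max:
                    if z[n, k] < bestz:
                        bestz = z[n, k]
                        best = k
            bound[n] = best
    # neighbour springs around the ring
    for n in range(npf):
        m = n + 1 if n + 1 < npf else 0
        d2 = (ring_x[n] * ring_x[n] + ring_x[m] * ring_x[m]
              - 2.0 * ring_x[n] * ring_x[m] * cosD
              + (ring_z[n] - ring_z[m]) ** 2)
        d = math.sqrt(d2)
        U += 0.5 * k_ring * (d - ring_d0) ** 2
        if d > 1e-12:
            g = k_ring * (d - ring_d0) / d
            frx[n] += g * (ring_x[n] - ring_x[m] * cosD)
            frz[n] += g * (ring_z[n] - ring_z[m])
            frx[m] += g * (ring_x[m] - ring_x[n] * cosD)
            frz[m] += g * (ring_z[m] - ring_z[n])
    return U


@njit(cache=True, fastmath=True)
def _ring_tubulin_back(z, x, K, npf, rho0, rt, k_rep,
                       ring_z, ring_x, bound,
                       R_dam1, l0, l_max, k_linker,
                       fz, fx):
    """Reaction forces of ring contacts on the tubulin monomers."""
    contact = R_dam1 + rt
    for n in range(npf):
        rzn = ring_z[n]
        rxn = ring_x[n]
        for k in range(K[n]):
            dz = rzn - z[n, k]
            if dz > contact or dz < -contact:
                continue
            dx = rxn - (rho0 + x[n, k])
            d = math.sqrt(dz * dz + dx * dx)
            if d < contact and d > 1e-12:
                g = -2.0 * k_rep * (contact - d) / d
                fz[n, k] -= g * dz
                fx[n, k] -= g * dx
        kb = bound[n]
        if 0 <= kb < K[n]:
            dz = rzn - z[n, kb]
            dx = rxn - (rho0 + x[n, kb])
            d = math.sqrt(dz * dz + dx * dx)
            if l0 <= d <= l_max and d > 1e-12:
                g = k_linker * (d - l0) / d
                fz[n, kb] -= g * dz
                fx[n, kb] -= g * dx


@njit(cache=True, fastmath=True)
def _obstacle_forces(z, x, K, mstart, npf, rho0, rt, k_rep,
                     obs_z, R_obs, F_load, fz, fx):
    """Obstacle sphere (centre on the axis at obs_z + R_obs) against
    all monomers; returns (U, dU/d obs_z).  F_load opposes growth."""
    U = 0.0
    fobs = F_load  # potential +F*z_surface
    zc = obs_z[0] + R_obs
    contact = R_obs + rt
    for n in range(npf):
        for k in range(mstart[n], K[n]):
            if z[n, k] < obs_z[0] - 6.0:
                continue
            rho = rho0 + x[n, k]
            dz = zc - z[n, k]
            d = math.sqrt(rho * rho + dz * dz)
            if d < contact:
                ov = contact - d
                U += k_rep * ov * ov
                g = -2.0 * k_rep * ov / d
                fobs += g * dz
                fz[n, k] -= g * dz
                fx[n, k] += g * rho  # d(d)/dx = rho/d, monomer side
    return U, fobs


@njit(cache=True, fastmath=True)
def mt_bd_steps(z, x, tau, ct, st, K, mstart, npf, noise, step0,
                dt, gq, gt, amp_q, amp_t,
                rho0, cosD, sinD, rt, k_intra, Bm, theta0, blat_m,
                lat_Ea, lat_Eb, lat_Ga, lat_Gb, lon_E, lon_G, inv_h, ntab,
                use_ring, ring_z, ring_x, bound,
                R_dam1, l0, l_max, k_linker, E_depth, k_rep,
                k_ring, ring_d0, f_sub, g_ring, amp_ring,
                use_obs, obs_z, R_obs, F_obs, g_obs, amp_obs):
    """Advance the lattice by noise.shape[0] Euler-Maruyama steps."""
    nsteps = noise.shape[0]
    cap = z.shape[1]
    fz = np.empty((npf, cap))
    fx = np.empty((npf, cap))
    ftau = np.empty((npf, cap))
    frz = np.empty(npf)
    frx = np.empty(npf)
    cq = dt / gq
    ctq = dt / gt
    cr = dt / g_ring
    co = dt / g_obs
    nmob = 0
    for n in range(npf):
        nmob += K[n] - mstart[n]
    ring_col = 3 * nmob
    obs_col = ring_col + (2 * npf if use_ring else 0)
    for istep in range(nsteps):
        mt_forces(z, x, tau, ct, st, K, mstart, npf, rho0, cosD, sinD,
                  rt, k_intra, Bm, theta0, blat_m,
                  lat_Ea, lat_Eb, lat_Ga, lat_Gb, lon_E, lon_G, inv_h, ntab,
                  fz, fx, ftau)
        if use_ring:
            _ring_forces(z, x, K, npf, rho0, rt, k_rep,
                         ring_z, ring_x, bound,
                         R_dam1, l0, l_max, k_linker, E_depth,
                         k_ring, ring_d0, cosD, f_sub, frz, frx)
            _ring_tubulin_back(z, x, K, npf, rho0, rt, k_rep,
                               ring_z, ring_x, bound,
                               R_dam1, l0, l_max, k_linker, fz, fx)
        if use_obs:
            _, fobs = _obstacle_forces(z, x, K, mstart, npf, rho0, rt,
                                       k_rep, obs_z, R_obs, 0.0, fz, fx)
            fobs += F_obs
            obs_z[0] += -co * fobs + amp_obs * noise[istep, obs_col]
        col = 0
        for n in range(npf):
            for k in range(mstart[n], K[n]):
                dzs = -cq * fz[n, k] + amp_q * noise[istep, col]
                dxs = -cq * fx[n, k] + amp_q * noise[istep, col + 1]
                if abs(dzs) > 10.0 or abs(dxs) > 10.0 or dzs != dzs or dxs != dxs:
                    return step0 + istep + 1
                z[n, k] += dzs
                x[n, k] += dxs
                dta = -ctq * ftau[n, k] + amp_t * noise[istep, col + 2]
                tau[n, k] += dta
                cd = 1.0 - 0.5 * dta * dta
                sd = dta * (1.0 - dta * dta / 6.0)
                c0 = ct[n, k]
                ct[n, k] = c0 * cd - st[n, k] * sd
                st[n, k] = st[n, k] * cd + c0 * sd
                col += 3
        if use_ring:
            # Langevin update of subunits, then project out the radial
            # drift of the ring centre (it may move only axially)
            dmean = 0.0
            for n in range(npf):
                ring_z[n] += -cr * frz[n] + amp_ring * noise[istep, ring_col + 2 * n]
                dxs = -cr * frx[n] + amp_ring * noise[istep, ring_col + 2 * n + 1]
                ring_x[n] += dxs
                dmean += dxs
            dmean /= npf
            for n in range(npf):
                ring_x[n] -= dmean
        gstep = step0 + istep + 1
        if gstep % 1024 == 0:
            for n in range(npf):
                for k in range(mstart[n], K[n]):
                    ct[n, k] = math.cos(tau[n, k])
                    st[n, k] = math.sin(tau[n, k])
    return 0
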