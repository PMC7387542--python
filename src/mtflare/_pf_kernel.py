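"""Compiled Brownian-dynamics kernel for a single protofilament chain.

One chain of spherical monomers in a plane; each monomer carries a
position {x, y} (x lateral, y axial toward the plus-end) and a
rotation angle tau.  Longitudinal interaction sites sit on the poles
at +-r_tub along the monomer axis u(tau) = (sin tau, cos tau), so the
rest spacing is 2 r_tub.  Consecutive links alternate between the
unbreakable intra-dimer Hookean spring and (optionally) the breakable
inter-dimer bond; a harmonic-only mode reproduces the isolated-PF
model in which the chain never fragments.

The overdamped Langevin update is the Ermak-McCammon / Euler-Maruyama
scheme: q <- q - dt/gamma dU/dq + sqrt(2 kB T dt/gamma) N(0,1).
Gaussian noise is pre-generated in batches by the caller (one row per
step); the kernel consumes it in order, which keeps runs bit-exact
for a fixed seed regardless of chunking.

An optional "bead" models a Dam1 subunit constrained to move only
axially at a fixed lateral offset, pulled by a constant force and
repelled by the monomers; it is used for zero-temperature maximal
force measurements and for bead-loaded fluctuation runs.

Status codes returned by the steppers: 0 ok, >0 instability at step
(status-1), -1 bead escaped past the chain tip (relaxation only),
-2 relaxation failed to converge.
"""

import math

import numpy as np
from numba import njit

# hysteresis state machine constants
_STATE_STRAIGHT = 0
_STATE_CURVED = 1


@njit(cache=True, fastmath=True)
def _chain_forces(x, y, tau, ct, st, n, k_intra, B, theta0, rt,
                  breakable, a_long, b_long, w_long,
                  fx, fy, ftau):
    """Fill fx/fy/ftau with dU/dq for the chain terms. Returns U."""
    for i in range(n):
        fx[i] = 0.0
        fy[i] = 0.0
        ftau[i] = 0.0
    U = 0.0
    inv_w = 1.0 / w_long
    inv_w2 = inv_w * inv_w
    for i in range(1, n):
        # link between i-1 and i: site_minus(i) - site_plus(i-1)
        dx = (x[i] - rt * st[i]) - (x[i - 1] + rt * st[i - 1])
        dy = (y[i] - rt * ct[i]) - (y[i - 1] + rt * ct[i - 1])
        d2 = dx * dx + dy * dy
        intra = (i - 1) % 2 == 0
        if intra or not breakable:
            g = k_intra  # dE/dd / d for the harmonic spring
            U += 0.5 * k_intra * d2
        else:
            d = math.sqrt(d2)
            xw = d * inv_w
            eb = math.exp(-xw)
            ew = math.exp(-xw * xw)
            U += 2.0 * a_long * xw * xw * eb - b_long * ew
            # E'(d)/d, smooth at d = 0
            g = 2.0 * a_long * inv_w2 * eb * (2.0 - xw) + 2.0 * b_long * inv_w2 * ew
        gx = g * dx
        gy = g * dy
        fx[i] += gx
        fy[i] += gy
        fx[i - 1] -= gx
        fy[i - 1] -= gy
        # site offsets rotate with tau: d(site)/dtau = +-rt*u'(tau)
        # u' = (cos tau, -sin tau)
        ftau[i] += -rt * (gx * ct[i] - gy * st[i])
        ftau[i - 1] += -rt * (gx * ct[i - 1] - gy * st[i - 1])
        # bending at hinge i (skip hinge internal to the frozen dimer)
        if i >= 2:
            th = tau[i] - tau[i - 1] - theta0
            U += 0.5 * B * th * th
            t = B * th
            ftau[i] += t
            ftau[i - 1] -= t
    return U


@njit(cache=True, fastmath=True)
def _bead_forces(x, y, n, bead_x, bead_z, k_rep, contact, fx, fy):
    """Repulsion between the bead and all monomers.

    Adds monomer forces in place; returns (U, dU/dbz).
    """
    U = 0.0
    fbz = 0.0
    for i in range(n):
        dx = bead_x - x[i]
        dy = bead_z - y[i]
        d = math.sqrt(dx * dx + dy * dy)
        if d < contact:
            ov = contact - d
            U += k_rep * ov * ov
            dEdd = -2.0 * k_rep * ov
            if d > 1e-12:
                fbz += dEdd * dy / d
                fx[i] += dEdd * (-dx / d)
                fy[i] += dEdd * (-dy / d)
    return U, fbz


@njit(cache=True, fastmath=True)
def pf_bd_steps(x, y, tau, ct, st, nfix, noise, step0,
                dt, gq, gt, amp_q, amp_t,
                k_intra, B, theta0, rt,
                breakable, a_long, b_long, w_long,
                bead, bead_x, bead_state, F_ext, k_rep, R_bead, g_bead, amp_b,
                mon_hinge, th_curved, th_straight, hyst,
                rec_stride, rec_x, rec_y, rec_tau, rec_angle):
    """Advance the chain by noise.shape[0] steps.

    bead_state: length-1 array holding the bead axial position.
    hyst: int64 array [state, event_count].
    Recording: frame j stored when (step0+i) % rec_stride == 0 at slot
    (step0+i)//rec_stride; rec_angle gets the monitored hinge angle
    every step (pass a zero-length array to disable).
    """
    n = x.shape[0]
    nsteps = noise.shape[0]
    fx = np.empty(n)
    fy = np.empty(n)
    ftau = np.empty(n)
    cq = dt / gq
    ctq = dt / gt
    cb = dt / g_bead
    contact = R_bead + rt
    record_angles = rec_angle.shape[0] > 0
    for istep in range(nsteps):
        _chain_forces(x, y, tau, ct, st, n, k_intra, B, theta0, rt,
                      breakable, a_long, b_long, w_long, fx, fy, ftau)
        if bead:
            _, fbz = _bead_forces(x, y, n, bead_x, bead_state[0],
                                  k_rep, contact, fx, fy)
            fbz += -F_ext
            bead_state[0] += -cb * fbz + amp_b * noise[istep, 3 * (n - nfix)]
        for i in range(nfix, n):
            j = 3 * (i - nfix)
            dxs = -cq * fx[i] + amp_q * noise[istep, j]
            dys = -cq * fy[i] + amp_q * noise[istep, j + 1]
            if abs(dxs) > 10.0 or abs(dys) > 10.0 or dxs != dxs or dys != dys:
                return step0 + istep + 1
            x[i] += dxs
            y[i] += dys
            dta = -ctq * ftau[i] + amp_t * noise[istep, j + 2]
            tau[i] += dta
            # incremental rotation of (cos, sin); 3rd-order accurate
            cd = 1.0 - 0.5 * dta * dta
            sd = dta * (1.0 - dta * dta / 6.0)
            c0 = ct[i]
            ct[i] = c0 * cd - st[i] * sd
            st[i] = st[i] * cd + c0 * sd
        gstep = step0 + istep + 1
        if gstep % 1024 == 0:
            for i in range(nfix, n):
                ct[i] = math.cos(tau[i])
                st[i] = math.sin(tau[i])
        # monitored hinge: hysteresis counting of curved->straight passages
        ang = tau[mon_hinge] - tau[mon_hinge - 1]
        if record_angles:
            rec_angle[istep] = ang
        if hyst[0] == _STATE_CURVED:
            if ang <= th_straight:
                hyst[0] = _STATE_STRAIGHT
                hyst[1] += 1
        else:
            if ang > th_curved:
                hyst[0] = _STATE_CURVED
        if gstep % rec_stride == 0:
            f = gstep // rec_stride - 1
            if 0 <= f < rec_x.shape[0]:
                for i in range(n):
                    rec_x[f, i] = x[i]
                    rec_y[f, i] = y[i]
                    rec_tau[f, i] = tau[i]
    return 0


@njit(cache=True, fastmath=True)
def pf_relax(x, y, tau, ct, st, nfix,
             dt, gq, gt,
             k_intra, B, theta0, rt,
             breakable, a_long, b_long, w_long,
             bead, bead_x, bead_state, F_ext, k_rep, R_bead, g_bead,
             grad_tol, max_steps, escape_margin):
    """Zero-temperature relaxation (gradient descent via the T=0 update).

    Terminates when the largest gradient component drops below
    grad_tol, the bead escapes past the chain tip (+escape_margin), or
    max_steps is exhausted.  Returns (status, steps, max_grad).
    """
    n = x.shape[0]
    fx = np.empty(n)
    fy = np.empty(n)
    ftau = np.empty(n)
    cq = dt / gq
    ctq = dt / gt
    cb = dt / g_bead
    contact = R_bead + rt
    gmax = 0.0
    for istep in range(max_steps):
        _chain_forces(x, y, tau, ct, st, n, k_intra, B, theta0, rt,
                      breakable, a_long, b_long, w_long, fx, fy, ftau)
        fbz = 0.0
        if bead:
            _, fbz = _bead_forces(x, y, n, bead_x, bead_state[0],
                                  k_rep, contact, fx, fy)
            fbz += -F_ext
        gmax = abs(fbz)
        for i in range(nfix, n):
            if abs(fx[i]) > gmax:
                gmax = abs(fx[i])
            if abs(fy[i]) > gmax:
                gmax = abs(fy[i])
            if abs(ftau[i]) > gmax:
                gmax = abs(ftau[i])
        if gmax < grad_tol:
            return 0, istep, gmax
        if bead:
            bead_state[0] += -cb * fbz
            # escape once the bead is past every monomer that could
            # still block its axial path (within lateral reach)
            zblock = -1e30
            for i in range(n):
                dx = x[i] - bead_x
                if -contact - 0.5 < dx < contact + 0.5 and y[i] > zblock:
                    zblock = y[i]
            if bead_state[0] > zblock + escape_margin:
                return -1, istep, gmax
        for i in range(nfix, n):
            x[i] += -cq * fx[i]
            y[i] += -cq * fy[i]
            tau[i] += -ctq * ftau[i]
            ct[i] = math.cos(tau[i])
            st[i] = math.sin(tau[i])
    return -2, max_steps, gmax


@njit(cache=True, fastmath=True)
def chain_energy(x, y, tau, ct, st, k_intra, B, theta0, rt,
                 breakable, a_long, b_long, w_long):
    n = x.shape[0]
    fx = np.empty(n)
    fy = np.empty(n)
    ftau = np.empty(n)
    return _chain_forces(x, y, tau, ct, st, n, k_intra, B, theta0, rt,
                         breakable, a_long, b_long, w_long, fx, fy, ftau)
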