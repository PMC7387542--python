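"""Single-protofilament experiments.

Brownian fluctuations of an isolated, intrinsically curved PF held by
its bottom dimer; measurement of the frequency of thermally driven
straightening at the lowest free hinge; the zero-temperature maximal
force a curved PF can exert on an axially dragged Dam1-sized sphere;
and the dynamic persistence length extracted from the decay of
angular-deflection correlations along the chain,
<cos(delta(s))> = exp(-s / xi_d).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import constants
from ._pf_kernel import pf_bd_steps, pf_relax, chain_energy
from .energetics import MechanicalParams, RingParams

_NOISE_CHUNK = 32768


class IntegrationInstabilityError(RuntimeError):
    """A coordinate became non-finite or moved > 10 nm in one step."""

    def __init__(self, step: int):
        super().__init__(
            f"integration instability detected at step {step}; "
            "reduce dt or check parameters"
        )
        self.step = step


class RelaxationError(RuntimeError):
    """Zero-temperature relaxation failed to converge."""


@dataclass
class PFChain:
    """Planar chain of tubulin monomers; the bottom dimer is fixed.

    positions[:, 0] is the lateral (x) and positions[:, 1] the axial
    (y) coordinate in nm; tau holds monomer rotation angles in rad.
    """

    positions: np.ndarray
    tau: np.ndarray
    n_fixed: int = 2

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        if self.positions.shape != (self.tau.shape[0], 2):
            raise ValueError("positions must have shape (n_monomers, 2)")
        if self.n_fixed < 2:
            raise ValueError("the bottom dimer is always fixed (n_fixed >= 2)")

    @property
    def n_monomers(self) -> int:
        return self.tau.shape[0]

    @property
    def fixed_mask(self) -> np.ndarray:
        m = np.zeros(self.n_monomers, dtype=bool)
        m[: self.n_fixed] = True
        return m

    @classmethod
    def equilibrium(cls, n_monomers: int = 16,
                    mech: MechanicalParams = MechanicalParams()) -> "PFChain":
        """Curved stress-free shape: every free hinge at theta0,
        every longitudinal bond unstretched."""
        tau = np.zeros(n_monomers)
        for i in range(2, n_monomers):
            tau[i] = tau[i - 1] + mech.theta0
        return cls._from_tau(tau, mech)

    @classmethod
    def straight(cls, n_monomers: int = 16,
                 mech: MechanicalParams = MechanicalParams()) -> "PFChain":
        """Straight chain (all tau = 0, bonds unstretched)."""
        return cls._from_tau(np.zeros(n_monomers), mech)

    @classmethod
    def _from_tau(cls, tau: np.ndarray,
                  mech: MechanicalParams) -> "PFChain":
        n = tau.shape[0]
        pos = np.zeros((n, 2))
        rt = mech.r_tub
        for i in range(1, n):
            u0 = np.array([math.sin(tau[i - 1]), math.cos(tau[i - 1])])
            u1 = np.array([math.sin(tau[i]), math.cos(tau[i])])
            pos[i] = pos[i - 1] + rt * (u0 + u1)
        return cls(pos, tau)

    def copy(self) -> "PFChain":
        return PFChain(self.positions.copy(), self.tau.copy(), self.n_fixed)


@dataclass
class SimulationConfig:
    """Integration settings for Brownian-dynamics runs.

    dt defaults to 2 ps; the stiffest mode (the intra-dimer spring,
    gamma_q / k_intra ~ 17 ps at eta = 1 mPa s) sets the stability
    margin and a startup check refuses dt > gamma_q / (5 k_intra).
    """

    dt: float = 2.0e-12
    T: float = constants.T_DEFAULT
    eta: float = constants.ETA_DEFAULT
    seed: int = 0
    duration: float = 1.0e-6
    record_stride: int = 1000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")

    def n_steps(self) -> int:
        return max(1, int(round(self.duration / self.dt)))

    def check_stability(self, mech: MechanicalParams) -> None:
        gq = constants.gamma_translation(mech.r_tub, self.eta)
        k_eff = max(mech.k_intra, 2.0 * mech.k_rep)
        dt_max = gq / (5.0 * k_eff)
        if self.dt > dt_max:
            raise ValueError(
                f"dt={self.dt:g} s exceeds the stability bound "
                f"gamma_q/(5 k_eff) = {dt_max:g} s"
            )


@dataclass
class StraighteningCriteria:
    """Two-threshold hysteresis rule for curved->straight passages."""

    theta_curved: float = 0.15
    theta_straight: float = 0.05
    monitored_index: Optional[int] = None  # default: lowest free monomer

    def __post_init__(self) -> None:
        if not self.theta_straight < self.theta_curved:
            raise ValueError("require theta_straight < theta_curved")


@dataclass
class Trajectory:
    """Recorded frames of a chain run plus in-kernel event counters."""

    times: np.ndarray
    positions: np.ndarray  # (n_frames, n_monomers, 2)
    tau: np.ndarray        # (n_frames, n_monomers)
    dt: float
    duration: float
    n_fixed: int
    straightening_events: int = 0
    angle_series: Optional[np.ndarray] = None  # per-step monitored angle
    bead_z: Optional[float] = None

    @property
    def n_frames(self) -> int:
        return self.tau.shape[0]

    def hinge_angles(self, hinge: int) -> np.ndarray:
        """Bending angle tau[hinge] - tau[hinge-1] per frame."""
        return self.tau[:, hinge] - self.tau[:, hinge - 1]


def _drags(mech: MechanicalParams, cfg: SimulationConfig):
    gq = constants.gamma_translation(mech.r_tub, cfg.eta)
    gt = constants.gamma_rotation(mech.r_tub, cfg.eta)
    return gq, gt


def simulate_single_pf(chain: PFChain, mech: MechanicalParams,
                       cfg: SimulationConfig,
                       crit: Optional[StraighteningCriteria] = None,
                       record_angle_series: bool = False,
                       bead: Optional[dict] = None) -> Trajectory:
    """Run Brownian dynamics of one chain and record frames.

    The same seed and config give a bit-identical trajectory.  If a
    StraighteningCriteria is supplied, curved->straight passages at
    the monitored hinge are counted in-kernel at full time resolution.
    bead: optional dict with keys x, z0, force_pN, ring (RingParams)
    enabling the axially constrained repulsive sphere.
    """
    cfg.check_stability(mech)
    crit = crit or StraighteningCriteria()
    n = chain.n_monomers
    nfix = chain.n_fixed
    mon = crit.monitored_index if crit.monitored_index is not None else nfix
    gq, gt = _drags(mech, cfg)
    kT = constants.KB * cfg.T
    amp_q = math.sqrt(2.0 * kT * cfg.dt / gq)
    amp_t = math.sqrt(2.0 * kT * cfg.dt / gt)

    x = chain.positions[:, 0].copy()
    y = chain.positions[:, 1].copy()
    tau = chain.tau.copy()
    ct = np.cos(tau)
    st = np.sin(tau)

    use_bead = bead is not None
    ring = (bead or {}).get("ring", RingParams())
    bead_x = float((bead or {}).get("x", 7.0))
    bead_state = np.array([float((bead or {}).get("z0", 0.0))])
    F_ext = float((bead or {}).get("force_pN", 0.0)) / constants.KCALMOL_NM_TO_PN
    g_bead = constants.gamma_translation(ring.R_dam1, cfg.eta)
    amp_b = math.sqrt(2.0 * kT * cfg.dt / g_bead)

    n_steps = cfg.n_steps()
    n_frames = n_steps // cfg.record_stride
    rec_x = np.empty((n_frames, n))
    rec_y = np.empty((n_frames, n))
    rec_tau = np.empty((n_frames, n))
    hyst = np.zeros(2, dtype=np.int64)
    init_angle = tau[mon] - tau[mon - 1]
    hyst[0] = 1 if init_angle > crit.theta_curved else 0

    angle_series = np.empty(n_steps) if record_angle_series else None
    # SFC64 is the fastest high-quality generator for the bulk noise
    # stream; the seed fully determines the trajectory
    rng = np.random.Generator(np.random.SFC64(cfg.seed))
    done = 0
    while done < n_steps:
        m = min(_NOISE_CHUNK, n_steps - done)
        noise = rng.standard_normal((m, 3 * (n - nfix) + 1))
        rec_angle = (angle_series[done:done + m] if record_angle_series
                     else np.empty(0))
        status = pf_bd_steps(
            x, y, tau, ct, st, nfix, noise, done,
            cfg.dt, gq, gt, amp_q, amp_t,
            mech.k_intra, mech.B_bend, mech.theta0, mech.r_tub,
            False, 0.0, 0.0, 1.0,
            use_bead, bead_x, bead_state, F_ext, mech.k_rep,
            ring.R_dam1, g_bead, amp_b,
            mon, crit.theta_curved, crit.theta_straight, hyst,
            cfg.record_stride, rec_x, rec_y, rec_tau, rec_angle)
        if status > 0:
            raise IntegrationInstabilityError(status - 1)
        done += m

    times = (np.arange(1, n_frames + 1)) * cfg.record_stride * cfg.dt
    positions = np.stack([rec_x, rec_y], axis=-1)
    return Trajectory(times, positions, rec_tau, cfg.dt,
                      n_steps * cfg.dt, nfix,
                      straightening_events=int(hyst[1]),
                      angle_series=angle_series,
                      bead_z=float(bead_state[0]) if use_bead else None)


def chain_potential_energy(chain: PFChain, mech: MechanicalParams) -> float:
    """Total chain energy (springs + bending) of a configuration."""
    tau = chain.tau
    return float(chain_energy(
        chain.positions[:, 0].copy(), chain.positions[:, 1].copy(),
        tau.copy(), np.cos(tau), np.sin(tau),
        mech.k_intra, mech.B_bend, mech.theta0, mech.r_tub,
        False, 0.0, 0.0, 1.0))


def count_passages(angles: np.ndarray, crit: StraighteningCriteria) -> int:
    """Hysteresis count of curved->straight passages in an angle series.

    A passage is scored only when the angle, having exceeded
    theta_curved, next drops to or below theta_straight; dithering at
    a single threshold is never counted.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle series")
    events = 0
    armed = angles[0] > crit.theta_curved
    for a in angles:
        if armed:
            if a <= crit.theta_straight:
                events += 1
                armed = False
        elif a > crit.theta_curved:
            armed = True
    return events


def straightening_frequency(trajectory, crit: StraighteningCriteria,
                            duration: Optional[float] = None) -> float:
    """Passages per second from curved to straight at the monitored hinge.

    Accepts a Trajectory (uses its full-resolution in-kernel count
    when available, otherwise the recorded frames) or a plain angle
    series with an explicit duration.
    """
    if isinstance(trajectory, Trajectory):
        if trajectory.n_frames == 0 and trajectory.angle_series is None:
            raise ValueError("empty trajectory")
        if trajectory.angle_series is not None:
            return count_passages(trajectory.angle_series, crit) / trajectory.duration
        if trajectory.straightening_events:
            return trajectory.straightening_events / trajectory.duration
        mon = crit.monitored_index if crit.monitored_index is not None else trajectory.n_fixed
        return count_passages(trajectory.hinge_angles(mon), crit) / trajectory.duration
    if duration is None:
        raise ValueError("duration required for a bare angle series")
    return count_passages(trajectory, crit) / duration


def measure_straightening_frequency(
        mech: MechanicalParams, cfg: SimulationConfig,
        crit: Optional[StraighteningCriteria] = None,
        n_monomers: int = 16) -> float:
    """Frequency of curved->straight passages for an equilibrated chain.

    Runs Brownian dynamics from the curved equilibrium shape and
    counts passages at the lowest free hinge at full time resolution.
    """
    chain = PFChain.equilibrium(n_monomers, mech)
    traj = simulate_single_pf(chain, mech, cfg, crit=crit or StraighteningCriteria())
    return traj.straightening_events / traj.duration


def max_sustainable_force(mech: MechanicalParams,
                          ring: RingParams = RingParams(),
                          bead_offset_x: float = 7.0,
                          n_monomers: int = 16,
                          tol_pN: float = 0.05,
                          f_hi_start: float = 1.0,
                          grad_tol: float = 1.0e-4,
                          max_steps: int = 400_000,
                          eta: float = constants.ETA_DEFAULT) -> float:
    """Largest axial force (pN) a curved PF sustains against a bead.

    The bead (radius R_dam1) moves only axially at lateral offset
    bead_offset_x and is dragged toward the plus-end by a constant
    force; the chain and bead are relaxed at zero temperature (the
    Langevin update with T = 0, i.e. gradient descent), and slow
    final convergence is polished with a quasi-Newton minimizer that
    reaches the same stationary condition.  A force is "sustained"
    when a stationary point exists with the bead blocked below the
    tip; it "fails" when the bead escapes past the chain tip.  The
    boundary is located by bisection to tol_pN.
    """
    from scipy.optimize import minimize

    gq = constants.gamma_translation(mech.r_tub, eta)
    gt = constants.gamma_rotation(mech.r_tub, eta)
    g_bead = constants.gamma_translation(ring.R_dam1, eta)
    # T=0 descent: the stiffest chain mode has eigenvalue ~ 4 k_intra,
    # so stability needs dt < 2 gamma_q / (4 k_intra) ~ 8.8 ps
    dt = 4.0e-12
    nfix = 2
    rt = mech.r_tub
    contact = ring.R_dam1 + rt

    def bead_start(chain: PFChain) -> float:
        """Axial position just below the first possible contact."""
        z0 = 0.0
        best = None
        for xi, yi in chain.positions:
            dx = xi - bead_offset_x
            if abs(dx) < contact:
                zi = yi - math.sqrt(contact * contact - dx * dx)
                if best is None or zi < best:
                    best = zi
        return z0 if best is None else min(best - 0.5, best)

    def energy_grad(vec, n, F_int):
        x = np.empty(n); y = np.empty(n); tau = np.empty(n)
        chain0 = PFChain.equilibrium(n, mech)
        x[:nfix] = chain0.positions[:nfix, 0]
        y[:nfix] = chain0.positions[:nfix, 1]
        tau[:nfix] = 0.0
        nf = n - nfix
        x[nfix:] = vec[0:nf]
        y[nfix:] = vec[nf:2 * nf]
        tau[nfix:] = vec[2 * nf:3 * nf]
        bz = vec[3 * nf]
        ct, st = np.cos(tau), np.sin(tau)
        fx = np.empty(n); fy = np.empty(n); ftau = np.empty(n)
        from ._pf_kernel import _chain_forces, _bead_forces
        U = _chain_forces(x, y, tau, ct, st, n, mech.k_intra, mech.B_bend,
                          mech.theta0, rt, False, 0.0, 0.0, 1.0,
                          fx, fy, ftau)
        Ub, fbz = _bead_forces(x, y, n, bead_offset_x, bz, mech.k_rep,
                               ring.R_dam1 + rt, fx, fy)
        U += Ub - F_int * bz
        g = np.concatenate([fx[nfix:], fy[nfix:], ftau[nfix:],
                            [fbz - F_int]])
        return U, g

    def relax(F_pN: float) -> bool:
        F_int = F_pN / constants.KCALMOL_NM_TO_PN
        chain = PFChain.equilibrium(n_monomers, mech)
        x = chain.positions[:, 0].copy()
        y = chain.positions[:, 1].copy()
        tau = chain.tau.copy()
        ct, st = np.cos(tau), np.sin(tau)
        bead_state = np.array([bead_start(chain)])
        # rounds of descent: a bead that keeps advancing is sliding
        # through (headed for escape); a stationary bead with a stalled
        # gradient is blocked and handed to the quasi-Newton polish
        status, steps, gmax = -2, 0, float("inf")
        prev_bz = -1e30
        for _ in range(24):
            status, steps, gmax = pf_relax(
                x, y, tau, ct, st, chain.n_fixed,
                dt, gq, gt,
                mech.k_intra, mech.B_bend, mech.theta0, mech.r_tub,
                False, 0.0, 0.0, 1.0,
                True, bead_offset_x, bead_state, F_int,
                mech.k_rep, ring.R_dam1, g_bead,
                grad_tol, max_steps, 2.0 * mech.r_tub)
            if status != -2:
                return status == 0
            if bead_state[0] - prev_bz < 0.05:
                break  # no longer advancing: blocked, not escaping
            prev_bz = bead_state[0]
        n = n_monomers
        nf = n - nfix
        z_cap = float(y.max()) + 2.0 * rt
        vec0 = np.concatenate([x[nfix:], y[nfix:], tau[nfix:],
                               [min(bead_state[0], z_cap)]])
        bounds = [(None, None)] * (3 * nf) + [(None, z_cap)]
        res = minimize(energy_grad, vec0, args=(n, F_int), jac=True,
                       method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 15000, "ftol": 1e-14,
                                "gtol": 0.5 * grad_tol})
        bz = res.x[-1]
        # an unobstructed bead runs to the cap under its load; an
        # interior endpoint therefore means a blocked (sustained)
        # configuration even when the fold-marginal gradient converges
        # slowly near the critical force
        return z_cap - bz >= 1e-3

    lo = 0.0
    hi = f_hi_start
    while relax(hi):
        lo = hi
        hi *= 2.0
        if hi > 1000.0:
            raise RelaxationError("no escape found below 1000 pN")
    while hi - lo > tol_pN:
        mid = 0.5 * (lo + hi)
        if relax(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def dynamic_persistence_length(trajectories: Sequence,
                               spacing: Optional[float] = None,
                               mech: MechanicalParams = MechanicalParams(),
                               min_snapshots: int = 100,
                               c_floor: float = 0.05) -> float:
    """Dynamic persistence length xi_d in micrometres.

    Pools snapshots from one or more trajectories, computes the
    per-monomer mean orientation (the equilibrium shape), and fits
    ln <cos(delta(s))> against arc separation s by least squares
    through the origin; returns -1/slope.  delta(s) is the difference
    of angular deflections from the mean shape between two monomers
    s apart along the contour.  A deflection-free ensemble gives
    slope 0 and xi_d = inf.
    """
    if spacing is None:
        spacing = 2.0 * mech.r_tub
    taus = []
    for tr in trajectories:
        if isinstance(tr, Trajectory):
            taus.append(tr.tau[:, tr.n_fixed:])
        else:
            taus.append(np.asarray(tr, dtype=float))
    tau = np.concatenate(taus, axis=0)
    if tau.shape[0] < min_snapshots:
        raise ValueError(
            f"need >= {min_snapshots} snapshots, got {tau.shape[0]}")
    delta = tau - tau.mean(axis=0, keepdims=True)
    n = delta.shape[1]
    seps, logc = [], []
    for j in range(1, n):
        c = float(np.mean(np.cos(delta[:, j:] - delta[:, :-j])))
        if c < c_floor:
            break
        seps.append(j * spacing)
        logc.append(math.log(c))
    if len(seps) < 3:
        raise ValueError("fewer than 3 usable arc-length separations")
    s = np.array(seps)
    lc = np.array(logc)
    denom = float(np.dot(s, s))
    slope = float(np.dot(s, lc)) / denom
    if slope >= 0.0:
        return math.inf
    return -1.0 / slope * 1e-3  # nm -> um
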