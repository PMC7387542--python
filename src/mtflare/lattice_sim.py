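"""Two-layer simulation of the 13-PF microtubule tip.

A fast Brownian-dynamics layer (Euler-Maruyama, shared kernel with the
single-PF module) propagates the mechanics of the mobile tip region,
and a slow kinetic Monte-Carlo layer, visited every t_kin (13 ms by
default), draws stochastic tubulin-dimer additions at PF tips
(P = k_on * c_tub * t_kin per PF), random GTP hydrolysis, and removes
detached oligomers whose basal inter-dimer bond has effectively
vanished (|E_long| < 0.1 kB T beyond the barrier).

Because full Brownian coverage of every 13-ms kinetic interval is an
HPC-scale computation, the Brownian window simulated per kinetic step
is configurable (Protocol.bd_window); the default None means the full
t_kin.  Reduced windows exploit the separation between mechanical
relaxation times (ns-us) and tubulin arrival times (hundreds of ms)
and are the package's standard desk-scale operating mode; see
docs/methods.md for what this approximation does and does not
preserve (detachment-limited rates are undersampled in proportion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional

import numpy as np
from scipy.optimize import minimize_scalar

from . import constants
from ._mt_kernel import make_bond_tables, mt_bd_steps
from .energetics import InteractionParams, MechanicalParams, RingParams
from .pf_mechanics import IntegrationInstabilityError
from . import tip_analysis

N_PF = 13
_NOISE_CHUNK = 16384


@dataclass(frozen=True)
class KineticParams:
    """Kinetic-layer constants.

    k_on in uM^-1 s^-1 per PF, c_tub in uM, t_kin and 1/k_hydr in s,
    detach_threshold in units of kB T.
    """

    k_on: float = 0.26
    c_tub: float = 10.0
    t_kin: float = 0.013
    k_hydr: float = 0.24
    detach_threshold: float = 0.1

    def __post_init__(self) -> None:
        for name in ("k_on", "c_tub", "t_kin", "k_hydr", "detach_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def p_add(self, c_tub: Optional[float] = None) -> float:
        c = self.c_tub if c_tub is None else c_tub
        p = self.k_on * c * self.t_kin
        if p > 1.0:
            raise ValueError(
                f"addition probability P = k_on*c_tub*t_kin = {p:.3f} > 1")
        return p


@dataclass(frozen=True)
class NucleotideEffect:
    """How GTP hydrolysis destabilizes the lattice.

    mode 'lateral-bond': hydrolysis weakens the lateral bond
    (b_lat 8 -> 4.7 kcal/mol) at fixed bending stiffness;
    mode 'bending-stiffness': hydrolysis stiffens the PF
    (B 78 -> 174 kcal/mol/rad^2) at fixed lateral bond strength.
    """

    mode: str = "lateral-bond"
    b_lat_GTP: float = 8.0
    b_lat_GDP: float = 4.7
    B_GTP: float = 174.0
    B_GDP: float = 174.0

    def __post_init__(self) -> None:
        if self.mode not in ("lateral-bond", "bending-stiffness"):
            raise ValueError(f"unknown nucleotide-effect mode {self.mode!r}")
        if self.mode == "lateral-bond" and self.B_GTP != self.B_GDP:
            raise ValueError("lateral-bond mode requires B_GTP == B_GDP")
        if self.mode == "bending-stiffness" and self.b_lat_GTP != self.b_lat_GDP:
            raise ValueError(
                "bending-stiffness mode requires b_lat_GTP == b_lat_GDP")

    @staticmethod
    def lateral_bond_mode() -> "NucleotideEffect":
        return NucleotideEffect()

    @staticmethod
    def bending_stiffness_mode() -> "NucleotideEffect":
        return NucleotideEffect(mode="bending-stiffness",
                                b_lat_GTP=4.7, b_lat_GDP=4.7,
                                B_GTP=78.0, B_GDP=174.0)

    def per_dimer(self, nuc: np.ndarray):
        """(b_lat, B) arrays for a GTP-flag array (1 = GTP)."""
        g = nuc.astype(bool)
        b = np.where(g, self.b_lat_GTP, self.b_lat_GDP)
        B = np.where(g, self.B_GTP, self.B_GDP)
        return b, B


@dataclass
class Event:
    time: float
    pf: int
    kind: str  # 'add' | 'hydrolysis' | 'detach' | 'ring_lost'
    size: int = 1


class MicrotubuleState:
    """Mechanical + chemical state of a 13-PF tip.

    Per PF: planar coordinates {z axial, x radial deviation} and
    rotation tau per monomer, a GTP flag per dimer, a monomer count
    K[n], and a frozen boundary below the mobile window of
    `mobile_dimers` terminal dimers.
    """

    def __init__(self, n_pf: int = N_PF,
                 mech: MechanicalParams = MechanicalParams(),
                 mobile_dimers: int = 20, capacity: int = 128):
        self.n_pf = n_pf
        self.mech = mech
        self.mobile_dimers = mobile_dimers
        self.rho0 = mech.r_tub / math.tan(math.pi / N_PF)
        self.z = np.zeros((n_pf, capacity))
        self.x = np.zeros((n_pf, capacity))
        self.tau = np.zeros((n_pf, capacity))
        self.nuc = np.zeros((n_pf, capacity // 2), dtype=np.uint8)
        self.K = np.zeros(n_pf, dtype=np.int64)

    # -- construction -----------------------------------------------------

    @classmethod
    def straight_lattice(cls, n_dimers: int, nucleotide: str = "GDP",
                         mech: MechanicalParams = MechanicalParams(),
                         n_pf: int = N_PF, mobile_dimers: int = 20
                         ) -> "MicrotubuleState":
        """Unstaggered straight wall (no seam, no helical rise): all
        x = 0, tau = 0, axial spacing 2 r_tub per monomer."""
        cap = max(64, 2 * n_dimers * 2)
        st = cls(n_pf, mech, mobile_dimers, cap)
        nm = 2 * n_dimers
        spacing = 2.0 * mech.r_tub
        for n in range(n_pf):
            st.z[n, :nm] = spacing * np.arange(nm)
            st.K[n] = nm
        st.nuc[:, :n_dimers] = 1 if nucleotide.upper() == "GTP" else 0
        return st

    def copy(self) -> "MicrotubuleState":
        new = MicrotubuleState(self.n_pf, self.mech, self.mobile_dimers,
                               self.z.shape[1])
        new.z[:] = self.z
        new.x[:] = self.x
        new.tau[:] = self.tau
        new.nuc[:] = self.nuc
        new.K[:] = self.K
        return new

    # -- derived views ----------------------------------------------------

    @property
    def capacity(self) -> int:
        return self.z.shape[1]

    @property
    def mstart(self) -> np.ndarray:
        return np.maximum(0, self.K - 2 * self.mobile_dimers)

    @property
    def n_dimers(self) -> np.ndarray:
        return self.K // 2

    def n_gtp(self) -> int:
        total = 0
        for n in range(self.n_pf):
            total += int(self.nuc[n, : self.K[n] // 2].sum())
        return total

    def monomer_arrays(self, effect: NucleotideEffect):
        """Per-monomer effective (b_lat, B) padded to capacity."""
        b_d, B_d = effect.per_dimer(self.nuc)
        blat_m = np.repeat(b_d, 2, axis=1).astype(float)
        Bm = np.repeat(B_d, 2, axis=1).astype(float)
        return blat_m, Bm

    def pf_polyline(self, n: int) -> np.ndarray:
        """(z, x) points of PF n from base to tip."""
        k = self.K[n]
        return np.column_stack([self.z[n, :k], self.x[n, :k]])

    def _ensure_capacity(self, needed: int) -> None:
        if needed <= self.capacity:
            return
        new_cap = max(needed, 2 * self.capacity)
        new_cap += new_cap % 2

        def grow(a, fill=0.0):
            out = np.full((self.n_pf, new_cap), fill, dtype=a.dtype)
            out[:, : a.shape[1]] = a
            return out

        self.z = grow(self.z)
        self.x = grow(self.x)
        self.tau = grow(self.tau)
        nuc = np.zeros((self.n_pf, new_cap // 2), dtype=np.uint8)
        nuc[:, : self.nuc.shape[1]] = self.nuc
        self.nuc = nuc

    # -- mutation used by the kinetic layer -------------------------------

    def append_dimer(self, n: int, gtp: bool, theta0: float) -> None:
        """Append one dimer continuing the tip's current tangent with
        unstretched bonds and each new hinge at theta0."""
        rt = self.mech.r_tub
        k = int(self.K[n])
        self._ensure_capacity(k + 2)
        if k == 0:
            t0 = 0.0
            z0, x0 = -2.0 * rt, 0.0
        else:
            t0 = self.tau[n, k - 1]
            z0, x0 = self.z[n, k - 1], self.x[n, k - 1]
        t1 = t0 + theta0
        t2 = t1 + theta0
        self.tau[n, k] = t1
        self.z[n, k] = z0 + rt * (math.cos(t0) + math.cos(t1))
        self.x[n, k] = x0 + rt * (math.sin(t0) + math.sin(t1))
        self.tau[n, k + 1] = t2
        self.z[n, k + 1] = self.z[n, k] + rt * (math.cos(t1) + math.cos(t2))
        self.x[n, k + 1] = self.x[n, k] + rt * (math.sin(t1) + math.sin(t2))
        self.nuc[n, k // 2] = 1 if gtp else 0
        self.K[n] = k + 2

    def truncate_pf(self, n: int, n_dimers_keep: int) -> None:
        self.K[n] = 2 * n_dimers_keep


# ---------------------------------------------------------------------------
# energies


def total_energy(state: MicrotubuleState, mech: MechanicalParams,
                 inter: InteractionParams,
                 effect: Optional[NucleotideEffect] = None,
                 decompose: bool = False):
    """Total lattice energy: lateral + inter-dimer longitudinal +
    intra-dimer spring + bending, summed over all subunits.

    NumPy implementation independent of the compiled stepping kernel;
    with decompose=True returns a dict of the four term classes.
    """
    effect = effect or NucleotideEffect(b_lat_GTP=inter.b_lat,
                                        b_lat_GDP=inter.b_lat,
                                        B_GTP=mech.B_bend, B_GDP=mech.B_bend)
    blat_m, Bm = state.monomer_arrays(effect)
    rt = mech.r_tub
    terms = {"spring": 0.0, "bending": 0.0, "longitudinal": 0.0,
             "lateral": 0.0}
    for n in range(state.n_pf):
        k = int(state.K[n])
        if k == 0:
            continue
        z, x, tau = state.z[n, :k], state.x[n, :k], state.tau[n, :k]
        ct, st_ = np.cos(tau), np.sin(tau)
        dz = (z[1:] - rt * ct[1:]) - (z[:-1] + rt * ct[:-1])
        dx = (x[1:] - rt * st_[1:]) - (x[:-1] + rt * st_[:-1])
        d2 = dz * dz + dx * dx
        intra = np.arange(k - 1) % 2 == 0
        terms["spring"] += 0.5 * mech.k_intra * d2[intra].sum()
        d = np.sqrt(d2[~intra])
        xw = d / inter.r_long
        terms["longitudinal"] += float(
            (2 * inter.a_long * xw ** 2 * np.exp(-xw)
             - inter.b_long * np.exp(-xw ** 2)).sum())
        Bh = 0.5 * (Bm[n, : k - 1] + Bm[n, 1:k])
        th = np.diff(tau) - mech.theta0
        terms["bending"] += float((0.5 * Bh * th * th).sum())
    for n in range(state.n_pf):
        if n + 1 < state.n_pf:
            m = n + 1
        elif state.n_pf == N_PF:
            m = 0
        else:
            continue
        k = int(min(state.K[n], state.K[m]))
        if k == 0:
            continue
        cosD, sinD = math.cos(2 * math.pi / N_PF), math.sin(2 * math.pi / N_PF)
        r1 = state.rho0 + state.x[n, :k]
        r2 = state.rho0 + state.x[m, :k]
        ax = r1 - r2 * cosD - rt * sinD
        ay = rt - r2 * sinD + rt * cosD
        az = state.z[n, :k] - state.z[m, :k]
        d = np.sqrt(ax * ax + ay * ay + az * az)
        b = 0.5 * (blat_m[n, :k] + blat_m[m, :k])
        xw = d / inter.r_lat
        terms["lateral"] += float(
            (2 * inter.a_lat * xw ** 2 * np.exp(-xw)
             - b * np.exp(-xw ** 2)).sum())
    if decompose:
        return terms
    return sum(terms.values())


def _longitudinal_barrier_distance(inter: InteractionParams) -> float:
    """Location of the inter-dimer activation barrier maximum (nm)."""
    if inter.a_long == 0:
        return 2.0 * inter.r_long
    w = inter.r_long

    def neg(r):
        xw = r / w
        return -(2 * inter.a_long * xw * xw * math.exp(-xw)
                 - inter.b_long * math.exp(-xw * xw))

    res = minimize_scalar(neg, bounds=(w, 6 * w), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# kinetic layer


def kinetic_step(state: MicrotubuleState, kin: KineticParams,
                 rng: np.random.Generator,
                 effect: Optional[NucleotideEffect] = None,
                 time: float = 0.0, c_tub: Optional[float] = None,
                 addition_filter: Optional[Callable] = None) -> List[Event]:
    """One kinetic Monte-Carlo visit: per-PF tubulin addition with
    probability P = k_on*c_tub*t_kin, then random GTP hydrolysis with
    per-dimer probability 1 - exp(-k_hydr*t_kin)."""
    effect = effect or NucleotideEffect()
    events: List[Event] = []
    p = kin.p_add(c_tub)
    theta0 = state.mech.theta0
    for n in range(state.n_pf):
        if p > 0 and rng.random() < p:
            if addition_filter is None or addition_filter(state, n):
                state.append_dimer(n, gtp=True, theta0=theta0)
                events.append(Event(time, n, "add", 1))
    if kin.k_hydr > 0:
        p_h = 1.0 - math.exp(-kin.k_hydr * kin.t_kin)
        for n in range(state.n_pf):
            nd = int(state.K[n]) // 2
            gtp_idx = np.nonzero(state.nuc[n, :nd])[0]
            if gtp_idx.size == 0:
                continue
            hyd = gtp_idx[rng.random(gtp_idx.size) < p_h]
            for j in hyd:
                state.nuc[n, j] = 0
                events.append(Event(time, n, "hydrolysis", 1))
    return events


def detach_oligomers(state: MicrotubuleState, inter: InteractionParams,
                     threshold: float = 0.1, T: float = constants.T_DEFAULT,
                     time: float = 0.0) -> List[Event]:
    """Remove terminal oligomers whose basal inter-dimer bond has
    effectively broken: site distance beyond the activation barrier
    and |E_long| below threshold*kBT.  The most basal broken bond
    wins, so a multi-dimer curl leaves as one oligomer."""
    kT = constants.KB * T
    rt = state.mech.r_tub
    d_barrier = _longitudinal_barrier_distance(inter)
    events: List[Event] = []
    for n in range(state.n_pf):
        k = int(state.K[n])
        nd = k // 2
        if nd < 2:
            continue
        j_low = int(state.mstart[n]) // 2 + 1
        for j in range(j_low, nd):
            ka, kb = 2 * j - 1, 2 * j
            dz = ((state.z[n, kb] - rt * math.cos(state.tau[n, kb]))
                  - (state.z[n, ka] + rt * math.cos(state.tau[n, ka])))
            dx = ((state.x[n, kb] - rt * math.sin(state.tau[n, kb]))
                  - (state.x[n, ka] + rt * math.sin(state.tau[n, ka])))
            d = math.hypot(dz, dx)
            if d <= d_barrier:
                continue
            xw = d / inter.r_long
            E = (2 * inter.a_long * xw * xw * math.exp(-xw)
                 - inter.b_long * math.exp(-xw * xw))
            if abs(E) < threshold * kT:
                removed = nd - j
                state.truncate_pf(n, j)
                events.append(Event(time, n, "detach", removed))
                break
    return events


def init_capped_mt(n_dimers: int = 50, cap_dimers: int = 225,
                   cap_length: float = 110.0,
                   rng: Optional[np.random.Generator] = None,
                   mech: MechanicalParams = MechanicalParams(),
                   mobile_dimers: int = 20) -> MicrotubuleState:
    """Straight GDP lattice with a stochastic GTP cap at the plus end.

    GTP probability is saturated near the tip and decays
    exponentially (scale cap_length/5) with distance, with the
    saturation depth solved so the expected GTP count equals
    cap_dimers.  cap_dimers = 0 gives a pure GDP lattice.
    """
    if cap_dimers > 13 * n_dimers:
        raise ValueError("GTP cap larger than the lattice")
    rng = rng or np.random.default_rng()
    st = MicrotubuleState.straight_lattice(n_dimers, "GDP", mech,
                                           mobile_dimers=mobile_dimers)
    if cap_dimers == 0:
        return st
    spacing = 4.0 * mech.r_tub  # nm per dimer
    s = spacing * np.arange(n_dimers)[::-1]  # distance from plus end
    lam = cap_length / 5.0

    def expected(s0):
        return 13.0 * np.minimum(1.0, np.exp(-(s - s0) / lam)).sum()

    lo, hi = -20.0 * cap_length, 2.0 * cap_length
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expected(mid) < cap_dimers:
            lo = mid
        else:
            hi = mid
    p = np.minimum(1.0, np.exp(-(s - 0.5 * (lo + hi)) / lam))
    for n in range(st.n_pf):
        st.nuc[n, :n_dimers] = (rng.random(n_dimers) < p).astype(np.uint8)
    return st


# ---------------------------------------------------------------------------
# Brownian layer plumbing


class _BDEngine:
    """Holds kernel arguments and advances the lattice state."""

    def __init__(self, state: MicrotubuleState, mech: MechanicalParams,
                 inter: InteractionParams, effect: NucleotideEffect,
                 dt: float, T: float, eta: float,
                 rng: np.random.Generator, coupler=None):
        self.state = state
        self.mech = mech
        self.inter = inter
        self.effect = effect
        self.dt = dt
        self.T = T
        self.rng = rng
        self.coupler = coupler
        kT = constants.KB * T
        self.gq = constants.gamma_translation(mech.r_tub, eta)
        self.gt = constants.gamma_rotation(mech.r_tub, eta)
        self.amp_q = math.sqrt(2 * kT * dt / self.gq)
        self.amp_t = math.sqrt(2 * kT * dt / self.gt)
        self.cosD = math.cos(2 * math.pi / N_PF)
        self.sinD = math.sin(2 * math.pi / N_PF)
        self.tables = make_bond_tables(inter.a_lat, inter.r_lat,
                                       inter.a_long, inter.b_long,
                                       inter.r_long)
        self.step = 0
        # coupler defaults (inert when unused)
        self.use_ring = coupler is not None and hasattr(coupler, "ring_z")
        self.use_obs = coupler is not None and hasattr(coupler, "obs_z")
        if self.use_ring:
            rp = coupler.params
            self.g_ring = constants.gamma_translation(rp.R_dam1, eta)
            self.amp_ring = math.sqrt(2 * kT * dt / self.g_ring)
        else:
            self.g_ring, self.amp_ring = 1.0, 0.0
        if self.use_obs:
            self.g_obs = constants.gamma_translation(coupler.radius, eta)
            self.amp_obs = math.sqrt(2 * kT * dt / self.g_obs)
        else:
            self.g_obs, self.amp_obs = 1.0, 0.0

    def advance(self, n_steps: int) -> None:
        st = self.state
        blat_m, Bm = st.monomer_arrays(self.effect)
        mstart = st.mstart
        tau = st.tau
        ct = np.cos(tau)
        sn = np.sin(tau)
        nmob = int((st.K - mstart).sum())
        ncols = 3 * nmob + (2 * st.n_pf if self.use_ring else 0) + 1
        c = self.coupler
        ring_z = c.ring_z if self.use_ring else np.zeros(1)
        ring_x = c.ring_x if self.use_ring else np.zeros(1)
        bound = c.bound if self.use_ring else np.full(1, -1, dtype=np.int64)
        rp = c.params if self.use_ring else RingParams()
        obs_z = c.obs_z if self.use_obs else np.zeros(1)
        done = 0
        while done < n_steps:
            m = min(_NOISE_CHUNK, n_steps - done)
            noise = self.rng.standard_normal((m, ncols))
            status = mt_bd_steps(
                st.z, st.x, tau, ct, sn, st.K, mstart, st.n_pf,
                noise, self.step,
                self.dt, self.gq, self.gt, self.amp_q, self.amp_t,
                st.rho0, self.cosD, self.sinD, self.mech.r_tub,
                self.mech.k_intra, Bm, self.mech.theta0, blat_m,
                *self.tables,
                self.use_ring, ring_z, ring_x, bound,
                rp.R_dam1, rp.l0, rp.l_max, rp.k_linker, rp.E_depth,
                self.mech.k_rep,
                getattr(c, "k_bond", 100.0) if self.use_ring else 0.0,
                getattr(c, "d0", 0.0) if self.use_ring else 0.0,
                (c.load_per_subunit() if self.use_ring else 0.0),
                self.g_ring, self.amp_ring,
                self.use_obs, obs_z,
                (c.radius if self.use_obs else 1.0),
                (c.axial_load() if self.use_obs else 0.0),
                self.g_obs, self.amp_obs)
            if status > 0:
                raise IntegrationInstabilityError(status - 1)
            done += m
            self.step += m


def brownian_substep(state: MicrotubuleState, mech: MechanicalParams,
                     inter: InteractionParams,
                     n_steps: int = 1, dt: float = 2.0e-12,
                     T: float = constants.T_DEFAULT,
                     eta: float = constants.ETA_DEFAULT,
                     rng: Optional[np.random.Generator] = None,
                     effect: Optional[NucleotideEffect] = None,
                     coupler=None) -> MicrotubuleState:
    """Euler-Maruyama update(s) of every mobile monomer in place."""
    eng = _BDEngine(state, mech, inter, effect or NucleotideEffect(
        b_lat_GTP=inter.b_lat, b_lat_GDP=inter.b_lat,
        B_GTP=mech.B_bend, B_GDP=mech.B_bend),
        dt, T, eta, rng or np.random.default_rng(), coupler)
    eng.advance(n_steps)
    return state


# ---------------------------------------------------------------------------
# protocols and runs


@dataclass
class Protocol:
    """Full parameter bundle for a lattice run."""

    mech: MechanicalParams = MechanicalParams()
    inter: InteractionParams = InteractionParams()
    kin: KineticParams = field(default_factory=KineticParams)
    effect: NucleotideEffect = field(default_factory=NucleotideEffect)
    duration: float = 1.0
    bd_window: Optional[float] = None  # BD seconds per kinetic step
    dt: float = 2.0e-12
    T: float = constants.T_DEFAULT
    eta: float = constants.ETA_DEFAULT
    seed: int = 0
    dilution: bool = False
    hydrolysis: bool = True
    coupler: Optional[object] = None
    snapshot_every: int = 0  # kinetic steps; 0 disables
    wall_tolerance: float = 1.5


@dataclass
class MTRun:
    """Result of a two-layer run.

    lengths is the curl-origin length (mean over PFs of where each PF
    leaves the wall); lengths_flux tracks polymer mass (mean dimer
    count per PF times the 8-nm dimer rise).  The two coincide once
    lateral zipping has equilibrated; at short Brownian windows the
    flux trace is the meaningful growth measure because wall
    incorporation of freshly added, still-curled dimers is a rare
    event that short windows undersample.
    """

    times: np.ndarray
    lengths: np.ndarray
    n_gtp: np.ndarray
    events: List[Event]
    state: MicrotubuleState
    lengths_flux: np.ndarray = None
    snapshots: List[List[np.ndarray]] = field(default_factory=list)
    ring_lost: bool = False


def mt_length(state: MicrotubuleState, wall_tolerance: float = 1.5) -> float:
    """MT length: mean over PFs of the curl-origin axial coordinate."""
    origins = []
    for n in range(state.n_pf):
        poly = state.pf_polyline(n)
        if poly.shape[0] < 2:
            origins.append(poly[-1, 0] if poly.shape[0] else 0.0)
            continue
        tr = tip_analysis.PFTrace(0, n, poly)
        origins.append(tip_analysis.curl_origin(tr, wall_tolerance).origin_z)
    return float(np.mean(origins))


def run_mt(state: MicrotubuleState, protocol: Protocol) -> MTRun:
    """Interleave Brownian bursts with kinetic events and detachment.

    Records (time, MT length, remaining GTP) once per kinetic step and
    every event.  Dilution sets the free tubulin concentration to zero
    from t = 0 while leaving hydrolysis running.
    """
    kin = protocol.kin
    if not protocol.hydrolysis:
        kin = replace(kin, k_hydr=0.0)
    c_tub = 0.0 if protocol.dilution else kin.c_tub
    rng = np.random.default_rng(protocol.seed)
    eng = _BDEngine(state, protocol.mech, protocol.inter, protocol.effect,
                    protocol.dt, protocol.T, protocol.eta, rng,
                    protocol.coupler)
    bd_window = protocol.bd_window if protocol.bd_window is not None \
        else kin.t_kin
    bd_steps = max(1, int(round(bd_window / protocol.dt)))
    n_kin = max(1, int(round(protocol.duration / kin.t_kin)))
    addition_filter = getattr(protocol.coupler, "addition_filter", None)
    times = np.empty(n_kin + 1)
    lengths = np.empty(n_kin + 1)
    lengths_flux = np.empty(n_kin + 1)
    ngtp = np.empty(n_kin + 1, dtype=np.int64)
    dimer_rise = 4.0 * protocol.mech.r_tub
    times[0] = 0.0
    lengths[0] = mt_length(state, protocol.wall_tolerance)
    lengths_flux[0] = float(state.n_dimers.mean()) * dimer_rise
    ngtp[0] = state.n_gtp()
    events: List[Event] = []
    snapshots: List[List[np.ndarray]] = []
    ring_lost = False
    for ik in range(n_kin):
        t = (ik + 1) * kin.t_kin
        eng.advance(bd_steps)
        events += kinetic_step(state, kin, rng, protocol.effect, time=t,
                               c_tub=c_tub, addition_filter=addition_filter)
        events += detach_oligomers(state, protocol.inter,
                                   kin.detach_threshold, protocol.T, time=t)
        times[ik + 1] = t
        lengths[ik + 1] = mt_length(state, protocol.wall_tolerance)
        lengths_flux[ik + 1] = float(state.n_dimers.mean()) * dimer_rise
        ngtp[ik + 1] = state.n_gtp()
        if protocol.snapshot_every and (ik + 1) % protocol.snapshot_every == 0:
            snapshots.append([state.pf_polyline(n).copy()
                              for n in range(state.n_pf)])
        if protocol.coupler is not None and hasattr(protocol.coupler,
                                                    "ring_z"):
            tip = max(state.z[n, state.K[n] - 1] for n in range(state.n_pf))
            if float(np.min(protocol.coupler.ring_z)) > tip + 8.0:
                events.append(Event(t, -1, "ring_lost", 0))
                ring_lost = True
                break
    last = ik + 2
    return MTRun(times[:last], lengths[:last], ngtp[:last], events, state,
                 lengths_flux[:last], snapshots, ring_lost)


def measure_rate(times: np.ndarray, lengths: np.ndarray,
                 burn_in: float = 0.0) -> float:
    """Least-squares slope (nm/s) of the length trace after burn-in."""
    times = np.asarray(times, float)
    lengths = np.asarray(lengths, float)
    keep = times >= burn_in
    if keep.sum() < 2 or np.ptp(times[keep]) == 0:
        raise ValueError("trace shorter than burn-in")
    return float(np.polyfit(times[keep], lengths[keep], 1)[0])
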