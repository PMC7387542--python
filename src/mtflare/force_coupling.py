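"""Mechanical couplers and force experiments.

Two couplers transmit force between the MT tip and the outside world:

* a Dam1 ring — 13 subunits, one per PF plane, joined by neighbour
  springs, repelled sterically by tubulin and attached through short
  flexible linkers (flat well + harmonic rise, rupture at l_max,
  rebinding to the most minus-end-proximal reachable monomer).  The
  ring centre may move only axially; a constant load is shared
  equally by the 13 subunits.
* a large sphere (5 um diameter by default) whose surface mimics a
  flat obstacle ahead of a growing tip.  It moves only axially, is
  repelled by every subunit, and vetoes tubulin additions whose
  placement would overlap it.

Force-velocity sweeps run the two-layer lattice simulation per load
and seed; the stall force is the zero crossing of mean velocity,
interpolated linearly between the bracketing loads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import constants
from .energetics import MechanicalParams, RingParams
from .lattice_sim import (MicrotubuleState, Protocol, brownian_substep,
                          measure_rate, mt_length, run_mt)


@dataclass
class ExternalLoad:
    """Constant axial load, potential w(z) = -F z.

    Positive magnitude is plus-end directed: assisting for a ring
    tracking a growing tip, opposing for an obstacle being pushed.
    """

    magnitude_pN: float = 0.0

    @property
    def internal(self) -> float:
        return self.magnitude_pN / constants.KCALMOL_NM_TO_PN


class Dam1Ring:
    """Ring state consumed by the lattice kernel (see _mt_kernel)."""

    def __init__(self, params: RingParams = RingParams(),
                 load_pN: float = 0.0, k_bond: float = 100.0,
                 ring_radius: Optional[float] = None,
                 z0: float = 0.0, n_pf: int = 13,
                 rho0: float = 8.12, r_tub: float = 2.0):
        self.params = params
        self.load = ExternalLoad(load_pN)
        self.k_bond = k_bond
        radius = ring_radius if ring_radius is not None \
            else rho0 + r_tub + params.R_dam1
        self.ring_x = np.full(n_pf, radius, dtype=float)
        self.ring_z = np.full(n_pf, z0, dtype=float)
        self.bound = np.full(n_pf, -1, dtype=np.int64)
        self.d0 = 2.0 * radius * math.sin(math.pi / n_pf)

    @classmethod
    def threaded(cls, state: MicrotubuleState,
                 params: RingParams = RingParams(),
                 load_pN: float = 0.0,
                 offset_below: float = 16.0,
                 wall_tolerance: float = 1.5,
                 **kw) -> "Dam1Ring":
        """Thread the ring on the MT, `offset_below` nm under the
        lowest curl origin (the default initial placement)."""
        z0 = mt_length(state, wall_tolerance) - offset_below
        return cls(params, load_pN, z0=z0, n_pf=state.n_pf,
                   rho0=state.rho0, r_tub=state.mech.r_tub, **kw)

    def load_per_subunit(self) -> float:
        return self.load.internal / self.ring_z.size

    def center_z(self) -> float:
        return float(self.ring_z.mean())


class Obstacle:
    """Axially mobile sphere approximating a flat obstacle."""

    def __init__(self, diameter: float = 5000.0, load_pN: float = 0.0,
                 surface_z: float = 0.0, clearance: float = 0.0):
        self.radius = diameter / 2.0
        self.load = ExternalLoad(load_pN)
        self.obs_z = np.array([surface_z + clearance])

    @classmethod
    def at_tip(cls, state: MicrotubuleState, load_pN: float = 0.0,
               clearance: float = 1.0, diameter: float = 5000.0
               ) -> "Obstacle":
        tip = max(float(state.z[n, state.K[n] - 1])
                  for n in range(state.n_pf))
        return cls(diameter, load_pN, surface_z=tip + 2 * state.mech.r_tub,
                   clearance=clearance)

    def axial_load(self) -> float:
        # opposing growth: potential +F z  =>  dU/dz = +F
        return self.load.internal

    def addition_filter(self, state: MicrotubuleState, n: int) -> bool:
        """Permit an addition only if the new dimer would not overlap
        the obstacle sphere."""
        rt = state.mech.r_tub
        k = int(state.K[n])
        if k == 0:
            return True
        t0 = state.tau[n, k - 1]
        z0, x0 = state.z[n, k - 1], state.x[n, k - 1]
        th0 = state.mech.theta0
        zc_center = self.obs_z[0] + self.radius
        zp, xp, tp = z0, x0, t0
        for _ in range(2):
            tn = tp + th0
            zn = zp + rt * (math.cos(tp) + math.cos(tn))
            xn = xp + rt * (math.sin(tp) + math.sin(tn))
            rho = state.rho0 + xn
            d = math.hypot(rho, zc_center - zn)
            if d < self.radius + rt:
                return False
            zp, xp, tp = zn, xn, tn
        return True


def ring_step(ring: Dam1Ring, state: MicrotubuleState,
              mech: MechanicalParams, inter, n_steps: int = 1,
              rng: Optional[np.random.Generator] = None,
              T: float = constants.T_DEFAULT, dt: float = 2.0e-12,
              effect=None) -> Dam1Ring:
    """Langevin update(s) of the ring coupled to the lattice."""
    brownian_substep(state, mech, inter, n_steps=n_steps, dt=dt, T=T,
                     rng=rng, effect=effect, coupler=ring)
    return ring


def ring_contact_force(state: MicrotubuleState, ring: Dam1Ring) -> float:
    """Net axial force (pN) transmitted to the ring by tubulin
    contacts (repulsion + linkers), evaluated on the current
    configuration.  At stall this balances the applied load."""
    mech = state.mech
    rp = ring.params
    contact = rp.R_dam1 + mech.r_tub
    f = 0.0
    for n in range(state.n_pf):
        rz, rx = ring.ring_z[n], ring.ring_x[n]
        for k in range(int(state.K[n])):
            dz = rz - state.z[n, k]
            dx = rx - (state.rho0 + state.x[n, k])
            d = math.hypot(dz, dx)
            if d < contact and d > 1e-12:
                f += 2.0 * mech.k_rep * (contact - d) * dz / d
        kb = int(ring.bound[n])
        if 0 <= kb < state.K[n]:
            dz = rz - state.z[n, kb]
            dx = rx - (state.rho0 + state.x[n, kb])
            d = math.hypot(dz, dx)
            if rp.l0 <= d <= rp.l_max and d > 1e-12:
                f -= rp.k_linker * (d - rp.l0) * dz / d
    return f * constants.KCALMOL_NM_TO_PN


# ---------------------------------------------------------------------------
# force-velocity sweeps


@dataclass
class StallResult:
    table: pd.DataFrame          # load_pN, mean_v, sd_v, n
    stall_pN: Optional[float]    # None when not bracketed
    bracketed: bool
    runs: list = field(default_factory=list)


def _default_coupler(mode: str, state: MicrotubuleState, load: float,
                     ring_params: RingParams):
    if mode == "ring":
        return Dam1Ring.threaded(state, ring_params, load_pN=load)
    if mode == "obstacle":
        return Obstacle.at_tip(state, load_pN=load)
    raise ValueError("mode must be 'ring' or 'obstacle'")


def stall_sweep(protocol: Protocol, loads: Sequence[float],
                state_factory: Callable[[int], MicrotubuleState],
                mode: str = "ring", n_seeds: int = 3,
                ring_params: RingParams = RingParams(),
                burn_in: float = 0.0,
                rate_fn: Optional[Callable] = None) -> StallResult:
    """Force-velocity table and stall estimate.

    For each load, n_seeds independent runs are made from fresh
    states; velocity is the least-squares slope of the length trace.
    rate_fn(load, seed) may replace the simulation entirely (used to
    exercise the sweep logic against synthetic velocity models).
    """
    rows = []
    all_runs = []
    for load in loads:
        vs = []
        for s in range(n_seeds):
            if rate_fn is not None:
                vs.append(float(rate_fn(load, s)))
                continue
            state = state_factory(protocol.seed + 1000 * s)
            coupler = _default_coupler(mode, state, load, ring_params)
            proto = replace(protocol, coupler=coupler,
                            seed=protocol.seed + 1000 * s)
            run = run_mt(state, proto)
            all_runs.append(run)
            vs.append(measure_rate(run.times, run.lengths, burn_in))
        rows.append({"load_pN": load, "mean_v": float(np.mean(vs)),
                     "sd_v": float(np.std(vs, ddof=1)) if len(vs) > 1 else 0.0,
                     "n": len(vs)})
    table = pd.DataFrame(rows).sort_values("load_pN", ignore_index=True)
    stall, bracketed = _zero_crossing(table["load_pN"].to_numpy(),
                                      table["mean_v"].to_numpy())
    return StallResult(table, stall, bracketed, all_runs)


def _zero_crossing(loads: np.ndarray, v: np.ndarray):
    """Linear interpolation of the velocity zero between bracketing
    loads; None when the sweep does not change sign."""
    for i in range(len(loads) - 1):
        if v[i] == 0.0:
            return float(loads[i]), True
        if v[i] * v[i + 1] < 0:
            f = v[i] / (v[i] - v[i + 1])
            return float(loads[i] + f * (loads[i + 1] - loads[i])), True
    if len(v) and v[-1] == 0.0:
        return float(loads[-1]), True
    return None, False


@dataclass
class AssistedGrowthResult:
    table: pd.DataFrame  # load_pN, mean_v, sd_v, acceleration


def assisted_growth(protocol: Protocol, loads: Sequence[float],
                    state_factory: Callable[[int], MicrotubuleState],
                    n_seeds: int = 3,
                    ring_params: RingParams = RingParams(),
                    burn_in: float = 0.0) -> AssistedGrowthResult:
    """Growth rate vs plus-end-directed (assisting) ring load.

    Intended for the GTP parametrization with hydrolysis off; the
    acceleration factor is rate(F)/rate(0) (forces are swept with 0
    prepended if absent)."""
    loads = list(loads)
    if 0.0 not in loads:
        loads = [0.0] + loads
    res = stall_sweep(protocol, loads, state_factory, mode="ring",
                      n_seeds=n_seeds, ring_params=ring_params,
                      burn_in=burn_in)
    table = res.table.copy()
    v0 = float(table.loc[table["load_pN"] == 0.0, "mean_v"].iloc[0])
    table["acceleration"] = table["mean_v"] / v0 if v0 != 0 else np.nan
    return AssistedGrowthResult(table)


def obstacle_growth(protocol: Protocol, loads: Sequence[float],
                    state_factory: Callable[[int], MicrotubuleState],
                    n_seeds: int = 3, burn_in: float = 0.0) -> StallResult:
    """Force-velocity curve for growth against the obstacle."""
    return stall_sweep(protocol, loads, state_factory, mode="obstacle",
                       n_seeds=n_seeds, burn_in=burn_in)
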