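"""Pairwise energy and force terms of the tubulin model.

All simulation layers share these pure functions: the intra-dimer
Hookean spring, the harmonic bending potential of the protofilament
(PF) hinge, the soft-sphere repulsion used for Dam1 subunits and the
obstacle, the breakable lateral/longitudinal tubulin-tubulin bond with
an activation barrier, and the piecewise Dam1 linker well.  Every
energy has a hand-derived analytic gradient; centered finite
differences are used only as a test oracle.

Conventions: energies in kcal/mol, distances in nm, angles in rad.
Gradient functions return dE/dx with respect to their first argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar


class ParameterError(ValueError):
    """An energy parameter violates its invariant."""


@dataclass(frozen=True)
class MechanicalParams:
    """Mechanical constants of a tubulin chain.

    k_intra : intra-dimer longitudinal spring stiffness, kcal/mol/nm^2
    B_bend  : harmonic PF bending stiffness, kcal/mol/rad^2
    theta0  : equilibrium inter-monomer bending angle, rad
    r_tub   : tubulin sphere radius, nm (longitudinal interaction
              sites sit on the poles at +-r_tub, so the rest spacing
              is 2*r_tub per monomer)
    k_rep   : soft repulsion stiffness, kcal/mol/nm^2
    """

    k_intra: float = 310.0
    B_bend: float = 174.0
    theta0: float = 0.2
    r_tub: float = 2.0
    k_rep: float = 100.0

    def __post_init__(self) -> None:
        if self.k_intra < 0 or self.B_bend < 0 or self.k_rep < 0:
            raise ParameterError("stiffnesses must be >= 0")
        if not (0.0 <= self.theta0 < np.pi / 2):
            raise ParameterError("theta0 must lie in [0, pi/2)")
        if self.r_tub <= 0:
            raise ParameterError("r_tub must be positive")


@dataclass(frozen=True)
class InteractionParams:
    """Breakable-bond parameters for lateral and longitudinal contacts.

    a_* scale the activation barrier, b_* are the well depths and r_*
    the width / barrier-steepness length scales of the two bond types.
    Defaults correspond to the calibrated GTP-state lattice; r_lat,
    r_long, a_long and b_long are artifact defaults (config-exposed,
    unconfirmed against the original supplementary table).
    """

    a_lat: float = 6.3
    b_lat: float = 8.0
    r_lat: float = 1.5
    a_long: float = 2.0
    b_long: float = 9.0
    r_long: float = 1.5

    def __post_init__(self) -> None:
        if self.r_lat <= 0 or self.r_long <= 0:
            raise ParameterError("bond widths must be positive")
        if self.b_lat < 0 or self.b_long < 0:
            raise ParameterError("well depths must be >= 0")
        if self.a_lat < 0 or self.a_long < 0:
            raise ParameterError("barrier scales must be >= 0")

    @staticmethod
    def gtp_defaults() -> "InteractionParams":
        """Strong lateral bonds representing GTP-tubulin (b_lat = 8)."""
        return InteractionParams(b_lat=8.0)

    @staticmethod
    def gdp_defaults() -> "InteractionParams":
        """Weak lateral bonds representing GDP-tubulin (b_lat = 4.7)."""
        return InteractionParams(b_lat=4.7)


@dataclass(frozen=True)
class RingParams:
    """Dam1 ring geometry and linker constants.

    E_depth is derived, not free: continuity of the linker well at
    l_max forces E_depth = k_linker*(l_max - l0)^2 / 2.
    """

    R_dam1: float = 3.0
    l0: float = 5.0
    l_max: float = 6.0
    k_linker: float = 0.01
    E_depth: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.l0 < self.l_max:
            raise ParameterError("require l0 < l_max")
        if self.k_linker < 0:
            raise ParameterError("k_linker must be >= 0")
        object.__setattr__(
            self, "E_depth", 0.5 * self.k_linker * (self.l_max - self.l0) ** 2
        )


# ---------------------------------------------------------------------------
# energies and analytic gradients


def spring_energy(d, params: MechanicalParams):
    """Hookean stretch energy k/2 d^2 of the intra-dimer bond."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("spring extension d must be >= 0")
    return 0.5 * params.k_intra * d * d


def spring_grad(d, params: MechanicalParams):
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("spring extension d must be >= 0")
    return params.k_intra * d


def bending_energy(theta, params: MechanicalParams):
    """Harmonic bending energy B/2 (theta - theta0)^2 of a PF hinge."""
    theta = np.asarray(theta, dtype=float)
    dt = theta - params.theta0
    return 0.5 * params.B_bend * dt * dt


def bending_grad(theta, params: MechanicalParams):
    theta = np.asarray(theta, dtype=float)
    return params.B_bend * (theta - params.theta0)


def repulsion_energy(d, R: float, r: float, k_rep: float):
    """Soft-sphere overlap penalty k_rep (R + r - d)^2 for d < R + r.

    Note the deliberate absence of a 1/2 prefactor, matching the form
    used for tubulin-Dam1/obstacle contacts.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("center distance d must be >= 0")
    overlap = np.maximum(R + r - d, 0.0)
    return k_rep * overlap * overlap


def repulsion_grad(d, R: float, r: float, k_rep: float):
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("center distance d must be >= 0")
    overlap = np.maximum(R + r - d, 0.0)
    return -2.0 * k_rep * overlap


def bond_energy(d, a: float, b: float, w: float):
    """Breakable tubulin-tubulin bond with an activation barrier.

    E(r) = 2 a (r/w)^2 exp(-r/w) - b exp(-r^2/w^2)

    The well bottom sits at r = 0 with depth exactly -b; the barrier
    term vanishes there and peaks near r = 2 w with height ~ 1.08 a
    (exactly 8 e^-2 a when b = 0).
    """
    if w <= 0:
        raise ParameterError("bond width w must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("site distance d must be >= 0")
    x = d / w
    return 2.0 * a * x * x * np.exp(-x) - b * np.exp(-x * x)


def bond_grad(d, a: float, b: float, w: float):
    if w <= 0:
        raise ParameterError("bond width w must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("site distance d must be >= 0")
    x = d / w
    return (2.0 * a / w) * np.exp(-x) * (2.0 * x - x * x) + (
        2.0 * b / w
    ) * x * np.exp(-x * x)


def bond_barrier(a: float, b: float, w: float) -> float:
    """Height of the activation barrier of :func:`bond_energy`.

    Numeric maximization on [w, 6w] (the barrier of the full
    expression always lies beyond the well and before the far tail).
    Returns 0 if the profile has no positive interior maximum.
    """
    if a == 0:
        return 0.0
    res = minimize_scalar(
        lambda r: -bond_energy(r, a, b, w), bounds=(w, 6.0 * w), method="bounded"
    )
    return max(float(-res.fun), 0.0)


def linker_energy(d, params: RingParams, r_tub: float = 2.0):
    """Dam1 linker attraction: flat well, harmonic rise, zero beyond l_max.

    Piecewise in the subunit-tubulin center distance d:
    -E_depth for d < l0 (the repulsion term handles overlap below
    R_dam1 + r_tub), -E_depth + k/2 (l0 - d)^2 for l0 <= d <= l_max,
    and 0 for d > l_max.  E_depth makes the potential continuous at
    l_max by construction.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("center distance d must be >= 0")
    E = params.E_depth
    rise = -E + 0.5 * params.k_linker * (params.l0 - d) ** 2
    out = np.where(
        d > params.l_max, 0.0, np.where(d >= params.l0, rise, -E)
    )
    return out


def linker_grad(d, params: RingParams, r_tub: float = 2.0):
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("center distance d must be >= 0")
    inside = (d >= params.l0) & (d <= params.l_max)
    return np.where(inside, params.k_linker * (d - params.l0), 0.0)
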