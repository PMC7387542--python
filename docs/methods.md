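# Model and methods

`mtflare` implements a planar Brownian-dynamics / kinetic Monte-Carlo
model of microtubule (MT) tip dynamics in which protofilaments (PFs)
are intrinsically curved and tips are therefore flared, during both
growth and shortening.  This note records the model equations, the
parameter choices and their provenance, the numerical scheme, the
desk-scale operating sizes used by the test suite and
`scripts/acceptance.py`, and the known limitations.

## Mechanical model

A tubulin monomer is a sphere of radius r_tub = 2 nm carrying two
planar coordinates (axial z toward the plus end, radial x) and a
rotation angle tau; alpha- and beta-tubulin are treated identically.
Longitudinal interaction sites sit on the monomer poles at +-r_tub
along the monomer axis, so the rest spacing is 4 nm per monomer and
8 nm per dimer.

Energy terms (kcal/mol, nm, rad):

* intra-dimer bond: Hookean, U = k/2 r^2 with k = 310 kcal/mol/nm^2,
  r the distance between facing longitudinal sites;
* bending at every monomer-monomer hinge: W = B/2 (theta - theta0)^2
  with theta = tau_i - tau_{i-1}; theta0 = 0.2 rad makes the relaxed
  PF curl outward ("ram's horn"); B defaults to 174 kcal/mol/rad^2,
  the physically motivated range being 14-300 (dynamic persistence
  length 0.2-4.2 um, see below);
* breakable inter-dimer longitudinal and lateral bonds:
  E(r) = 2 a (r/w)^2 exp(-r/w) - b exp(-r^2/w^2),
  a well of depth exactly -b at r = 0 separated from the unbound
  state by an activation barrier whose height scales with a (equal to
  8 e^-2 a ~ 1.083 a when b = 0, peaking near r = 2w);
* soft-sphere repulsion against Dam1 subunits and the obstacle:
  rho(d) = k_rep (R + r - d)^2 for d < R + r with
  k_rep = 100 kcal/mol/nm^2 (note: no 1/2 prefactor — implemented in
  the form the model defines, unlike the intra-dimer spring);
* Dam1 linker attraction: flat well of depth
  E = k_linker (l_max - l0)^2 / 2 out to l0 = 5 nm, harmonic rise to
  l_max = 6 nm, zero beyond; k_linker = 0.01 kcal/mol/nm^2.  This
  makes the linker well ~0.008 kBT deep, i.e. coupling to the ring is
  dominated by steric repulsion from flared PFs rather than adhesion.

Parameters whose numeric values are not fixed by the published model
description are artifact defaults, config-exposed and flagged here:
r_lat = r_long = 1.5 nm (bond width; barrier at ~3 nm, a plausible
protein-contact scale), a_long = 2.0 kcal/mol, b_long = 9.0 kcal/mol
(order chosen a priori by a Kramers estimate so that inter-dimer
rupture is a rare event on the Brownian timescale, as required for
shortening at tens of dimers per second per PF).

Nucleotide state acts at dimer granularity in one of two modes:
weakened lateral bonds (b_lat 8.0 -> 4.7 kcal/mol at fixed B = 174)
or stiffened PFs (B 78 -> 174 kcal/mol/rad^2 at fixed b_lat = 4.7).
A lateral bond between dimers of different states uses the arithmetic
mean of the two b_lat values; a hinge between monomers of different
dimers uses the mean B.

## Geometry of the 13-PF lattice

Each PF moves only in the radial plane at azimuth 2 pi n / 13 that
contains the MT axis.  The wall radius rho0 = r_tub cot(pi/13)
~ 8.12 nm is the unique radius at which the lateral sites (placed at
+-r_tub along the azimuthal tangent) of resting neighbours coincide,
so the perfect straight lattice has every lateral bond at its well
bottom.  Lateral separations are evaluated as true 3D distances
between sites in adjacent planes; curling outward stretches lateral
bonds geometrically.  The ring is unstaggered (no seam, no 3-start
helical rise), consistent with treating alpha and beta identically.
Lateral partners are monomers of equal index in adjacent PFs.

## Dynamics

Overdamped Langevin (Ermak-McCammon / Euler-Maruyama):

    q_i <- q_i - dt/gamma_q dU/dq_i + sqrt(2 kB T dt / gamma_q) N(0,1)

and likewise for tau with gamma_tau.  Drags are Stokes values for a
2-nm sphere in water, gamma_q = 6 pi r eta, gamma_tau = 8 pi r^3 eta,
with eta = 1.0e-3 Pa s (config-exposed) and T = 310 K.  kB T at
310 K is 0.616 kcal/mol.

dt defaults to 2 ps.  The stiffest collective spring mode has
eigenvalue ~4 k_intra, giving a stability ceiling of
2 gamma_q / (4 k_intra) ~ 8.8 ps; the startup check refuses
dt > gamma_q / (5 k_eff).  A convergence test (halving dt leaves the
straightening frequency within error bars) is part of the suite.
Zero-temperature relaxations use dt = 4 ps.  For tangent-fluctuation
statistics of very soft chains (B = 14), dt = 1 ps is used: at 2 ps
the Euler-Maruyama variance inflation of the stiff position modes
leaks into the hinge-angle statistics at the percent level, which a
persistence-length fit amplifies.

Gaussian noise is drawn with numpy's ziggurat sampler (SFC64 stream
for the single-PF kernel); one master seed fully determines a run.
Compiled kernels (numba) advance the chain or lattice in batches;
monomer orientations keep incrementally rotated (cos, sin) pairs with
an exact resynchronization every 1024 steps.

The bond terms in the lattice kernel are evaluated from tabulated
energy/force-factor tables (5 pm spacing, linear interpolation, zero
beyond 24 nm); the interpolation error is orders of magnitude below
thermal forces.  Force factors are expressed as E'(r)/r, which is
smooth at r = 0, so coincident sites are well defined.

## Two-layer scheme and kinetic events

Between kinetic visits every t_kin = 13 ms, the Brownian layer
advances the mobile tip region: the terminal `mobile_dimers` dimers
per PF (default 20); everything below is a frozen boundary whose
bonds still act on the mobile side.  At each kinetic visit:

* each PF independently gains one GTP dimer with probability
  P = k_on c_tub t_kin (k_on per PF, in uM^-1 s^-1; P > 1 is a
  configuration error); the new dimer continues the tip tangent with
  unstretched bonds and each new hinge at theta0;
* every GTP dimer hydrolyzes with probability 1 - exp(-k_hydr t_kin),
  k_hydr = 0.24 /s, switching its parameters instantaneously;
* detachment: scanning each PF from the most basal mobile bond, the
  first inter-dimer bond whose site distance lies beyond the
  activation barrier with |E_long| < 0.1 kB T severs the PF there and
  the whole terminal oligomer is removed (a multi-dimer curl leaves
  as one event).  The beyond-the-barrier condition prevents the rule
  from firing at the well-to-barrier zero crossing of E_long.

MT length is the mean over PFs of the curl-origin axial position
(where each PF leaves the wall, wall tolerance 1.5 nm); rates are
least-squares slopes of length vs time after a configurable burn-in.
Runs also record a polymer-mass length (mean dimers per PF times
8 nm).  The two measures coincide once lateral zipping has
equilibrated; at reduced Brownian windows (below) the mass trace is
the meaningful growth measure.

## Couplers

The Dam1 ring is 13 subunits of radius 3 nm, one per PF plane,
joined to their neighbours by stiff springs (k = 100 kcal/mol/nm^2,
rest length the initial chord; the published model states only that
the spheres are "connected"), repelled by tubulin via rho(d) and
attached by the linker well.  A linker detaches when stretched past
l_max and rebinds the most minus-end-proximal monomer within reach.
The ring centre may move only axially: the mean radial displacement
of the subunits is projected out each step.  A constant load is
shared equally by the 13 subunits.  Subunit rotation is omitted: no
energy term couples to it, so the coordinate would be inert.

The obstacle is a 5-um-diameter sphere whose surface plays the role
of a flat barrier; it moves only axially with its (very large) Stokes
drag, interacts with every subunit through rho(d), and vetoes any
tubulin addition whose placement would overlap it.

Stall forces are zero crossings of the mean force-velocity curve,
interpolated linearly between bracketing loads, with >= 3 seeds per
load in production use.

Single-PF maximal force: a Dam1-sized bead constrained to the line
x = 7 nm is dragged plus-end-ward with constant force against the
curved PF at zero temperature.  A force is sustained when a
stationary blocked configuration exists and fails when the bead
passes every monomer within lateral reach; the boundary is bisected
to 0.05 pN (0.1 pN in sweeps).  Slow fold-marginal convergence near
the critical force is resolved with a bounded L-BFGS polish whose
stationarity condition (max gradient < 1e-4 kcal/mol/nm) matches the
descent's.  Measured: the maximal force is linear in B over 35-300
(R^2 > 0.999), and 13 PFs at B = 35 sustain ~27 pN, the basis for
calibrating B against the ~30 pN depolymerization force.

## Dynamic persistence length

xi_d is defined by <cos(delta(s))> = exp(-s / xi_d), delta(s) the
angular deflection from the equilibrium shape accumulated over arc
separation s.  The estimator pools snapshots, subtracts the
per-monomer mean orientation, averages cos of deflection differences
over all monomer pairs at each separation, and fits ln C(s) vs s
through the origin (separations with C < 0.05 are dropped); a
deflection-free ensemble returns infinity.  Because the hinge-angle
marginal is exactly Boltzmann (positions integrate out), the closed
form is xi_d = 2 l B / kB T with l = 4 nm per hinge: B = 14 maps to
0.18 um and B = 300 to 3.9 um, reproducing the published 0.2-4.2 um
correspondence.  Slow collective modes (microseconds for soft
chains) dominate the estimator variance; measurements therefore pool
several seeds and, for B = 14, use shorter (8-monomer) chains whose
slowest mode relaxes ~8x faster — the per-hinge statistic itself is
length-independent.

## Straightening frequency

A PF monomer is "curved" when its hinge angle exceeds 0.15 rad and
"straight" below 0.05 rad; a passage is counted only on a complete
curved-to-straight crossing (two-threshold hysteresis, counted
in-kernel at full time resolution), so dithering at a single
threshold never counts.  At B = 174 the 16-monomer chain passes at
~5e7 /s at the lowest free hinge — far above the 1e5 /s floor that
matters for growth (tubulin arrivals are 1-40 /s).  In this
implementation the frequency saturates with chain length beyond ~6
monomers (local few-monomer librations dominate the passages), so
the length dependence is only visible between the shortest chains.

## Calibration

`calibration.calibrate` reproduces the staged search: fix B from a
plausible range; start from the yeast k_on = 0.26 /uM/s/PF; scan
{a_lat, b_lat, b_long} at 10 uM for parameter sets matching
shortening (~ -400 nm/s, curls 40-80 nm) and growth (~ 20 nm/s,
curls 15-40 nm); check the ~30 pN stall for the shortening sets
(failure returns to the next B); scan concentration for the growth
sets, require a critical concentration of 0-2 uM, and rescale k_on
and c_tub at constant product to match the experimental slope.
"~" targets carry a +-15% relative tolerance (config-exposed; none
is stated in the model description).  The search logic is decoupled
from the measurement backend via a runner object; the default runner
wires in the desk-scale lattice simulation, and the unit tests drive
the staged logic with analytic surrogate backends.  Every
measurement lands in an audit trail with its seeds.

## Trace analysis

Traces are ordered (z, x) polylines per PF, minus-to-plus.  LOESS
smoothing (lowess, default span 0.25, one robustness iteration)
regresses both coordinates on arc length — axial noise corrupts
contour lengths and headings as much as radial noise — and retains
the endpoints.  The curl origin is detected in two stages: scan
backward from the tip while |x| exceeds the 1.5-nm wall tolerance,
then extrapolate back along the fitted curl geometry to zero heading
(ds = 2 tol / theta_c, which is far less sensitive to the fitted
curvature than theta_c / kappa; capped by the trace start).  Curl
length is the contour length from that origin to the tip.  Mean
curvature is the signed turning rate: a chord-length-weighted
regression of unwrapped chord headings on mid-chord arc position —
identical to total turn / length for an ideal arc, robust to point
noise, and sign-preserving so that averaging does not fold noise
into a positive bias.  Raggedness is the sample (n-1) standard
deviation of curl-origin axial positions over the >= 2 scored PFs of
one MT.  Adjacent-PF Spearman correlations pool pairs (pf, pf+1 mod
13) across MTs, mid-rank ties, and use the large-sample p value.

The synthetic fixture generator writes straight-wall + circular-arc
traces with configurable curvature (0.02-0.06 /nm), curl length,
origin spread, and isotropic point noise, plus a sidecar truth
table.  With 1 nm noise, recovery of curl length and curvature is
better than 10% on average over the grid cells whose curls clear the
wall tolerance plus noise (a curl whose maximal radial excursion is
below ~2.5 nm is not detectable at that noise level, matching the
practical limit of hand tracing).  What the fixtures do not emulate:
missing-wedge anisotropy, curvature variation along one curl, and
tracing gaps — recovery numbers speak to the estimator, not to
cryoET data quality.

## Desk-scale operating sizes and what they preserve

The published simulations covered every 13-ms kinetic interval with
Brownian dynamics at dt ~ ps on an HPC cluster (~1e10 steps per
simulated second per lattice).  On one CPU this package's standard
test and acceptance sizes instead use a reduced Brownian window per
kinetic step (Protocol.bd_window, typically 5-100 ns against the
full 13 ms) and a small mobile tip window (4-6 terminal dimers per
PF), relying on the separation between mechanical relaxation (ns-us)
and tubulin arrival (hundreds of ms).

This preserves, quantitatively: mechanical equilibration, thermal
statistics, addition kinetics, and therefore growth rates by polymer
mass (~2.1 nm/s per uM, ~20 nm/s at 10 uM with k_on = 0.26),
linearity of growth in concentration, a near-zero critical
concentration, hydrolysis kinetics (cap decay at k_hydr), and the
independence of adjacent-PF curls.  It undersamples, in proportion
to the window ratio, every thermally activated bond-network event:
lateral zip/unzip (whose rates at the calibrated barrier are tens
per second, i.e. tens of ms) and inter-dimer rupture.  Consequently
rapid GDP-lattice disassembly at -400 nm/s, ring stall forces
(~2.5 pN at a_lat = 2.1 vs ~30 pN at 6.3), pushing stalls, the
~2-fold force-accelerated assembly, steady-state curl lengths and
their concentration insensitivity, and raggedness growth are not
reproduced at desk scale; the corresponding checks in
tests/test_acceptance.py run the genuine machinery at the reduced
sizes and are expected to fail there, serving as an explicit record
of the scale gap rather than being weakened.  The zero-temperature
force computations (no thermal activation involved) carry the
force-generation results at full fidelity.

## Known limitations

* Strictly planar per-PF motion: no out-of-plane PF clusters or
  sheets, no PF twist.
* No seam and no helical rise; alpha/beta asymmetry ignored.
* Detachment checks run on the kinetic layer, not every Brownian
  step; sub-t_kin rupture-rebind sequences are invisible.
* The Dam1 ring has no subunit rotation energetics and a single
  linker per subunit.
* Catastrophe statistics at physiological tubulin are out of scope
  (they require minutes of simulated time even at full scale).
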