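# Methods

`ciliaflow` simulates tissue-scale transport and mixing by airway cilia in
the zero-Reynolds-number limit.  Cilia are prescribed-motion rigid rods, the
fluid is an unbounded Newtonian half-space over a no-slip wall, and passive
tracers probe the resulting flow.  This note records the model, its
parameters, the numerical choices, and what the package's tests do and do
not establish.

## Cilium beat model

Each cilium is a rigid rod anchored at a base point on the wall plane
(z = 0).  Its configuration is given by an azimuthal phase
`phi(t) = phi0 + omega*t` (counterclockwise about the vertical through the
base), a polar angle `theta(phi)` measured from the wall plane, and a length
`L(phi)`:

- **Length law.**  `L = 7 um` during the effective stroke (`phi` in
  [0, pi]); during recovery the rod shortens following the cubic
  `-0.3235 phi^3 + 5.2009 phi^2 - 26.6650 phi + 49.4710` (phi in radians,
  L in um), reaching a minimum of about 5.45 um.  The printed cubic meets
  the 7-um branch only to within 1e-3 um at `phi = pi` and 9e-3 um at
  `phi = 2 pi`; we subtract the linear interpolant of the two endpoint
  mismatches so that the rod *position* is exactly continuous across stroke
  switches.  Without this, the once-per-cycle position jump (~0.06 um at the
  tip) destroys the convergence of any time integrator; the adjustment is
  below 0.01 um everywhere.
- **Polar angle.**  Only the range [0.8, 2.4] rad is constrained by
  experiment; the mapping `theta(phi)` is a modelling choice.  The default
  is `theta = 1.6 + 0.8 sin(phi)`: the rod stands tallest at mid-effective
  stroke and sweeps lowest at mid-recovery.  This alignment produces the
  beat asymmetry that drives clearance: the -x tip motion occurs while the
  tip rides high (imparting shear at cilium-tip heights), the +x backflow
  while it sweeps low near the wall, so the cycle-averaged flow at
  z = 5-7 um points toward -x, and tracer ensembles drift down-left
  (-x, -y) and upward — the phenomenology of mucociliary clearance with a
  counterclockwise beat.  A phase scan over the one-parameter family
  `theta = 1.6 + 0.8 cos(phi - delta)` shows this is the only alignment
  with all of these signs; the `cosine` and `triangle` alternatives
  (theta_min at phi = 0) are retained as config options but pump +x at tip
  height.  Node velocities are exact chain-rule derivatives, including the
  shortening term; `dL/dphi` at the stroke switches uses the one-sided
  value of the active branch.
- **Time unit.**  One beat cycle.  The literature values (18 Hz beat) enter
  only when converting cycles to seconds; because published time labels for
  this system are internally inconsistent (400 cycles labelled both as
  22.2 s and 11.11 s), run artifacts store both second scales (cycles/18
  and cycles/36) alongside the canonical cycle count.

## Stokes flow

Forces are spread over blobs `psi_eps(r) = 15 eps^4/(8 pi (r^2+eps^2)^{7/2})`
with `eps = 0.1 um` (the cilium radius).  The free-space velocity of one
regularized Stokeslet is

    8 pi mu u(x) = [f (r^2 + 2 eps^2) + (f.b) b] / (r^2 + eps^2)^{3/2}.

**Wall image system.**  The no-slip condition at z = 0 is enforced in
closed form by an image system derived for this blob family: over a basis
of image-centred rational divergence-free fields we solved the linear
conditions that (i) the total velocity vanishes identically on z = 0,
(ii) the correction is exactly divergence-free, (iii) its eps -> 0 limit is
biharmonic away from the image point (hence the classical point-force image
system of Blake: image Stokeslet, Stokeslet doublet, potential dipole), and
(iv) the two-point kernel is reciprocal.  The resulting 40-term solution
collapses to five scalar factors (`ciliaflow/_wall_image.py`) and was
verified to 50 significant digits.  The residual Stokes forcing of the
eps^2 correction terms is concentrated at the image point below the wall
and decays like 1/r^5; inside the flow domain the field is an exact
incompressible Stokes flow to the order of the regularization itself.  The
pairwise mobility matrix built from this kernel is symmetric to machine
precision.

**Forcing.**  Each rod carries nodes at fixed arclength fractions
`sigma_i = i/15` (base node omitted; it sits on the wall with zero
velocity).  In the default resistive mode the Stokeslet strengths are
`f_i = gamma v_i` with `v_i` the prescribed node velocity; `gamma` is a
single scalar calibrated per beat configuration so that the fluid speed at
the tip of one isolated mid-stroke rod equals the prescribed tip speed
(gamma ~ 1.05 at the defaults).  A mobility mode solves the dense
3M x 3M system `G f = v` so the flow interpolates the node velocities
exactly; it serves as a validation path and is exact to 1e-6 in tests.
Because Stokes flow is linear, mu is set to 1 and only gamma/mu matters;
absolute velocity magnitudes in physical units are not predictions of this
model, transport geometry and relative rates are.

With 15 nodes the inter-node spacing (~0.47 um) is several blob widths, so
the near field of a rod is a chain of distinguishable force bumps rather
than a smooth slender body.  Tracers that approach a rod within ~1 um feel
these bumps; their individual trajectories are chaotic, and only ensemble
statistics (center of mass, mixing number, Ripley's K) are reproducible
across step sizes.  Tracers above the tip region converge at the
integrator's formal order.

## Tissue geometry

A cluster is a 3x3 lattice of rods at D = 4 um spacing (nominal footprint
8x8 um, the bounding box of the bases).  Arrays are three clusters on the
x-axis at center-to-center spacing Dc; since each 4-um-spaced cell of
cilia effectively occupies 12x12 um, Dc = 3D places the clusters
edge-to-edge, forming one continuous 9x3 lattice.  Random patches place
`round(nu Lx Ly / 64)` clusters uniformly in a 100x100 um patch by
rejection sampling, with nominal footprints kept inside the patch and
non-overlapping (Chebyshev center separation >= 8 um).  The nominal-footprint
overlap rule keeps densities up to nu ~ 0.5 placeable; nu = 0.4 (62
clusters) samples in milliseconds.  Metachronal phase lags are applied per
column within each cluster: column k (increasing x) starts at phase
k*phi0, so the activity pattern is a sawtooth that repeats every cluster;
phi0 > 0 is antiplectic under the convention that the effective stroke
points toward -x.

## Tracers and integration

Tracers are massless and advected with classical RK4 at 100 steps per beat
cycle by default.  Stage times at step endpoints are nudged inward by
1e-9 dt so that when a step boundary coincides with a stroke switch the
correct one-sided branch of the length law is used; with even
steps-per-cycle (switches on step boundaries) the integrator then retains
its formal fourth order (measured slope ~4), and tracers above the tips
self-converge to < 1e-3 um under step halving.  Scenario runs in the test
suite and acceptance script use 20-40 steps per cycle, 100 beat cycles,
and 250-500 tracers — reduced problem sizes chosen so ensemble statistics
are stable (the quantities asserted are ranking and sign contracts, which
are insensitive to these counts).

Default seeding regions: single cluster — a box over the cluster,
[-10,10]^2 x [1,9] um; three clusters — a band spanning the array,
[-(Dc+12), Dc+12] x [-10,10] x [5,9] um (scaling the parcel with the
machine keeps the per-spacing comparison undiluted by far-field tracers);
tissue patch — [-50,50]^2 x [5,9] um.  Boundaries are open; tracers may
leave laterally and are never re-injected.  The wall-corrected flow
vanishes at z = 0, so tracers cannot cross the wall except by integration
error; crossings beyond 1e-6 um trigger a warning and are clamped.

## Analysis statistics

- **Center of mass**: unweighted mean tracer position; ensembles of
  realizations report mean +/- sd.
- **Mixing number**: `m = (prod_i min_j |z_i - z_j|^2)^{1/N1}` over groups
  (A, B), computed in log space with a KD-tree; asymmetric in the group
  order, computed exactly as defined with A the first group (a symmetrized
  variant is available).  Distances use the full 3-D positions.  In a
  strong flow over an open domain, m/m0 can *grow* while the cloud dilates
  (m scales with the square of any uniform dilation) even as the groups
  interpenetrate; relative comparisons between coordination modes remain
  meaningful and are what the tests assert.
- **Ripley's K**: `K(r) = A/(n(n-1)) * #{ordered pairs within r}` in a
  rectangular window, no edge correction by default (translation
  correction available); the CSR reference is `pi r^2`, and the crossing
  radius r0 is the first +to- crossing of `K - pi r^2` after an initial
  exceedance, linearly interpolated.  Tip-layer analyses select tracers by
  *initial* height (the band |z0 - 7| <= 1 um), following the convention
  of tracking marked particle cohorts.
- **Cycle-averaged fields**: periodic trapezoid average of the velocity
  over 64 equispaced phases on a horizontal grid, with planar vorticity
  `dv/dx - du/dy` by central differences (one-sided at edges; exact for
  linear fields).

## What the simulations do and do not establish

The generator produces the study conditions themselves (cluster layouts,
densities 0.1-0.4, spacings 3D-12D, phase lags up to 2pi/3); there is no
external data.  Passing tests show that the implementation solves the
stated model correctly (kernel identities to machine precision, integrator
order, estimator oracles) and that the model reproduces the qualitative
transport phenomenology: down-left and upward single-cluster transport
with one counterclockwise swirl, monotone decrease of transverse and
vertical transport with cluster spacing, an interior optimum of x-transport
at intermediate spacing, weakening of clearance under metachronal phase
lags with faster vertical mixing for antiplectic waves, and tracer
clustering (swirl size) growing with ciliary density.

Quantitative placements differ from the published study in ways traceable
to the unprescribed parts of the model, chiefly theta(phi): in this
realization the x-transport optimum falls at Dc = 7D (5D and 9D within a
few percent) rather than 5D, and antiplectic lags up to 2pi/3 weaken but
do not reverse the transport direction.  The optimum's location also
depends measurably on the tracer-seeding convention (parcel fixed vs
scaled with the array), which published figure captions do not pin down.
Absolute mixing-number trajectories grow with cloud expansion (above), so
only their ordering across phase lags is asserted.  None of these
statistics model mucus viscoelasticity, the periciliary layer, ciliary
flexibility, or emergent (hydrodynamically self-organized) metachrony —
all outside this package's scope.
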