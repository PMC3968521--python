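# Methods

## Scope and model idea

`emboflow` is a desk-scale, reduced-order simulator of embolic-particle
transport through the cerebral arterial network. Patient-specific CFD studies
of embolus routing couple a 3-D Navier-Stokes solution on an MRI-derived
circle-of-Willis (CoW) geometry to Lagrangian particle tracking. Neither the
imaging geometry nor a 3-D solver is needed for the questions this package
addresses — which outlet territories emboli of a given size and density reach,
how fast they travel, how long they reside, and how tortuous their paths are —
provided the *flow-division structure* and the *advection field topology* of
the network are preserved. The package therefore replaces:

- the MRI geometry with a **synthetic CoW tube network** (constant-radius
  tubes on 3-D centerlines, three inlets L_ICA / R_ICA / BA, a complete
  communicating-artery ring, and 21 named terminal outlets grouped into the
  left/right MCA, ACA, and posterior territories);
- the 3-D flow solve with a **Hagen-Poiseuille resistance network**
  (resistance `8 mu L / (pi r^4)` per segment, nodal mass conservation,
  velocity inlets, pressure or fixed-flow outlets) plus **analytic
  axisymmetric Poiseuille profiles** inside each tube;
- nothing on the particle side: the sphere force balance, wall restitution
  model, release protocols, and outcome statistics are implemented in full.

This substitution is the package's principal fidelity gap: secondary flows,
recirculation, and true junction hydrodynamics are absent, so
patient-specific percentages (exact per-outlet splits, histogram peak
positions, tortuosity magnitudes) are not reproduced — only conservation
structure, territory-level routing, and qualitative orderings are.

## Synthetic vasculature

Coordinates are millimetres in a right-handed frame (+x right, +y anterior,
+z superior). Trunk calibres sit inside the 1-4 mm diameter range of the
major cerebral arteries: ICA 4.0 mm (right) / 3.8 mm (left) — the right
deliberately larger, mirroring the asymmetry that skews feeding-flow shares —
BA 3.0 mm, MCA 3.0 mm, ACA-A1 2.4 mm, PCA 2.2 mm, communicating arteries
1.4 mm. The right MCA tree carries six outlets against the left's four, and
the left carotid termination is built as a T (MCA and A1 leave the nearly
vertical ICA at right angles) while the right is a Y — the local branching
contrast that territory distributions are known to be sensitive to.

Two geometric choices matter for particle transport and were made after
observing artifacts of the idealized tube union:

- **Rounded carinae.** Each flow-dividing daughter branch starts with a
  near-node waypoint that hugs the parent axis before curving away. Without
  it, the wedge between daughter tubes is uncovered lumen-adjacent dead
  space: a particle riding the parent axis flies into the parent's end-cap,
  where the blended field keeps pushing it axially, and chatters at the apex
  indefinitely. Anatomically, flow dividers are rounded and daughters leave
  smoothly; the waypoints encode exactly that.
- **No perfect symmetry.** The basilar tip sits slightly off the midline and
  the two posterior junctions are not mirror images. A perfectly symmetric
  apex is a measure-zero stagnation point in reality but a particle trap in
  a blended field; real basilar bifurcations are never symmetric.

Vessel lengths and branch angles are not published for the reference
geometry; the defaults are anatomically plausible and fixed. The generator
is deterministic per (variant, diameter_scale, seed); the seed only jitters
terminal branch lengths by up to 0.4 mm. Variants remove the left posterior
communicating artery (`no_L_PCoA`) or the anterior communicating segment
(`no_R_ACoA`), each a single-edge removal that leaves the ring connected.

**Terminal calibration.** Only terminal-branch radii carry the calibration
burden; trunks are never rescaled. A fixed-point iteration rescales each
territory's terminal radii by `(target/achieved)^(1/4)` (Poiseuille
resistance scales as `r^-4`) until solved territory outflows match the
physiological split ACA:MCA:posterior = 20:60:20 within 1 percentage point
(default; both targets and tolerance are arguments). Convergence typically
takes ~9 iterations; non-convergence raises with the last achieved split.

## Flow solve and field reconstruction

Inlet velocity conditions (default 0.2 m/s on all three inlets) are imposed
as fixed volumetric inflows `Q = v pi r^2`, i.e. the profile is treated as
developed — the 10-diameter straight inlet extensions applied by
`extend_inlets` justify this. Outlets are 0 Pa by default; the alternative
"M1" mode prescribes flows on all outlets but one pressure reference, which
`run_experiment` fills with the physiological territory totals distributed
over outlets in proportion to the base solution's within-territory shares.
The nodal system is solved sparsely; junction imbalance is verified below
1e-10 of total inflow on every solve. Flow is steady, matching constant
boundary conditions; pulsatility is out of scope.

Inside a tube the velocity is `u = 2 (Q/pi r^2)(1 - (s/r)^2) t_hat` with `s`
the distance from the centerline and `t_hat` the flow-oriented tangent; the
pressure gradient is uniform along the axis. Where tubes overlap (junctions),
fields are blended with inverse-distance-to-axis weights
`w ~ 1/(eps + d)^3`, `eps = 0.01 mm`. The cubic power matters: with linear
weights, near-equal contributions at bifurcation apexes produce artificial
mid-lumen stagnation zones that trap the majority of particles; the cubic
blend leaves single-tube profiles exact and lets the nearest axis dominate
decisively in overlaps. The blended field is continuous but not
divergence-free; the error is confined to junction-sized regions.

## Particle model

Spherical rigid emboli with diameter `phi` and density `rho_p`;
`m_p = (pi/6) phi^3 rho_p`. The force balance is

    (m_p + C_VM rho_F V) dU_p/dt =
        F_D + F_B + F_P + C_VM rho_F V (DU_F/Dt)

- **Drag** `F_D = 0.5 C_D rho_F A_P |U_s| U_s` with
  `C_D = max((24/Re_s)(1 + 0.15 Re_s^0.687), 0.44)` (Schiller-Naumann with
  the conventional 0.44 Newton-regime floor; a `literal_44` mode retains the
  alternatively printed floor of 44). Implemented in the Stokes-factorized
  form `k(|U_s|) U_s`, regular as `U_s -> 0`.
- **Buoyancy** `F_B = (pi/6) phi^3 (rho_p - rho_F) g`. The default gravity
  vector is **zero**: at 9.81 m/s^2 the 800 um, +/-250 kg/m^3 cases settle at
  ~2 cm/s and reach a 3 mm vessel wall within ~0.15 s regardless of
  orientation, after which they crawl in the slow near-wall layer — behaviour
  inconsistent with the fast, core-riding trajectories reported for light
  large emboli in this class of study. Zero gravity reproduces that physics;
  the vector is fully configurable for sensitivity studies (the settling
  validation tests pass explicit nonzero gravity).
- **Pressure-gradient force** `F_P = -(pi/6) phi^3 grad(p)`, signed so the
  force points from high to low pressure; the opposite sign would push
  particles upstream and break the tracer limit.
- **Virtual mass** with `C_VM = 0.5`: the particle-acceleration part is
  moved to the left-hand side; the fluid acceleration along the trajectory is
  approximated by finite differences of the sampled fluid velocity between
  substeps.

Blood is Newtonian with `rho_F = 1056 kg/m^3`, `mu = 3.2e-3 Pa s`. Coupling
is one-way: momentum feedback on the flow and particle-particle collisions
are negligible for <= 800 um spheres in mm-scale vessels and are omitted;
the seeded release jitter (sigma = 5% of inlet radius) stands in for the
trajectory spread such interactions produce.

**Integration.** Outer step 0.01 s, total time 5 s (500 steps). Within an
outer step the drag term is integrated exactly per substep (exponential
update with frozen coefficients), which is unconditionally stable and exact
through the stiff limit `tau_p = rho_p phi^2 / (18 mu) << dt`. The substep is
`clip(0.1 tau_p, 5e-5 s, 1e-3 s)`: the lower floor exists because resolving
far below `tau_p` adds nothing once the drag update is exact (and makes the
tracer limit computationally unbounded); the upper cap keeps per-substep
displacement well below a vessel radius for collision detection.

**Walls.** Collision is detected when the wall distance falls below the
particle radius (finite-size contact, as a sphere touches when its centre is
`phi/2` away) — point-particle contact would let large emboli crawl in the
zero-velocity no-slip layer indefinitely. The penetrating centre is projected
back along the sampled outward normal (first-order contact resolution) and
the velocity is reflected with restitution coefficients: normal component
scaled by `-e_perp`, tangential by `e_par`; defaults (1, 1) give elastic
specular bounces; (0, 0) deposits the particle.

**Releases.** Core mode: one site at each inlet-plane centre, one particle
per site per outer step for 100 steps (300 particles over the three inlets).
Near-wall mode: six sites at 90% of the inlet radius — three in the L_ICA,
two in the R_ICA, one in the BA (angles evenly spaced per inlet, a choice;
the reference protocol gives counts but not coordinates). Injection velocity
0.2 m/s along the inlet axis; jittered positions clipped to stay inside the
lumen. After the release window the simulation continues particle-free to
5 s; remaining particles are marked trapped and excluded from exit
statistics (the conventional treatment of recirculation-zone stragglers).

## Outcome statistics

- **Exit distribution:** percent of *exited* particles per outlet, per
  territory group (MCAs / ACAs / BA+PCA), or per side; trapped and deposited
  counts are reported alongside but excluded from the 100% base.
- **Average travel speed:** path length / residence time per exited
  particle; histograms use 0.025 m/s bins (speed) and 0.1 s bins (residence),
  half-open with an upper-inclusive last bin, normalized to 1. Bin widths
  resolve the 0.05 m/s peak spacing this literature reports; both are
  configurable. The reported "M-shaped" near-wall histograms and specific
  peak positions are geometry-specific and treated as qualitative only.
- **Tortuosity:** `100 x (path - route)/route`, with the route the shortest
  centerline path from release inlet to exit outlet. Slightly negative
  values (corner-cutting relative to the polyline route) are possible and
  reported as computed.

## Problem sizes and reproducibility

The canned experiment matrix runs the nine (diameter x density) cases —
200/500/800 um at 800/1050/1300 kg/m^3 — under both release modes; the
default `reproduce-paper` configuration uses 50 particles per cell (the
reference protocol's ~300 per cell is a config knob away) and completes in
a few minutes on one CPU. All randomness flows from a single integer seed
through per-cell hashed sub-seeds; identical (config, seed) pairs reproduce
every output file byte-for-byte. The run manifest records the config hash,
seed, and schema version.

## Known limitations

- No secondary flows, recirculation, or true junction hydrodynamics: trapped
  fractions, histogram shapes, and tortuosity magnitudes are not
  quantitatively comparable to 3-D CFD; territory routing and orderings are
  the meaningful outputs.
- The blended junction velocity field is not divergence-free.
- Particle-wall contact is first-order (projection, not exact time-of-impact
  backtracking); with substep displacements ~0.1 mm the positional error per
  bounce is far below a vessel radius.
- Particles are rigid spheres: no deformation, lysis, tumbling of irregular
  fragments, or lodging/occlusion mechanics (a particle wider than a branch
  is still advected as a point with finite-size wall contact).
- Near-wall release sites and branch angles are plausible defaults, not
  measurements.
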