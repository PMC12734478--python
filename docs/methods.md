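# Methods

poreflow reconstructs and analyses the size-selective exit region of an
asymmetric virus-removal membrane at voxel resolution: synthetic
structure generation and fouling, FIB-SEM-style image-stack processing,
pore morphometry, Stokes permeability, and Lagrangian nanoparticle
challenge. This note records the models, the parameters that matter,
the numerical choices, and the limits of what the synthetic tests can
show about real membranes.

## Voxel structures and conventions

A membrane is a binary occupancy grid (pore = 1, solid = 0) on an
isotropic cubic lattice, 7 nm voxels by default. The third array axis
is the flow direction; index 0 is the reconstruction inlet (the open,
large-pore side) and the last index the size-selective exit face.
Connectivity is 6-neighbour (face-sharing) throughout — the strictest
standard choice, and the one consistent with face-centred flow:
percolation requires a chain of face-adjacent pore voxels from inlet to
exit. Structures persist as raw-encoded NRRD or as raw + JSON sidecar;
a file without voxel-size metadata is refused rather than guessed at.

## Synthetic membrane generator

The generator exists so every downstream stage can be scored against
known ground truth. It draws Gaussian white noise, smooths it with an
isotropic Gaussian kernel whose width follows a depth-dependent
correlation-length profile (implemented by blending a handful of
uniformly smoothed volumes linearly in sigma, adequate because sigma
varies slowly with depth), and thresholds each depth slice at the
quantile of its target porosity. Porosity is therefore controlled
essentially exactly per slice; pore size is controlled by the kernel
width. Draws that fail to percolate are retried with fresh substreams
and an explicit error names the seed after bounded retries.

Default profile, chosen once to emulate the exit region of a highly
asymmetric virus filter: porosity 0.40 at the inlet falling
quadratically in depth to 0.35 at the exit (the decline concentrated
toward the exit), and correlation length tapering 14 → 7 nm, which puts
local pore diameters at roughly 14–56 nm near the inlet and 14–28 nm at
the exit on a 7 nm grid — small enough that a 20 nm particle is
retained by geometry. The spatial statistics of real membranes are not
known to this fidelity; the defaults reproduce the reported porosity
range and the discrete diameter peaks near multiples of two voxels, not
any measured correlation structure.

Randomness: one master seed; each operation derives a named substream
(CRC-based key into a `SeedSequence`), so every artifact is
independently reproducible.

## Synthetic fouling

Protein deposition is emulated geometrically, not kinetically: a fixed
fraction of candidate voxels — pore voxels sharing a face with solid
(wall sites) — is converted to solid. Sampling weights are
`local_size^(-size_weight) * exit_proximity^(depth_weight)`, where
local size is the covering-sphere local thickness (each voxel receives
the radius of the largest inscribed pore sphere containing it, computed
by sphere painting from the Euclidean distance map). The raw distance
map itself is ~1 on every wall voxel and cannot distinguish the wall of
a small pore from the wall of a large one; local thickness is the
quantity that makes the size bias real. Defaults `size_weight = 4`,
`depth_weight = 1` were calibrated once so that fouling reproduces the
qualitative signature seen in fouled filters: a sharp reduction in the
number of small pores with comparatively little change in the large
ones, concentrated toward the exit.

Selection uses Gumbel top-k keys on the log-weights, so the voxels
deposited at a smaller fraction are a strict subset of those at a
larger fraction under the same seed. That nesting makes the flux ratio
monotone in the deposited fraction, which is what lets a plain
bisection calibrate `deposit_fraction` against a target flux-decline
ratio J/J0 (fouled/clean simulated permeability) to a stated tolerance,
warm-starting each candidate solve from the clean field. Deposition is
single-round (wall monolayer only) — no adsorption kinetics, no protein
transport, no multilayer growth.

## Stack rendering and reconstruction

The renderer produces one grayscale image per structure layer along the
milling axis. Image rows run down the membrane depth with the exit at
the top, directly beneath a flat bright carbon band (the protective
deposition layer used as an alignment reference); margins of background
surround the content. Corruptions, all recorded as ground truth:
per-slice integer (dx, dy) drift, additive Gaussian noise, a
multiplicative per-slice brightness gradient along the stack, and an
optional bright protein phase on deposited voxels. Drift beyond the
margin raises an error rather than silently cropping membrane content.

Reconstruction mirrors practice for drifted FIB-SEM stacks:

* **Alignment** is integer-only — no interpolation ever touches pixel
  values, so pore shapes cannot be distorted. Vertical shifts come from
  normalized cross-correlation of the reference slice's carbon band
  (template rows expanded a few pixels past the band, because the flat
  band interior is featureless; the signal is at its edges) against
  each slice; residual horizontal shifts from integer phase correlation
  between consecutive vertically aligned slices, accumulated relative
  to slice 0. Pixels shifted out of frame are flagged invalid and
  excluded from every downstream count. A correlation peak below 0.5
  aborts with the slice named.
* **Enhancement** applies per-slice tile-based clip-limited adaptive
  histogram equalization (8×8 tiles, clip limit 0.01 — conservative
  defaults, exposed as parameters) followed by division by a
  large-kernel Gaussian background estimate, flattening the depthwise
  brightness drift; output is rescaled into the input range. Constant
  slices pass through with a warning.
* **Segmentation** splits the depth range at a user-settable boundary
  (default mid-depth), thresholds each zone independently — Otsu's
  two-class criterion unless manual cuts are given; dark = pore — and
  concatenates the zones into one binary structure. A unimodality guard
  (Otsu class separation below 3.5× the within-class spread, the
  single-Gaussian value being ≈2.7) demands a manual threshold instead
  of silently thresholding noise. The carbon band never enters the
  structure.

On the default rendered fixture (48³, drift ±5 px, 2× depth gradient,
noise sd 6 at phase separation 110) this chain recovers drift within
±1 px, slab porosity within ±0.03, and permeability within ±20%.

## Morphometry

Porosity profiles count pore voxels per 250 nm slab along the flow axis
(the slab rounded to whole voxel layers, a final partial slab reported
at its true thickness), plotted at slab midpoints in µm from the inlet;
an optional validity mask excludes alignment-invalidated voxels.

Pore sizes use the Euclidean distance map: for every pore voxel, the
exact centre-to-centre distance to the nearest solid voxel, doubled and
scaled by the voxel size. Distances are computed on the full 3D volume
and then sliced to the requested depth slab (sizing pores by their true
3D surroundings). Domain faces are open — no solid padding — which
biases diameters of pores touching the lateral faces upward; this
matches the stated computation being reproduced and is noted as a bias,
not corrected. This per-voxel statistic deliberately underestimates
covering-sphere local thickness (a voxel one step from the wall of a
huge pore reports a small value); it is the reproduced method, not a
metrological recommendation. On a 7 nm grid the diameter histogram
peaks near multiples of two voxels — a voxelization artifact of the
structure, not of the metric, which takes non-integer values (√2, √5,
…) wherever nearest solids are diagonal.

## Stokes flow and permeability

Flow is steady incompressible Stokes on the marker-and-cell staggered
grid: pressures at pore-cell centres, velocities on faces. No-slip is
exact for the face-normal component and second-order for tangential
components via half-cell reflection ghosts. Lateral domain faces are
symmetry planes (zero normal velocity, zero tangential shear); inlet
and outlet are open faces at fixed pressure. Fully open buffer layers
(3 by default) are appended at both ends to decouple the pressure
condition from the structure; an `extend` buffer mode instead
replicates the end slices, giving fully developed in/outflow for the
translation-invariant analytic test geometries. Isolated pore regions
not connected to both faces are excluded from the solve (their velocity
is identically zero).

By linearity the system is solved once at unit forcing and rescaled so
the achieved pressure drop across the structure — measured between the
half-cell-extrapolated inlet and exit faces, buffers excluded — equals
the requested transmembrane pressure (210 kPa default, water-like
viscosity 1.0 mPa·s); this is equivalent to iterating on the inlet
velocity and satisfies the 10⁻³ relative match (0.21 kPa at 210 kPa) by
construction, which `verify_pressure_match` confirms from the field.

Two backends solve the saddle system [[A, G], [Gᵀ, 0]]:

* `mg` (default): restarted GMRES preconditioned block-triangularly,
  with each velocity Laplacian approximated by one Galerkin multigrid
  V-cycle (prolongation piecewise-constant tangentially and linear
  along the component axis on OR-coarsened pore masks; damped-Jacobi
  smoothing; coarse operators PᵀAP; a 1e-10 diagonal shift guards the
  exactly singular open-column modes of the flow-axis block at the
  coarsest level) and the pressure block by V-cycles on the SIMPLE
  Schur approximation Ŝ = Gᵀ diag(A)⁻¹ G — the throat-conductance
  network Laplacian, which is what actually conditions the Schur
  complement of a porous geometry.
* `direct`: Schur-complement CG with exact per-component sparse LU
  inverses and an LU of Ŝ as preconditioner. Slower (factorization
  bound) but independent; the two backends are cross-checked against
  each other in the tests.

Default residual tolerance is 1e-8 (relative); the reported
diagnostics are the maximum discrete divergence relative to the peak
face speed and the relative momentum residual. `permeability` refuses
to report κ when divergence exceeds its tolerance (1e-6 by default;
drivers that deliberately solve to looser tolerances — the challenge at
1e-5, the fouling calibration at 1e-7 — gate at 1000× their solve
tolerance, ample for particle transport, trend-level per-batch
permeabilities, and flux ratios asserted at ±0.05).
κ = (Q/A)/ΔP with Q integrated over the exit plane, A the full
cross-section (pore + solid), converted to L m⁻² h⁻¹ kPa⁻¹
(1 L m⁻² h⁻¹ kPa⁻¹ = 2.7778·10⁻¹⁰ (m/s)/Pa). Validation: square-duct
flux within 5% of the rectangular-duct series solution at 32 voxels
across, cylindrical-tube permeability within 5% of Hagen–Poiseuille at
24 voxels per diameter (effective radius from the voxelized
cross-section area), monotone grid convergence, exact linearity in ΔP,
and superset monotonicity (blocking voxels never increases κ).

## Particle transport and batch challenge

Particles move in the overdamped limit: displacement = interpolated
fluid velocity × dt plus an isotropic Gaussian Brownian step of
per-axis variance 2 D dt, with D = kT/(3πµd) (Stokes–Einstein;
≈2.1·10⁻¹¹ m²/s for 20 nm in water at 293 K). Velocity interpolation is
MAC-trilinear with solid-face values zero. The time step satisfies both
an advective CFL (half a voxel per step) and a Brownian bound (3σ of
one step ≤ one voxel). The Brownian bound cannot tunnel walls: a 20 nm
hard sphere would need a single jump of order 2r + h ≈ 27 nm to cross a
solid voxel, four times the 3σ limit, and every step is additionally
bisected to the contact surface.

Wall interaction is hard-sphere geometric, using the buffered pore
mask's distance map φ (trilinear, minus half a voxel, times voxel
size ≈ distance to the solid surface): a step that would bring φ below
the particle radius is bisected to contact, the unused remainder is
projected onto the local tangent plane (∇φ by central differences), and
the slide is itself bisected; if no tangential motion is feasible the
particle stays put — the deterministic, capture-promoting resolution of
multi-wall contacts. Capture is declared when a particle in wall
contact moves slower than 1 nm/s averaged over a 50-step trailing
window (a wedged particle, whose every move is rejected, trips this at
the first window). A step cap (10⁵ by default) terminates stalled
particles, as captured at their last contact if they ever touched a
wall; the cap is ~5× the steady advective transit time of the default
geometry. No electrostatic, hydrophobic, or adhesive wall forces are
modelled — capture is purely geometric confinement.

Seeding places particles 100 nm above the structure inlet, either
flux-weighted by the inlet-face normal velocity (`inflow_random`) or on
a regular lattice (the 20×15 grid of 300 tracer positions for
trajectory work). The Stokes solve keeps its standard 3-layer buffer;
above it, particles are tracked kinematically with sampled fields
clamped to the inlet plane and a reflecting floor 50 nm below the
seeding plane — an approximation of the open feed half-space that
avoids paying for a deep, badly conditioned open solve region.

The batch challenge runs the depth-filtration loop: per batch, solve
flow on the current geometry (warm-started from the previous field),
inject and track `batch_size` real plus `ghosts_per_batch` ghost
particles (ghosts enter retention statistics but never deposit, so they
sharpen statistics without touching the flow), rasterize each captured
real particle's sphere onto the voxel grid, convert voxels whose
cumulative particle volume fraction exceeds 0.5 to solid, and continue.
Sphere–voxel overlap uses deterministic 6³ subvoxel sampling (~1%
volume accuracy; the 0.5 threshold is insensitive at that level).
Defaults mirror the study design: 30 batches × 25 particles of 20 nm at
210 kPa, optionally +100 ghosts per batch; particle concentration
(10⁸/mL) is carried as metadata only — the batch schedule, not the
concentration, drives the computation. Loss of percolation mid-run is
not an error: remaining batches report zero flow and their particles
are recorded as retained at the blocked front.

Retention is LRV = log10(Nin/Nout). Complete retention reports the
lower bound log10(Nin + 1) — one further particle is assumed to pass —
and lower bounds are floored, not rounded, at reporting precision
(log10(751) = 2.8756 reads 2.87: rounding up would overstate a bound).
Capture-depth profiles histogram capture positions along the flow axis
in µm from the inlet; the clean-vs-fouled difference of means measures
the upstream capture shift caused by exit-side pore blockage.

## Orchestration

`PipelineConfig` is a flat serializable record (YAML round-trip with
schema validation and unknown-key rejection) of every stage toggle and
parameter plus one master seed. `run_pipeline` executes
generate → foul/calibrate → render → align → enhance → segment →
morphometry → flow → challenge → report, writing every artifact under
the output directory and a manifest with SHA-256 hashes, per-stage
derived seeds, and solver diagnostics. Identical config + seed gives
identical hashes. A stage failure writes the partial manifest and
re-raises naming the stage. The CLI mirrors the stages as thin
subcommands.

## Problem sizes and test design

The automated tests run on deliberately small volumes chosen to
exercise every code path with honest statistics: the shared default
membrane is 64³ (0.45 µm cube) for the fouling calibrations, the full
30-batch challenge, and the capture-shift comparison; the rendered
reconstruction fixture is 48³; analytic flow oracles use 16–64 voxel
ducts and 24-voxel-diameter tubes; the distance-map oracle checks
structures up to 32³ against an exhaustive KD-tree search. The
library itself has no such limits — the pipeline default is 96³ and
scales with memory and patience (solve cost grows roughly linearly in
voxel count with the multigrid backend).

## What passing tests do and do not show

The synthetic generator matches the reported porosity range, the
asymmetry direction, and the voxel-discretized pore-size peaks — not
the true (unpublished) spatial statistics of any commercial membrane.
Consequently: absolute permeabilities of synthetic volumes are not
comparable to measured membrane permeabilities; fouling here is a
calibrated geometric emulation, so calibration targets (J/J0 = 0.6,
0.1) demonstrate that the control loop works, not that protein deposits
this way; capture-depth comparisons are asserted as a direction (fouled
captures shift toward the inlet), never as a magnitude. Real FIB-SEM
data additionally contain curtaining, charging streaks, sub-voxel
partial-volume effects, and non-integer drift, none of which are
rendered; the alignment/segmentation scores are therefore upper bounds
on real-data performance.

## Known limitations

* Per-voxel distance-map sizing underestimates covering-sphere pore
  thickness (documented divergence retained for fidelity to the
  reproduced workflow).
* Finite particle size enters only through the wall-contact radius and
  the blocking volume — no hydrodynamic hindrance, lubrication, or
  wall-corrected drag.
* The fouled structure's protein phase is a voxel relabeling; no
  compressible cake layer or multilayer growth.
* The in-contact capture speed reads the particle displacement rate
  (not the fluid speed at the particle position); the 1 nm/s threshold
  needs the stated 50-step window to be operational.
* Permeability of the imaged exit region only; no full-thickness
  (~140 µm) membrane model.
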