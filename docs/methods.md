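# Methods

This note documents the models, conventions and numerical choices
behind each analysis, what the synthetic generators emulate, and the
limits of what the test suite can show about real data.

## Conventions and units

Positions are Å, times ps, velocities Å/ps, masses amu, forces
kJ/mol/Å in memory (the columnar pair-force file format uses kJ/mol/nm,
converted on read/write). Pressures and stresses are reported in bar;
the conversion constant 16 605.39 bar per kJ/mol/Å³ (equivalently
16.6054 bar per kJ/mol/nm³) is recorded in every stress output, because
silent unit errors are the dominant failure mode in pressure-profile
work. Surface tension is reported in bar·Å and mN/m (1 bar·Å =
0.01 mN/m).

Residue numbers are PDB author numbers everywhere; internal 0-based
atom indices are never written to reports. Only orthorhombic periodic
boxes are supported — every observable here is defined on z-slabs
normal to the membrane, and triclinic wrapping would complicate the
minimum-image segment weights for no analytical gain — so triclinic
input is rejected with an explicit message. Alternate locations in PDB
input keep the highest-occupancy conformer (tie: first encountered).

## Conformational-state metrics

**Superposition.** Least-squares rigid superposition (Kabsch, via SVD)
on atom pairs matched 1:1 by (chain, author resid, atom name); the
rotation is always proper. Degenerate (collinear) selections are
rejected because the rotation is undetermined. The test suite checks
the minimised RMSD against an independent quaternion-grid search with
simplex refinement.

**Gating distances.** Fenestration G324↔P198 (adjacent chain), zipper
W326↔R237, expansion M322↔G212 (same chain), all configurable. The
adjacent-chain mapping of the homodimer is an explicit symmetric map
(A↔B), never inferred from geometry. Distances default to Cα–Cα —
reproducible from Cα-only models — with a minimum-heavy-atom mode for
questions that are sterically heavy-atom notions (fenestration
closure). All distances are minimum-image.

**State labels.** A frame is "down" when its RMSD to the down
reference plus a margin is below its RMSD to the up reference (and
symmetrically); otherwise "intermediate". The default margin of 0.5 Å
is small against the several-Å down/up separation of the references.
RMSD is computed on the dimer by default (chain-restricted selections
give per-chain series).

**Event detection.** Each gating-distance series is smoothed with a
centred moving average (default 5 frames) and an event is the first
frame at which the smoothed series crosses the midpoint between the
down and up reference values *and stays across* for a dwell time
(default 5 frames). The dwell suppresses noise-driven spurious
crossings; the midpoint makes the detector symmetric in the two
states. Chains are detected independently: the two subunits move
stochastically and need not transition together. Undetected events are
reported as absent, and the order flag requires
t_unzip ≤ t_expand ≤ t_close.

## Membrane geometry

**Cross-sectional area.** For each 1 Å z-slice, the area of the union
of disks contributed by atoms whose van-der-Waals spheres cut the slice
plane (disk radius √(r² − Δz²)), rasterised on an xy grid of 0.25 Å
cells anti-aliased with a 4×4 subgrid. The estimator is deterministic,
monotone under atom addition, and converges to the analytic union area
(single-circle and two-circle closed forms agree to well under 1% at
the defaults). Radii come from a bundled Bondi-style element table
(unknown elements: 1.7 Å); the table id is recorded in the output. The
z origin is the bilayer midplane (mean phosphate plane of the two
leaflets) when lipids are present, else the selection's z centroid;
"cytoplasmic half" means z < 0 after recentring. Per-frame profiles
are averaged on a common grid after recentring each frame
independently, with the per-slice spread reported.

**Thickness and area per lipid.** Thickness is the distance between
the mean z of the head-group phosphates of the two leaflets (leaflets
assigned per frame by the sign of z about the phosphate mean); area per
lipid is exact arithmetic, Lx·Ly divided by the per-leaflet lipid
count.

## Local stress and the lateral pressure profile

The per-slab stress is the Hardy / Irving–Kirkwood–Noll form for
pairwise forces: kinetic term Σ mᵢvᵢ⊗vᵢ over atoms in the slab, virial
term Σ w_b(i,j)·r_ij⊗f_ij with w_b the fraction of the straight
minimum-image segment between the pair lying in slab b (Irving–
Kirkwood contour with a top-hat bond function). The top-hat contour is
the canonical choice and makes the partition of unity exact, which in
turn makes conservation exact: the volume-weighted slab sum equals the
whole-box virial + kinetic stress identically (verified to 1e-6
relative against an unbinned implementation). Forces are consumed, not
computed — the package's contribution is the localisation and binning
math with verifiable inputs — except for the built-in synthetic
potentials used in validation. If a trajectory lacks velocities, the
kinetic term may be replaced by the ideal thermal term ρ(z)kT·I at a
stated temperature; the substitution is flagged in the output metadata.

The profile convention is P = −σ, P_∥ = (Pxx+Pyy)/2, P_⊥ = Pzz,
P_L = P_∥ − P_⊥ (an exact pointwise identity in the implementation),
γ = −∫P_L dz by the trapezoidal rule on bin centres. The slab width
defaults to 1 Å (0.1 nm); requested widths that do not divide the box
height are rescaled with a warning. Only z-resolved profiles are
produced; the 3-D field is binned along z and implicitly averaged over
xy, because every observable of interest here is z-resolved. Profile
comparison reports the per-bin P_L difference plus region-integrated
changes over configurable z-intervals (defaults: bilayer core ±10 Å
and the two interfacial bands to ±25 Å).

## Occupancy analyses

**Filter sites.** S0–S4 are ordered non-overlapping z-intervals along
the pore axis, supplied explicitly in config (the synthetic default is
five 3 Å sites). For real structures a helper derives them from the
carbonyl-oxygen plane positions: midpoints between consecutive planes
bound the inner sites, and S0 spans one inter-plane spacing above the
top plane. A site is occupied in a frame when ≥ 1 ion's axial
coordinate lies in its interval ("probability of ions in the filter");
a per-ion-normalised mean count is available as an option.

**Water and dewetting.** Waters within a cylinder (default radius
5 Å) around the pore axis are histogrammed along z; the cavity count
is the number inside a configured z-interval. Dewetting events are
maximal runs of frames with count below a threshold (default 5 waters)
lasting at least a minimum duration; runs separated by a single wet
frame are never merged. The detector is checked against a run-length-
encoding oracle.

**Lipid contacts.** Lipid tails are all lipid heavy atoms minus a
configured head-group atom list. The contact metric is the minimum-
image minimum distance from tail atoms to the target residue's atoms;
"bound" means within 4 Å (the criterion used for lipids occupying the
fenestration site at P198). The series is paired with a structural
metric — fenestration width, or the F226–L243 tip-groove width with
S240 as the contact anchor — for state-dependence scatter analysis.

## Synthetic study conditions

The generators define the conditions under which the pipeline is
validated; their defaults are fixed and are not tuned per test.

*Channel model*: two chains related by a two-fold rotation about z,
each four ideal α-helices of Cα beads spanning author resids 70–100,
190–215, 218–248 and 300–335, so every residue the analyses address by
number exists. The six gating-marker Cαs are placed explicitly so the
three distances equal the requested reference values exactly. Defaults:
fenestration 12 → 6 Å (the fenestration closes on down → up), zipper
6 → 14 Å and expansion 8 → 14 Å (both open). The directions follow the
observed movements; the magnitudes are idealised several-Å separations
chosen once so that midpoint-crossing detection is well-posed.
Transitions are logistic steps of width 2 ps centred on the planted
per-chain event times (defaults 20/40/60 ps and 30/50/70 ps in a
100-frame, 1 ps/frame window) with additive i.i.d. Gaussian noise on
the distances — the simplest noise model that supports recovery
statistics. The generator enforces unzip ≤ expand ≤ close so recovery
tests are well-posed.

*Bilayer*: 120 pseudo-lipids per leaflet (one phosphate-like head bead
at z = ±thickness/2 plus optional Gaussian jitter, four tail beads), 36 Å
phosphate-plane separation and 64 Ų per lipid, emulating an
unstretched POPC membrane of the size used in atomistic channel
simulations (240 lipids).

*Pore traces*: ions placed at the centres of scheduled sites, waters
uniform in the cavity cylinder except during planted dewetting
intervals; displaced waters are parked outside the cylinder so the atom
count stays constant.

*Force systems*: ideal gas (Maxwell–Boltzmann velocities at 310 K, no
pair forces), a harmonic pair aligned with z (force recorded exactly,
f = −k(r−r₀)r̂), and a truncated Lennard-Jones fluid with exactly
recorded pairwise forces. Positions are resampled per frame; there is
no integration, because the stress machinery is agnostic to dynamics.

**What the synthetic systems do not emulate** — and hence what passing
tests do not show about real data: no physical dynamics or force-field
realism; no side chains (Cα beads only), so the min-heavy-atom distance
mode is exercised on small fixtures rather than full residues; no
lipid chemistry beyond labelled head/tail beads; no water geometry; no
protein–lipid coupling. The tests demonstrate that the *measurement*
machinery is correct against known ground truth, not that any
biological conclusion follows from a given trajectory.

## Problem sizes and external inputs

The validation suite uses deliberately modest problem sizes — e.g.
100-frame transitions over 100 replicate seeds for order recovery,
2 000 frames of a 200-particle ideal gas for the pressure checks,
50-frame jittered bilayers — chosen so the full suite and the
acceptance script each run in well under a minute of compute per check
while leaving the statistical criteria (3-standard-error bounds,
≥ 95/100 recovery) meaningful.

Two checks require inputs the package cannot generate or ship: the
down/up crystal-structure pair for the cross-sectional-area expansion
(deposited PDB entries, placed under `data/external/`), and an MD-
engine-generated POPC bilayer trajectory for the absolute thickness
check. The corresponding acceptance tests execute the full computation
when those files are present and otherwise fail with a message saying
what to supply; the underlying operations are validated on closed
forms and synthetic constructions either way.

## Known limitations

* No Harasima contour or curvature-corrected stress; many-body force
  decompositions beyond pairwise tables (e.g. protein-embedded
  profiles) are out of scope.
* No solvent-excluded-surface or alpha-shape areas — the area profile
  is a projected vdW union, which is the right object for comparing
  expansion between conformations but not a molecular surface.
* No free-energy landscapes, Markov-state models, permeation counting
  or conductance estimation.
* The composite-model building step used for gapped crystal structures
  is not reproduced; analyses that need a residue absent from the
  model raise an error naming it.
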