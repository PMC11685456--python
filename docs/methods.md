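# Methods

This note records the models implemented in `hspdyn`, the parameter defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions that affect results.

## Scientific setting

Hsp70 chaperones cycle between ADP- and ATP-bound states; a nucleotide
exchange factor (NEF) of the GrpE family accelerates ADP release by prying
open the nucleotide-binding domain (NBD). In the human mitochondrial system
— mortalin (HSPA9) with the dimeric NEF GrpEL1 — the functionally relevant
geometry changes are: an outward rotation of the NBD IIB lobe (~15° relative
to an ADP-bound bacterial DnaK reference, ~6° beyond the bacterial
DnaK–GrpE complex), bending of the GrpEL1 long α-helical stalk (~13° in the
human complex, ~26° in a bacterial one, relative to a straight predicted
dimer), several protein–protein interfaces of order 100–220 Å² buried
surface, a ~6 Å translation of the substrate-binding domain (SBD) upon
mutating a key β-wing tyrosine, and SBD angular substates sampled over
all-atom MD trajectories. `hspdyn` implements the measurements behind each
of these numbers as generic operations; it does not ship the deposited
coordinates, so the published values themselves are only reproducible after
fetching those entries.

## Superposition and RMSD

Rigid fits use the closed-form Kabsch solution via SVD of the 3×3
cross-covariance of centered, paired coordinates, with the reflection branch
corrected (`det R = +1` always). Fits are unweighted: the published domain
RMSDs are computed over backbone N, Cα, C, O subsets, and no mass or
B-factor weighting is stated anywhere, so uniform weights are the honest
choice. Degenerate inputs (< 3 points, near-collinear sets, where the
optimal rotation is not unique) raise instead of returning an arbitrary
branch.

Domain RMSD series align every frame to the reference frame (frame 0 by
default, configurable) **on the same domain selection being measured** —
this removes collective rigid-body motion so the series reports internal
flexibility only, which is how per-domain trajectory RMSD is conventionally
defined. Per-atom (anchor Cα) deviation series instead take an explicit
external alignment selection; the default in the pipeline is the full
complex backbone. The alignment context for anchor-atom deviations is a
genuine free choice — published anchor-residue RMSD plots rarely state it —
so it is a documented, configurable parameter rather than a constant.

When a trajectory is compared against a prescribed aggregate (e.g. a mean ±
sd over replicates), both pooled-frame statistics and per-replicate means
can be formed from the per-frame series; the package reports per-series mean
and sample sd and leaves pooling to the caller.

## Rotation, bend, displacement

`subdomain_rotation` superposes conformation B onto conformation A using a
stationary *align* region (for NBD-lobe work: lobes IA+IB), then quantifies
the probe region's reorientation either as the rotation magnitude of the
probe-to-probe Kabsch fit (`axis-angle`, exact for rigid probes) or as the
angle between the probes' principal axes (`helix-axis`, matching the
"inward-facing α-helix as a lever arm" style of analysis). Axis signs are
oriented from first to last residue so the angle is well defined in
[0°, 180°].

Because no publication states exact lobe or helix boundaries, the package
ships an **editable annotation file**
(`src/hspdyn/data/nbd_annotations.json`) with literature-conventional spans
transferred from the DnaK NBD fold onto mortalin author numbering. These are
starting points for real analyses, not assignments; every rotation number
depends on them and users should edit them to their own assignment.

`stalk_bend_angle` splits a helical stalk at a residue junction and returns
the angle between the proximal and distal segment axes. With an external
straight reference structure the proximal segments are superposed first and
the distal axes compared — the published way of measuring stalk bending
against a predicted straight dimer. Without a reference (`"self"`), the
inter-segment angle itself is returned; for a stalk that is straight when
unbent the two definitions coincide. Each segment must contain at least 6
residues for a stable principal axis.

`centroid_displacement` reports the distance between probe-region centroids
after alignment — the measurement behind domain-translation statements such
as an SBD shifting away from a β-wing.

## SASA, buried area, contacts

SASA is Shrake–Rupley: for each atom, the fraction of quasi-uniform sphere
points at radius `r_vdw + probe` not inside any neighbour's expanded sphere,
times the expanded-sphere area. Points come from a deterministic
golden-angle spiral lattice, so results are bit-for-bit reproducible at a
fixed point count — there is no sampling RNG. Defaults: probe 1.4 Å (water),
960 points/atom (per-atom areas converged to ~1–2 %; the test suite checks
convergence against 10 000 points), Bondi-style vdW radii with a 1.7 Å
fallback plus logged warning for unknown elements (set
`fallback_radius=None` to make unknown elements an error).

Buried surface area between disjoint selections A and B is
`SASA(A alone) + SASA(B alone) − SASA(A∪B)`. Published interface areas
rarely state which convention (total vs. per-interface half) or radii set
the reporting server used, and conventions differ by ~10–20 %; the default
here is **per-interface** (half the total), matching common interface-server
practice, and the convention tag always travels with the number.

Contacts are classified by distance only: any heavy-atom pair ≤ 4.5 Å is a
contact (vdW); pairs of N/O heavy atoms ≤ 3.5 Å are upgraded to
hbond-capable; oppositely charged side-chain groups (Arg NH1/NH2/NE,
Lys NZ, His ND1/NE2 vs. Asp OD1/OD2, Glu OE1/OE2) ≤ 4.0 Å to salt-bridge.
These are standard literature cutoffs and all configurable. No angular
hydrogen-bond criteria and no π-stacking geometry are applied — the classes
say what the distances permit, not what the electron density proves.

## Anisotropic network model

Nodes are residue Cα atoms (residues lacking Cα are dropped with a
warning; calcium ions named "CA" are excluded by element). The Hessian of
the elastic-network potential `E = (γ/2) Σ (|r_ij| − |r0_ij|)²` over pairs
within the cutoff has off-diagonal 3×3 super-elements
`−γ (r_ij r_ijᵀ)/|r_ij|²` and diagonal super-elements equal to minus the
row sum, making every block row sum to zero exactly (translational
invariance). Defaults: cutoff 10 Å, γ = 1 (arbitrary units — eigenvalues
scale linearly in γ, eigenvectors are γ-independent), 10 retained modes.
"10 modes" means 10 **non-rigid** modes, the convention of the standard ANM
packages: the six zero-frequency rigid-body modes of a connected network are
always detected (relative tolerance 1e-8 of the largest eigenvalue) and
skipped, and any count other than six raises — that is the cheapest reliable
detector of a disconnected or degenerate network. Retained eigenvectors get
a deterministic sign (first non-zero component positive) so degenerate pairs
are reproducible.

A dense symmetric eigensolver is used up to 2000 nodes; above that, a
shift-invert Lanczos solver for the smallest eigenpairs. Mode extension to
all atoms copies each residue's node vector to every atom of that residue
and re-normalises columns — a visualisation aid, not a physical refinement.
MSF and cross-correlations follow the retained-mode sums; with *all*
non-rigid modes retained they equal the Hessian pseudo-inverse exactly,
which is how the implementation is verified. No temperature or mass scaling
is applied, so MSF units are Å²·γ⁻¹ up to a constant — shapes, not absolute
B-factors. Where both conformations of a complex are available, each is
analysed separately.

## Trajectory angle analysis

Vectors are defined between anchor Cα atoms; the built-ins follow the
mortalin–GrpEL1 convention (v1: mortalin 569→597 within the SBDα lid; v2:
569→GrpEL1-B 200; v3: 569→GrpEL1-B 98). Angles are
`arccos` of the clamped normalised dot product, in [0°, 180°] (vectors are
undirected), computed at every saved frame (stride 1 by default).

Substate occupancy uses half-open bins `[lo, hi)` with the last bin closed;
frames outside the spec are counted separately so covered data always sums
to 100 %. Published substate ranges are printed with 0.1° gaps
(…–95.9°, 96°–…); `region_boundaries_from_printed` closes them at gap
midpoints (95.95°) so no frame is unassignable, and an exhaustive scan test
confirms every value inside a printed range maps back to that range.

The KDE is Gaussian with Silverman's rule-of-thumb bandwidth by default —
no kernel or bandwidth is ever stated alongside published angle-density
curves, and Silverman is the conventional default. A fixed bandwidth in
degrees is accepted instead (required for constant series, and preferable
when resolving close substates: Silverman deliberately over-smooths
multimodal data). The evaluation grid spans the data range padded by
`max(5°, 4 bandwidths)` on each side so the curve integrates to 1 within
1e-3; the fixed-bandwidth branch evaluates the kernel sum directly since a
covariance-based estimator cannot represent zero-variance data.

## Synthetic generators

The generators provide ground truth for every analysis stage without any
download: ideal α-helices (rise 1.5 Å, twist 100°, Cα radius 2.3 Å), stalks
with an exact constructed kink, structure pairs whose probe region is
rotated by an exact angle about a seeded random axis, two-chain complexes at
controlled centroid separation, and trajectories whose anchor-defined angle
follows a prescribed mixture of Gaussian angular substates (independent
draws or a Markov chain) with isotropic positional noise added afterwards.
Every generator is a pure function of its arguments including the seed; each
derives an independent RNG stream from (seed, generator-name), so adding a
generator never shifts another's output.

Default trajectory conditions used by the acceptance checks: 5000 frames,
three substates at 85/100/115° with 2/1.5/2° widths and 55/30/15 %
occupancies, 0.05 Å positional noise — sized so occupancy recovery can be
judged against 3 binomial standard deviations in well under a minute.
Dummy backbone atoms (N, C, O) sit at fixed offsets from each Cα: adequate
for selection logic, surface-area and network-model exercises, **not**
stereochemically real. The generators do not emulate force-field physics,
side chains, solvent, or the real complex's sequence; a passing recovery
test therefore demonstrates that the measurement machinery is correct, not
that any physical simulation would show these motions.

Known bias worth stating: the principal axis of a finite helical segment
deviates from the construction axis by a few tenths of a degree (the helix
phase is asymmetric unless the segment covers whole turns), so constructed
stalk bends are recovered with a systematic ≈ 0.7° offset at the 20+20
residue fixture size — within the 1° recovery tolerance, and deterministic.

## Pipeline and provenance

Analyses can be driven by a JSON config naming inputs, domain/vector
definitions and an ordered task list. Every output file carries the
config hash (computed over the config minus the output directory), the seed
and the package version; CSV values are written at 6 significant digits,
JSON at full precision; identical config + seed reproduces outputs
byte-for-byte. The run log records each task with the parameters actually
used. CLI exit codes: 0 success, 2 validation error, 1 runtime error.

## Test and acceptance problem sizes

The test suite and `scripts/acceptance.py` run entirely on synthetic
fixtures: 30–40-residue helices, 5-node finite-difference Hessians,
40-node pseudo-inverse comparisons, 10-point Kabsch clouds against a
seeded brute-force rotation search (coarse random quaternions plus
shrinking local refinement), two-sphere SASA closed forms, and 5000-frame
angle trajectories. These sizes keep the full suite and the acceptance
script in the seconds-to-minutes range while leaving every tolerance
meaningful.

## Limitations

* Deposited-structure numbers (the ~15°/~13°/~26° angles, the 108–219 Å²
  interfaces, the ~6 Å SBD shift) require fetching the published models;
  the operations are implemented and tested on constructed ground truth,
  and the NBD annotation file documents where boundary choices enter.
* No flexible/iterative-trim superposition; selections must be pre-matched
  between structures (no sequence alignment).
* SASA has no analytic derivatives and no reentrant (molecular) surface;
  contact classes are distance-only.
* The ANM is Cα-only, unweighted, temperature-free; no Gaussian (isotropic)
  network model variant.
* Binary trajectory formats (DCD/XTC) are out of scope; convert to
  multi-model PDB or XYZ first.
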