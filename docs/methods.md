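# Methods

## Data model and units

All analyses run on a single in-memory model (`MolecularSystem`): a flat
atom table, author-numbered residues (never re-indexed — published residue
numbers such as R41 or K38 must survive every table), an explicit
entity map (receptor / individual glycan chains / ligand chains), and a
stack of coordinate frames with per-frame orthorhombic boxes. Internal
units are nm and ns; PDB Å are converted at the I/O boundary. File parsing
and writing is delegated entirely to MDAnalysis.

Entity assignment is explicit configuration rather than inferred from chain
IDs, because glycan chains share chains with the protein in several common
conventions. Hydrogens, when present in the topology, participate in all
distance computations; the contact definitions below say "any atom" and
mean it. An `include`-style exclusion can be expressed through the
selection language if a hydrogen-free convention is wanted.

## Contacts and coverage

The primitive is the per-frame minimum distance from each residue of a
group to any atom of a target selection. Two backends exist — vectorised
all-pairs and a KD-tree (periodic boxes through the tree's toroidal
metric) — and are required by the test suite to agree to 1e-9 nm; the
brute-force path is the reference. Minimum-image is applied for
orthorhombic boxes only; triclinic boxes are rejected at load time rather
than silently mishandled.

Coverage uses a strict `<` at the cutoff (default 0.3 nm). The tie set is
measure-zero in floating point but the convention must be fixed for
bit-reproducibility; strict `<` is used everywhere (coverage, contact
counts, binding-event thresholds).

Contact maps between entities (default cutoff 0.6 nm) count atom *pairs*
per frame by default; counting distinct participating atoms is available
behind `count_mode="atoms"` since both conventions appear in the
literature. Replica aggregation is always the unweighted mean of
per-replica time means; unequal-length replicas are still weighted equally
and trigger a warning.

Surface distance maps report the replica-averaged time-mean minimum
distance per residue, plus a display column clamped to 0.3–1.5 nm — the
range that renders usefully as a surface colour ramp; the unclamped value
is retained alongside.

## Binding events

Association/dissociation events are detected on the ligand→receptor
min-distance series with two-threshold hysteresis: bound is entered when
the distance drops below `on_cutoff` (0.3 nm) and left when it exceeds
`off_cutoff` (0.5 nm); the gap absorbs boundary rattling. Bound and
unbound intervals shorter than `min_dwell` (1 ns) are then merged into the
surrounding state, shortest interval first (earliest on ties), interior
intervals being absorbed by their equal-state neighbours and edge
intervals flipping into their single neighbour. These thresholds are an
operational definition — spontaneous-binding studies typically report
cycles without publishing a criterion — so all three parameters are
configurable and recorded in output headers. With `off_cutoff == on_cutoff`
and zero dwell the detector degenerates to simple thresholding, which the
tests exploit.

## Mode coverage statistic

Per replica, the coverage of a binding mode is the footprint-weighted mean
of per-residue glycan contact fractions, normalised by the weight sum; the
report is the replica mean with the sample standard error
(`std(ddof=1)/√n`, the standard choice for replica ensembles; with one
replica the SE is reported as not-available rather than 0). When all
replicas produce bitwise-identical values the SE is returned as exactly 0
rather than the ~1e-17 round-off that naive mean-subtraction yields — the
planted-ground-truth tests assert exact zero.

Footprint weights are an input artifact (TSV: `mode, residue_id, weight`):
the per-residue ligand-contact weights of a published binding mode come
from whatever study characterised that mode, and are not something this
package can derive. The bundled `footprints_cd44.tsv` contains binary
*membership* lists for the CD44 hyaluronan-binding domain assembled from
the residue sets named in the accompanying analyses, and is labelled as
such; it demonstrates the machinery and defines the toy scenario's modes.
A missing footprint residue in a replica's coverage is an error, never a
silent zero — in practice it means the group selection was wrong.

Replicas are flat: a 3-starting-configurations × 5-replicas design is
treated as 15 equal replicas. Grouping by starting configuration instead
changes only the SE bookkeeping and can be done by calling `mode_coverage`
per group.

## Surface areas

SASA is Shrake–Rupley from first principles: each atom's van der Waals
sphere (bundled Bondi-by-element table, in nm) is expanded by the probe
radius (0.14 nm water), `n_points` quasi-uniform test points are placed on
it by a deterministic golden-section spiral (seedless, hence bit-stable
tests), and a point is accessible iff it lies strictly outside every other
expanded sphere. 960 points give ~0.03 % error on an isolated sphere and
<1 % against the analytic two-sphere cap formula. Exactly coincident
equal spheres are a degenerate case where the point test is numerically
undefined; the lowest-index sphere owns the surface and the duplicates
report zero, so the total remains one sphere's area. Results from other
SASA tools will differ slightly wherever their radii tables differ;
absolute agreement with any specific tool's numbers is not claimed.

Buried interface between disjoint parts A and B is
`(SASA(A alone) + SASA(B alone) − SASA(A∪B))/2` with the partner's atoms
fully removed in the "alone" terms; the un-halved total is available by
flag since both conventions are in use. Replica interface reports default
to the final frame (the end-state convention for spontaneous-binding
trajectories); a frame window average is available through `at=`. Waters
and ions are simply never selected.

## NMR titration analysis

Combined CSP is `√(ΔδH² + (w·ΔδN)²)` with `w = 0.2`, the conventional
nitrogen scaling for backbone amides; `w` is configurable and recorded in
outputs. The minimal-shift profile matches each free peak to its nearest
bound peak over the whole observed pool (primary + doubled + unassigned
peaks), yielding a guaranteed lower bound on the true perturbation — the
dominance `minimal ≤ assigned` is asserted property-style in the tests.

Titration classification operationalises categories that spectroscopists
traditionally call by eye, so the thresholds are explicit and logged:
a signal is *disappeared* when its intensity at the first titration point
falls below `f_gone = 0.1` of the free intensity; *instant* when the
first-point CSP reaches `f_inst = 0.8` of the final CSP (final CSP above a
`floor = 0.02` ppm); *gradual* when perturbed but not instant; doubled
peaks are flagged from the secondary peak slot. Instant vs gradual maps
1:1 onto strong (sub-µM) vs weak (>10 µM) interaction labels; no Kd
fitting is attempted or implied.

## Synthetic ground truth

The generator plants answers by construction, not by simulating physics:

* Receptor residues sit on a rigid planar lattice (1.2 nm spacing,
  default 150 residues numbered 20–169 with small per-residue atom
  clusters), glycan chains attach at the five glycosylation-site positions
  (25, 57, 100, 110, 120), and the ligand approaches from the opposite
  face — so a planted contact can only ever touch its intended residue at
  the 0.3/0.6 nm cutoffs.
* Occlusion of residue *r* at fraction *p* is planted by moving a dedicated
  glycan bead to 0.25 nm above that residue's centre in a seeded random
  subset of exactly `round(p·n_frames)` frames, parked >0.75 nm away
  otherwise. Contact fractions are therefore *exact*, which is what lets
  acceptance tests assert equality rather than tolerance. Default planted
  fractions put the heaviest occlusion on the canonical-groove residues,
  intermediate on the flanking arginines, lightest on the upright patch.
* The ligand follows a scripted bound/unbound schedule (bound = 0.25 nm
  from epitope residues, unbound = 3 nm away), so event detection has an
  exact expected answer.
* Identical scenarios re-run with offset seeds give replicas whose planted
  fractions are identical (different frame subsets), making the expected
  replica SE exactly zero — a sharp test of the SE bookkeeping.

What this deliberately does **not** emulate: glycan polymer dynamics and
conformer sampling, glycan–glycan interlocking (inter-glycan contact maps
on toy data are legitimately zero), partial/graded residue burial,
correlated occlusion between neighbouring residues, and force-field
physics of any kind. Passing the planted-recovery tests certifies the
*bookkeeping* — distances, counting, weighting, replica statistics — not
the realism of any simulation. Analyses of real trajectories inherit all
caveats of those trajectories.

The titration generator likewise plants categories: instant responses get
their full perturbation from the first point, gradual ones scale with
ratio/max-ratio, disappearances zero the intensity, doubled residues gain
a secondary peak; optional Gaussian noise is added to every shift. At zero
noise the classifier must recover 100 % of planted categories; with noise
approaching the perturbation floor, recovery is no longer guaranteed and
the generator warns.

## Problem sizes and determinism

The acceptance script runs the toy study at 15 replicas × 1000 frames
(~500 atoms), 100 random systems for backend equivalence, 960-point SASA
fixtures, and a 150-residue titration — sizes chosen so the whole
recomputation completes in well under a minute per stage while still
exercising the full study structure. All randomness flows from explicit
seeds (`numpy.random.default_rng`); sphere points are seedless and
deterministic; reruns of any CLI command with identical config and inputs
produce byte-identical primary outputs.

## Known limitations

* Triclinic periodic boxes are not supported (rejected, not approximated).
* The SASA implementation is sphere-sampling only; no Lee–Richards slices,
  no curvature weighting.
* Footprint weights bundled here are binary membership stand-ins, not the
  original published per-residue contact weights.
* The binding-event criterion, CSP classification thresholds, and the
  nitrogen weight are conventions, not fitted quantities; conclusions that
  hinge on them should be checked for threshold sensitivity (the API makes
  this a one-argument change).
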