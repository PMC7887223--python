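# Methods

`oligosym` quantifies the geometry and dynamics of homopentameric
ligand-gated ion channels (pLGICs): how wide the ion pore is and where it
constricts, how subunits rearrange between conformations, how often each
ring arrangement of subunit states occurs after cryo-EM symmetry expansion,
and how ions and waters behave in MD trajectories of the channel.  This note
records the models, conventions and numerical choices behind each stage, and
what the synthetic ground-truth suite does and does not demonstrate.

## Structural model and conventions

Coordinates are read and written through gemmi; author chain ids and author
residue numbering are preserved throughout, so residue labels match the ones
printed in structural work on the 5-HT3A receptor (e.g. the 9′ gate residue
L260, the M4/MA tryptophan W426).  Alternate locations collapse to a single
conformer: highest occupancy wins, ties break toward altloc A — a
deterministic single-conformer geometry.  Waters and hetero residues are
excluded from selections unless requested.  The default van der Waals set is
a HOLE-like "simple" table (C 1.85, N 1.75, O 1.65, S 2.00, P 2.10,
H 1.00 Å; fallback 2.00 Å for unknown elements) and is configurable per
call; hydrogens are excluded from pore calculations by default.

Orientation conventions, used consistently everywhere: the pore axis points
toward the extracellular side; a positive twist is counter-clockwise viewed
from the extracellular side (right-hand rule about the axis); helix axes are
oriented N→C; ring positions 0–4 increase counter-clockwise viewed from the
extracellular side.  Because deposited models do not state the chain-id ↔
ring-position convention, the toolkit records its own and the mapping is
explicit wherever it matters.

## Pore profiling (maximal sphere)

At each plane perpendicular to the pore axis the profiler maximizes the
clearance f(p) = min_i(‖p − x_i‖ − vdw_i) over points p in the plane; R(S)
= f(p*) is the radius of the largest sphere centred in that plane touching
no atom — the same quantity HOLE computes.  Numerics:

* plane spacing 0.25 Å (0.5 Å in the fast test configuration); Nelder–Mead
  maximization from the neighbouring plane's centre plus 16 deterministic
  pseudo-random restarts (seeded; fixed seed ⇒ bitwise-identical output);
* the track is confined to a disc of radius 2.5 Å around the previous
  plane's centre and 12 Å around the axis.  A wide per-plane search disc is
  unusable here: outside a tapering wall of atoms the clearance grows
  without bound, so an unconstrained plane-wise maximum jumps from the pore
  lumen to the channel exterior (observable on an hourglass fixture).  The
  small tracking disc is what makes the plane-wise maximum mean "the pore";
  it also matches the convergence rule, which flags any sample whose centre
  jumps more than 1 Å from its neighbour;
* the sweep runs up the axis and back down, keeping the per-plane best —
  this resolves hourglass entrapment, where a downhill track started on one
  side cannot reach the wide chamber on the other;
* clearances above 15 Å are capped and the sample flagged as open bulk.

The constriction is the converged sample of minimal radius (ties break
toward the smaller axial coordinate); its lining residues are those of the
atoms realizing, or within 0.5 Å of, the minimal clearance.  Samples are
classified into conductance bands — sub-conductive < 1.8 Å, intermediate
1.8–3.3 Å (closed on the left), wide > 3.3 Å — and against the radius of a
hydrated sodium ion, 2.76 Å.  For trajectories the profile is computed per
frame and summarised as mean ± sd per plane.

Tests verify the profiler against an exhaustive 0.1 Å-lattice grid search
(agreement within 0.05 Å on tube fixtures of ≤ 2000 atoms), against the
analytic clearance of a cylinder (a − vdw), and for monotonicity under atom
deletion, determinism and rigid invariance.

## Rigid-body comparison

Superposition is the closed-form least-squares (Kabsch) solution via SVD,
with the reflection guard ensuring a proper rotation.  Probe displacements
between two conformations are always measured in an explicit alignment
frame (the printed value depends on it); the deposited-model reproduction
scans the plausible frames — same-subunit ECD, whole-pentamer ECD, whole
pentamer — and reports each.  "Backbone" means N, Cα, C, O.  Helix tilt is
the angle between principal axes of the Cα clouds, oriented N→C, reported
raw in [0°, 180°); for matched helices the acute supplement is what a
structural description quotes.  The twist of a rotation about the pore axis
is extracted by swing–twist decomposition of the quaternion.  The pore axis
of a pentamer is the least-squares line through per-residue ring centroids
(the centroid of the five chains' Cα at each shared residue number), which
is exact for an ideal C5 ring and degrades gracefully under asymmetry.
TMD thickness is the difference of the mean axial coordinates of two Cα
rings (residues 221 and 426 in the receptor's numbering).

The inter-subunit deviation matrix maps chain j onto chain i's ring position
by the ideal cyclic rotation about the estimated pore axis (both handedness
signs are tried, the smaller RMSD kept) with no further fitting.  Plain
pairwise superposition RMSD is also available, but for subunits that differ
by rigid rearrangements it is identically zero and blind to the arrangement
asymmetry the matrix is meant to expose; the C5-frame definition is what
separates a "major rotation / minor shift" group from a "minor rotation /
major shift" group as a two-block structure.

## Ring-configuration statistics

After symmetry expansion each particle carries five class labels in ring
order; the starting subunit is arbitrary, so arrangements are identified up
to cyclic rotation only.  Reflections are *not* identified — a subunit ring
embedded in a membrane is chiral — and with a binary more/less-open (M/L)
alphabet this yields exactly 8 classes on a pentamer (the dihedral count
would be smaller).  The canonical form is the lexicographically smallest
rotation under plain byte-order label comparison.  Enumeration is by brute
force over k⁵ tuples; tests check the count against the Burnside necklace
formula (1/n) Σ_{d|n} φ(d) k^{n/d} for k ≤ 6, n ≤ 7 and orbit equivalence
exhaustively for k ≤ 3.  A ring's asymmetry score is the *sum* of
per-subunit deviation values (a user-supplied label → deviation scale, e.g.
backbone RMSD of each monomer class to the symmetric reference); the sum is
rotation-invariant, and mean-vs-sum only changes the scale by 5.  An
arrangement of a target label is "consecutive" when its positions form one
contiguous arc (the arc may wrap the ring seam), classified by counting
target → non-target transitions around the ring; counts of 0, 1 and 5 are
degenerate.  Raw classification classes (e.g. 16 3D classes) are collapsed
to groups through a user-supplied map which must cover every label present.

## Trajectory analyses

Trajectories carry per-frame coordinates for protein, ions and waters
(water ≡ its oxygen), a frame spacing and the pore axis.  Permeation events
are detected by a per-ion three-state machine over the axial coordinate: an
event is one ion entering an axial slab through one boundary and exiting
through the other, with any dwell time; same-side re-exit records nothing,
and a step jumping clear across the slab counts.  The default slab is the
axial span of the transmembrane domain, symmetric about its midpoint, with
no minimum dwell (at 0.2 ns frame spacing a 2–3 ns traversal is well
sampled).  Event lists are exactly time-reversal symmetric (directions flip)
and invariant to subsampling that keeps at least one frame per boundary
crossing.

Water counts near a residue selection count oxygens within a cutoff
(default 4 Å) of *any* atom of the named residues across all chains;
whether "near residue X" means its Cα or the whole residue is a
configuration choice, defaulting to the whole residue.  RMSF superposes
every frame onto the running mean structure (two passes) using a fit
selection, then takes per-atom root-mean-square deviations; the fit makes
the result invariant under global rigid motion, and for iid Gaussian jitter
of σ per axis the closed form √3·σ is recovered to better than 0.05 Å at
5000 frames once the fitted six degrees of freedom are negligible (≳100
atoms).  Production analyses default to the final quarter of frames (the
stabilised window) and backbone-RMSD time series exclude a configurable
residue range defaulting to 309–334, the amphipathic MX helices whose
disordered linkers make them uninformative.

Helix bend profiles smooth the Cα trace with a 4-point moving average (one
helical turn) before fitting window principal axes — without smoothing an
ideal helix shows ~3° of spurious phase wobble at window 7, with it < 0.5°
— and report the angle between the axes of the windows either side of each
residue; the kink is the argmax (ties toward the smaller residue number).
The pore-lining helix bundle is classified by comparing mean ring radii of
the extracellular and intracellular helix ends: 'A' when the top is
narrower by more than δ = 1 Å, 'V' when the bottom is, 'H' otherwise.

## Synthetic ground truth

The generator emulates the study conditions at desk scale:

* **Pentamer**: five subunits of four ideal α-helices (rise 1.5 Å, 100°
  per residue, Cα circle radius 2.3 Å, 27 residues ⇒ 39 Å span, matching a
  lipid-embedded TMD) in exact C5 symmetry about z, Cα-only with an
  effective 2.3 Å pseudo-atom radius; helix axis distances 12/8/12/16 Å
  from the pore with the pore-lining helix innermost, first residues
  221/251/281/311 shared across chains.  Every geometric measure in scope
  is Cα- or clearance-based, so Cα-only models suffice.
* **Subunit modes**: per-chain rigid perturbations — a twist about the
  subunit's own vertical bundle axis plus a radial shift — defaulting to
  the two reported rearrangement modes: major rotation / minor shift
  (12°, 0.5 Å) for chains A/C and minor rotation / major shift (3°, 2 Å)
  for B/D/E.  Ground-truth transforms are returned for recovery tests.
* **Class tables**: particles drawn from a declared canonical-configuration
  distribution, uniformly ring-rotated (the starting subunit of an expanded
  particle is arbitrary), then optionally label-confused row-stochastically.
  The default binary distribution puts 24 % on the consensus two-
  non-consecutive-M arrangement — the one externally reported population —
  and spreads the remainder so that non-consecutive arrangements outweigh
  consecutive ones at equal M count, the reported qualitative pattern; the
  seven individual weights are package choices, not reported values.  A
  two-state 61/39 mixture helper mirrors the symmetric/asymmetric particle
  split.  The deviation-scale default is a monotone stand-in for the
  reported monomer-class ranking A < E < C < D < B.
* **Trajectories**: each planned slab crossing gets its own ion and time
  window — reservoir random walk, then a noisy but strictly monotone
  traversal (monotonicity by cumulative maximum ⇒ the planned crossing
  count is exact by construction, not by tuning), then the far reservoir.
  Aborted entries penetrate at most half-way and are clamped to one side of
  the far boundary.  Defaults: 1000 frames × 0.2 ns (a 200 ns run), slab
  ±20 Å, 2 up + 2 down crossings of ~2.4 ns each plus 6 aborted entries,
  0.5 Å path noise.  In-range waters are placed within the cutoff of the
  gate ring at a Poisson rate (λ = 3/frame) with background waters parked
  in bulk.  Random streams are per-purpose sub-seeded so adding a consumer
  never shifts another stream; a fixed spec is bitwise reproducible.

What passing on synthetic data shows — and does not.  The generator's
pentamers are rigid Cα skeletons: recovery of twists/shifts to 0.2°/0.05 Å
demonstrates the measurement chain, not robustness to internal backbone
strain, side-chain rotamers or coordinate error, all present in real
models.  Its trajectories have no physics: crossings are planted, so exact
event recovery validates the detector's bookkeeping, not sampling adequacy
of rare permeations in a real 200 ns simulation.  Class tables draw iid
particles; real classification errors are correlated with particle quality.
The deposited-model tier exists precisely to close part of this gap and
runs whenever local copies of the six entries are supplied.

## Problem sizes

Defaults used by the analysis scripts and the acceptance script: tube
fixtures of ~1200 atoms profiled at 0.5 Å spacing with 8 restarts; 20,000
particles per class table; 1000-frame trajectories; 5000 frames × 150 atoms
for the RMSF closed form.  These sizes give binomial/Poisson errors well
inside every stated tolerance.

## Known limitations

* The profiler reports the plane-constrained maximal sphere, as HOLE does;
  for strongly tilted or branched channels a curved-centerline method would
  differ near sharp kinks.
* `estimate_pore_axis` assumes five chains with matched numbering; heavily
  diverged ring positions bias the centroid line.
* The deposited-model measurements depend on the superposition frame; the
  frame scan reports all candidates rather than asserting one convention.
* No electrostatics, free energy or conductance prediction anywhere: pore
  geometry and event counting only.
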