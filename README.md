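# oligosym

Quantitative analysis of homopentameric ligand-gated ion-channel (pLGIC)
structures and simulations: HOLE-style pore-radius profiling, rigid-body
comparison of conformations, ring-configuration (necklace) statistics for
cryo-EM symmetry-expansion output, and MD-trajectory hydration/permeation
analyses — with a seeded synthetic-data generator so the entire pipeline
runs end to end with known ground truth and no downloads.

It is written for structural biologists and simulators working on receptors
such as the 5-HT3A serotonin receptor: five identical subunits around a
central ion pore, an extracellular domain (ECD) that binds agonist and a
four-helix transmembrane domain (TMD, helices M1–M4 with the pore lined by
M2) that opens asymmetrically.

## What it computes

**Pore profile.** At each plane perpendicular to the pore axis the largest
sphere centred in that plane touching no atom:

    R(S) = max_p  min_i ( ‖p − x_i‖ − vdw_i ),   p in the plane at S,

found by seeded multi-start local optimization tracked along the axis with
an up-and-down sweep.  The constriction (minimum R, with lining residues)
and conductance bands (< 1.8 Å sub-conductive, 1.8–3.3 Å intermediate,
> 3.3 Å wide; hydrated Na⁺ radius 2.76 Å) follow from the profile.

**Rigid-body measurements.** Kabsch superposition and RMSD; probe-atom
displacements in an explicit alignment frame; helix tilts from principal
axes; the twist component of a rotation about the pore axis (swing–twist
decomposition); TMD thickness between two Cα rings; and an inter-subunit
deviation matrix in the ideal-C5 frame whose block structure separates
subunit rearrangement modes.

**Ring configurations.** Symmetry-expanded particles carry five class
labels in ring order; arrangements are identified up to cyclic rotation
(no reflections — the ring is chiral).  Canonical forms, necklace counts
(8 binary pentamer classes, matching Burnside's (1/n) Σ φ(d) k^{n/d}),
population tallies, rotation-invariant asymmetry scores, and
consecutive/non-consecutive arrangement classification.

**Trajectories.** Water counts near the gate residues, ion permeation
events via a per-ion slab state machine, RMSF about the superposed mean
structure, helix bend/kink profiles, and A/H/V classification of the
pore-lining helix bundle.

## Worked example

```sh
python analysis/01_build_models.py
python analysis/02_compare_conformations.py
```

builds an ideal C5 pentamer and its asymmetric counterpart (subunits A/C
perturbed by a major-rotation/minor-shift mode, B/D/E by a
minor-rotation/major-shift mode) and recovers the modes by superposition:

```
chain A: twist  +12.0 deg, shift  0.50 A
chain B: twist   +3.0 deg, shift  2.00 A
chain C: twist  +12.0 deg, shift  0.50 A
chain D: twist   +3.0 deg, shift  2.00 A
chain E: twist   +3.0 deg, shift  2.00 A
deviation matrix: within-mode max 0.35 A, between-mode min 1.46 A -> two-block structure confirmed
TMD thickness (rings 221-247): 39.0 A
```

Each chain's planted twist and shift is recovered exactly, and the
deviation matrix splits the five subunits into the two rearrangement
groups.  Continuing with `analysis/03_pore_profiles.py` through
`analysis/05_trajectory_permeation.py`:

```
pentamer_c5: min diameter 6.80 A at S=+15.0 (lining A/274, D/274, C/274); 73/73 samples pass a hydrated Na+
cylinder control: mean radius 8.150 A (analytic 10 - 1.85 = 8.150)
most prevalent: LLMLM at 23.8 % (non_consecutive more-open subunits)
  2 more-open subunits: non-consecutive 23.8 % vs consecutive 9.7 %
1000 frames x 0.2 ns, slab (-20.0, 20.0) A: 4 permeation events detected (4 planned)
waters within 4.0 A of the gate ring: mean 2.87 per frame (drawn at Poisson rate 3.0)
```

— the profiler reproduces the analytic cylinder clearance, the tally
recovers the drawn configuration populations with the non-consecutive
arrangements outnumbering consecutive ones, and the permeation detector
finds exactly the planted crossings.

The same stages are scriptable through the CLI:
`oligosym pore|compare|tally|traj|simulate|defaults|repro` (see
`oligosym --help`; `oligosym repro` recomputes the deposited-model
measurement table from local coordinate files).

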