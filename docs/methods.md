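# Methods

This note documents the models and numerical choices behind dimergate:
what each statistic measures, how the synthetic trajectory generator is
built, which parameters matter, and what the synthetic tests do and do
not establish about real data.

## The system and the statistics

dimergate targets homodimeric membrane transporters of the BtuCD type:
two sequence-identical transmembrane subunits (TMD) forming the
substrate translocation pathway, and two nucleotide-binding subunits
(NBD) beneath them, the whole assembly two-fold symmetric about the
membrane normal at rest. Conformational transitions between the
outward-facing (O) and inward-facing (I) states involve (i) a rigid-body
"spin" of the NBD dimer against the TMD dimer, (ii) opening/closing of
the periplasmic and cytoplasmic gates of the pore, and (iii) possible
transient breaking of the two-fold symmetry.

### Spin angle

For a frame of Cα coordinates, the reference structure's TMD dimer is
least-squares superposed (Kabsch, proper rotations only, unweighted)
onto the frame's TMD Cα set, and the reference NBD dimer onto the
frame's NBD set. Each overlap carries the reference subunit mass
centers into the frame; the spin angle is the angle between the line
connecting the two transported TMD centers and the line connecting the
two NBD centers. By default both lines are projected onto the membrane
plane before the angle is taken, so the statistic isolates rotation
about the transporter's quasi-two-fold axis; `project=False` gives the
raw 3D angle.

The projection normal is *not* the fixed laboratory z axis: the
reference normal (z of the pre-oriented input, overridable) is carried
through the TMD-overlap rotation, i.e. the membrane plane is attached
to the TMD. This makes the projected angle exactly invariant under any
global rigid motion of the frame, which a lab-fixed normal would
violate. Angles are reported in [0°, 180°) with the half-1 → half-2
center direction fixing the line orientations; a signed variant (sign
from the normal) is available for continuity across frames.

### Symmetry-breaking statistics

A residue pair (i, j) is selected when its Cα distance is strictly
below the cutoff d0 (default 8 Å) in the reference structure, and both
symmetry partners i′, j′ (the same-numbered residues of the paired
chain) are mapped. The pair set is selected once and held fixed along a
trajectory. Pairs are labelled by region class: within-TMD, within-NBD,
TMD–NBD interface, and the two cross-half interfaces TMD–TMD′ and
NBD–NBD′. A pair and its symmetry image are distinct entries when both
meet the cutoff; `deduplicate=True` keeps one representative per image
pair instead (both conventions exist because printed pair counts in the
literature do not always state which was used).

Per frame, each pair contributes |d_ij − d_i′j′|, a superposition-free
internal-coordinate quantity that vanishes identically for a two-fold
symmetric structure. The asymmetry coefficient C_asymm aggregates it
over the pair set; both the mean-absolute form (default) and the
root-mean-square form are implemented, and the mean-absolute value
never exceeds the RMS value (Jensen). Along a trajectory, the per-pair
coefficient A_ij is the quadratic mean of |d_ij − d_i′j′| over frames
(reducing to the per-frame value for a single frame, so static
structures use the same code path). Pairs with A_ij above a threshold
(default 0.8 Å) are flagged as asymmetric residue pairs (ARPs) and
summarized per region class; a separate display histogram bins all
pairs at the 0.5/1.0/2.0 Å tier edges.

### Channel geometry

`pore_profile` re-implements the maximal-inscribed-sphere idea of HOLE:
at each z along the channel axis, maximize over in-plane centers c the
clearance min_a(‖(c, z) − x_a‖ − r_a) with r_a the atom's van der Waals
radius. The optimizer is a multi-start compass (pattern) search — the
previous slice's optimum plus four jittered starts, step halving from
1 Å down to 0.01 Å — which an exhaustive 0.05 Å grid oracle validates
at test scale. Because the clearance grows without bound outside the
structure, a slice whose optimum exceeds the escape cap (default 10 Å)
is reported capped, not as an error; the cap doubles as the search's
termination criterion. Atoms within 0.1 Å of the binding clearance are
reported as the slice's lining residues. vdW radii come from a bundled
per-element table (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20, P 1.80 Å,
default 1.70), overridable per call.

Gate layers are z-slabs named after a lining residue: the window is
either explicit or centered at the mean z of the residue's two partner
Cα atoms in the reference frame with a ±2 Å default half-width.
`layer_radius_series` reports the minimum profile radius inside the
window per frame. `dpair_series` is the plain Euclidean distance
between the two symmetry-equivalent Cα atoms of a residue (no
superposition); `delta_dpair` its absolute difference between two end
states; `min_residue_distance_series` the minimal heavy-atom contact
distance between two residues (hydrogens excluded).

## The synthetic generator

The generator exists to give every statistic a labelled input: exact
symmetry nulls, constructed rotations, injections of known location and
amplitude, and steered transitions whose schedule is the ground truth.

**Geometry.** Four chains of 40 beads (Cα-like, r = 1.7 Å): two
TMD-role chains stacked as partial rings around z (10 levels, 2 Å
apart), two NBD-role chains packed as quasi-uniform balls below the
channel. Half 2 is the exact 180° rotation of half 1 about z in both
end states, so C_asymm = 0 to machine precision at rest. In state O the
wall radius widens linearly from 4.5 Å at the bottom (cytoplasmic gate)
to 8.0 Å at the top (periplasmic gate) — pore radii ≈2.8 and ≈6.3 Å
after the bead radius, the occluded/open scale reported for BtuCD-type
channels — and state I reverses the profile. The NBD dimer axis sits at
30° from the TMD dimer axis in state O and 38° in state I, so a steered
O→I run sweeps the spin angle over the range such transporters show.
The seed only jitters the NBD bead packing (identically in both
halves); the same seed is bitwise reproducible.

**Elastic network.** Single-cutoff (7 Å) harmonic springs over the
union of contacts of the two end states; equilibrium lengths are taken
from the run's start state. The network is deliberately soft
(k_spring = 0.02 reduced units): it preserves local shape against the
thermal noise but does not encode two basins — the steering target
supplies the second state. Connectivity is verified at build time.

**Steering potential.** U(t) = k/(2N) · (rmsd(t) − rmsd*(t))², with
rmsd(t) the best-fit RMSD of the current coordinates to the target and
rmsd*(t) a preset, monotonically non-increasing schedule starting at
the best-fit RMSD between the end states (clamped, with a warning, if
configured larger) and ending at 0. Forces are the exact gradient at
the optimal fit: the target is superposed onto the frame each step, and
by the envelope argument the gradient through the optimal rotation
vanishes, so the per-bead force is −(k/N)(rmsd − rmsd*)(x_i − y_i)/(N·rmsd)
with y the fitted target. Centroid matching makes the forces sum to
zero exactly; finite differences confirm the gradient to 1e-5 relative.
At rmsd = 0 the direction is undefined and forces are set to zero.

The default run schedule uses k = 3N² rather than a literature value:
only the per-bead restraint stiffness k/N² is meaningful at toy scale,
and 3 per Å² dominates the network stiffness (k_spring × mean degree
≈ 0.6) enough that the run tracks its schedule to ≈0.15 Å RMS and ends
≈0.13 Å from the target. `steering_energy` accepts any k, in the
kcal/mol/Å² convention, passed through as-is.

**Dynamics.** Overdamped (position) Langevin: x ← x + (dt/γ)F + ξ with
dt = 0.01, friction γ = 1, and ξ Gaussian with variance 2·kT·dt/γ at
kT = 0.01 (all reduced units), scaled by the `temperature_factor`.
A run whose rmsd to target exceeds twice its initial value (floored at
1 Å so null runs can fluctuate) aborts with an instability error
advising a smaller step or larger friction. k = 0 contributes exactly
zero steering force, so such a run is bitwise identical to an unsteered
integration of the same random stream.

**Gate ordering.** A two-state toy steered on global RMSD does not, by
itself, reproduce the event ordering of a real transporter: the path
linearly interpolates/rotates and both gates change together. The
preset therefore stiffens the elastic contacts inside the start state's
occluded gate layer (600× base stiffness) and lets each such contact
rupture irreversibly once stretched beyond 0.3 Å — a minimal model of
the tightly packed hydrophobic constriction that holds a closed gate
shut until the surrounding transition has progressed. The open gate
closes on schedule while the occluded gate resists and then snaps,
producing a window of frames in which both gate-layer pore radii lie at
or below both end-state minima: the double-occluded intermediate. Set
`gate_stiffen=1` for the plain network.

**Injection.** `inject_asymmetry` displaces named residues of one half
along reproducible random unit directions by a fixed amplitude (static)
or linearly growing across frames. Because the statistics are built
from internal distances of a fixed pair set, a static injection flags
exactly the pairs touching the injected residues or their symmetry
images, which the recovery tests exploit; amplitude 0 is the identity.

## What the synthetic tests do and do not show

The generator provides exact nulls and constructed signals, so passing
tests establish the *correctness of the statistics* (selection rules,
invariances, closed forms, recovery of known perturbations) and the
*internal consistency of the steering simulator* (gradient, tracking,
determinism). They do not establish anything about BtuCD energetics:
the elastic network is single-basin and soft, the gate-rupture model is
phenomenological, timescales are schedule-imposed, and there is no
membrane, solvent, or sequence. Quantitative claims about real
structures require the accession checks (`scripts/accession_checks.py`,
network required), which recompute pair counts, C_asymm, static ARPs
and the spin angle directly from deposited coordinates.

## Numerical choices and edge cases

- Kabsch uses SVD with the determinant sign correction (no mirrors);
  near-collinear point sets raise a conditioning error since the
  in-line rotation is undefined. RMSD is unweighted.
- Pair cutoff is strict (< d0); the KD-tree candidate query is ≤ and is
  post-filtered.
- The pore optimizer's multi-starts are deterministic (previous center
  ± 1 Å diagonal offsets), keeping profiles reproducible without a seed.
- PDB I/O goes through gemmi; a validation pre-pass reports unparseable
  coordinate fields with their line number. Altloc blank/'A' kept,
  others dropped; insertion-coded residues stay distinct; numbering is
  never changed. Coordinates round-trip at PDB precision (3 decimals).
- Trajectories are multi-model PDB; every model must contain the full
  analysis selection or the reader names the offending model and atom.
- Problem sizes in the test suite and acceptance script (160-bead toy,
  3000-step runs, ≤24-atom-per-ring pore oracles) were chosen as the
  smallest systems that exercise every code path with comfortable
  statistical margins.

## Known limitations

- The homodimer map pairs same-numbered residues of paired chains; it
  does not do sequence alignment, so engineered constructs with shifted
  numbering need pre-renumbered inputs.
- Pore profiles assume a pre-oriented channel axis (or an explicit
  axis); there is no automatic axis detection.
- The layer/pore machinery treats each slice independently; strongly
  tilted or branched channels are outside its scope, as in the original
  maximal-inscribed-sphere method.
- Heavy-atom contact distances require an all-atom trajectory; the toy
  generator emits Cα-like beads only.
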