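# dimergate

Gating geometry and symmetry-breaking analysis for homodimeric membrane
transporters, plus a coarse-grained targeted-steering trajectory
generator for exercising the analyses with known ground truth.

## What it is for

ABC importers of the BtuCD type are two-fold symmetric: two identical
transmembrane subunits (TMD) enclose the substrate translocation
pathway and two nucleotide-binding subunits (NBD) drive it. Their
transport cycle alternates between outward-facing (O) and inward-facing
(I) conformations, and the interesting questions about a transition
trajectory are geometric ones: how far has the NBD dimer *spun* against
the TMD dimer, which *gate* of the pore is open at each moment, and
does the transition *break the two-fold symmetry*? dimergate computes
these quantities from structures and trajectories (PDB / multi-model
PDB), for structural biologists and simulators analyzing such systems.

The statistics at the core:

- **Spin angle** — superpose the reference TMD dimer onto a frame's TMD
  Cα set and the reference NBD dimer onto its NBD set; the angle between
  the lines connecting the transported subunit mass centers (projected
  onto the membrane plane) measures the relative rotation of the two
  dimers about the quasi-C₂ axis.
- **C_asymm** — for residue pairs (i, j) with Cα distance d_ij < d₀
  (default 8 Å) and symmetry partners (i′, j′) in the opposite half,
  aggregate |d_ij − d_i′j′| over the pair set (mean-absolute by default,
  RMS optional). Zero iff the structure is exactly two-fold symmetric.
- **A_ij / ARPs** — per pair, the quadratic mean of |d_ij − d_i′j′|
  along a trajectory; pairs with A_ij > 0.8 Å are *asymmetric residue
  pairs*, located by region (within-TMD, within-NBD, interfaces).
- **Pore geometry** — maximal-inscribed-sphere pore-radius profiles
  along the channel axis (HOLE-style, re-implemented with a grid-oracle
  validated optimizer), per-layer gate radii, symmetry-pair distances
  d_pair and minimal inter-residue contact distances.
- **Targeted steering simulator** — a four-chain elastic-network toy
  homodimer with exactly symmetric O and I end states, evolved by
  overdamped Langevin dynamics under the steering potential
  U = k/(2N)·(rmsd(t) − rmsd*(t))² with a monotone target schedule
  rmsd*(t); supports asymmetry injection of known location/amplitude.

## Worked example

```python
import numpy as np
from dimergate import (build_toy_homodimer, run_steered, select_pairs,
                       casymm_series, spin_angle_series, layer_radius_series)

dimer = build_toy_homodimer(seed=1)          # symmetric O/I end states
structure = dimer.as_structure("O")
selection = dimer.selection()
hmap = dimer.homodimer_map()

pairs = select_pairs(structure, selection, hmap, d0=8.0)
steered = run_steered(dimer, "O", seed=2)    # steered O -> I transition

_, angles = spin_angle_series(steered.trajectory, structure, hmap)
c = casymm_series(steered.trajectory, pairs)
layers = dimer.gate_layers()
cyto = layer_radius_series(steered.trajectory, layers["cytoplasmic"],
                           reference=structure, step=0.5)
peri = layer_radius_series(steered.trajectory, layers["periplasmic"],
                           reference=structure, step=0.5)
```

prints (via the obvious `print` lines):

```
symmetry pairs (d0=8 A): 2449
  by region: {'TMD': 552, "TMD-TMD'": 144, 'TMD-NBD': 192, 'NBD': 1560, "NBD-NBD'": 1}
schedule tracking RMS: 0.152 A, final RMSD to target: 0.130 A
spin angle: 29.9 deg -> 37.9 deg
C_asymm: start 0.000 A, peak 0.277 A, end 0.108 A
cytoplasmic gate radius: 2.80 -> 4.63 A
periplasmic gate radius: 5.98 -> 2.88 A
double-occluded frames: 6 of 101
```

Reading it: the steered run tracks its RMSD schedule to ≈0.15 Å and
arrives ≈0.13 Å from the target state. Along the way the NBD dimer
spins from 30° to 38°, C_asymm rises from its exact-symmetry null only
to thermal-motion levels (the O→I transition stays essentially
symmetric), the periplasmic gate closes (6.0 → 2.9 Å pore radius) while
the cytoplasmic gate opens (2.8 → 4.6 Å) — and 6 frames in the middle
have *both* gates at occluded radii: the double-occluded intermediate.

The same analyses run from the shell on any structure/trajectory:

```
dimergate pipeline --config run.cfg        # simulate + pairs/spin/casymm/arps/...
dimergate pairs --structure protein.pdb --out out/
```

with a flat `key = value` config naming chain roles
(`half1 = A,C`, `half2 = B,D`, `regions = A:TMD,B:TMD,C:NBD,D:NBD`),
analysis parameters and the simulation block; every output is delimited
text with a header recording version, config hash and seed.

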