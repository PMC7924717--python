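# markermol

**Marker-pose-driven molecular scenes with real-time observables.**

Web-browser augmented reality can turn a printed fiducial marker into a
handle for a virtual molecule: a tracking library reports a rigid 6-DOF
transform per marker per video frame, and lightweight JavaScript recomputes
interactions and even experimental observables on every update tick.
`markermol` re-implements that computational core as a rendering-independent
Python library and CLI, so the same calculations can be scripted, tested and
reproduced without a camera or a browser.  It is aimed at structural
biologists and educators who want the *engine* behind such interactive
scenes: pose handling, coarse-grained models, interaction rules, scattering
and NMR observables, and toy constrained mechanics.

## What it computes

Molecules (read from PDB via gemmi) are anchored through a chosen atom —
canonically an alpha carbon — to a pose `(q, t, s)`: a unit quaternion, a
translation in Å, and a display-only zoom.  A *scene* is the set of world
coordinates obtained from the current poses; every observable below is a
function of the scene and can be evaluated per frame of a pose trajectory.

- **Interaction rules** (per update tick):
  - clashes: sphere pairs with center distance `d < 3 Å` (or `d < r_i + r_j`
    for coarse beads);
  - electrostatics: `E = k q₁q₂ / (ε r)` with
    `k = 332.0636 kcal·Å·mol⁻¹·e⁻²`;
  - hydrogen bond display for `2 Å < d(N,O) < 3 Å`; proton transfer eligible
    when the proton is within 2 Å of the receiving heavy atom;
  - stochastic proton exchange between a lysine ammonium and a glutamate
    carboxylate, a two-state Markov chain in detailed balance whose
    stationary occupancies are 70 % protonated Lys / 30 % protonated Glu
    (ratio 70/30 = 2.33) — deliberately shifted from the real acidity ratio
    so both states are watchable.
- **Coarse graining**: two beads per residue (Cα + sidechain centroid;
  glycine a single Cα bead), radii `∝ V_residue^{1/3}` from a bundled
  residue-volume table, six physicochemical color classes.
- **SAXS**: the Debye sum over residue beads,
  `I(q) = Σᵢⱼ fᵢfⱼ sin(qr_ij)/(qr_ij)`, plus a reduced χ² against an
  experimental profile with the closed-form optimal scale.
- **PCS**: pseudocontact shifts
  `Δδ = (1/12πr³)[Δχ_ax(3cos²θ−1) + (3/2)Δχ_rh sin²θ cos2φ]` and a
  unit-area Lorentzian trace per resonance.
- **Contacts**: predicted residue-residue contacts (e.g. coevolution
  predictions tiered high/intermediate/low) scored against the scene's
  representative beads; line width grows
  with distance, satisfaction cutoff 8 Å.
- **Mechanics**: position-based dynamics with fixed-distance constraints
  (1-2/1-3 pairs for bonded molecules — dihedrals stay free, like a plastic
  modeling kit), velocity rescaling to a set temperature, worm-like-chain
  entropy and strain readouts for a six-bead glycine linker strung between
  two anchored domains, and the zero-strain maximum extension
  (`(n+1)·spacing`, 26.6 Å for the defaults).

## Worked example

```sh
markermol demo lys_glu --out demo_out --seed 1
```

```
markermol 0.1.0 demo: lys_glu
seed: 1

Stochastic proton exchange (transfer geometry always permitting):
  ticks: 100000
  protonated-lysine fraction: 0.6958 (target 0.70)
  LYS/GLU occupancy ratio:    2.287 (target 2.33)
Session table: demo_out/lys_glu_session.tsv
```

The demo writes the lysine/glutamate fragment PDBs, a 60-frame approach
trajectory, and a per-frame TSV of distance, Coulomb energy/force, clash
count, hydrogen-bond flags and the current proton holder.  The printed
fraction is the time average of a 10⁵-tick exchange run: it fluctuates
around 0.70 within Monte-Carlo error because that is the stationary
distribution the per-tick hop probabilities (0.03 forward, 0.07 backward)
are constructed to give.

Other demos: `linker` (two coarse-grained domains tethered by a hexaglycine
chain, reporting center distance, WLC entropy and strain per tick),
`saxs_fit` (χ² = 0 at the generating pose of a synthetic target, sharply
positive at displaced poses), `pcs_probe` (shift scan around a paramagnetic
center; 1.0610 ppm at 10 Å on the unique axis for Δχ_ax = 2×10⁻³² m³).

Library use mirrors the CLI:

```python
import numpy as np
from markermol import (read_pdb, coarse_grain, AnchoredMolecule, Pose,
                       assemble_scene, saxs_debye, fit_saxs)

beads = coarse_grain(read_pdb("protein.pdb"))
scene = assemble_scene([AnchoredMolecule(beads, 0, Pose.identity(), "A")])
profile = saxs_debye(scene["A"].world_coords, 1.0, np.linspace(0.01, 0.5, 50))
```

## Layout

| Module | Contents |
| --- | --- |
| `markermol.structio` | PDB/SAXS/contact/pose-trajectory I-O, poses, scenes |
| `markermol.coarse` | two-bead residue models, radii, color classes |
| `markermol.interactions` | clashes, Coulomb, H-bonds, proton exchange |
| `markermol.observables` | Debye SAXS + χ², PCS + spectrum, contact scoring |
| `markermol.mechanics` | constraint dynamics, WLC entropy, strain, extension |
| `markermol.fixtures` | seeded generators for all test/demo systems |
| `markermol.objexport` | Wavefront OBJ+MTL ball-and-stick export |
| `markermol.session`, `markermol.cli` | reproducible sessions, `markermol` CLI |

See `docs/methods.md` for the models, default parameters and their
rationale, numerical choices, and known limitations.
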