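# Methods

This note documents the models implemented in `markermol`, the defaults
chosen where the underlying design was open, and what the synthetic test
systems do and do not establish about real data.

## Poses, scenes and the zoom factor

A pose is a rigid 6-DOF transform: unit quaternion (tolerance 1e-9 on the
norm), translation in Å, and a positive display *zoom*.  Anchoring maps
local coordinates by `x ↦ R(s(x − a)) + t` with `a` the anchor atom (the
alpha carbon pinned to the marker center in the interactive original), so
the anchor lands exactly on the translation.  The zoom is a screen-fit
correction only: `assemble_scene` always builds world coordinates at scale
1, and every physical calculation consumes those unscaled Å coordinates.
Zoom is honored in exactly one place, mesh export.  Pose interpolation
(used for a scripted binding coordinate) is linear in translation and scale
and follows the shortest great-circle arc (slerp) in rotation.

Pose trajectories are stored as plain text, one line per molecule per
frame: `frame mol_id qw qx qy qz tx ty tz [scale]`.  The format is an
artifact of this package — in the interactive setting poses stream from
marker tracking and are never serialized — and is labeled as such.

## PDB handling

Reading goes through gemmi: ATOM and HETATM records, file order preserved,
coordinates as written.  Alternate locations default to
highest-occupancy-then-first; hydrogens are kept.  CONECT records become
the bond list; files without CONECT get distance-inferred bonds (cutoff =
covalent-radii sum + 0.4 Å).  gemmi silently zero-fills malformed
coordinate fields, so an explicit pre-pass validates the three coordinate
columns and reports the offending line.  Insertion codes are carried
separately from the integer residue number so (index, icode) stays a unique
residue key.

## Coarse graining

Two beads per residue: a backbone bead on the Cα and a sidechain bead at
the *unweighted* centroid of the sidechain heavy atoms (mass weighting is a
flag; unweighted is the default because the original description does not
specify and the difference is well below bead resolution).  Glycine is a
single backbone bead.  Radii are cube roots of mean residue volumes
(Zamyatnin-type consensus table, bundled as replaceable TSV data; glycine
60.1 ų → 3.92 Å raw).  Raw cube-root radii (3.9–6.1 Å) overlap massively
at the 3.8 Å Cα spacing, so the default applies a 0.5 scale factor for
display and collision work while `scale_factor=1` recovers the raw value —
the table fixes *relative* sizes, not an absolute contact distance.
Color classes: Asp/Glu negative; Lys/Arg/His positive (His grouped with the
basic residues; only four sidechain classes exist so His had to be placed);
Ser/Thr/Asn/Gln/Tyr/Cys polar; the rest hydrophobic; backbone and linker
beads have their own classes.  A four-beads-per-residue variant is
mentioned in the source material's figure caption but never specified; it
is noted here and not guessed at.

## Interaction rules

All pairwise rules are per *tick* — one evaluation interval, nominally
200 ms of wall clock in the interactive original, but nothing in the
dynamics depends on wall time.

- **Clashes.** Center mode (atomistic rule): distance strictly below 3 Å.
  Radius-sum mode (coarse beads): below `r_i + r_j`.  Neighbor search uses
  a k-d tree; the test suite pins it against a brute-force double loop.
- **Electrostatics.** Point-charge Coulomb with
  `k = 332.0636 kcal·Å·mol⁻¹·e⁻²`, dielectric ε = 1 by default
  (configurable; no value is prescribed by the source).  The bundled
  lysine/glutamate fragments carry +1 e on the ammonium N and −0.5 e on
  each carboxylate O.
- **Hydrogen bonds.** Display when the donor-acceptor heavy-atom distance
  lies strictly inside (2, 3) Å; window boundaries are exclusive for
  display and inclusive for transfer eligibility (≤ 2 Å proton-acceptor) —
  the strictness at the boundary was unspecified, so the choice is
  documented rather than load-bearing.
- **Proton exchange.** A two-state Markov chain.  Target stationary
  occupancies (0.70 protonated-Lys, 0.30 protonated-Glu) are a *setting*,
  not a prediction; detailed balance fixes
  `p_backward = p_forward · 0.70/0.30`.  The per-tick forward probability
  0.03 is an artifact default chosen so exchanges are visible on a seconds
  timescale at 200 ms ticks (giving p_backward = 0.07); the stationary
  distribution is independent of this rate, only the correlation time
  changes.  Monte-Carlo checks use a 3σ band inflated by the chain's
  autocorrelation factor √(1 + 2/p_forward).

## SAXS

`I(q) = Σᵢⱼ fᵢfⱼ sinc(q·r_ij)` evaluated over beads, with `sinc(0) = 1`.
Default form factors are `fᵢ = 1` per bead (the fast interactive choice);
an electron-count mode distributes tabulated per-residue electron numbers
over each residue's beads as a rough step toward parameterized scattering
centers.  Neither mode includes solvent contrast or q-dependent atomic form
factors; profiles are *residue-grained Debye* curves, good for relative
pose discrimination, not for absolute comparison with measured curves.

The fit metric is the reduced chi-square with closed-form optimal linear
scale: `c = Σ(I_c I_e/σ²)/Σ(I_c²/σ²)`,
`χ² = (1/(N−1)) Σ((c·I_c − I_e)/σ)²`, σ = 1 where absent.  The original
reports only "a metric of fit quality"; the convention used here is
recorded in all outputs.

Synthetic targets are generated by the package itself (two toy helical
domains at a known pose, optional Gaussian noise of stated fractional σ), so
the χ² = 0 self-fit and the pose-discriminability property (χ² strictly
positive at ≥ 5 Å displacements) are *internal consistency* checks: they
show the engine recovers its own generating pose, not that it can dock real
proteins against measured data.

## Pseudocontact shifts

`Δδ = (1/(12π r³)) [Δχ_ax (3cos²θ − 1) + (3/2) Δχ_rh sin²θ cos2φ] · 10⁶`
ppm, with (r, θ, φ) the probe's spherical coordinates in the tensor frame
(θ from the unique axis), r converted to meters inside the function, and
anisotropies supplied on the conventional 10⁻³² m³ scale.  Reference
values: 1.0610 ppm at r = 10 Å, θ = 0, Δχ_ax = 2×10⁻³² m³; exact zero at
the magic angle; r⁻³ scaling; zero spherical average (traceless tensor).
Default tensor magnitudes and the 1 ppm Lorentzian linewidth (FWHM) of the
spectrum trace are configurable artifact choices — no specific ferric-heme
tensor is asserted.

## Contact scoring

A predicted contact resolves to its residues' representative beads
(sidechain bead if present, else backbone).  Satisfaction cutoff 8 Å
between those beads — the standard coevolution-contact convention — and
display width `w_min + slope·max(0, d − d_sat)`, so lines are thin exactly
when contacts are satisfied.  Numeric scores bin to tiers at configurable
thresholds (defaults 0.9 / 0.6); explicit tier labels pass through.

## Constrained mechanics

Position-based dynamics with unit masses, k_B = 1 and the tick as time
unit; a temperature T therefore targets mean kinetic energy (3/2)T per
free bead with velocities in Å/tick (default T = 0.002, i.e. ~0.08 Å RMS
displacement per tick — small against the 1.5 Å bonds it must preserve).

One step: free positions drift `x += v·dt`; interleaved Gauss-Seidel sweeps
restore the fixed-distance constraints (equality, relative tolerance 1e-3,
cap 50 outer iterations) and push apart overlapping unconstrained sphere
pairs (inequality, half-strength corrections, looser 5 % depth tolerance so
the soft collisions cannot destabilize the hard constraints); velocities
are recomputed from actual displacements, mixed with a seeded thermal
component (20 %) for ergodicity, and rescaled so kinetic energy matches the
set temperature exactly — a deliberately simple isokinetic thermostat
matching the "velocities continuously updated to match the set temperature"
behavior of the original engine.  Everything is deterministic given the
state seed.  Beads flagged fixed (rigidly pose-attached) never move.

Constraint topology for bonded molecules: one constraint per 1-2 pair and
per 1-3 pair at current distances, 1-4 pairs free — bonds and angles hold
while dihedrals rotate.  A note on degenerate geometry: if a 1-3 distance
equals the sum of its two bond lengths (perfectly collinear atoms) the
constraint manifold is singular there and projection converges arbitrarily
slowly; realistic (tetrahedral) input geometry avoids this, and the bundled
chain fixtures are built tetrahedral for that reason.

Linker model: n free beads (default 6, glycine-sized) between two fixed
anchors, n+1 constraints all at the 3.8 Å Cα spacing; anchors farther apart
than the contour `(n+1)·spacing` are rejected as infeasible, anchors closer
than it get a seeded sideways buckle so all bond lengths are satisfiable.
Maximum zero-strain anchor separation is the contour (26.6 Å for defaults);
with rigid-domain anchor-to-center offsets supplied, the center-to-center
maximum is reported both as the free-rotation bound
(contour + |o_a| + |o_b|) and as the fixed-orientation exact value from
bounded 1-D optimization along the separation axis (the objective is convex
in the separation, so the optimum sits at an interval endpoint; the
optimizer plus endpoint candidates cover both cases).

**WLC entropy.**  `S(r) = ln r² − 3r² / (4pL·(1 − (r/L)²))` in k_B up to an
additive constant, with contour L = (n+1)·spacing and persistence length
p = 4 Å (an artifact default of the right order for a glycine-rich tether;
neither value is prescribed by the source).  The form is the Gaussian-limit
radial density with an inverse-quadratic finite-extensibility correction:
exact in the low-extension regime, monotone decreasing beyond the modal
extension, divergent to −∞ as r → L.  It is an interpolation, not the full
WLC propagator — adequate for the qualitative "entropy cost of stretching"
readout it backs.

**Strain.**  `Σᵢ ((dᵢ − d₀)/d₀)²` over consecutive-bead distances: zero
exactly at the equilibrium spacing, quadratic under stretch — the simplest
functional form consistent with its described behavior.

## Synthetic systems and what passing means

All inputs are generated: idealized sidechain fragments (tetrahedral
angles, 1.5 Å C–C), canonical-geometry toy helices with schematic seeded
sidechain clusters, and Debye profiles computed from known poses.  Tests
against these establish internal correctness — closed forms, oracle
equivalence, conservation and convergence contracts, determinism — at
deliberately modest problem sizes (10–100 beads, 10³–10⁴ dynamics steps,
10⁵ Markov ticks), chosen as comfortable single-core workloads.  They do
not establish accuracy on real structures: no real sidechain geometry,
no solvent or contrast effects in scattering, no validated force field.
The published ~40 Å maximum domain separation for the real two-domain
system requires its deposited coordinates as input; the packaged check runs
the same analysis on generated domains against a grid-search oracle.

## Known limitations

- No pKa prediction or physical proton-transfer kinetics; the 70/30 setting
  is pedagogical by construction.
- SAXS lacks solvent-corrected, q-dependent form factors; χ² values against
  real measured profiles are not meaningful in absolute terms.
- The dynamics has no dihedral, electrostatic or solvent terms; it is a
  constraint-projection toy, not molecular dynamics.
- OBJ export writes triangle meshes with per-class flat materials only (no
  cartoons, surfaces or volumetric data).
- mmCIF is not read; PDB only.
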