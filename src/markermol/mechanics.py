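"""Constrained thermal mechanics for small molecules and disordered linkers.

The engine is deliberately minimal, in the spirit of rigid-body game physics:
spheres of defined radii joined by fixed-distance constraints, positions
propagated by a position-based (SHAKE-like) projection scheme, and velocities
continuously rescaled to match a set temperature.  For small molecules the
constraint topology fixes distances between atoms separated by one or two
bonds while leaving dihedral rotations free — the behavior of a plastic
modeling kit.  For a disordered linker of n beads strung between two anchored
domains the same machinery yields end-to-end sampling, worm-like-chain
entropy estimates and a strain penalty for overstretched bonds.

Units are reduced: lengths in angstroms, one tick as the time unit, unit bead
masses, and k_B = 1, so a temperature T means a target mean kinetic energy of
(3/2) T per free bead with velocities in A/tick.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import InfeasibleError, ValidationError
from .structio import Structure

logger = logging.getLogger(__name__)

#: Relative constraint-violation tolerance of the projection solver.
CONSTRAINT_TOL = 1e-3

#: Residual relative overlap depth tolerated between unconstrained spheres.
#: Looser than CONSTRAINT_TOL: overlaps are soft inequality corrections,
#: the fixed-distance constraints are the hard contract.
OVERLAP_TOL = 0.05

#: Gauss-Seidel sweep cap per step.
MAX_PROJECTION_ITER = 50

#: Default number of linker beads and their spacing (A): a hexaglycine tether.
DEFAULT_LINKER_BEADS = 6
DEFAULT_LINKER_SPACING = 3.8

#: Default worm-like-chain persistence length for a Gly linker (A).
DEFAULT_PERSISTENCE = 4.0


# ---------------------------------------------------------------------------
# Constraint sets
# ---------------------------------------------------------------------------

@dataclass
class ConstraintSet:
    """Fixed-distance constraints: (index_i, index_j, target distance in A)."""

    pairs: list[tuple[int, int, float]]
    topology: str = "molecule_12_13"  # or "linker_chain"

    def __post_init__(self) -> None:
        seen = set()
        for i, j, d in self.pairs:
            if d <= 0:
                raise ValidationError(f"constraint ({i},{j}) target {d} <= 0")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValidationError(f"duplicate constraint pair {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    def index_pairs(self) -> set[tuple[int, int]]:
        return {(min(i, j), max(i, j)) for i, j, _ in self.pairs}


def build_molecule_constraints(structure: Structure) -> ConstraintSet:
    """Constraints for a bonded small molecule: 1-2 and 1-3 pairs.

    Every bonded pair and every pair sharing a bonded neighbor gets a
    fixed-distance constraint at its current distance; 1-4 pairs are left
    free so rotations about bonds survive, as in a plastic modeling kit.
    """
    if not structure.bonds:
        raise ValidationError("structure has no bonds; nothing to constrain")
    coords = structure.coords
    n = len(coords)
    adjacency: dict[int, set[int]] = {i: set() for i in range(n)}
    for i, j in structure.bonds:
        adjacency[i].add(j)
        adjacency[j].add(i)
    for i in range(n):
        if not adjacency[i]:
            warnings.warn(f"atom index {i} is disconnected; no constraints added",
                          stacklevel=2)
    pairs: set[tuple[int, int]] = set()
    for i, j in structure.bonds:
        pairs.add((min(i, j), max(i, j)))
    for center in range(n):
        for i, j in itertools.combinations(sorted(adjacency[center]), 2):
            pairs.add((i, j))
    out = [(i, j, float(np.linalg.norm(coords[i] - coords[j])))
           for i, j in sorted(pairs)]
    return ConstraintSet(out, topology="molecule_12_13")


def build_linker_constraints(anchor_a, anchor_b,
                             n_beads: int = DEFAULT_LINKER_BEADS,
                             spacing: float = DEFAULT_LINKER_SPACING,
                             seed: int = 0) -> tuple[ConstraintSet, np.ndarray]:
    """A disordered-linker chain strung between two fixed anchors.

    Returns ``(constraints, positions)`` over ``n_beads + 2`` sites: index 0
    is anchor_a, indices 1..n are the free linker beads, index n+1 is
    anchor_b.  There are ``n_beads + 1`` constraints, all at ``spacing``.
    The initial chain lies along the anchor-anchor segment; when the anchors
    sit closer than the contour length the chain is buckled sideways (seeded
    perturbation + projection) so every constraint is satisfiable.
    """
    if n_beads < 0:
        raise ValidationError("n_beads must be >= 0")
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    a = np.asarray(anchor_a, dtype=float)
    b = np.asarray(anchor_b, dtype=float)
    contour = (n_beads + 1) * spacing
    gap = float(np.linalg.norm(b - a))
    if gap > contour + 1e-9:
        raise InfeasibleError(
            f"anchors {gap:.3f} A apart exceed linker contour {contour:.3f} A")
    positions = np.empty((n_beads + 2, 3))
    positions[0] = a
    positions[-1] = b
    for k in range(1, n_beads + 1):
        positions[k] = a + (b - a) * (k / (n_beads + 1))
    pairs = [(k, k + 1, float(spacing)) for k in range(n_beads + 1)]
    constraints = ConstraintSet(pairs, topology="linker_chain")
    fixed = np.zeros(n_beads + 2, dtype=bool)
    fixed[0] = fixed[-1] = True
    if n_beads > 0 and gap < contour - 1e-9:
        rng = np.random.default_rng(seed)
        # buckle sideways so the slack chain can satisfy its bond lengths
        positions[1:-1] += rng.normal(scale=0.3 * spacing, size=(n_beads, 3))
        project_constraints(positions, constraints, fixed,
                            max_iter=500, tol=1e-6)
    return constraints, positions


# ---------------------------------------------------------------------------
# Position-based dynamics
# ---------------------------------------------------------------------------

@dataclass
class DynamicsState:
    """Mutable-free snapshot of a constrained-dynamics run."""

    positions: np.ndarray            # (n, 3) A
    velocities: np.ndarray           # (n, 3) A/tick
    radii: np.ndarray                # (n,) A
    temperature_target: float = 0.0  # reduced units (k_B = 1, m = 1)
    fixed: np.ndarray | None = None  # (n,) bool; True = pinned to its pose
    seed: int = 0
    tick: int = 0
    converged: bool = True
    _rng: np.random.Generator | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        n = len(self.positions)
        if self.velocities.shape != (n, 3) or self.radii.shape != (n,):
            raise ValidationError("positions, velocities and radii must be congruent")
        if self.fixed is None:
            self.fixed = np.zeros(n, dtype=bool)
        self.fixed = np.asarray(self.fixed, dtype=bool)
        if self.temperature_target < 0:
            raise ValidationError("temperature_target must be >= 0")
        if self._rng is None:
            self._rng = np.random.default_rng(self.seed)

    @property
    def rng(self) -> np.random.Generator:
        return self._rng

    @property
    def n_free(self) -> int:
        return int((~self.fixed).sum())

    def kinetic_energy_per_free_bead(self) -> float:
        free = ~self.fixed
        if not free.any():
            return 0.0
        return float(0.5 * (self.velocities[free] ** 2).sum() / free.sum())


def project_constraints(positions: np.ndarray, constraints: ConstraintSet,
                        fixed: np.ndarray, max_iter: int = MAX_PROJECTION_ITER,
                        tol: float = CONSTRAINT_TOL) -> bool:
    """Gauss-Seidel projection of pairwise distance constraints, in place.

    Fixed sites have zero projection weight.  Returns True when the maximum
    relative violation dropped below ``tol`` within the iteration cap.
    """
    for _ in range(max_iter):
        worst = 0.0
        for i, j, d0 in constraints.pairs:
            delta = positions[j] - positions[i]
            d = float(np.linalg.norm(delta))
            if d < 1e-12:
                # coincident points: split along an arbitrary axis
                delta = np.array([d0, 0.0, 0.0])
                d = 1e-12
            err = (d - d0) / d0
            worst = max(worst, abs(err))
            wi = 0.0 if fixed[i] else 1.0
            wj = 0.0 if fixed[j] else 1.0
            wsum = wi + wj
            if wsum == 0.0:
                continue
            corr = (d - d0) / d * delta
            positions[i] += (wi / wsum) * corr
            positions[j] -= (wj / wsum) * corr
        if worst < tol:
            return True
    return max_constraint_violation(positions, constraints) < tol


def max_constraint_violation(positions: np.ndarray,
                             constraints: ConstraintSet) -> float:
    """Maximum relative |d_ij - target| / target over all constraints."""
    if not constraints.pairs:
        return 0.0
    worst = 0.0
    for i, j, d0 in constraints.pairs:
        d = float(np.linalg.norm(positions[j] - positions[i]))
        worst = max(worst, abs(d - d0) / d0)
    return worst


def resolve_overlaps(positions: np.ndarray, radii: np.ndarray,
                     fixed: np.ndarray, exclude: set[tuple[int, int]]) -> float:
    """One sweep pushing apart overlapping sphere pairs not joined by a
    constraint.  Returns the worst relative overlap depth seen."""
    n = len(positions)
    worst = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if (i, j) in exclude:
                continue
            delta = positions[j] - positions[i]
            d = float(np.linalg.norm(delta))
            limit = radii[i] + radii[j]
            if d >= limit or limit <= 0:
                continue
            worst = max(worst, (limit - d) / limit)
            if d < 1e-12:
                delta = np.array([limit, 0.0, 0.0])
                d = 1e-12
            wi = 0.0 if fixed[i] else 1.0
            wj = 0.0 if fixed[j] else 1.0
            if wi + wj == 0.0:
                continue
            # half-strength push: keeps the inequality correction from
            # fighting the equality constraints in the interleaved solver
            corr = 0.5 * (d - limit) / d * delta
            positions[i] += (wi / (wi + wj)) * corr
            positions[j] -= (wj / (wi + wj)) * corr
    return worst


def _solve_positions(positions: np.ndarray, constraints: ConstraintSet,
                     radii: np.ndarray, fixed: np.ndarray,
                     max_iter: int, tol: float) -> bool:
    """Interleaved Gauss-Seidel sweeps over equality (distance) constraints
    and inequality (sphere-overlap) corrections, so neither undoes the other."""
    exclude = constraints.index_pairs()
    for _ in range(max_iter):
        project_constraints(positions, constraints, fixed, max_iter=5, tol=0.1 * tol)
        overlap = resolve_overlaps(positions, radii, fixed, exclude)
        if max_constraint_violation(positions, constraints) < tol and overlap < OVERLAP_TOL:
            return True
    project_constraints(positions, constraints, fixed, max_iter=30, tol=0.1 * tol)
    return max_constraint_violation(positions, constraints) < tol


def dynamics_step(state: DynamicsState, constraints: ConstraintSet,
                  dt: float = 1.0, max_iter: int = MAX_PROJECTION_ITER,
                  tol: float = CONSTRAINT_TOL,
                  noise_mix: float = 0.2) -> DynamicsState:
    """Advance the constrained system by one tick.

    The cycle: free positions drift with their velocities; distance
    constraints are restored by iterative projection; overlapping
    unconstrained sphere pairs are separated; velocities are recomputed from
    the actual displacement and then rescaled so the mean kinetic energy per
    free bead matches the set temperature, with a seeded random admixture
    (``noise_mix``) that keeps the sampling ergodic.  Fixed (pose-attached)
    beads never move.  Deterministic for a fixed state seed.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    pos = state.positions.copy()
    vel = state.velocities.copy()
    free = ~state.fixed
    target_ke = 1.5 * state.temperature_target

    prev = pos.copy()
    pos[free] += vel[free] * dt
    ok = _solve_positions(pos, constraints, state.radii, state.fixed,
                          max_iter, tol)
    if not ok:
        logger.debug("constraint projection hit iteration cap at tick %d",
                     state.tick + 1)
    pos[state.fixed] = state.positions[state.fixed]
    vel = np.zeros_like(vel)
    vel[free] = (pos[free] - prev[free]) / dt

    if state.temperature_target > 0 and free.any():
        thermal = state.rng.normal(scale=np.sqrt(state.temperature_target),
                                   size=vel[free].shape)
        mixed = (1.0 - noise_mix) * vel[free] + noise_mix * thermal
        ke = 0.5 * float((mixed ** 2).sum()) / free.sum()
        if ke < 1e-30:
            mixed = thermal
            ke = 0.5 * float((mixed ** 2).sum()) / free.sum()
        vel[free] = mixed * np.sqrt(target_ke / ke)

    return replace(state, positions=pos, velocities=vel, tick=state.tick + 1,
                   converged=ok, _rng=state.rng)


def run_dynamics(state: DynamicsState, constraints: ConstraintSet,
                 n_steps: int, dt: float = 1.0, sample_every: int = 1,
                 **step_kwargs) -> tuple[DynamicsState, list[np.ndarray]]:
    """Advance ``n_steps`` ticks, collecting position snapshots."""
    samples: list[np.ndarray] = []
    for k in range(n_steps):
        state = dynamics_step(state, constraints, dt, **step_kwargs)
        if (k + 1) % sample_every == 0:
            samples.append(state.positions.copy())
    return state, samples


# ---------------------------------------------------------------------------
# Worm-like-chain entropy and strain
# ---------------------------------------------------------------------------

def wlc_entropy(end_to_end, contour: float,
                persistence: float = DEFAULT_PERSISTENCE):
    """Configurational entropy (in k_B, up to a constant) of a WLC linker.

    Uses the radial end-to-end density ``P(r) ~ r^2 exp(-3 r^2 / (4 p L))``
    of the flexible (Gaussian) limit with a finite-extensibility correction
    ``1 / (1 - (r/L)^2)`` in the exponent, so the density — and hence the
    entropy ``S = ln P`` — is exact in the low-extension regime and diverges
    to -inf as the chain straightens toward its contour length L.
    Accepts scalars or arrays; requires ``0 <= r < L``.
    """
    r = np.asarray(end_to_end, dtype=float)
    if contour <= 0 or persistence <= 0:
        raise ValidationError("contour and persistence lengths must be positive")
    if np.any(r < 0) or np.any(r >= contour):
        raise ValidationError("end-to-end distance must satisfy 0 <= r < contour")
    x2 = (r / contour) ** 2
    with np.errstate(divide="ignore"):
        s = np.log(r * r) - 3.0 * r * r / (4.0 * persistence * contour * (1.0 - x2))
    return float(s) if np.isscalar(end_to_end) else s


def linker_strain(bond_distances, target: float) -> float:
    """Dimensionless strain: sum of squared relative bond-length deviations.

    Zero exactly when every consecutive-bead distance equals the equilibrium
    spacing; grows quadratically as the user pulls the linker beads apart.
    """
    d = np.asarray(bond_distances, dtype=float)
    if target <= 0:
        raise ValidationError("target spacing must be positive")
    if d.size == 0:
        raise ValidationError("empty bond-distance list")
    return float(np.sum(((d - target) / target) ** 2))


@dataclass
class LinkerReport:
    """Per-tick linker observables displayed alongside the scene."""

    center_distance: float
    entropy: float
    strain: float
    bond_distances: np.ndarray
    end_to_end: float


def linker_report(positions: np.ndarray, constraints: ConstraintSet,
                  center_a: np.ndarray, center_b: np.ndarray,
                  spacing: float = DEFAULT_LINKER_SPACING,
                  persistence: float = DEFAULT_PERSISTENCE) -> LinkerReport:
    """Assemble the real-time readout for a linker chain state."""
    if constraints.topology != "linker_chain":
        raise ValidationError("linker_report needs linker_chain topology")
    d = np.array([float(np.linalg.norm(positions[j] - positions[i]))
                  for i, j, _ in constraints.pairs])
    contour = sum(t for _, _, t in constraints.pairs)
    r = float(np.linalg.norm(positions[-1] - positions[0]))
    r_safe = min(r, contour * (1 - 1e-9))
    return LinkerReport(
        center_distance=float(np.linalg.norm(np.asarray(center_b) - np.asarray(center_a))),
        entropy=float(wlc_entropy(r_safe, contour, persistence)) if r_safe > 0 else -np.inf,
        strain=linker_strain(d, spacing),
        bond_distances=d,
        end_to_end=r,
    )


# ---------------------------------------------------------------------------
# Maximum extension
# ---------------------------------------------------------------------------

@dataclass
class MaxExtensionReport:
    anchor_anchor: float
    center_center_bound: float | None = None
    center_center_exact: float | None = None


def max_extension(constraints: ConstraintSet,
                  offset_a=None, offset_b=None,
                  axis=(1.0, 0.0, 0.0)) -> MaxExtensionReport:
    """Maximum zero-strain anchor separation of a linker, and center variants.

    The anchor-anchor maximum is the contour length (sum of constraint
    targets: a fully straightened chain).  When world-frame anchor-to-center
    offsets of the two rigid domains are supplied, also reports the
    center-to-center upper bound (contour + |offset_a| + |offset_b|, attained
    when rotations are free) and the pose-constrained exact maximum for the
    given fixed offsets, found by 1-D optimization of the separation along
    the anchor-anchor axis.
    """
    if constraints.topology != "linker_chain":
        raise ValidationError("max_extension is defined for linker_chain topology")
    contour = float(sum(t for _, _, t in constraints.pairs))
    report = MaxExtensionReport(anchor_anchor=contour)
    if offset_a is None or offset_b is None:
        return report
    oa = np.asarray(offset_a, dtype=float)
    ob = np.asarray(offset_b, dtype=float)
    report.center_center_bound = contour + float(np.linalg.norm(oa)) + float(np.linalg.norm(ob))
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    w = ob - oa

    def center_sep(s: float) -> float:
        return float(np.linalg.norm(s * axis + w))

    res = minimize_scalar(lambda s: -center_sep(s), bounds=(0.0, contour),
                          method="bounded")
    candidates = [center_sep(0.0), center_sep(contour), center_sep(float(res.x))]
    report.center_center_exact = max(candidates)
    return report
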