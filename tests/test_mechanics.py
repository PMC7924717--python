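"""Constraint topologies, position-based dynamics, WLC entropy, strain."""

import numpy as np
import pytest

from markermol.errors import InfeasibleError, ValidationError
from markermol.fixtures import zigzag_chain
from markermol.mechanics import (ConstraintSet, DynamicsState,
                                 build_linker_constraints,
                                 build_molecule_constraints, dynamics_step,
                                 linker_report, linker_strain,
                                 max_constraint_violation, max_extension,
                                 run_dynamics, wlc_entropy)
from markermol.structio import Atom, Structure


def dihedral_deg(p):
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return np.degrees(np.arctan2(m1 @ n2, n1 @ n2))


# ---------------------------------------------------------------------------
# Constraint construction
# ---------------------------------------------------------------------------

def test_linear_chain_12_13_topology(butane_like):
    cons = build_molecule_constraints(butane_like)
    assert cons.index_pairs() == {(0, 1), (1, 2), (2, 3), (0, 2), (1, 3)}
    # 1-4 pair A-D deliberately free (dihedral rotation)
    assert (0, 3) not in cons.index_pairs()


def test_methane_star_constraint_count():
    c = np.zeros(3)
    h = 1.09 * np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)
    atoms = [Atom(1, "C", "C", "LIG", 1, "A", c)] + [
        Atom(i + 2, f"H{i + 1}", "H", "LIG", 1, "A", h[i]) for i in range(4)]
    star = Structure(atoms, [(0, i) for i in range(1, 5)])
    cons = build_molecule_constraints(star)
    assert len(cons) == 10  # 4 bonds + C(4,2)=6 angle constraints


def test_disconnected_atom_warns():
    atoms = zigzag_chain(3).atoms + [Atom(9, "X", "C", "LIG", 2, "A",
                                          np.array([30.0, 0, 0]))]
    st = Structure(atoms, [(0, 1), (1, 2)])
    with pytest.warns(UserWarning, match="disconnected"):
        build_molecule_constraints(st)


def test_no_bonds_is_an_error():
    with pytest.raises(ValidationError):
        build_molecule_constraints(zigzag_chain(1))


def test_duplicate_constraints_rejected():
    with pytest.raises(ValidationError):
        ConstraintSet([(0, 1, 1.0), (1, 0, 2.0)])


# ---------------------------------------------------------------------------
# Linker construction
# ---------------------------------------------------------------------------

def test_linker_has_n_plus_one_constraints():
    cons, pos = build_linker_constraints([0, 0, 0], [20.0, 0, 0], n_beads=6)
    assert len(cons) == 7
    assert len(pos) == 8
    assert max_constraint_violation(pos, cons) < 1e-3


def test_linker_fully_extended_is_collinear_zero_strain():
    cons, pos = build_linker_constraints([0, 0, 0], [26.6, 0, 0],
                                         n_beads=6, spacing=3.8)
    d = np.array([np.linalg.norm(pos[j] - pos[i]) for i, j, _ in cons.pairs])
    assert linker_strain(d, 3.8) == pytest.approx(0.0, abs=1e-12)
    assert np.abs(pos[:, 1:]).max() < 1e-9  # collinear along x


def test_linker_compact_anchors_still_feasible():
    cons, pos = build_linker_constraints([0, 0, 0], [1.0, 0, 0], n_beads=6)
    assert max_constraint_violation(pos, cons) < 1e-3


def test_linker_overstretched_anchors_error():
    with pytest.raises(InfeasibleError):
        build_linker_constraints([0, 0, 0], [30.0, 0, 0], n_beads=6, spacing=3.8)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def test_zero_temperature_is_static(butane_like):
    cons = build_molecule_constraints(butane_like)
    n = len(butane_like)
    state = DynamicsState(butane_like.coords, np.zeros((n, 3)), np.full(n, 0.3),
                          temperature_target=0.0, seed=0)
    out = state
    for _ in range(50):
        out = dynamics_step(out, cons)
    assert out.positions == pytest.approx(state.positions, abs=1e-12)


def test_constraints_hold_every_step(butane_like):
    cons = build_molecule_constraints(butane_like)
    n = len(butane_like)
    state = DynamicsState(butane_like.coords, np.zeros((n, 3)), np.full(n, 0.3),
                          temperature_target=0.002, seed=1)
    for _ in range(500):
        state = dynamics_step(state, cons)
        assert max_constraint_violation(state.positions, cons) < 1e-3


def test_chain_rotates_while_bonds_and_angles_hold(butane_like):
    """Bonds and 1-3 distances conserved, dihedral explores > 90 degrees."""
    cons = build_molecule_constraints(butane_like)
    n = len(butane_like)
    state = DynamicsState(butane_like.coords, np.zeros((n, 3)), np.full(n, 0.3),
                          temperature_target=0.002, seed=5)
    worst = 0.0
    dihedrals = []
    for _ in range(10_000):
        state = dynamics_step(state, cons)
        worst = max(worst, max_constraint_violation(state.positions, cons))
        dihedrals.append(dihedral_deg(state.positions))
    assert worst < 1e-3
    assert max(dihedrals) - min(dihedrals) > 90.0


def test_equipartition(butane_like):
    """Mean kinetic energy per free bead matches (3/2) T after burn-in."""
    cons = build_molecule_constraints(butane_like)
    n = len(butane_like)
    temperature = 0.002
    state = DynamicsState(butane_like.coords, np.zeros((n, 3)), np.full(n, 0.3),
                          temperature_target=temperature, seed=9)
    kes = []
    for k in range(2000):
        state = dynamics_step(state, cons)
        if k >= 200:
            kes.append(state.kinetic_energy_per_free_bead())
    assert np.mean(kes) == pytest.approx(1.5 * temperature, rel=0.10)


def test_fixed_beads_never_move():
    cons, pos = build_linker_constraints([0, 0, 0], [15.0, 0, 0], n_beads=6)
    fixed = np.zeros(len(pos), bool)
    fixed[0] = fixed[-1] = True
    state = DynamicsState(pos, np.zeros_like(pos), np.full(len(pos), 1.9),
                          temperature_target=0.002, fixed=fixed, seed=2)
    for _ in range(300):
        state = dynamics_step(state, cons)
        assert state.positions[0] == pytest.approx(pos[0], abs=1e-12)
        assert state.positions[-1] == pytest.approx(pos[-1], abs=1e-12)


def test_dynamics_deterministic_for_seed(butane_like):
    cons = build_molecule_constraints(butane_like)
    n = len(butane_like)

    def run(seed):
        s = DynamicsState(butane_like.coords, np.zeros((n, 3)), np.full(n, 0.3),
                          temperature_target=0.002, seed=seed)
        s, _ = run_dynamics(s, cons, 100)
        return s.positions

    assert run(7) == pytest.approx(run(7), abs=0)
    assert not np.allclose(run(7), run(8))


def test_linker_never_exceeds_contour():
    """End-to-end sampling is bounded by the straight-chain extension."""
    cons, pos = build_linker_constraints([0, 0, 0], [20.0, 0, 0], n_beads=6)
    fixed = np.zeros(len(pos), bool)
    fixed[0] = fixed[-1] = True
    state = DynamicsState(pos, np.zeros_like(pos), np.full(len(pos), 1.9),
                          temperature_target=0.002, fixed=fixed, seed=3)
    bound = max_extension(cons).anchor_anchor * (1 + 1e-3)
    state, samples = run_dynamics(state, cons, 3000, sample_every=10)
    for p in samples:
        path = sum(np.linalg.norm(p[k + 1] - p[k]) for k in range(len(p) - 1))
        assert np.linalg.norm(p[-1] - p[0]) <= path  # sanity: triangle inequality
        assert np.linalg.norm(p[-1] - p[0]) <= bound


# ---------------------------------------------------------------------------
# WLC entropy
# ---------------------------------------------------------------------------

L, P = 26.6, 4.0


def test_entropy_decreases_toward_extension():
    assert wlc_entropy(0.9 * L, L, P) < wlc_entropy(0.5 * L, L, P)


def test_entropy_gaussian_limit_low_extension():
    """Matches the Gaussian-chain form within 2% for r < 0.3 L."""
    r = np.linspace(0.05 * L, 0.3 * L, 25)
    s = wlc_entropy(r, L, P)
    gauss = np.log(r ** 2) - 3 * r ** 2 / (4 * P * L)
    span = gauss.max() - gauss.min()
    assert np.abs(s - gauss).max() <= 0.02 * np.abs(gauss).max() + 1e-12 or \
        np.abs((s - gauss) / span).max() <= 0.02


def test_entropy_diverges_at_contour():
    assert wlc_entropy(0.999 * L, L, P) < wlc_entropy(0.99 * L, L, P) - 1.0


def test_entropy_domain():
    with pytest.raises(ValidationError):
        wlc_entropy(L, L, P)
    with pytest.raises(ValidationError):
        wlc_entropy(-1.0, L, P)


def test_entropy_pure_function():
    assert wlc_entropy(10.0, L, P) == wlc_entropy(10.0, L, P)


# ---------------------------------------------------------------------------
# Strain
# ---------------------------------------------------------------------------

def test_strain_zero_at_equilibrium():
    assert linker_strain([3.8] * 7, 3.8) == 0.0


def test_strain_single_stretched_bond():
    d = [3.8] * 6 + [3.8 * 1.1]
    assert linker_strain(d, 3.8) == pytest.approx(0.01)


def test_strain_uniform_stretch():
    lam = 1.07
    n = 7
    assert linker_strain([3.8 * lam] * n, 3.8) == pytest.approx(n * (lam - 1) ** 2)


def test_strain_validation():
    with pytest.raises(ValidationError):
        linker_strain([], 3.8)
    with pytest.raises(ValidationError):
        linker_strain([3.8], 0.0)


# ---------------------------------------------------------------------------
# Maximum extension
# ---------------------------------------------------------------------------

def test_max_extension_defaults():
    cons, _ = build_linker_constraints([0, 0, 0], [10.0, 0, 0],
                                       n_beads=6, spacing=3.8)
    assert max_extension(cons).anchor_anchor == pytest.approx(26.6)


def test_max_extension_zero_bead_linker():
    cons, _ = build_linker_constraints([0, 0, 0], [3.0, 0, 0],
                                       n_beads=0, spacing=3.8)
    assert max_extension(cons).anchor_anchor == pytest.approx(3.8)


def test_max_extension_center_variant_matches_grid_search(rng):
    cons, _ = build_linker_constraints([0, 0, 0], [10.0, 0, 0],
                                       n_beads=6, spacing=3.8)
    off_a = rng.normal(scale=5, size=3)
    off_b = rng.normal(scale=5, size=3)
    rep = max_extension(cons, off_a, off_b)
    contour = rep.anchor_anchor
    grid = np.linspace(0.0, contour, 2001)
    oracle = max(np.linalg.norm(s * np.array([1.0, 0, 0]) + (off_b - off_a))
                 for s in grid)
    assert rep.center_center_exact == pytest.approx(oracle, abs=0.1)
    assert rep.center_center_exact <= rep.center_center_bound + 1e-9


def test_max_extension_wrong_topology(butane_like):
    cons = build_molecule_constraints(butane_like)
    with pytest.raises(ValidationError):
        max_extension(cons)


def test_linker_report_fields():
    cons, pos = build_linker_constraints([0, 0, 0], [20.0, 0, 0], n_beads=6)
    rep = linker_report(pos, cons, np.zeros(3), np.array([25.0, 0, 0]))
    assert rep.center_distance == pytest.approx(25.0)
    assert rep.strain == pytest.approx(0.0, abs=1e-5)
    assert rep.end_to_end == pytest.approx(20.0, abs=1e-6)
    assert np.isfinite(rep.entropy)
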