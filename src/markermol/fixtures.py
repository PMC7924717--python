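"""Programmatic generation of idealized test and demo systems.

The original web apps loaded hand-prepared coordinate files; this package
instead generates every input it needs: a lysine/glutamate sidechain pair
with a titratable proton, hexaglycine linker chains, toy alpha-helical
domains with schematic sidechains, two-domain + linker assemblies, and
synthetic SAXS targets computed from a known pose (optionally with Gaussian
noise).  Geometries are idealized — tetrahedral angles, 1.5 A C-C bonds,
3.8 A alpha-carbon spacing — and every randomized element is driven by an
explicit seed, so the same call always returns the same coordinates.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError
from .structio import Atom, Pose, Structure, AnchoredMolecule, assemble_scene

FIXTURE_KINDS = ("lys_glu_pair", "hexaglycine_linker", "two_domain_linker",
                 "toy_helix", "synthetic_saxs_target")

_TETRAHEDRAL_HALF = np.deg2rad((180.0 - 109.471) / 2.0)
CC_BOND = 1.5
CN_BOND = 1.47
CO_BOND = 1.25
NH_BOND = 1.0

#: Sidechain heavy-atom counts of the 20 canonical residues.
SIDECHAIN_HEAVY_COUNT = {
    "ALA": 1, "ARG": 7, "ASN": 4, "ASP": 4, "CYS": 2, "GLN": 5, "GLU": 5,
    "GLY": 0, "HIS": 6, "ILE": 4, "LEU": 4, "LYS": 5, "MET": 4, "PHE": 7,
    "PRO": 3, "SER": 2, "THR": 3, "TRP": 10, "TYR": 8, "VAL": 3,
}

_DEFAULT_SEQUENCE = ("ALA", "ASP", "LYS", "LEU", "GLY", "ASN", "PHE", "TYR",
                     "THR", "ARG", "TRP", "HIS", "SER", "GLU", "GLN", "CYS",
                     "ILE", "MET", "PRO", "VAL")


def _zigzag(n: int, bond: float, start=np.zeros(3)) -> np.ndarray:
    """Idealized all-anti chain: bond vectors alternate about the x axis."""
    pos = np.empty((n, 3))
    pos[0] = start
    for k in range(1, n):
        sign = 1.0 if k % 2 else -1.0
        step = bond * np.array([np.cos(_TETRAHEDRAL_HALF),
                                sign * np.sin(_TETRAHEDRAL_HALF), 0.0])
        pos[k] = pos[k - 1] + step
    return pos


def _make_atoms(names, elements, positions, residue_name, chain_id,
                residue_index=1, charges=None, serial_start=1) -> list[Atom]:
    charges = charges or {}
    return [Atom(serial=serial_start + i, name=nm, element=el,
                 residue_name=residue_name, residue_index=residue_index,
                 chain_id=chain_id, position=positions[i],
                 partial_charge=charges.get(nm, 0.0))
            for i, (nm, el) in enumerate(zip(names, elements))]


def zigzag_chain(n_atoms: int = 4, bond: float = CC_BOND,
                 element: str = "C", chain_id: str = "A") -> Structure:
    """An idealized all-anti carbon chain (tetrahedral angles, bonded 1-2).

    The butane-like test body for constrained dynamics: 1-2/1-3 constraints
    built from it are non-degenerate (1-3 distances strictly shorter than two
    bond lengths), so bond rotations stay free while angles hold.
    """
    pos = _zigzag(n_atoms, bond)
    atoms = [Atom(serial=i + 1, name=f"{element}{i + 1}", element=element,
                  residue_name="LIG", residue_index=1, chain_id=chain_id,
                  position=pos[i]) for i in range(n_atoms)]
    bonds = [(i, i + 1) for i in range(n_atoms - 1)]
    return Structure(atoms, bonds, id="zigzag_chain")


def lysine_sidechain(chain_id: str = "A") -> Structure:
    """A protonated lysine sidechain fragment: CA-CB-CG-CD-CE-NZ(+1) + 3 H.

    The ammonium nitrogen carries the +1 charge; HZ1 is the titratable
    proton that the transfer emulator moves to the glutamate carboxylate.
    """
    heavy = _zigzag(6, CC_BOND)
    heavy[5] = heavy[4] + (heavy[5] - heavy[4]) * (CN_BOND / CC_BOND)
    nz = heavy[5]
    ce = heavy[4]
    out = (nz - ce) / np.linalg.norm(nz - ce)
    perp = np.array([-out[1], out[0], 0.0])
    protons = [nz + NH_BOND * out,
               nz + NH_BOND * (0.5 * perp + np.array([0, 0, 0.85])),
               nz + NH_BOND * (0.5 * perp + np.array([0, 0, -0.85]))]
    names = ["CA", "CB", "CG", "CD", "CE", "NZ", "HZ1", "HZ2", "HZ3"]
    elements = ["C"] * 5 + ["N"] + ["H"] * 3
    atoms = _make_atoms(names, elements, np.vstack([heavy, protons]),
                        "LYS", chain_id, charges={"NZ": 1.0})
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (5, 7), (5, 8)]
    return Structure(atoms, bonds, id="lys_fragment")


def glutamate_sidechain(chain_id: str = "B") -> Structure:
    """A deprotonated glutamate sidechain: CA-CB-CG-CD(-OE1,-OE2), -1 total."""
    heavy = _zigzag(4, CC_BOND)
    cd = heavy[3]
    cg = heavy[2]
    axis = (cd - cg) / np.linalg.norm(cd - cg)
    perp = np.array([-axis[1], axis[0], 0.0])
    oe1 = cd + CO_BOND * (np.cos(np.deg2rad(60)) * axis + np.sin(np.deg2rad(60)) * perp)
    oe2 = cd + CO_BOND * (np.cos(np.deg2rad(60)) * axis - np.sin(np.deg2rad(60)) * perp)
    names = ["CA", "CB", "CG", "CD", "OE1", "OE2"]
    elements = ["C"] * 4 + ["O", "O"]
    atoms = _make_atoms(names, elements, np.vstack([heavy, [oe1, oe2]]),
                        "GLU", chain_id, charges={"OE1": -0.5, "OE2": -0.5})
    bonds = [(0, 1), (1, 2), (2, 3), (3, 4), (3, 5)]
    return Structure(atoms, bonds, id="glu_fragment")


def hexaglycine_linker(n_residues: int = 6, spacing: float = 3.8,
                       chain_id: str = "L") -> Structure:
    """n glycine residues as bare alpha carbons, equally spaced along x."""
    atoms = [Atom(serial=i + 1, name="CA", element="C", residue_name="GLY",
                  residue_index=i + 1, chain_id=chain_id,
                  position=np.array([i * spacing, 0.0, 0.0]))
             for i in range(n_residues)]
    bonds = [(i, i + 1) for i in range(n_residues - 1)]
    return Structure(atoms, bonds, id="hexaglycine")


def toy_helix(n_residues: int = 10, sequence=None, chain_id: str = "A",
              seed: int = 0, structure_id: str = "toy_helix") -> Structure:
    """An idealized alpha-helical domain with schematic sidechains.

    Alpha carbons follow the canonical helix (rise 1.5 A, 100 deg/residue,
    radius 2.3 A); each residue gets N, C, O backbone atoms on the helical
    path and a seeded cluster of sidechain heavy atoms pointing radially
    outward, sized per residue type.
    """
    rng = np.random.default_rng(seed)
    seq = list(sequence) if sequence is not None else [
        _DEFAULT_SEQUENCE[i % len(_DEFAULT_SEQUENCE)] for i in range(n_residues)]
    if len(seq) != n_residues:
        raise ValidationError("sequence length must equal n_residues")
    atoms: list[Atom] = []
    radius, rise, twist = 2.3, 1.5, np.deg2rad(100.0)
    serial = 1
    for i, resname in enumerate(seq):
        resname = resname.upper()
        theta = i * twist
        ca = np.array([radius * np.cos(theta), radius * np.sin(theta), i * rise])
        outward = np.array([np.cos(theta), np.sin(theta), 0.0])
        tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
        backbone = {
            "N": ca - 1.46 * tangent * 0.7 - np.array([0, 0, 0.5]),
            "CA": ca,
            "C": ca + 1.52 * tangent * 0.7 + np.array([0, 0, 0.5]),
        }
        backbone["O"] = backbone["C"] + 1.23 * outward
        for nm, p in backbone.items():
            atoms.append(Atom(serial=serial, name=nm, element=nm[0],
                              residue_name=resname, residue_index=i + 1,
                              chain_id=chain_id, position=p))
            serial += 1
        n_side = SIDECHAIN_HEAVY_COUNT.get(resname, 3)
        if n_side:
            cb = ca + 1.53 * outward
            for k in range(n_side):
                name = "CB" if k == 0 else f"CG{k}"
                p = cb + 0.8 * k * outward + rng.normal(scale=0.45, size=3)
                atoms.append(Atom(serial=serial, name=name, element="C",
                                  residue_name=resname, residue_index=i + 1,
                                  chain_id=chain_id, position=p))
                serial += 1
    return Structure(atoms, bonds=[], id=structure_id)


def generate_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Dispatch to one of the named fixture generators.

    Returns structures and/or profiles depending on ``kind``; deterministic
    for a fixed seed.  See the individual builders for geometry details.
    """
    params = dict(params or {})
    if kind == "lys_glu_pair":
        return {"lysine": lysine_sidechain(params.get("chain_a", "A")),
                "glutamate": glutamate_sidechain(params.get("chain_b", "B"))}
    if kind == "hexaglycine_linker":
        return hexaglycine_linker(params.get("n_residues", 6),
                                  params.get("spacing", 3.8))
    if kind == "toy_helix":
        return toy_helix(params.get("n_residues", 10), params.get("sequence"),
                         params.get("chain_id", "A"), seed=seed)
    if kind == "two_domain_linker":
        na = params.get("n_residues_a", 8)
        nb = params.get("n_residues_b", 8)
        dom_a = toy_helix(na, chain_id="A", seed=seed, structure_id="domain_a")
        dom_b = toy_helix(nb, chain_id="B", seed=seed + 1, structure_id="domain_b")
        return {
            "domain_a": dom_a,
            "domain_b": dom_b,
            # tether the C-terminal CA of A to the N-terminal CA of B
            "anchor_a_index": dom_a.atom_index("CA", residue_index=na),
            "anchor_b_index": dom_b.atom_index("CA", residue_index=1),
            "n_linker_beads": params.get("n_linker_beads", 6),
            "spacing": params.get("spacing", 3.8),
        }
    if kind == "synthetic_saxs_target":
        return synthetic_saxs_target(
            n_residues=params.get("n_residues", 12),
            displacement=params.get("displacement", (15.0, 5.0, 0.0)),
            q_grid=params.get("q_grid"),
            sigma=params.get("sigma", 0.0),
            seed=seed)
    raise ValidationError(f"unknown fixture kind {kind!r}; known: {FIXTURE_KINDS}")


def synthetic_saxs_target(n_residues: int = 12, displacement=(15.0, 5.0, 0.0),
                          q_grid=None, sigma: float = 0.0, seed: int = 0) -> dict:
    """A two-domain scene at a known pose plus its Debye profile as 'data'.

    Builds two coarse-grained toy helices, places the second at the given
    translation (the generating pose), computes the residue-grained Debye
    profile on ``q_grid`` (default 0.01-0.5 1/A, 50 points) and adds Gaussian
    noise of standard deviation ``sigma`` (fraction of I(q), per point).
    With ``sigma=0`` a fit at the generating pose returns chi2 = 0 exactly.
    """
    from .coarse import coarse_grain
    from .observables import saxs_debye_scene
    from .structio import SAXSProfile

    if q_grid is None:
        q_grid = np.linspace(0.01, 0.5, 50)
    q_grid = np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    dom_a = toy_helix(n_residues, chain_id="A", seed=seed, structure_id="saxs_a")
    dom_b = toy_helix(n_residues, chain_id="B", seed=seed + 1, structure_id="saxs_b")
    beads_a = coarse_grain(dom_a)
    beads_b = coarse_grain(dom_b)
    pose_b = Pose(translation=np.asarray(displacement, dtype=float))
    molecules = [AnchoredMolecule(beads_a, 0, Pose.identity(), "A"),
                 AnchoredMolecule(beads_b, 0, pose_b, "B")]
    scene = assemble_scene(molecules)
    profile = saxs_debye_scene(scene, q_grid)
    intensity = profile.intensity.copy()
    sig = None
    if sigma > 0:
        sig = sigma * intensity
        intensity = intensity + rng.normal(scale=sig)
    target = SAXSProfile(q_grid, intensity, sig)
    return {"profile": target, "beads_a": beads_a, "beads_b": beads_b,
            "true_pose": pose_b, "molecules": molecules, "scene": scene}
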