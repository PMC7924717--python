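"""Structures, rigid 6-DOF poses, assembled scenes and the plain-text formats
around them.

The central abstraction is a *scene*: one or more molecules, each anchored to a
rigid-body pose (rotation + translation + display zoom) through a designated
anchor atom, mirroring how a fiducial marker drives a molecule in augmented
reality.  All physics and observables downstream consume world coordinates in
angstroms; the pose ``scale`` is a display-only zoom applied at export time.

File formats handled here: PDB (read, via gemmi; write for fixtures),
two/three-column SAXS profiles, TSV residue-contact tables and a plain-text
pose-trajectory format (one frame per line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation, Slerp

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Extra margin added to the sum of covalent radii when inferring bonds (A).
BOND_TOLERANCE = 0.4

_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """A single atom with coordinates in angstroms.

    ``residue_index`` keeps the author-assigned residue number from the source
    file; insertion codes are carried separately in ``insertion_code`` so the
    pair (index, icode) remains a unique residue key.
    ``partial_charge`` is in elementary-charge units (default 0).
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray
    partial_charge: float = 0.0
    insertion_code: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValidationError(f"atom {self.serial}: position must be a finite 3-vector")
        if not self.element:
            raise ValidationError(f"atom {self.serial}: element must be non-empty")

    @property
    def residue_key(self) -> str:
        return f"{self.residue_index}{self.insertion_code}"

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def is_backbone(self) -> bool:
        return self.name in _BACKBONE_NAMES


@dataclass
class Structure:
    """An ordered collection of atoms plus a bond list (atom-index pairs)."""

    atoms: list[Atom]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        cleaned = []
        for i, j in self.bonds:
            if i == j:
                raise ValidationError(f"self-bond on atom index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"bond ({i}, {j}) out of range for {n} atoms")
            cleaned.append((min(i, j), max(i, j)))
        self.bonds = sorted(set(cleaned))

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of positions in angstroms, file order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.partial_charge for a in self.atoms], dtype=float)

    def atom_index(self, name: str, residue_index: int | None = None,
                   chain_id: str | None = None) -> int:
        """Index of the first atom matching name (and optional residue/chain)."""
        for i, a in enumerate(self.atoms):
            if a.name != name:
                continue
            if residue_index is not None and a.residue_index != residue_index:
                continue
            if chain_id is not None and a.chain_id != chain_id:
                continue
            return i
        raise KeyError(f"no atom {name!r} (residue {residue_index}, chain {chain_id}) in {self.id!r}")

    def residues(self) -> list[tuple[str, str, str, list[int]]]:
        """Group atoms by residue, preserving order.

        Returns (chain_id, residue_key, residue_name, atom indices) tuples.
        """
        out: list[tuple[str, str, str, list[int]]] = []
        seen: dict[tuple[str, str], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_key)
            if key not in seen:
                seen[key] = len(out)
                out.append((a.chain_id, a.residue_key, a.residue_name, []))
            out[seen[key]][3].append(i)
        return out


@dataclass
class Pose:
    """Rigid 6-DOF transform: unit quaternion (w, x, y, z) + translation (A).

    ``scale`` is a positive display zoom; it never reaches the physics, which
    always works at scale 1 (see :func:`assemble_scene`).
    """

    quaternion: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.quaternion = np.asarray(self.quaternion, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.quaternion.shape != (4,):
            raise ValidationError("quaternion must have 4 components (w, x, y, z)")
        norm = float(np.linalg.norm(self.quaternion))
        if abs(norm - 1.0) > 1e-9:
            raise ValidationError(f"quaternion norm {norm:.12f} != 1 (non-unit rotation)")
        if self.translation.shape != (3,):
            raise ValidationError("translation must be a 3-vector")
        if not self.scale > 0:
            raise ValidationError("scale must be positive")

    @classmethod
    def identity(cls) -> "Pose":
        return cls()

    @classmethod
    def from_rotation(cls, rotation: Rotation, translation=(0.0, 0.0, 0.0),
                      scale: float = 1.0) -> "Pose":
        x, y, z, w = rotation.as_quat()
        return cls(np.array([w, x, y, z]), np.asarray(translation, dtype=float), scale)

    @property
    def rotation(self) -> Rotation:
        w, x, y, z = self.quaternion
        return Rotation.from_quat([x, y, z, w])

    @property
    def matrix(self) -> np.ndarray:
        """3x3 orthonormal rotation matrix (determinant +1)."""
        return self.rotation.as_matrix()


def apply_pose(points: np.ndarray, pose: Pose, anchor: Sequence[float]) -> np.ndarray:
    """Map local points into world coordinates through a rigid pose.

    Each point maps to ``R @ (scale * (p - anchor)) + t``, so the anchor point
    itself lands exactly on the pose translation and, at scale 1, all pairwise
    distances are preserved (rigid motion).
    """
    if not isinstance(pose, Pose):
        raise ValidationError("pose must be a Pose instance")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    anchor = np.asarray(anchor, dtype=float)
    world = (pose.scale * (pts - anchor)) @ pose.matrix.T + pose.translation
    return world


def interpolate_pose(current: Pose, target: Pose, t: float) -> Pose:
    """Interpolate between two poses along a straight line / great-circle arc.

    Translation and scale interpolate linearly; rotation follows the shortest
    great-circle arc (slerp).  ``t`` = 0 returns ``current``, 1 returns
    ``target``.  Used to drive a predefined binding coordinate that brings two
    molecules together.
    """
    if not 0.0 <= t <= 1.0:
        raise ValidationError(f"interpolation fraction t={t} outside [0, 1]")
    if t == 0.0:
        return replace(current)
    if t == 1.0:
        return replace(target)
    slerp = Slerp([0.0, 1.0], Rotation.concatenate([current.rotation, target.rotation]))
    rot = slerp(t)
    trans = (1.0 - t) * current.translation + t * target.translation
    scale = (1.0 - t) * current.scale + t * target.scale
    return Pose.from_rotation(rot, trans, scale)


@dataclass
class AnchoredMolecule:
    """A structure or bead model rigidly attached to a pose via an anchor atom.

    The anchor plays the role of the alpha carbon pinned to the marker center:
    after assembly the anchor sits exactly at the pose translation.
    """

    molecule: object  # Structure or coarse.BeadModel (duck-typed via .coords)
    anchor_index: int
    pose: Pose = field(default_factory=Pose.identity)
    mol_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.local_coords())
        if not (0 <= self.anchor_index < n):
            raise ValidationError(
                f"anchor index {self.anchor_index} out of range for {n} sites")
        if not self.mol_id:
            self.mol_id = getattr(self.molecule, "id", "") or getattr(
                self.molecule, "source_id", "") or "mol"

    def local_coords(self) -> np.ndarray:
        return self.molecule.coords

    def radii(self) -> np.ndarray:
        mol = self.molecule
        if hasattr(mol, "radii") and not callable(getattr(mol, "radii")):
            return np.asarray(mol.radii, dtype=float)
        if hasattr(mol, "atoms"):
            return np.array([display_radius(a.element) for a in mol.atoms])
        raise ValidationError("molecule carries neither beads nor atoms")


def display_radius(element: str) -> float:
    """Ball-and-stick display radius for an element (quarter van der Waals)."""
    return 0.25 * float(gemmi.Element(element).vdw_r)


@dataclass
class SceneMolecule:
    """One molecule of an assembled scene, in world coordinates (A)."""

    mol_id: str
    world_coords: np.ndarray
    radii: np.ndarray
    source: object
    pose: Pose
    anchor_index: int


@dataclass
class Scene:
    """World-coordinate snapshot of every anchored molecule."""

    molecules: list[SceneMolecule]

    def __getitem__(self, mol_id: str) -> SceneMolecule:
        for m in self.molecules:
            if m.mol_id == mol_id:
                return m
        raise KeyError(mol_id)

    def all_coords(self) -> np.ndarray:
        return np.vstack([m.world_coords for m in self.molecules])


def assemble_scene(molecules: Sequence[AnchoredMolecule]) -> Scene:
    """Place every molecule in world coordinates through its pose.

    The anchor atom of each molecule lands at its pose translation; zoom is
    deliberately NOT applied here — physics and observables always see
    unscaled angstrom coordinates, the zoom being a display correction only.
    """
    if len(molecules) == 0:
        raise ValidationError("a scene needs at least one molecule")
    out = []
    for am in molecules:
        local = am.local_coords()
        anchor = local[am.anchor_index]
        pose1 = replace(am.pose, scale=1.0)
        world = apply_pose(local, pose1, anchor)
        out.append(SceneMolecule(am.mol_id, world, am.radii(), am.molecule,
                                 am.pose, am.anchor_index))
    return Scene(out)


# ---------------------------------------------------------------------------
# PDB input / output
# ---------------------------------------------------------------------------

def _validate_pdb_coordinates(path: Path) -> None:
    # gemmi zero-fills unparsable coordinate fields, so check them explicitly
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    fld = line[lo:hi].strip()
                    try:
                        float(fld)
                    except ValueError:
                        raise FormatError(
                            f"{path}: non-numeric coordinate {fld!r} on line {lineno}")


def read_pdb(path, altloc: str = "occupancy", keep_hydrogens: bool = True,
             infer_bonds_if_missing: bool = True) -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Both ATOM and HETATM records are kept, in file order, with coordinates
    exactly as written.  Alternate locations are resolved per ``altloc``:
    ``"occupancy"`` (default) keeps the highest-occupancy conformer, ties
    broken by file order; ``"first"`` keeps the first conformer seen.
    CONECT records become bonds; when a file carries none, bonds are inferred
    from interatomic distances (cutoff = sum of covalent radii + 0.4 A).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")
    if altloc not in ("occupancy", "first"):
        raise ValidationError(f"unknown altloc policy {altloc!r}")
    _validate_pdb_coordinates(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc

    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    if len(st) == 0:
        raise FormatError(f"{path}: no models / no parseable atoms")
    model = st[0]
    for chain in model:
        for res in chain:
            chosen: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for atom in res:
                if not keep_hydrogens and atom.element.is_hydrogen():
                    continue
                if atom.name not in chosen:
                    chosen[atom.name] = atom
                    order.append(atom.name)
                elif altloc == "occupancy" and atom.occ > chosen[atom.name].occ:
                    chosen[atom.name] = atom
            for name in order:
                atom = chosen[name]
                idx = len(atoms)
                serial_to_index[atom.serial] = idx
                atoms.append(Atom(
                    serial=atom.serial,
                    name=name,
                    element=atom.element.name,
                    residue_name=res.name,
                    residue_index=res.seqid.num,
                    chain_id=chain.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    insertion_code=(res.seqid.icode or "").strip(),
                ))
    if not atoms:
        raise FormatError(f"{path}: zero parseable ATOM/HETATM records")

    bonds: list[tuple[int, int]] = []
    for serial, partners in st.conect_map.items():
        for partner in partners:
            if serial in serial_to_index and partner in serial_to_index:
                i, j = serial_to_index[serial], serial_to_index[partner]
                if i != j:
                    bonds.append((min(i, j), max(i, j)))
    structure = Structure(atoms=atoms, bonds=sorted(set(bonds)),
                          id=path.stem)
    if not structure.bonds and infer_bonds_if_missing:
        structure.bonds = infer_bonds(structure)
    return structure


def infer_bonds(structure: Structure) -> list[tuple[int, int]]:
    """Distance-based bond inference: d < r_cov(i) + r_cov(j) + 0.4 A."""
    coords = structure.coords
    radii = np.array([gemmi.Element(a.element).covalent_r for a in structure.atoms])
    if len(coords) < 2:
        return []
    tree = cKDTree(coords)
    rmax = 2 * radii.max() + BOND_TOLERANCE
    bonds = []
    for i, j in tree.query_pairs(rmax):
        d = np.linalg.norm(coords[i] - coords[j])
        if d < radii[i] + radii[j] + BOND_TOLERANCE and d > 1e-6:
            bonds.append((min(i, j), max(i, j)))
    return sorted(bonds)


def write_pdb(structure: Structure, path) -> None:
    """Write a Structure as minimal PDB ATOM/HETATM + CONECT records."""
    path = Path(path)
    lines = []
    for i, a in enumerate(structure.atoms):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"ATOM  {a.serial:5d} {name:<4.4s} {a.residue_name:<3.3s} "
            f"{a.chain_id[:1] or 'A'}{a.residue_index:4d}{a.insertion_code[:1] or ' '}   "
            f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2.2s}")
    serials = [a.serial for a in structure.atoms]
    partners: dict[int, list[int]] = {}
    for i, j in structure.bonds:
        partners.setdefault(serials[i], []).append(serials[j])
        partners.setdefault(serials[j], []).append(serials[i])
    for s in sorted(partners):
        for k in range(0, len(partners[s]), 4):
            chunk = "".join(f"{p:5d}" for p in sorted(partners[s])[k:k + 4])
            lines.append(f"CONECT{s:5d}{chunk}")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# SAXS profiles
# ---------------------------------------------------------------------------

@dataclass
class SAXSProfile:
    """A 1-D scattering profile I(q), optionally with per-point errors."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise ValidationError("sigma length differs from q length")
        if self.q.shape != self.intensity.shape or self.q.ndim != 1:
            raise ValidationError("q and intensity must be 1-D arrays of equal length")
        if len(self.q) and not np.all(np.diff(self.q) > 0):
            raise ValidationError("q grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.q)


def read_saxs_profile(path) -> SAXSProfile:
    """Read a 2- or 3-column (q, I[, sigma]) plain-text profile.

    Comment lines start with '#'.  Rows with non-positive q are dropped (with
    a logged count); a non-ascending grid is sorted with a warning.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric field in line {line!r}") from exc
            if len(vals) < 2:
                raise FormatError(f"{path}: need >= 2 columns, got {len(vals)}")
            rows.append(vals[:3])
    if not rows:
        raise FormatError(f"{path}: empty profile")
    ncol = min(len(r) for r in rows)
    arr = np.array([r[:ncol] for r in rows], dtype=float)
    keep = arr[:, 0] > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d rows with non-positive q from %s", dropped, path)
    arr = arr[keep]
    if not np.all(np.diff(arr[:, 0]) > 0):
        logger.warning("q grid in %s not strictly ascending; sorting", path)
        arr = arr[np.argsort(arr[:, 0], kind="stable")]
    sigma = arr[:, 2] if ncol >= 3 else None
    return SAXSProfile(arr[:, 0], arr[:, 1], sigma)


def write_saxs_profile(profile: SAXSProfile, path, header: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# q(A^-1) I(q)" + (" sigma" if profile.sigma is not None else "") + "\n")
        for i in range(len(profile)):
            row = f"{profile.q[i]:.16e} {profile.intensity[i]:.16e}"
            if profile.sigma is not None:
                row += f" {profile.sigma[i]:.16e}"
            fh.write(row + "\n")


# ---------------------------------------------------------------------------
# Residue-contact tables
# ---------------------------------------------------------------------------

TIERS = ("high", "intermediate", "low")


@dataclass
class ContactPrediction:
    """A predicted residue-residue contact (e.g. from coevolution analysis)."""

    residue_a: tuple[str, int]
    residue_b: tuple[str, int]
    tier: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValidationError(f"tier must be one of {TIERS}, got {self.tier!r}")


def read_contact_table(path, high_threshold: float = 0.9,
                       intermediate_threshold: float = 0.6) -> list[ContactPrediction]:
    """Read a TSV of contacts: chain_a, res_a, chain_b, res_b, tier-or-score.

    A numeric fifth column is binned into tiers (score >= ``high_threshold``
    -> high, >= ``intermediate_threshold`` -> intermediate, else low);
    explicit tier labels pass through unchanged.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=["chain_a", "res_a", "chain_b", "res_b", "tier"],
                         dtype={"chain_a": str, "chain_b": str})
    except pd.errors.EmptyDataError:
        return []
    out: list[ContactPrediction] = []
    for _, row in df.iterrows():
        raw = str(row["tier"]).strip()
        score = None
        try:
            score = float(raw)
        except ValueError:
            pass
        if score is not None:
            tier = ("high" if score >= high_threshold
                    else "intermediate" if score >= intermediate_threshold
                    else "low")
        else:
            tier = raw.lower()
            if tier not in TIERS:
                raise FormatError(f"{path}: unknown tier label {raw!r}")
        out.append(ContactPrediction(
            (str(row["chain_a"]), int(row["res_a"])),
            (str(row["chain_b"]), int(row["res_b"])),
            tier, score))
    return out


# ---------------------------------------------------------------------------
# Pose trajectories
# ---------------------------------------------------------------------------
# One frame per line: frame_index  mol_id  qw qx qy qz  tx ty tz  [scale]
# This plain-text record replaces the live marker-tracking stream of an AR
# session; '#' starts a comment.

def read_pose_trajectory(path) -> list[dict[str, Pose]]:
    """Read a pose trajectory; returns one {mol_id: Pose} mapping per frame."""
    path = Path(path)
    frames: dict[int, dict[str, Pose]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (9, 10):
                raise FormatError(f"{path}:{lineno}: expected 9 or 10 fields, got {len(parts)}")
            try:
                frame = int(parts[0])
                nums = [float(p) for p in parts[2:]]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric field") from exc
            quat = np.array(nums[0:4])
            quat = quat / np.linalg.norm(quat)
            scale = nums[7] if len(nums) == 8 else 1.0
            frames.setdefault(frame, {})[parts[1]] = Pose(quat, np.array(nums[4:7]), scale)
    return [frames[k] for k in sorted(frames)]


def write_pose_trajectory(frames: Iterable[dict[str, Pose]], path,
                          header: str = "") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# frame mol_id qw qx qy qz tx ty tz scale\n")
        for i, frame in enumerate(frames):
            for mol_id, pose in frame.items():
                q, t = pose.quaternion, pose.translation
                fh.write(f"{i} {mol_id} "
                         f"{q[0]:.12g} {q[1]:.12g} {q[2]:.12g} {q[3]:.12g} "
                         f"{t[0]:.12g} {t[1]:.12g} {t[2]:.12g} {pose.scale:.12g}\n")
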