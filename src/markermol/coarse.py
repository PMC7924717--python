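"""Residue-grained bead models: two spheres per residue.

Each amino acid is reduced to a backbone bead centered on its alpha carbon and
a sidechain bead at the centroid of its sidechain heavy atoms; glycine, having
no heavy sidechain, becomes a single backbone bead.  Bead radii are the cube
root of tabulated mean residue volumes, so relative amino-acid sizes are
respected, times a configurable scale factor (default 0.5: raw cube roots of
3.9-6.1 A would overlap heavily at the 3.8 A alpha-carbon spacing of a chain,
so half-size beads are used for display and collision work while the raw value
stays recoverable with ``scale_factor=1``).

Beads carry one of six physicochemical color classes used throughout display
and OBJ export: hydrophobic (gray), negative (red), positive (blue), polar
uncharged (green), backbone (black) and linker (orange).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .structio import Structure

logger = logging.getLogger(__name__)

DEFAULT_RADIUS_SCALE = 0.5

COLOR_CLASSES = ("hydrophobic", "negative", "positive", "polar", "backbone", "linker")

_NEGATIVE = {"ASP", "GLU"}
_POSITIVE = {"LYS", "ARG", "HIS"}  # His grouped with the basic residues
_POLAR = {"SER", "THR", "ASN", "GLN", "TYR", "CYS"}

_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def _load_table(filename: str) -> dict[str, float]:
    text = resources.files("markermol.data").joinpath(filename).read_text()
    table: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            code, value = line.split()
            table[code.upper()] = float(value)
    return table


RESIDUE_VOLUMES: dict[str, float] = _load_table("residue_volumes.tsv")
RESIDUE_ELECTRONS: dict[str, float] = _load_table("residue_electrons.tsv")


def load_volume_table(path) -> dict[str, float]:
    """Load a user-supplied residue-volume table (TSV: code, volume in A^3)."""
    table: dict[str, float] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            code, value = line.split()
            table[code.upper()] = float(value)
    return table


def residue_radius(residue_name: str, scale_factor: float = DEFAULT_RADIUS_SCALE,
                   volume_table: dict[str, float] | None = None) -> float:
    """Bead radius in angstroms: cube root of the residue volume, scaled."""
    table = volume_table if volume_table is not None else RESIDUE_VOLUMES
    code = residue_name.upper()
    if code not in table:
        raise ValidationError(
            f"unknown residue {residue_name!r}; valid codes: {sorted(table)}")
    return float(table[code]) ** (1.0 / 3.0) * scale_factor


def residue_class(residue_name: str, kind: str) -> str:
    """Physicochemical color class of a bead.

    Backbone and linker beads take their kind's own class; sidechain beads are
    classified as negative (Asp/Glu), positive (Lys/Arg/His), polar uncharged
    (Ser/Thr/Asn/Gln/Tyr/Cys) or hydrophobic (everything else).
    """
    code = residue_name.upper()
    if code not in RESIDUE_VOLUMES:
        raise ValidationError(f"unknown residue {residue_name!r}")
    if kind == "backbone":
        return "backbone"
    if kind == "linker":
        return "linker"
    if kind != "sidechain":
        raise ValidationError(f"unknown bead kind {kind!r}")
    if code in _NEGATIVE:
        return "negative"
    if code in _POSITIVE:
        return "positive"
    if code in _POLAR:
        return "polar"
    return "hydrophobic"


@dataclass
class Bead:
    position: np.ndarray
    radius: float
    kind: str  # backbone | sidechain | linker
    residue_name: str
    residue_index: int
    chain_id: str
    color_class: str

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.radius > 0:
            raise ValidationError("bead radius must be positive")


@dataclass
class BeadModel:
    """Ordered bead list for one (or part of one) molecule.

    For a protein chain the bead count is 2*n_residues - n_glycines: every
    residue contributes a backbone bead and every non-glycine a sidechain bead.
    """

    beads: list[Bead]
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.beads)

    @property
    def coords(self) -> np.ndarray:
        return np.array([b.position for b in self.beads], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([b.radius for b in self.beads], dtype=float)

    def find(self, chain_id: str, residue_index: int,
             prefer_sidechain: bool = True) -> int:
        """Index of the bead representing a residue (sidechain bead if present)."""
        backbone = None
        for i, b in enumerate(self.beads):
            if b.chain_id == chain_id and b.residue_index == residue_index:
                if b.kind == "sidechain" and prefer_sidechain:
                    return i
                if backbone is None:
                    backbone = i
        if backbone is None:
            raise KeyError(f"residue {chain_id}:{residue_index} not in bead model "
                           f"{self.source_id!r}")
        return backbone


def coarse_grain(structure: Structure, scale_factor: float = DEFAULT_RADIUS_SCALE,
                 mass_weighted: bool = False,
                 volume_table: dict[str, float] | None = None) -> BeadModel:
    """Reduce an atomistic structure to two beads per residue.

    Backbone bead at the alpha-carbon position; sidechain bead at the center
    of the sidechain heavy atoms — unweighted centroid by default, atomic-mass
    weighted with ``mass_weighted=True``.  Glycine yields a single
    backbone-kind bead at its alpha carbon.
    """
    import gemmi  # local: only needed for atomic masses

    beads: list[Bead] = []
    for chain_id, residue_key, residue_name, indices in structure.residues():
        atoms = [structure.atoms[i] for i in indices]
        ca = next((a for a in atoms if a.name == "CA"), None)
        if ca is None:
            raise ValidationError(
                f"residue {chain_id}:{residue_key} ({residue_name}) has no CA atom")
        radius = residue_radius(residue_name, scale_factor, volume_table)
        resnum = ca.residue_index
        beads.append(Bead(ca.position.copy(), radius, "backbone", residue_name,
                          resnum, chain_id, residue_class(residue_name, "backbone")))
        side = [a for a in atoms if not a.is_backbone and not a.is_hydrogen]
        if residue_name.upper() == "GLY":
            continue
        if not side:
            warnings.warn(f"residue {chain_id}:{residue_key} ({residue_name}) has no "
                          "sidechain heavy atoms; backbone-only bead", stacklevel=2)
            continue
        pos = np.array([a.position for a in side])
        if mass_weighted:
            w = np.array([gemmi.Element(a.element).weight for a in side])
            center = (pos * w[:, None]).sum(axis=0) / w.sum()
        else:
            center = pos.mean(axis=0)
        beads.append(Bead(center, radius, "sidechain", residue_name, resnum,
                          chain_id, residue_class(residue_name, "sidechain")))
    return BeadModel(beads, source_id=structure.id)


def scattering_weights(model: BeadModel, mode: str = "unit") -> np.ndarray:
    """Per-bead scattering weights for the Debye sum.

    ``"unit"`` (default) gives every bead weight 1 — the fast, simple choice.
    ``"electrons"`` distributes the residue electron count over the residue's
    beads (all on the single bead for glycine, half-and-half otherwise), a
    rough step toward parameterized coarse-grained scattering centers.
    """
    if mode == "unit":
        return np.ones(len(model))
    if mode != "electrons":
        raise ValidationError(f"unknown scattering-weight mode {mode!r}")
    counts: dict[tuple[str, int], int] = {}
    for b in model.beads:
        key = (b.chain_id, b.residue_index)
        counts[key] = counts.get(key, 0) + 1
    out = np.empty(len(model))
    for i, b in enumerate(model.beads):
        total = RESIDUE_ELECTRONS.get(b.residue_name.upper(), 60.0)
        out[i] = total / counts[(b.chain_id, b.residue_index)]
    return out
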