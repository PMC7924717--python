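"""Wavefront OBJ + MTL export of ball-and-stick scenes.

Every sphere (atom or bead) becomes an icosphere mesh and every bond a
cylinder, grouped as one ``o`` object each, with one MTL material per color
class.  This is the one place the pose ``scale`` (display zoom) is honored:
physics always runs unzoomed, but exported meshes are scaled for screen fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .coarse import BeadModel
from .errors import MarkermolError
from .structio import Scene, display_radius

#: Diffuse colors of the bead color classes (and a default for elements).
CLASS_COLORS = {
    "hydrophobic": (0.55, 0.55, 0.55),
    "negative": (0.85, 0.10, 0.10),
    "positive": (0.15, 0.25, 0.85),
    "polar": (0.10, 0.65, 0.20),
    "backbone": (0.05, 0.05, 0.05),
    "linker": (0.95, 0.55, 0.10),
    "bond": (0.75, 0.75, 0.75),
}

ELEMENT_COLORS = {
    "C": (0.35, 0.35, 0.35), "N": (0.2, 0.3, 0.9), "O": (0.9, 0.15, 0.15),
    "H": (0.95, 0.95, 0.95), "S": (0.9, 0.8, 0.15), "P": (0.9, 0.55, 0.1),
}


@dataclass
class ObjExportReport:
    n_objects: int
    n_vertices: int
    n_faces: int
    obj_path: Path
    mtl_path: Path
    materials: list[str]


def _sphere_material(source, index: int) -> str:
    if isinstance(source, BeadModel):
        return source.beads[index].color_class
    atom = source.atoms[index]
    return f"elem_{atom.element.upper()}"


def _material_color(name: str):
    if name.startswith("elem_"):
        return ELEMENT_COLORS.get(name[5:], (0.8, 0.2, 0.8))
    return CLASS_COLORS[name]


def write_obj_ballstick(scene: Scene, path_prefix, sphere_subdivisions: int = 1,
                        bond_radius: float = 0.15, cylinder_sections: int = 12,
                        apply_zoom: bool = True) -> ObjExportReport:
    """Write ``<prefix>.obj`` and ``<prefix>.mtl`` for an assembled scene.

    Spheres honor per-site radii (bead radii or quarter-vdW atom radii);
    bonds of atomistic molecules become cylinders.  ``sphere_subdivisions=0``
    gives bare icosahedra (12 vertices, 20 faces per sphere).
    """
    prefix = Path(path_prefix)
    obj_path = prefix.with_suffix(".obj")
    mtl_path = prefix.with_suffix(".mtl")
    try:
        obj_fh = open(obj_path, "w")
    except OSError as exc:
        raise MarkermolError(f"cannot write {obj_path}: {exc}") from exc

    materials: list[str] = []
    n_objects = n_vertices = n_faces = 0
    with obj_fh:
        obj_fh.write(f"mtllib {mtl_path.name}\n")
        v_offset = 1  # OBJ indices are 1-based and global
        for mol in scene.molecules:
            zoom = mol.pose.scale if apply_zoom else 1.0
            center0 = mol.world_coords.mean(axis=0)
            coords = center0 + zoom * (mol.world_coords - center0)
            for i, pos in enumerate(coords):
                mesh = trimesh.creation.icosphere(
                    subdivisions=sphere_subdivisions,
                    radius=zoom * float(mol.radii[i]))
                mat = _sphere_material(mol.source, i)
                if mat not in materials:
                    materials.append(mat)
                v_offset = _write_mesh(obj_fh, mesh, pos,
                                       f"{mol.mol_id}_sphere{i}", mat, v_offset)
                n_objects += 1
                n_vertices += len(mesh.vertices)
                n_faces += len(mesh.faces)
            for k, (i, j) in enumerate(getattr(mol.source, "bonds", [])):
                seg = np.vstack([coords[i], coords[j]])
                if np.linalg.norm(seg[1] - seg[0]) < 1e-9:
                    continue
                mesh = trimesh.creation.cylinder(
                    radius=zoom * bond_radius, segment=seg,
                    sections=cylinder_sections)
                if "bond" not in materials:
                    materials.append("bond")
                v_offset = _write_mesh(obj_fh, mesh, np.zeros(3),
                                       f"{mol.mol_id}_bond{k}", "bond", v_offset)
                n_objects += 1
                n_vertices += len(mesh.vertices)
                n_faces += len(mesh.faces)

    with open(mtl_path, "w") as fh:
        for mat in materials:
            r, g, b = _material_color(mat)
            fh.write(f"newmtl {mat}\nKa {r:.3f} {g:.3f} {b:.3f}\n"
                     f"Kd {r:.3f} {g:.3f} {b:.3f}\nKs 0.2 0.2 0.2\nNs 20\n\n")
    return ObjExportReport(n_objects, n_vertices, n_faces, obj_path, mtl_path,
                           materials)


def _write_mesh(fh, mesh: trimesh.Trimesh, offset: np.ndarray, name: str,
                material: str, v_offset: int) -> int:
    fh.write(f"o {name}\nusemtl {material}\n")
    for v in mesh.vertices + offset:
        fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
    for vn in mesh.vertex_normals:
        fh.write(f"vn {vn[0]:.6f} {vn[1]:.6f} {vn[2]:.6f}\n")
    for f in mesh.faces:
        a, b, c = (int(x) + v_offset for x in f)
        fh.write(f"f {a}//{a} {b}//{b} {c}//{c}\n")
    return v_offset + len(mesh.vertices)
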