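"""PDB/mmCIF reading and writing (atom records only).

Only the first altloc ('A' or blank) is kept; author residue numbering is
preserved on output.  Parsing is delegated to biotite; this module only
converts between its ``AtomArray`` and :class:`~commloop.geometry.AtomStructure`.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .geometry import AtomStructure, Residue

log = logging.getLogger("commloop.io")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower().lstrip(".")
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "ent"):
        return "pdb"
    if suffix in ("cif", "mmcif", "pdbx"):
        return "cif"
    raise ValueError(f"cannot infer structure format from {path.name!r}")


def read_structure(path, fmt: str | None = None) -> AtomStructure:
    """Read a PDB or mmCIF file into an AtomStructure (first altloc kept)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    try:
        if fmt == "pdb":
            from biotite.structure.io.pdb import PDBFile
            f = PDBFile.read(str(path))
            arr = f.get_structure(model=1, altloc="first",
                                  extra_fields=["b_factor", "occupancy"])
        else:
            from biotite.structure.io.pdbx import CIFFile, get_structure
            f = CIFFile.read(str(path))
            arr = get_structure(f, model=1, altloc="first",
                                extra_fields=["b_factor", "occupancy"])
    except Exception as exc:  # pragma: no cover - error path
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc
    arr = arr[~arr.hetero]
    return atom_array_to_structure(arr)


def atom_array_to_structure(arr) -> AtomStructure:
    residues: list[Residue] = []
    key = None
    for i in range(arr.array_length()):
        k = (arr.chain_id[i], int(arr.res_id[i]), arr.ins_code[i]
             if hasattr(arr, "ins_code") else "")
        if k != key:
            residues.append(Residue(str(arr.res_name[i]), str(arr.chain_id[i]),
                                    int(arr.res_id[i])))
            if hasattr(arr, "b_factor"):
                residues[-1].b_factor = float(arr.b_factor[i])
            key = k
        name = str(arr.atom_name[i])
        if name in residues[-1].atoms:
            log.warning("duplicate atom %s in residue %s%d kept first",
                        name, k[0], k[1])
            continue
        residues[-1].atoms[name] = np.asarray(arr.coord[i], dtype=float)
    struct = AtomStructure(residues)
    struct.validate_finite()
    return struct


def structure_to_atom_array(struct: AtomStructure):
    import biotite.structure as bst

    n_atoms = sum(len(r.atoms) for r in struct.residues)
    arr = bst.AtomArray(n_atoms)
    arr.add_annotation("b_factor", float)
    arr.add_annotation("occupancy", float)
    i = 0
    for res in struct.residues:
        for name, xyz in res.atoms.items():
            arr.chain_id[i] = res.chain
            arr.res_id[i] = res.res_id
            arr.res_name[i] = res.name
            arr.atom_name[i] = name
            arr.element[i] = "S" if name.startswith("S") else name[:1]
            arr.hetero[i] = False
            arr.b_factor[i] = res.b_factor
            arr.occupancy[i] = res.occupancy
            arr.coord[i] = xyz
            i += 1
    return arr


def write_structure(struct: AtomStructure, path, fmt: str | None = None) -> None:
    """Write an AtomStructure as PDB or mmCIF (atom records only)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    arr = structure_to_atom_array(struct)
    if fmt == "pdb":
        from biotite.structure.io.pdb import PDBFile
        f = PDBFile()
        f.set_structure(arr)
        f.write(str(path))
    else:
        from biotite.structure.io.pdbx import CIFFile, set_structure
        f = CIFFile()
        set_structure(f, arr)
        f.write(str(path))
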