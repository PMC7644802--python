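"""Thin wrappers around biotite for reading/writing PDB fragment files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from .errors import LibraryError
from .geometry import PointSet


def load_atoms(path, model: int = 1) -> struc.AtomArray:
    """Read one model of a PDB file as a biotite ``AtomArray``.

    Missing element columns are tolerated: elements are inferred from atom
    names.
    """
    path = Path(path)
    try:
        f = pdb.PDBFile.read(str(path))
        atoms = pdb.get_structure(f, model=model)
    except Exception as exc:  # biotite raises various parse errors
        raise LibraryError(f"cannot parse PDB file {path}: {exc}") from exc
    if atoms.array_length() == 0:
        raise LibraryError(f"PDB file {path} contains no atoms")
    if (atoms.element == "").any():
        atoms.element = struc.infer_elements(atoms)
    return atoms


def model_count(path) -> int:
    f = pdb.PDBFile.read(str(Path(path)))
    return f.get_model_count()


def save_atoms(path, atoms: struc.AtomArray, extra_models: list | None = None):
    """Write an ``AtomArray`` (optionally followed by further models) as PDB."""
    f = pdb.PDBFile()
    if extra_models:
        # models may be heterogeneous (different atom counts): write blocks
        lines = []
        for i, m in enumerate([atoms] + list(extra_models), start=1):
            sub = pdb.PDBFile()
            pdb.set_structure(sub, m)
            lines.append(f"MODEL     {i:>4}")
            lines.extend(sub.lines)
            lines.append("ENDMDL")
        f.lines = lines
    else:
        pdb.set_structure(f, atoms)
    f.write(str(Path(path)))


def atom_labels(atoms: struc.AtomArray) -> list[str]:
    """Stable per-atom labels ``chain:resid:atomname``."""
    return [
        f"{c}:{int(r)}:{a}"
        for c, r, a in zip(atoms.chain_id, atoms.res_id, atoms.atom_name)
    ]


def coords64(atoms: struc.AtomArray) -> np.ndarray:
    """Coordinates as float64, re-quantized to the file's 3 decimals.

    biotite stores coordinates as float32; PDB files carry exactly three
    decimals, so rounding the widened values to 3 decimals is lossless and
    removes the float32 representation error (~1e-7 A).
    """
    return np.round(np.asarray(atoms.coord, dtype=np.float64), 3)


def as_pointset(atoms: struc.AtomArray) -> PointSet:
    return PointSet(coords=coords64(atoms), labels=atom_labels(atoms))
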