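"""Convert a coarse-grained design into an all-atom model.

Fragment atoms are projected through each instance's world transform, caps
are appended at every free extendable terminus (posed through the library's
pair transforms exactly like ordinary modules), chains are assigned to
maximal N->C linked paths, residues renumbered 1..n per chain, and the model
is emitted as an mmCIF atom_site loop.

Junction overlap removal uses the pair's ``drop_b_residues`` range (dropped
from the N-side module of each link); the toy library declares none.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .design_model import DesignScene
from .errors import CappingError, SceneError, ValidationError
from .geometry import PointSet, RigidTransform, compose
from .module_library import Library
from . import structio

#: C->N distance above which chain continuity is warned about (ideal ~1.33 A)
PEPTIDE_BOND_TOL = 2.0


def read_pdb_fragment(path) -> PointSet:
    """Read a PDB fragment as a labelled point set (``chain:resid:atom``)."""
    return structio.as_pointset(structio.load_atoms(path))


# ---------------------------------------------------------------------------
# capping
# ---------------------------------------------------------------------------


@dataclass
class Placement:
    """One rigid fragment placement in the capped design."""

    instance_id: str
    proto: str
    world: RigidTransform
    is_cap: bool = False
    host: tuple[str, str, str] | None = None  # (instance, chain, term) for caps


@dataclass
class CappedDesign:
    placements: list[Placement]
    #: (host instance, chain, term) -> cap placement
    caps_at: dict[tuple[str, str, str], Placement]


def _opposite(term: str) -> str:
    return "C" if term == "N" else "N"


def add_caps(scene: DesignScene) -> CappedDesign:
    """Pure capping pass: one cap per free extendable terminus.

    Sealed and occupied termini receive nothing.  Raises CappingError naming
    the interface token if the library lacks the needed cap prototype.
    """
    lib: Library = scene.library
    placements = [
        Placement(instance_id=iid, proto=m.proto, world=m.world)
        for iid, m in sorted(scene.modules.items())
    ]
    caps_at = {}
    for iid in sorted(scene.modules):
        mod = scene.modules[iid]
        proto = lib.get_module(mod.proto)
        for (chain, term), occ in sorted(mod.occupancy.items()):
            if occ is not None:  # occupied or sealed
                continue
            token = proto.chains[chain].iface(term)
            if token is None:
                continue
            cap_name = ("Ncap_" if term == "N" else "Ccap_") + token
            if cap_name not in lib.modules:
                raise CappingError(
                    f"no cap prototype for interface token {token!r} "
                    f"({cap_name!r} missing)"
                )
            cap_proto = lib.get_module(cap_name)
            pair = lib.find_pair(
                mod.proto, chain, term,
                cap_name, cap_proto.single_chain_id, _opposite(term),
            )
            cap = Placement(
                instance_id=f"{cap_name}@{iid}:{chain}{term}",
                proto=cap_name,
                world=compose(mod.world, pair.t),
                is_cap=True,
                host=(iid, chain, term),
            )
            placements.append(cap)
            caps_at[(iid, chain, term)] = cap
    return CappedDesign(placements=placements, caps_at=caps_at)


# ---------------------------------------------------------------------------
# chain assignment
# ---------------------------------------------------------------------------


def _chain_id_for(index: int) -> str:
    letters = string.ascii_uppercase
    if index < 26:
        return letters[index]
    index -= 26
    return letters[index // 26] + letters[index % 26]


def linked_paths(scene: DesignScene) -> list[list[tuple[str, str]]]:
    """Maximal N->C linked paths of (instance_id, chain_id) nodes.

    Deterministic: paths ordered by (network name, lowest instance id in
    path).
    """
    nodes = [
        (iid, cid)
        for iid in sorted(scene.modules)
        for cid in sorted(scene.library.get_module(scene.modules[iid].proto).chains)
    ]
    paths = []
    seen = set()
    for node in nodes:
        iid, cid = node
        occ = scene.modules[iid].occupancy.get((cid, "N"))
        if isinstance(occ, tuple):
            continue  # N side linked: not a path start
        path = []
        cur: tuple[str, str] | None = node
        while cur is not None:
            if cur in seen:
                raise SceneError(f"cyclic or branching chain at {cur}")
            seen.add(cur)
            path.append(cur)
            nxt = scene.modules[cur[0]].occupancy.get((cur[1], "C"))
            cur = (nxt[0], nxt[1]) if isinstance(nxt, tuple) else None
        paths.append(path)
    leftovers = [n for n in nodes if n not in seen]
    if leftovers:
        # pure cycles have no free N terminus; take lowest node as start
        raise SceneError(
            f"cyclic chain topology not supported for stitching: {leftovers[:3]}"
        )
    paths.sort(key=lambda p: (scene.network_of(p[0][0]), min(n[0] for n in p)))
    return paths


def assign_chains(scene: DesignScene) -> dict[tuple[tuple[str, str], ...], str]:
    """Map each maximal N->C path to an output chain id (A, B, ... AA, ...)."""
    return {
        tuple(path): _chain_id_for(i) for i, path in enumerate(linked_paths(scene))
    }


# ---------------------------------------------------------------------------
# model assembly
# ---------------------------------------------------------------------------


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray


@dataclass
class Residue:
    name: str
    number: int
    atoms: list[Atom]
    source: tuple[str, int]  # (instance id or cap id, original residue index)


@dataclass
class StitchChain:
    chain_id: str
    residues: list[Residue]


@dataclass
class StitchedModel:
    chains: list[StitchChain]
    warnings: list[str] = field(default_factory=list)

    @property
    def atom_count(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    def coords(self) -> np.ndarray:
        return np.array(
            [a.coord for c in self.chains for r in c.residues for a in r.atoms]
        ).reshape(-1, 3)


def _fragment_residues(lib: Library, proto: str, chain_id: str):
    """Fragment residues of one chain, ordered by residue id."""
    atoms = lib.load_fragment(proto)
    mask = atoms.chain_id == chain_id
    sub = atoms[mask]
    out = []
    for rid in sorted(set(int(r) for r in sub.res_id)):
        rmask = sub.res_id == rid
        out.append(
            (
                rid,
                str(sub.res_name[rmask][0]),
                list(sub.atom_name[rmask]),
                list(sub.element[rmask]),
                structio.coords64(sub[rmask]),
            )
        )
    return out


def _drop_range_for(scene: DesignScene, iid: str, cid: str) -> tuple[int, int] | None:
    """drop_b_residues of the pair that links into this node's N terminus."""
    occ = scene.modules[iid].occupancy.get((cid, "N"))
    if not isinstance(occ, tuple):
        return None
    parent_iid, parent_chain, _ = occ
    pair = scene.library.find_pair(
        scene.modules[parent_iid].proto, parent_chain, "C",
        scene.modules[iid].proto, cid, "N",
    )
    return pair.drop_b_residues


def stitch(
    scene: DesignScene, out_path=None, *, strict_continuity: bool = False
) -> StitchedModel:
    """Assemble the all-atom model; optionally write mmCIF to ``out_path``."""
    findings = scene.validate()
    if findings:
        raise ValidationError(findings)
    lib = scene.library
    capped = add_caps(scene)
    chain_map = assign_chains(scene)

    chains = []
    warnings = []
    for path, chain_id in chain_map.items():
        residues: list[Residue] = []

        def emit(source_id, proto, frag_chain, world, drop=None):
            for rid, rname, anames, elems, coords in _fragment_residues(
                lib, proto, frag_chain
            ):
                if drop is not None and drop[0] <= rid <= drop[1]:
                    continue
                atoms = [
                    Atom(name=n, element=e, coord=c)
                    for n, e, c in zip(anames, elems, world.apply_points(coords))
                ]
                residues.append(
                    Residue(
                        name=rname, number=0, atoms=atoms, source=(source_id, rid)
                    )
                )

        first_iid, first_cid = path[0]
        ncap = capped.caps_at.get((first_iid, first_cid, "N"))
        if ncap is not None:
            emit(ncap.instance_id, ncap.proto,
                 lib.get_module(ncap.proto).single_chain_id, ncap.world)
        for iid, cid in path:
            mod = scene.modules[iid]
            emit(iid, mod.proto, cid, mod.world,
                 drop=_drop_range_for(scene, iid, cid))
        last_iid, last_cid = path[-1]
        ccap = capped.caps_at.get((last_iid, last_cid, "C"))
        if ccap is not None:
            emit(ccap.instance_id, ccap.proto,
                 lib.get_module(ccap.proto).single_chain_id, ccap.world)

        for i, res in enumerate(residues, start=1):
            res.number = i
        # peptide-bond continuity between consecutive residues
        for prev, cur in zip(residues, residues[1:]):
            c_atom = next((a for a in prev.atoms if a.name == "C"), None)
            n_atom = next((a for a in cur.atoms if a.name == "N"), None)
            if c_atom is None or n_atom is None:
                continue
            d = float(np.linalg.norm(c_atom.coord - n_atom.coord))
            if d > PEPTIDE_BOND_TOL:
                warnings.append(
                    f"chain {chain_id}: C-N distance {d:.2f} A between "
                    f"residues {prev.number} and {cur.number}"
                )
        chains.append(StitchChain(chain_id=chain_id, residues=residues))

    model = StitchedModel(chains=chains, warnings=warnings)
    if strict_continuity and warnings:
        raise ValidationError(warnings)
    if out_path is not None:
        write_mmcif(model, out_path)
    return model


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_mmcif(model: StitchedModel, path):
    """Write the model as a minimal mmCIF atom_site loop (3-decimal coords)."""
    if model.atom_count == 0:
        raise SceneError("refusing to write an empty model")
    lines = [
        "data_blockfold_model",
        "#",
        "loop_",
        "_atom_site.group_PDB",
        "_atom_site.id",
        "_atom_site.type_symbol",
        "_atom_site.label_atom_id",
        "_atom_site.label_alt_id",
        "_atom_site.label_comp_id",
        "_atom_site.label_asym_id",
        "_atom_site.label_entity_id",
        "_atom_site.label_seq_id",
        "_atom_site.pdbx_PDB_ins_code",
        "_atom_site.Cartn_x",
        "_atom_site.Cartn_y",
        "_atom_site.Cartn_z",
        "_atom_site.occupancy",
        "_atom_site.B_iso_or_equiv",
        "_atom_site.auth_seq_id",
        "_atom_site.auth_comp_id",
        "_atom_site.auth_asym_id",
        "_atom_site.auth_atom_id",
        "_atom_site.pdbx_PDB_model_num",
    ]
    serial = 0
    for entity, chain in enumerate(model.chains, start=1):
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coord
                lines.append(
                    f"ATOM {serial} {atom.element} {atom.name} . {res.name} "
                    f"{chain.chain_id} {entity} {res.number} ? "
                    f"{x:.3f} {y:.3f} {z:.3f} 1.00 0.00 "
                    f"{res.number} {res.name} {chain.chain_id} {atom.name} 1"
                )
    lines.append("#")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pdb(model: StitchedModel, path):
    """Legacy PDB output; refused when the model exceeds format limits."""
    if model.atom_count == 0:
        raise SceneError("refusing to write an empty model")
    if model.atom_count > 99999:
        raise SceneError(
            f"model has {model.atom_count} atoms; PDB format allows at most "
            "99999 — write mmCIF instead"
        )
    for chain in model.chains:
        if len(chain.chain_id) > 1:
            raise SceneError(
                f"chain id {chain.chain_id!r} does not fit the single-character "
                "PDB chain column — write mmCIF instead"
            )
    lines = []
    serial = 0
    for chain in model.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.coord
                name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3}"
                lines.append(
                    f"ATOM  {serial:>5} {name}{res.name:>4} {chain.chain_id}"
                    f"{res.number:>4}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
                    f"          {atom.element:>2}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
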