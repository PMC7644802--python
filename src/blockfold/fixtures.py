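"""Deterministic synthetic toy module library.

Generates PDB fragments, posed pair structures, a manifest, and a sidecar
file of analytically known pair transforms, then runs the normal library
build on them.  Every transform in the toy library is exact by construction,
so it serves as ground truth for placement, collision, solver, and stitching
tests without any downloaded data.

Geometry: toy "atoms" wind about z like an idealized helix, but are built
from a residue template with two-decimal coordinates rotated only by
multiples of 90 degrees (exact rotation-matrix entries).  Every emitted
coordinate — including the posed module in each pair structure — is then
exactly representable at the PDB format's three decimals, so writing and
re-reading fragments loses nothing and the library build recovers the
analytic pair transforms to machine precision.  The twist per residue is
``360/m`` degrees for an ``m``-residue module, so a module's successor
transform is a pure translation ``(0, 0, rise)``.  Backbone atom names
N, CA, C, O are used so peptide-bond continuity checks are meaningful;
consecutive C->N distances are well under 2 A by construction, including
across module boundaries.  Exactness holds for the default config
(4 residues/module, 90-degree bend, C2/C4 hubs); other configs remain
valid but are only as precise as the PDB format.

Toy prototypes:

- ``H4``, ``K4``    - straight single-chain core modules
- ``H4_j1_K4``      - junction bent by ``junction_bend`` degrees about x
- ``Ncap_*/Ccap_*`` - two-residue caps for both interface tokens
- ``H4_C<n>``       - cyclic hubs, n arms related by exact Rz(360/n),
                      C-termini extendable, N-sides sealed
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc

from . import structio
from .errors import LibraryError, SchemaError
from .geometry import (
    RigidTransform,
    compose,
    rotation_about_axis,
    rotation_about_point,
)
from .module_library import Library, build_library, save_library
from .path_guide import PathGuide

_ELEMENT = {"N": "N", "CA": "C", "C": "C", "O": "O"}
_ATOM_NAMES = ("N", "CA", "C", "O")

_RESNAMES = {
    "H4": "ALA",
    "K4": "GLY",
    "H4_j1_K4": "SER",
    "Ncap_H4": "PRO",
    "Ccap_H4": "THR",
    "Ncap_K4": "VAL",
    "Ccap_K4": "LEU",
}

CAP_RESIDUES = 2


@dataclass(frozen=True)
class ToyLibraryConfig:
    rise_per_module: float = 6.0  # Angstrom
    junction_bend: float = 90.0  # degrees, about x at the junction point
    hub_symmetries: tuple[int, ...] = (2, 4)
    atoms_per_residue: int = 4
    residues_per_module: int = 4
    seed: int = 0
    hub_arm_offset: float = 6.0  # Angstrom, arm displacement from hub axis

    def __post_init__(self):
        if self.rise_per_module <= 0:
            raise SchemaError("rise_per_module must be > 0")
        if not (0.0 <= self.junction_bend < 180.0):
            raise SchemaError("junction_bend must be in [0, 180)")
        if any(n < 2 for n in self.hub_symmetries):
            raise SchemaError("hub symmetry order must be >= 2")
        if not (3 <= self.atoms_per_residue <= 4):
            raise SchemaError("atoms_per_residue must be 3 or 4")
        if self.residues_per_module < 2:
            raise SchemaError("residues_per_module must be >= 2")

    @property
    def twist_per_res(self) -> float:
        return 360.0 / self.residues_per_module

    @property
    def rise_per_res(self) -> float:
        return self.rise_per_module / self.residues_per_module


# ---------------------------------------------------------------------------
# analytic geometry
# ---------------------------------------------------------------------------

# per-residue backbone template (two-decimal coordinates, Angstrom); the z
# column is augmented with i * rise_per_res for residue index i
_TEMPLATE = {
    "N": np.array([1.5, 0.0, 0.0]),
    "CA": np.array([1.1, 0.8, 0.15]),
    "C": np.array([0.4, 1.4, 0.3]),
    "O": np.array([0.4, 2.6, 0.3]),
}


def _rz_exact(angle_deg: float) -> np.ndarray:
    """Rotation about z; exact {0, +/-1} entries at multiples of 90 degrees."""
    k = angle_deg / 90.0
    if k == int(k):
        c, s = [(1, 0), (0, 1), (-1, 0), (0, -1)][int(k) % 4]
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], dtype=float)
    return rotation_about_axis([0, 0, 1], angle_deg)


def _rx_exact(angle_deg: float) -> np.ndarray:
    k = angle_deg / 90.0
    if k == int(k):
        c, s = [(1, 0), (0, 1), (-1, 0), (0, -1)][int(k) % 4]
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    return rotation_about_axis([1, 0, 0], angle_deg)


def _residue_coords(cfg: ToyLibraryConfig, i: int) -> dict[str, np.ndarray]:
    rot = _rz_exact(cfg.twist_per_res * i)
    shift = np.array([0.0, 0.0, cfg.rise_per_res * i])
    names = _ATOM_NAMES[: cfg.atoms_per_residue]
    return {n: rot @ _TEMPLATE[n] + shift for n in names}


def shift_transform(cfg: ToyLibraryConfig, k: int) -> RigidTransform:
    """Exact transform carrying residue index ``i`` to ``i + k``."""
    return RigidTransform(
        rotation=_rz_exact(cfg.twist_per_res * k),
        translation=[0.0, 0.0, cfg.rise_per_res * k],
    )


def bend_transform(cfg: ToyLibraryConfig, k: int) -> RigidTransform:
    """Successor transform after ``k`` residues, bent about x at the joint.

    The pivot is the landing position of the child's first N atom, so the
    inter-module peptide bond geometry is identical to the straight case.
    """
    t0 = shift_transform(cfg, k)
    pivot = t0.apply_vector(_TEMPLATE["N"])
    rot = _rx_exact(cfg.junction_bend)
    return compose(rotation_about_point(pivot, rot), t0)


def hub_arm_transform(cfg: ToyLibraryConfig, i: int, n: int) -> RigidTransform:
    """Placement of hub arm ``i`` of ``n`` in the hub's local frame."""
    rot = _rz_exact(360.0 * i / n)
    return RigidTransform(
        rotation=rot, translation=rot @ np.array([cfg.hub_arm_offset, 0.0, 0.0])
    )


def _chain_atoms(
    cfg: ToyLibraryConfig, n_res: int, chain_id: str, res_name: str,
    world: RigidTransform | None = None,
) -> struc.AtomArray:
    names = _ATOM_NAMES[: cfg.atoms_per_residue]
    n_atoms = n_res * len(names)
    atoms = struc.AtomArray(n_atoms)
    coords = np.zeros((n_atoms, 3))
    res_ids = np.zeros(n_atoms, dtype=int)
    atom_names = []
    idx = 0
    for i in range(n_res):
        placed = _residue_coords(cfg, i)
        for name in names:
            coords[idx] = placed[name]
            res_ids[idx] = i + 1
            atom_names.append(name)
            idx += 1
    if world is not None:
        coords = world.apply_points(coords)
    atoms.coord = coords
    atoms.chain_id = np.full(n_atoms, chain_id)
    atoms.res_id = res_ids
    atoms.res_name = np.full(n_atoms, res_name)
    atoms.atom_name = np.array(atom_names)
    atoms.element = np.array([_ELEMENT[n] for n in atom_names])
    atoms.hetero = np.zeros(n_atoms, dtype=bool)
    return atoms


def _hub_atoms(cfg: ToyLibraryConfig, n: int) -> struc.AtomArray:
    chains = []
    for i in range(n):
        cid = chr(ord("A") + i)
        chains.append(
            _chain_atoms(
                cfg, cfg.residues_per_module, cid, "PHE",
                world=hub_arm_transform(cfg, i, n),
            )
        )
    return struc.concatenate(chains)


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------


@dataclass
class ToyGroundTruth:
    """Analytic pair transforms recorded alongside the generated library."""

    config: ToyLibraryConfig
    pair_transforms: dict[tuple, RigidTransform] = field(default_factory=dict)


def _declared_pairs(cfg: ToyLibraryConfig):
    """Forward (C->N) pair list with analytic transforms."""
    m = cfg.residues_per_module
    t_straight = shift_transform(cfg, m)
    t_bent = bend_transform(cfg, m)
    t_after_cap = shift_transform(cfg, CAP_RESIDUES)
    pairs = [
        ("H4", "A", "H4", "A", t_straight),
        ("H4", "A", "H4_j1_K4", "A", t_straight),
        ("H4_j1_K4", "A", "K4", "A", t_bent),
        ("K4", "A", "K4", "A", t_straight),
        ("H4", "A", "Ccap_H4", "A", t_straight),
        ("K4", "A", "Ccap_K4", "A", t_straight),
        ("H4_j1_K4", "A", "Ccap_K4", "A", t_bent),
        ("Ncap_H4", "A", "H4", "A", t_after_cap),
        ("Ncap_H4", "A", "H4_j1_K4", "A", t_after_cap),
        ("Ncap_K4", "A", "K4", "A", t_after_cap),
    ]
    for n in cfg.hub_symmetries:
        hub = f"H4_C{n}"
        for i in range(n):
            cid = chr(ord("A") + i)
            t_arm = compose(hub_arm_transform(cfg, i, n), t_straight)
            pairs.append((hub, cid, "H4", "A", t_arm))
            pairs.append((hub, cid, "H4_j1_K4", "A", t_arm))
            pairs.append((hub, cid, "Ccap_H4", "A", t_arm))
    return pairs


def generate_toy_library(config: ToyLibraryConfig, out_dir) -> Library:
    """Emit fragments, pair structures, manifest and sidecar; build library.

    Output layout under ``out_dir``: ``fragments/``, ``pairs/``,
    ``manifest.json``, ``library.json``, ``ground_truth.json``.  Byte
    deterministic for a fixed config.
    """
    out_dir = Path(out_dir)
    frag_dir = out_dir / "fragments"
    pair_dir = out_dir / "pairs"
    try:
        frag_dir.mkdir(parents=True, exist_ok=True)
        pair_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise LibraryError(f"cannot create output directory: {exc}") from exc

    cfg_res = config.residues_per_module
    fragments: dict[str, struc.AtomArray] = {
        "H4": _chain_atoms(config, cfg_res, "A", _RESNAMES["H4"]),
        "K4": _chain_atoms(config, cfg_res, "A", _RESNAMES["K4"]),
        "H4_j1_K4": _chain_atoms(config, cfg_res, "A", _RESNAMES["H4_j1_K4"]),
    }
    for cap in ("Ncap_H4", "Ccap_H4", "Ncap_K4", "Ccap_K4"):
        fragments[cap] = _chain_atoms(config, CAP_RESIDUES, "A", _RESNAMES[cap])
    for n in config.hub_symmetries:
        fragments[f"H4_C{n}"] = _hub_atoms(config, n)

    for name in sorted(fragments):
        structio.save_atoms(frag_dir / f"{name}.pdb", fragments[name])

    manifest: dict = {
        "version": "1",
        "rmsd_tolerance": 0.5,
        "modules": {},
        "pairs": [],
    }
    for name in sorted(fragments):
        entry: dict = {"fragment": f"{name}.pdb"}
        if name.startswith("H4_C"):
            n = int(name.split("_C")[1])
            entry["chains"] = {
                chr(ord("A") + i): {
                    "n_extendable": False,
                    "n_iface": None,
                    "c_extendable": True,
                    "c_iface": "H4",
                }
                for i in range(n)
            }
        manifest["modules"][name] = entry

    truth_pairs = []
    for a, a_chain, b, b_chain, t in _declared_pairs(config):
        fname = f"{a}.{a_chain}C--{b}.{b_chain}N.pdb"
        posed_b = fragments[b].copy()
        posed_b.coord = t.apply_points(fragments[b].coord)
        structio.save_atoms(pair_dir / fname, fragments[a], extra_models=[posed_b])
        manifest["pairs"].append(
            {
                "file": fname,
                "a": a, "a_chain": a_chain, "a_term": "C",
                "b": b, "b_chain": b_chain, "b_term": "N",
            }
        )
        truth_pairs.append(
            {
                "a": a, "a_chain": a_chain, "a_term": "C",
                "b": b, "b_chain": b_chain, "b_term": "N",
                **t.to_dict(),
            }
        )

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "config": {
                    "rise_per_module": config.rise_per_module,
                    "junction_bend": config.junction_bend,
                    "hub_symmetries": list(config.hub_symmetries),
                    "atoms_per_residue": config.atoms_per_residue,
                    "residues_per_module": config.residues_per_module,
                    "seed": config.seed,
                    "hub_arm_offset": config.hub_arm_offset,
                },
                "pairs": truth_pairs,
            },
            fh, indent=1, sort_keys=True,
        )
        fh.write("\n")

    lib = build_library(frag_dir, pair_dir, manifest)
    save_library(lib, out_dir / "library.json")
    return lib


# ---------------------------------------------------------------------------
# chains and guides for solver tests
# ---------------------------------------------------------------------------


def build_chain_worlds(
    lib: Library, protos: list[str], start: RigidTransform | None = None
) -> list[tuple[str, RigidTransform]]:
    """World transforms of a single-chain module sequence built from identity
    (or ``start``) by repeated pair-transform composition."""
    if not protos:
        return []
    world = start if start is not None else RigidTransform()
    out = [(protos[0], world)]
    for a, b in zip(protos, protos[1:]):
        a_chain = lib.get_module(a).single_chain_id
        b_chain = lib.get_module(b).single_chain_id
        pair = lib.find_pair(a, a_chain, "C", b, b_chain, "N")
        world = compose(world, pair.t)
        out.append((b, world))
    return out


def chain_coms(lib: Library, placed: list[tuple[str, RigidTransform]]) -> np.ndarray:
    return np.array(
        [w.apply_vector(lib.get_module(p).com) for p, w in placed]
    ).reshape(-1, 3)


def random_chain(lib: Library, length: int, rng: np.random.Generator) -> list[str]:
    """Random compatible single-chain module sequence (no hubs, no caps)."""
    single = sorted(
        name
        for name, proto in lib.modules.items()
        if proto.cls in ("core", "junction")
    )
    chain = [str(rng.choice(single))]
    while len(chain) < length:
        from .module_library import compatible_successors

        cur = chain[-1]
        descs = [
            d
            for d in compatible_successors(
                lib, cur, lib.get_module(cur).single_chain_id, "C"
            )
            if lib.get_module(d.to_proto).cls in ("core", "junction")
        ]
        if not descs:
            break
        chain.append(descs[int(rng.integers(len(descs)))].to_proto)
    return chain


def generate_guide_from_chain(
    lib: Library,
    chain_spec: list[str],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PathGuide:
    """Path guide with joints at the chain's module centers of mass.

    The chain is built from the identity pose; joints are optionally
    perturbed by seeded isotropic Gaussian noise; bridges follow the path.
    """
    placed = build_chain_worlds(lib, chain_spec)
    if not placed:
        raise SchemaError("chain_spec must contain at least one module")
    coms = chain_coms(lib, placed)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        coms = coms + rng.normal(scale=noise_sd, size=coms.shape)
    guide = PathGuide()
    prev = None
    for xyz in coms:
        if prev is None:
            prev = guide.add_joint(xyz)
        else:
            prev = guide.extrude_joint(prev, xyz)
    return guide
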