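"""Build, serialize, and query the module database.

The library is the single source of truth for module prototypes, termini
interface compatibility, centers of mass, collision radii, and the pairwise
rigid transforms used to pose one module relative to another.  Compatibility
is stored explicitly as a pair list; the naming grammar is a convenience and
validation layer only.

Transform convention: a pair transform ``t`` is parent->child, i.e. extruding
module ``b`` from a placed module ``a`` puts ``b`` at
``compose(a.world, pair.t)``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import structio
from .errors import (
    IncompatiblePairError,
    InvalidNameError,
    LibraryError,
    SchemaError,
)
from .geometry import PointSet, RigidTransform, compose, invert, superpose

SCHEMA_VERSION = "1"
DEFAULT_PAIR_RMSD_TOL = 0.5  # Angstrom

CLS_CORE = "core"
CLS_JUNCTION = "junction"
CLS_HUB = "hub"
CLS_CAP = "cap"

_TERMS = ("N", "C")


# ---------------------------------------------------------------------------
# naming grammar
# ---------------------------------------------------------------------------

_JUNCTION_RE = re.compile(r"^(?P<n>[^_]+(?:_[^_]+)*?)_j(?P<idx>\d+)_(?P<c>.+)$")
_HUB_RE = re.compile(r"^(?P<base>[^_]+)_(?P<tag>[A-Za-z]*C(?P<sym>\d+)(?:_\d+)?)$")
_CAP_RE = re.compile(r"^(?P<side>Ncap|Ccap)_(?P<core>.+)$")


@dataclass(frozen=True)
class NameInfo:
    """Classification of a module name under the naming grammar."""

    cls: str
    n_iface: str | None = None
    c_iface: str | None = None
    bridged_cores: tuple[str, str] | None = None
    junction_index: int | None = None
    hub_base: str | None = None
    symmetry: str | None = None
    cap_side: str | None = None


def parse_module_name(name: str) -> NameInfo:
    """Classify a module name as core, junction, hub, or cap.

    Junction names bridge two core tokens (``A_j<i>_B`` is compatible at the
    N-terminus with C-terminal interfaces of kind ``A`` and vice versa).
    Hub names carry a cyclic-symmetry tag; unrecognized suffix decorations on
    the tag are kept opaque.  Anything that matches no production is a core
    module whose interface token at both termini is its own name.
    """
    if not name:
        raise InvalidNameError("empty module name")
    if "." in name:
        raise InvalidNameError(
            f"module name {name!r} contains reserved '.' separator"
        )
    m = _CAP_RE.match(name)
    if m:
        core = m.group("core")
        if m.group("side") == "Ncap":
            return NameInfo(cls=CLS_CAP, c_iface=core, cap_side="N")
        return NameInfo(cls=CLS_CAP, n_iface=core, cap_side="C")
    m = _JUNCTION_RE.match(name)
    if m:
        return NameInfo(
            cls=CLS_JUNCTION,
            n_iface=m.group("n"),
            c_iface=m.group("c"),
            bridged_cores=(m.group("n"), m.group("c")),
            junction_index=int(m.group("idx")),
        )
    m = _HUB_RE.match(name)
    if m:
        return NameInfo(
            cls=CLS_HUB,
            hub_base=m.group("base"),
            symmetry=f"C{m.group('sym')}",
        )
    return NameInfo(cls=CLS_CORE, n_iface=name, c_iface=name)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ChainDef:
    chain_id: str
    n_extendable: bool
    c_extendable: bool
    n_iface: str | None
    c_iface: str | None
    residue_count: int

    def extendable(self, term: str) -> bool:
        return self.n_extendable if term == "N" else self.c_extendable

    def iface(self, term: str) -> str | None:
        return self.n_iface if term == "N" else self.c_iface


@dataclass
class ModuleProto:
    """One building-block prototype."""

    name: str
    cls: str
    chains: dict[str, ChainDef]
    com: np.ndarray
    radius: float
    fragment_path: str
    symmetry: str | None = None

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float).reshape(3)
        if self.cls in (CLS_CORE, CLS_JUNCTION, CLS_CAP) and len(self.chains) != 1:
            raise LibraryError(
                f"{self.cls} module {self.name!r} must have exactly one chain"
            )
        if self.cls == CLS_HUB and len(self.chains) < 2:
            raise LibraryError(f"hub {self.name!r} must have at least 2 chains")

    @property
    def single_chain_id(self) -> str:
        (cid,) = self.chains.keys()
        return cid


@dataclass
class PairTransform:
    """Relative pose of module ``b`` extruded from a terminus of module ``a``."""

    a_name: str
    a_chain: str
    a_term: str
    b_name: str
    b_chain: str
    b_term: str
    t: RigidTransform
    superposition_rmsd: float = 0.0
    drop_b_residues: tuple[int, int] | None = None

    def __post_init__(self):
        if self.a_term not in _TERMS or self.b_term not in _TERMS:
            raise LibraryError(f"bad terminus in pair {self.key()}")
        if self.a_term == self.b_term:
            raise LibraryError(
                f"pair {self.key()}: bonded termini must be N-to-C"
            )

    def key(self) -> tuple:
        return (
            self.a_name, self.a_chain, self.a_term,
            self.b_name, self.b_chain, self.b_term,
        )

    def reversed(self) -> "PairTransform":
        return PairTransform(
            a_name=self.b_name, a_chain=self.b_chain, a_term=self.b_term,
            b_name=self.a_name, b_chain=self.a_chain, b_term=self.a_term,
            t=invert(self.t),
            superposition_rmsd=self.superposition_rmsd,
            drop_b_residues=None,
        )


@dataclass(frozen=True, order=True)
class ExtrusionDescriptor:
    """One legal extrusion choice at a terminus.

    Serialized as ``:<chain1>(<term1>)->(<term2>)<chain2>:<name2>`` where
    side 1 is the module being extruded from and side 2 the new module.
    """

    from_chain: str
    from_term: str
    to_term: str
    to_chain: str
    to_proto: str

    def __str__(self) -> str:
        return (
            f":{self.from_chain}({self.from_term})"
            f"->({self.to_term}){self.to_chain}:{self.to_proto}"
        )

    _RE = re.compile(
        r"^:(?P<c1>[^()]+)\((?P<t1>[NC])\)->\((?P<t2>[NC])\)(?P<c2>[^:]+):(?P<name>.+)$"
    )

    @classmethod
    def parse(cls, s: str) -> "ExtrusionDescriptor":
        m = cls._RE.match(s.replace(" ", ""))
        if m is None:
            raise SchemaError(f"malformed extrusion descriptor {s!r}")
        return cls(
            from_chain=m.group("c1"), from_term=m.group("t1"),
            to_term=m.group("t2"), to_chain=m.group("c2"),
            to_proto=m.group("name"),
        )


@dataclass
class Library:
    """The module database."""

    modules: dict[str, ModuleProto] = field(default_factory=dict)
    pairs: list[PairTransform] = field(default_factory=list)
    version: str = SCHEMA_VERSION
    units: str = "angstrom"
    base_dir: Path | None = None
    _pair_index: dict[tuple, list[PairTransform]] = field(
        default_factory=dict, repr=False
    )
    _fragment_cache: dict[str, object] = field(default_factory=dict, repr=False)

    # -- indexing --------------------------------------------------------

    def reindex(self):
        self._pair_index = {}
        for p in self.pairs:
            self._pair_index.setdefault(
                (p.a_name, p.a_chain, p.a_term), []
            ).append(p)

    def pairs_from(self, name: str, chain_id: str, term: str) -> list[PairTransform]:
        if not self._pair_index and self.pairs:
            self.reindex()
        return self._pair_index.get((name, chain_id, term), [])

    def find_pair(
        self, a_name, a_chain, a_term, b_name, b_chain, b_term
    ) -> PairTransform:
        for p in self.pairs_from(a_name, a_chain, a_term):
            if (p.b_name, p.b_chain, p.b_term) == (b_name, b_chain, b_term):
                return p
        raise LibraryError(
            f"no pair transform {a_name}:{a_chain}({a_term}) -> "
            f"({b_term}){b_chain}:{b_name}"
        )

    def get_module(self, name: str) -> ModuleProto:
        try:
            return self.modules[name]
        except KeyError:
            raise LibraryError(f"unknown module prototype {name!r}") from None

    @property
    def token_set(self) -> set[str]:
        tokens = set()
        for proto in self.modules.values():
            for ch in proto.chains.values():
                for tok in (ch.n_iface, ch.c_iface):
                    if tok:
                        tokens.add(tok)
        return tokens

    def load_fragment(self, name: str):
        """Fragment atoms of a prototype (cached biotite AtomArray)."""
        if name not in self._fragment_cache:
            proto = self.get_module(name)
            path = Path(proto.fragment_path)
            if not path.is_absolute() and self.base_dir is not None:
                path = self.base_dir / path
            self._fragment_cache[name] = structio.load_atoms(path)
        return self._fragment_cache[name]

    # -- validation ------------------------------------------------------

    def validate(self):
        """Check all library invariants; raise LibraryError on violation."""
        seen = set()
        for p in self.pairs:
            for name, chain, term in (
                (p.a_name, p.a_chain, p.a_term),
                (p.b_name, p.b_chain, p.b_term),
            ):
                proto = self.get_module(name)
                if chain not in proto.chains:
                    raise LibraryError(
                        f"pair {p.key()} references unknown chain "
                        f"{chain!r} of {name!r}"
                    )
            if p.key() in seen:
                raise LibraryError(f"duplicate pair {p.key()}")
            seen.add(p.key())
        # compatibility symmetry: the reverse link must exist
        for p in self.pairs:
            rk = p.reversed().key()
            if rk not in seen:
                raise LibraryError(f"pair {p.key()} lacks its reverse {rk}")
        # every extendable terminus appears in at least one pair
        for proto in self.modules.values():
            if proto.cls == CLS_CAP:
                continue
            for ch in proto.chains.values():
                for term in _TERMS:
                    if not ch.extendable(term):
                        continue
                    plist = self.pairs_from(proto.name, ch.chain_id, term)
                    if not plist:
                        raise LibraryError(
                            f"extendable terminus {proto.name}:{ch.chain_id}"
                            f"({term}) appears in no pair"
                        )
        # capping closure
        for tok in sorted(self._used_tokens()):
            for side in ("Ncap", "Ccap"):
                cap = f"{side}_{tok}"
                if cap not in self.modules:
                    raise LibraryError(
                        f"interface token {tok!r} used at an extendable "
                        f"terminus but cap {cap!r} is missing"
                    )

    def _used_tokens(self) -> set[str]:
        used = set()
        for proto in self.modules.values():
            if proto.cls == CLS_CAP:
                continue
            for ch in proto.chains.values():
                if ch.n_extendable and ch.n_iface:
                    used.add(ch.n_iface)
                if ch.c_extendable and ch.c_iface:
                    used.add(ch.c_iface)
        return used


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def compute_com_radius(pts: PointSet) -> tuple[np.ndarray, float]:
    """Unweighted center of mass and max center-to-point distance."""
    if len(pts) == 0:
        raise LibraryError("cannot compute com/radius of an empty point set")
    com = pts.coords.mean(axis=0)
    radius = float(np.max(np.linalg.norm(pts.coords - com, axis=1)))
    return com, radius


def compute_pair_transform(
    pair_a: PointSet,
    pair_b: PointSet,
    a_fragment: PointSet,
    b_fragment: PointSet,
    *,
    rmsd_tol: float = DEFAULT_PAIR_RMSD_TOL,
) -> tuple[RigidTransform, float]:
    """Recover the parent->child transform from a posed pair structure.

    ``pair_a``/``pair_b`` are the two module regions of the pair structure
    (shared frame); fragments are the canonical single-module coordinates.
    Points are matched by label.  Returns ``(t, rmsd)`` with
    ``t = invert(T_a) o T_b`` and rmsd the worse of the two fits.
    """

    def matched(fragment: PointSet, region: PointSet) -> PointSet:
        if fragment.labels is None or region.labels is None:
            raise IncompatiblePairError("pair matching requires labelled points")
        index = {lab: i for i, lab in enumerate(region.labels)}
        rows = []
        for lab in fragment.labels:
            if lab not in index:
                raise IncompatiblePairError(
                    f"label {lab!r} of fragment not found in pair structure"
                )
            rows.append(region.coords[index[lab]])
        return PointSet(coords=np.array(rows), labels=list(fragment.labels))

    t_a, rmsd_a = superpose(a_fragment, matched(a_fragment, pair_a))
    t_b, rmsd_b = superpose(b_fragment, matched(b_fragment, pair_b))
    rmsd = max(rmsd_a, rmsd_b)
    if rmsd > rmsd_tol:
        raise IncompatiblePairError(
            f"pair superposition rmsd {rmsd:.3f} A exceeds tolerance {rmsd_tol} A"
        )
    return compose(invert(t_a), t_b), rmsd


def compatible_successors(
    lib: Library, proto_name: str, chain_id: str, term: str
) -> list[ExtrusionDescriptor]:
    """All legal extrusions from one terminus, caps excluded, sorted."""
    proto = lib.get_module(proto_name)
    if chain_id not in proto.chains:
        raise LibraryError(f"unknown chain {chain_id!r} of {proto_name!r}")
    if term not in _TERMS:
        raise LibraryError(f"unknown terminus {term!r}")
    if not proto.chains[chain_id].extendable(term):
        return []
    descs = [
        ExtrusionDescriptor(
            from_chain=chain_id, from_term=term,
            to_term=p.b_term, to_chain=p.b_chain, to_proto=p.b_name,
        )
        for p in lib.pairs_from(proto_name, chain_id, term)
        if lib.get_module(p.b_name).cls != CLS_CAP
    ]
    return sorted(descs, key=str)


# ---------------------------------------------------------------------------
# building from fragment + pair structure files
# ---------------------------------------------------------------------------


def _chain_defs_from_config(name, info, chain_cfg, fragment) -> dict[str, ChainDef]:
    chain_ids = sorted(set(fragment.chain_id))
    defs = {}
    for cid in chain_ids:
        mask = fragment.chain_id == cid
        nres = len(set(fragment.res_id[mask]))
        cfg = (chain_cfg or {}).get(cid, {})
        if info.cls == CLS_CAP:
            default_ext = (False, False)
            n_iface = info.n_iface
            c_iface = info.c_iface
        else:
            default_ext = (True, True)
            n_iface = info.n_iface if info.cls != CLS_HUB else info.hub_base
            c_iface = info.c_iface if info.cls != CLS_HUB else info.hub_base
        defs[cid] = ChainDef(
            chain_id=cid,
            n_extendable=bool(cfg.get("n_extendable", default_ext[0])),
            c_extendable=bool(cfg.get("c_extendable", default_ext[1])),
            n_iface=cfg.get("n_iface", n_iface),
            c_iface=cfg.get("c_iface", c_iface),
            residue_count=nres,
        )
    for ch in defs.values():
        if info.cls in (CLS_CORE, CLS_JUNCTION) and not (
            ch.n_extendable or ch.c_extendable
        ):
            raise LibraryError(
                f"{info.cls} module {name!r} chain {ch.chain_id!r} has no "
                "extendable terminus"
            )
    return defs


def build_library(fragments_dir, pairs_dir, config) -> Library:
    """Construct a validated Library from fragment PDBs and pair structures.

    ``config`` is the manifest (dict or path to JSON) declaring modules and
    which two fragments each pair structure joins.  Pair structure files hold
    module ``a`` as model 1 and module ``b`` as model 2, posed in a shared
    frame.  The reverse of every declared pair is added automatically.
    Output is deterministic: modules and pairs are sorted.
    """
    fragments_dir = Path(fragments_dir)
    pairs_dir = Path(pairs_dir)
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = json.load(fh)
    rmsd_tol = float(config.get("rmsd_tolerance", DEFAULT_PAIR_RMSD_TOL))

    modules_cfg = config.get("modules")
    if not modules_cfg:
        raise LibraryError("empty library: manifest declares no modules")

    lib = Library(base_dir=fragments_dir)
    for name in sorted(modules_cfg):
        if name in lib.modules:
            raise LibraryError(f"duplicate prototype name {name!r}")
        mcfg = modules_cfg[name]
        info = parse_module_name(name)
        frag_rel = mcfg.get("fragment", f"{name}.pdb")
        fragment = structio.load_atoms(fragments_dir / frag_rel)
        com, radius = compute_com_radius(structio.as_pointset(fragment))
        lib.modules[name] = ModuleProto(
            name=name,
            cls=mcfg.get("cls", info.cls),
            chains=_chain_defs_from_config(name, info, mcfg.get("chains"), fragment),
            com=com,
            radius=radius,
            fragment_path=frag_rel,
            symmetry=mcfg.get("symmetry", info.symmetry),
        )

    for entry in config.get("pairs", []):
        a_name, b_name = entry["a"], entry["b"]
        pair_path = pairs_dir / entry["file"]
        pair_a = structio.as_pointset(structio.load_atoms(pair_path, model=1))
        pair_b = structio.as_pointset(structio.load_atoms(pair_path, model=2))
        a_frag = structio.as_pointset(lib.load_fragment(a_name))
        b_frag = structio.as_pointset(lib.load_fragment(b_name))
        t, rmsd = compute_pair_transform(
            pair_a, pair_b, a_frag, b_frag, rmsd_tol=rmsd_tol
        )
        drop = entry.get("drop_b")
        pair = PairTransform(
            a_name=a_name, a_chain=entry["a_chain"], a_term=entry["a_term"],
            b_name=b_name, b_chain=entry["b_chain"], b_term=entry["b_term"],
            t=t, superposition_rmsd=rmsd,
            drop_b_residues=tuple(drop) if drop else None,
        )
        lib.pairs.append(pair)

    # add missing reverse pairs for compatibility symmetry
    keys = {p.key() for p in lib.pairs}
    for p in list(lib.pairs):
        rev = p.reversed()
        if rev.key() not in keys:
            lib.pairs.append(rev)
            keys.add(rev.key())

    lib.pairs.sort(key=lambda p: p.key())
    lib.reindex()
    lib.validate()
    return lib


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _lib_to_dict(lib: Library) -> dict:
    return {
        "version": lib.version,
        "units": lib.units,
        "modules": {
            name: {
                "cls": proto.cls,
                "chains": {
                    cid: {
                        "n_extendable": ch.n_extendable,
                        "c_extendable": ch.c_extendable,
                        "n_iface": ch.n_iface,
                        "c_iface": ch.c_iface,
                        "residue_count": ch.residue_count,
                    }
                    for cid, ch in sorted(proto.chains.items())
                },
                "com": [float(x) for x in proto.com],
                "radius": float(proto.radius),
                "fragment": proto.fragment_path,
                "symmetry": proto.symmetry,
            }
            for name, proto in sorted(lib.modules.items())
        },
        "pairs": [
            {
                "a": p.a_name, "a_chain": p.a_chain, "a_term": p.a_term,
                "b": p.b_name, "b_chain": p.b_chain, "b_term": p.b_term,
                "rot": p.t.to_dict()["rot"],
                "tran": p.t.to_dict()["tran"],
                "rmsd": float(p.superposition_rmsd),
                "drop_b": list(p.drop_b_residues) if p.drop_b_residues else None,
            }
            for p in sorted(lib.pairs, key=lambda p: p.key())
        ],
        "tokens": sorted(lib.token_set),
    }


def save_library(lib: Library, path):
    path = Path(path)
    doc = _lib_to_dict(lib)
    if lib.base_dir is not None:
        # fragment paths are stored relative to the library file itself
        import os

        for name, md in doc["modules"].items():
            absolute = (lib.base_dir / md["fragment"]).resolve()
            md["fragment"] = os.path.relpath(absolute, path.parent.resolve())
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=False)
        fh.write("\n")


def load_library(path) -> Library:
    path = Path(path)
    try:
        with open(path) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed library JSON {path}: {exc}") from exc
    if not isinstance(data, dict) or "version" not in data:
        raise SchemaError("missing field", field="version")
    if data["version"] != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported library schema version {data['version']!r}",
            field="version",
        )
    if data.get("units") != "angstrom":
        raise SchemaError("library units must be 'angstrom'", field="units")
    lib = Library(version=data["version"], base_dir=path.parent)
    try:
        for name, md in data["modules"].items():
            chains = {
                cid: ChainDef(
                    chain_id=cid,
                    n_extendable=cd["n_extendable"],
                    c_extendable=cd["c_extendable"],
                    n_iface=cd["n_iface"],
                    c_iface=cd["c_iface"],
                    residue_count=cd["residue_count"],
                )
                for cid, cd in md["chains"].items()
            }
            lib.modules[name] = ModuleProto(
                name=name, cls=md["cls"], chains=chains, com=md["com"],
                radius=md["radius"], fragment_path=md["fragment"],
                symmetry=md.get("symmetry"),
            )
        for pd in data["pairs"]:
            lib.pairs.append(
                PairTransform(
                    a_name=pd["a"], a_chain=pd["a_chain"], a_term=pd["a_term"],
                    b_name=pd["b"], b_chain=pd["b_chain"], b_term=pd["b_term"],
                    t=RigidTransform(rotation=pd["rot"], translation=pd["tran"]),
                    superposition_rmsd=pd["rmsd"],
                    drop_b_residues=(
                        tuple(pd["drop_b"]) if pd.get("drop_b") else None
                    ),
                )
            )
    except KeyError as exc:
        raise SchemaError(f"missing field {exc}", field=str(exc)) from exc
    lib.reindex()
    lib.validate()
    return lib
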