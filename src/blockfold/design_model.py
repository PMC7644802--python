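"""The editable design scene.

Placement, compatibility-filtered extrusion, mirror-linked symmetric growth,
link occupancy, connected-component network bookkeeping, and sphere-based
collision detection.

Conventions:

- Instance ids are ``NAME.NNN`` with the lowest unused 3-digit suffix.
- A placed module's pose never changes except through whole-network moves
  (``transform_network`` / ``join_networks``).
- Collision test: two modules collide when the distance between their world
  centers of mass is below ``f * (r1 + r2) + padding`` with overlap factor
  ``f`` (default 0.75) and padding 2 A.  Library radii are exact (no
  padding); the padding applied here guarantees that any inter-module atom
  pair closer than the padding is flagged at ``f = 1``.  Directly linked
  neighbors are always exempt, since bonded modules necessarily have
  overlapping bounding spheres.
- Networks are exactly the connected components of the link graph at all
  times; creation and splitting are automatic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import (
    CollisionError,
    LibraryError,
    MirrorError,
    OccupiedTerminusError,
    SceneError,
    SchemaError,
)
from .geometry import RigidTransform, compose, invert
from .module_library import (
    CLS_CAP,
    ExtrusionDescriptor,
    Library,
    compatible_successors,
)
from .path_guide import PathGuide, guide_from_dict, guide_to_dict

DESIGN_VERSION = "1"
DEFAULT_COLLISION_FACTOR = 0.75
DEFAULT_COLLISION_PADDING = 2.0  # Angstrom

Terminus = tuple[str, str, str]  # (instance_id, chain_id, term)


@dataclass
class Link:
    a: Terminus
    b: Terminus

    def key(self) -> tuple:
        return tuple(sorted((self.a, self.b)))

    def other(self, end: Terminus) -> Terminus:
        return self.b if end == self.a else self.a


@dataclass
class PlacedModule:
    instance_id: str
    proto: str
    world: RigidTransform
    # (chain_id, term) -> None (free) | "sealed" | Terminus of the partner
    occupancy: dict[tuple[str, str], object] = field(default_factory=dict)
    color: str | None = None


class DesignScene:
    """Aggregate root holding modules, links, networks, mirrors and guides."""

    def __init__(
        self,
        library: Library,
        collision_factor: float = DEFAULT_COLLISION_FACTOR,
        auto_collision_check: bool = True,
        collision_padding: float = DEFAULT_COLLISION_PADDING,
    ):
        if not (0.0 < collision_factor <= 1.5):
            raise SceneError("collision factor must be in (0, 1.5]")
        self.library = library
        self.collision_factor = collision_factor
        self.collision_padding = collision_padding
        self.auto_collision_check = auto_collision_check
        self.modules: dict[str, PlacedModule] = {}
        self.links: list[Link] = []
        self.networks: dict[str, set[str]] = {}
        self.mirror_groups: dict[str, list[tuple[str, str]]] = {}
        self.guide = PathGuide()

    # ------------------------------------------------------------------
    # id allocation and lookups
    # ------------------------------------------------------------------

    def _new_instance_id(self, proto: str) -> str:
        n = 1
        while f"{proto}.{n:03d}" in self.modules:
            n += 1
        return f"{proto}.{n:03d}"

    def _new_network_id(self) -> str:
        n = 1
        while f"net.{n:03d}" in self.networks:
            n += 1
        return f"net.{n:03d}"

    def _new_group_id(self) -> str:
        n = 1
        while f"mg.{n:03d}" in self.mirror_groups:
            n += 1
        return f"mg.{n:03d}"

    def _require(self, instance_id: str) -> PlacedModule:
        if instance_id not in self.modules:
            raise SceneError(f"unknown instance {instance_id!r}")
        return self.modules[instance_id]

    def network_of(self, instance_id: str) -> str:
        for nid, members in self.networks.items():
            if instance_id in members:
                return nid
        raise SceneError(f"instance {instance_id!r} belongs to no network")

    def world_com(self, instance_id: str) -> np.ndarray:
        mod = self._require(instance_id)
        return mod.world.apply_vector(self.library.get_module(mod.proto).com)

    def free_termini(self, instance_id: str) -> list[tuple[str, str]]:
        mod = self._require(instance_id)
        return sorted(
            key for key, occ in mod.occupancy.items() if occ is None
        )

    def linked_neighbors(self, instance_id: str) -> set[str]:
        out = set()
        for link in self.links:
            if link.a[0] == instance_id:
                out.add(link.b[0])
            elif link.b[0] == instance_id:
                out.add(link.a[0])
        return out

    def mirror_group_of(self, instance_id: str, chain_id: str) -> str | None:
        for gid, members in self.mirror_groups.items():
            if (instance_id, chain_id) in members:
                return gid
        return None

    # ------------------------------------------------------------------
    # collision
    # ------------------------------------------------------------------

    def check_collision(
        self,
        candidate: tuple[str, RigidTransform],
        exempt: set[str] = frozenset(),
        factor: float | None = None,
    ) -> list[str]:
        """Ids of placed modules whose bounding sphere the candidate enters."""
        proto_name, world = candidate
        proto = self.library.get_module(proto_name)
        com = world.apply_vector(proto.com)
        f = self.collision_factor if factor is None else factor
        hits = []
        for iid in sorted(self.modules):
            if iid in exempt:
                continue
            other = self.modules[iid]
            oproto = self.library.get_module(other.proto)
            d = float(np.linalg.norm(com - other.world.apply_vector(oproto.com)))
            if d < f * (proto.radius + oproto.radius) + self.collision_padding:
                hits.append(iid)
        return hits

    def _collision_guard(self, proto_name, world, exempt):
        if not self.auto_collision_check:
            return
        hits = self.check_collision((proto_name, world), exempt=set(exempt))
        if hits:
            raise CollisionError(f"candidate {proto_name}", hits[0])

    # ------------------------------------------------------------------
    # placement and extrusion
    # ------------------------------------------------------------------

    def _init_occupancy(self, proto_name: str) -> dict:
        proto = self.library.get_module(proto_name)
        occ: dict[tuple[str, str], object] = {}
        for cid, ch in proto.chains.items():
            occ[(cid, "N")] = None if ch.n_extendable else "sealed"
            occ[(cid, "C")] = None if ch.c_extendable else "sealed"
        return occ

    def place_module(
        self, proto_name: str, world: RigidTransform, color: str | None = None
    ) -> str:
        proto = self.library.get_module(proto_name)
        if proto.cls == CLS_CAP:
            raise SceneError(
                f"cap prototype {proto_name!r} cannot be placed interactively"
            )
        self._collision_guard(proto_name, world, exempt=set())
        iid = self._new_instance_id(proto_name)
        self.modules[iid] = PlacedModule(
            instance_id=iid, proto=proto_name, world=world,
            occupancy=self._init_occupancy(proto_name), color=color,
        )
        self.networks[self._new_network_id()] = {iid}
        # symmetric hubs: all chain growth points are mirror-linked on spawn
        if proto.cls == "hub" and proto.symmetry and len(proto.chains) > 1:
            self.mirror_groups[self._new_group_id()] = [
                (iid, cid) for cid in sorted(proto.chains)
            ]
        return iid

    def extrude(self, from_instance: str, desc) -> list[str]:
        """Extrude a compatible module; mirror groups extrude atomically."""
        if isinstance(desc, str):
            desc = ExtrusionDescriptor.parse(desc)
        parent = self._require(from_instance)
        gid = self.mirror_group_of(from_instance, desc.from_chain)
        members = (
            list(self.mirror_groups[gid])
            if gid is not None
            else [(from_instance, desc.from_chain)]
        )

        # plan all placements before mutating anything (all-or-nothing)
        plans = []
        planned_coms = []
        child_proto = self.library.get_module(desc.to_proto)
        if child_proto.cls == CLS_CAP:
            raise SceneError("caps are not offered for extrusion")
        for iid, chain in members:
            mod = self._require(iid)
            key = (chain, desc.from_term)
            if key not in mod.occupancy:
                raise SceneError(f"unknown terminus {key} on {iid}")
            if mod.occupancy[key] == "sealed":
                raise SceneError(f"terminus {chain}({desc.from_term}) of {iid} is sealed")
            if mod.occupancy[key] is not None:
                raise OccupiedTerminusError(
                    f"terminus {chain}({desc.from_term}) of {iid} is occupied"
                )
            allowed = compatible_successors(self.library, mod.proto, chain, desc.from_term)
            want = ExtrusionDescriptor(
                from_chain=chain, from_term=desc.from_term,
                to_term=desc.to_term, to_chain=desc.to_chain,
                to_proto=desc.to_proto,
            )
            if want not in allowed:
                raise LibraryError(
                    f"descriptor {want} is not a compatible extrusion of "
                    f"{mod.proto}:{chain}({desc.from_term})"
                )
            pair = self.library.find_pair(
                mod.proto, chain, desc.from_term,
                desc.to_proto, desc.to_chain, desc.to_term,
            )
            child_world = compose(mod.world, pair.t)
            if self.auto_collision_check:
                hits = self.check_collision(
                    (desc.to_proto, child_world), exempt={iid}
                )
                if hits:
                    raise CollisionError(f"extrusion of {desc.to_proto}", hits[0])
                child_com = child_world.apply_vector(child_proto.com)
                for prev_com in planned_coms:
                    d = float(np.linalg.norm(child_com - prev_com))
                    if d < (
                        self.collision_factor * 2 * child_proto.radius
                        + self.collision_padding
                    ):
                        raise CollisionError(
                            f"extrusion of {desc.to_proto}", "mirror sibling"
                        )
                planned_coms.append(child_com)
            plans.append((iid, chain, pair, child_world))

        # commit
        new_ids = []
        for iid, chain, pair, child_world in plans:
            child_id = self._new_instance_id(desc.to_proto)
            self.modules[child_id] = PlacedModule(
                instance_id=child_id, proto=desc.to_proto, world=child_world,
                occupancy=self._init_occupancy(desc.to_proto),
            )
            a = (iid, chain, desc.from_term)
            b = (child_id, desc.to_chain, desc.to_term)
            self.links.append(Link(a=a, b=b))
            self.modules[iid].occupancy[(chain, desc.from_term)] = b
            self.modules[child_id].occupancy[(desc.to_chain, desc.to_term)] = a
            nid = self.network_of(iid)
            self.networks[nid].add(child_id)
            # child was spawned into its parent's network, not a fresh one
            new_ids.append(child_id)
        if len(new_ids) > 1:
            self.mirror_groups[self._new_group_id()] = [
                (cid, desc.to_chain) for cid in new_ids
            ]
        return new_ids

    # ------------------------------------------------------------------
    # mirror groups
    # ------------------------------------------------------------------

    def link_by_mirror(self, instance_ids: list[str]) -> str:
        if len(set(instance_ids)) < 2:
            raise MirrorError("mirror link needs at least two distinct instances")
        protos = {self._require(i).proto for i in instance_ids}
        if len(protos) != 1:
            raise MirrorError(
                f"mirror-linked modules must share a prototype, got {sorted(protos)}"
            )
        proto = self.library.get_module(protos.pop())
        if len(proto.chains) != 1:
            raise MirrorError("hubs are mirror-linked automatically at placement")
        cid = proto.single_chain_id
        for iid in instance_ids:
            if self.mirror_group_of(iid, cid) is not None:
                raise MirrorError(f"{iid!r} already belongs to a mirror group")
        gid = self._new_group_id()
        self.mirror_groups[gid] = [(iid, cid) for iid in sorted(set(instance_ids))]
        return gid

    def unlink_mirror(self, group_id: str):
        if group_id not in self.mirror_groups:
            raise MirrorError(f"unknown mirror group {group_id!r}")
        del self.mirror_groups[group_id]

    # ------------------------------------------------------------------
    # networks
    # ------------------------------------------------------------------

    def _link_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.modules)
        for link in self.links:
            g.add_edge(link.a[0], link.b[0])
        return g

    def recompute_networks(self):
        """Re-derive connected components, keeping old ids where possible.

        Each old network id is retained by the component containing its
        lexicographically smallest former member; new components get fresh
        ids.
        """
        g = self._link_graph()
        comps = [set(c) for c in nx.connected_components(g)]
        old = dict(self.networks)
        self.networks = {}
        claimed = set()
        for nid in sorted(old):
            members = old[nid]
            anchor = min(members) if members else None
            if anchor is None:
                continue
            for c in comps:
                if anchor in c and id(c) not in claimed:
                    self.networks[nid] = c
                    claimed.add(id(c))
                    break
        for c in comps:
            if id(c) not in claimed:
                self.networks[self._new_network_id()] = c
                claimed.add(id(c))

    def join_networks(self, a: Terminus, b: Terminus) -> str:
        """Merge two networks by forming a link; b's network is repositioned."""
        a_iid, a_chain, a_term = a
        b_iid, b_chain, b_term = b
        mod_a = self._require(a_iid)
        mod_b = self._require(b_iid)
        nid_a = self.network_of(a_iid)
        nid_b = self.network_of(b_iid)
        if nid_a == nid_b:
            raise SceneError("termini belong to the same network")
        for mod, chain, term in ((mod_a, a_chain, a_term), (mod_b, b_chain, b_term)):
            occ = mod.occupancy.get((chain, term), "missing")
            if occ == "missing":
                raise SceneError(
                    f"unknown terminus {chain}({term}) on {mod.instance_id}"
                )
            if occ is not None:
                raise OccupiedTerminusError(
                    f"terminus {chain}({term}) of {mod.instance_id} is not free"
                )
        pair = self.library.find_pair(
            mod_a.proto, a_chain, a_term, mod_b.proto, b_chain, b_term
        )
        delta = compose(compose(mod_a.world, pair.t), invert(mod_b.world))
        moved = {
            iid: compose(delta, self.modules[iid].world)
            for iid in self.networks[nid_b]
        }
        if self.auto_collision_check:
            for iid, world in moved.items():
                exempt = set(self.networks[nid_b])
                if iid == b_iid:
                    exempt.add(a_iid)
                hits = self.check_collision(
                    (self.modules[iid].proto, world), exempt=exempt
                )
                if hits:
                    raise CollisionError(iid, hits[0])
        for iid, world in moved.items():
            self.modules[iid].world = world
        self.links.append(Link(a=a, b=b))
        mod_a.occupancy[(a_chain, a_term)] = b
        mod_b.occupancy[(b_chain, b_term)] = a
        self.networks[nid_a] |= self.networks.pop(nid_b)
        return nid_a

    def delete_instance(self, instance_id: str):
        self._require(instance_id)
        for link in list(self.links):
            if instance_id in (link.a[0], link.b[0]):
                other = link.other(
                    link.a if link.a[0] == instance_id else link.b
                )
                if other[0] in self.modules:
                    self.modules[other[0]].occupancy[(other[1], other[2])] = None
                self.links.remove(link)
        for gid, members in list(self.mirror_groups.items()):
            members = [m for m in members if m[0] != instance_id]
            if len(members) < 2:
                del self.mirror_groups[gid]
            else:
                self.mirror_groups[gid] = members
        nid = self.network_of(instance_id)
        self.networks[nid].discard(instance_id)
        if not self.networks[nid]:
            del self.networks[nid]
        del self.modules[instance_id]
        self.recompute_networks()

    def transform_network(self, network_id: str, t: RigidTransform):
        if network_id not in self.networks:
            raise SceneError(f"unknown network {network_id!r}")
        members = self.networks[network_id]
        moved = {
            iid: compose(t, self.modules[iid].world) for iid in members
        }
        if self.auto_collision_check:
            for iid, world in moved.items():
                hits = self.check_collision(
                    (self.modules[iid].proto, world), exempt=set(members)
                )
                if hits:
                    raise CollisionError(iid, hits[0])
        for iid, world in moved.items():
            self.modules[iid].world = world

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------

    def validate(self) -> list[str]:
        """Scene-invariant findings (empty list = valid)."""
        findings = []
        # network partition
        g = self._link_graph()
        comps = {frozenset(c) for c in nx.connected_components(g)}
        declared = {frozenset(m) for m in self.networks.values()}
        if comps != declared:
            findings.append("networks are not the link-graph components")
        # collisions (linked neighbors exempt)
        for iid in sorted(self.modules):
            mod = self.modules[iid]
            exempt = self.linked_neighbors(iid) | {iid}
            for hit in self.check_collision((mod.proto, mod.world), exempt=exempt):
                if hit > iid:
                    findings.append(f"collision between {iid} and {hit}")
        # occupancy bookkeeping
        occupied = sum(
            1
            for mod in self.modules.values()
            for occ in mod.occupancy.values()
            if occ is not None and occ != "sealed"
        )
        if occupied != 2 * len(self.links):
            findings.append(
                f"occupancy count {occupied} != 2 * links {len(self.links)}"
            )
        # mirror groups reference live instances of one prototype
        for gid, members in self.mirror_groups.items():
            protos = set()
            for iid, cid in members:
                if iid not in self.modules:
                    findings.append(f"mirror group {gid} references missing {iid}")
                else:
                    protos.add(self.modules[iid].proto)
            if len(protos) > 1:
                findings.append(f"mirror group {gid} mixes prototypes {sorted(protos)}")
        return findings


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def scene_to_dict(scene: DesignScene) -> dict:
    networks = []
    for nid in sorted(scene.networks):
        mods = []
        for iid in sorted(scene.networks[nid]):
            mod = scene.modules[iid]
            t = mod.world.to_dict()
            links = []
            for link in scene.links:
                lo, hi = link.key()
                if lo[0] == iid:
                    src, dst = lo, hi
                elif hi[0] == iid and lo[0] != iid:
                    continue  # serialized on the lower endpoint only
                else:
                    continue
                links.append(
                    {
                        "chain": src[1], "term": src[2],
                        "to": {"id": dst[0], "chain": dst[1], "term": dst[2]},
                    }
                )
            links.sort(key=lambda d: (d["chain"], d["term"], d["to"]["id"]))
            mods.append(
                {
                    "id": iid,
                    "proto": mod.proto,
                    "rot": t["rot"],
                    "tran": [x / 10.0 for x in t["tran"]],
                    "color": mod.color,
                    "links": links,
                }
            )
        networks.append({"name": nid, "modules": mods})
    return {
        "version": DESIGN_VERSION,
        "units": "nm",
        "collision_factor": scene.collision_factor,
        "networks": networks,
        "mirror_groups": {
            gid: [list(m) for m in scene.mirror_groups[gid]]
            for gid in sorted(scene.mirror_groups)
        },
        "pg_networks": guide_to_dict(scene.guide),
    }


def export_design(scene: DesignScene, path):
    with open(Path(path), "w") as fh:
        json.dump(scene_to_dict(scene), fh, indent=1)
        fh.write("\n")


def scene_from_dict(data: dict, library: Library) -> DesignScene:
    for req in ("version", "units", "networks"):
        if req not in data:
            raise SchemaError("missing field", field=req)
    if data["version"] != DESIGN_VERSION:
        raise SchemaError(
            f"unsupported design version {data['version']!r}", field="version"
        )
    if data["units"] != "nm":
        raise SchemaError("design units must be 'nm'", field="units")
    scene = DesignScene(
        library,
        collision_factor=float(data.get("collision_factor", DEFAULT_COLLISION_FACTOR)),
        auto_collision_check=False,
    )
    pending_links = []
    for ni, net in enumerate(data["networks"]):
        try:
            nid = net["name"]
            members = set()
            for md in net["modules"]:
                iid = md["id"]
                if iid in scene.modules:
                    raise SchemaError(f"duplicate instance id {iid!r}")
                if iid.split(".")[0] != md["proto"]:
                    raise SchemaError(
                        f"instance id {iid!r} does not match proto {md['proto']!r}",
                        field=f"networks[{ni}]",
                    )
                world = RigidTransform(
                    rotation=md["rot"],
                    translation=[x * 10.0 for x in md["tran"]],
                )
                scene.modules[iid] = PlacedModule(
                    instance_id=iid, proto=md["proto"], world=world,
                    occupancy=scene._init_occupancy(md["proto"]),
                    color=md.get("color"),
                )
                members.add(iid)
                for ld in md.get("links", []):
                    pending_links.append(
                        (
                            (iid, ld["chain"], ld["term"]),
                            (ld["to"]["id"], ld["to"]["chain"], ld["to"]["term"]),
                        )
                    )
            scene.networks[nid] = members
        except KeyError as exc:
            raise SchemaError(
                f"missing field {exc}", field=f"networks[{ni}]"
            ) from exc
    for a, b in pending_links:
        for end in (a, b):
            if end[0] not in scene.modules:
                raise SchemaError(f"link references unknown instance {end[0]!r}")
            if (end[1], end[2]) not in scene.modules[end[0]].occupancy:
                raise SchemaError(f"link references unknown terminus {end}")
        scene.links.append(Link(a=a, b=b))
        scene.modules[a[0]].occupancy[(a[1], a[2])] = b
        scene.modules[b[0]].occupancy[(b[1], b[2])] = a
    for gid, members in data.get("mirror_groups", {}).items():
        scene.mirror_groups[gid] = [tuple(m) for m in members]
    scene.guide = guide_from_dict(data.get("pg_networks", []))
    scene.auto_collision_check = True
    # structural inconsistencies reject the file; collisions are left to an
    # explicit validate call so offending designs can still be inspected
    bad = [f for f in scene.validate() if not f.startswith("collision")]
    if bad:
        raise SchemaError("imported design is inconsistent: " + "; ".join(bad))
    return scene


def import_design(path, library: Library) -> DesignScene:
    try:
        with open(Path(path)) as fh:
            data = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"malformed design JSON: {exc}") from exc
    return scene_from_dict(data, library)
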