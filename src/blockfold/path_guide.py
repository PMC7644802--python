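"""Geometry-only target-shape graphs: joints (nodes) and bridges (edges).

A path guide specifies the shape an automated design should follow.  Joints
are freely movable points; bridges are unweighted edges whose length is
simply the distance between their joints.  In hybrid designs a joint may be
attached to a placed module, turning its incident bridges into extrusion
intents from that module and contributing a full pose constraint to the
solver spec.

Coordinates are Angstrom internally; guide/spec files use nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .errors import SceneError, SchemaError, ValidationError

#: a joint closer than this to a module's center of mass, without a declared
#: attachment, is flagged as ambiguous overlap intent (Angstrom)
OVERLAP_INTENT_TOL = 1.0

SPEC_VERSION = "1"


@dataclass
class Joint:
    joint_id: str
    position: np.ndarray
    attached: dict | None = None  # {"instance", "chain", "term"} hints

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)


@dataclass
class Finding:
    kind: str  # overlap-intention | link-availability | dangling-bridge
    subject: str
    detail: str

    def __str__(self) -> str:
        return f"[{self.kind}] {self.subject}: {self.detail}"

    def to_dict(self) -> dict:
        return {"kind": self.kind, "subject": self.subject, "detail": self.detail}


class PathGuide:
    """Mutable joint/bridge graph with automatic pg-network bookkeeping."""

    def __init__(self):
        self.joints: dict[str, Joint] = {}
        self.bridges: list[tuple[str, str]] = []

    # -- helpers ---------------------------------------------------------

    def _new_joint_id(self) -> str:
        n = 1
        while f"joint.{n:03d}" in self.joints:
            n += 1
        return f"joint.{n:03d}"

    def _require(self, joint_id: str) -> Joint:
        if joint_id not in self.joints:
            raise SceneError(f"unknown joint {joint_id!r}")
        return self.joints[joint_id]

    def bridge_set(self) -> set[frozenset]:
        return {frozenset(b) for b in self.bridges}

    def pg_networks(self) -> list[list[str]]:
        """Connected components, each sorted, ordered by lowest joint id."""
        g = nx.Graph()
        g.add_nodes_from(self.joints)
        g.add_edges_from(self.bridges)
        comps = [sorted(c) for c in nx.connected_components(g)]
        return sorted(comps, key=lambda c: c[0])

    # -- operations ------------------------------------------------------

    def add_joint(self, position) -> str:
        position = np.asarray(position, dtype=float).reshape(3)
        if not np.all(np.isfinite(position)):
            raise SceneError("joint position must be finite")
        jid = self._new_joint_id()
        self.joints[jid] = Joint(joint_id=jid, position=position)
        return jid

    def extrude_joint(self, from_joint: str, position) -> str:
        self._require(from_joint)
        jid = self.add_joint(position)
        self.bridges.append((from_joint, jid))
        return jid

    def bridge_two_joints(self, a: str, b: str):
        self._require(a)
        self._require(b)
        if a == b:
            raise SceneError(f"cannot bridge joint {a!r} to itself")
        if frozenset((a, b)) in self.bridge_set():
            raise SceneError(f"bridge {a!r}-{b!r} already exists")
        self.bridges.append((a, b))

    def move_joint(self, joint_id: str, position):
        j = self._require(joint_id)
        position = np.asarray(position, dtype=float).reshape(3)
        if not np.all(np.isfinite(position)):
            raise SceneError("joint position must be finite")
        j.position = position

    def delete_joint(self, joint_id: str):
        self._require(joint_id)
        del self.joints[joint_id]
        self.bridges = [b for b in self.bridges if joint_id not in b]

    def bridges_at(self, joint_id: str) -> list[tuple[str, str]]:
        return [b for b in self.bridges if joint_id in b]


# ---------------------------------------------------------------------------
# hybrid-design operations (take a DesignScene duck-typed: .guide, .modules,
# .library, .world_com(instance_id), .free_termini(instance_id))
# ---------------------------------------------------------------------------


def move_joint_to_module(scene, joint_id: str, instance_id: str):
    """Pin a joint onto a placed module (joint position := module world com).

    Bridges incident to the joint become extrusion intents from the module.
    Idempotent when re-applied with the same module.
    """
    joint = scene.guide._require(joint_id)
    if instance_id not in scene.modules:
        raise SceneError(f"unknown module instance {instance_id!r}")
    if joint.attached and joint.attached["instance"] != instance_id:
        raise SceneError(
            f"joint {joint_id!r} already attached to "
            f"{joint.attached['instance']!r}"
        )
    joint.position = scene.world_com(instance_id)
    joint.attached = {"instance": instance_id, "chain": None, "term": None}


def validate_partial(scene) -> list[Finding]:
    """Sanity checks for hybrid (partial) designs.

    Reports: joints overlapping a module com without declared attachment;
    attachments whose (hinted or required) termini are not available; and
    bridges dangling from attachments to missing modules.
    """
    findings: list[Finding] = []
    guide: PathGuide = scene.guide
    for jid in sorted(guide.joints):
        joint = guide.joints[jid]
        att = joint.attached
        if att is None:
            for iid in sorted(scene.modules):
                d = float(np.linalg.norm(joint.position - scene.world_com(iid)))
                if d < OVERLAP_INTENT_TOL:
                    findings.append(
                        Finding(
                            "overlap-intention", jid,
                            f"joint lies {d:.3f} A from com of {iid} but is "
                            "not attached to it",
                        )
                    )
            continue
        iid = att["instance"]
        if iid not in scene.modules:
            for a, b in guide.bridges_at(jid):
                findings.append(
                    Finding(
                        "dangling-bridge", f"{a}-{b}",
                        f"endpoint {jid} attached to missing module {iid!r}",
                    )
                )
            if not guide.bridges_at(jid):
                findings.append(
                    Finding(
                        "dangling-bridge", jid,
                        f"attached to missing module {iid!r}",
                    )
                )
            continue
        free = scene.free_termini(iid)
        if att["chain"] is not None and att["term"] is not None:
            if (att["chain"], att["term"]) not in free:
                findings.append(
                    Finding(
                        "link-availability", jid,
                        f"hinted terminus {att['chain']}({att['term']}) of "
                        f"{iid} is not available",
                    )
                )
        else:
            needed = len(guide.bridges_at(jid))
            if needed > len(free):
                findings.append(
                    Finding(
                        "link-availability", jid,
                        f"{needed} bridge(s) at joint but only {len(free)} "
                        f"free termini on {iid}",
                    )
                )
    return findings


def solver_spec_dict(scene) -> dict:
    """Solver-spec document for a validated scene (units nm)."""
    guide: PathGuide = scene.guide
    networks = []
    for comp in guide.pg_networks():
        joints = []
        for jid in comp:
            joint = guide.joints[jid]
            fixed = None
            if joint.attached is not None:
                iid = joint.attached["instance"]
                mod = scene.modules[iid]
                free = scene.free_termini(iid)
                chain = joint.attached["chain"]
                term = joint.attached["term"]
                if chain is None or term is None:
                    chain, term = free[0] if free else (None, None)
                t = mod.world.to_dict()
                fixed = {
                    "proto": mod.proto,
                    "rot": t["rot"],
                    "tran": [x / 10.0 for x in t["tran"]],
                    "chain": chain,
                    "term": term,
                }
            joints.append(
                {
                    "id": jid,
                    "xyz": [float(x) / 10.0 for x in joint.position],
                    "fixed": fixed,
                }
            )
        bridges = sorted(
            [sorted(b) for b in guide.bridges if b[0] in comp or b[1] in comp]
        )
        networks.append({"joints": joints, "bridges": bridges})
    return {"version": SPEC_VERSION, "units": "nm", "pg_networks": networks}


def export_solver_spec(scene, path):
    """Write the solver spec; refuses if validate_partial reports findings."""
    findings = validate_partial(scene)
    if findings:
        raise ValidationError(findings)
    doc = solver_spec_dict(scene)
    with open(Path(path), "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


# -- guide (de)serialization fragments shared with the design JSON ----------


def guide_to_dict(guide: PathGuide) -> list[dict]:
    networks = []
    for comp in guide.pg_networks():
        joints = []
        for jid in comp:
            j = guide.joints[jid]
            joints.append(
                {
                    "id": jid,
                    "xyz": [float(x) / 10.0 for x in j.position],
                    "attached": dict(j.attached) if j.attached else None,
                }
            )
        bridges = sorted(
            [sorted(b) for b in guide.bridges if b[0] in comp or b[1] in comp]
        )
        networks.append({"joints": joints, "bridges": bridges})
    return networks


def guide_from_dict(pg_networks: list) -> PathGuide:
    guide = PathGuide()
    if not isinstance(pg_networks, list):
        raise SchemaError("must be a list", field="pg_networks")
    for i, net in enumerate(pg_networks):
        for j in net.get("joints", []):
            try:
                jid = j["id"]
                xyz = [float(x) * 10.0 for x in j["xyz"]]
            except KeyError as exc:
                raise SchemaError(
                    f"missing field {exc}", field=f"pg_networks[{i}].joints"
                ) from exc
            if jid in guide.joints:
                raise SchemaError(
                    f"duplicate joint id {jid!r}", field=f"pg_networks[{i}]"
                )
            guide.joints[jid] = Joint(
                joint_id=jid, position=xyz, attached=j.get("attached") or None
            )
        for b in net.get("bridges", []):
            guide.bridges.append((b[0], b[1]))
    for a, b in guide.bridges:
        if a not in guide.joints or b not in guide.joints:
            raise SchemaError(f"bridge {a}-{b} references unknown joint")
    return guide
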