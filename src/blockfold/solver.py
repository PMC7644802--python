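"""Reference automated designer.

Given a solver spec (pg-networks of joints/bridges plus optional fixed-module
constraints), searches single-chain module sequences whose centers of mass
best fit the guide, and emits a Solution JSON that the design scene can
import.

The optimizer is a seeded deterministic beam search over the extrusion graph
(with an exhaustive mode for small instances) behind a small, pluggable
surface; population-based metaheuristics are deliberately out of scope.

Objective: a symmetric chamfer-style measure -- the root mean square of (a)
each module com's distance to the nearest point of the guide polyline and
(b) each joint's distance to the nearest com.  Zero iff the coms lie on the
polyline and every joint is met.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import IntegrityError, NoSolutionError, SchemaError
from .geometry import RigidTransform, compose
from .module_library import Library, compatible_successors

SOLUTION_VERSION = "1"
SPEC_VERSION = "1"

_GROWABLE = ("core", "junction")  # hub branching is not searched


def _opposite(term: str) -> str:
    return "C" if term == "N" else "N"


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _point_segment_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def score_fit(
    chain_coms: np.ndarray,
    joint_positions: np.ndarray,
    bridges: list[tuple[int, int]],
) -> float:
    """Chamfer-style fit score (Angstrom, lower is better).

    ``bridges`` index into ``joint_positions``; with no bridges the guide
    polyline degenerates to the joint points themselves.
    """
    coms = np.asarray(chain_coms, dtype=float).reshape(-1, 3)
    joints = np.asarray(joint_positions, dtype=float).reshape(-1, 3)
    if len(coms) == 0 or len(joints) == 0:
        raise NoSolutionError("score_fit needs at least one com and one joint")
    dists = []
    for com in coms:
        if bridges:
            d = min(
                _point_segment_dist(com, joints[i], joints[j]) for i, j in bridges
            )
        else:
            d = float(np.min(np.linalg.norm(joints - com, axis=1)))
        dists.append(d)
    for joint in joints:
        dists.append(float(np.min(np.linalg.norm(coms - joint, axis=1))))
    return float(np.sqrt(np.mean(np.square(dists))))


# ---------------------------------------------------------------------------
# spec
# ---------------------------------------------------------------------------


@dataclass
class SolverSpec:
    """Parsed solver input; coordinates in Angstrom."""

    pg_networks: list[dict]
    max_chain_length: int | None = None
    beam_width: int = 8
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict, **kwargs) -> "SolverSpec":
        if data.get("version") != SPEC_VERSION:
            raise SchemaError(
                f"unsupported spec version {data.get('version')!r}",
                field="version",
            )
        if data.get("units") != "nm":
            raise SchemaError("spec units must be 'nm'", field="units")
        nets = []
        for ni, net in enumerate(data.get("pg_networks", [])):
            joints = []
            for j in net.get("joints", []):
                try:
                    fixed = j["fixed"]
                    if fixed is not None:
                        fixed = {
                            "proto": fixed["proto"],
                            "world": RigidTransform(
                                rotation=fixed["rot"],
                                translation=[x * 10.0 for x in fixed["tran"]],
                            ),
                            "chain": fixed["chain"],
                            "term": fixed["term"],
                        }
                    joints.append(
                        {
                            "id": j["id"],
                            "xyz": np.array([float(x) * 10.0 for x in j["xyz"]]),
                            "fixed": fixed,
                        }
                    )
                except KeyError as exc:
                    raise SchemaError(
                        f"missing field {exc}", field=f"pg_networks[{ni}].joints"
                    ) from exc
            nets.append(
                {"joints": joints, "bridges": [tuple(b) for b in net.get("bridges", [])]}
            )
        if not nets:
            raise SchemaError("spec contains no pg_networks", field="pg_networks")
        return cls(pg_networks=nets, **kwargs)

    @classmethod
    def load(cls, path, **kwargs) -> "SolverSpec":
        try:
            with open(Path(path)) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed spec JSON: {exc}") from exc
        return cls.from_dict(data, **kwargs)

    def to_dict(self) -> dict:
        nets = []
        for net in self.pg_networks:
            joints = []
            for j in net["joints"]:
                fixed = j["fixed"]
                if fixed is not None:
                    t = fixed["world"].to_dict()
                    fixed = {
                        "proto": fixed["proto"],
                        "rot": t["rot"],
                        "tran": [x / 10.0 for x in t["tran"]],
                        "chain": fixed["chain"],
                        "term": fixed["term"],
                    }
                joints.append(
                    {
                        "id": j["id"],
                        "xyz": [float(x) / 10.0 for x in j["xyz"]],
                        "fixed": fixed,
                    }
                )
            nets.append({"joints": joints, "bridges": [list(b) for b in net["bridges"]]})
        return {"version": SPEC_VERSION, "units": "nm", "pg_networks": nets}

    def save(self, path):
        with open(Path(path), "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


# ---------------------------------------------------------------------------
# solution
# ---------------------------------------------------------------------------


@dataclass
class Solution:
    networks: list[dict]  # {"chain": [element...], "score": float}
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version": SOLUTION_VERSION,
            "units": "nm",
            "networks": [
                {
                    "chain": [
                        {
                            "proto": el["proto"],
                            "chain": el["chain"],
                            "term": el["term"],
                            "rot": el["world"].to_dict()["rot"],
                            "tran": [
                                x / 10.0 for x in el["world"].to_dict()["tran"]
                            ],
                        }
                        for el in net["chain"]
                    ],
                    "score": float(net["score"]),
                }
                for net in self.networks
            ],
            "meta": dict(self.meta),
        }

    def save(self, path):
        with open(Path(path), "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "Solution":
        try:
            with open(Path(path)) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed solution JSON: {exc}") from exc
        if data.get("version") != SOLUTION_VERSION:
            raise SchemaError(
                f"unsupported solution version {data.get('version')!r}",
                field="version",
            )
        networks = []
        for net in data.get("networks", []):
            chain = [
                {
                    "proto": el["proto"],
                    "chain": el["chain"],
                    "term": el["term"],
                    "world": RigidTransform(
                        rotation=el["rot"],
                        translation=[x * 10.0 for x in el["tran"]],
                    ),
                }
                for el in net["chain"]
            ]
            networks.append({"chain": chain, "score": float(net["score"])})
        return cls(networks=networks, meta=data.get("meta", {}))


# ---------------------------------------------------------------------------
# search
# ---------------------------------------------------------------------------


def _align_rotation(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Minimal rotation carrying direction u onto direction v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = np.cross(u, v)
    s = float(np.linalg.norm(c))
    d = float(u @ v)
    if s < 1e-12:
        if d > 0:
            return np.eye(3)
        # antiparallel: 180 deg about a deterministic perpendicular axis
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    axis = c / s
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * k + (1 - d) * (k @ k)


@dataclass
class _State:
    chain: list[dict]  # {"proto","chain","term","world"}
    grow: tuple[str, str, str] | None  # (proto, chain_id, term) to extend
    desc_seq: tuple[str, ...]
    score: float = np.inf

    def coms(self, lib: Library) -> np.ndarray:
        return np.array(
            [
                el["world"].apply_vector(lib.get_module(el["proto"]).com)
                for el in self.chain
            ]
        )


_COLLISION_PADDING = 2.0  # Angstrom; matches the design scene's default


def _successor_states(
    lib: Library, state: _State, collision_factor: float
) -> list[_State]:
    if state.grow is None:
        return []
    proto, chain_id, term = state.grow
    out = []
    for d in compatible_successors(lib, proto, chain_id, term):
        child = lib.get_module(d.to_proto)
        if child.cls not in _GROWABLE:
            continue
        pair = lib.find_pair(
            proto, chain_id, term, d.to_proto, d.to_chain, d.to_term
        )
        world = compose(state.chain[-1]["world"], pair.t)
        com = world.apply_vector(child.com)
        # chain self-avoidance at the configured sphere overlap factor
        clash = False
        for el in state.chain[:-1]:
            other = lib.get_module(el["proto"])
            dist = float(
                np.linalg.norm(com - el["world"].apply_vector(other.com))
            )
            if dist < (
                collision_factor * (child.radius + other.radius)
                + _COLLISION_PADDING
            ):
                clash = True
                break
        if clash:
            continue
        out.append(
            _State(
                chain=state.chain
                + [
                    {
                        "proto": d.to_proto,
                        "chain": d.to_chain,
                        "term": d.to_term,
                        "world": world,
                    }
                ],
                grow=(d.to_proto, d.to_chain, _opposite(d.to_term)),
                desc_seq=state.desc_seq + (str(d),),
            )
        )
    return out


def _start_states(lib: Library, net: dict) -> list[_State]:
    joints = net["joints"]
    fixed = [j for j in joints if j["fixed"] is not None]
    starts: list[_State] = []
    if fixed:
        # fixed poses are mandatory, unaltered starts; grow from the
        # declared free terminus of the lowest-id fixed joint
        j = sorted(fixed, key=lambda j: j["id"])[0]
        f = j["fixed"]
        starts.append(
            _State(
                chain=[
                    {
                        "proto": f["proto"],
                        "chain": f["chain"],
                        "term": None,
                        "world": f["world"],
                    }
                ],
                grow=(f["proto"], f["chain"], f["term"]),
                desc_seq=(f"@{f['proto']}",),
            )
        )
        return starts
    anchor = min(joints, key=lambda j: j["id"])
    neighbor_ids = sorted(
        b[1] if b[0] == anchor["id"] else b[0]
        for b in net["bridges"]
        if anchor["id"] in b
    )
    jmap = {j["id"]: j for j in joints}
    direction = None
    if neighbor_ids:
        direction = jmap[neighbor_ids[0]]["xyz"] - anchor["xyz"]
        if np.linalg.norm(direction) < 1e-9:
            direction = None
    for name in sorted(lib.modules):
        proto = lib.get_module(name)
        if proto.cls not in _GROWABLE:
            continue
        cid = proto.single_chain_id
        rotations: list[tuple[str, np.ndarray]] = []
        if direction is None:
            rotations.append(("", np.eye(3)))
        else:
            # one candidate orientation per first-step descriptor: align the
            # predicted com displacement with the guide direction
            for d in compatible_successors(lib, name, cid, "C"):
                child = lib.get_module(d.to_proto)
                if child.cls not in _GROWABLE:
                    continue
                pair = lib.find_pair(name, cid, "C", d.to_proto, d.to_chain, d.to_term)
                u = pair.t.rotation @ child.com + pair.t.translation - proto.com
                if np.linalg.norm(u) < 1e-9:
                    continue
                rotations.append((str(d), _align_rotation(u, direction)))
            if not rotations:
                rotations.append(("", np.eye(3)))
        for tag, rot in rotations:
            world = RigidTransform(
                rotation=rot, translation=anchor["xyz"] - rot @ proto.com
            )
            starts.append(
                _State(
                    chain=[
                        {"proto": name, "chain": cid, "term": None, "world": world}
                    ],
                    grow=(name, cid, "C"),
                    desc_seq=(f"@{name}|{tag}",),
                )
            )
    return starts


def _solve_network(
    lib: Library,
    net: dict,
    max_len: int,
    beam_width: int | None,
    collision_factor: float,
) -> tuple[list[dict], float]:
    joints = net["joints"]
    jpos = np.array([j["xyz"] for j in joints]).reshape(-1, 3)
    jindex = {j["id"]: i for i, j in enumerate(joints)}
    bridges = [(jindex[a], jindex[b]) for a, b in net["bridges"]]

    def rank(states: list[_State]) -> list[_State]:
        for s in states:
            s.score = score_fit(s.coms(lib), jpos, bridges)
        return sorted(states, key=lambda s: (s.score, s.desc_seq))

    frontier = rank(_start_states(lib, net))
    if not frontier:
        raise NoSolutionError("no compatible start module for pg-network")
    best = frontier[0]
    if beam_width is not None:
        frontier = frontier[:beam_width]
    for _ in range(max_len - 1):
        expanded: list[_State] = []
        for s in frontier:
            expanded.extend(_successor_states(lib, s, collision_factor))
        if not expanded:
            break
        expanded = rank(expanded)
        if expanded[0].score < best.score or (
            expanded[0].score == best.score
            and expanded[0].desc_seq < best.desc_seq
        ):
            best = expanded[0]
        frontier = expanded if beam_width is None else expanded[:beam_width]
    if not np.isfinite(best.score):
        raise NoSolutionError("search budget exhausted without a finite score")
    return best.chain, best.score


def solve(
    spec: SolverSpec,
    lib: Library,
    *,
    exhaustive: bool = False,
    collision_factor: float = 0.75,
) -> Solution:
    """Deterministic search for module chains fitting each pg-network."""
    networks = []
    for net in spec.pg_networks:
        max_len = spec.max_chain_length or (len(net["joints"]) + 2)
        chain, score = _solve_network(
            lib,
            net,
            max_len=max_len,
            beam_width=None if exhaustive else spec.beam_width,
            collision_factor=collision_factor,
        )
        networks.append({"chain": chain, "score": score})
    return Solution(
        networks=networks,
        meta={
            "seed": spec.seed,
            "beam": None if exhaustive else spec.beam_width,
            "algorithm": "exhaustive" if exhaustive else "beam",
        },
    )


# ---------------------------------------------------------------------------
# import into a design scene
# ---------------------------------------------------------------------------


def import_solution(scene, path) -> list[str]:
    """Place and link a solution's chains into a scene; returns network ids.

    Consecutive world transforms are verified against the library's pair
    transforms (tolerance 1e-6) before anything is placed.
    """
    sol = path if isinstance(path, Solution) else Solution.load(path)
    lib: Library = scene.library
    # verify first, then place
    for net in sol.networks:
        chain = net["chain"]
        for prev, cur in zip(chain, chain[1:]):
            pair = lib.find_pair(
                prev["proto"],
                lib.get_module(prev["proto"]).single_chain_id
                if len(lib.get_module(prev["proto"]).chains) == 1
                else prev["chain"],
                "C",
                cur["proto"], cur["chain"], cur["term"],
            )
            expected = compose(prev["world"], pair.t)
            if not expected.allclose(cur["world"], tol=1e-6):
                raise IntegrityError(
                    f"transform of {cur['proto']} inconsistent with pair "
                    "transforms (tampered or corrupted solution)"
                )
    network_ids = []
    for net in sol.networks:
        chain = net["chain"]
        if not chain:
            continue
        first = chain[0]
        iid = scene.place_module(first["proto"], first["world"])
        prev_id = iid
        for cur in chain[1:]:
            prev_proto = scene.modules[prev_id].proto
            prev_chain = lib.get_module(prev_proto).single_chain_id
            desc_str = (
                f":{prev_chain}(C)->({cur['term']}){cur['chain']}:{cur['proto']}"
            )
            (prev_id,) = scene.extrude(prev_id, desc_str)
        network_ids.append(scene.network_of(iid))
    return network_ids
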