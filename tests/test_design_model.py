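import json

import numpy as np
import pytest

from blockfold.design_model import (
    DesignScene,
    export_design,
    import_design,
    scene_from_dict,
    scene_to_dict,
)
from blockfold.errors import (
    CollisionError,
    LibraryError,
    MirrorError,
    OccupiedTerminusError,
    SceneError,
    SchemaError,
)
from blockfold.fixtures import build_chain_worlds
from blockfold.geometry import RigidTransform, compose, rotation_about_axis
from blockfold.structio import coords64

FAR = RigidTransform(translation=[100.0, 0.0, 0.0])


def trans(x, y, z):
    return RigidTransform(translation=[x, y, z])


class TestPlaceModule:
    def test_first_placement(self, scene):
        iid = scene.place_module("H4", RigidTransform())
        assert iid == "H4.001"
        assert len(scene.networks) == 1
        assert scene.network_of(iid) == "net.001"

    def test_second_far_placement_new_network(self, scene):
        scene.place_module("H4", RigidTransform())
        iid = scene.place_module("H4", FAR)
        assert iid == "H4.002"
        assert len(scene.networks) == 2

    def test_same_pose_collides(self, scene):
        scene.place_module("H4", RigidTransform())
        with pytest.raises(CollisionError):
            scene.place_module("H4", RigidTransform())

    def test_cap_refused(self, scene):
        with pytest.raises(SceneError):
            scene.place_module("Ccap_H4", RigidTransform())

    def test_unknown_proto(self, scene):
        with pytest.raises(LibraryError):
            scene.place_module("XX", RigidTransform())

    def test_freed_numbers_reused(self, scene):
        a = scene.place_module("H4", RigidTransform())
        b = scene.place_module("H4", FAR)
        scene.delete_instance(a)
        c = scene.place_module("H4", trans(0, 100, 0))
        assert c == "H4.001"  # lowest unused suffix again

    def test_collision_check_can_be_disabled(self, toy_lib):
        scene = DesignScene(toy_lib, auto_collision_check=False)
        scene.place_module("H4", RigidTransform())
        scene.place_module("H4", RigidTransform())  # allowed, but...
        assert any("collision" in f for f in scene.validate())


class TestExtrude:
    def test_chain_worlds_match_repeated_composition(self, scene, toy_lib):
        iid = scene.place_module("H4", RigidTransform())
        pair = toy_lib.find_pair("H4", "A", "C", "H4", "A", "N")
        expected = RigidTransform()
        for k in range(1, 5):
            (iid,) = scene.extrude(iid, ":A(C)->(N)A:H4")
            expected = compose(expected, pair.t)
            assert scene.modules[iid].world.allclose(expected, tol=1e-9)
        assert len(scene.networks) == 1

    def test_occupied_terminus(self, scene):
        iid = scene.place_module("H4", RigidTransform())
        scene.extrude(iid, ":A(C)->(N)A:H4")
        with pytest.raises(OccupiedTerminusError):
            scene.extrude(iid, ":A(C)->(N)A:H4")

    def test_incompatible_descriptor(self, scene):
        iid = scene.place_module("K4", RigidTransform())
        with pytest.raises(LibraryError):
            scene.extrude(iid, ":A(C)->(N)A:H4")  # K4 C-term is K4-type

    def test_extrude_towards_n_terminus(self, scene):
        iid = scene.place_module("H4", RigidTransform())
        (child,) = scene.extrude(iid, ":A(N)->(C)A:H4")
        assert np.allclose(
            scene.modules[child].world.translation, [0, 0, -6.0], atol=1e-9
        )

    def test_junction_then_k4(self, scene):
        iid = scene.place_module("H4", RigidTransform())
        (j,) = scene.extrude(iid, ":A(C)->(N)A:H4_j1_K4")
        (k,) = scene.extrude(j, ":A(C)->(N)A:K4")
        assert scene.modules[k].proto == "K4"
        assert len(scene.networks) == 1
        assert scene.validate() == []


class TestCollision:
    def test_far_apart_no_collision(self, scene):
        scene.place_module("H4", RigidTransform())
        assert scene.check_collision(("H4", FAR)) == []

    def test_duplicate_pose_collides(self, scene):
        scene.place_module("H4", RigidTransform())
        assert scene.check_collision(("H4", RigidTransform())) == ["H4.001"]

    def test_exempt_respected(self, scene):
        scene.place_module("H4", RigidTransform())
        assert scene.check_collision(("H4", RigidTransform()), exempt={"H4.001"}) == []

    def test_conservative_vs_atom_scan(self, toy_lib, rng):
        # sphere test at f=1 must flag every placement with atoms closer
        # than the 2 A padding (zero false negatives)
        scene = DesignScene(toy_lib, collision_factor=1.0, auto_collision_check=False)
        base = scene.place_module("H4", RigidTransform())
        frag = coords64(toy_lib.load_fragment("H4"))
        from conftest import random_rotation

        for _ in range(200):
            world = RigidTransform(
                rotation=random_rotation(rng),
                translation=rng.uniform(-12, 12, size=3),
            )
            moved = world.apply_points(frag)
            dmin = np.min(
                np.linalg.norm(frag[:, None] - moved[None, :], axis=-1)
            )
            flagged = bool(scene.check_collision(("H4", world), factor=1.0))
            if dmin < 2.0:
                assert flagged, f"false negative at atom distance {dmin:.2f}"


class TestMirror:
    def test_link_and_extrude_two(self, scene):
        a = scene.place_module("H4", RigidTransform())
        b = scene.place_module("H4", FAR)
        gid = scene.link_by_mirror([a, b])
        new = scene.extrude(a, ":A(C)->(N)A:H4")
        assert len(new) == 2
        assert scene.mirror_group_of(new[0], "A") == scene.mirror_group_of(new[1], "A")

    def test_mixed_prototypes_rejected(self, scene):
        a = scene.place_module("H4", RigidTransform())
        b = scene.place_module("K4", FAR)
        with pytest.raises(MirrorError):
            scene.link_by_mirror([a, b])

    def test_singleton_rejected(self, scene):
        a = scene.place_module("H4", RigidTransform())
        with pytest.raises(MirrorError):
            scene.link_by_mirror([a])

    def test_hub_auto_mirror(self, scene):
        hub = scene.place_module("H4_C4", RigidTransform())
        gid = scene.mirror_group_of(hub, "A")
        assert gid is not None
        assert len(scene.mirror_groups[gid]) == 4

    def test_hub_mirror_extrusion_grows_all_arms(self, scene):
        hub = scene.place_module("H4_C4", RigidTransform())
        new = scene.extrude(hub, ":A(C)->(N)A:H4")
        assert len(new) == 4
        assert scene.validate() == []

    def test_unlink_then_single_extrusion(self, scene):
        a = scene.place_module("H4", RigidTransform())
        b = scene.place_module("H4", FAR)
        gid = scene.link_by_mirror([a, b])
        scene.unlink_mirror(gid)
        new = scene.extrude(a, ":A(C)->(N)A:H4")
        assert len(new) == 1

    def test_unlink_unknown(self, scene):
        with pytest.raises(MirrorError):
            scene.unlink_mirror("mg.999")

    def test_link_unlink_link_equivalent(self, scene):
        a = scene.place_module("H4", RigidTransform())
        b = scene.place_module("H4", FAR)
        g1 = scene.link_by_mirror([a, b])
        members = list(scene.mirror_groups[g1])
        scene.unlink_mirror(g1)
        g2 = scene.link_by_mirror([a, b])
        assert sorted(scene.mirror_groups[g2]) == sorted(members)

    def test_mirror_extrusion_atomic_on_failure(self, scene, toy_lib):
        a = scene.place_module("H4", RigidTransform())
        b = scene.place_module("H4", FAR)
        scene.link_by_mirror([a, b])
        # blocker sits where b's child would land (com at [100,0,6]+com_z)
        com = toy_lib.get_module("H4").com
        blocker_world = RigidTransform(
            translation=np.array([100.0, 0.0, 6.0]) + com - com  # child origin
        )
        blocker_world = RigidTransform(
            translation=[100.0, 0.0, 12.0]
        )  # within padded sphere of b's child site, clear of b itself
        scene.place_module("K4", blocker_world)
        before = set(scene.modules)
        with pytest.raises(CollisionError):
            scene.extrude(a, ":A(C)->(N)A:H4")
        assert set(scene.modules) == before
        assert scene.validate() == []

    def test_mirror_congruence_c4(self, scene, toy_lib):
        # three rounds of mirror extrusion: arm i superposes on arm 0
        # under Rz(90 i) with rmsd < 1e-6
        hub = scene.place_module("H4_C4", RigidTransform())
        frontier = {cid: hub for cid in "ABCD"}
        new = scene.extrude(hub, ":A(C)->(N)A:H4")
        for _ in range(2):
            new = scene.extrude(new[0], ":A(C)->(N)A:H4")
        arms = {i: [] for i in range(4)}
        frag = coords64(toy_lib.load_fragment("H4"))
        hub_children = sorted(
            iid for iid in scene.modules if iid.startswith("H4.")
        )
        # group arm modules by which hub chain they descend from
        def root_chain(iid):
            cur = (iid, "A", "N")
            while True:
                occ = scene.modules[cur[0]].occupancy[(cur[1], "N")]
                assert isinstance(occ, tuple)
                if occ[0] == hub:
                    return occ[1]
                cur = occ
        for iid in hub_children:
            atoms = scene.modules[iid].world.apply_points(frag)
            arms[ord(root_chain(iid)) - ord("A")].append(atoms)
        for i in range(1, 4):
            rot = rotation_about_axis([0, 0, 1], 90.0 * i)
            a0 = np.concatenate(arms[0])
            ai = np.concatenate(arms[i])
            rmsd = float(np.sqrt(np.mean(np.sum((a0 @ rot.T - ai) ** 2, axis=1))))
            assert rmsd < 1e-6


class TestNetworks:
    def test_join_two_singletons(self, scene):
        a = scene.place_module("H4", RigidTransform())
        b = scene.place_module("H4", FAR)
        nid = scene.join_networks((a, "A", "C"), (b, "A", "N"))
        assert len(scene.networks) == 1
        assert scene.networks[nid] == {a, b}
        assert len(scene.links) == 1

    def test_join_matches_extrusion_oracle(self, scene, toy_lib):
        a = scene.place_module("H4", RigidTransform())
        b = scene.place_module("H4", FAR)
        scene.join_networks((a, "A", "C"), (b, "A", "N"))
        oracle = DesignScene(toy_lib)
        oa = oracle.place_module("H4", RigidTransform())
        (ob,) = oracle.extrude(oa, ":A(C)->(N)A:H4")
        assert scene.modules[b].world.allclose(oracle.modules[ob].world, tol=1e-9)

    def test_join_incompatible(self, scene):
        a = scene.place_module("H4", RigidTransform())
        b = scene.place_module("H4", FAR)
        with pytest.raises(LibraryError):
            scene.join_networks((a, "A", "C"), (b, "A", "C"))

    def test_join_same_network_rejected(self, scene):
        a = scene.place_module("H4", RigidTransform())
        (b,) = scene.extrude(a, ":A(C)->(N)A:H4")
        with pytest.raises(SceneError):
            scene.join_networks((a, "A", "N"), (b, "A", "C"))

    def test_delete_middle_splits(self, scene):
        a = scene.place_module("H4", RigidTransform())
        (b,) = scene.extrude(a, ":A(C)->(N)A:H4")
        (c,) = scene.extrude(b, ":A(C)->(N)A:H4")
        scene.delete_instance(b)
        assert len(scene.networks) == 2
        assert scene.validate() == []

    def test_delete_terminal_keeps_one_network(self, scene):
        a = scene.place_module("H4", RigidTransform())
        (b,) = scene.extrude(a, ":A(C)->(N)A:H4")
        (c,) = scene.extrude(b, ":A(C)->(N)A:H4")
        scene.delete_instance(c)
        assert len(scene.networks) == 1
        assert scene.networks[scene.network_of(a)] == {a, b}

    def test_delete_unknown(self, scene):
        with pytest.raises(SceneError):
            scene.delete_instance("H4.999")

    def test_transform_network_identity(self, scene):
        a = scene.place_module("H4", RigidTransform())
        before = scene.modules[a].world
        scene.transform_network(scene.network_of(a), RigidTransform())
        assert scene.modules[a].world.allclose(before, tol=0.0)

    def test_transform_network_translation_shifts_coms(self, scene):
        a = scene.place_module("H4", RigidTransform())
        (b,) = scene.extrude(a, ":A(C)->(N)A:H4")
        coms = [scene.world_com(a).copy(), scene.world_com(b).copy()]
        scene.transform_network(scene.network_of(a), trans(0, 50, 0))
        assert np.allclose(scene.world_com(a), coms[0] + [0, 50, 0], atol=1e-9)
        assert np.allclose(scene.world_com(b), coms[1] + [0, 50, 0], atol=1e-9)

    def test_transform_network_preserves_internal_distances(self, scene, rng):
        from conftest import random_rotation

        a = scene.place_module("H4", RigidTransform())
        (b,) = scene.extrude(a, ":A(C)->(N)A:H4")
        d_before = np.linalg.norm(scene.world_com(a) - scene.world_com(b))
        t = RigidTransform(
            rotation=random_rotation(rng), translation=rng.uniform(-30, 30, 3)
        )
        scene.transform_network(scene.network_of(a), t)
        d_after = np.linalg.norm(scene.world_com(a) - scene.world_com(b))
        assert abs(d_before - d_after) < 1e-9

    def test_random_ops_network_partition_invariant(self, toy_lib, rng):
        import networkx as nx

        scene = DesignScene(toy_lib, auto_collision_check=False)
        spots = iter(range(1000))
        for step in range(200):
            op = rng.integers(4)
            ids = sorted(scene.modules)
            try:
                if op == 0 or not ids:
                    scene.place_module(
                        "H4", trans(20.0 * next(spots), 0, 0)
                    )
                elif op == 1:
                    iid = ids[int(rng.integers(len(ids)))]
                    term = "C" if rng.integers(2) else "N"
                    opp = "N" if term == "C" else "C"
                    scene.extrude(iid, f":A({term})->({opp})A:H4")
                elif op == 2:
                    iid = ids[int(rng.integers(len(ids)))]
                    scene.delete_instance(iid)
                elif op == 3 and len(scene.networks) >= 2:
                    frees = [
                        (iid, c, t)
                        for iid in ids
                        if iid in scene.modules
                        for (c, t) in scene.free_termini(iid)
                    ]
                    a = frees[int(rng.integers(len(frees)))]
                    others = [
                        f
                        for f in frees
                        if scene.network_of(f[0]) != scene.network_of(a[0])
                        and f[2] != a[2]
                    ]
                    if others:
                        scene.join_networks(a, others[0])
            except (SceneError, LibraryError):
                pass
            # invariant: networks == connected components, recomputed fresh
            g = nx.Graph()
            g.add_nodes_from(scene.modules)
            for link in scene.links:
                g.add_edge(link.a[0], link.b[0])
            fresh = {frozenset(c) for c in nx.connected_components(g)}
            declared = {frozenset(m) for m in scene.networks.values()}
            assert fresh == declared, f"partition broken at step {step}"
            occupied = sum(
                1
                for m in scene.modules.values()
                for occ in m.occupancy.values()
                if occ is not None and occ != "sealed"
            )
            assert occupied == 2 * len(scene.links)


class TestSerialization:
    def _build(self, toy_lib):
        scene = DesignScene(toy_lib)
        a = scene.place_module("H4", RigidTransform(), color="red")
        (b,) = scene.extrude(a, ":A(C)->(N)A:H4_j1_K4")
        (c,) = scene.extrude(b, ":A(C)->(N)A:K4")
        scene.place_module("H4_C2", trans(60, 0, 0))
        j1 = scene.guide.add_joint([0, 0, 40.0])
        j2 = scene.guide.extrude_joint(j1, [0, 10.0, 40.0])
        return scene

    def test_roundtrip_structural_equality(self, toy_lib, tmp_path):
        scene = self._build(toy_lib)
        p = tmp_path / "design.json"
        export_design(scene, p)
        again = import_design(p, toy_lib)
        assert set(again.modules) == set(scene.modules)
        for iid in scene.modules:
            assert again.modules[iid].world.allclose(scene.modules[iid].world, tol=0.0)
            assert again.modules[iid].color == scene.modules[iid].color
        assert {l.key() for l in again.links} == {l.key() for l in scene.links}
        assert again.networks == scene.networks
        assert again.mirror_groups == scene.mirror_groups
        assert set(again.guide.joints) == set(scene.guide.joints)

    def test_roundtrip_byte_identical(self, toy_lib, tmp_path):
        scene = self._build(toy_lib)
        p1, p2 = tmp_path / "d1.json", tmp_path / "d2.json"
        export_design(scene, p1)
        export_design(import_design(p1, toy_lib), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_scene_roundtrip(self, toy_lib, tmp_path):
        scene = DesignScene(toy_lib)
        p = tmp_path / "empty.json"
        export_design(scene, p)
        again = import_design(p, toy_lib)
        assert again.modules == {}
        assert again.links == []

    def test_missing_units_rejected(self, toy_lib):
        doc = scene_to_dict(DesignScene(toy_lib))
        del doc["units"]
        with pytest.raises(SchemaError, match="units"):
            scene_from_dict(doc, toy_lib)

    def test_units_are_nm(self, toy_lib, tmp_path):
        scene = DesignScene(toy_lib)
        scene.place_module("H4", trans(10.0, 0, 0))  # 10 A = 1 nm
        p = tmp_path / "units.json"
        export_design(scene, p)
        doc = json.loads(p.read_text())
        assert doc["units"] == "nm"
        assert doc["networks"][0]["modules"][0]["tran"] == [1.0, 0.0, 0.0]

    def test_id_proto_mismatch_rejected(self, toy_lib):
        doc = scene_to_dict(DesignScene(toy_lib))
        doc["networks"] = [
            {
                "name": "net.001",
                "modules": [
                    {
                        "id": "K4.001",
                        "proto": "H4",
                        "rot": np.eye(3).tolist(),
                        "tran": [0, 0, 0],
                        "color": None,
                        "links": [],
                    }
                ],
            }
        ]
        with pytest.raises(SchemaError):
            scene_from_dict(doc, toy_lib)
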