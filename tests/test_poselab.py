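"""Scaffold reduction, pose clustering, PLIFs, and site geometry."""

import numpy as np
import pytest
from rdkit import Chem

from ensdock.poselab import (
    Pose,
    PoseClusterSet,
    ScaffoldPose,
    STEROID_MCS_SMARTS,
    cluster_poses,
    detect_salt_bridges,
    halogen_bond_geometry,
    interaction_frequency,
    map_mcs,
    murcko_scaffold,
    plif,
    pocket_volume,
    prioritize_clusters,
    radius_of_gyration,
)
from ensdock.structio import Atom, Structure
from ensdock.synthkit import make_pose_field

from conftest import make_point_structure


class TestMurckoScaffold:
    def test_toluene_reduces_to_benzene(self):
        sc = murcko_scaffold(Chem.MolFromSmiles("Cc1ccccc1"))
        assert Chem.MolToSmiles(sc) == "c1ccccc1"

    def test_estrone_reduces_to_bare_tetracycle(self):
        estrone = Chem.MolFromSmiles("CC12CCC3c4ccc(O)cc4CCC3C1CCC2=O")
        sc = murcko_scaffold(estrone)
        # independent oracle: ring atoms + ring-ring linkers walked by hand
        ri = estrone.GetRingInfo()
        ring_atoms = {a for ring in ri.AtomRings() for a in ring}
        assert sc.GetRingInfo().NumRings() == 4
        # scaffold keeps exactly the ring systems (fused: no linkers here)
        assert sc.GetNumAtoms() == len(ring_atoms) + 1  # +1: exocyclic ketone O
        assert all(a.GetSymbol() in ("C", "O") for a in sc.GetAtoms())

    def test_acyclic_gives_empty_scaffold(self):
        sc = murcko_scaffold(Chem.MolFromSmiles("CCCCCC"))
        assert sc.GetNumAtoms() == 0

    def test_unparsable_rejected(self):
        with pytest.raises(ValueError):
            murcko_scaffold(None)


class TestMapMCS:
    def test_steroid_poses_fully_mapped(self):
        poses, _ = make_pose_field(1, 3, 0.1, seed=0)
        mapped = map_mcs(poses)
        assert len(mapped) == 3
        assert all(sp.coords.shape == (18, 3) for sp in mapped)

    def test_mapped_coordinates_match_substructure_oracle(self):
        poses, _ = make_pose_field(1, 1, 0.0, seed=0)
        pose = poses[0]
        mapped = map_mcs([pose])[0]
        query = Chem.MolFromSmarts(STEROID_MCS_SMARTS)
        match = pose.mol.GetSubstructMatch(query)
        np.testing.assert_allclose(mapped.coords, pose.xyz[list(match)])

    def test_nonmatching_pose_excluded_with_warning(self, caplog):
        poses, _ = make_pose_field(1, 2, 0.1, seed=0)
        benzene = Chem.MolFromSmiles("c1ccccc1")
        odd = Pose(pose_id="odd", compound_id="benzene",
                   elements=["C"] * 6, xyz=np.zeros((6, 3)), mol=benzene)
        with caplog.at_level("WARNING"):
            mapped = map_mcs(poses + [odd])
        assert len(mapped) == 2
        assert "odd" in caplog.text

    def test_all_nonmatching_rejected(self):
        benzene = Chem.MolFromSmiles("c1ccccc1")
        odd = Pose(pose_id="odd", compound_id="x", elements=["C"] * 6,
                   xyz=np.zeros((6, 3)), mol=benzene)
        with pytest.raises(ValueError):
            map_mcs([odd])


def _sp(pose_id, compound_id, coords):
    return ScaffoldPose(pose_id=pose_id, compound_id=compound_id,
                        coords=np.asarray(coords, dtype=float))


class TestClusterPoses:
    def test_identical_poses_single_cluster(self):
        c = np.random.default_rng(0).uniform(0, 5, (8, 3))
        cs = cluster_poses([_sp("a", "x", c), _sp("b", "y", c)])
        assert cs.n_clusters == 1

    def test_translated_poses_split(self):
        c = np.random.default_rng(0).uniform(0, 5, (8, 3))
        cs = cluster_poses([_sp("a", "x", c), _sp("b", "y", c + [10.0, 0, 0])])
        assert cs.n_clusters == 2

    def test_planted_three_sites_recovered(self):
        poses, labels = make_pose_field(3, 10, 0.3, seed=0)
        cs = cluster_poses(map_mcs(poses), cutoff=2.0)
        assert cs.n_clusters == 3
        site_of = {p.pose_id: l for p, l in zip(poses, labels)}
        for cl in cs.clusters:
            assert len({site_of[sp.pose_id] for sp in cl}) == 1  # no mislabels

    def test_input_order_invariance(self):
        poses, _ = make_pose_field(3, 6, 0.3, seed=1)
        mapped = map_mcs(poses)
        part1 = {frozenset(sp.pose_id for sp in cl)
                 for cl in cluster_poses(mapped).clusters}
        part2 = {frozenset(sp.pose_id for sp in cl)
                 for cl in cluster_poses(mapped[::-1]).clusters}
        assert part1 == part2

    def test_mixed_atom_counts_rejected(self):
        with pytest.raises(ValueError):
            cluster_poses([_sp("a", "x", np.zeros((5, 3))),
                           _sp("b", "y", np.zeros((6, 3)))])


class TestPrioritizeClusters:
    def _clusterset(self, memberships):
        clusters = [
            [_sp(f"c{i}_p{j}", cid, np.zeros((4, 3)))
             for j, cid in enumerate(members)]
            for i, members in enumerate(memberships)
        ]
        return PoseClusterSet(clusters=clusters)

    def test_full_coverage_kept(self):
        cs = self._clusterset([["a", "b", "c"]])
        kept = prioritize_clusters(cs, active_ids={"a", "b", "c"})
        assert kept[0]["coverage"] == pytest.approx(1.0)

    def test_exact_half_coverage_dropped(self):
        cs = self._clusterset([["a"]])
        assert prioritize_clusters(cs, active_ids={"a", "b"}) == []

    def test_single_enriched_cluster_pattern(self):
        # coverages {15/16, 5/16, 2/16} with duplicated poses per compound
        actives = {f"a{i}" for i in range(16)}
        cs = self._clusterset([
            [f"a{i}" for i in range(15)] + ["a0", "a1"],
            [f"a{i}" for i in range(5)],
            ["a0", "a1"],
        ])
        kept = prioritize_clusters(cs, active_ids=actives)
        assert len(kept) == 1
        assert kept[0]["cluster"] == 0
        assert kept[0]["n_poses"] == 17 and kept[0]["n_compounds"] == 15

    def test_empty_active_set_rejected(self):
        with pytest.raises(ValueError):
            prioritize_clusters(self._clusterset([["a"]]), active_ids=set())


def _residue(res_name, named_atoms, res_index=1, chain="A"):
    atoms = []
    for name, el, xyz in named_atoms:
        atoms.append(Atom(element=el, name=name, res_index=res_index,
                          res_name=res_name, chain=chain, xyz=tuple(xyz), vdw=1.6))
    return atoms


class TestPLIF:
    def test_carboxylate_accepts_ligand_hydroxyl(self):
        receptor = Structure(atoms=_residue(
            "GLU", [("OE1", "O", (0.0, 0.0, 0.0)), ("CD", "C", (1.2, 0.0, 0.0))]))
        # ligand O-H pointing at the carboxylate O, D-H...A angle ~160°
        pose = Pose(pose_id="p", compound_id="c", elements=["O", "H"],
                    xyz=np.array([[2.9, 0.0, 0.0], [1.95, 0.15, 0.0]]))
        bits = plif(pose, receptor)
        assert bits.get(("A:GLU1", "H-acceptor"))

    def test_lysine_forms_ionic_contact(self):
        receptor = Structure(atoms=_residue("LYS", [("NZ", "N", (0.0, 0.0, 0.0))]))
        pose = Pose(pose_id="p", compound_id="c", elements=["O"],
                    xyz=np.array([[3.5, 0.0, 0.0]]), charges=np.array([-1.0]))
        bits = plif(pose, receptor)
        assert bits.get(("A:LYS1", "ionic"))

    def test_distant_atoms_empty_fingerprint(self):
        receptor = Structure(atoms=_residue("GLU", [("OE1", "O", (0, 0, 0))]))
        pose = Pose(pose_id="p", compound_id="c", elements=["O"],
                    xyz=np.array([[10.0, 0.0, 0.0]]))
        assert plif(pose, receptor) == {}

    def test_untyped_atoms_listed(self):
        receptor = Structure(atoms=_residue("GLY", [("N", "N", (0, 0, 0))]))
        pose = Pose(pose_id="p", compound_id="c", elements=["Xx"],
                    xyz=np.zeros((1, 3)))
        with pytest.raises(ValueError, match="Xx"):
            plif(pose, receptor)

    def test_invariant_under_rigid_transform_of_complex(self):
        receptor = Structure(atoms=_residue(
            "GLU", [("OE1", "O", (0.0, 0.0, 0.0)), ("CD", "C", (1.2, 0.0, 0.0))]))
        pose = Pose(pose_id="p", compound_id="c", elements=["O", "H"],
                    xyz=np.array([[2.9, 0.0, 0.0], [1.95, 0.15, 0.0]]))
        bits0 = plif(pose, receptor)
        theta = np.radians(73.0)
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        shift = np.array([4.0, -6.0, 2.5])
        receptor2 = receptor.with_coords(receptor.coords() @ rot.T + shift)
        pose2 = Pose(pose_id="p", compound_id="c", elements=["O", "H"],
                     xyz=pose.xyz @ rot.T + shift)
        assert plif(pose2, receptor2) == bits0


class TestInteractionFrequency:
    def test_frequent_residue_flagged(self):
        rows = [{("A:GLN196", "H-donor"): True} for _ in range(41)]
        rows += [{} for _ in range(59)]
        table = interaction_frequency(rows, min_fraction=0.10)
        row = table[table.residue == "A:GLN196"].iloc[0]
        assert row.frequency == pytest.approx(0.41)
        assert bool(row.key_residue)

    def test_rare_residue_unflagged(self):
        rows = [{("A:SER1", "H-donor"): True}] + [{}] * 19
        table = interaction_frequency(rows, min_fraction=0.10)
        assert not bool(table.iloc[0].key_residue)

    def test_single_row_frequencies_binary(self):
        table = interaction_frequency([{("A:SER1", "H-donor"): True}])
        assert set(table.frequency) <= {0.0, 1.0}

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError):
            interaction_frequency([])


class TestSaltBridges:
    def _receptor(self, dist, base=("LYS", "NZ")):
        atoms = _residue("GLU", [("OE1", "O", (0, 0, 0))], res_index=74)
        atoms += _residue(base[0], [(base[1], base[1][0], (dist, 0, 0))],
                          res_index=200)
        return Structure(atoms=atoms)

    def test_close_pair_reported(self):
        bridges = detect_salt_bridges(self._receptor(3.2))
        assert len(bridges) == 1
        assert bridges[0][0] == "A:GLU74" and bridges[0][2] == pytest.approx(3.2)

    def test_distant_pair_ignored(self):
        assert detect_salt_bridges(self._receptor(6.0)) == []

    def test_like_charges_ignored(self):
        atoms = _residue("GLU", [("OE1", "O", (0, 0, 0))], res_index=74)
        atoms += _residue("GLU", [("OE1", "O", (3.0, 0, 0))], res_index=95)
        assert detect_salt_bridges(Structure(atoms=atoms)) == []


class TestHalogenBonds:
    @pytest.mark.parametrize(
        "angle_deg, expected",
        [(150.0, True), (95.0, False), (180.0, True), (119.0, False)],
    )
    def test_angle_window(self, angle_deg, expected):
        x = np.array([1.8, 0.0, 0.0])
        theta = np.radians(180.0 - angle_deg)
        o = x + 3.5 * np.array([np.cos(theta), np.sin(theta), 0.0])
        dist, angle, plausible = halogen_bond_geometry((0, 0, 0), x, o)
        assert dist == pytest.approx(3.5)
        assert angle == pytest.approx(angle_deg, abs=1e-6)
        assert plausible is expected

    def test_distance_window(self):
        _, _, ok = halogen_bond_geometry((0, 0, 0), (1.8, 0, 0), (8.5, 0, 0))
        assert not ok   # 6.7 Å exceeds the 6.0 Å bound

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            halogen_bond_geometry((0, 0, 0), (0, 0, 0), (1, 0, 0))


def hollow_shell(radius, n=2000, vdw=1.7, seed=1):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    return make_point_structure(pts * (radius + vdw), vdw=vdw, res_name="SHL")


class TestPocketVolume:
    def test_hollow_shell_matches_analytic_sphere(self):
        r = 8.0
        vol = pocket_volume(hollow_shell(r), (0, 0, 0), site_radius=r, grid=1.0)
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * r ** 3, rel=0.10)

    def test_packed_site_near_zero(self):
        grid = np.array(np.meshgrid(*[np.arange(-6, 7, 2.0)] * 3)).reshape(3, -1).T
        packed = make_point_structure(grid, vdw=1.9)
        vol = pocket_volume(packed, (0, 0, 0), site_radius=5.0, grid=1.0)
        assert vol < 30.0

    def test_grid_convergence(self):
        r = 8.0
        shell = hollow_shell(r)
        v1 = pocket_volume(shell, (0, 0, 0), site_radius=r, grid=1.0)
        v2 = pocket_volume(shell, (0, 0, 0), site_radius=r, grid=0.5)
        assert abs(v1 - v2) / v2 < 0.05

    def test_monotone_under_added_atoms(self):
        r = 6.0
        shell = hollow_shell(r, n=1200)
        v0 = pocket_volume(shell, (0, 0, 0), site_radius=r, grid=1.0)
        blocked = Structure(atoms=shell.atoms + [
            Atom(element="C", name="C", res_index=9999, res_name="BLK", chain="Z",
                 xyz=(3.0, 0.0, 0.0), vdw=2.5)])
        v1 = pocket_volume(blocked, (0, 0, 0), site_radius=r, grid=1.0)
        assert v1 <= v0

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            pocket_volume(hollow_shell(5.0, n=100), (0, 0, 0), 5.0, grid=0.0)


class TestRadiusOfGyration:
    def test_single_point_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_points_closed_form(self):
        assert radius_of_gyration(np.array([[0, 0, 0], [2.0, 0, 0]])) == 1.0

    def test_random_cloud_matches_direct_formula(self, rng):
        pts = rng.uniform(0, 10, (30, 3))
        masses = rng.uniform(1, 3, 30)
        com = (pts * masses[:, None]).sum(axis=0) / masses.sum()
        oracle = np.sqrt((masses * ((pts - com) ** 2).sum(axis=1)).sum()
                         / masses.sum())
        assert radius_of_gyration(pts, masses) == pytest.approx(oracle)
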