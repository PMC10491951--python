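"""Docked-pose loading, top-pose selection, frequency refinement, sampler."""

import numpy as np
import pytest

from interdct.library import InterDCTConfig
from interdct.prediction import InterDCTPrediction
from interdct.refinement import (
    DockedPose,
    frequency_refine,
    load_poses,
    naive_pose_sampler,
    pose_interface,
    refine,
    select_top_poses,
)
from interdct.structure import ResidueKey, write_pdb
from interdct.synthetic import generate_poses, make_query


def key(n):
    return ResidueKey("A", n, "", "ALA")


def prediction(numbers):
    residues = frozenset(key(n) for n in numbers)
    return InterDCTPrediction(
        query_id="Q", residues=residues, support={r: 1.0 for r in residues},
        path_taken="clustered", template_ids=("T",),
    )


@pytest.fixture(scope="module")
def posed_query(family):
    query, truth = make_query(family, group=0, seed=7)
    poses = generate_poses(query.structure, truth, n_at_patch=30, n_elsewhere=30, seed=3)
    return query, truth, poses


class TestPoseGeometry:
    def test_at_patch_pose_contacts_only_patch(self, posed_query):
        query, truth, poses = posed_query
        patch_pose = next(p for p in poses if "patch" in p.pose_id)
        iface = pose_interface(query.structure, "A", patch_pose)
        assert iface <= truth
        assert len(iface) >= 0.8 * len(truth)

    def test_elsewhere_pose_contacts_no_patch_residue(self, posed_query):
        query, truth, poses = posed_query
        for pose in poses:
            if "else" in pose.pose_id:
                assert pose_interface(query.structure, "A", pose) & truth == frozenset()

    def test_far_probe_has_empty_interface(self, posed_query):
        query, _, poses = posed_query
        far = poses[0].probe.copy()
        for _, a in far.atoms():
            a.coords = a.coords + np.array([0.0, 500.0, 0.0])
        pose = DockedPose(pose_id="far", probe_id="p", probe=far)
        assert pose_interface(query.structure, "A", pose) == frozenset()

    def test_pose_interface_deterministic(self, posed_query):
        query, _, poses = posed_query
        a = pose_interface(query.structure, "A", poses[0])
        b = pose_interface(query.structure, "A", poses[0])
        assert a == b


class TestSelectTopPoses:
    def test_patch_poses_separate_from_off_patch(self, posed_query):
        query, truth, poses = posed_query
        interfaces = [pose_interface(query.structure, "A", p) for p in poses]
        initial = prediction(sorted(k.seq_number for k in truth))
        top = select_top_poses(poses, interfaces, initial, n=30)
        assert len(top) == 30
        assert all("patch" in poses[i].pose_id for i in top)

    def test_n_larger_than_pose_count_uses_all(self):
        poses = [DockedPose(pose_id=f"p{i}", probe_id="x", probe=None) for i in range(4)]
        interfaces = [frozenset({key(1)})] * 4
        top = select_top_poses(poses, interfaces, prediction([1]), n=100)
        assert len(top) == 4

    def test_equal_f_ties_break_by_pose_id(self):
        poses = [DockedPose(pose_id=f"p{i}", probe_id="x", probe=None) for i in (3, 1, 2)]
        interfaces = [frozenset({key(1)})] * 3
        top = select_top_poses(poses, interfaces, prediction([1]), n=2)
        assert [poses[i].pose_id for i in top] == ["p1", "p2"]

    def test_all_empty_interfaces_signal_skip(self):
        poses = [DockedPose(pose_id="p0", probe_id="x", probe=None)]
        assert select_top_poses(poses, [frozenset()], prediction([1]), n=5) == []


class TestFrequencyRefine:
    def test_identical_top_poses_reproduce_initial(self):
        initial = prediction(range(1, 9))
        refined = frequency_refine([initial.residues] * 20, initial)
        assert refined.residues == initial.residues
        assert all(v == 1.0 for v in refined.tp_frequency.values())

    def test_add_rule_strictly_above_35_percent(self):
        initial = prediction(range(1, 9))
        extra = key(20)
        tops = [initial.residues | {extra}] * 36 + [initial.residues] * 64
        refined = frequency_refine(tops, initial)
        assert extra in refined.residues  # 0.36 > 0.35
        tops = [initial.residues | {extra}] * 35 + [initial.residues] * 65
        refined = frequency_refine(tops, initial)
        assert extra not in refined.residues  # 0.35 not > 0.35

    def test_keep_rule_strictly_above_50_percent(self):
        initial = prediction(range(1, 9))
        weak = key(8)
        strong = initial.residues - {weak}
        tops = [initial.residues] * 50 + [strong] * 50
        refined = frequency_refine(tops, initial)
        assert weak not in refined.residues  # 0.50 not > 0.50
        tops = [initial.residues] * 51 + [strong] * 49
        refined = frequency_refine(tops, initial)
        assert weak in refined.residues  # 0.51 > 0.50

    def test_matches_independent_frequency_recount(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            universe = [key(n) for n in range(1, 30)]
            initial = prediction(rng.choice(range(1, 30), size=8, replace=False))
            tops = [
                frozenset(k for k in universe if rng.random() < 0.4) for _ in range(40)
            ]
            refined = frequency_refine(tops, initial)
            expect = set()
            for r in universe:
                freq = sum(r in t for t in tops) / len(tops)
                if r in initial.residues and freq > 0.50:
                    expect.add(r)
                if r not in initial.residues and freq > 0.35:
                    expect.add(r)
            if not expect:
                expect = set(initial.residues)  # empty-refinement fallback
            assert refined.residues == frozenset(expect)


class TestRefineDriver:
    def test_pose_count_contract(self, posed_query):
        """3 probes x 20 poses -> exactly 60 pose interfaces evaluated."""
        query, truth, _ = posed_query
        poses = []
        for probe in range(3):
            poses.extend(
                generate_poses(query.structure, truth, n_at_patch=10, n_elsewhere=10,
                               seed=probe, probe_id=f"probe{probe}")
            )
        initial = prediction(sorted(k.seq_number for k in truth))
        refined = refine(query.structure, "A", poses, initial,
                         InterDCTConfig(n_top_poses=20))
        assert refined.n_poses_evaluated == 3 * 20 == 60
        assert refined.n_top_poses == 20

    def test_refinement_preserves_planted_interface(self, posed_query):
        query, truth, poses = posed_query
        initial = prediction(sorted(k.seq_number for k in truth))
        refined = refine(query.structure, "A", poses, initial,
                         InterDCTConfig(n_top_poses=20))
        assert refined.residues == truth


class TestLoadPoses:
    def test_directory_round_trip(self, tmp_path, posed_query):
        query, _, poses = posed_query
        for pose in poses[:5]:
            write_pdb(pose.probe, tmp_path / f"{pose.pose_id}.pdb")
        loaded = load_poses(tmp_path, query.structure)
        assert len(loaded) == 5
        assert {p.pose_id for p in loaded} == {p.pose_id for p in poses[:5]}

    def test_empty_directory_raises(self, tmp_path):
        from interdct.structure import StructureModel

        with pytest.raises(ValueError):
            load_poses(tmp_path, StructureModel(id="q", chains=[]))

    def test_file_without_probe_chain_skipped(self, tmp_path, posed_query):
        query, _, poses = posed_query
        write_pdb(query.structure.subset(["A"]), tmp_path / "noprobe.pdb")
        write_pdb(poses[0].probe, tmp_path / f"{poses[0].pose_id}.pdb")
        loaded = load_poses(tmp_path, query.structure)
        assert len(loaded) == 1


class TestNaivePoseSampler:
    def test_deterministic_and_contact_without_clash(self, posed_query):
        query, _, poses = posed_query
        probe = poses[0].probe
        a = naive_pose_sampler(query.structure, "A", probe, n=5, seed=9)
        b = naive_pose_sampler(query.structure, "A", probe, n=5, seed=9)
        for pa, pb in zip(a, b):
            ca = np.array([at.coords for _, at in pa.probe.atoms()])
            cb = np.array([at.coords for _, at in pb.probe.atoms()])
            np.testing.assert_array_equal(ca, cb)
        q_xyz, q_rad, _ = query.structure.atom_arrays(["A"])
        for pose in a:
            p_xyz, p_rad, _ = pose.probe.atom_arrays()
            d = np.linalg.norm(q_xyz[:, None] - p_xyz[None, :], axis=2)
            cutoff = q_rad[:, None] + p_rad[None, :] + 2.8
            clash = 0.7 * (q_rad[:, None] + p_rad[None, :])
            assert (d < cutoff).any()
            assert not (d < clash).any()
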