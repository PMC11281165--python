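"""Joint angles, ROM, opposition, thumb AROM and the normal-consistency
metric, each checked against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_rotation
from handdx import kinematics as kin
from handdx.errors import DegenerateSegment, NoEvaluableFaces, TooFewFrames
from handdx.kinematics import AngleTrajectory
from handdx.skeleton import LANDMARK_INDEX, JointSpec, LandmarkFrame, MotionSequence
from handdx.synthetic import generate_pose


def frame_with_triplet(x, y, z, joint=None):
    """A frame placing the given joint's triplet at X, Y, Z; the other
    landmarks are scattered deterministically so the frame validates."""
    rng = np.random.default_rng(0)
    pts = rng.normal(scale=50.0, size=(21, 3))
    p, v, d = (joint or JointSpec("index_MCP", (0, 5, 6), "MCP")).triplet
    pts[p], pts[v], pts[d] = x, y, z
    return LandmarkFrame(pts)


INDEX_MCP = JointSpec("index_MCP", (0, 5, 6), "MCP")


class TestJointAngle:
    def test_collinear_chain_reads_zero_flexion(self):
        frame = frame_with_triplet((0, 0, 0), (10, 0, 0), (20, 0, 0))
        assert kin.joint_angle(frame, INDEX_MCP) == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_bones_read_90(self):
        frame = frame_with_triplet((0, 0, 0), (10, 0, 0), (10, 10, 0))
        assert kin.joint_angle(frame, INDEX_MCP) == pytest.approx(90.0, abs=1e-12)

    def test_matches_law_of_cosines_oracle(self, rng):
        """On random non-degenerate triplets the angle equals the
        law-of-cosines value computed from pairwise distances alone."""
        for _ in range(300):
            x, y, z = rng.normal(scale=40.0, size=(3, 3))
            a = np.linalg.norm(y - x)
            b = np.linalg.norm(z - y)
            c = np.linalg.norm(z - x)
            if min(a, b) < 1e-3:
                continue
            # interior angle at Y of triangle XYZ; flexion is its supplement
            cos_interior = np.clip((a**2 + b**2 - c**2) / (2 * a * b), -1, 1)
            expected = 180.0 - np.degrees(np.arccos(cos_interior))
            frame = frame_with_triplet(x, y, z)
            assert kin.joint_angle(frame, INDEX_MCP) == pytest.approx(
                expected, abs=1e-9
            )

    def test_symmetric_in_chain_direction(self, rng):
        x, y, z = rng.normal(scale=40.0, size=(3, 3))
        fwd = frame_with_triplet(x, y, z)
        reversed_joint = JointSpec("index_MCP", (6, 5, 0), "MCP")
        assert kin.joint_angle(fwd, INDEX_MCP) == pytest.approx(
            kin.joint_angle(fwd, reversed_joint), abs=1e-12
        )

    def test_rigid_motion_and_scale_invariance(self, topo, geom, rng):
        angles = {"index_MCP": 37.0, "middle_PIP": 80.0, "thumb_DIP": 12.0}
        frame = generate_pose(geom, angles)
        reference = [kin.joint_angle(frame, j) for j in topo.joints]
        for _ in range(20):
            rot = random_rotation(rng)
            shift = rng.normal(scale=100.0, size=3)
            scale = float(rng.uniform(0.1, 10.0))
            moved = LandmarkFrame(scale * frame.points @ rot.T + shift)
            got = [kin.joint_angle(moved, j) for j in topo.joints]
            np.testing.assert_allclose(got, reference, atol=1e-9)

    def test_degenerate_segment_raises(self):
        frame = frame_with_triplet((0, 0, 0), (0, 0, 0), (10, 0, 0))
        with pytest.raises(DegenerateSegment):
            kin.joint_angle(frame, INDEX_MCP)

    @settings(derandomize=True, max_examples=150)
    @given(coords=st.lists(st.floats(-100.0, 100.0), min_size=9, max_size=9))
    def test_result_always_within_0_180(self, coords):
        x, y, z = np.asarray(coords).reshape(3, 3)
        if min(np.linalg.norm(y - x), np.linalg.norm(z - y)) <= 1e-6:
            return  # degenerate triplet: no angle defined
        frame = frame_with_triplet(x, y, z)
        assert 0.0 <= kin.joint_angle(frame, INDEX_MCP) <= 180.0


class TestTrajectoryAndRom:
    def test_single_frame_trajectory(self, geom, topo):
        seq = MotionSequence([generate_pose(geom, {"index_MCP": 20.0})])
        traj = kin.angle_trajectory(seq, topo.joint("index_MCP"))
        assert len(traj) == 1
        assert traj.values[0] == pytest.approx(20.0, abs=1e-9)

    def test_constant_pose_gives_identical_values(self, geom, topo):
        frame = generate_pose(geom, {"ring_PIP": 45.0})
        seq = MotionSequence([frame] * 5)
        traj = kin.angle_trajectory(seq, topo.joint("ring_PIP"))
        assert np.ptp(traj.values) == 0.0

    def test_rom_is_max_minus_min(self):
        traj = AngleTrajectory("index_MCP", [10.0, 50.0, 30.0])
        assert kin.range_of_motion(traj) == pytest.approx(40.0)

    def test_rom_constant_trajectory_is_zero(self):
        assert kin.range_of_motion(AngleTrajectory("x", [12.0] * 4)) == 0.0

    def test_rom_permutation_invariant(self, rng):
        values = rng.uniform(0, 180, size=30)
        expected = np.sort(values)[-1] - np.sort(values)[0]
        for _ in range(10):
            perm = rng.permutation(values)
            assert kin.range_of_motion(AngleTrajectory("x", perm)) == pytest.approx(
                expected
            )

    def test_rom_never_decreases_with_more_frames(self, rng):
        values = list(rng.uniform(0, 180, size=10))
        rom = kin.range_of_motion(AngleTrajectory("x", values))
        for extra in rng.uniform(0, 180, size=20):
            values.append(extra)
            new_rom = kin.range_of_motion(AngleTrajectory("x", values))
            assert new_rom >= rom - 1e-12
            rom = new_rom

    def test_rom_needs_two_frames(self):
        with pytest.raises(TooFewFrames):
            kin.range_of_motion(AngleTrajectory("x", [5.0]))

    def test_trajectory_error_reports_frame_index(self, geom):
        good = generate_pose(geom, {})
        bad = LandmarkFrame(np.zeros((21, 3)))
        seq = MotionSequence([good, bad])
        with pytest.raises(DegenerateSegment, match="frame 1"):
            kin.angle_trajectory(seq, INDEX_MCP)


class TestOpposition:
    def place(self, distance, geom):
        frame = generate_pose(geom, {})
        frame.points[LANDMARK_INDEX["thumb_tip"]] = (
            frame.points[LANDMARK_INDEX["little_MCP"]] + [distance, 0.0, 0.0]
        )
        return frame

    def test_coincident_points_distance_zero(self, geom):
        assert kin.opposition_distance(self.place(0.0, geom)) == pytest.approx(0.0)

    def test_axis_aligned_distance(self, geom):
        assert kin.opposition_distance(self.place(30.0, geom)) == pytest.approx(30.0)

    def test_matches_euclidean_oracle(self, geom, rng):
        frame = generate_pose(geom, {"thumb_MCP": 30.0})
        frame.points += rng.normal(size=(21, 3))
        a = frame.points[LANDMARK_INDEX["thumb_tip"]]
        b = frame.points[LANDMARK_INDEX["little_MCP"]]
        expected = np.sqrt(((a - b) ** 2).sum())
        assert kin.opposition_distance(frame) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "distance,outcome",
        [(29.0, "achieved"), (30.0, "not_achieved"), (31.0, "not_achieved")],
    )
    def test_30mm_margin_is_strict(self, geom, distance, outcome):
        """The 3 cm contact margin: strictly below 30 mm succeeds; the
        boundary value itself does not."""
        seq = MotionSequence([self.place(distance, geom)])
        result = kin.opposition_test(seq)
        assert result.outcome == outcome
        assert result.min_distance_mm == pytest.approx(distance)

    def test_minimum_over_frames_decides(self, geom):
        seq = MotionSequence([self.place(80.0, geom), self.place(25.0, geom)])
        assert kin.opposition_test(seq).outcome == "achieved"


class TestThumbArom:
    def test_static_thumb_gives_zero(self, geom, topo):
        seq = MotionSequence([generate_pose(geom, {})] * 3)
        assert kin.thumb_total_arom(seq, topo) == pytest.approx(0.0, abs=1e-9)

    def test_equals_sum_of_component_roms(self, geom, topo, rng):
        frames = [
            generate_pose(
                geom,
                {"thumb_MCP": float(rng.uniform(0, 60)),
                 "thumb_DIP": float(rng.uniform(0, 60))},
            )
            for _ in range(6)
        ]
        seq = MotionSequence(frames)
        expected = sum(
            kin.range_of_motion(kin.angle_trajectory(seq, topo.joint(n)))
            for n in ("thumb_MCP", "thumb_DIP")
        )
        assert kin.thumb_total_arom(seq, topo) == pytest.approx(expected)


class TestNormalConsistency:
    def flexed(self, geom):
        return generate_pose(
            geom, {"index_MCP": 40.0, "index_PIP": 30.0, "middle_MCP": 25.0,
                   "thumb_MCP": 35.0, "ring_DIP": 20.0, "little_PIP": 15.0}
        )

    def test_identity_is_zero(self, geom, topo):
        gt = self.flexed(geom)
        result = kin.normal_consistency(gt, gt, topo)
        assert result.value == pytest.approx(0.0, abs=1e-9)
        assert result.n_faces_evaluated > 0

    def test_translation_invariant(self, geom, topo):
        gt = self.flexed(geom)
        pred = LandmarkFrame(gt.points + np.array([12.0, -7.0, 3.0]))
        assert kin.normal_consistency(pred, gt, topo).value == pytest.approx(
            0.0, abs=1e-9
        )

    def test_scaling_pred_invariant(self, geom, topo, rng):
        gt = self.flexed(geom)
        pred = LandmarkFrame(gt.points + rng.normal(scale=2.0, size=(21, 3)))
        v1 = kin.normal_consistency(pred, gt, topo).value
        v2 = kin.normal_consistency(LandmarkFrame(3.0 * pred.points), gt, topo).value
        assert v1 == pytest.approx(v2, rel=1e-9)

    def test_normal_displacement_matches_bruteforce_oracle(self, geom, topo):
        """Displacing one predicted vertex along its gt face normal produces
        a positive value equal to a per-edge dot-product recomputation."""
        gt = self.flexed(geom)
        face = topo.faces[2]  # an index-finger face
        e1 = gt.points[face[1]] - gt.points[face[0]]
        e2 = gt.points[face[2]] - gt.points[face[0]]
        normal = np.cross(e1, e2)
        normal /= np.linalg.norm(normal)
        pred_pts = gt.points.copy()
        pred_pts[face[1]] += 5.0 * normal
        pred = LandmarkFrame(pred_pts)

        result = kin.normal_consistency(pred, gt, topo)
        assert result.value > 0

        expected = 0.0
        for i, j, k in topo.faces:
            g1 = gt.points[j] - gt.points[i]
            g2 = gt.points[k] - gt.points[i]
            n = np.cross(g1, g2)
            if np.linalg.norm(n) <= 1e-9 * np.linalg.norm(g1) * np.linalg.norm(g2):
                continue
            n = n / np.linalg.norm(n)
            for a, b in ((i, j), (j, k), (k, i)):
                edge = pred.points[a] - pred.points[b]
                expected += abs(np.dot(edge / np.linalg.norm(edge), n))
        assert result.value == pytest.approx(expected, abs=1e-9)

    def test_fully_extended_gt_has_no_evaluable_faces(self, geom, topo):
        """Every face of a fully extended hand is collinear (each finger's
        landmarks lie on the metacarpal line), so the metric is undefined."""
        gt = generate_pose(geom, {})
        with pytest.raises(NoEvaluableFaces):
            kin.normal_consistency(gt, gt, topo)

    def test_collinear_faces_are_skipped_not_counted(self, geom, topo):
        gt = generate_pose(geom, {"index_MCP": 40.0})  # only index faces bend
        pred = gt
        result = kin.normal_consistency(pred, gt, topo)
        assert result.n_faces_evaluated < len(topo.faces)

    def test_zero_length_pred_edge_raises(self, geom, topo):
        gt = self.flexed(geom)
        pred_pts = gt.points.copy()
        pred_pts[6] = pred_pts[5]  # collapse an index edge
        with pytest.raises(DegenerateSegment):
            kin.normal_consistency(LandmarkFrame(pred_pts), gt, topo)
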