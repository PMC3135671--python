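"""Rigid superposition: Kabsch fit, ensemble alignment, anchor transfer."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from confsel.align import (AlignmentSelection, RigidTransform, align_ensemble,
                           kabsch_fit, place_anchor)
from confsel.errors import DegenerateGeometryError, SelectionError
from confsel.synthetic import (EnsembleConfig, build_scaffold,
                               generate_ensemble, generate_reference_complex)


def horn_quaternion_fit(moving, target):
    """Independent closed-form oracle: Horn's quaternion-eigenvalue method."""
    X = moving - moving.mean(axis=0)
    Y = target - target.mean(axis=0)
    S = X.T @ Y
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    eigvals, eigvecs = np.linalg.eigh(N)
    w, x, y, z = eigvecs[:, -1]
    R = Rotation.from_quat([x, y, z, w]).as_matrix()
    t = target.mean(axis=0) - R @ moving.mean(axis=0)
    residual = moving @ R.T + t - target
    return R, t, float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))


class TestKabschFit:
    def test_identity_on_identical_point_sets(self, rng):
        points = rng.normal(size=(6, 3))
        transform, rmsd = kabsch_fit(points, points)
        assert transform.is_identity(atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered(self, rng):
        points = rng.normal(size=(5, 3))
        transform, rmsd = kabsch_fit(points, points + np.array([1.0, 0.0, 0.0]))
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(transform.translation, [1.0, 0.0, 0.0], atol=1e-12)
        assert rmsd < 1e-12

    def test_recovers_random_rotation(self, rng):
        points = rng.normal(size=(5, 3))
        R = Rotation.random(random_state=42).as_matrix()
        t = rng.normal(size=3)
        transform, rmsd = kabsch_fit(points, points @ R.T + t)
        assert np.allclose(transform.rotation, R, atol=1e-9)
        assert rmsd < 1e-9

    def test_agrees_with_quaternion_oracle_on_noisy_pairs(self, rng):
        # noisy targets: the optimum is nontrivial, both methods must agree
        for _ in range(100):
            moving = rng.normal(size=(7, 3))
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            target = moving @ R.T + rng.normal(size=3) + 0.1 * rng.normal(size=(7, 3))
            transform, rmsd = kabsch_fit(moving, target)
            R_oracle, t_oracle, rmsd_oracle = horn_quaternion_fit(moving, target)
            assert rmsd == pytest.approx(rmsd_oracle, abs=1e-9)
            assert np.allclose(transform.rotation, R_oracle, atol=1e-7)

    def test_reflection_branch_yields_proper_rotation(self, rng):
        # mirrored target: the unconstrained optimum is a reflection
        moving = rng.normal(size=(6, 3))
        target = moving * np.array([-1.0, 1.0, 1.0])
        transform, _ = kabsch_fit(moving, target)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_points_rejected(self):
        line = np.outer(np.arange(4, dtype=float), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(line, line)

    def test_too_few_or_mismatched_points_rejected(self, rng):
        pts = rng.normal(size=(2, 3))
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(pts, pts)
        with pytest.raises(DegenerateGeometryError):
            kabsch_fit(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))


class TestRigidTransform:
    def test_rejects_improper_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([-1.0, 1.0, 1.0]), np.zeros(3))

    def test_compose_and_inverse(self, rng):
        R = Rotation.random(random_state=0).as_matrix()
        transform = RigidTransform(R, rng.normal(size=3))
        assert transform.compose(transform.inverse()).is_identity(atol=1e-12)


class TestAlignEnsemble:
    def test_recovers_known_rigid_perturbations(self):
        # jitter-free frames differ from canonical by a pure rigid motion
        ens = generate_ensemble(EnsembleConfig(n_frames=50, atom_jitter_sd=0.0, seed=21))
        reference = generate_reference_complex().receptor
        aligned, rmsds, _ = align_ensemble(ens.frames, reference=reference)
        assert np.all(rmsds < 1e-6)
        selection = AlignmentSelection()
        target = selection.resolve(reference)
        for frame in aligned:
            assert np.linalg.norm(selection.resolve(frame) - target, axis=1).max() < 1e-6

    def test_alignment_is_rigid(self, small_two_state_ensemble):
        frame = small_two_state_ensemble.frames[0]
        aligned, _, _ = align_ensemble([frame],
                                       reference=generate_reference_complex().receptor)
        before = np.linalg.norm(frame.coords[:, None] - frame.coords[None, :], axis=2)
        after = np.linalg.norm(aligned[0].coords[:, None] - aligned[0].coords[None, :], axis=2)
        assert np.abs(before - after).max() < 1e-9

    def test_idempotent_on_aligned_ensemble(self, small_two_state_ensemble):
        reference = generate_reference_complex().receptor
        aligned, _, _ = align_ensemble(small_two_state_ensemble.frames, reference=reference)
        again, _, transforms = align_ensemble(aligned, reference=reference)
        for frame, refit in zip(aligned, again):
            assert np.abs(frame.coords - refit.coords).max() < 1e-9
        assert all(t.is_identity(atol=1e-9) for t in transforms)

    def test_single_frame_equal_to_reference_unchanged(self, open_frame):
        aligned, rmsds, transforms = align_ensemble([open_frame], reference=open_frame)
        assert transforms[0].is_identity(atol=1e-9)
        assert np.allclose(aligned[0].coords, open_frame.coords, atol=1e-9)
        assert rmsds[0] < 1e-12

    def test_unresolvable_selection_names_frame(self, open_frame):
        # frame 1 is missing a fit atom that the reference resolves fine
        broken = open_frame.copy()
        idx = broken.atom_index(("HIS", 2, "NE2"))
        broken.atom_names[idx] = "XX"
        with pytest.raises(SelectionError, match="frame 1"):
            align_ensemble([open_frame, broken], reference=open_frame)

    def test_unresolvable_reference_selection_reported(self, open_frame):
        bad = AlignmentSelection((("ZN", 1, "ZN"), ("HIS", 2, "NE2"), ("XXX", 9, "QQ")))
        with pytest.raises(SelectionError, match="reference"):
            align_ensemble([open_frame], selection=bad, reference=open_frame)


class TestPlaceAnchor:
    def test_identity_frame_gets_template_coordinates(self, reference_complex):
        pose = place_anchor(reference_complex, reference_complex.receptor)
        assert np.allclose(pose.coords, reference_complex.anchor.coords, atol=1e-9)
        assert pose.usable
        assert pose.chelation_distance == pytest.approx(2.0, abs=1e-9)

    def test_rotated_frame_gets_rotated_template(self, reference_complex):
        R = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        rotated = reference_complex.receptor.transformed(R, np.array([1.0, -2.0, 0.5]))
        pose = place_anchor(reference_complex, rotated)
        expected = reference_complex.anchor.coords @ R.T + np.array([1.0, -2.0, 0.5])
        assert np.allclose(pose.coords, expected, atol=1e-9)
        assert pose.usable

    def test_displaced_zinc_marks_frame_unusable(self, reference_complex):
        frame = reference_complex.receptor.copy()
        frame.coords[frame.atom_index(("ZN", 1, "ZN"))] += np.array([5.0, 0.0, 0.0])
        pose = place_anchor(reference_complex, frame)
        # the least-squares fit partially follows the displaced zinc, so the
        # failure is flagged through the degraded site-fit RMSD
        assert not pose.usable
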