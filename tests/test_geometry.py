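"""DNA geometry: ideal B-DNA, superposition, splicing, roll bends, kinks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intasome.geometry import (
    IDEAL_RISE,
    IDEAL_TWIST_DEG,
    bend_roll,
    generate_bdna,
    kink_rotate,
    splice,
    superpose,
)


def _assert_orthonormal(path, tol=1e-8):
    for t in path.triads:
        assert np.allclose(t.T @ t, np.eye(3), atol=tol)
        assert np.linalg.det(t) > 0


# ---------------------------------------------------------------- B-DNA

class TestGenerateBdna:
    def test_single_bp_is_identity_frame_at_origin(self):
        p = generate_bdna("A")
        assert len(p) == 1
        assert np.allclose(p.origins[0], 0)
        assert np.allclose(p.triads[0], np.eye(3))

    def test_end_to_end_distance_is_collinear_rise(self):
        p = generate_bdna("A" * 21, rise=3.38)
        assert np.linalg.norm(p.origins[-1] - p.origins[0]) == pytest.approx(
            20 * 3.38, abs=1e-12
        )

    def test_two_full_turns_restore_triad(self):
        p = generate_bdna("A" * 22, twist_deg=720.0 / 21.0)
        assert np.allclose(p.triads[21], p.triads[0], atol=1e-8)

    def test_step_parameters_match_request(self):
        p = generate_bdna("ACGT" * 5, twist_deg=34.5, rise=3.3)
        assert np.allclose(p.step_twist(), 34.5, atol=1e-9)
        assert np.allclose(p.step_roll(), 0.0, atol=1e-9)
        assert np.allclose(p.step_rise(), 3.3, atol=1e-12)

    @pytest.mark.parametrize("seq", ["", "AXT", "acgu"])
    def test_bad_sequences_rejected(self, seq):
        with pytest.raises(ValueError):
            generate_bdna(seq)


# ---------------------------------------------------------------- superpose

class TestSuperpose:
    def test_identical_sets_give_identity(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        t, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-7)
        assert np.allclose(t.translation, 0, atol=1e-7)

    def test_recovers_known_rotation_translation(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        r = Rotation.from_rotvec([0.3, -0.5, 0.9]).as_matrix()
        tvec = np.array([5.0, -2.0, 1.5])
        t, rmsd = superpose(pts @ r.T + tvec, pts)
        assert rmsd < 1e-6
        assert np.allclose(t.rotation @ r, np.eye(3), atol=1e-6)

    def test_mirror_image_never_reflected(self):
        pts = np.random.default_rng(2).normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        t, rmsd = superpose(mirrored, pts)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)
        assert rmsd > 0.1

    def test_cardinality_mismatch_and_collinear_rejected(self):
        pts = np.random.default_rng(3).normal(size=(6, 3))
        with pytest.raises(ValueError, match="cardinality"):
            superpose(pts[:5], pts)
        line = np.outer(np.arange(6.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            superpose(line, line)


# ---------------------------------------------------------------- splice

class TestSplice:
    def test_ideal_to_ideal_is_seamless(self):
        a, b = generate_bdna("A" * 30), generate_bdna("G" * 40)
        s = splice(a, b, splint_len=4)
        assert len(s) == 70
        assert s.sequence == "A" * 30 + "G" * 40
        assert np.allclose(s.step_twist(), IDEAL_TWIST_DEG, atol=1e-6)
        assert np.allclose(s.step_rise(), IDEAL_RISE, atol=1e-6)
        # collinear axis throughout
        d = s.origins[-1] - s.origins[0]
        steps = np.diff(s.origins, axis=0)
        assert np.abs(np.cross(steps, d)).max() < 1e-9

    def test_upstream_never_moves(self):
        a, b = generate_bdna("A" * 20), generate_bdna("C" * 20)
        ref = a.origins.copy()
        s = splice(a, b, splint_len=5)
        assert np.array_equal(s.origins[:20], ref)

    def test_bent_input_step_parameters_preserved(self):
        bent = bend_roll(generate_bdna("A" * 30), 15, 25.0)
        straight = generate_bdna("T" * 30)
        s = splice(bent, straight, splint_len=4)
        assert np.allclose(s.step_twist()[:29], bent.step_twist(), atol=1e-6)
        assert np.allclose(s.step_roll()[:29], bent.step_roll(), atol=1e-6)
        assert np.allclose(s.step_twist()[30:], straight.step_twist(), atol=1e-6)

    def test_associativity_on_straight_ideals(self):
        a = generate_bdna("A" * 12)
        b = generate_bdna("C" * 15)
        c = generate_bdna("G" * 18)
        left = splice(splice(a, b, 4), c, 4)
        right = splice(a, splice(b, c, 4), 4)
        rmsd = np.sqrt(np.mean(np.sum((left.origins - right.origins) ** 2, axis=1)))
        assert rmsd < 1e-6

    def test_short_inputs_rejected(self):
        with pytest.raises(ValueError):
            splice(generate_bdna("AAA"), generate_bdna("A" * 20), splint_len=4)


# ---------------------------------------------------------------- bend_roll

class TestBendRoll:
    def test_zero_roll_is_identity(self):
        p = generate_bdna("A" * 20)
        q = bend_roll(p, 7, 0.0)
        assert np.allclose(q.origins, p.origins, atol=1e-10)
        assert np.allclose(q.triads, p.triads, atol=1e-10)

    def test_only_target_step_changes(self):
        p = generate_bdna("A" * 25)
        q = bend_roll(p, 10, 5.0)
        roll = q.step_roll()
        assert roll[9] == pytest.approx(5.0, abs=1e-8)
        mask = np.ones(24, bool)
        mask[9] = False
        assert np.allclose(roll[mask], 0.0, atol=1e-8)
        assert np.allclose(q.step_twist(), IDEAL_TWIST_DEG, atol=1e-8)
        assert np.allclose(q.step_rise(), IDEAL_RISE, atol=1e-8)

    def test_zero_twist_rolls_trace_planar_arc(self):
        n_steps, theta = 9, 12.0
        p = generate_bdna("A" * (n_steps + 1), twist_deg=0.0)
        for i in range(1, n_steps + 1):
            p = bend_roll(p, i, theta)
        t0, t1 = p.triads[0][:, 2], p.triads[-1][:, 2]
        total = np.rad2deg(np.arccos(np.clip(np.dot(t0, t1), -1, 1)))
        assert total == pytest.approx(n_steps * theta, abs=1e-8)
        # planarity: all origins in the bend plane
        normal = np.array([0.0, 1.0, 0.0])
        assert np.abs(p.origins @ normal).max() < 1e-8

    def test_opposite_rolls_cancel(self):
        p = generate_bdna("A" * 20)
        q = bend_roll(bend_roll(p, 8, 1.0), 8, -1.0)
        assert np.allclose(q.origins, p.origins, atol=1e-8)
        assert np.allclose(q.triads, p.triads, atol=1e-8)

    @pytest.mark.parametrize("idx", [0, 20, -1])
    def test_out_of_range_step_rejected(self, idx):
        with pytest.raises(IndexError):
            bend_roll(generate_bdna("A" * 20), idx, 1.0)


# ---------------------------------------------------------------- kink_rotate

@pytest.fixture()
def doubly_kinked():
    # 40 deg/step twist puts the two kinks (9 bp apart) exactly in helical
    # phase, so their bend axes are parallel and the total bend is 80 deg.
    p = generate_bdna("A" * 30, twist_deg=40.0)
    return bend_roll(bend_roll(p, 8, 40.0), 17, 40.0)


class TestKinkRotate:
    def test_zero_angle_is_identity(self, doubly_kinked):
        q = kink_rotate(doubly_kinked, 8, 17, "in_plane", 0.0)
        assert np.allclose(q.origins, doubly_kinked.origins, atol=1e-10)

    def test_in_plane_keeps_both_kink_origins(self, doubly_kinked):
        q = kink_rotate(doubly_kinked, 8, 17, "in_plane", 5.0)
        for k in (8, 17):
            assert np.linalg.norm(q.origins[k] - doubly_kinked.origins[k]) < 1e-10
        assert np.abs(q.origins[18:] - doubly_kinked.origins[18:]).max() > 0.1

    def test_in_plane_changes_total_bend(self, doubly_kinked):
        def total_bend(path):
            t0, t1 = path.triads[0][:, 2], path.triads[-1][:, 2]
            return np.rad2deg(np.arccos(np.clip(np.dot(t0, t1), -1, 1)))

        deeper = kink_rotate(doubly_kinked, 8, 17, "in_plane", 5.0)
        assert total_bend(deeper) == pytest.approx(total_bend(doubly_kinked) + 5.0, abs=0.3)

    def test_torsion_preserves_radii_about_kink_axis(self, doubly_kinked):
        q = kink_rotate(doubly_kinked, 8, 17, "torsion", 8.0)
        axis = doubly_kinked.origins[17] - doubly_kinked.origins[8]
        axis /= np.linalg.norm(axis)

        def radii(path):
            d = path.origins - doubly_kinked.origins[8]
            return np.linalg.norm(d - np.outer(d @ axis, axis), axis=1)

        assert np.allclose(radii(q), radii(doubly_kinked), atol=1e-8)

    def test_large_angle_warns(self, doubly_kinked):
        with pytest.warns(UserWarning, match="deg"):
            kink_rotate(doubly_kinked, 8, 17, "torsion", 12.0)

    def test_coincident_or_bad_indices_rejected(self, doubly_kinked):
        with pytest.raises((IndexError, ValueError)):
            kink_rotate(doubly_kinked, 17, 17, "in_plane", 2.0)
        with pytest.raises(IndexError):
            kink_rotate(doubly_kinked, 5, 40, "torsion", 2.0)


# ---------------------------------------------------------------- properties

@settings(deadline=None, max_examples=30)
@given(
    roll=st.floats(-45, 45),
    step=st.integers(1, 18),
    twist=st.floats(20, 45),
)
def test_operations_preserve_frame_orthonormality(roll, step, twist):
    """Every geometry op yields proper orthonormal triads."""
    p = generate_bdna("A" * 20, twist_deg=twist)
    q = bend_roll(p, step, roll)
    _assert_orthonormal(q)
    if step < 18:
        r = kink_rotate(q, step - 1, step + 1, "torsion", 5.0)
        _assert_orthonormal(r)


@settings(deadline=None, max_examples=20)
@given(n1=st.integers(5, 25), n2=st.integers(5, 25))
def test_splice_length_additivity(n1, n2):
    s = splice(generate_bdna("A" * n1), generate_bdna("C" * n2), splint_len=4)
    assert len(s) == n1 + n2
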