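import numpy as np
import pytest

from footgrf import estimator as est
from footgrf.estimator import (
    DOUBLE,
    FLIGHT,
    SINGLE,
    ExternalForceSeries,
    SinkageField,
    VppState,
    cop,
    detect_phase,
    distribute_vertical,
    estimate,
    external_forces,
    horizontal_double,
    horizontal_single,
    sinkage,
    transverse_grm,
    vpp_position,
)
from footgrf.exceptions import DimensionError, GeometryError, PhaseError
from footgrf.kinio import ContactState, SegmentKinematics
from footgrf.model import GRAVITY, SEGMENTS


def make_kin(com_acc, com_pos=None, rate=100.0, trunk_R=None):
    """Minimal 12-segment kinematics with prescribed COM channels."""
    com_acc = np.asarray(com_acc, float)
    F = com_acc.shape[0]
    if com_pos is None:
        com_pos = np.zeros_like(com_acc)
    R = np.broadcast_to(np.eye(3), (F, 12, 3, 3)).copy()
    if trunk_R is not None:
        R[:, SEGMENTS.index("torso")] = trunk_R
    return SegmentKinematics(
        rate=rate, com_positions=np.asarray(com_pos, float),
        com_accelerations=com_acc,
        orientations=R, origins=np.zeros((F, 12, 3)),
        joint_angles=np.zeros((F, 23)), ankle_origins=np.zeros((F, 2, 3)),
    )


def make_contacts(p_y, v_y=None, p_x=None, p_z=None, rate=100.0):
    """20-point contact state; first 10 points left, last 10 right."""
    p_y = np.asarray(p_y, float)
    F = p_y.shape[0]
    pos = np.zeros((F, 20, 3))
    pos[..., 1] = p_y
    if p_x is not None:
        pos[..., 0] = p_x
    if p_z is not None:
        pos[..., 2] = p_z
    v = np.zeros_like(p_y) if v_y is None else np.asarray(v_y, float)
    return ContactState(
        rate=rate, positions=pos, vertical_velocities=v,
        foot_of_point=np.repeat([0, 1], 10), ankle_origin=np.zeros((F, 2, 3)),
    )


class TestExternalForces:
    def test_static_body_carries_its_weight(self, subject, static_trial):
        f = external_forces(static_trial.kin, subject)
        i = static_trial.kin.n_frames // 2
        assert f.F_ext[i, 1] == pytest.approx(55.2 * GRAVITY, rel=1e-9)
        assert abs(f.F_ext[i, 0]) < 1e-6
        assert abs(f.F_ext[i, 2]) < 1e-6

    def test_free_fall_zero_vertical(self, subject):
        acc = np.zeros((5, 12, 3))
        acc[..., 1] = -GRAVITY
        f = external_forces(make_kin(acc), subject)
        assert np.allclose(f.F_ext, 0.0, atol=1e-9)

    def test_single_oscillating_segment_matches_one_body_oracle(self, subject):
        """One segment accelerating while the rest hang still: F_ext is that
        segment's m*a plus the whole-body weight."""
        rng = np.random.default_rng(3)
        a = rng.normal(size=(7, 3))
        acc = np.zeros((7, 12, 3))
        s = SEGMENTS.index("tibia_l")
        acc[:, s] = a
        f = external_forces(make_kin(acc), subject)
        m_s = subject.segment_masses[s]
        expect = m_s * a
        expect[:, 1] += subject.body_mass * GRAVITY
        assert np.allclose(f.F_ext, expect, atol=1e-9)

    def test_dimension_mismatch_rejected(self, subject):
        kin = make_kin(np.zeros((4, 12, 3)))
        kin.com_accelerations = np.zeros((4, 11, 3))
        with pytest.raises(DimensionError):
            external_forces(kin, subject)


class TestSinkage:
    @pytest.mark.parametrize("p_y, v_y, expect", [
        (-0.005, 0.0, 0.005),    # sunk and quiet -> depth
        (-0.005, 0.10, 0.0),     # lifting faster than v_crit -> gated
        (0.002, -0.1, 0.0),      # above ground -> no contact
    ])
    def test_gating_law(self, p_y, v_y, expect):
        c = make_contacts(np.full((2, 20), p_y), np.full((2, 20), v_y))
        h = sinkage(c, p_crit=0.0, v_crit=0.05)
        assert np.allclose(h.h, expect)
        assert np.all(h.h >= 0)


class TestDistribution:
    def test_single_sunk_foot_takes_everything(self):
        p_y = np.zeros((3, 20))
        p_y[:, :10] = -0.01   # left sunk
        p_y[:, 10:] = 0.05
        c = make_contacts(p_y)
        f = ExternalForceSeries(np.tile([0.0, 600.0, 0.0], (3, 1)))
        fy, _, _ = distribute_vertical(sinkage(c), f, c)
        assert np.allclose(fy[:, 0], 600.0)
        assert np.allclose(fy[:, 1], 0.0)

    def test_two_to_one_sinkage_splits_two_to_one(self):
        p_y = np.full((2, 20), 0.05)
        p_y[:, 0] = -0.002
        p_y[:, 10] = -0.001
        c = make_contacts(p_y)
        f = ExternalForceSeries(np.tile([0.0, 600.0, 0.0], (2, 1)))
        fy, _, _ = distribute_vertical(sinkage(c), f, c)
        assert np.allclose(fy[:, 0], 400.0)
        assert np.allclose(fy[:, 1], 200.0)

    def test_moments_equal_pointwise_wrench_sum(self):
        """The closed-form foot moments equal brute-force summation of the
        per-point load moments about the ankle origin."""
        rng = np.random.default_rng(11)
        F = 40
        p_y = rng.uniform(-0.03, 0.02, (F, 20))
        p_x = rng.uniform(-0.1, 0.2, (F, 20))
        p_z = rng.uniform(-0.06, 0.06, (F, 20))
        c = make_contacts(p_y, p_x=p_x, p_z=p_z)
        f = ExternalForceSeries(
            np.column_stack([rng.normal(size=F), rng.uniform(300, 800, F),
                             rng.normal(size=F)])
        )
        h = sinkage(c)
        fy, mx, mz = distribute_vertical(h, f, c)
        w = h.h / np.where(h.h.sum(1) > 0, h.h.sum(1), 1)[:, None]
        for k in (0, 1):
            cols = slice(0, 10) if k == 0 else slice(10, 20)
            load = w[:, cols] * f.F_ext[:, 1:2]
            assert np.allclose(fy[:, k], load.sum(1), atol=1e-10)
            assert np.allclose(mx[:, k], -(load * p_z[:, cols]).sum(1), atol=1e-10)
            assert np.allclose(mz[:, k], (load * p_x[:, cols]).sum(1), atol=1e-10)

    def test_no_sinkage_means_flight_and_zero_output(self):
        c = make_contacts(np.full((3, 20), 0.04))
        f = ExternalForceSeries(np.tile([0.0, 500.0, 0.0], (3, 1)))
        h = sinkage(c)
        fy, mx, mz = distribute_vertical(h, f, c)
        assert np.all(fy == 0) and np.all(mx == 0) and np.all(mz == 0)
        assert np.all(detect_phase(h, c.foot_of_point) == FLIGHT)


class TestPhase:
    def test_phase_labels(self):
        p_y = np.full((3, 20), 0.05)
        p_y[0, :] = -0.01            # both feet
        p_y[1, 3] = -0.01            # left only
        c = make_contacts(p_y)
        phase = detect_phase(sinkage(c), c.foot_of_point)
        assert list(phase) == [DOUBLE, SINGLE, FLIGHT]

    def test_walk_phase_sequence_matches_truth(self, walk_trial):
        w = estimate(walk_trial.kin, walk_trial.contacts, walk_trial.model)
        assert np.array_equal(w.phase, walk_trial.truth_phase)
        # alternating single -> double -> single structure
        runs = [p for p, _ in __import__("itertools").groupby(w.phase)]
        assert set(runs) == {SINGLE, DOUBLE}
        assert all(a != b for a, b in zip(runs, runs[1:]))


class TestHorizontalSingle:
    def test_identity_assignment_and_conservation(self):
        f = ExternalForceSeries(np.array([[12.0, 540.0, -3.0]]))
        out = horizontal_single(f, np.array([1]))
        assert np.allclose(out[0, 1], [12.0, -3.0])   # stance foot
        assert np.allclose(out[0, 0], 0.0)            # swing foot
        assert np.allclose(out.sum(axis=1), [[12.0, -3.0]])

    def test_rejects_non_single_phase(self):
        f = ExternalForceSeries(np.zeros((2, 3)))
        with pytest.raises(PhaseError):
            horizontal_single(f, np.zeros(2, int), phase=np.array([SINGLE, DOUBLE]))


class TestCop:
    def test_direct_division(self):
        out = cop(np.array([700.0]), np.array([0.0]), np.array([70.0]))
        assert np.allclose(out[0], [0.1, 0.0, 0.0])

    def test_below_floor_is_undefined(self):
        out = cop(np.array([1.0]), np.array([0.0]), np.array([0.5]),
                  force_floor=5.0)
        assert np.all(np.isnan(out[0]))

    def test_single_active_point_puts_cop_on_it(self):
        p_y = np.full((2, 20), 0.05)
        p_y[:, 14] = -0.02
        p_x = np.full((2, 20), 0.0)
        p_z = np.full((2, 20), 0.0)
        p_x[:, 14], p_z[:, 14] = 0.13, -0.02
        c = make_contacts(p_y, p_x=p_x, p_z=p_z)
        f = ExternalForceSeries(np.tile([0.0, 500.0, 0.0], (2, 1)))
        fy, mx, mz = distribute_vertical(sinkage(c), f, c)
        out = cop(fy[:, 1], mx[:, 1], mz[:, 1])
        assert np.allclose(out[:, 0], 0.13, atol=1e-12)
        assert np.allclose(out[:, 2], -0.02, atol=1e-12)

    def test_cop_is_sinkage_weighted_centroid_inside_hull(self):
        """Random sinkage: the COP equals the per-foot weighted centroid of
        the active points, hence lies in their convex hull."""
        rng = np.random.default_rng(5)
        F = 30
        p_y = rng.uniform(-0.03, 0.01, (F, 20))
        p_x = rng.uniform(-0.1, 0.2, (F, 20))
        p_z = rng.uniform(-0.06, 0.06, (F, 20))
        c = make_contacts(p_y, p_x=p_x, p_z=p_z)
        f = ExternalForceSeries(np.tile([0.0, 600.0, 0.0], (F, 1)))
        h = sinkage(c)
        fy, mx, mz = distribute_vertical(h, f, c)
        for k, cols in ((0, slice(0, 10)), (1, slice(10, 20))):
            out = cop(fy[:, k], mx[:, k], mz[:, k])
            hw = h.h[:, cols]
            active = hw.sum(1) > 0
            cen_x = (hw * p_x[:, cols]).sum(1)[active] / hw.sum(1)[active]
            cen_z = (hw * p_z[:, cols]).sum(1)[active] / hw.sum(1)[active]
            assert np.allclose(out[active, 0], cen_x, atol=1e-10)
            assert np.allclose(out[active, 2], cen_z, atol=1e-10)
            # convex combination: inside the active points' bounding hull
            wgt = hw[active] / hw[active].sum(1, keepdims=True)
            assert np.all(wgt >= 0)
            assert np.allclose(wgt.sum(1), 1.0)


class TestVpp:
    def test_upright_trunk_offsets_straight_up(self, subject):
        kin = make_kin(np.zeros((3, 12, 3)),
                       com_pos=np.zeros((3, 12, 3)))
        v = vpp_position(kin, subject)
        assert np.allclose(v.r_vpp - v.whole_body_com, [0.0, 0.0375, 0.0])

    def test_pitched_trunk_rotates_the_offset(self, subject):
        from footgrf.kinio import euler_zxy_to_matrix

        R = euler_zxy_to_matrix(-np.pi / 2, 0.0, 0.0)  # pitch 90 deg forward
        kin = make_kin(np.zeros((2, 12, 3)), trunk_R=R)
        v = vpp_position(kin, subject)
        assert np.allclose(v.r_vpp - v.whole_body_com, [0.0375, 0.0, 0.0],
                           atol=1e-12)

    def test_com_is_mass_weighted_mean(self, subject):
        pos = np.zeros((2, 12, 3))
        pos[:, 0, 1] = 1.0  # pelvis COM raised
        kin = make_kin(np.zeros((2, 12, 3)), com_pos=pos)
        v = vpp_position(kin, subject)
        frac = subject.segment_masses[0] / subject.body_mass
        assert np.allclose(v.whole_body_com[:, 1], frac)


class TestHorizontalDouble:
    def test_cop_under_vpp_gives_zero_shear(self):
        vpp = VppState(np.array([[0.2, 1.0, 0.0]]), np.zeros((1, 3)))
        cop_lab = np.array([[[0.2, 0.0, 0.0], [0.2, 0.0, 0.0]]])
        out, _ = horizontal_double(np.array([[300.0, 300.0]]), cop_lab, vpp)
        assert np.allclose(out, 0.0)

    def test_direct_substitution(self):
        vpp = VppState(np.array([[0.1, 1.0, 0.0]]), np.zeros((1, 3)))
        cop_lab = np.array([[[0.0, 0.0, 0.0], [np.nan, np.nan, np.nan]]])
        out, alpha = horizontal_double(np.array([[700.0, 0.0]]), cop_lab, vpp)
        assert alpha[0, 0] == pytest.approx(700.0)
        assert np.allclose(out[0, 0], [70.0, 0.0])

    def test_force_parallel_to_cop_vpp_lever(self, walk_trial):
        w = estimate(walk_trial.kin, walk_trial.contacts, walk_trial.model)
        from footgrf.estimator import vpp_position as vp

        vpp = vp(walk_trial.kin, walk_trial.model)
        dbl = w.phase == DOUBLE
        for k in (0, 1):
            lever = vpp.r_vpp[dbl] - w.cop[dbl, k]
            force = w.force[dbl, k]
            cr = np.cross(lever, force)
            assert np.all(np.linalg.norm(cr, axis=1)
                          <= 1e-9 * np.linalg.norm(force, axis=1)
                          * np.linalg.norm(lever, axis=1) + 1e-12)

    def test_vpp_below_cop_rejected(self):
        vpp = VppState(np.array([[0.0, -0.1, 0.0]]), np.zeros((1, 3)))
        cop_lab = np.zeros((1, 2, 3))
        with pytest.raises(GeometryError):
            horizontal_double(np.array([[100.0, 100.0]]), cop_lab, vpp)


class TestTransverseGrm:
    def test_direct_cases(self):
        assert transverse_grm(np.array(0.0), np.array(10.0),
                              np.array([0.1, 0.0, 0.0])) == pytest.approx(-1.0)
        assert transverse_grm(np.array(5.0), np.array(10.0),
                              np.array([0.0, 0.0, 0.0])) == pytest.approx(0.0)

    def test_matches_vector_cross_oracle(self):
        rng = np.random.default_rng(9)
        fx, fz = rng.normal(size=(2, 50))
        pts = rng.normal(size=(50, 3))
        pts[:, 1] = 0.0
        got = transverse_grm(fx, fz, pts)
        forces = np.column_stack([fx, np.zeros(50), fz])
        oracle = np.cross(pts, forces)[:, 1]
        assert np.allclose(got, oracle, atol=1e-12)


class TestEstimateComposition:
    def test_vertical_conservation_machine_precision(self, walk_trial):
        w = estimate(walk_trial.kin, walk_trial.contacts, walk_trial.model)
        contact = w.phase != FLIGHT
        total = w.force[contact, :, 1].sum(axis=1)
        assert np.allclose(total, w.f_ext[contact, 1], rtol=1e-12, atol=1e-9)

    def test_single_support_horizontal_conservation(self, walk_trial):
        w = estimate(walk_trial.kin, walk_trial.contacts, walk_trial.model)
        sgl = w.phase == SINGLE
        assert np.allclose(w.force[sgl, :, 0].sum(axis=1), w.f_ext[sgl, 0],
                           atol=1e-9)
        assert np.allclose(w.force[sgl, :, 2].sum(axis=1), w.f_ext[sgl, 2],
                           atol=1e-9)

    def test_vertical_force_nonnegative(self, walk_trial):
        w = estimate(walk_trial.kin, walk_trial.contacts, walk_trial.model)
        assert np.all(w.force[..., 1] >= -1e-12)

    def test_flight_frames_zero_everything(self, subject):
        kin = make_kin(np.zeros((5, 12, 3)))
        c = make_contacts(np.full((5, 20), 0.05))
        w = estimate(kin, c, subject)
        assert np.all(w.phase == FLIGHT)
        assert np.all(w.force == 0.0)
        assert np.all(w.moment == 0.0)

    def test_scale_equivariance_in_mass(self, static_trial):
        """Doubling every mass doubles every force and moment."""
        from footgrf.model import build_subject_model

        m1 = build_subject_model(55.2, static_trial.markers)
        m2 = build_subject_model(110.4, static_trial.markers)
        kin = static_trial.kin
        contacts = static_trial.contacts
        w1 = estimate(kin, contacts, m1)
        w2 = estimate(kin, contacts, m2)
        assert np.allclose(w2.force, 2 * w1.force, atol=1e-8)
        assert np.allclose(w2.moment, 2 * w1.moment, atol=1e-8)

    def test_lab_moment_origin_consistent_with_cop_cross_force(self, walk_trial):
        w = estimate(walk_trial.kin, walk_trial.contacts, walk_trial.model,
                     moment_origin="lab")
        loaded = np.isfinite(w.cop[..., 0])
        oracle = np.cross(np.nan_to_num(w.cop), w.force)
        assert np.allclose(w.moment[loaded], oracle[loaded], atol=1e-9)

    def test_frame_mismatch_rejected(self, subject):
        kin = make_kin(np.zeros((5, 12, 3)))
        c = make_contacts(np.full((4, 20), 0.05))
        with pytest.raises(DimensionError):
            estimate(kin, c, subject)
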