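"""Synthetic standing and walking trials with exact ground-truth wrenches.

The generator stands in for laboratory motion-capture + force-plate data.
It authors, on a common clock:

* whole-body COM trajectories in closed form (forward progression with
  vertical and lateral oscillation), realized exactly by the 12 segment
  COMs — eleven segments follow plausible rigid motions (two-link leg
  inverse kinematics, feet tracing stance/swing paths) and the torso
  absorbs the residual so the mass-weighted COM matches the prescription
  to machine precision;
* 49-marker trajectories emitted rigidly from those segment poses, so the
  Procrustes pipeline recovers the poses exactly on noise-free data;
* 20 contact-point trajectories whose vertical courses emulate sole
  compression: each point descends, dwells ~8-30 mm below the ground plane
  while loaded, and lifts off heel-to-toe.  Contact trajectories are
  authored directly rather than rigidly attached to the foot segments —
  real soles deform, rigid segments cannot;
* ground-truth per-foot wrenches defined by applying the sinkage
  distribution law to those authored contacts with the *analytic* external
  force, and — during double support — the VPP construction itself, which
  is the only available definition of horizontal double-support truth.

Truth and estimate therefore differ only through what the estimator must
measure (finite-difference COM accelerations instead of the closed form),
which is exactly the error the round-trip tests quantify.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .estimator import (
    ExternalForceSeries,
    FootWrenchSeries,
    VppState,
    estimate_core,
)
from .exceptions import ParameterError
from .kinio import (
    ContactState,
    MarkerTrajectories,
    SegmentKinematics,
    differentiate,
    fit_segment_poses,
)
from .model import (
    GRAVITY,
    SEGMENTS,
    SubjectModel,
    _CONTACT_TEMPLATE,
    _scaled_anthropometry,
    build_subject_model,
    default_marker_map,
)

__all__ = ["SyntheticTrial", "default_subject", "generate_static",
           "generate_walk", "add_noise"]

# standing geometry, m
PELVIS_HEIGHT = 0.86
ANKLE_HEIGHT = 0.09
STEP_WIDTH = 0.09          # lateral ankle offset from the midline
FEMUR_LEN = 0.3962
TIBIA_LEN = 0.43
SWING_CLEARANCE = 0.04     # contact-point height during swing
VERTICAL_OFFSET = 0.030

# walking-cycle timing, fractions of one stride (heel strike of the foot at 0)
STANCE_END = 0.71          # ankle stationary until here
POINT_ON = 0.05            # first point fully planted
POINT_ON_SPREAD = 0.06     # heel-to-toe stagger of planting
POINT_OFF = 0.45           # heel lift begins
POINT_OFF_SPREAD = 0.20    # heel-to-toe stagger of lift-off
DESCENT = 0.05             # duration of the planting ramp
RISE = 0.06                # duration of the lift-off ramp

# COM oscillation amplitudes, m
COM_OSC_X = 0.010
COM_OSC_Y = 0.015
COM_OSC_Z = 0.020


@dataclass
class SyntheticTrial:
    """A generated trial: inputs for the estimator plus its ground truth."""

    markers: MarkerTrajectories
    kin: SegmentKinematics
    contacts: ContactState
    truth_wrenches: FootWrenchSeries
    seed: int
    model: SubjectModel

    @property
    def truth_phase(self) -> np.ndarray:
        return self.truth_wrenches.phase

    @property
    def rate(self) -> float:
        return self.markers.rate


def _smoothstep(u):
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _frame_from_y(ydir: np.ndarray) -> np.ndarray:
    """Right-handed frames (F x 3 x 3) with +y along ``ydir`` and +x forward."""
    y = ydir / np.linalg.norm(ydir, axis=-1, keepdims=True)
    xhint = np.zeros_like(y)
    xhint[..., 0] = 1.0
    z = np.cross(xhint, y)
    z /= np.linalg.norm(z, axis=-1, keepdims=True)
    x = np.cross(y, z)
    return np.stack([x, y, z], axis=-1)


def _leg_poses(hip: np.ndarray, ankle: np.ndarray):
    """Two-link knee IK: femur/tibia poses from hip and ankle paths."""
    d = ankle - hip
    dist = np.linalg.norm(d, axis=-1)
    reach = 0.995 * (FEMUR_LEN + TIBIA_LEN)
    scale = np.minimum(1.0, reach / dist)
    ankle_eff = hip + d * scale[:, None]
    d = ankle_eff - hip
    dist = np.linalg.norm(d, axis=-1)
    u = d / dist[:, None]
    cos_t = np.clip(
        (dist ** 2 + FEMUR_LEN ** 2 - TIBIA_LEN ** 2) / (2 * dist * FEMUR_LEN),
        -1.0, 1.0,
    )
    sin_t = np.sqrt(1.0 - cos_t ** 2)
    xhint = np.zeros_like(u)
    xhint[:, 0] = 1.0
    w = xhint - (np.sum(xhint * u, axis=-1, keepdims=True)) * u
    w /= np.linalg.norm(w, axis=-1, keepdims=True)
    knee = hip + FEMUR_LEN * (cos_t[:, None] * u + sin_t[:, None] * w)
    R_femur = _frame_from_y(hip - knee)
    R_tibia = _frame_from_y(knee - ankle_eff)
    return R_femur, hip, R_tibia, knee, ankle_eff


_FOOT_OFFSETS = {  # child origin offsets below the ankle, right side
    "calcn": np.array([-0.04877, -0.04195, 0.00792]),
    "toes": np.array([-0.04877 + 0.1788, -0.04195 - 0.002, 0.00792 + 0.00108]),
}


def _foot_poses(ankle_eff: np.ndarray, side: str):
    """Talus/calcaneus/toes poses: unrotated, translating with the ankle."""
    F = ankle_eff.shape[0]
    eye = np.broadcast_to(np.eye(3), (F, 3, 3))
    sgn = -1.0 if side == "l" else 1.0
    out = {f"talus_{side}": (eye, ankle_eff)}
    for base, off in _FOOT_OFFSETS.items():
        o = off * np.array([1.0, 1.0, sgn])
        out[f"{base}_{side}"] = (eye, ankle_eff + o)
    return out


def _body_poses(body_mass: float, com_target: np.ndarray,
                ankle_l: np.ndarray, ankle_r: np.ndarray):
    """All 12 segment poses; the torso absorbs the COM residual."""
    F = com_target.shape[0]
    eye = np.broadcast_to(np.eye(3), (F, 3, 3))
    masses, _, com_off = _scaled_anthropometry(body_mass)
    seg_i = {s: i for i, s in enumerate(SEGMENTS)}

    pelvis_o = np.column_stack([
        com_target[:, 0] + 0.05,
        np.full(F, PELVIS_HEIGHT),
        0.5 * com_target[:, 2],
    ])
    poses = {"pelvis": (eye, pelvis_o)}
    for side, ankle in (("l", ankle_l), ("r", ankle_r)):
        sgn = -1.0 if side == "l" else 1.0
        hip = pelvis_o + np.array([-0.0707, -0.0661, sgn * 0.0835])
        R_f, o_f, R_t, o_t, ankle_eff = _leg_poses(hip, ankle)
        poses[f"femur_{side}"] = (R_f, o_f)
        poses[f"tibia_{side}"] = (R_t, o_t)
        poses.update(_foot_poses(ankle_eff, side))

    # torso COM makes the mass-weighted segment COMs hit com_target exactly
    total = np.zeros((F, 3))
    for seg, (R, o) in poses.items():
        i = seg_i[seg]
        total += masses[i] * (o + np.einsum("fij,j->fi", R, com_off[i]))
    m_torso = masses[seg_i["torso"]]
    torso_com = (masses.sum() * com_target - total) / m_torso
    torso_o = torso_com - com_off[seg_i["torso"]]
    poses["torso"] = (eye, torso_o)
    return poses


def _markers_from_poses(poses: dict, rate: float) -> MarkerTrajectories:
    marker_map = default_marker_map()
    names = list(marker_map)
    F = next(iter(poses.values()))[1].shape[0]
    pos = np.zeros((F, len(names), 3))
    for j, name in enumerate(names):
        seg, local = marker_map[name]
        R, o = poses[seg]
        pos[:, j] = o + np.einsum("fij,j->fi", R, local)
    return MarkerTrajectories(names, pos, rate)


def _template_centroid():
    """Horizontal sinkage-weighted centroid of the standing contact layout
    (ankle-relative, right-foot z sign)."""
    h = np.array([VERTICAL_OFFSET - row[4] for row in _CONTACT_TEMPLATE])
    x = np.array([row[2] for row in _CONTACT_TEMPLATE])
    z = np.array([row[3] for row in _CONTACT_TEMPLATE])
    return float((h * x).sum() / h.sum()), float((h * z).sum() / h.sum())


COM_HEIGHT = PELVIS_HEIGHT + 0.12  # standing whole-body COM height, m


def _standing_geometry(F: int):
    """Quiet-standing COM target and ankle paths.

    The whole-body COM is placed directly above the standing sinkage-
    weighted contact centroid, so the posture is in exact equilibrium.
    """
    cx, _ = _template_centroid()
    com = np.tile([cx, COM_HEIGHT, 0.0], (F, 1))
    a_l = np.tile([0.0, ANKLE_HEIGHT, -STEP_WIDTH], (F, 1))
    a_r = np.tile([0.0, ANKLE_HEIGHT, STEP_WIDTH], (F, 1))
    return com, a_l, a_r


def _standing_markers(body_mass: float, F: int, rate: float):
    """Static markers plus the malleolus-midpoint ankle origins.

    Two passes: the second re-centres the COM target over the marker-derived
    ankle origins (only the torso moves, so the origins are unchanged and
    the equilibrium alignment is exact).
    """
    com, a_l, a_r = _standing_geometry(F)
    cx, _ = _template_centroid()
    markers = None
    mid = None
    for _ in range(2):
        poses = _body_poses(body_mass, com, a_l, a_r)
        markers = _markers_from_poses(poses, rate)
        mid = np.zeros((F, 2, 3))
        for k, side in enumerate(("L", "R")):
            mid[:, k] = 0.5 * (markers.get(f"{side}ANK") + markers.get(f"{side}ANKM"))
        com = np.column_stack([
            mid[:, :, 0].mean(axis=1) + cx,
            np.full(F, COM_HEIGHT),
            mid[:, :, 2].mean(axis=1),
        ])
    return markers, mid


def default_subject(body_mass: float = 55.2, rate: float = 100.0) -> SubjectModel:
    """A calibrated subject built from a generated static standing trial."""
    F = int(round(0.6 * rate))
    markers, _ = _standing_markers(body_mass, F, rate)
    return build_subject_model(body_mass, markers)


def generate_static(model: SubjectModel, duration: float = 1.0,
                    rate: float = 100.0) -> SyntheticTrial:
    """Motionless heel-biased standing with exact ground truth.

    Truth: each foot carries half the body weight at the standing
    sinkage-weighted centroid COP with zero horizontal force.
    """
    if duration < 0.5:
        raise ParameterError("static trials must last at least 0.5 s")
    from .estimator import DOUBLE
    from .kinio import compute_contact_points

    F = int(round(duration * rate))
    markers, mid = _standing_markers(model.body_mass, F, rate)
    kin = fit_segment_poses(markers, model)
    contacts = compute_contact_points(kin, model)

    weight = model.body_mass * GRAVITY
    cx, cz = _template_centroid()
    force = np.zeros((F, 2, 3))
    force[:, :, 1] = weight / 2.0
    cop = np.zeros((F, 2, 3))
    cop_rel = np.zeros((F, 2, 3))
    for k, zsgn in enumerate((-1.0, 1.0)):
        cop_rel[:, k, 0] = cx
        cop_rel[:, k, 2] = zsgn * cz
        cop[:, k, 0] = mid[:, k, 0] + cx
        cop[:, k, 2] = mid[:, k, 2] + zsgn * cz
    moment = np.zeros((F, 2, 3))
    moment[..., 0] = -cop_rel[..., 2] * force[..., 1]
    moment[..., 2] = cop_rel[..., 0] * force[..., 1]
    truth = FootWrenchSeries(
        rate=rate, force=force, moment=moment, cop=cop,
        phase=np.full(F, DOUBLE), moment_origin="ankle",
        f_ext=np.column_stack([np.zeros(F), np.full(F, weight), np.zeros(F)]),
    )
    return SyntheticTrial(markers=markers, kin=kin, contacts=contacts,
                          truth_wrenches=truth, seed=0, model=model)


def _point_height_profile(phase: np.ndarray, depth: float, u: float) -> np.ndarray:
    """Vertical course of one contact point over cycle phase in [0, 1).

    Swing clearance -> planting ramp -> loaded dwell at ``-depth`` ->
    lift-off ramp -> swing clearance, staggered heel-to-toe by ``u``.
    """
    a = POINT_ON + POINT_ON_SPREAD * u
    b = POINT_OFF + POINT_OFF_SPREAD * u
    C = SWING_CLEARANCE
    y = np.full_like(phase, C)
    down = (phase >= a - DESCENT) & (phase < a)
    y[down] = C - (C + depth) * _smoothstep((phase[down] - (a - DESCENT)) / DESCENT)
    dwell = (phase >= a) & (phase < b)
    y[dwell] = -depth
    up = (phase >= b) & (phase < b + RISE)
    y[up] = -depth + (C + depth) * _smoothstep((phase[up] - b) / RISE)
    return y


def _ankle_path(cycles: np.ndarray, stride: float, side: str) -> np.ndarray:
    """Ankle trajectory: stationary through stance, swinging forward after."""
    k = np.floor(cycles)
    phase = cycles - k
    adv = _smoothstep((phase - STANCE_END) / (1.0 - STANCE_END))
    x = stride * (k + adv)
    lift = 0.04 * np.sin(np.pi * np.clip(
        (phase - STANCE_END) / (1.0 - STANCE_END), 0.0, 1.0))
    z = -STEP_WIDTH if side == "l" else STEP_WIDTH
    return np.column_stack([x, ANKLE_HEIGHT + lift, np.full_like(x, z)])


def generate_walk(model: SubjectModel, n_strides: int = 4, speed: float = 1.25,
                  rate: float = 100.0, seed: int = 0,
                  stride_length: float = 1.1) -> SyntheticTrial:
    """A level-walking trial with exact ground truth.

    The left/right vertical load split is encoded in the contact-point
    sinkage: points plant and lift heel-to-toe, so during the ~10% double-
    support windows load transfers progressively from the trailing to the
    leading foot.  Truth wrenches apply the sinkage distribution law to the
    authored contacts with the closed-form external force; horizontal
    double-support truth is defined by the VPP construction.  Deterministic
    for a given seed.
    """
    if n_strides < 1:
        raise ParameterError("need at least one stride")
    if speed <= 0:
        raise ParameterError("walking speed must be positive")
    rng = np.random.default_rng(seed)
    ph = rng.uniform(-0.3, 0.3, size=3)  # oscillation phase jitter

    T = stride_length / speed
    F = int(round(n_strides * T * rate)) + 1
    t = np.arange(F) / rate

    # analytic whole-body COM and external force
    w2, w1 = 4 * np.pi / T, 2 * np.pi / T
    com = np.column_stack([
        speed * t + COM_OSC_X * np.sin(w2 * t + ph[0]),
        COM_HEIGHT + COM_OSC_Y * np.sin(w2 * t + ph[1]),
        COM_OSC_Z * np.sin(w1 * t + ph[2]),
    ])
    com_acc = np.column_stack([
        -COM_OSC_X * w2 ** 2 * np.sin(w2 * t + ph[0]),
        -COM_OSC_Y * w2 ** 2 * np.sin(w2 * t + ph[1]),
        -COM_OSC_Z * w1 ** 2 * np.sin(w1 * t + ph[2]),
    ])
    M = model.body_mass
    f_ext = np.column_stack([
        M * com_acc[:, 0],
        M * (com_acc[:, 1] + GRAVITY),
        M * com_acc[:, 2],
    ])

    c_r = t / T + 0.30   # start mid right stance
    c_l = t / T + 0.80
    ankle_r = _ankle_path(c_r, stride_length, "r")
    ankle_l = _ankle_path(c_l, stride_length, "l")
    # keep the feet under the advancing COM
    x_shift = float(np.mean(com[:, 0]) - 0.5 * (ankle_r[:, 0] + ankle_l[:, 0]).mean())
    ankle_r[:, 0] += x_shift
    ankle_l[:, 0] += x_shift

    poses = _body_poses(M, com, ankle_l, ankle_r)
    markers = _markers_from_poses(poses, rate)
    kin = fit_segment_poses(markers, model)

    # authored contact-point trajectories (ankle-relative horizontals)
    layout = model.contact_layout
    xs = np.array([p.ankle_offset[0] for p in layout.points])
    u_all = (xs - xs.min()) / (xs.max() - xs.min())
    pos = np.zeros((F, 20, 3))
    for j, pt in enumerate(layout.points):
        cyc = c_l if pt.foot == "left" else c_r
        phase = cyc - np.floor(cyc)
        depth = VERTICAL_OFFSET - pt.sole_height
        pos[:, j, 0] = pt.ankle_offset[0]
        pos[:, j, 1] = _point_height_profile(phase, depth, u_all[j])
        pos[:, j, 2] = pt.ankle_offset[1]
    contacts = ContactState(
        rate=rate,
        positions=pos,
        vertical_velocities=differentiate(pos[..., 1], rate),
        foot_of_point=layout.foot_of_point,
        ankle_origin=kin.ankle_origins.copy(),
    )

    vpp = VppState(
        r_vpp=com + np.array([0.0, model.vpp_offset, 0.0]),
        whole_body_com=com,
    )
    truth = estimate_core(
        ExternalForceSeries(f_ext), contacts, vpp, model, rate,
    )
    return SyntheticTrial(markers=markers, kin=kin, contacts=contacts,
                          truth_wrenches=truth, seed=seed, model=model)


def add_noise(trial: SyntheticTrial, amplitude: float, seed: int = 0) -> SyntheticTrial:
    """Uniform white noise in [-amplitude, +amplitude] on every contact-point
    coordinate; kinematics and truth are untouched.  Vertical velocities are
    rebuilt from the noisy heights."""
    if amplitude < 0:
        raise ParameterError("noise amplitude must be non-negative")
    noisy = trial.contacts.copy()
    if amplitude > 0:
        rng = np.random.default_rng(seed)
        noisy.positions = noisy.positions + rng.uniform(
            -amplitude, amplitude, size=noisy.positions.shape
        )
    noisy.vertical_velocities = differentiate(noisy.positions[..., 1], noisy.rate)
    return replace(trial, contacts=noisy, seed=seed)
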