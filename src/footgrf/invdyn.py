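"""Joint torques by recursive Newton-Euler inverse dynamics.

The 23-DOF torque vector solves ``tau = I(q) qdd + Gamma(q, qd, wrenches)``
over the 12-segment tree: an outward pass propagates angular velocity,
angular acceleration and COM acceleration joint by joint (each elementary
rotation treated as its own intermediate frame, so chained intrinsic Euler
rotations are handled exactly), and an inward pass accumulates the
force/moment each joint must transmit, projecting it onto the instantaneous
joint axes to obtain generalized forces.  Estimated ground reaction forces
are applied to the calcaneus bodies at their centres of pressure (the
distribution scheme leaves no free couple at the COP).  The six pelvis
generalized forces are reported, not zeroed: on dynamically consistent
input they vanish, so they serve as a consistency diagnostic.

Prismatic DOFs are supported at the tree root only (the pelvis global
translations), which is all the model requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DimensionError, ParameterError
from .kinio import SegmentKinematics, differentiate
from .model import DOF_NAMES, GRAVITY_VEC, SEGMENTS, SubjectModel

__all__ = [
    "BodySpec", "KinematicTree", "JointTorqueSeries",
    "rnea", "tree_from_model", "forward_kinematics",
    "inverse_dynamics", "pelvis_residual",
]


@dataclass
class BodySpec:
    """One rigid body and the joint connecting it to its parent."""

    name: str
    parent: str | None            # None = world
    joint_origin: np.ndarray      # 3, joint centre in the parent frame
    dofs: list                    # [(kind 'P'|'R', local axis 3-vector, dof name)]
    mass: float
    com: np.ndarray               # 3, local, from the joint centre
    inertia: np.ndarray           # 3x3, local, about the COM


@dataclass
class KinematicTree:
    bodies: list[BodySpec]

    def __post_init__(self):
        names = [b.name for b in self.bodies]
        if len(set(names)) != len(names):
            raise ParameterError("duplicate body names")
        self.index = {n: i for i, n in enumerate(names)}
        for b in self.bodies:
            if b.parent is not None and self.index[b.parent] >= self.index[b.name]:
                raise ParameterError("bodies must be topologically ordered")
            I = np.asarray(b.inertia, float)
            if not np.allclose(I, I.T) or np.any(np.linalg.eigvalsh(I) < -1e-12):
                raise ParameterError(f"inertia of {b.name!r} not symmetric PSD")
            seen_rot = False
            for kind, _, _ in b.dofs:
                if kind == "R":
                    seen_rot = True
                elif kind == "P" and (b.parent is not None or seen_rot):
                    raise ParameterError(
                        "prismatic DOFs are supported only at the root, "
                        "before any rotation"
                    )
        self.dof_names = [nm for b in self.bodies for _, _, nm in b.dofs]
        self.nq = len(self.dof_names)


@dataclass
class JointTorqueSeries:
    """Generalized forces per frame; root translational DOFs carry newtons,
    rotational DOFs newton-metres."""

    tau: np.ndarray          # frames x nq
    dof_names: list[str]
    rate: float = np.nan

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.tau, columns=self.dof_names)
        if np.isfinite(self.rate):
            df.insert(0, "time", np.arange(len(df)) / self.rate)
        return df


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    a = axis
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _frame_pass(tree: KinematicTree, q, qd, qdd, gravity):
    """Outward pass for one frame: world pose and spatial kinematics."""
    n = len(tree.bodies)
    R = [None] * n
    o = [None] * n
    a_o = [None] * n      # linear acceleration of the joint origin point
    w = [None] * n
    wd = [None] * n
    com_w = [None] * n
    a_com = [None] * n
    axes_w = [None] * n   # per body: list of world axes, aligned with dofs
    k = 0
    for i, b in enumerate(tree.bodies):
        if b.parent is None:
            Rp, op = np.eye(3), np.zeros(3)
            ap, wp, wdp = np.zeros(3), np.zeros(3), np.zeros(3)
        else:
            p = tree.index[b.parent]
            Rp, op, ap, wp, wdp = R[p], o[p], a_o[p], w[p], wd[p]
        d = Rp @ b.joint_origin
        oi = op + d
        ai = ap + np.cross(wdp, d) + np.cross(wp, np.cross(wp, d))
        Ri, wi, wdi = Rp.copy(), wp.copy(), wdp.copy()
        ax_list = []
        for kind, axis, _ in b.dofs:
            aw = Ri @ axis
            ax_list.append(aw)
            if kind == "P":
                # root only: carrier frame is inertial
                oi = oi + aw * q[k]
                ai = ai + aw * qdd[k]
            else:
                wdi = wdi + aw * qdd[k] + np.cross(wi, aw * qd[k])
                wi = wi + aw * qd[k]
                Ri = Ri @ _rot(axis, q[k])
            k += 1
        R[i], o[i], a_o[i], w[i], wd[i], axes_w[i] = Ri, oi, ai, wi, wdi, ax_list
        r = Ri @ b.com
        com_w[i] = oi + r
        a_com[i] = ai + np.cross(wdi, r) + np.cross(wi, np.cross(wi, r))
    return R, o, a_o, w, wd, com_w, a_com, axes_w


def rnea_frame(tree: KinematicTree, q, qd, qdd, gravity=GRAVITY_VEC, ext=None):
    """Inverse dynamics for a single state.

    ``ext`` maps body name -> (force, moment, application point), all in
    world coordinates.  Returns the nq generalized-force vector.
    """
    R, o, a_o, w, wd, com_w, a_com, axes_w = _frame_pass(tree, q, qd, qdd, gravity)
    n = len(tree.bodies)
    f = [None] * n
    nmom = [None] * n
    children = [[] for _ in range(n)]
    for i, b in enumerate(tree.bodies):
        if b.parent is not None:
            children[tree.index[b.parent]].append(i)
    for i in reversed(range(n)):
        b = tree.bodies[i]
        Iw = R[i] @ b.inertia @ R[i].T
        fi = b.mass * (a_com[i] - gravity)
        ni = Iw @ wd[i] + np.cross(w[i], Iw @ w[i]) + np.cross(com_w[i] - o[i], fi)
        if ext and b.name in ext:
            Fe, Me, pe = ext[b.name]
            fi = fi - Fe
            ni = ni - np.cross(pe - o[i], Fe) - Me
        for c in children[i]:
            fi = fi + f[c]
            ni = ni + nmom[c] + np.cross(o[c] - o[i], f[c])
        f[i], nmom[i] = fi, ni
    tau = np.zeros(tree.nq)
    k = 0
    for i, b in enumerate(tree.bodies):
        for (kind, _, _), aw in zip(b.dofs, axes_w[i]):
            tau[k] = (f[i] if kind == "P" else nmom[i]) @ aw
            k += 1
    return tau


def rnea(tree: KinematicTree, q, qd, qdd, gravity=GRAVITY_VEC, ext=None):
    """Vectorized-over-frames inverse dynamics.

    ``q``, ``qd``, ``qdd`` are frames x nq; ``ext`` maps body name ->
    (forces, moments, points), each frames x 3.
    """
    q, qd, qdd = (np.atleast_2d(np.asarray(x, float)) for x in (q, qd, qdd))
    if q.shape[1] != tree.nq:
        raise DimensionError(f"q has {q.shape[1]} columns, tree has {tree.nq} DOF")
    F = q.shape[0]
    tau = np.zeros((F, tree.nq))
    for t in range(F):
        ext_t = None
        if ext:
            ext_t = {nm: (Fe[t], Me[t], pe[t]) for nm, (Fe, Me, pe) in ext.items()}
        tau[t] = rnea_frame(tree, q[t], qd[t], qdd[t], gravity, ext_t)
    return tau


def forward_kinematics(tree: KinematicTree, q):
    """World orientation, origin and COM of every body at configuration q."""
    R, o, _, _, _, com_w, _, _ = _frame_pass(
        tree, np.asarray(q, float), np.zeros(tree.nq), np.zeros(tree.nq), GRAVITY_VEC
    )
    return (np.stack(R), np.stack(o), np.stack(com_w))


def tree_from_model(model: SubjectModel) -> KinematicTree:
    """The 12-body, 23-DOF tree of a calibrated subject."""
    bodies = []
    for i, entry in enumerate(model.joint_tree):
        seg = entry["segment"]
        bodies.append(BodySpec(
            name=seg,
            parent=entry["parent"],
            joint_origin=np.asarray(entry["origin"], float),
            dofs=list(entry["dofs"]),
            mass=float(model.segment_masses[i]),
            com=model.segment_com_offsets[i],
            inertia=model.segment_inertias[i],
        ))
    tree = KinematicTree(bodies)
    if tree.dof_names != list(DOF_NAMES):
        raise ParameterError("model joint tree does not match the canonical DOF order")
    return tree


def inverse_dynamics(kin: SegmentKinematics, wrenches, model: SubjectModel) -> JointTorqueSeries:
    """Joint torques from joint kinematics and estimated foot wrenches.

    ``qd``/``qdd`` come from the kinematics (finite differences of the
    joint angles when not already present).  Each foot's ground reaction
    force acts on its calcaneus at the lab-frame COP with no free couple;
    frames with an undefined COP (unloaded foot) contribute no wrench.
    """
    q = kin.joint_angles
    F = q.shape[0]
    if wrenches.n_frames != F:
        raise DimensionError(
            f"kinematics have {F} frames, wrenches {wrenches.n_frames}"
        )
    qd = kin.joint_rates if kin.joint_rates is not None else differentiate(q, kin.rate)
    qdd = kin.joint_accels if kin.joint_accels is not None else differentiate(q, kin.rate, order=2)
    tree = tree_from_model(model)
    ext = {}
    for k, seg in ((0, "calcn_l"), (1, "calcn_r")):
        Fe = wrenches.force[:, k].copy()
        pe = np.nan_to_num(wrenches.cop[:, k])
        loaded = np.isfinite(wrenches.cop[:, k, 0])
        Fe[~loaded] = 0.0
        ext[seg] = (Fe, np.zeros((F, 3)), pe)
    tau = rnea(tree, q, qd, qdd, ext=ext)
    return JointTorqueSeries(tau=tau, dof_names=list(DOF_NAMES), rate=kin.rate)


def pelvis_residual(tau: JointTorqueSeries) -> np.ndarray:
    """The six pelvis generalized forces (frames x 6): residual force (N)
    and moment (N m) the kinematics and wrenches leave unexplained."""
    cols = [tau.dof_names.index(n) for n in DOF_NAMES[:6]]
    return tau.tau[:, cols]
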