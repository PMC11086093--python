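"""Ground reaction force/moment estimation by sinkage-based distribution.

The method turns whole-body kinematics into per-foot ground reaction
wrenches without any optimization:

1. the translational equations of motion give the total external force
   ``F_ext = sum_s m_s (r_ddot_s - g)`` over the 12 segment COMs;
2. each contact point's *sinkage* — its penetration depth below the ground
   plane, gated by a critical height ``p_crit`` and vertical velocity
   ``v_crit`` — acts as a proxy for local load: the vertical force and the
   horizontal-axis moments distribute ``F_ext_y`` over the points in
   proportion to sinkage;
3. the centre of pressure (COP) of each foot follows from the vertical
   force and those moments;
4. horizontal forces are the horizontal external force during single
   support, and during double support are directed from each foot's COP
   toward the *virtual pivot point* (VPP), a point a fixed distance above
   the whole-body COM along the trunk's longitudinal axis;
5. the transverse (vertical-axis) moment closes the wrench from the
   horizontal forces and the COP.

All distribution steps are exact algebra on the measured kinematics, which
is what makes the estimator optimization-free and fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DimensionError, GeometryError, ParameterError, PhaseError
from .kinio import (
    ContactState,
    MarkerTrajectories,
    SegmentKinematics,
    compute_contact_points,
    differentiate,
    fit_segment_poses,
    lowpass_filter,
)
from .model import GRAVITY, SEGMENTS, SubjectModel

__all__ = [
    "ExternalForceSeries", "SinkageField", "FootWrenchSeries", "VppState",
    "external_forces", "sinkage", "distribute_vertical", "detect_phase",
    "horizontal_single", "cop", "vpp_position", "horizontal_double",
    "transverse_grm", "estimate", "estimate_core", "estimate_from_markers",
    "condition_contacts",
    "FLIGHT", "SINGLE", "DOUBLE", "PHASE_NAMES",
]

FLIGHT, SINGLE, DOUBLE = 0, 1, 2
PHASE_NAMES = {FLIGHT: "flight", SINGLE: "single", DOUBLE: "double"}

FORCE_FLOOR_FRACTION = 0.01  # of body weight; below it the COP is undefined


@dataclass
class ExternalForceSeries:
    """Whole-body external force per frame, N, lab axes."""

    F_ext: np.ndarray  # frames x 3

    @property
    def n_frames(self) -> int:
        return self.F_ext.shape[0]


@dataclass
class SinkageField:
    """Per-point sinkage h >= 0 (m) under the position/velocity gate."""

    h: np.ndarray       # frames x 20, m
    p_crit: float = 0.0
    v_crit: float = 0.05


@dataclass
class VppState:
    """Virtual pivot point, whole-body COM and the per-foot scaling alpha."""

    r_vpp: np.ndarray           # frames x 3, m
    whole_body_com: np.ndarray  # frames x 3, m
    alpha: np.ndarray | None = None  # frames x 2, N/m (left, right)


@dataclass
class FootWrenchSeries:
    """Per-foot ground reaction wrench series.

    ``force``/``moment``/``cop`` are frames x 2 x 3 with foot index
    0 = left, 1 = right.  ``cop`` is expressed in the lab frame with its
    vertical component fixed at the ground height (NaN where the vertical
    force is below the COP floor).  ``moment`` is reported about the owning
    foot's ankle origin projected to the ground (``moment_origin='ankle'``)
    or about the lab origin (``'lab'``).
    """

    rate: float
    force: np.ndarray   # frames x 2 x 3, N
    moment: np.ndarray  # frames x 2 x 3, N m
    cop: np.ndarray     # frames x 2 x 3, m, lab frame
    phase: np.ndarray   # frames, {0 flight, 1 single, 2 double}
    moment_origin: str = "ankle"
    f_ext: np.ndarray | None = None  # frames x 3, diagnostic

    feet = ("left", "right")

    @property
    def n_frames(self) -> int:
        return self.force.shape[0]

    @property
    def phase_labels(self) -> np.ndarray:
        return np.array([PHASE_NAMES[p] for p in self.phase])

    def channel_frame(self) -> pd.DataFrame:
        """Wide table: time plus per-foot force/COP/moment channels."""
        t = np.arange(self.n_frames) / self.rate
        cols = {"time": t}
        for k, foot in enumerate(self.feet):
            for j, ax in enumerate("xyz"):
                cols[f"{foot}_force_{ax}"] = self.force[:, k, j]
            for j, ax in enumerate("xyz"):
                cols[f"{foot}_cop_{ax}"] = self.cop[:, k, j]
            for j, ax in enumerate("xyz"):
                cols[f"{foot}_moment_{ax}"] = self.moment[:, k, j]
        return pd.DataFrame(cols)

    def write_mot(self, path) -> None:
        from .kinio import write_sto

        write_sto(self.channel_frame().fillna(0.0), path, name="ground_reactions")


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def external_forces(kin: SegmentKinematics, model: SubjectModel) -> ExternalForceSeries:
    """Total external force from the translational equations of motion.

    ``F_ext_x = sum m_s a_xs``, ``F_ext_y = sum m_s (a_ys + g)``,
    ``F_ext_z = sum m_s a_zs`` with g the gravitational magnitude; a static
    body therefore carries ``F_ext_y`` equal to its weight.
    """
    acc = kin.com_accelerations
    if acc.shape[1] != model.segment_masses.shape[0]:
        raise DimensionError(
            f"kinematics carry {acc.shape[1]} segments, model has "
            f"{model.segment_masses.shape[0]} masses"
        )
    m = model.segment_masses
    F = np.einsum("s,fsi->fi", m, acc)
    F[:, 1] += m.sum() * GRAVITY
    return ExternalForceSeries(F_ext=F)


def sinkage(contacts: ContactState, p_crit: float = 0.0, v_crit: float = 0.05) -> SinkageField:
    """Gated penetration depth per contact point.

    ``h_i = p_crit - p_yi`` where the point is below the critical height
    *and* its vertical velocity is below the critical velocity; otherwise 0.
    The velocity gate discards points that are lifting off, whose depth no
    longer reflects load.
    """
    p_y = contacts.positions[..., 1]
    v_y = contacts.vertical_velocities
    if p_y.shape != v_y.shape:
        raise DimensionError("contact heights and velocities misaligned")
    h = np.where((p_y < p_crit) & (v_y < v_crit), p_crit - p_y, 0.0)
    return SinkageField(h=h, p_crit=p_crit, v_crit=v_crit)


def distribute_vertical(h: SinkageField, f_ext: ExternalForceSeries, contacts: ContactState):
    """Distribute the vertical external force over the sunk contact points.

    Returns per-foot ``(F_GR_y, M_GR_x, M_GR_z)`` arrays (frames x 2): each
    point takes the share ``h_i / sum_k h_k`` of ``F_ext_y``; the frontal
    and sagittal moments are the moments of those point loads about the
    owning foot's ankle origin (``M_x = -sum w_i p_zi F_ext_y``,
    ``M_z = +sum w_i p_xi F_ext_y``).  Frames with no sinkage anywhere
    return zeros (flight).
    """
    H = h.h
    F = H.shape[0]
    if f_ext.n_frames != F or contacts.n_frames != F:
        raise DimensionError("sinkage, forces and contacts have different lengths")
    total = H.sum(axis=1)
    safe = np.where(total > 0, total, 1.0)
    w = H / safe[:, None]          # frames x 20, rows sum to 1 where contact
    fy = f_ext.F_ext[:, 1]
    p_x = contacts.positions[..., 0]
    p_z = contacts.positions[..., 2]
    foot = contacts.foot_of_point
    out_fy = np.zeros((F, 2))
    out_mx = np.zeros((F, 2))
    out_mz = np.zeros((F, 2))
    for k in (0, 1):
        mask = foot == k
        out_fy[:, k] = w[:, mask].sum(axis=1) * fy
        out_mx[:, k] = -(w[:, mask] * p_z[:, mask]).sum(axis=1) * fy
        out_mz[:, k] = (w[:, mask] * p_x[:, mask]).sum(axis=1) * fy
    none = total <= 0
    out_fy[none] = 0.0
    out_mx[none] = 0.0
    out_mz[none] = 0.0
    return out_fy, out_mx, out_mz


def detect_phase(h: SinkageField, foot_of_point: np.ndarray) -> np.ndarray:
    """Support phase per frame from per-foot total sinkage.

    double if both feet sink, single if exactly one, flight if neither.
    """
    H = h.h
    left = H[:, foot_of_point == 0].sum(axis=1) > 0
    right = H[:, foot_of_point == 1].sum(axis=1) > 0
    return np.where(left & right, DOUBLE, np.where(left | right, SINGLE, FLIGHT))


def horizontal_single(f_ext: ExternalForceSeries, stance: np.ndarray,
                      phase: np.ndarray | None = None):
    """Assign the horizontal external force to the stance foot.

    ``stance`` holds the stance-foot index (0 left, 1 right) per frame;
    the swing foot carries zero horizontal force.  When ``phase`` labels
    are supplied, any non-single-support frame is rejected.  Returns
    frames x 2 x 2 ((F_GR_x, F_GR_z) per foot).
    """
    if phase is not None and np.any(np.asarray(phase) != SINGLE):
        raise PhaseError("horizontal_single called on non-single-support frames")
    F = f_ext.n_frames
    out = np.zeros((F, 2, 2))
    idx = np.arange(F)
    out[idx, stance, 0] = f_ext.F_ext[:, 0]
    out[idx, stance, 1] = f_ext.F_ext[:, 2]
    return out


def cop(f_gr_y: np.ndarray, m_gr_x: np.ndarray, m_gr_z: np.ndarray,
        force_floor: float = 0.0) -> np.ndarray:
    """Centre of pressure from the vertical force and horizontal-axis moments.

    ``p_COP_x = M_GR_z / F_GR_y``, ``p_COP_y = 0``,
    ``p_COP_z = -M_GR_x / F_GR_y``, in the frame the moments are expressed
    in (ankle-relative when they come from :func:`distribute_vertical`).
    Entries with ``F_GR_y <= force_floor`` are NaN (undefined COP).
    """
    f_gr_y = np.asarray(f_gr_y, float)
    ok = f_gr_y > force_floor
    safe = np.where(ok, f_gr_y, 1.0)
    out = np.stack([
        np.where(ok, np.asarray(m_gr_z) / safe, np.nan),
        np.zeros_like(f_gr_y),
        np.where(ok, -np.asarray(m_gr_x) / safe, np.nan),
    ], axis=-1)
    out[..., 1] = np.where(ok, 0.0, np.nan)
    return out


def vpp_position(kin: SegmentKinematics, model: SubjectModel) -> VppState:
    """Whole-body COM and the virtual pivot point above it.

    The VPP sits ``model.vpp_offset`` (default 37.5 mm) above the mass-
    weighted whole-body COM along the trunk segment's longitudinal (local
    +y) axis expressed in the lab frame.
    """
    m = model.segment_masses
    com = np.einsum("s,fsi->fi", m, kin.com_positions) / m.sum()
    i_torso = SEGMENTS.index("torso")
    trunk_up = kin.orientations[:, i_torso, :, 1]  # world image of local +y
    r_vpp = com + model.vpp_offset * trunk_up
    return VppState(r_vpp=r_vpp, whole_body_com=com)


def horizontal_double(f_gr_y: np.ndarray, cop_lab: np.ndarray, vpp: VppState):
    """Horizontal forces directed from each foot's COP toward the VPP.

    For each loaded foot, ``alpha = F_GR_y / (r_VPP_y - p_COP_y)`` and the
    horizontal components follow the COP-to-VPP direction:
    ``F_GR_x = alpha (r_VPP_x - p_COP_x)``, ``F_GR_z = alpha (r_VPP_z -
    p_COP_z)``.  COP and VPP must share the lab frame.  Returns
    (frames x 2 x 2 horizontal forces, frames x 2 alpha).
    """
    F = f_gr_y.shape[0]
    out = np.zeros((F, 2, 2))
    alpha = np.zeros((F, 2))
    lever_y = vpp.r_vpp[:, None, 1] - cop_lab[..., 1]  # frames x 2
    loaded = (f_gr_y > 0) & np.isfinite(cop_lab[..., 0])
    if np.any(loaded & (lever_y <= 0)):
        raise GeometryError("VPP at or below a loaded foot's COP")
    safe = np.where(loaded, lever_y, 1.0)
    alpha = np.where(loaded, f_gr_y / safe, 0.0)
    out[..., 0] = alpha * np.where(loaded, vpp.r_vpp[:, None, 0] - cop_lab[..., 0], 0.0)
    out[..., 1] = alpha * np.where(loaded, vpp.r_vpp[:, None, 2] - cop_lab[..., 2], 0.0)
    return out, alpha


def transverse_grm(f_gr_x: np.ndarray, f_gr_z: np.ndarray, cop_pts: np.ndarray) -> np.ndarray:
    """Vertical-axis moment from the horizontal forces acting at the COP:
    ``M_GR_y = p_COP_z F_GR_x - p_COP_x F_GR_z`` (same frame as the COP)."""
    p_x = np.nan_to_num(cop_pts[..., 0])
    p_z = np.nan_to_num(cop_pts[..., 2])
    return p_z * f_gr_x - p_x * f_gr_z


# ---------------------------------------------------------------------------
# composed estimator
# ---------------------------------------------------------------------------

def estimate_core(f_ext: ExternalForceSeries, contacts: ContactState,
                  vpp: VppState, model: SubjectModel, rate: float,
                  moment_origin: str = "ankle") -> FootWrenchSeries:
    """Distribution flow from precomputed external forces and VPP.

    Sinkage -> vertical distribution -> phase detection -> horizontal
    forces (single-support identity or double-support VPP construction)
    -> transverse moment.  :func:`estimate` wraps this with the external
    forces and VPP derived from segment kinematics.
    """
    if moment_origin not in ("ankle", "lab"):
        raise ParameterError("moment_origin must be 'ankle' or 'lab'")
    F = f_ext.n_frames
    if contacts.n_frames != F:
        raise DimensionError(
            f"forces have {F} frames, contacts {contacts.n_frames}"
        )
    h = sinkage(contacts, model.p_crit, model.v_crit)
    fy, mx, mz = distribute_vertical(h, f_ext, contacts)
    phase = detect_phase(h, contacts.foot_of_point)

    floor = FORCE_FLOOR_FRACTION * model.body_mass * GRAVITY
    cop_rel = cop(fy, mx, mz, force_floor=floor)  # ankle-relative, frames x 2 x 3
    cop_lab = cop_rel.copy()
    cop_lab[..., 0] += contacts.ankle_origin[..., 0]
    cop_lab[..., 2] += contacts.ankle_origin[..., 2]

    horizontal = np.zeros((F, 2, 2))
    single = phase == SINGLE
    if np.any(single):
        left_on = h.h[:, contacts.foot_of_point == 0].sum(axis=1) > 0
        stance = np.where(left_on, 0, 1)[single]
        hs = horizontal_single(
            ExternalForceSeries(f_ext.F_ext[single]), stance
        )
        # a stance foot below the COP force floor cannot carry shear
        ok = np.isfinite(cop_lab[single, :, 0])
        horizontal[single] = np.where(ok[..., None], hs, 0.0)

    double = phase == DOUBLE
    if np.any(double):
        hd, alpha = horizontal_double(
            fy[double], cop_lab[double],
            VppState(vpp.r_vpp[double], vpp.whole_body_com[double]),
        )
        horizontal[double] = hd
        full_alpha = np.zeros((F, 2))
        full_alpha[double] = alpha
        vpp.alpha = full_alpha

    # transverse moment about the same origin as the reported moments
    cop_m = cop_rel if moment_origin == "ankle" else cop_lab
    my = transverse_grm(horizontal[..., 0], horizontal[..., 1], cop_m)
    if moment_origin == "lab":
        # horizontal-axis moments re-expressed about the lab origin:
        # full wrench = force acting at the lab COP with no free couple
        mx = np.nan_to_num(-cop_lab[..., 2] * fy)
        mz = np.nan_to_num(cop_lab[..., 0] * fy)

    force = np.zeros((F, 2, 3))
    force[..., 0] = horizontal[..., 0]
    force[..., 1] = fy
    force[..., 2] = horizontal[..., 1]
    moment = np.stack([mx, my, mz], axis=-1)
    return FootWrenchSeries(
        rate=rate, force=force, moment=moment, cop=cop_lab,
        phase=phase, moment_origin=moment_origin, f_ext=f_ext.F_ext,
    )


def estimate(kin: SegmentKinematics, contacts: ContactState, model: SubjectModel,
             moment_origin: str = "ankle") -> FootWrenchSeries:
    """Full per-foot GRF/GRM/COP estimation from segment kinematics.

    Composes external forces -> sinkage -> vertical distribution -> phase
    detection -> horizontal forces (single-support identity or
    double-support VPP construction) -> transverse moment.  Moments are
    reported about each foot's grounded ankle origin or about the lab
    origin (``moment_origin``).
    """
    if kin.n_frames != contacts.n_frames:
        raise DimensionError(
            f"kinematics have {kin.n_frames} frames, contacts {contacts.n_frames}"
        )
    f_ext = external_forces(kin, model)
    vpp = vpp_position(kin, model)
    return estimate_core(f_ext, contacts, vpp, model, kin.rate,
                         moment_origin=moment_origin)


def condition_contacts(contacts: ContactState, cutoff: float = 6.0) -> ContactState:
    """Apply the measurement low-pass to contact positions and rebuild
    vertical velocities — the conditioning marker-derived contact points
    receive on their way into the estimator."""
    out = contacts.copy()
    out.positions = lowpass_filter(contacts.positions, contacts.rate, cutoff)
    out.vertical_velocities = differentiate(out.positions[..., 1], contacts.rate)
    return out


def estimate_from_markers(markers: MarkerTrajectories, model: SubjectModel,
                          cutoff: float = 6.0,
                          moment_origin: str = "ankle") -> FootWrenchSeries:
    """Marker-to-wrench pipeline: low-pass filter the markers, fit segment
    poses, derive contact points, and run :func:`estimate`."""
    filtered = markers.copy()
    filtered.positions = lowpass_filter(markers.positions, markers.rate, cutoff)
    kin = fit_segment_poses(filtered, model)
    contacts = compute_contact_points(kin, model)
    return estimate(kin, contacts, model, moment_origin=moment_origin)
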