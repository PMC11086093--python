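"""Marker I/O, signal conditioning and segment/contact-point kinematics.

Readers cover the tab-separated TRC marker format and STO/MOT-style
time-series tables, the de facto text interchange formats of gait labs.
Signal conditioning follows standard practice: zero-phase (forward-backward)
Butterworth low-pass with the cutoff pre-warped so the *net* response is
-3 dB at the nominal frequency, and finite-difference differentiation
(central interior, one-sided ends).

Segment poses are fitted per frame by orthogonal Procrustes (Kabsch)
registration of each segment's markers against their calibrated local
positions; joint angles are extracted with the intrinsic Z-X-Y Euler
sequence.  This replaces a global inverse-kinematics solve: each segment is
fitted independently, which is exact on rigid noise-free data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .exceptions import (
    DegenerateFitError,
    DimensionError,
    FormatError,
    MissingMarkerError,
    ParameterError,
)
from .model import DOF_NAMES, SEGMENTS, SubjectModel

__all__ = [
    "MarkerTrajectories", "SegmentKinematics", "ContactState",
    "read_markers", "read_trc", "write_trc", "read_sto", "write_sto",
    "lowpass_filter", "differentiate", "rigid_register",
    "fit_segment_poses", "compute_contact_points",
    "euler_zxy_to_matrix", "matrix_to_euler_zxy",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MarkerTrajectories:
    """Named 3-D marker trajectories, metres, uniformly sampled."""

    names: list[str]
    positions: np.ndarray  # frames x markers x 3, m
    rate: float            # Hz

    def __post_init__(self):
        if self.rate <= 0:
            raise ParameterError("sampling rate must be positive")
        if self.positions.ndim != 3 or self.positions.shape[1] != len(self.names):
            raise DimensionError("positions must be frames x len(names) x 3")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def get(self, name: str) -> np.ndarray:
        try:
            return self.positions[:, self.names.index(name)]
        except ValueError:
            raise MissingMarkerError(name) from None

    def copy(self) -> "MarkerTrajectories":
        return MarkerTrajectories(list(self.names), self.positions.copy(), self.rate)

    def fill_gaps(self, max_gap: int = 10) -> "MarkerTrajectories":
        """Linearly interpolate NaN gaps up to ``max_gap`` frames."""
        pos = self.positions.copy()
        t = np.arange(self.n_frames)
        for m in range(pos.shape[1]):
            bad = np.isnan(pos[:, m]).any(axis=1)
            if not bad.any():
                continue
            runs = np.diff(np.flatnonzero(np.diff(np.r_[0, bad.view(np.int8), 0])))[::2]
            if bad[0] or bad[-1] or (runs.max() if runs.size else 0) > max_gap:
                raise FormatError(
                    f"marker {self.names[m]!r} has an unfillable gap "
                    f"(> {max_gap} frames or at the trial boundary)"
                )
            for k in range(3):
                pos[bad, m, k] = np.interp(t[bad], t[~bad], pos[~bad, m, k])
        return MarkerTrajectories(list(self.names), pos, self.rate)


@dataclass
class SegmentKinematics:
    """Per-frame segment poses, COM kinematics and joint coordinates."""

    rate: float
    com_positions: np.ndarray      # frames x 12 x 3, m
    com_accelerations: np.ndarray  # frames x 12 x 3, m/s^2
    orientations: np.ndarray       # frames x 12 x 3 x 3, world <- segment
    origins: np.ndarray            # frames x 12 x 3, m (segment frame origins)
    joint_angles: np.ndarray       # frames x 23, rad (pelvis tx/ty/tz in m)
    ankle_origins: np.ndarray      # frames x 2 x 3, m (left, right)
    joint_rates: np.ndarray | None = None
    joint_accels: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.com_positions.shape[0]

    def copy(self) -> "SegmentKinematics":
        return SegmentKinematics(
            self.rate, self.com_positions.copy(), self.com_accelerations.copy(),
            self.orientations.copy(), self.origins.copy(), self.joint_angles.copy(),
            self.ankle_origins.copy(),
            None if self.joint_rates is None else self.joint_rates.copy(),
            None if self.joint_accels is None else self.joint_accels.copy(),
        )


@dataclass
class ContactState:
    """Per-frame foot contact-point kinematics.

    ``positions[..., 0]`` and ``positions[..., 2]`` are horizontal
    coordinates relative to the owning foot's ankle origin; ``positions[..., 1]``
    is the world height above the ground plane y = 0.
    """

    rate: float
    positions: np.ndarray           # frames x 20 x 3, m
    vertical_velocities: np.ndarray  # frames x 20, m/s
    foot_of_point: np.ndarray       # 20, 0 = left, 1 = right
    ankle_origin: np.ndarray        # frames x 2 x 3, m (left, right)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def lab_positions(self) -> np.ndarray:
        """Contact points in the lab frame (ankle origin added back)."""
        lab = self.positions.copy()
        ank = self.ankle_origin[:, self.foot_of_point]  # frames x 20 x 3
        lab[..., 0] += ank[..., 0]
        lab[..., 2] += ank[..., 2]
        return lab

    def copy(self) -> "ContactState":
        return ContactState(
            self.rate, self.positions.copy(), self.vertical_velocities.copy(),
            self.foot_of_point.copy(), self.ankle_origin.copy(),
        )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_markers(path, dialect: str = "trc") -> MarkerTrajectories:
    """Read marker trajectories; only the text TRC dialect is supported."""
    if dialect == "trc":
        return read_trc(path)
    if dialect == "c3d":
        raise FormatError("C3D reading is not supported; export the trial as TRC")
    raise FormatError(f"unknown marker dialect {dialect!r}")


def read_trc(path) -> MarkerTrajectories:
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6 or not lines[0].startswith("PathFileType"):
        raise FormatError(f"{path}: not a TRC file (missing PathFileType header)")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    meta = dict(zip(keys, vals))
    try:
        rate = float(meta["DataRate"])
        n_markers = int(meta["NumMarkers"])
        units = meta["Units"].strip().lower()
    except (KeyError, ValueError) as e:
        raise FormatError(f"{path}: malformed TRC header line 3: {e}") from None
    if units not in ("mm", "m"):
        raise FormatError(f"{path}: ambiguous Units={units!r} (expected mm or m)")
    scale = 1e-3 if units == "mm" else 1.0
    header = lines[3].split("\t")
    names = [n for n in header[2:] if n.strip()]
    if len(names) != n_markers:
        raise FormatError(
            f"{path}: header names {len(names)} != NumMarkers {n_markers}"
        )
    rows = []
    for ln in lines[5:]:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        vals = [float(v) if v.strip() else np.nan for v in parts[2:2 + 3 * n_markers]]
        if len(vals) != 3 * n_markers:
            raise FormatError(f"{path}: data row with {len(vals)} values: {ln[:60]!r}")
        rows.append(vals)
    data = np.array(rows).reshape(len(rows), n_markers, 3) * scale
    return MarkerTrajectories(names, data, rate)


def write_trc(traj: MarkerTrajectories, path, units: str = "mm") -> None:
    path = Path(path)
    scale = 1e3 if units == "mm" else 1.0
    n, m = traj.n_frames, len(traj.names)
    out = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{traj.rate:g}\t{traj.rate:g}\t{n}\t{m}\t{units}\t{traj.rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(traj.names) + "\t\t",
        "\t\t" + "\t".join(f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(m)),
    ]
    t = traj.time
    for i in range(n):
        vals = "\t".join(f"{v:.8f}" for v in (traj.positions[i] * scale).ravel())
        out.append(f"{i+1}\t{t[i]:.5f}\t{vals}")
    path.write_text("\n".join(out) + "\n")


def read_sto(path) -> pd.DataFrame:
    """Read an STO/MOT-style tab-separated time series into a DataFrame."""
    path = Path(path)
    lines = path.read_text().splitlines()
    try:
        hdr_end = next(i for i, ln in enumerate(lines) if ln.strip() == "endheader")
    except StopIteration:
        raise FormatError(f"{path}: no 'endheader' line") from None
    cols = lines[hdr_end + 1].split("\t")
    data = [
        [float(v) for v in ln.split("\t")]
        for ln in lines[hdr_end + 2:] if ln.strip()
    ]
    return pd.DataFrame(data, columns=cols)


def write_sto(df: pd.DataFrame, path, name: str = "series") -> None:
    path = Path(path)
    header = [
        name,
        "version=1",
        f"nRows={len(df)}",
        f"nColumns={df.shape[1]}",
        "inDegrees=no",
        "endheader",
    ]
    body = ["\t".join(df.columns)]
    for row in df.itertuples(index=False):
        body.append("\t".join(f"{v:.8f}" for v in row))
    path.write_text("\n".join(header + body) + "\n")


# ---------------------------------------------------------------------------
# signal conditioning
# ---------------------------------------------------------------------------

def lowpass_filter(signal: np.ndarray, rate: float, cutoff: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass, -3 dB at ``cutoff``.

    The filter runs forward and backward (no phase lag); each pass uses half
    the nominal order and the design cutoff is pre-warped so that the *net*
    two-pass response is -3 dB at the requested frequency.
    """
    if cutoff <= 0 or rate <= 0:
        raise ParameterError("rate and cutoff must be positive")
    if rate <= 2 * cutoff:
        raise ParameterError(f"cutoff {cutoff} Hz not below Nyquist {rate / 2} Hz")
    if order % 2 or order < 2:
        raise ParameterError("order must be an even integer >= 2")
    n_pass = order // 2
    # net attenuation of two identical passes is -3 dB where each pass loses
    # sqrt(2)-1 in squared magnitude
    correction = (2 ** 0.5 - 1) ** (-1.0 / (2 * n_pass))
    fc = cutoff * correction
    if fc >= rate / 2:
        raise ParameterError("pre-warped cutoff reaches Nyquist; raise the rate")
    b, a = butter(n_pass, fc / (rate / 2))
    x = np.asarray(signal, float)
    if x.shape[0] < 3 * max(len(a), len(b)):
        raise ParameterError("signal too short to filter")
    return filtfilt(b, a, x, axis=0)


def differentiate(signal: np.ndarray, rate: float, order: int = 1) -> np.ndarray:
    """Finite-difference derivative along axis 0.

    ``order=1``: central differences in the interior, one-sided at the ends.
    ``order=2``: three-point second-difference stencil in the interior (exact
    on quadratics); end frames copy their nearest interior value.
    """
    x = np.asarray(signal, float)
    if x.shape[0] < 3:
        raise ParameterError("differentiation needs at least 3 frames")
    dt = 1.0 / rate
    if order == 1:
        return np.gradient(x, dt, axis=0, edge_order=2)
    if order == 2:
        out = np.empty_like(x)
        out[1:-1] = (x[2:] - 2 * x[1:-1] + x[:-2]) / dt ** 2
        out[0] = out[1]
        out[-1] = out[-2]
        return out
    raise ParameterError("order must be 1 or 2")


# ---------------------------------------------------------------------------
# rigid registration and Euler angles
# ---------------------------------------------------------------------------

def rigid_register(local: np.ndarray, world: np.ndarray, context: str = "segment"):
    """Least-squares rigid transform: ``R @ local + t ~= world`` (Kabsch).

    ``world`` may be a single (n, 3) cloud or a batch (frames, n, 3); the
    rotation is the closed-form SVD orthogonal-Procrustes solution.
    """
    local = np.asarray(local, float)
    world = np.asarray(world, float)
    single = world.ndim == 2
    W = world[None] if single else world
    if local.shape[0] < 3:
        raise DegenerateFitError(context)
    lc = local - local.mean(axis=0)
    # collinearity check on the local template
    if np.linalg.svd(lc, compute_uv=False)[1] < 1e-10:
        raise DegenerateFitError(context)
    wc = W - W.mean(axis=1, keepdims=True)
    H = np.einsum("ni,fnj->fij", lc, wc)
    U, _, Vt = np.linalg.svd(H)
    V = Vt.transpose(0, 2, 1)
    Ut = U.transpose(0, 2, 1)
    D = np.repeat(np.eye(3)[None], len(W), axis=0)
    D[:, 2, 2] = np.sign(np.linalg.det(V @ Ut))
    R = V @ D @ Ut  # world <- local, per frame
    t = W.mean(axis=1) - np.einsum("fij,j->fi", R, local.mean(axis=0))
    if single:
        return R[0], t[0]
    return R, t


def euler_zxy_to_matrix(a, b, c) -> np.ndarray:
    """Rotation matrix of the intrinsic Z(a)-X(b)-Y(c) Euler sequence."""
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    return np.array([
        [ca * cc - sa * sb * sc, -sa * cb, ca * sc + sa * sb * cc],
        [sa * cc + ca * sb * sc, ca * cb, sa * sc - ca * sb * cc],
        [-cb * sc, sb, cb * cc],
    ])


def matrix_to_euler_zxy(R: np.ndarray):
    """Inverse of :func:`euler_zxy_to_matrix`; warns near gimbal lock."""
    R = np.asarray(R)
    sb = np.clip(R[..., 2, 1], -1.0, 1.0)
    b = np.arcsin(sb)
    if np.any(np.abs(sb) > 0.999):
        warnings.warn("ZXY Euler extraction near gimbal lock (|X angle| -> 90 deg)",
                      RuntimeWarning, stacklevel=2)
    a = np.arctan2(-R[..., 0, 1], R[..., 1, 1])
    c = np.arctan2(-R[..., 2, 0], R[..., 2, 2])
    return a, b, c


# ---------------------------------------------------------------------------
# pose fitting and contact-point kinematics
# ---------------------------------------------------------------------------

def _attach_talus(orientations, origins, model: SubjectModel, side: str):
    """Talus pose from the calcaneus via the inverse subtalar offset.

    The talus carries no markers (as in standard gait marker sets); its
    orientation copies the calcaneus and its origin back-projects the
    subtalar joint offset.
    """
    i_tal = SEGMENTS.index(f"talus_{side}")
    i_cal = SEGMENTS.index(f"calcn_{side}")
    entry = next(e for e in model.joint_tree if e["segment"] == f"calcn_{side}")
    off = entry["origin"]
    orientations[:, i_tal] = orientations[:, i_cal]
    origins[:, i_tal] = origins[:, i_cal] - np.einsum(
        "fij,j->fi", orientations[:, i_cal], off
    )


def fit_segment_poses(markers: MarkerTrajectories, model: SubjectModel) -> SegmentKinematics:
    """Per-segment rigid pose fit and joint-coordinate extraction.

    Each marker-bearing segment is registered per frame against its
    calibrated marker locals (orthogonal Procrustes); the markerless tali are
    attached to their calcanei.  COM positions map the calibrated COM offsets
    through the fitted poses; accelerations are second finite differences.
    Joint angles use the intrinsic Z-X-Y sequence (single-DOF joints keep the
    component on their axis).
    """
    F = markers.n_frames
    orientations = np.zeros((F, 12, 3, 3))
    origins = np.zeros((F, 12, 3))
    for i, seg in enumerate(SEGMENTS):
        names = model.markers_on(seg)
        if not names:
            continue  # talus: attached below
        local = np.array([model.marker_map[m][1] for m in names])
        world = np.stack([markers.get(m) for m in names], axis=1)
        if np.isnan(world).any():
            raise MissingMarkerError(names[0], f"NaN frames on segment {seg}")
        R, t = rigid_register(local, world, context=seg)
        orientations[:, i] = R
        origins[:, i] = t
    for side in ("l", "r"):
        _attach_talus(orientations, origins, model, side)

    com = origins + np.einsum("fsij,sj->fsi", orientations, model.segment_com_offsets)
    acc = differentiate(com, markers.rate, order=2)

    # ankle origins: malleolus marker midpoints (left, right)
    ank = np.zeros((F, 2, 3))
    for k, side in enumerate(("L", "R")):
        ank[:, k] = 0.5 * (markers.get(f"{side}ANK") + markers.get(f"{side}ANKM"))

    q = np.zeros((F, 23))
    tree = {e["segment"]: e for e in model.joint_tree}
    idx = {s: SEGMENTS.index(s) for s in SEGMENTS}

    def rel(child, parent):
        Rp = orientations[:, idx[parent]]
        Rc = orientations[:, idx[child]]
        return np.einsum("fji,fjk->fik", Rp, Rc)

    q[:, 0:3] = origins[:, idx["pelvis"]]
    a, b, c = matrix_to_euler_zxy(orientations[:, idx["pelvis"]])
    q[:, 3], q[:, 4], q[:, 5] = a, b, c
    a, b, c = matrix_to_euler_zxy(rel("torso", "pelvis"))
    q[:, 6], q[:, 7], q[:, 8] = a, b, c
    col = {n: j for j, n in enumerate(DOF_NAMES)}
    for side in ("r", "l"):
        a, b, c = matrix_to_euler_zxy(rel(f"femur_{side}", "pelvis"))
        q[:, col[f"hip_{side}_flexion"]] = a
        q[:, col[f"hip_{side}_adduction"]] = b
        q[:, col[f"hip_{side}_rotation"]] = c
        a, _, _ = matrix_to_euler_zxy(rel(f"tibia_{side}", f"femur_{side}"))
        q[:, col[f"knee_{side}_flexion"]] = a
        a, _, _ = matrix_to_euler_zxy(rel(f"talus_{side}", f"tibia_{side}"))
        q[:, col[f"ankle_{side}_flexion"]] = a
        _, b, _ = matrix_to_euler_zxy(rel(f"calcn_{side}", f"talus_{side}"))
        q[:, col[f"subtalar_{side}_inversion"]] = b
        a, _, _ = matrix_to_euler_zxy(rel(f"toes_{side}", f"calcn_{side}"))
        q[:, col[f"mtp_{side}_flexion"]] = a

    return SegmentKinematics(
        rate=markers.rate,
        com_positions=com,
        com_accelerations=acc,
        orientations=orientations,
        origins=origins,
        joint_angles=q,
        ankle_origins=ank,
        joint_rates=differentiate(q, markers.rate, order=1),
        joint_accels=differentiate(q, markers.rate, order=2),
    )


def compute_contact_points(kin: SegmentKinematics, model: SubjectModel) -> ContactState:
    """Contact-point trajectories from rigid foot-segment poses.

    Each point is the forward map of its calibrated local position through
    the owning segment's fitted pose; vertical velocity is the central
    finite difference of the world height; horizontal components are
    re-expressed relative to the per-frame ankle origin of the owning foot.
    """
    layout = model.contact_layout
    F = kin.n_frames
    pos = np.zeros((F, 20, 3))
    for j, pt in enumerate(layout.points):
        i = SEGMENTS.index(pt.segment)
        world = kin.origins[:, i] + np.einsum(
            "fij,j->fi", kin.orientations[:, i], pt.local_position
        )
        foot_idx = 0 if pt.foot == "left" else 1
        ank = kin.ankle_origins[:, foot_idx]
        pos[:, j, 0] = world[:, 0] - ank[:, 0]
        pos[:, j, 1] = world[:, 1]
        pos[:, j, 2] = world[:, 2] - ank[:, 2]
    vy = differentiate(pos[..., 1], kin.rate, order=1)
    return ContactState(
        rate=kin.rate,
        positions=pos,
        vertical_velocities=vy,
        foot_of_point=layout.foot_of_point,
        ankle_origin=kin.ankle_origins.copy(),
    )
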