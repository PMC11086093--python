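"""Whole-body multibody model, anthropometry and static calibration.

The skeleton is a 12-segment, 23-DOF articulated model of the kind used for
barefoot gait analysis: pelvis (6 global DOF), torso (3-DOF back joint),
and per leg a femur (3-DOF hip), tibia (1-DOF knee), talus (1-DOF ankle),
calcaneus (1-DOF subtalar) and toe segment (1-DOF metatarsophalangeal).
Ball joints and the global pelvis rotation use the intrinsic Z-X-Y Euler
sequence (flexion-extension, ab/adduction, axial rotation).

Segment masses, centre-of-mass offsets and inertia tensors follow the
published Gait2392 default subject (75.1646 kg); masses and inertias scale
linearly with subject mass while the geometry is held fixed.

Ground-contact geometry: 20 contact points, 10 per foot, attached to the
calcaneus and toe segments.  Horizontal locations come from an ankle-relative
template; vertical locations are calibrated from a static standing trial so
each point sits ``vertical_offset`` (default 30 mm) below its sole reference,
i.e. below the ground plane, which encodes the standing sole compression that
the sinkage-based force distribution reads out during gait.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .exceptions import CalibrationError, MissingMarkerError, ParameterError

GRAVITY = 9.81  # m/s^2, magnitude; +y is up
GRAVITY_VEC = np.array([0.0, -GRAVITY, 0.0])

#: canonical segment order used by every frames x 12 array in the package
SEGMENTS = (
    "pelvis", "torso",
    "femur_r", "tibia_r", "talus_r", "calcn_r", "toes_r",
    "femur_l", "tibia_l", "talus_l", "calcn_l", "toes_l",
)

#: canonical generalized-coordinate order (23 DOF)
DOF_NAMES = (
    "pelvis_tx", "pelvis_ty", "pelvis_tz",
    "pelvis_tilt", "pelvis_list", "pelvis_rotation",
    "back_flexion", "back_bending", "back_rotation",
    "hip_r_flexion", "hip_r_adduction", "hip_r_rotation",
    "knee_r_flexion", "ankle_r_flexion", "subtalar_r_inversion",
    "mtp_r_flexion",
    "hip_l_flexion", "hip_l_adduction", "hip_l_rotation",
    "knee_l_flexion", "ankle_l_flexion", "subtalar_l_inversion",
    "mtp_l_flexion",
)

# ---------------------------------------------------------------------------
# Gait2392 default-subject anthropometry (75.1646 kg reference subject)
# ---------------------------------------------------------------------------

_REFERENCE_MASS = 75.1646  # kg, sum of the reference segment masses below

_REF_SEGMENT_MASS = {
    "pelvis": 11.777, "torso": 34.2366,
    "femur": 9.3014, "tibia": 3.7075, "talus": 0.1,
    "calcn": 1.25, "toes": 0.2166,
}

# principal inertia about the segment COM, segment frame, kg m^2
_REF_INERTIA = {
    "pelvis": (0.1028, 0.0871, 0.0579),
    "torso": (1.4745, 0.7555, 1.4314),
    "femur": (0.1339, 0.0351, 0.1412),
    "tibia": (0.0504, 0.0051, 0.0511),
    "talus": (0.0010, 0.0010, 0.0010),
    "calcn": (0.0014, 0.0039, 0.0041),
    "toes": (0.0001, 0.0002, 0.0010),
}

# segment COM in the segment frame (origin at the proximal joint), right side
_COM_OFFSET = {
    "pelvis": (-0.0707, 0.0, 0.0),
    "torso": (-0.03, 0.32, 0.0),
    "femur": (0.0, -0.17, 0.0),
    "tibia": (0.0, -0.1867, 0.0),
    "talus": (0.0, 0.0, 0.0),
    "calcn": (0.1, 0.03, 0.0),
    "toes": (0.0346, 0.006, -0.0175),
}

# joint-centre location in the parent frame, right side
_JOINT_OFFSET = {
    "torso": ("pelvis", (-0.1007, 0.0815, 0.0)),
    "femur": ("pelvis", (-0.0707, -0.0661, 0.0835)),
    "tibia": ("femur", (-0.0045, -0.3962, 0.0)),
    "talus": ("tibia", (0.0, -0.43, 0.0)),
    "calcn": ("talus", (-0.04877, -0.04195, 0.00792)),
    "toes": ("calcn", (0.1788, -0.002, 0.00108)),
}

# joint DOFs per segment: (kind, local axis, dof suffix); Z-X-Y for 3-DOF joints
_ZXY = (("R", (0, 0, 1)), ("R", (1, 0, 0)), ("R", (0, 1, 0)))
_JOINT_DOFS = {
    "pelvis": (("P", (1, 0, 0)), ("P", (0, 1, 0)), ("P", (0, 0, 1))) + _ZXY,
    "torso": _ZXY,
    "femur": _ZXY,
    "tibia": (("R", (0, 0, 1)),),
    "talus": (("R", (0, 0, 1)),),
    "calcn": (("R", (1, 0, 0)),),
    "toes": (("R", (0, 0, 1)),),
}

# ---------------------------------------------------------------------------
# default 49-marker template: name -> (segment, local position), right side
# given explicitly; left side mirrored in z
# ---------------------------------------------------------------------------

_MARKER_TEMPLATE_MID = {
    "RASI": ("pelvis", (0.02, 0.02, 0.12)),
    "LASI": ("pelvis", (0.02, 0.02, -0.12)),
    "RPSI": ("pelvis", (-0.14, 0.03, 0.045)),
    "LPSI": ("pelvis", (-0.14, 0.03, -0.045)),
    "SACR": ("pelvis", (-0.15, 0.05, 0.0)),
    "C7": ("torso", (-0.05, 0.42, 0.0)),
    "CLAV": ("torso", (0.04, 0.38, 0.0)),
    "STRN": ("torso", (0.06, 0.25, 0.0)),
    "T10": ("torso", (-0.08, 0.22, 0.0)),
    "RACR": ("torso", (-0.02, 0.45, 0.18)),
    "LACR": ("torso", (-0.02, 0.45, -0.18)),
    "RHEAD": ("torso", (0.0, 0.62, 0.07)),
    "LHEAD": ("torso", (0.0, 0.62, -0.07)),
    "FHEAD": ("torso", (0.07, 0.60, 0.0)),
    "BHEAD": ("torso", (-0.07, 0.60, 0.0)),
}

_MARKER_TEMPLATE_SIDE = {
    # femur
    "THI": ("femur", (0.03, -0.15, 0.05)),
    "THI2": ("femur", (0.04, -0.25, 0.03)),
    "FTHI": ("femur", (0.06, -0.20, 0.0)),
    "KNE": ("femur", (0.0, -0.39, 0.055)),
    "KNEM": ("femur", (0.0, -0.39, -0.045)),
    # tibia; the malleolus pair defines the ankle origin
    "TIB": ("tibia", (0.02, -0.15, 0.05)),
    "TIB2": ("tibia", (0.03, -0.25, 0.04)),
    "ANK": ("tibia", (-0.005, -0.42, 0.045)),    # lateral malleolus
    "ANKM": ("tibia", (-0.005, -0.42, -0.045)),  # medial malleolus
    # calcaneus
    "HEE": ("calcn", (-0.02, 0.03, 0.0)),
    "MT5": ("calcn", (0.16, 0.015, 0.055)),
    "MT1": ("calcn", (0.17, 0.02, -0.04)),
    "MT2": ("calcn", (0.17, 0.02, 0.005)),
    "NAV": ("calcn", (0.10, 0.06, -0.02)),
    # toes
    "TOE": ("toes", (0.05, 0.01, -0.01)),
    "TOEL": ("toes", (0.03, 0.008, 0.035)),
    "TOEM": ("toes", (0.035, 0.01, -0.035)),
}

# ankle-relative contact template: (name, segment, x, z, sole reference height)
# sole heights encode unloaded sole curvature; static calibration places each
# point sole_height - vertical_offset relative to the ground, so standing
# sinkage is 30 mm at the heel, 14 mm at the metatarsals, 8 mm at the toes
# (heel-biased, matching a weight-on-heels calibration posture).
_CONTACT_TEMPLATE = (
    ("heel_med", "calcn", -0.060, -0.025, 0.000),
    ("heel_lat", "calcn", -0.060, 0.025, 0.000),
    ("met1", "calcn", 0.080, -0.045, 0.016),
    ("met2", "calcn", 0.090, -0.005, 0.016),
    ("met3", "calcn", 0.095, 0.035, 0.016),
    ("met4", "calcn", 0.070, 0.060, 0.016),
    ("toe1", "toes", 0.140, -0.035, 0.022),
    ("toe2", "toes", 0.150, 0.000, 0.022),
    ("toe3", "toes", 0.145, 0.030, 0.022),
    ("toe4", "toes", 0.170, -0.010, 0.022),
)


def _mirror(v):
    return (v[0], v[1], -v[2])


def default_marker_map() -> dict[str, tuple[str, np.ndarray]]:
    """Template marker map: name -> (segment, local position).

    49 markers; left-side locals and segments mirror the right side in z.
    """
    out = {}
    for name, (seg, loc) in _MARKER_TEMPLATE_MID.items():
        out[name] = (seg, np.array(loc, float))
    for name, (seg, loc) in _MARKER_TEMPLATE_SIDE.items():
        out["R" + name] = (seg + "_r", np.array(loc, float))
        out["L" + name] = (seg + "_l", np.array(_mirror(loc), float))
    return out


def default_mass_fractions() -> np.ndarray:
    """Unitless segment mass fractions in ``SEGMENTS`` order.

    Derived from the Gait2392 default-subject segment masses, normalized to
    sum to exactly 1.  Left/right values are identical by construction.
    """
    masses = np.array(
        [_REF_SEGMENT_MASS[s.split("_")[0]] for s in SEGMENTS], float
    )
    return masses / masses.sum()


@dataclass
class ContactPoint:
    name: str
    foot: str                  # 'left' | 'right'
    segment: str               # 'calcn_r', 'toes_l', ...
    local_position: np.ndarray  # 3, m, in the owning segment frame
    ankle_offset: np.ndarray    # (x, z) ankle-relative horizontal template, m
    sole_height: float          # unloaded sole reference height, m
    reference_height: float = 0.0  # calibrated world reference height, m


@dataclass
class ContactLayout:
    points: list[ContactPoint]
    vertical_offset: float = 0.030  # m toward the ground at calibration

    def __post_init__(self):
        if len(self.points) != 20:
            raise ParameterError(f"contact layout needs 20 points, got {len(self.points)}")
        for foot in ("left", "right"):
            n = sum(1 for p in self.points if p.foot == foot)
            if n != 10:
                raise ParameterError(f"{foot} foot has {n} contact points, needs 10")

    def foot_mask(self, foot: str) -> np.ndarray:
        return np.array([p.foot == foot for p in self.points])

    @property
    def foot_of_point(self) -> np.ndarray:
        """0 for left, 1 for right, per point."""
        return np.array([0 if p.foot == "left" else 1 for p in self.points])


@dataclass
class SubjectModel:
    """Calibrated subject: anthropometry, marker map and contact layout."""

    body_mass: float                      # kg
    segment_masses: np.ndarray            # 12, kg, SEGMENTS order
    segment_inertias: np.ndarray          # 12 x 3 x 3, kg m^2, segment frames
    segment_com_offsets: np.ndarray       # 12 x 3, m, segment frames
    joint_tree: list[dict]                # per segment: parent, origin, dofs
    marker_map: dict[str, tuple[str, np.ndarray]]
    contact_layout: ContactLayout
    vpp_offset: float = 0.0375            # m above whole-body COM, trunk frame
    p_crit: float = 0.0                   # m, critical contact height
    v_crit: float = 0.05                  # m/s, critical vertical velocity

    def __post_init__(self):
        total = float(np.sum(self.segment_masses))
        if abs(total - self.body_mass) > 1e-3 * self.body_mass:
            raise ParameterError(
                f"segment masses sum to {total:.4f} kg != body mass {self.body_mass:.4f} kg"
            )

    def segment_index(self, name: str) -> int:
        return SEGMENTS.index(name)

    def markers_on(self, segment: str) -> list[str]:
        return [m for m, (s, _) in self.marker_map.items() if s == segment]

    def copy(self) -> "SubjectModel":
        return copy.deepcopy(self)


def default_joint_tree() -> list[dict]:
    """Kinematic tree in SEGMENTS order: parent, joint origin, DOF list.

    DOF entries are (kind, local axis, global dof name) with kind 'P'
    (prismatic) or 'R' (revolute); rotations are intrinsic in listed order.
    """
    suffix_names = {
        "pelvis": ("pelvis_tx", "pelvis_ty", "pelvis_tz",
                   "pelvis_tilt", "pelvis_list", "pelvis_rotation"),
        "torso": ("back_flexion", "back_bending", "back_rotation"),
        "femur": ("hip_{s}_flexion", "hip_{s}_adduction", "hip_{s}_rotation"),
        "tibia": ("knee_{s}_flexion",),
        "talus": ("ankle_{s}_flexion",),
        "calcn": ("subtalar_{s}_inversion",),
        "toes": ("mtp_{s}_flexion",),
    }
    tree = []
    for seg in SEGMENTS:
        base, _, side = seg.partition("_")
        if base == "pelvis":
            parent, origin = None, (0.0, 0.0, 0.0)
        else:
            pbase, origin = _JOINT_OFFSET[base]
            parent = pbase if pbase == "pelvis" else f"{pbase}_{side}" if side else pbase
            if side == "l":
                origin = _mirror(origin)
        names = [n.format(s=side) for n in suffix_names[base]]
        dofs = [
            (kind, np.array(ax, float), nm)
            for (kind, ax), nm in zip(_JOINT_DOFS[base], names)
        ]
        tree.append({
            "segment": seg,
            "parent": parent,
            "origin": np.array(origin, float),
            "dofs": dofs,
        })
    return tree


def default_config() -> dict:
    """Editable model configuration (mass fractions, templates, tree)."""
    return {
        "mass_fractions": default_mass_fractions(),
        "marker_map": default_marker_map(),
        "contact_template": [list(row) for row in _CONTACT_TEMPLATE],
        "joint_tree": default_joint_tree(),
        "vertical_offset": 0.030,
        "vpp_offset": 0.0375,
        "p_crit": 0.0,
        "v_crit": 0.05,
        "stillness_tolerance": 0.005,  # m, max marker excursion in the static trial
    }


def save_config(cfg: dict, path) -> None:
    """Write the editable calibration tables to YAML.

    Covers mass fractions, the contact template, the marker map and the
    scalar thresholds; the joint tree is structural and stays in code.
    """
    import yaml

    out = {
        "mass_fractions": [float(v) for v in cfg["mass_fractions"]],
        "contact_template": [
            [str(r[0]), str(r[1]), float(r[2]), float(r[3]), float(r[4])]
            for r in cfg["contact_template"]
        ],
        "marker_map": {
            name: {"segment": seg, "local": [float(v) for v in loc]}
            for name, (seg, loc) in cfg["marker_map"].items()
        },
        "vertical_offset": float(cfg["vertical_offset"]),
        "vpp_offset": float(cfg["vpp_offset"]),
        "p_crit": float(cfg["p_crit"]),
        "v_crit": float(cfg["v_crit"]),
        "stillness_tolerance": float(cfg["stillness_tolerance"]),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)


def load_config(path) -> dict:
    """Read a YAML model config, merged over :func:`default_config`."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = default_config()
    if "mass_fractions" in raw:
        cfg["mass_fractions"] = np.asarray(raw["mass_fractions"], float)
    if "contact_template" in raw:
        cfg["contact_template"] = [list(r) for r in raw["contact_template"]]
    if "marker_map" in raw:
        cfg["marker_map"] = {
            name: (entry["segment"], np.asarray(entry["local"], float))
            for name, entry in raw["marker_map"].items()
        }
    for key in ("vertical_offset", "vpp_offset", "p_crit", "v_crit",
                "stillness_tolerance"):
        if key in raw:
            cfg[key] = float(raw[key])
    return cfg


def _scaled_anthropometry(body_mass: float):
    """Masses, inertias and COM offsets scaled to ``body_mass``."""
    scale = body_mass / _REFERENCE_MASS
    fractions = default_mass_fractions()
    masses = fractions * body_mass
    inertias = np.zeros((12, 3, 3))
    coms = np.zeros((12, 3))
    for i, seg in enumerate(SEGMENTS):
        base, _, side = seg.partition("_")
        inertias[i] = np.diag(_REF_INERTIA[base]) * scale
        com = _COM_OFFSET[base]
        coms[i] = _mirror(com) if side == "l" else com
    return masses, inertias, coms


def build_subject_model(body_mass: float, static_trial, config: dict | None = None) -> SubjectModel:
    """Calibrate a :class:`SubjectModel` from a static standing trial.

    Parameters
    ----------
    body_mass : float
        Subject mass in kg.
    static_trial : MarkerTrajectories
        A motionless standing trial (>= 0.5 s) containing every marker of the
        configured marker map, with the subject standing on the ground plane
        y = 0 and weight biased toward the heels.
    config : dict, optional
        Overrides for :func:`default_config` entries.

    The calibration (i) refines marker local positions in least-squares
    rigid-fitted segment frames and (ii) places each contact point at its
    template horizontal location relative to the per-foot ankle origin with a
    world height of ``sole_height - vertical_offset`` (30 mm toward the
    ground), expressed in the owning segment's frame.
    """
    # imported here: kinio depends on model for the segment list
    from .kinio import rigid_register

    if body_mass <= 0:
        raise ParameterError("body_mass must be positive")
    cfg = default_config()
    if config:
        cfg.update(config)

    marker_map = cfg["marker_map"]
    for name in marker_map:
        if name not in static_trial.names:
            raise MissingMarkerError(name, "static calibration trial")
    if static_trial.positions.shape[0] / static_trial.rate < 0.5:
        raise CalibrationError("static trial shorter than 0.5 s")

    pos = static_trial.positions  # frames x markers x 3
    excursion = np.linalg.norm(pos.max(axis=0) - pos.min(axis=0), axis=-1).max()
    if excursion > cfg["stillness_tolerance"]:
        raise CalibrationError(
            f"static trial moves {excursion * 1e3:.1f} mm, exceeds "
            f"{cfg['stillness_tolerance'] * 1e3:.1f} mm stillness tolerance"
        )
    mean_pos = {n: pos[:, static_trial.names.index(n)].mean(axis=0) for n in static_trial.names}

    # rigid fit of each marker-bearing segment against the template locals
    poses = {}
    for seg in SEGMENTS:
        names = [m for m, (s, _) in marker_map.items() if s == seg]
        if len(names) < 3:
            continue
        local = np.array([marker_map[m][1] for m in names])
        world = np.array([mean_pos[m] for m in names])
        R, t = rigid_register(local, world, context=seg)
        poses[seg] = (R, t)

    # refine marker locals in the fitted frames (idempotent on exact data)
    refined_map = {}
    for m, (seg, _) in marker_map.items():
        R, t = poses[seg]
        refined_map[m] = (seg, R.T @ (mean_pos[m] - t))

    masses, inertias, coms = _scaled_anthropometry(body_mass)

    points = []
    for foot, side in (("left", "l"), ("right", "r")):
        lat = mean_pos[f"{side.upper()}ANK"]
        med = mean_pos[f"{side.upper()}ANKM"]
        ankle = 0.5 * (lat + med)
        zsign = -1.0 if side == "l" else 1.0
        for name, segbase, x, z, sole in cfg["contact_template"]:
            seg = f"{segbase}_{side}"
            R, t = poses[seg]
            ref_y = float(sole)
            world = np.array([ankle[0] + x, ref_y - cfg["vertical_offset"],
                              ankle[2] + zsign * z])
            points.append(ContactPoint(
                name=f"{name}_{side}", foot=foot, segment=seg,
                local_position=R.T @ (world - t),
                ankle_offset=np.array([x, zsign * z]),
                sole_height=float(sole),
                reference_height=ref_y,
            ))
    # left foot first to match foot index 0 = left
    layout = ContactLayout(points=points, vertical_offset=cfg["vertical_offset"])

    return SubjectModel(
        body_mass=float(body_mass),
        segment_masses=masses,
        segment_inertias=inertias,
        segment_com_offsets=coms,
        joint_tree=cfg["joint_tree"],
        marker_map=refined_map,
        contact_layout=layout,
        vpp_offset=cfg["vpp_offset"],
        p_crit=cfg["p_crit"],
        v_crit=cfg["v_crit"],
    )
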