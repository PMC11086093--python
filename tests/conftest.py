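import numpy as np
import pytest

from footgrf import syngait
from footgrf.kinio import MarkerTrajectories
from footgrf.model import SEGMENTS


@pytest.fixture(scope="session")
def subject():
    """Calibrated 55.2 kg subject (study-mean mass)."""
    return syngait.default_subject(55.2)


@pytest.fixture(scope="session")
def subject70():
    return syngait.default_subject(70.0)


@pytest.fixture(scope="session")
def static_trial(subject):
    return syngait.generate_static(subject, duration=1.0)


@pytest.fixture(scope="session")
def walk_trial(subject):
    """Noise-free 4-stride walk at the default speed."""
    return syngait.generate_walk(subject, n_strides=4, speed=1.25, seed=1)


def markers_from_poses(model, poses, rate=100.0):
    """Emit marker trajectories rigidly from explicit segment poses.

    ``poses`` maps segment name -> (R, t) with R (F,3,3) or (3,3) and t
    (F,3) or (3,); segments not listed use the identity pose.
    """
    names = list(model.marker_map)
    frames = 3
    for R, t in poses.values():
        t = np.atleast_2d(t)
        frames = max(frames, t.shape[0])
    pos = np.zeros((frames, len(names), 3))
    for j, name in enumerate(names):
        seg, local = model.marker_map[name]
        R, t = poses.get(seg, (np.eye(3), np.zeros(3)))
        R = np.broadcast_to(np.atleast_3d(R).reshape(-1, 3, 3), (frames, 3, 3))
        t = np.broadcast_to(np.atleast_2d(t), (frames, 3))
        pos[:, j] = np.einsum("fij,j->fi", R, local) + t
    return MarkerTrajectories(names, pos, rate)


@pytest.fixture
def static_posed_markers(subject):
    """The subject's own static markers reconstructed from fitted poses."""
    def build(extra_poses=None, frames=60):
        from footgrf.kinio import fit_segment_poses

        trial = syngait.generate_static(subject, duration=max(0.6, frames / 100))
        kin = trial.kin
        poses = {
            seg: (kin.orientations[:frames, i], kin.origins[:frames, i])
            for i, seg in enumerate(SEGMENTS)
        }
        if extra_poses:
            poses.update(extra_poses)
        return markers_from_poses(subject, poses)

    return build
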