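"""Hand-eye calibration of the laparoscope: the fixed camera-to-marker transform.

The laparoscope carries a rigid optical-marker body (frame ``M``) tracked by
the optical tracking system (frame ``O``); the camera (frame ``C``) observes
a printed calibration plate whose own optical markers tie the plate frame to
``O``.  Each posed view of the plate yields a pair of rigid transforms, and
the fixed hand-eye transform ``T_C^M`` satisfies, for every pose,

    T_C^M = T_O^M . T_C^O

which is linear in the unknowns.  Stacking all poses gives a 12N x 12 system
with per-pose blocks

    [ I3 (x) (R_O^M)^-1   Z_{9,3} ] [ vec(R_C^M) ]   [ vec(R_C^O)                   ]
    [ Z_{3,9}   (R_O^M)^-1        ] [ t_C^M      ] = [ t_C^O + (R_O^M)^-1 . t_O^M   ]

where ``(x)`` is the Kronecker product, ``vec`` stacks columns, and ``Z`` are
zero blocks.  The system is solved jointly by dense least squares and the
rotation block is projected back to SO(3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import DegenerateMotionError, InsufficientPosesError
from .geometry import RigidTransform, compose, invert, rotation_geodesic_deg

MIN_POSES = 3
#: Pose sets whose marker rotations all lie within this geodesic angle of one
#: another are rejected as degenerate motion.
_MIN_ROTATION_SPREAD_DEG = 0.5


@dataclass(frozen=True)
class PosePair:
    """One posed view of the calibration plate.

    ``tracker_to_marker`` is the tracked pose of the plate/tracker frame in
    the laparoscope-marker frame (T_O^M, frames O -> M); ``plate_to_camera``
    is the plate pose observed by the camera, expressed as the transform from
    the camera frame to the plate frame (T_C^O, frames C -> O).  Whether a
    real tracker reports T_O^M or its inverse is device-specific; generator
    and solver here share this one convention.
    """

    tracker_to_marker: RigidTransform
    plate_to_camera: RigidTransform

    def __post_init__(self) -> None:
        a, b = self.tracker_to_marker, self.plate_to_camera
        if (a.from_frame, a.to_frame) != ("O", "M"):
            raise ValueError(f"tracker_to_marker must map O->M, got {a.from_frame}->{a.to_frame}")
        if (b.from_frame, b.to_frame) != ("C", "O"):
            raise ValueError(f"plate_to_camera must map C->O, got {b.from_frame}->{b.to_frame}")


@dataclass(frozen=True, eq=False)
class KroneckerSystem:
    """The stacked linear system: 12 rows per pose, 12 unknowns [vec(R_C^M); t_C^M]."""

    matrix: np.ndarray
    rhs: np.ndarray
    n_poses: int

    def residual(self, rotation: np.ndarray, translation: np.ndarray) -> float:
        """RMS residual of the stacked equations at a candidate solution."""
        x = np.concatenate([np.asarray(rotation).reshape(9, order="F"), np.asarray(translation).reshape(3)])
        return float(np.linalg.norm(self.matrix @ x - self.rhs) / np.sqrt(len(self.rhs)))


@dataclass(frozen=True, eq=False)
class HandEyeResult:
    """Solved hand-eye transform with its least-squares residual."""

    t_cm: RigidTransform
    residual_rms: float
    n_poses: int


def build_system(pairs: Sequence[PosePair]) -> KroneckerSystem:
    """Assemble the stacked 12N x 12 least-squares system from pose pairs."""
    if len(pairs) < MIN_POSES:
        raise InsufficientPosesError(
            f"hand-eye calibration needs at least {MIN_POSES} pose pairs, got {len(pairs)}"
        )
    blocks = []
    rhs = []
    eye3 = np.eye(3)
    for pair in pairs:
        r_om_inv = pair.tracker_to_marker.rotation.T  # (R_O^M)^-1
        t_om = pair.tracker_to_marker.translation
        block = np.zeros((12, 12))
        block[:9, :9] = np.kron(eye3, r_om_inv)
        block[9:, 9:] = r_om_inv
        blocks.append(block)
        rhs.append(pair.plate_to_camera.rotation.reshape(9, order="F"))
        rhs.append(pair.plate_to_camera.translation + r_om_inv @ t_om)
    return KroneckerSystem(np.vstack(blocks), np.concatenate(rhs), len(pairs))


def _project_to_rotation(m: np.ndarray) -> np.ndarray:
    """Nearest proper rotation (Frobenius) via SVD with determinant correction."""
    u, _, vt = np.linalg.svd(m)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def _check_rotation_diversity(pairs: Sequence[PosePair]) -> None:
    rots = [p.tracker_to_marker.rotation for p in pairs]
    spread = max(
        rotation_geodesic_deg(rots[0], r) for r in rots[1:]
    )
    if spread < _MIN_ROTATION_SPREAD_DEG:
        raise DegenerateMotionError(
            "marker rotations are (nearly) identical across all poses "
            f"(max geodesic spread {spread:.3f} deg); rotate the laparoscope "
            "between plate views to constrain the hand-eye rotation reliably"
        )


class HandEyeCalibrator(BaseEstimator):
    """Least-squares hand-eye solver over posed calibration-plate views.

    scikit-learn style estimator: ``fit`` consumes a list of
    :class:`PosePair` and exposes the solution as fitted attributes.

    Parameters
    ----------
    check_diversity : bool, default True
        Reject pose sets whose marker rotations are all identical.  The
        stacked system itself stays numerically full-rank in that case, but
        the calibration then rests on a single effective orientation and is
        untrustworthy on real data.

    Attributes
    ----------
    t_cm_ : RigidTransform
        The hand-eye transform, camera frame -> marker frame, with the
        rotation re-orthonormalized onto SO(3).
    residual_rms_ : float
        RMS residual of the stacked system at the raw (pre-projection)
        least-squares solution.
    n_poses_ : int
    """

    def __init__(self, check_diversity: bool = True):
        self.check_diversity = check_diversity

    def fit(self, pairs: Sequence[PosePair], y=None) -> "HandEyeCalibrator":
        system = build_system(pairs)
        if self.check_diversity:
            _check_rotation_diversity(pairs)
        rank = np.linalg.matrix_rank(system.matrix)
        if rank < 12:
            raise DegenerateMotionError(
                f"stacked hand-eye system is rank deficient (rank {rank} < 12); "
                "the pose set does not constrain all 12 unknowns"
            )
        x, *_ = np.linalg.lstsq(system.matrix, system.rhs, rcond=None)
        raw_rot = x[:9].reshape(3, 3, order="F")
        self.residual_rms_ = float(
            np.linalg.norm(system.matrix @ x - system.rhs) / np.sqrt(len(system.rhs))
        )
        self.t_cm_ = RigidTransform(_project_to_rotation(raw_rot), x[9:], "C", "M")
        self.n_poses_ = system.n_poses
        return self

    def result(self) -> HandEyeResult:
        return HandEyeResult(self.t_cm_, self.residual_rms_, self.n_poses_)


def solve_handeye(pairs: Sequence[PosePair]) -> HandEyeResult:
    """Solve the stacked hand-eye system; see :class:`HandEyeCalibrator`."""
    return HandEyeCalibrator().fit(pairs).result()


def handeye_residual(pairs: Sequence[PosePair], result: HandEyeResult) -> dict:
    """Per-pose consistency of a solved hand-eye against the observed plate poses.

    For each pair the plate pose predicted from the solution,
    ``(T_O^M)^-1 . T_C^M``, is compared with the observed ``T_C^O``; rotation
    errors are geodesic degrees, translation errors millimetres.
    """
    rot_err = []
    tr_err = []
    for pair in pairs:
        predicted = compose(invert(pair.tracker_to_marker), result.t_cm)
        rot_err.append(rotation_geodesic_deg(predicted.rotation, pair.plate_to_camera.rotation))
        tr_err.append(float(np.linalg.norm(predicted.translation - pair.plate_to_camera.translation)))
    rot = np.array(rot_err)
    tr = np.array(tr_err)
    return {
        "rotation_mean_deg": float(rot.mean()),
        "rotation_max_deg": float(rot.max()),
        "translation_mean_mm": float(tr.mean()),
        "translation_max_mm": float(tr.max()),
    }


def load_pose_pairs(path: Union[str, Path]) -> list[PosePair]:
    """Read a JSON array of {tracker_to_marker, plate_to_camera} transform objects."""
    entries = json.loads(Path(path).read_text())
    pairs = []
    for e in entries:
        ttm = e["tracker_to_marker"]
        ptc = e["plate_to_camera"]
        pairs.append(
            PosePair(
                RigidTransform.from_matrix(np.array(ttm["matrix"], dtype=float), "O", "M"),
                RigidTransform.from_matrix(np.array(ptc["matrix"], dtype=float), "C", "O"),
            )
        )
    return pairs


def save_pose_pairs(pairs: Sequence[PosePair], path: Union[str, Path]) -> None:
    entries = [
        {
            "tracker_to_marker": {"from": "O", "to": "M", "matrix": p.tracker_to_marker.matrix.tolist()},
            "plate_to_camera": {"from": "C", "to": "O", "matrix": p.plate_to_camera.matrix.tolist()},
        }
        for p in pairs
    ]
    Path(path).write_text(json.dumps(entries, indent=1) + "\n")
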