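"""Rigid image-to-patient registration.

Two registrations are provided:

* point-based least squares over labeled correspondences (cauterization
  marks annotated on the CT model vs. the same marks sampled on the liver
  with a tracked tool tip), solved in closed form by the classical
  centroid/cross-covariance SVD construction with determinant correction so
  the result is always a proper rotation; and
* a small point-to-point iterative closest point (ICP) refinement used to
  compensate the model-to-model shape change introduced by fiducial
  insertion.

Both are exposed as scikit-learn style estimators (``fit`` / ``transform``)
and as thin module-level functions.  The least-squares optimum is symmetric
in which frame the residual is measured in; the implementation demeans in the
image frame and reports FRE there.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateGeometryError
from .geometry import RigidTransform, invert

MIN_CORRESPONDENCES = 3
_COLLINEARITY_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class CorrespondenceSet:
    """Labeled point correspondences between image (CT) and patient frames.

    Pairing is by label (marks ``a``..``o``); both arrays are (n, 3) in mm.
    """

    image_points: np.ndarray
    patient_points: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        img = np.atleast_2d(np.asarray(self.image_points, dtype=float))
        pat = np.atleast_2d(np.asarray(self.patient_points, dtype=float))
        labels = tuple(self.labels)
        if not (len(img) == len(pat) == len(labels)):
            raise ValueError("image points, patient points and labels must have equal counts")
        if len(labels) != len(set(labels)):
            raise ValueError("mark labels must be unique")
        if len(labels) < MIN_CORRESPONDENCES:
            raise DegenerateGeometryError(
                f"rigid registration needs at least {MIN_CORRESPONDENCES} correspondences, got {len(labels)}"
            )
        object.__setattr__(self, "image_points", img)
        object.__setattr__(self, "patient_points", pat)
        object.__setattr__(self, "labels", labels)

    @classmethod
    def from_labeled(cls, image: dict[str, np.ndarray], patient: dict[str, np.ndarray]) -> "CorrespondenceSet":
        """Build from two label->point dicts, pairing on the shared labels."""
        shared = sorted(set(image) & set(patient))
        if not shared:
            raise ValueError("no shared labels between image and patient point sets")
        return cls(
            np.array([image[k] for k in shared]),
            np.array([patient[k] for k in shared]),
            tuple(shared),
        )

    def subset(self, labels: Sequence[str]) -> "CorrespondenceSet":
        idx = [self.labels.index(l) for l in labels]
        return CorrespondenceSet(self.image_points[idx], self.patient_points[idx], tuple(labels))


@dataclass(frozen=True, eq=False)
class RegistrationResult:
    """Estimated image-to-patient transform with its fiducial registration error."""

    transform: RigidTransform  # frames I -> P (i.e. T_I^P = (T_P^I)^-1)
    fre_rms: float
    n_markers: int

    @property
    def t_pi(self) -> RigidTransform:
        """The P -> I spelling used in the AR chain (inverse of ``transform``)."""
        return invert(self.transform)


def _check_not_collinear(points: np.ndarray) -> None:
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= _COLLINEARITY_TOL * max(s[0], 1.0):
        raise DegenerateGeometryError(
            "correspondence points are collinear; the rotation about their "
            "common axis is unconstrained"
        )


class RigidRegistration(BaseEstimator, TransformerMixin):
    """Closed-form rigid point-set registration (least squares via SVD).

    ``fit(X, y)`` estimates the proper rigid motion mapping source points
    ``X`` (image frame, (n, 3) mm) onto target points ``y`` (patient frame):
    both sets are demeaned, the cross-covariance is decomposed by SVD, and a
    determinant correction guards against reflections.  ``transform(X)``
    applies the fitted motion.

    Attributes
    ----------
    rotation_ : (3, 3) ndarray
    translation_ : (3,) ndarray
    transform_ : RigidTransform, frames ``from_frame`` -> ``to_frame``
    fre_ : float
        Root-mean-square residual (mm) over the points used in the fit
        (the fiducial registration error).
    """

    def __init__(self, from_frame: str = "I", to_frame: str = "P"):
        self.from_frame = from_frame
        self.to_frame = to_frame

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RigidRegistration":
        src = np.atleast_2d(np.asarray(X, dtype=float))
        dst = np.atleast_2d(np.asarray(y, dtype=float))
        if src.shape != dst.shape or src.shape[1] != 3:
            raise ValueError(f"expected matching (n, 3) arrays, got {src.shape} and {dst.shape}")
        if len(src) < MIN_CORRESPONDENCES:
            raise DegenerateGeometryError(
                f"rigid registration needs at least {MIN_CORRESPONDENCES} points, got {len(src)}"
            )
        _check_not_collinear(src)
        src_c = src - src.mean(axis=0)
        dst_c = dst - dst.mean(axis=0)
        h = src_c.T @ dst_c
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(vt.T @ u.T))
        r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
        t = dst.mean(axis=0) - r @ src.mean(axis=0)
        self.rotation_ = r
        self.translation_ = t
        self.transform_ = RigidTransform(r, t, self.from_frame, self.to_frame)
        self.fre_ = float(np.sqrt(np.mean(np.sum((src @ r.T + t - dst) ** 2, axis=1))))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.rotation_.T + self.translation_


def rigid_register_svd(c: CorrespondenceSet) -> RegistrationResult:
    """Estimate the image-to-patient transform from labeled correspondences."""
    est = RigidRegistration().fit(c.image_points, c.patient_points)
    return RegistrationResult(est.transform_, est.fre_, len(c.labels))


def fre(result: RegistrationResult, c: CorrespondenceSet) -> float:
    """RMS of ``||T . p_image - p_patient||`` over the correspondences (mm)."""
    mapped = result.transform.apply(c.image_points)
    return float(np.sqrt(np.mean(np.sum((mapped - c.patient_points) ** 2, axis=1))))


class ICPRegistration(BaseEstimator, TransformerMixin):
    """Point-to-point iterative closest point between two unlabeled clouds.

    Alternates nearest-neighbour matching (equidistant ties broken toward
    the lowest target index, for determinism) with the closed-form rigid
    fit until the mean residual changes by less than ``tol`` mm or
    ``max_iter`` is reached.  The mean residual is non-increasing across
    iterations.  No trimming by default; ``trim_fraction`` drops the worst
    matches each iteration.

    Attributes
    ----------
    transform_ : RigidTransform (source frame -> target frame)
    residuals_ : list of float, mean residual after each iteration (mm)
    n_iter_ : int
    converged_ : bool
        False when ``max_iter`` was exhausted; a warning is emitted, the
        best estimate is still returned.
    """

    def __init__(
        self,
        max_iter: int = 100,
        tol: float = 1e-4,
        trim_fraction: float = 0.0,
        from_frame: str = "I",
        to_frame: str = "I",
    ):
        self.max_iter = max_iter
        self.tol = tol
        self.trim_fraction = trim_fraction
        self.from_frame = from_frame
        self.to_frame = to_frame

    def fit(self, X: np.ndarray, y: np.ndarray, init: RigidTransform | None = None) -> "ICPRegistration":
        source = np.atleast_2d(np.asarray(X, dtype=float))
        target = np.atleast_2d(np.asarray(y, dtype=float))
        if len(source) == 0 or len(target) == 0:
            raise ValueError("ICP requires non-empty source and target clouds")
        if len(source) < 10 or len(target) < 10:
            raise DegenerateGeometryError("ICP clouds should have at least 10 points each")
        if init is None:
            r, t = np.eye(3), np.zeros(3)
        else:
            r, t = init.rotation, init.translation
        tree = cKDTree(target)  # cKDTree returns the lowest index on ties
        residuals: list[float] = []
        prev = np.inf
        converged = False
        n_keep = max(MIN_CORRESPONDENCES, int(np.ceil(len(source) * (1.0 - self.trim_fraction))))
        for iteration in range(self.max_iter):
            moved = source @ r.T + t
            dists, idx = tree.query(moved)
            if self.trim_fraction > 0:
                keep = np.argsort(dists, kind="stable")[:n_keep]
            else:
                keep = slice(None)
            est = RigidRegistration().fit(source[keep], target[idx[keep]])
            r, t = est.rotation_, est.translation_
            mean_res = float(np.mean(np.linalg.norm(source @ r.T + t - target[idx], axis=1)))
            residuals.append(mean_res)
            if mean_res < self.tol or abs(prev - mean_res) < self.tol:
                converged = True
                break
            prev = mean_res
        if not converged:
            warnings.warn(
                f"ICP did not converge within {self.max_iter} iterations "
                f"(last mean residual {residuals[-1]:.3f} mm); returning best estimate",
                RuntimeWarning,
                stacklevel=2,
            )
        self.rotation_ = r
        self.translation_ = t
        self.transform_ = RigidTransform(r, t, self.from_frame, self.to_frame)
        self.residuals_ = residuals
        self.n_iter_ = len(residuals)
        self.converged_ = converged
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.rotation_.T + self.translation_


def icp_register(
    source_cloud: np.ndarray,
    target_cloud: np.ndarray,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> RigidTransform:
    """Rigidly align ``source_cloud`` onto ``target_cloud`` by ICP."""
    est = ICPRegistration(max_iter=max_iter, tol=tol).fit(source_cloud, target_cloud, init=init)
    return est.transform_


# ---------------------------------------------------------------------------
# Point-set file I/O: labeled XYZ text ("label x y z") and JSON.

def load_labeled_points(path: Union[str, Path]) -> dict[str, np.ndarray]:
    """Read labeled points from XYZ text (``label x y z`` per line) or JSON."""
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError:
        points = {}
        for line in text.strip().splitlines():
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 4:
                raise ValueError(f"expected 'label x y z', got {line!r}")
            points[parts[0]] = np.array(parts[1:], dtype=float)
        return points
    return {k: np.asarray(v, dtype=float) for k, v in payload.items()}


def save_labeled_points(points: dict[str, np.ndarray], path: Union[str, Path]) -> None:
    lines = [f"{label} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for label, p in points.items()]
    Path(path).write_text("\n".join(lines) + "\n")
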