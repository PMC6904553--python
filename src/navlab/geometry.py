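"""Coordinate frames, rigid transforms, pinhole projection and the AR transform chain.

Frame conventions
-----------------
Five named frames are used throughout the package:

``I``
    image space (the CT scan / segmented 3D model),
``P``
    patient space on the operating table, materialised by tool-tip sampling,
``O``
    the optical tracking system,
``M``
    the rigid optical-marker body mounted on the laparoscope,
``C``
    the laparoscope camera.

A :class:`RigidTransform` with ``from_frame="A"`` and ``to_frame="B"`` maps
point coordinates expressed in frame ``A`` to coordinates in frame ``B``.  In
the field's sub/superscript notation this object is ``T_A^B`` (subscript:
source frame, superscript: destination frame); the image-to-patient transform
is therefore written either ``T_I^P`` or, as the inverse appearing in the AR
chain, ``(T_P^I)^-1`` — both denote the same estimated registration.

Camera convention: +z forward (optical axis), x right, y down, pixel origin
at the top-left corner.  3D units are millimetres, 2D units are pixels.
Lenses are modelled distortion-free (pure pinhole): the synthetic frames are
generated with the same model, so simulation and evaluation are
self-consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .exceptions import BehindCameraError, FrameMismatchError

#: Closed set of frame labels: image/CT, patient, optical tracker,
#: laparoscope marker body, camera.
FRAME_LABELS = frozenset({"I", "P", "O", "M", "C"})

_ORTHONORMALITY_TOL = 1e-9


def _check_frame(label: str) -> str:
    if label not in FRAME_LABELS:
        raise ValueError(f"unknown frame label {label!r}; expected one of {sorted(FRAME_LABELS)}")
    return label


def _check_rotation(r: np.ndarray, tol: float = _ORTHONORMALITY_TOL) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got shape {r.shape}")
    err = np.max(np.abs(r.T @ r - np.eye(3)))
    if err > tol:
        raise ValueError(f"rotation not orthonormal (max |R^T R - I| = {err:.3e} > {tol:g})")
    if np.linalg.det(r) < 0:
        raise ValueError("rotation has determinant -1 (reflection, not a rotation)")
    return r


@dataclass(frozen=True, eq=False)
class RigidTransform:
    """Proper rigid motion between two labeled coordinate frames.

    Parameters
    ----------
    rotation : (3, 3) ndarray
        Orthonormal with determinant +1 (checked to 1e-9).
    translation : (3,) ndarray
        In millimetres.
    from_frame, to_frame : str
        Labels from the closed set ``{I, P, O, M, C}``.
    """

    rotation: np.ndarray
    translation: np.ndarray
    from_frame: str
    to_frame: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")
        object.__setattr__(self, "translation", t)
        _check_frame(self.from_frame)
        _check_frame(self.to_frame)

    @classmethod
    def identity(cls, frame: str = "I", to_frame: str | None = None) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), frame, to_frame if to_frame is not None else frame)

    @classmethod
    def from_matrix(cls, m: np.ndarray, from_frame: str, to_frame: str) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"homogeneous matrix must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("bottom row of homogeneous matrix must be (0, 0, 0, 1)")
        return cls(m[:3, :3], m[:3, 3], from_frame, to_frame)

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 form with bottom row (0, 0, 0, 1)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (..., 3) from ``from_frame`` into ``to_frame``."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters mapping camera-frame 3D points (mm) to pixels.

    The model is distortion-free; ``fx, fy`` are focal lengths and
    ``cx, cy`` the principal point, all in pixels.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.image_width and 0 <= self.cy < self.image_height):
            raise ValueError("principal point must lie inside the image")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 calibration matrix K."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def contains(self, pixel: "Pixel") -> bool:
        return 0 <= pixel.u < self.image_width and 0 <= pixel.v < self.image_height


@dataclass(frozen=True)
class Pixel:
    """Continuous image coordinates; may fall outside the image (flagged, never clamped)."""

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError("pixel coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v])


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Compose two transforms: the result maps ``b.from_frame`` to ``a.to_frame``.

    Equals the matrix product of homogeneous forms, ``a.matrix @ b.matrix``.
    Frame labels are checked strictly: ``a.from_frame`` must equal
    ``b.to_frame``.
    """
    if a.from_frame != b.to_frame:
        raise FrameMismatchError(a.from_frame, b.to_frame)
    r = a.rotation @ b.rotation
    t = a.rotation @ b.translation + a.translation
    return RigidTransform(r, t, b.from_frame, a.to_frame)


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse transform: rotation transposed, translation -R^T t, frames swapped."""
    rt = t.rotation.T
    return RigidTransform(rt, -rt @ t.translation, t.to_frame, t.from_frame)


def project(k: CameraIntrinsics, p_camera: np.ndarray) -> Pixel:
    """Project one camera-frame 3D point (mm, +z forward) to a pixel.

    Raises :class:`BehindCameraError` when depth z <= 0.
    """
    x, y, z = np.asarray(p_camera, dtype=float).reshape(3)
    if z <= 0:
        raise BehindCameraError(f"point depth z = {z:.3f} mm is not in front of the camera")
    return Pixel(k.fx * x / z + k.cx, k.fy * y / z + k.cy)


def unproject(k: CameraIntrinsics, pixel: Pixel, depth: float) -> np.ndarray:
    """Back-project a pixel to the camera-frame 3D point at the given depth (mm)."""
    if depth <= 0:
        raise BehindCameraError(f"depth {depth:.3f} mm must be positive")
    return depth * (np.linalg.inv(k.matrix) @ np.array([pixel.u, pixel.v, 1.0]))


@dataclass(frozen=True, eq=False)
class ARChain:
    """The AR reprojection operator: image-frame 3D point -> pixel + camera depth.

    Built from the transform chain

        T_I^C = M_I . (T_C^M)^-1 . (T_M^O)^-1 . T_P^O . (T_P^I)^-1

    i.e. image -> patient (inverse registration) -> tracker -> laparoscope
    marker body (inverse tracked pose) -> camera (inverse hand-eye), followed
    by the pinhole intrinsics.  ``t_ic`` caches the rigid part (I -> C).
    """

    intrinsics: CameraIntrinsics
    t_ic: RigidTransform = field(repr=False)

    def __call__(self, point_image: np.ndarray) -> tuple[Pixel, float]:
        """Project one image-frame point; returns (pixel, camera depth in mm)."""
        p_cam = self.t_ic.apply(np.asarray(point_image, dtype=float).reshape(3))
        return project(self.intrinsics, p_cam), float(p_cam[2])

    def project_points(self, points_image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized projection of (n, 3) image-frame points.

        Returns (pixels (n, 2), depths (n,)); points behind the camera get
        NaN pixels and their (non-positive) depth, flagged rather than fatal.
        """
        p_cam = self.t_ic.apply(np.atleast_2d(np.asarray(points_image, dtype=float)))
        z = p_cam[:, 2]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = self.intrinsics.fx * p_cam[:, 0] / z + self.intrinsics.cx
            v = self.intrinsics.fy * p_cam[:, 1] / z + self.intrinsics.cy
        px = np.stack([u, v], axis=1)
        px[z <= 0] = np.nan
        return px, z

    def in_image(self, pixels: np.ndarray) -> np.ndarray:
        """Boolean visibility flags for (n, 2) pixel coordinates."""
        px = np.atleast_2d(pixels)
        k = self.intrinsics
        ok = np.isfinite(px).all(axis=1)
        return ok & (px[:, 0] >= 0) & (px[:, 0] < k.image_width) & (px[:, 1] >= 0) & (px[:, 1] < k.image_height)


def build_ar_chain(
    k: CameraIntrinsics,
    t_cm: RigidTransform,
    t_mo: RigidTransform,
    t_po: RigidTransform,
    t_pi: RigidTransform,
) -> ARChain:
    """Assemble the AR projection operator from its four rigid transforms.

    Parameters follow the navigation system's data sources: ``t_cm`` the
    hand-eye calibration (C -> M), ``t_mo`` the tracked laparoscope-marker
    pose (M -> O), ``t_po`` the tracked patient pose (P -> O) and ``t_pi``
    the image-to-patient registration stated as P -> I (its inverse, I -> P,
    is what the registration module estimates).  Frame labels are checked;
    with all four transforms identity the operator reduces to plain pinhole
    projection.
    """
    expected = {"t_cm": ("C", "M"), "t_mo": ("M", "O"), "t_po": ("P", "O"), "t_pi": ("P", "I")}
    for name, (f, t) in expected.items():
        tr = {"t_cm": t_cm, "t_mo": t_mo, "t_po": t_po, "t_pi": t_pi}[name]
        if (tr.from_frame, tr.to_frame) != (f, t):
            raise FrameMismatchError(f"{name} expected {f}->{t}", f"got {tr.from_frame}->{tr.to_frame}")
    # I -> P -> O -> M -> C
    t_ic = compose(invert(t_cm), compose(invert(t_mo), compose(t_po, invert(t_pi))))
    return ARChain(k, t_ic)


def pixel_error_to_mm(
    k: CameraIntrinsics, observed: Pixel, reprojected: Pixel, depth: float
) -> float:
    """Convert a 2D reprojection error to millimetres at a known depth.

    Both pixels are back-projected through the inverse calibration matrix to
    rays, scaled to ``depth`` (the camera-frame depth of the reprojected AR
    point — the only depth the navigation system knows), and the Euclidean
    distance of the two 3D points is returned.  Algebraically this equals
    ``depth * ||K^-1 (du, dv, 0)||``.
    """
    if depth <= 0:
        raise BehindCameraError(f"depth {depth:.3f} mm must be positive")
    p_obs = unproject(k, observed, depth)
    p_rep = unproject(k, reprojected, depth)
    return float(np.linalg.norm(p_obs - p_rep))


def pixel_errors_to_mm(k: CameraIntrinsics, observed: np.ndarray, reprojected: np.ndarray, depths: np.ndarray) -> np.ndarray:
    """Vectorized :func:`pixel_error_to_mm` for (n, 2) pixel arrays."""
    d = np.asarray(depths, dtype=float)
    if np.any(d <= 0):
        raise BehindCameraError("all depths must be positive")
    du = (np.asarray(observed)[:, 0] - np.asarray(reprojected)[:, 0]) / k.fx
    dv = (np.asarray(observed)[:, 1] - np.asarray(reprojected)[:, 1]) / k.fy
    return d * np.hypot(du, dv)


def rotation_geodesic_deg(r1: np.ndarray, r2: np.ndarray) -> float:
    """Geodesic angle (degrees) between two rotation matrices."""
    c = (np.trace(np.asarray(r1).T @ np.asarray(r2)) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix (sign-corrected)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_rigid_transform(
    rng: np.random.Generator,
    from_frame: str = "I",
    to_frame: str = "P",
    translation_scale: float = 100.0,
) -> RigidTransform:
    return RigidTransform(
        random_rotation(rng), rng.uniform(-translation_scale, translation_scale, 3), from_frame, to_frame
    )


# ---------------------------------------------------------------------------
# File I/O: JSON {from, to, matrix} and 4-line whitespace-separated text.

def save_transform(t: RigidTransform, path: Union[str, Path]) -> None:
    payload = {"from": t.from_frame, "to": t.to_frame, "matrix": t.matrix.tolist()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_transform(
    path: Union[str, Path], from_frame: str | None = None, to_frame: str | None = None
) -> RigidTransform:
    """Read a transform from JSON ``{from, to, matrix}`` or 4-line plain text.

    Plain-text files carry no frame labels, so ``from_frame``/``to_frame``
    must be supplied for them (and may override the JSON labels).
    """
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError:
        rows = [line.split() for line in text.strip().splitlines() if line.strip()]
        m = np.array(rows, dtype=float)
        if m.shape != (4, 4):
            raise ValueError(f"plain-text transform must be 4 lines of 4 numbers, got {m.shape}")
        if from_frame is None or to_frame is None:
            raise ValueError("plain-text transform files need explicit from_frame/to_frame")
        return RigidTransform.from_matrix(m, from_frame, to_frame)
    m = np.array(payload["matrix"], dtype=float)
    return RigidTransform.from_matrix(
        m, from_frame or payload["from"], to_frame or payload["to"]
    )


def save_intrinsics(k: CameraIntrinsics, path: Union[str, Path]) -> None:
    payload = {
        "fx": k.fx, "fy": k.fy, "cx": k.cx, "cy": k.cy,
        "width": k.image_width, "height": k.image_height,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_intrinsics(path: Union[str, Path]) -> CameraIntrinsics:
    payload = json.loads(Path(path).read_text())
    return CameraIntrinsics(
        fx=payload["fx"], fy=payload["fy"], cx=payload["cx"], cy=payload["cy"],
        image_width=payload["width"], image_height=payload["height"],
    )
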