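"""Independent oracles used by the tests.

Everything here is deliberately written against plain numpy (no navlab
internals) so the tests compare two independent routes to the same quantity.
"""

from __future__ import annotations

import numpy as np


def homogeneous(rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    m = np.eye(4)
    m[:3, :3] = rotation
    m[:3, 3] = translation
    return m


def chain_product(*matrices: np.ndarray) -> np.ndarray:
    """Left-to-right product of homogeneous matrices."""
    out = np.eye(4)
    for m in matrices:
        out = out @ m
    return out


def project_homogeneous(k: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Pinhole projection via explicit K [I|0] p and perspective divide."""
    ph = k @ np.asarray(point, dtype=float)
    return ph[:2] / ph[2]


def unproject_at_depth(k: np.ndarray, pixel: np.ndarray, depth: float) -> np.ndarray:
    return depth * (np.linalg.inv(k) @ np.array([pixel[0], pixel[1], 1.0]))


def expected_tre2(fiducials: np.ndarray, target: np.ndarray, fle2: float) -> float:
    """First-order closed-form expected TRE^2 of point-based rigid registration.

    E[TRE^2(r)] = (<FLE^2>/N) * (1 + (1/3) * sum_k d_k^2 / f_k^2), where d_k is
    the distance of the target from principal axis k of the fiducial
    configuration and f_k the RMS distance of the fiducials from that axis.
    """
    f = np.asarray(fiducials, dtype=float)
    c = f.mean(axis=0)
    centered = f - c
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    coords = centered @ vt.T  # fiducials in principal-axis coordinates
    others = [(1, 2), (0, 2), (0, 1)]
    f_axis2 = np.array([(coords[:, list(o)] ** 2).sum(axis=1).mean() for o in others])
    r = (np.asarray(target, dtype=float) - c) @ vt.T
    d_axis2 = np.array([(r[list(o)] ** 2).sum() for o in others])
    n = len(f)
    return float(fle2 / n * (1.0 + np.sum(d_axis2 / f_axis2) / 3.0))


def pairwise_user_distances(annotations_by_user: dict, labels) -> list[float]:
    """Brute-force double loop over user pairs and marks."""
    users = sorted(annotations_by_user)
    out = []
    for mark in labels:
        for i in range(len(users)):
            for j in range(i + 1, len(users)):
                a = np.asarray(annotations_by_user[users[i]][mark])
                b = np.asarray(annotations_by_user[users[j]][mark])
                out.append(float(np.linalg.norm(a - b)))
    return out


def rotation_angle_deg(r1: np.ndarray, r2: np.ndarray) -> float:
    c = (np.trace(r1.T @ r2) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
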