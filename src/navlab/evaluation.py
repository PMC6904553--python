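"""Accuracy evaluation: fiducial localization error, target registration error,
and the marker-subset resampling experiment.

FLE (fiducial localization error) is the 3D distance between a clinician's
annotation of a cauterization mark on the CT-derived model and the inserted
fiducial's ground-truth position.  TRE (target registration error) is the
error of the AR overlay measured at marks *not* used for the registration:
each held-out mark is reprojected through the full AR chain and the pixel
offset to the observed 2D centroid is converted to millimetres at the
reprojected point's camera depth through the inverse intrinsics matrix.

The marker-subset experiment mirrors the study protocol: for each condition
(user annotations on the intraoperative model, user annotations on the
preoperative/deformed model, or inserted-fiducial ground truth), a varying
number N of marks is drawn at random, the image-to-patient registration is
computed from those marks, and TRE is evaluated on the remaining marks over
all video frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import NavlabError
from .geometry import (
    ARChain,
    CameraIntrinsics,
    RigidTransform,
    invert,
    pixel_errors_to_mm,
)
from .registration import CorrespondenceSet, RigidRegistration, rigid_register_svd

CONDITIONS = ("intraop-user", "preop-user", "fiducial")

RESULTS_COLUMNS = ["trial", "condition", "user", "n_markers", "repeat", "frame", "mark", "tre_mm"]


# ---------------------------------------------------------------------------
# Trial container


@dataclass(frozen=True, eq=False)
class Frame:
    """One laparoscopic video frame: tracked camera-marker pose + 2D mark centroids."""

    t_mo: RigidTransform  # M -> O, from optical tracking
    centroids: dict[str, tuple[float, float]]  # observed pixel centroids by mark label


@dataclass
class TrialData:
    """Everything one animal trial contributes to the evaluation.

    ``marks`` are the ground-truth cauterization-mark positions on the
    intraoperative model (image frame); ``preop_marks`` the same marks on the
    deformed preoperative model; ``fiducials`` the user-independent inserted
    fiducial positions; ``annotations`` maps ``(user_id, variant)`` with
    variant in {"intraop", "preop"} to labeled image-frame points;
    ``patient_points`` are the tool-sampled mark positions in the patient
    frame.
    """

    trial_id: str
    trial_index: int
    marks: dict[str, np.ndarray]
    preop_marks: dict[str, np.ndarray]
    fiducials: dict[str, np.ndarray]
    annotations: dict[tuple[str, str], dict[str, np.ndarray]]
    patient_points: dict[str, np.ndarray]
    frames: list[Frame]
    intrinsics: CameraIntrinsics
    t_cm: RigidTransform  # hand-eye used by the navigation system
    t_po: RigidTransform  # tracked patient pose, P -> O
    t_ip_true: RigidTransform | None = None  # hidden ground truth, diagnostics only
    has_fiducials: bool = True

    @property
    def users(self) -> tuple[str, ...]:
        return tuple(sorted({u for (u, _) in self.annotations}))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.marks))

    def __post_init__(self) -> None:
        labels = set(self.marks)
        for frame in self.frames:
            extra = set(frame.centroids) - labels
            if extra:
                raise ValueError(f"frame observes unknown mark labels: {sorted(extra)}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Protocol parameters for the marker-subset resampling experiment."""

    n_markers_range: tuple[int, int] = (3, 10)  # inclusive
    repeats: int = 10
    frames_per_trial: int = 100
    seed: int = 0
    conditions: tuple[str, ...] = CONDITIONS

    def __post_init__(self) -> None:
        lo, hi = self.n_markers_range
        if lo < 3:
            raise ValueError("at least 3 markers are needed for a rigid registration")
        if self.repeats < 1 or self.frames_per_trial < 1:
            raise ValueError("repeats and frames_per_trial must be positive")
        unknown = set(self.conditions) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown conditions {sorted(unknown)}; valid: {CONDITIONS}")

    def validate_against(self, n_marks: int) -> None:
        lo, hi = self.n_markers_range
        if hi > n_marks - 1:
            raise ValueError(
                f"max n_markers {hi} must leave at least one mark for TRE "
                f"(trial has {n_marks} marks)"
            )


@dataclass
class ExperimentResult:
    """Long-format TRE records plus the registration subset of every cell."""

    records: pd.DataFrame  # columns RESULTS_COLUMNS
    subsets: pd.DataFrame  # columns trial, condition, user, n_markers, repeat, reg_marks

    def save(self, directory: Union[str, Path]) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.records.to_csv(directory / "tre_records.csv", index=False)
        self.subsets.to_csv(directory / "registration_subsets.csv", index=False)

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "ExperimentResult":
        directory = Path(directory)
        return cls(
            pd.read_csv(directory / "tre_records.csv"),
            pd.read_csv(directory / "registration_subsets.csv"),
        )


# ---------------------------------------------------------------------------
# FLE


def compute_fle(
    annotations: Mapping[str, np.ndarray],
    truth: Mapping[str, np.ndarray],
    trial: str = "",
    user: str = "",
) -> pd.DataFrame:
    """Per-mark Euclidean distance (mm) between annotations and ground truth."""
    shared = sorted(set(annotations) & set(truth))
    if not shared:
        raise NavlabError("no shared mark labels between annotations and ground truth")
    d = [float(np.linalg.norm(np.asarray(annotations[k]) - np.asarray(truth[k]))) for k in shared]
    return pd.DataFrame({"trial": trial, "user": user, "mark": shared, "fle_mm": d})


def round_half_up(x: float, decimals: int = 1) -> float:
    """Presentation rounding: half values round away from zero."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def summarize_fle(results: pd.DataFrame, group_by: str = "user") -> pd.DataFrame:
    """Mean and sample standard deviation of FLE per group.

    Groups with a single record get sigma 0 and ``std_defined`` False.
    Values are returned unrounded; round at presentation only
    (:func:`round_half_up`).
    """
    if group_by not in ("user", "trial", "mark"):
        raise ValueError("group_by must be one of user|trial|mark")
    if results.empty:
        raise NavlabError("no FLE results to summarize")
    g = results.groupby(group_by)["fle_mm"]
    out = pd.DataFrame({"mean_mm": g.mean(), "std_mm": g.std(ddof=1), "n": g.size()})
    out["std_defined"] = out["n"] > 1
    out["std_mm"] = out["std_mm"].fillna(0.0)
    return out.reset_index()


def inter_user_variability(
    annotations_by_user: Mapping[str, Mapping[str, np.ndarray]],
    labels: Sequence[str] | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Spread of annotations across clinicians.

    For every mark, Euclidean distances between all unordered user pairs are
    collected; the mean and sample standard deviation over all (mark, pair)
    distances are returned together with the per-pair table.  This pairwise
    definition is one interpretation of "inter-user variability"; the study
    protocol does not pin down a formula.
    """
    users = sorted(annotations_by_user)
    if len(users) < 2:
        raise NavlabError("inter-user variability needs at least 2 users")
    if labels is None:
        labels = sorted(set.intersection(*(set(annotations_by_user[u]) for u in users)))
    rows = []
    for mark in labels:
        for i, u1 in enumerate(users):
            for u2 in users[i + 1 :]:
                d = float(
                    np.linalg.norm(
                        np.asarray(annotations_by_user[u1][mark])
                        - np.asarray(annotations_by_user[u2][mark])
                    )
                )
                rows.append((mark, u1, u2, d))
    table = pd.DataFrame(rows, columns=["mark", "user_a", "user_b", "distance_mm"])
    return float(table["distance_mm"].mean()), float(table["distance_mm"].std(ddof=1)), table


# ---------------------------------------------------------------------------
# TRE


def compute_tre_frame(
    chain: ARChain,
    marks_image: Mapping[str, np.ndarray],
    observed: Mapping[str, tuple[float, float]],
    exclude: Iterable[str] = (),
) -> tuple[list[tuple[str, float]], list[str]]:
    """TRE (mm) for every evaluable mark in one frame.

    Marks used for the registration (``exclude``) are never evaluated; marks
    without an observed centroid in this frame are not evaluable.  Each
    remaining mark is reprojected through the AR chain and the pixel offset
    to the observation is converted to mm at the reprojected camera depth.
    Marks that land behind the camera are skipped and returned as flags.
    """
    exclude = set(exclude)
    labels = [l for l in sorted(observed) if l in marks_image and l not in exclude]
    if not labels:
        return [], []
    pts = np.array([marks_image[l] for l in labels], dtype=float)
    obs = np.array([observed[l] for l in labels], dtype=float)
    pixels, depths = chain.project_points(pts)
    ok = depths > 0
    skipped = [l for l, good in zip(labels, ok) if not good]
    if not np.any(ok):
        return [], skipped
    err = pixel_errors_to_mm(chain.intrinsics, obs[ok], pixels[ok], depths[ok])
    results = [(l, float(e)) for l, e in zip(np.array(labels)[ok], err)]
    return results, skipped


def _condition_sources(trial: TrialData, condition: str, user: str | None):
    """Image-side registration points and reprojection model for a condition."""
    if condition == "intraop-user":
        return trial.annotations[(user, "intraop")], trial.marks
    if condition == "preop-user":
        return trial.annotations[(user, "preop")], trial.preop_marks
    if condition == "fiducial":
        return trial.fiducials, trial.marks
    raise ValueError(f"unknown condition {condition!r}")


def run_marker_subset_experiment(trial: TrialData, cfg: ExperimentConfig) -> ExperimentResult:
    """The full resampling protocol for one trial.

    For every condition x user x N x repeat cell, N marks are drawn uniformly
    without replacement (one rng stream per (condition, user, N), derived
    from the master seed), the rigid registration is fit on those marks, the
    AR chain is rebuilt, and TRE is evaluated for all non-registration marks
    across all frames.  Fully reproducible from ``cfg.seed``.
    """
    cfg.validate_against(len(trial.marks))
    labels = list(trial.labels)
    frames = trial.frames[: cfg.frames_per_trial]
    # registration-independent left part of the chain, P -> C, one per frame
    left = [invert(trial.t_cm) @ invert(f.t_mo) @ trial.t_po for f in frames]
    records: list[tuple] = []
    subsets: list[tuple] = []
    lo, hi = cfg.n_markers_range
    for ci, condition in enumerate(cfg.conditions):
        if condition == "fiducial" and not trial.has_fiducials:
            continue
        users: tuple[str | None, ...] = trial.users if condition != "fiducial" else (None,)
        for ui, user in enumerate(users):
            image_points, marks_model = _condition_sources(trial, condition, user)
            for n in range(lo, hi + 1):
                rng = np.random.default_rng([cfg.seed, trial.trial_index, ci, ui, n])
                for rep in range(cfg.repeats):
                    subset = sorted(rng.choice(labels, size=n, replace=False).tolist())
                    corr = CorrespondenceSet(
                        np.array([image_points[l] for l in subset]),
                        np.array([trial.patient_points[l] for l in subset]),
                        tuple(subset),
                    )
                    reg = rigid_register_svd(corr)
                    user_label = user if user is not None else "-"
                    subsets.append(
                        (trial.trial_id, condition, user_label, n, rep, " ".join(subset))
                    )
                    for fi, (frame, left_f) in enumerate(zip(frames, left)):
                        chain = ARChain(trial.intrinsics, left_f @ reg.transform)
                        tre, _skipped = compute_tre_frame(
                            chain, marks_model, frame.centroids, exclude=subset
                        )
                        records.extend(
                            (trial.trial_id, condition, user_label, n, rep, fi, mark, v)
                            for mark, v in tre
                        )
    return ExperimentResult(
        pd.DataFrame(records, columns=RESULTS_COLUMNS),
        pd.DataFrame(
            subsets,
            columns=["trial", "condition", "user", "n_markers", "repeat", "reg_marks"],
        ),
    )


def summarize_tre(table: pd.DataFrame, group_by: str = "condition_n") -> pd.DataFrame:
    """Grouped mean +/- sigma of TRE (mm).

    ``group_by`` is ``condition_n`` (condition x number of markers, the
    layout of the per-N results tables), ``user`` or ``condition``.  Sigma is
    the sample standard deviation over records; single-record groups get 0
    with ``std_defined`` False.
    """
    keys = {
        "condition_n": ["condition", "n_markers"],
        "user": ["condition", "user"],
        "condition": ["condition"],
    }
    if group_by not in keys:
        raise ValueError("group_by must be one of condition_n|user|condition")
    if table.empty:
        raise NavlabError("no TRE records to summarize")
    g = table.groupby(keys[group_by])["tre_mm"]
    out = pd.DataFrame({"mean_mm": g.mean(), "std_mm": g.std(ddof=1), "n": g.size()})
    out["std_defined"] = out["n"] > 1
    out["std_mm"] = out["std_mm"].fillna(0.0)
    return out.reset_index()


def tre_deltas(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition decrease of mean TRE for consecutive marker counts.

    Row ``N`` holds mean TRE(N) - mean TRE(N+1), i.e. the accuracy gained by
    adding one more registration marker.
    """
    per_n = summarize_tre(table, "condition_n")
    rows = []
    for condition, sub in per_n.groupby("condition"):
        sub = sub.sort_values("n_markers")
        means = sub["mean_mm"].to_numpy()
        ns = sub["n_markers"].to_numpy()
        for i in range(len(ns) - 1):
            if ns[i + 1] == ns[i] + 1:
                rows.append((condition, int(ns[i]), int(ns[i + 1]), float(means[i] - means[i + 1])))
    return pd.DataFrame(rows, columns=["condition", "n_from", "n_to", "delta_mm"])


def compare_conditions(table: pd.DataFrame, a: str, b: str) -> dict:
    """Descriptive two-sample comparison of TRE between two conditions.

    Reports the difference of means (a - b), the pooled standard deviation,
    and a Welch two-sample statistic.  Deliberately no repeated-measures
    modelling or multiple-testing machinery.
    """
    xa = table.loc[table["condition"] == a, "tre_mm"].to_numpy()
    xb = table.loc[table["condition"] == b, "tre_mm"].to_numpy()
    if len(xa) == 0 or len(xb) == 0:
        raise NavlabError(f"condition missing from table: {a if len(xa) == 0 else b}")
    na, nb = len(xa), len(xb)
    pooled = np.sqrt(
        ((na - 1) * np.var(xa, ddof=1) + (nb - 1) * np.var(xb, ddof=1)) / (na + nb - 2)
    )
    welch = stats.ttest_ind(xa, xb, equal_var=False)
    return {
        "condition_a": a,
        "condition_b": b,
        "mean_a": float(xa.mean()),
        "mean_b": float(xb.mean()),
        "mean_difference": float(xa.mean() - xb.mean()),
        "pooled_std": float(pooled),
        "welch_t": float(welch.statistic),
        "welch_p": float(welch.pvalue),
        "n_a": na,
        "n_b": nb,
    }


# ---------------------------------------------------------------------------
# 3D registration-level TRE Monte Carlo (for validation against the
# closed-form expected-TRE prediction of point-based registration theory)


def monte_carlo_tre3d(
    marks: np.ndarray,
    fiducial_idx: Sequence[int],
    target_idx: Sequence[int],
    fle_sigma: float,
    reps: int,
    seed: int = 0,
) -> np.ndarray:
    """3D TRE samples at target marks under isotropic fiducial localization noise.

    The fiducials' image-side positions are perturbed by isotropic Gaussian
    noise of per-axis sigma ``fle_sigma`` (so E[FLE^2] = 3 sigma^2), the rigid
    registration is re-fit, and the 3D displacement of each (noise-free)
    target mark under the fitted transform is recorded.  The true transform is
    the identity, which is no loss of generality for a rigid-invariant
    registration.  Returns an array of shape (reps, n_targets) in mm.
    """
    marks = np.asarray(marks, dtype=float)
    fid = marks[list(fiducial_idx)]
    targets = marks[list(target_idx)]
    rng = np.random.default_rng(seed)
    est = RigidRegistration()
    out = np.empty((reps, len(targets)))
    for r in range(reps):
        noisy = fid + rng.normal(0.0, fle_sigma, fid.shape)
        est.fit(noisy, fid)
        out[r] = np.linalg.norm(est.transform(targets) - targets, axis=1)
    return out


# ---------------------------------------------------------------------------
# Packaged worked example: per-marker FLE table from the three fiducial trials


def load_fle_table() -> pd.DataFrame:
    """Per-marker FLE values (mm) for subjects A-C, as published; long format."""
    with resources.files("navlab.data").joinpath("fle_per_marker.csv").open() as f:
        return pd.read_csv(f)


def save_results_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table.to_csv(path, index=False)


def save_summary_json(summary: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, default=float) + "\n")
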