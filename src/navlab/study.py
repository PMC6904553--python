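"""End-to-end study orchestration: simulate trials, calibrate, register, evaluate, report.

``run_study`` composes the whole pipeline: a hand-eye calibration solved from
generated plate poses, several synthetic animal trials, the marker-subset TRE
experiment per trial, FLE and inter-user variability summaries, per-N tables,
delta tables, condition comparisons and plots.  Everything is reproducible
from the master seed (plots excepted, as files).

The default configuration is scaled down from the full protocol (100 frames
per trial, 10 repeats -> 320,000 AR frames) to stay desk-feasible:
4 trials x 20 frames x 5 repeats, ~200 registrations per condition.
``full_scale=True`` restores the full counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from . import evaluation
from .evaluation import (
    ExperimentConfig,
    ExperimentResult,
    compare_conditions,
    compute_fle,
    inter_user_variability,
    round_half_up,
    summarize_fle,
    summarize_tre,
    tre_deltas,
)
from .geometry import CameraIntrinsics, random_rigid_transform
from .handeye import solve_handeye
from .synthetic import (
    DeformationModel,
    PhantomConfig,
    TrackingModel,
    TrialConfig,
    UserModel,
    default_users,
    generate_handeye_dataset,
    generate_trial,
)

logger = logging.getLogger("navlab")

DEFAULT_INTRINSICS = CameraIntrinsics(800.0, 800.0, 480.0, 270.0, 960, 540)


@dataclass(frozen=True)
class StudyConfig:
    """Master configuration of a simulated accuracy study.

    The master seed is mandatory and drives every generator; sub-seeds are
    derived per trial and per stage.  ``n_fiducial_trials`` trials carry
    inserted fiducials (user-independent ground truth), mirroring a protocol
    where fiducials were only placed in a subset of the animals.
    """

    seed: int
    n_trials: int = 4
    n_fiducial_trials: int = 3
    n_users: int = 5
    phantom: PhantomConfig = PhantomConfig()
    deformation: DeformationModel = DeformationModel()
    tracking: TrackingModel = TrackingModel()
    intrinsics: CameraIntrinsics = DEFAULT_INTRINSICS
    sigma_intraop: float = 10.5
    preop_ratio: float = 1.45
    user_bias_scale: float = 3.0
    centroid_noise_px: float = 2.0
    insertion_displacement: float = 1.0
    insertion_rigid_angle_deg: float = 2.0
    insertion_rigid_translation_mm: float = 4.0
    handeye_poses: int = 15
    handeye_noise: tuple[float, float] = (0.0, 0.0)
    n_frames: int = 20
    repeats: int = 5
    n_markers_range: tuple[int, int] = (3, 10)
    conditions: tuple[str, ...] = evaluation.CONDITIONS
    full_scale: bool = False

    def __post_init__(self) -> None:
        if self.n_fiducial_trials > self.n_trials:
            raise ValueError("n_fiducial_trials cannot exceed n_trials")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")

    def effective(self) -> "StudyConfig":
        """Resolve the full-scale flag into concrete counts."""
        if self.full_scale:
            return replace(self, n_frames=100, repeats=10, full_scale=False)
        return self

    @classmethod
    def zero_noise(cls, seed: int, **overrides) -> "StudyConfig":
        """A fully noiseless world: the pipeline must close to numerical zero."""
        defaults = dict(
            seed=seed,
            deformation=DeformationModel(magnitude=0.0),
            tracking=TrackingModel(breathing_amplitude=0.0, jitter_sigma=0.0),
            sigma_intraop=0.0,
            user_bias_scale=0.0,
            centroid_noise_px=0.0,
            insertion_displacement=0.0,
            insertion_rigid_angle_deg=0.0,
            insertion_rigid_translation_mm=0.0,
            handeye_noise=(0.0, 0.0),
        )
        defaults.update(overrides)
        if "n_fiducial_trials" not in defaults:
            defaults["n_fiducial_trials"] = min(3, defaults.get("n_trials", 4))
        return cls(**defaults)


def load_study_config(path: Union[str, Path]) -> StudyConfig:
    """Read a study configuration from YAML or JSON.

    Nested sections (phantom, deformation, tracking, intrinsics) accept the
    corresponding dataclass fields; omitted values fall back to defaults.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    for key, cls in (
        ("phantom", PhantomConfig),
        ("deformation", DeformationModel),
        ("tracking", TrackingModel),
        ("intrinsics", CameraIntrinsics),
    ):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = cls(**raw[key])
    for key in ("n_markers_range", "conditions", "handeye_noise"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return StudyConfig(**raw)


@dataclass
class StudyReport:
    """Everything a study run produces, with optional on-disk bundle."""

    config: StudyConfig
    records: pd.DataFrame
    subsets: pd.DataFrame
    fle: pd.DataFrame
    summary: dict
    failures: list[str] = field(default_factory=list)
    output_dir: Path | None = None


def _build_users(cfg: StudyConfig) -> tuple[UserModel, ...]:
    return default_users(
        n_users=cfg.n_users,
        bias_scale=cfg.user_bias_scale,
        seed=cfg.seed + 7,
        sigma_intraop=cfg.sigma_intraop,
        preop_ratio=cfg.preop_ratio,
    )


def _trial_config(cfg: StudyConfig, index: int, users) -> TrialConfig:
    return TrialConfig(
        trial_id=f"trial{index + 1}",
        trial_index=index,
        phantom=cfg.phantom,
        deformation=cfg.deformation,
        tracking=cfg.tracking,
        users=users,
        intrinsics=cfg.intrinsics,
        n_frames=cfg.n_frames,
        centroid_noise_px=cfg.centroid_noise_px,
        has_fiducials=index < cfg.n_fiducial_trials,
        insertion_displacement=cfg.insertion_displacement,
        insertion_rigid_angle_deg=cfg.insertion_rigid_angle_deg,
        insertion_rigid_translation_mm=cfg.insertion_rigid_translation_mm,
        seed=cfg.seed * 1000 + index * 10 + 11,
    )


def run_study(cfg: StudyConfig, output_dir: Union[str, Path, None] = None) -> StudyReport:
    """Run the full simulated accuracy study.

    Solves one hand-eye calibration, generates ``n_trials`` trials, runs the
    marker-subset experiment for every trial and condition, and assembles the
    summary (condition means, per-N means, deltas, comparisons, FLE,
    inter-user variability).  A trial that fails is recorded in
    ``report.failures`` and the study continues.  When ``output_dir`` is
    given, CSV tables, plots and a JSON summary are written there.
    """
    cfg = cfg.effective()
    t0 = time.time()
    rng = np.random.default_rng(cfg.seed)
    true_t_cm = random_rigid_transform(rng, "C", "M", translation_scale=120.0)
    pairs = generate_handeye_dataset(
        true_t_cm, cfg.handeye_poses, noise=cfg.handeye_noise, seed=cfg.seed + 1
    )
    handeye = solve_handeye(pairs)
    logger.info("hand-eye solved from %d poses, residual %.3e", handeye.n_poses, handeye.residual_rms)

    users = _build_users(cfg)
    exp_cfg = ExperimentConfig(
        n_markers_range=cfg.n_markers_range,
        repeats=cfg.repeats,
        frames_per_trial=cfg.n_frames,
        seed=cfg.seed,
        conditions=cfg.conditions,
    )

    all_records, all_subsets, fle_frames, failures = [], [], [], []
    annotations_by_trial = {}
    for i in range(cfg.n_trials):
        tcfg = _trial_config(cfg, i, users)
        stage_start = time.time()
        try:
            trial = generate_trial(tcfg, handeye.t_cm)
            result = evaluation.run_marker_subset_experiment(trial, exp_cfg)
        except Exception as exc:  # partial failure: record and continue
            logger.exception("trial %s failed", tcfg.trial_id)
            failures.append(f"{tcfg.trial_id}: {exc}")
            continue
        all_records.append(result.records)
        all_subsets.append(result.subsets)
        annotations_by_trial[tcfg.trial_id] = trial
        if trial.has_fiducials:
            for user in trial.users:
                fle_frames.append(
                    compute_fle(
                        trial.annotations[(user, "intraop")],
                        trial.fiducials,
                        trial=trial.trial_id,
                        user=user,
                    )
                )
        logger.info("trial %s done in %.1f s", tcfg.trial_id, time.time() - stage_start)

    if not all_records:
        raise RuntimeError(f"all trials failed: {failures}")
    records = pd.concat(all_records, ignore_index=True)
    subsets = pd.concat(all_subsets, ignore_index=True)
    fle = (
        pd.concat(fle_frames, ignore_index=True)
        if fle_frames
        else pd.DataFrame(columns=["trial", "user", "mark", "fle_mm"])
    )

    summary = _summarize(cfg, records, fle, annotations_by_trial, handeye)
    summary["runtime_s"] = round(time.time() - t0, 2)
    summary["failures"] = failures

    report = StudyReport(cfg, records, subsets, fle, summary, failures)
    if output_dir is not None:
        report.output_dir = Path(output_dir)
        _write_bundle(report)
    return report


def _summarize(cfg, records, fle, trials, handeye) -> dict:
    per_condition = summarize_tre(records, "condition")
    per_n = summarize_tre(records, "condition_n")
    deltas = tre_deltas(records)
    cond_means = dict(zip(per_condition["condition"], per_condition["mean_mm"]))

    inter_user = {}
    for variant in ("intraop", "preop"):
        dists = []
        for trial in trials.values():
            by_user = {u: trial.annotations[(u, variant)] for u in trial.users}
            if len(by_user) >= 2:
                mean, std, _ = inter_user_variability(by_user)
                dists.append((mean, std))
        if dists:
            inter_user[variant] = {
                "mean_mm": float(np.mean([m for m, _ in dists])),
                "std_mm": float(np.mean([s for _, s in dists])),
            }

    comparisons = {}
    for a, b in (("preop-user", "intraop-user"), ("intraop-user", "fiducial")):
        if {a, b} <= set(records["condition"].unique()):
            comparisons[f"{a}_vs_{b}"] = compare_conditions(records, a, b)

    summary = {
        "seed": cfg.seed,
        "n_trials": int(records["trial"].nunique()),
        "n_records": int(len(records)),
        "handeye_residual_rms": handeye.residual_rms,
        "condition_mean_tre_mm": cond_means,
        "per_n_mean_tre_mm": {
            cond: {
                int(n): float(m)
                for n, m in zip(sub["n_markers"], sub["mean_mm"])
            }
            for cond, sub in per_n.groupby("condition")
        },
        "tre_deltas_mm": deltas.to_dict(orient="records"),
        "comparisons": comparisons,
        "inter_user_variability_mm": inter_user,
    }
    if not fle.empty:
        by_user = summarize_fle(fle, "user")
        summary["fle_mean_mm"] = float(fle["fle_mm"].mean())
        summary["fle_std_mm"] = float(fle["fle_mm"].std(ddof=1))
        summary["fle_by_user_mm"] = dict(zip(by_user["user"], by_user["mean_mm"]))
    return summary


def _write_bundle(report: StudyReport) -> None:
    out = report.output_dir
    out.mkdir(parents=True, exist_ok=True)
    ExperimentResult(report.records, report.subsets).save(out)
    report.fle.to_csv(out / "fle_records.csv", index=False)
    report_tables(report.records, report.fle, out)
    (out / "summary.json").write_text(json.dumps(report.summary, indent=2, default=float) + "\n")
    _plots(report, out)
    logger.info("report bundle written to %s", out)


def report_tables(
    records: pd.DataFrame, fle: pd.DataFrame, out_dir: Union[str, Path]
) -> dict[str, pd.DataFrame]:
    """Render the per-N mean +/- sigma table, the delta table and the FLE table.

    Presentation values are rounded half-up to 1 decimal (2 for deltas); the
    raw CSVs stay unrounded.  Conditions absent from the records are omitted
    with a notice in the returned dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_n = summarize_tre(records, "condition_n")
    wide = per_n.pivot(index="n_markers", columns="condition", values=["mean_mm", "std_mm"])
    rendered = pd.DataFrame(index=wide.index)
    for cond in per_n["condition"].unique():
        rendered[cond] = [
            f"{round_half_up(m, 1)} ± {round_half_up(s, 1)}"
            for m, s in zip(wide[("mean_mm", cond)], wide[("std_mm", cond)])
        ]
    rendered.to_csv(out_dir / "tre_per_n.csv")

    deltas = tre_deltas(records)
    deltas["delta_mm"] = [round_half_up(v, 2) for v in deltas["delta_mm"]]
    deltas.to_csv(out_dir / "tre_deltas.csv", index=False)

    tables = {"tre_per_n": rendered, "tre_deltas": deltas}
    if not fle.empty:
        fle_user = summarize_fle(fle, "user")
        fle_user["mean_mm"] = [round_half_up(v, 1) for v in fle_user["mean_mm"]]
        fle_user["std_mm"] = [round_half_up(v, 1) for v in fle_user["std_mm"]]
        fle_user.to_csv(out_dir / "fle_by_user.csv", index=False)
        tables["fle_by_user"] = fle_user
    missing = set(evaluation.CONDITIONS) - set(records["condition"].unique())
    if missing:
        tables["notice"] = f"conditions absent from results: {sorted(missing)}"
    return tables


def render_report_tables(results_dir: Union[str, Path]) -> dict[str, pd.DataFrame]:
    """Re-render tables from a previously written results directory."""
    results_dir = Path(results_dir)
    missing = [
        str(p) for p in (results_dir / "tre_records.csv", results_dir / "fle_records.csv")
        if not p.exists()
    ]
    if missing:
        raise FileNotFoundError(f"missing result files: {missing}")
    records = pd.read_csv(results_dir / "tre_records.csv")
    fle = pd.read_csv(results_dir / "fle_records.csv")
    return report_tables(records, fle, results_dir)


def _plots(report: StudyReport, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    per_n = summarize_tre(report.records, "condition_n")
    fig, ax = plt.subplots(figsize=(6, 4))
    for cond, sub in per_n.groupby("condition"):
        sub = sub.sort_values("n_markers")
        ax.errorbar(sub["n_markers"], sub["mean_mm"], yerr=sub["std_mm"], marker="o", capsize=3, label=cond)
    ax.set_xlabel("number of registration markers N")
    ax.set_ylabel("TRE [mm]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "tre_vs_n.png", dpi=120)
    plt.close(fig)

    deltas = tre_deltas(report.records)
    if not deltas.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        for cond, sub in deltas.groupby("condition"):
            ax.plot(sub["n_from"], sub["delta_mm"], marker="s", label=cond)
        ax.axhline(0.0, color="gray", lw=0.8)
        ax.set_xlabel("N (delta = mean TRE(N) - mean TRE(N+1))")
        ax.set_ylabel("TRE decrease [mm]")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "tre_deltas.png", dpi=120)
        plt.close(fig)

    if not report.fle.empty:
        fig, ax = plt.subplots(figsize=(6, 4))
        report.fle.boxplot(column="fle_mm", by="user", ax=ax)
        ax.set_ylabel("FLE [mm]")
        fig.suptitle("")
        ax.set_title("per-user fiducial localization error")
        fig.tight_layout()
        fig.savefig(out_dir / "fle_by_user.png", dpi=120)
        plt.close(fig)
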