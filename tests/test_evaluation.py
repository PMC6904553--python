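import numpy as np
import pandas as pd
import pytest

from navlab.evaluation import (
    ExperimentConfig,
    compare_conditions,
    compute_fle,
    compute_tre_frame,
    inter_user_variability,
    load_fle_table,
    round_half_up,
    run_marker_subset_experiment,
    summarize_fle,
    summarize_tre,
    tre_deltas,
)
from navlab.exceptions import NavlabError
from navlab.geometry import ARChain, RigidTransform, build_ar_chain, invert
from navlab.synthetic import TrialConfig, UserModel, generate_trial

from _oracles import pairwise_user_distances


@pytest.fixture(scope="module")
def noiseless_trial():
    from navlab.geometry import random_rigid_transform

    rng = np.random.default_rng(77)
    t_cm = random_rigid_transform(rng, "C", "M", 120.0)
    from navlab.synthetic import DeformationModel, TrackingModel

    cfg = TrialConfig(
        trial_id="t0",
        trial_index=0,
        deformation=DeformationModel(magnitude=0.0),
        tracking=TrackingModel(breathing_amplitude=0.0, jitter_sigma=0.0),
        users=(UserModel("A", sigma_intraop=0.0),),
        n_frames=6,
        centroid_noise_px=0.0,
        seed=9,
    )
    return generate_trial(cfg, t_cm)


class TestFLE:
    def test_exact_annotations_give_zero(self, rng):
        truth = {c: rng.uniform(-50, 50, 3) for c in "abc"}
        table = compute_fle(truth, truth)
        assert (table["fle_mm"] == 0).all()

    def test_345_offset(self, rng):
        truth = {c: rng.uniform(-50, 50, 3) for c in "abc"}
        ann = {k: v.copy() for k, v in truth.items()}
        ann["b"] = ann["b"] + np.array([3.0, 4.0, 0.0])
        table = compute_fle(ann, truth).set_index("mark")
        assert table.loc["b", "fle_mm"] == pytest.approx(5.0, abs=1e-12)
        assert table.loc["a", "fle_mm"] == 0.0

    def test_no_shared_labels_errors(self):
        with pytest.raises(NavlabError, match="shared"):
            compute_fle({"a": np.zeros(3)}, {"b": np.zeros(3)})

    @pytest.mark.parametrize("subject,expected", [("A", 29.4), ("B", 31.6), ("C", 28.5)])
    def test_published_per_marker_table_row_means(self, subject, expected):
        table = load_fle_table()
        row = table[table["subject"] == subject]
        assert len(row) == 15
        assert round_half_up(row["fle_mm"].mean(), 1) == expected

    def test_summarize_single_value_flags_undefined_sigma(self):
        df = pd.DataFrame({"trial": ["t"], "user": ["A"], "mark": ["a"], "fle_mm": [4.2]})
        out = summarize_fle(df, "user")
        assert out.loc[0, "mean_mm"] == 4.2
        assert out.loc[0, "std_mm"] == 0.0
        assert not out.loc[0, "std_defined"]


class TestRounding:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [(29.35, 1, 29.4), (29.44999, 1, 29.4), (2.5, 0, 3.0), (-0.05, 1, -0.1), (1.25, 1, 1.3)],
    )
    def test_half_up(self, value, decimals, expected):
        assert round_half_up(value, decimals) == expected


class TestInterUserVariability:
    def test_identical_users_give_zero(self, rng):
        ann = {c: rng.uniform(-50, 50, 3) for c in "abcd"}
        mean, std, _ = inter_user_variability({"A": ann, "B": ann, "C": ann})
        assert mean == 0.0 and std == 0.0

    def test_constant_offset_pair(self, rng):
        ann = {c: rng.uniform(-50, 50, 3) for c in "abcd"}
        shifted = {k: v + np.array([10.0, 0, 0]) for k, v in ann.items()}
        mean, std, _ = inter_user_variability({"A": ann, "B": shifted})
        assert mean == pytest.approx(10.0, abs=1e-12)
        assert std == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self, rng):
        by_user = {
            u: {c: rng.uniform(-50, 50, 3) for c in "abcde"} for u in ("A", "B", "C")
        }
        mean, std, table = inter_user_variability(by_user)
        oracle = pairwise_user_distances(by_user, sorted("abcde"))
        assert mean == pytest.approx(np.mean(oracle), abs=1e-12)
        assert std == pytest.approx(np.std(oracle, ddof=1), abs=1e-12)
        assert len(table) == len(oracle)

    def test_single_user_errors(self):
        with pytest.raises(NavlabError):
            inter_user_variability({"A": {"a": np.zeros(3)}})


class TestComputeTREFrame:
    def test_perfect_world_gives_zero(self, noiseless_trial):
        trial = noiseless_trial
        chain = build_ar_chain(
            trial.intrinsics,
            trial.t_cm,
            trial.frames[0].t_mo,
            trial.t_po,
            invert(trial.t_ip_true),
        )
        tre, skipped = compute_tre_frame(chain, trial.marks, trial.frames[0].centroids)
        assert not skipped
        assert max(v for _, v in tre) < 1e-6

    def test_in_plane_translation_appears_as_tre(self, noiseless_trial):
        # shift the registration parallel to the image plane of a frame
        trial = noiseless_trial
        frame = trial.frames[0]
        left = invert(trial.t_cm) @ invert(frame.t_mo) @ trial.t_po
        # 10 mm along the camera x axis, expressed in the patient frame
        offset_p = left.rotation.T @ np.array([10.0, 0.0, 0.0])
        shifted = RigidTransform(
            trial.t_ip_true.rotation,
            trial.t_ip_true.translation + offset_p,
            "I",
            "P",
        )
        chain = ARChain(trial.intrinsics, left @ shifted)
        tre, _ = compute_tre_frame(chain, trial.marks, frame.centroids)
        values = np.array([v for _, v in tre])
        assert np.allclose(values, 10.0, rtol=1e-6)

    def test_excluded_labels_absent_from_output(self, noiseless_trial):
        trial = noiseless_trial
        chain = build_ar_chain(
            trial.intrinsics,
            trial.t_cm,
            trial.frames[0].t_mo,
            trial.t_po,
            invert(trial.t_ip_true),
        )
        tre, _ = compute_tre_frame(
            chain, trial.marks, trial.frames[0].centroids, exclude={"a", "b", "c"}
        )
        labels = {l for l, _ in tre}
        assert labels.isdisjoint({"a", "b", "c"})
        assert labels == set(trial.marks) - {"a", "b", "c"}


class TestMarkerSubsetExperiment:
    def test_zero_noise_trial_gives_zero_tre(self, noiseless_trial):
        cfg = ExperimentConfig(n_markers_range=(3, 6), repeats=2, frames_per_trial=4, seed=2)
        result = run_marker_subset_experiment(noiseless_trial, cfg)
        assert len(result.records) > 0
        assert result.records["tre_mm"].max() < 1e-6

    def test_same_seed_reproduces_identical_tables(self, noiseless_trial):
        cfg = ExperimentConfig(n_markers_range=(3, 5), repeats=2, frames_per_trial=3, seed=4)
        a = run_marker_subset_experiment(noiseless_trial, cfg)
        b = run_marker_subset_experiment(noiseless_trial, cfg)
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.subsets, b.subsets)

    def test_registration_marks_never_evaluated(self, noiseless_trial):
        cfg = ExperimentConfig(n_markers_range=(3, 6), repeats=2, frames_per_trial=3, seed=6)
        result = run_marker_subset_experiment(noiseless_trial, cfg)
        merged = result.records.merge(
            result.subsets, on=["trial", "condition", "user", "n_markers", "repeat"]
        )
        overlap = [
            mark in regs.split()
            for mark, regs in zip(merged["mark"], merged["reg_marks"])
        ]
        assert not any(overlap)

    def test_invalid_config_rejected_before_compute(self, noiseless_trial):
        with pytest.raises(ValueError):
            ExperimentConfig(n_markers_range=(2, 5))
        cfg = ExperimentConfig(n_markers_range=(3, 15))
        with pytest.raises(ValueError, match="at least one mark"):
            run_marker_subset_experiment(noiseless_trial, cfg)


class TestSummaries:
    @staticmethod
    def _fixture_table():
        rows = []
        # two conditions with hand-computed group means: 2.0 and 5.0
        for i, v in enumerate([1.0, 2.0, 3.0]):
            rows.append(("t", "intraop-user", "A", 3, 0, i, "d", v))
        for i, v in enumerate([4.0, 5.0, 6.0]):
            rows.append(("t", "preop-user", "A", 3, 0, i, "d", v))
        return pd.DataFrame(
            rows,
            columns=["trial", "condition", "user", "n_markers", "repeat", "frame", "mark", "tre_mm"],
        )

    def test_known_group_means(self):
        out = summarize_tre(self._fixture_table(), "condition").set_index("condition")
        assert out.loc["intraop-user", "mean_mm"] == pytest.approx(2.0)
        assert out.loc["preop-user", "mean_mm"] == pytest.approx(5.0)
        assert out.loc["intraop-user", "std_mm"] == pytest.approx(1.0)

    def test_single_record_flags_sigma(self):
        table = self._fixture_table().iloc[[0]]
        out = summarize_tre(table, "condition")
        assert out.loc[0, "mean_mm"] == 1.0 and not out.loc[0, "std_defined"]

    def test_deltas_of_monotone_sequence_are_nonnegative(self):
        rows = []
        for n, mean in [(3, 9.0), (4, 7.0), (5, 6.5), (6, 6.4)]:
            for i in range(3):
                rows.append(("t", "intraop-user", "A", n, 0, i, "d", mean))
        table = pd.DataFrame(
            rows,
            columns=["trial", "condition", "user", "n_markers", "repeat", "frame", "mark", "tre_mm"],
        )
        deltas = tre_deltas(table)
        assert (deltas["delta_mm"] >= 0).all()
        assert deltas.loc[deltas["n_from"] == 3, "delta_mm"].iloc[0] == pytest.approx(2.0)


class TestCompareConditions:
    @staticmethod
    def _table(a_values, b_values):
        rows = [("t", "intraop-user", "A", 3, 0, i, "d", v) for i, v in enumerate(a_values)]
        rows += [("t", "fiducial", "-", 3, 0, i, "d", v) for i, v in enumerate(b_values)]
        return pd.DataFrame(
            rows,
            columns=["trial", "condition", "user", "n_markers", "repeat", "frame", "mark", "tre_mm"],
        )

    def test_identical_groups_zero_difference(self, rng):
        v = rng.uniform(5, 15, 50)
        out = compare_conditions(self._table(v, v), "intraop-user", "fiducial")
        assert out["mean_difference"] == pytest.approx(0.0, abs=1e-12)

    def test_recovers_known_mean_shift(self, rng):
        a = rng.normal(40.0, 1.0, 500)
        b = rng.normal(20.0, 1.0, 500)
        out = compare_conditions(self._table(a, b), "intraop-user", "fiducial")
        assert out["mean_difference"] == pytest.approx(20.0, abs=0.2)
        assert out["welch_p"] < 1e-10

    def test_swapped_arguments_negate_difference(self, rng):
        a = rng.normal(30.0, 2.0, 100)
        b = rng.normal(20.0, 2.0, 100)
        t = self._table(a, b)
        x = compare_conditions(t, "intraop-user", "fiducial")
        y = compare_conditions(t, "fiducial", "intraop-user")
        assert x["mean_difference"] == pytest.approx(-y["mean_difference"], abs=1e-12)

    def test_missing_condition_errors(self, rng):
        t = self._table(rng.normal(30, 1, 10), rng.normal(20, 1, 10))
        with pytest.raises(NavlabError):
            compare_conditions(t, "intraop-user", "preop-user")
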