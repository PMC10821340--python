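"""Metrics, LOSO splits, dataset selection and grid bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from eewalk import evaluate as ev
from eewalk.evaluate import (
    DATASET_DEFS,
    loso_splits,
    mape,
    nrmse,
    run_experiment_grid,
    select_dataset,
)
from eewalk.models import build_mlp
from eewalk.preprocess import ScalerParams
from eewalk.simulator import Activity, BodyLocation, TrialCondition, standard_conditions
from eewalk.train import TrainConfig
from tests.conftest import make_dummy_trial


class TestMetrics:
    def test_perfect_prediction(self):
        assert nrmse([10.0, 20.0], [10.0, 20.0], 70.0) == 0.0
        assert mape([10.0, 20.0], [10.0, 20.0]) == 0.0

    def test_hand_values(self):
        # RMSE = sqrt((1+1)/2) = 1 W over 70 kg
        assert nrmse([10.0, 12.0], [11.0, 11.0], 70.0) == pytest.approx(1 / 70)
        assert mape([90.0], [100.0]) == pytest.approx(10.0)

    def test_loop_oracles(self):
        rng = np.random.default_rng(1)
        p, t = rng.uniform(100, 800, 20), rng.uniform(100, 800, 20)
        loop_rmse = np.sqrt(sum((pi - ti) ** 2 for pi, ti in zip(p, t)) / 20)
        assert nrmse(p, t, 72.0) == pytest.approx(loop_rmse / 72.0, abs=1e-12)
        loop_mape = 100 * sum(abs(pi - ti) / ti for pi, ti in zip(p, t)) / 20
        assert mape(p, t) == pytest.approx(loop_mape, abs=1e-12)

    def test_nrmse_homogeneity(self):
        p, t = np.array([10.0, 12.0]), np.array([11.0, 11.0])
        assert nrmse(2 * p, 2 * t, 70.0) == pytest.approx(2 * nrmse(p, t, 70.0))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            nrmse([1.0], [1.0], 0.0)
        with pytest.raises(ValueError):
            mape([1.0], [0.0])
        with pytest.raises(ValueError):
            nrmse([1.0], [1.0, 2.0], 70.0)


class TestLosoSplits:
    def test_seven_subjects_seven_folds(self):
        ids = [f"S{i}" for i in range(7)]
        folds = loso_splits(ids)
        assert len(folds) == 7
        assert sorted(test for _, test in folds) == sorted(ids)
        for train, test in folds:
            assert len(train) == 6
            assert test not in train

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            loso_splits(["a", "a", "b"])

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            loso_splits(["a"])


class TestSelectDataset:
    @pytest.fixture()
    def protocol_trials(self, subject):
        return [make_dummy_trial(subject, c) for c in standard_conditions()]

    @pytest.mark.parametrize("ds,expected", [("D1", 6), ("D2", 4), ("D3", 8)])
    def test_conditions_per_subject(self, protocol_trials, ds, expected):
        assert len(select_dataset(protocol_trials, DATASET_DEFS[ds])) == expected

    def test_d1_excludes_running(self, protocol_trials):
        out = select_dataset(protocol_trials, DATASET_DEFS["D1"])
        assert all(t.condition.activity is not Activity.LEVEL_RUN for t in out)


class TestEvaluateFold:
    def test_constant_predictor_on_matching_truth_is_exact(self, walk_trial):
        """A model that always outputs the trial's truth has zero error."""
        from eewalk import metabolic
        truth = metabolic.trial_ground_truth(walk_trial.breaths, walk_trial.condition).ee_w
        model = build_mlp(seed=0)
        for _, layer, key, arr in model.net.named_params():
            layer.params[key] = np.zeros_like(arr)
        model.scalers = ScalerParams(
            channel_mean=np.zeros(6), channel_sd=np.ones(6),
            y_min=truth, y_max=truth + 1.0,
            feat_min=np.array([60.0, 1.6]), feat_max=np.array([85.0, 1.9]),
        )
        fold = ev.evaluate_fold(model, [walk_trial], BodyLocation.SHANK,
                                input_format="stride", fs=100.0)
        assert fold.nrmse_w_per_kg == pytest.approx(0.0, abs=1e-9)
        assert fold.mape_pct == pytest.approx(0.0, abs=1e-9)
        assert fold.n_test_predictions == len(fold.per_trial) * fold.per_trial["n"][0]

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            ev.evaluate_fold(build_mlp(), [], BodyLocation.SHANK)


class TestExperimentGrid:
    @pytest.fixture(scope="module")
    def small_trials(self):
        from eewalk.simulator import standard_protocol
        return standard_protocol(2, seed=3, locations=[BodyLocation.SHANK])

    def _grid_kwargs(self):
        return dict(
            datasets=["D2"],
            locations=[BodyLocation.SHANK],
            archs=["mlp"],
            formats=[(2.0, 100.0)],
            hop_s=4.0,
            train_cfg=TrainConfig(epochs=2, batch_size=64, seed=0),
            base_seed=11,
        )

    def test_one_row_per_cell_and_fold(self, small_trials):
        report = run_experiment_grid(small_trials, **self._grid_kwargs())
        assert len(report.rows) == 2  # 1 cell x 2 LOSO folds
        assert set(report.rows["fold"]) == {"S01", "S02"}
        assert (report.rows["nrmse_w_kg"] >= 0).all()
        means = report.cell_means()
        assert len(means) == 1 and means["n_folds"][0] == 2

    def test_rerun_reproduces_report(self, small_trials):
        r1 = run_experiment_grid(small_trials, **self._grid_kwargs())
        r2 = run_experiment_grid(small_trials, **self._grid_kwargs())
        pd.testing.assert_frame_equal(r1.rows, r2.rows)

    def test_failed_cell_recorded_grid_continues(self, small_trials):
        kw = self._grid_kwargs()
        kw["locations"] = [BodyLocation.CHEST, BodyLocation.SHANK]  # chest not simulated
        report = run_experiment_grid(small_trials, **kw)
        assert len(report.rows) == 2  # shank cells still completed
        assert len(report.errors) == 2
        assert all(e["location"] == "chest" for e in report.errors)
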