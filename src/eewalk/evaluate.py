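"""Leave-one-subject-out evaluation and the experiment grid.

Metrics follow the field's conventions for steady-state EE estimation:
NRMSE is the root-mean-square error normalized by the held-out subject's
body weight (W/kg), MAPE the mean absolute percentage error against the
ground-truth EE.  Both are computed only on steady-state predictions —
windows and strides are cut exclusively from each trial's steady-state
interval, so this holds by construction — and pool all test windows of a
fold; per-trial means are carried in the report alongside.

Dataset definitions: D1 = level + inclined walking, D2 = level walking +
running, D3 = everything.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .gait import build_stride_set
from .models import ModelState, build_model, predict_set
from .preprocess import WindowSet, concat_window_sets, extract_windows
from .simulator import Activity, BodyLocation, Trial
from .train import TrainConfig, train_model

__all__ = [
    "DatasetDef",
    "DATASET_DEFS",
    "FoldResult",
    "EvaluationReport",
    "nrmse",
    "mape",
    "loso_splits",
    "select_dataset",
    "build_input_set",
    "evaluate_fold",
    "run_experiment_grid",
]


@dataclass(frozen=True)
class DatasetDef:
    """Which activities a train/test dataset includes."""

    id: str
    activities: frozenset

    def __contains__(self, activity: Activity) -> bool:
        return Activity(activity) in self.activities


DATASET_DEFS: Dict[str, DatasetDef] = {
    "D1": DatasetDef("D1", frozenset({Activity.LEVEL_WALK, Activity.INCLINE_WALK})),
    "D2": DatasetDef("D2", frozenset({Activity.LEVEL_WALK, Activity.LEVEL_RUN})),
    "D3": DatasetDef("D3", frozenset(Activity)),
}


@dataclass
class FoldResult:
    """Pooled test metrics for one held-out subject."""

    held_out_subject: str
    nrmse_w_per_kg: float
    mape_pct: float
    n_test_predictions: int
    per_trial: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.nrmse_w_per_kg < 0 or self.mape_pct < 0:
            raise ValueError("metrics must be >= 0")


@dataclass
class EvaluationReport:
    """Flat per-(cell, fold) rows plus cell means; serializable."""

    rows: pd.DataFrame
    errors: List[dict] = field(default_factory=list)

    def cell_means(self) -> pd.DataFrame:
        keys = ["dataset", "location", "arch", "seq_s", "fs_hz"]
        return (self.rows.groupby(keys, as_index=False)
                .agg(nrmse_w_kg=("nrmse_w_kg", "mean"), mape_pct=("mape_pct", "mean"),
                     n_folds=("fold", "nunique")))

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json
        payload = {
            "rows": self.rows.to_dict(orient="records"),
            "cell_means": self.cell_means().to_dict(orient="records"),
            "errors": self.errors,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# metrics


def nrmse(pred_w: np.ndarray, truth_w: np.ndarray, weight_kg: float) -> float:
    """RMSE normalized by body weight, W/kg."""
    if weight_kg <= 0:
        raise ValueError("weight_kg must be > 0")
    pred_w = np.asarray(pred_w, dtype=float)
    truth_w = np.asarray(truth_w, dtype=float)
    if pred_w.shape != truth_w.shape or pred_w.size == 0:
        raise ValueError("pred and truth must be non-empty arrays of equal shape")
    return float(np.sqrt(np.mean((pred_w - truth_w) ** 2)) / weight_kg)


def mape(pred_w: np.ndarray, truth_w: np.ndarray) -> float:
    """Mean absolute percentage error, %; truth must be strictly positive."""
    pred_w = np.asarray(pred_w, dtype=float)
    truth_w = np.asarray(truth_w, dtype=float)
    if pred_w.shape != truth_w.shape or pred_w.size == 0:
        raise ValueError("pred and truth must be non-empty arrays of equal shape")
    if np.any(truth_w <= 0):
        raise ValueError("truth values must be > 0 for MAPE")
    return float(100.0 * np.mean(np.abs(pred_w - truth_w) / truth_w))


def loso_splits(subjects: Sequence[str]) -> List[Tuple[List[str], str]]:
    """One (train ids, test id) fold per subject."""
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    if len(set(subjects)) != len(subjects):
        raise ValueError("duplicate subject ids")
    return [([s for s in subjects if s != held], held) for held in subjects]


def select_dataset(trials: Sequence[Trial], dd: DatasetDef) -> List[Trial]:
    """Trials whose activity belongs to the dataset definition."""
    return [t for t in trials if t.condition.activity in dd]


# ---------------------------------------------------------------------------
# fold machinery


def build_input_set(
    trials: Sequence[Trial],
    location: BodyLocation,
    input_format: str,
    seq_time_s: float = 2.0,
    fs: float = 100.0,
    hop_s: float = 1.0,
) -> WindowSet:
    """Window or stride sets for a list of trials, concatenated."""
    if input_format == "window":
        sets = [extract_windows(t, location, seq_time_s, fs, hop_s) for t in trials]
    elif input_format == "stride":
        sets = [build_stride_set(t, location, fs) for t in trials]
    else:
        raise ValueError(f"unknown input format {input_format!r}")
    return concat_window_sets(sets)


def evaluate_fold(
    model: ModelState,
    test_trials: Sequence[Trial],
    location: BodyLocation,
    input_format: str = "window",
    seq_time_s: float = 2.0,
    fs: float = 100.0,
    hop_s: float = 1.0,
) -> FoldResult:
    """Pooled steady-state metrics of a trained model on one held-out subject."""
    if not test_trials:
        raise ValueError("empty test set")
    subjects = {t.subject.id for t in test_trials}
    if len(subjects) != 1:
        raise ValueError("test trials must all belong to the held-out subject")
    weight = test_trials[0].subject.weight_kg

    ts = build_input_set(test_trials, location, input_format, seq_time_s, fs, hop_s)
    if len(ts) == 0:
        raise ValueError("no test windows/strides")
    pred = predict_set(model, ts)
    truth = ts.y_w

    per_trial = (pd.DataFrame({"trial": ts.meta["trial"], "pred_w": pred, "truth_w": truth})
                 .groupby("trial", as_index=False)
                 .agg(pred_w=("pred_w", "mean"), truth_w=("truth_w", "first"),
                      n=("pred_w", "size")))
    return FoldResult(
        held_out_subject=subjects.pop(),
        nrmse_w_per_kg=nrmse(pred, truth, weight),
        mape_pct=mape(pred, truth),
        n_test_predictions=len(ts),
        per_trial=per_trial,
    )


def run_fold(
    trials: Sequence[Trial],
    train_ids: Sequence[str],
    test_id: str,
    location: BodyLocation,
    arch: str,
    input_format: str,
    seq_time_s: float,
    fs: float,
    hop_s: float,
    train_cfg: TrainConfig,
    model_seed: int = 0,
) -> Tuple[ModelState, FoldResult]:
    """Train on the fold's training subjects, evaluate on the held-out one."""
    train_trials = [t for t in trials if t.subject.id in set(train_ids)]
    test_trials = [t for t in trials if t.subject.id == test_id]
    train_set = build_input_set(train_trials, location, input_format, seq_time_s, fs, hop_s)
    input_len = train_set.x.shape[1]
    model = build_model(arch, input_len=input_len, seed=model_seed)
    model, _ = train_model(model, train_set, train_cfg)
    fold = evaluate_fold(model, test_trials, location, input_format, seq_time_s, fs, hop_s)
    return model, fold


def run_experiment_grid(
    trials: Sequence[Trial],
    datasets: Sequence[str] = ("D3",),
    locations: Sequence[BodyLocation] = (BodyLocation.SHANK,),
    archs: Sequence[str] = ("cnn_lstm",),
    formats: Sequence[Tuple[float, float]] = ((2.0, 100.0),),
    hop_s: float = 1.0,
    train_cfg: TrainConfig = TrainConfig(),
    base_seed: int = 0,
    max_folds: Optional[int] = None,
) -> EvaluationReport:
    """Cross-product of datasets x locations x architectures x input formats.

    ``formats`` pairs are (sequence time s, sampling rate Hz); for the
    stride MLP the pair degenerates to the stride grid and only ``fs``
    matters.  Each cell runs LOSO (optionally truncated to ``max_folds``
    folds); a failing cell is recorded and the grid continues.  The whole
    grid is deterministic given ``base_seed``.
    """
    subjects = sorted({t.subject.id for t in trials})
    rows, errors = [], []
    cell_idx = 0
    for ds_id in datasets:
        ds_trials = select_dataset(trials, DATASET_DEFS[ds_id])
        for loc in locations:
            loc = BodyLocation(loc)
            for arch in archs:
                input_format = "stride" if arch == "mlp" else "window"
                for seq_s, fs in formats:
                    cell_idx += 1
                    folds = loso_splits(subjects)
                    if max_folds is not None:
                        folds = folds[:max_folds]
                    for fi, (train_ids, test_id) in enumerate(folds):
                        seed = base_seed + 1000 * cell_idx + fi
                        try:
                            cfg = TrainConfig(**{**train_cfg.__dict__, "seed": seed})
                            _, fold = run_fold(
                                ds_trials, train_ids, test_id, loc, arch,
                                input_format, seq_s, fs, hop_s, cfg, model_seed=seed,
                            )
                            rows.append({
                                "dataset": ds_id, "location": loc.value, "arch": arch,
                                "seq_s": seq_s, "fs_hz": fs, "fold": test_id,
                                "nrmse_w_kg": fold.nrmse_w_per_kg,
                                "mape_pct": fold.mape_pct,
                                "n_predictions": fold.n_test_predictions,
                            })
                        except Exception as exc:  # record and continue
                            errors.append({
                                "dataset": ds_id, "location": loc.value, "arch": arch,
                                "seq_s": seq_s, "fs_hz": fs, "fold": test_id,
                                "error": f"{type(exc).__name__}: {exc}",
                            })
    return EvaluationReport(rows=pd.DataFrame(rows), errors=errors)
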