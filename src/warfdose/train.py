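"""Training protocol: loss, fit statistics, sweep, repeated training.

The protocol is: MSE loss on normalized doses; at most 100 epochs with
early stopping (patience 10 epochs, minimum improvement 1e-4 in
normalized-loss units); hyperparameters tuned sequentially axis by axis
(hidden size, batch size, number of LSTM layers, learning rate), each
candidate scored by the mean test-set dose accuracy of three seeded
training replicates; the final configuration trained ten times with
different seeds and the candidate with the best test accuracy (ties
broken by lower RMSE) selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .dataset import SplitPlan, StructuredSample, build_cohort_samples
from .models import DoseModelConfig, DoseModelResults, DoseSequenceModel, ModelArtifact

__all__ = [
    "FitStats",
    "SweepPlan",
    "mse_loss",
    "fit_stats",
    "dose_accuracy",
    "train_one",
    "sweep",
    "train_repeated",
    "select_best",
]


def mse_loss(y_pred, y) -> float:
    """Mean squared error Σ(ŷᵢ − yᵢ)²/n."""
    y_pred = np.asarray(y_pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_pred.shape != y.shape:
        raise ValueError(f"length mismatch: {y_pred.shape} vs {y.shape}")
    if y_pred.size == 0:
        raise ValueError("empty vectors")
    return float(np.mean((y_pred - y) ** 2))


def dose_accuracy(y_pred, y, tol: float = 0.20) -> float:
    """Fraction of predictions within ±tol of the reference (inclusive)."""
    y_pred = np.asarray(y_pred, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.mean(np.abs(y_pred - y) <= tol * y))


@dataclass(frozen=True)
class FitStats:
    """Denormalized goodness-of-fit summary over one evaluation set."""

    mse: float
    mae: float
    rmse: float
    r2: float | None  # None when the references have zero variance
    accuracy: float  # within ±tol
    tol: float = 0.20
    n: int = 0
    label: str = ""

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "n": self.n,
            "mse": self.mse,
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "accuracy": self.accuracy,
        }


def fit_stats(y_pred, y, tol: float = 0.20, label: str = "") -> FitStats:
    """MSE/MAE/RMSE/R² plus tolerance accuracy on denormalized values."""
    y_pred = np.asarray(y_pred, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_pred.shape != y.shape:
        raise ValueError("length mismatch")
    if y.size < 2:
        raise ValueError("need n >= 2 for fit statistics")
    mse = float(np.mean((y_pred - y) ** 2))
    mae = float(np.mean(np.abs(y_pred - y)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0 else 1.0 - float(np.sum((y_pred - y) ** 2)) / ss_tot
    return FitStats(
        mse=mse,
        mae=mae,
        rmse=float(np.sqrt(mse)),
        r2=r2,
        accuracy=dose_accuracy(y_pred, y, tol),
        tol=tol,
        n=int(y.size),
        label=label,
    )


@dataclass
class FoldData:
    """Resolved train/validation samples for one fold."""

    train: tuple[StructuredSample, ...]
    val: tuple[StructuredSample, ...]


def resolve_fold(records, split: SplitPlan, fold: int = 0, target: str = "dose") -> FoldData:
    by_id = {r.patient_id: r for r in records}
    train_ids, val_ids = split.fold(fold)
    return FoldData(
        train=tuple(build_cohort_samples((by_id[i] for i in train_ids if i in by_id), target)),
        val=tuple(build_cohort_samples((by_id[i] for i in val_ids if i in by_id), target)),
    )


def train_one(
    config: DoseModelConfig,
    fold_data: FoldData,
    max_epochs: int = 100,
    patience: int = 10,
    min_delta: float = 1e-4,
    target: Literal["dose", "inr"] = "dose",
) -> DoseModelResults:
    """Train a single model on one fold under the early-stopping protocol."""
    model = DoseSequenceModel(fold_data.train, fold_data.val, config, target)
    return model.fit(max_epochs=max_epochs, patience=patience, min_delta=min_delta)


@dataclass(frozen=True)
class SweepPlan:
    """Sequential (coordinate-wise) hyperparameter search plan."""

    hidden_size: tuple[int, ...] = (32, 64, 128, 256)
    batch_size: tuple[int, ...] = (16, 32, 64)
    num_layers: tuple[int, ...] = (1, 2, 3)
    learning_rate: tuple[float, ...] = (0.001, 0.005, 0.01, 0.025, 0.05)
    reps: int = 3
    score_on: Literal["test", "val"] = "test"

    def __post_init__(self) -> None:
        for axis in ("hidden_size", "batch_size", "num_layers", "learning_rate"):
            if not getattr(self, axis):
                raise ValueError(f"empty grid for axis {axis!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")

    @property
    def axes(self) -> tuple[str, ...]:
        return ("hidden_size", "batch_size", "num_layers", "learning_rate")


def _score_config(
    config: DoseModelConfig,
    records,
    split: SplitPlan,
    reps: int,
    score_on: str,
    max_epochs: int,
    fold: int,
) -> float:
    """Mean tolerance accuracy of `reps` seeded replicates on the score set."""
    by_id = {r.patient_id: r for r in records}
    fold_data = resolve_fold(records, split, fold)
    score_samples = (
        build_cohort_samples([by_id[i] for i in split.test_ids if i in by_id])
        if score_on == "test"
        else fold_data.val
    )
    ref = np.array([s.label for s in score_samples])
    accs = []
    for rep in range(reps):
        cfg = replace(config, seed=config.seed + rep)
        res = train_one(cfg, fold_data, max_epochs=max_epochs)
        preds = res.artifact.predict_samples(score_samples)
        accs.append(dose_accuracy(preds, ref))
    return float(np.mean(accs))


def sweep(
    plan: SweepPlan,
    records,
    split: SplitPlan,
    base_config: DoseModelConfig = DoseModelConfig(),
    max_epochs: int = 100,
    fold: int = 0,
) -> tuple[DoseModelConfig, pd.DataFrame]:
    """Coordinate-wise sequential sweep.

    Axis by axis: evaluate each candidate with the other axes held at
    their current values, fix the winner, move on.  Single-candidate
    axes are adopted without training (there is nothing to compare).
    Returns the winning configuration and the full sweep table.
    """
    config = base_config
    rows = []
    for axis in plan.axes:
        candidates = getattr(plan, axis)
        if len(candidates) == 1:
            config = replace(config, **{axis: candidates[0]})
            rows.append({"axis": axis, "candidate": candidates[0], "score": None,
                         "selected": True})
            continue
        scores = []
        for cand in candidates:
            cfg = replace(config, **{axis: cand})
            score = _score_config(cfg, records, split, plan.reps, plan.score_on,
                                  max_epochs, fold)
            scores.append(score)
        best_i = int(np.argmax(scores))
        for i, (cand, score) in enumerate(zip(candidates, scores)):
            rows.append({"axis": axis, "candidate": cand, "score": score,
                         "selected": i == best_i})
        config = replace(config, **{axis: candidates[best_i]})
    return config, pd.DataFrame(rows)


def select_best(stats: Sequence[FitStats]) -> int:
    """Index of the best candidate: highest accuracy, ties → lower RMSE."""
    if not stats:
        raise ValueError("no candidates")
    order = sorted(range(len(stats)), key=lambda i: (-stats[i].accuracy, stats[i].rmse))
    return order[0]


def train_repeated(
    config: DoseModelConfig,
    records,
    split: SplitPlan,
    eval_samples: Sequence[StructuredSample] | None = None,
    reps: int = 10,
    max_epochs: int = 100,
    fold: int = 0,
    target: Literal["dose", "inr"] = "dose",
) -> tuple[list[tuple[ModelArtifact, FitStats]], ModelArtifact, pd.DataFrame]:
    """Train `reps` candidates differing only by seed and select the best.

    Candidates are ranked on ``eval_samples`` (defaults to the split's
    held-out test patients) by tolerance accuracy, ties broken by lower
    RMSE.  Returns (candidates, best artifact, selection table).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    fold_data = resolve_fold(records, split, fold, target)
    if eval_samples is None:
        by_id = {r.patient_id: r for r in records}
        eval_samples = build_cohort_samples(
            [by_id[i] for i in split.test_ids if i in by_id], target
        )
    ref = np.array([s.label for s in eval_samples])
    tol = 0.20 if target == "dose" else 0.30

    candidates: list[tuple[ModelArtifact, FitStats]] = []
    for rep in range(reps):
        cfg = replace(config, seed=config.seed + rep)
        res = train_one(cfg, fold_data, max_epochs=max_epochs, target=target)
        preds = res.artifact.predict_samples(eval_samples)
        st = fit_stats(preds, ref, tol=tol, label=f"rep{rep}")
        candidates.append((res.artifact, st))
    best_i = select_best([st for _, st in candidates])
    table = pd.DataFrame(
        [{**st.as_dict(), "seed": art.config.seed, "selected": i == best_i}
         for i, (art, st) in enumerate(candidates)]
    )
    return candidates, candidates[best_i][0], table
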