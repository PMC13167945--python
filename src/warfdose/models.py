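"""Dose-prediction model: two-branch network, Model/Results API, artifacts.

The architecture mirrors the clinical dosing network: fixed covariates
pass through a one-hidden-layer feedforward branch, the visit sequence
through stacked (optionally bidirectional) LSTM layers whose per-step
hidden states are max-pooled over valid time positions; the two
representations are concatenated and mapped linearly to one scalar —
the normalized dose (or INR) at the decision visit.

Usage follows the Model/Results convention::

    model = DoseSequenceModel.from_cohort(records, config, split=plan)
    res = model.fit()
    print(res.summary())
    doses = res.predict(external_records)

`ModelArtifact` is the serializable bundle (config, learned parameters,
normalization statistics, training log, split fingerprint) that
round-trips through ``save``/``load`` with bitwise-identical
predictions.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from . import nnet
from .core import FIXED_FEATURES, NormalizationStats, PatientRecord
from .dataset import (
    STEP_FEATURES,
    Batch,
    SplitPlan,
    StructuredSample,
    build_cohort_samples,
    build_samples,
    collate,
    compute_stats,
    denormalize_label,
)

__all__ = [
    "DoseModelConfig",
    "ModelArtifact",
    "DoseSequenceModel",
    "DoseModelResults",
    "predict_dose",
    "predict_inr",
]


@dataclass(frozen=True)
class DoseModelConfig:
    """Architecture and optimization hyperparameters.

    Defaults are the tuned operating point of the reference protocol:
    hidden size 128, two recurrent layers, batch size 32, learning rate
    0.025 (Adam), bidirectional sequence branch.
    """

    hidden_size: int = 128
    num_layers: int = 2
    bidirectional: bool = True
    batch_size: int = 32
    learning_rate: float = 0.025
    ffn_hidden: int = 64
    dropout: float = 0.0
    seed: int = 0
    max_dose: float = 10.0  # mg/day clamp for denormalized dose output
    max_len: int | None = None  # truncate sequences to most recent steps

    def __post_init__(self) -> None:
        if self.hidden_size < 1 or self.num_layers < 1:
            raise ValueError("hidden_size and num_layers must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError(f"dropout must lie in [0, 1), got {self.dropout}")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be > 0 and batch_size >= 1")

    def network_spec(self) -> nnet.NetworkSpec:
        return nnet.NetworkSpec(
            input_size=len(STEP_FEATURES),
            fixed_size=len(FIXED_FEATURES),
            hidden_size=self.hidden_size,
            num_layers=self.num_layers,
            bidirectional=self.bidirectional,
            ffn_hidden=self.ffn_hidden,
        )


def _fingerprint(ids: Iterable[str]) -> str:
    h = hashlib.sha256()
    for pid in sorted(ids):
        h.update(pid.encode())
        h.update(b"\0")
    return h.hexdigest()[:16]


@dataclass
class ModelArtifact:
    """A trained model with everything needed to reproduce its predictions."""

    config: DoseModelConfig
    params: dict[str, np.ndarray]
    stats: NormalizationStats
    training_log: pd.DataFrame
    target: Literal["dose", "inr"] = "dose"
    split_fingerprint: str = ""

    def predict_samples(self, samples: Sequence[StructuredSample]) -> np.ndarray:
        """Denormalized predictions (mg/day or INR), clamped to valid range."""
        batch = collate(samples, self.stats, self.config.max_len)
        preds = nnet.forward(
            self.params, self.config.network_spec(), batch.fixed, batch.steps, batch.mask
        )
        out = denormalize_label(preds, self.stats)
        if self.target == "dose":
            return np.clip(out, 0.0, self.config.max_dose)
        return np.clip(out, 0.1, None)  # INR is physically positive

    def predict_records(self, records: Iterable[PatientRecord]) -> np.ndarray:
        """Predictions for every decision visit of the given records."""
        return self.predict_samples(build_cohort_samples(records, self.target))

    # -- serialization ----------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": {**self.config.__dict__},
            "target": self.target,
            "split_fingerprint": self.split_fingerprint,
        }
        (d / "config.yaml").write_text(yaml.safe_dump(meta), encoding="utf-8")
        self.stats.to_frame().to_csv(d / "stats.csv", index=False)
        np.savez(d / "params.npz", **self.params)
        self.training_log.to_csv(d / "training_log.csv", index=False)

    @classmethod
    def load(cls, directory) -> "ModelArtifact":
        d = Path(directory)
        meta = yaml.safe_load((d / "config.yaml").read_text(encoding="utf-8"))
        cfg = meta["config"]
        if cfg.get("max_len") is not None:
            cfg["max_len"] = int(cfg["max_len"])
        config = DoseModelConfig(**cfg)
        stats = NormalizationStats.from_frame(
            pd.read_csv(d / "stats.csv", float_precision="round_trip")
        )
        with np.load(d / "params.npz") as z:
            params = {k: z[k] for k in z.files}
        log = pd.read_csv(d / "training_log.csv")
        return cls(
            config=config,
            params=params,
            stats=stats,
            training_log=log,
            target=meta["target"],
            split_fingerprint=meta.get("split_fingerprint", ""),
        )


class DoseSequenceModel:
    """Sequence dosing model bound to training and validation data.

    Construct with pre-built samples or via :meth:`from_cohort`, then
    call :meth:`fit` to run mini-batch Adam with early stopping and
    obtain a :class:`DoseModelResults`.
    """

    def __init__(
        self,
        train_samples: Sequence[StructuredSample],
        val_samples: Sequence[StructuredSample],
        config: DoseModelConfig = DoseModelConfig(),
        target: Literal["dose", "inr"] = "dose",
    ):
        if not train_samples or not val_samples:
            raise ValueError("both training and validation sets must be non-empty")
        self.train_samples = tuple(train_samples)
        self.val_samples = tuple(val_samples)
        self.config = config
        self.target = target
        # leakage guard: statistics from the training split only
        self.stats = compute_stats(self.train_samples)

    @classmethod
    def from_cohort(
        cls,
        records: Sequence[PatientRecord],
        config: DoseModelConfig = DoseModelConfig(),
        split: SplitPlan | None = None,
        fold: int = 0,
        target: Literal["dose", "inr"] = "dose",
    ) -> "DoseSequenceModel":
        """Build train/validation samples from a cohort and a split plan."""
        if split is None:
            from .dataset import make_split

            split = make_split(records, seed=config.seed)
        train_ids, val_ids = split.fold(fold)
        by_id = {r.patient_id: r for r in records}
        train = build_cohort_samples((by_id[i] for i in train_ids if i in by_id), target)
        val = build_cohort_samples((by_id[i] for i in val_ids if i in by_id), target)
        model = cls(train, val, config, target)
        model._split_fingerprint = _fingerprint(train_ids)
        return model

    # -----------------------------------------------------------------
    def fit(
        self,
        max_epochs: int = 100,
        patience: int = 10,
        min_delta: float = 1e-4,
        seed: int | None = None,
    ) -> "DoseModelResults":
        """Train with MSE loss, Adam, and patience-based early stopping.

        Stops after ``patience`` consecutive epochs whose validation loss
        fails to improve on the best so far by at least ``min_delta``;
        the returned parameters are those of the best validation epoch.
        """
        cfg = self.config
        rng_seed = cfg.seed if seed is None else seed
        spec = cfg.network_spec()
        params = nnet.init_params(spec, rng_seed)
        opt = nnet.Adam(params, lr=cfg.learning_rate)
        rng = np.random.default_rng(rng_seed + 1)

        val_batch = collate(self.val_samples, self.stats, cfg.max_len)
        # normalize/pad the training set once; mini-batches slice the arrays
        full = collate(self.train_samples, self.stats, cfg.max_len)
        n = len(self.train_samples)
        stopper = EarlyStopper(patience=patience, min_delta=min_delta)
        best_params = {k: v.copy() for k, v in params.items()}
        best_epoch = 0
        log_rows = []
        for epoch in range(1, max_epochs + 1):
            order = rng.permutation(n)
            train_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                t_max = int(full.lengths[idx].max())
                drop = None
                if cfg.dropout > 0:
                    width = spec.ffn_hidden + spec.pooled_width
                    drop = (rng.random((len(idx), width)) >= cfg.dropout) / (1 - cfg.dropout)
                preds, cache = nnet.forward(
                    params, spec, full.fixed[idx], full.steps[idx, :t_max],
                    full.mask[idx, :t_max], return_cache=True, drop_mask=drop,
                )
                loss, dpred = nnet.mse_and_grad(preds, full.labels[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged at epoch {epoch} (non-finite loss)"
                    )
                grads = nnet.backward(params, spec, cache, dpred)
                opt.step(params, grads)
                train_loss += loss * len(idx)
            train_loss /= n

            val_preds = nnet.forward(params, spec, val_batch.fixed, val_batch.steps, val_batch.mask)
            val_loss, _ = nnet.mse_and_grad(val_preds, val_batch.labels)
            improved = stopper.update(val_loss)
            if improved:
                best_params = {k: v.copy() for k, v in params.items()}
                best_epoch = epoch
            log_rows.append(
                {"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss,
                 "improved": improved}
            )
            if stopper.should_stop:
                break

        log = pd.DataFrame(log_rows)
        artifact = ModelArtifact(
            config=replace(cfg, seed=rng_seed),
            params=best_params,
            stats=self.stats,
            training_log=log,
            target=self.target,
            split_fingerprint=getattr(self, "_split_fingerprint", _fingerprint(
                {s.patient_id for s in self.train_samples}
            )),
        )
        return DoseModelResults(self, artifact, best_epoch=best_epoch)


class EarlyStopper:
    """Patience-based stopping on validation loss.

    An epoch "improves" when its loss undercuts the best so far by at
    least ``min_delta``; after ``patience`` consecutive non-improving
    epochs training stops.  A flat loss from epoch 1 therefore stops
    after epoch 1 + patience.
    """

    def __init__(self, patience: int = 10, min_delta: float = 1e-4):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.stale = 0

    def update(self, loss: float) -> bool:
        if loss < self.best - self.min_delta:
            self.best = loss
            self.stale = 0
            return True
        self.stale += 1
        return False

    @property
    def should_stop(self) -> bool:
        return self.stale >= self.patience


class DoseModelResults:
    """Fitted-model results: artifact, diagnostics, and summary table."""

    def __init__(self, model: DoseSequenceModel, artifact: ModelArtifact, best_epoch: int):
        self.model = model
        self.artifact = artifact
        self.best_epoch = best_epoch
        self.n_epochs = len(artifact.training_log)
        self.training_log = artifact.training_log

    # -- prediction -------------------------------------------------------
    def predict(self, data) -> np.ndarray:
        """Predict doses (mg/day) or INR for records or pre-built samples."""
        if data and isinstance(data[0], PatientRecord):
            samples = build_cohort_samples(data, self.artifact.target)
        else:
            samples = data
        return self.artifact.predict_samples(samples)

    def fit_stats(self, samples: Sequence[StructuredSample] | None = None):
        from .train import fit_stats  # local import avoids module cycle

        samples = self.model.val_samples if samples is None else samples
        preds = self.artifact.predict_samples(samples)
        ref = np.array([s.label for s in samples])
        return fit_stats(preds, ref, tol=0.20 if self.artifact.target == "dose" else 0.30)

    def summary(self) -> str:
        from .train import fit_stats

        cfg = self.artifact.config
        val = self.fit_stats()
        arch = "Bi-LSTM" if cfg.bidirectional else "LSTM"
        lines = [
            f"{'Dose' if self.artifact.target == 'dose' else 'INR'} sequence model ({arch})",
            "=" * 58,
            f"hidden size      {cfg.hidden_size:>8}    layers        {cfg.num_layers:>8}",
            f"batch size       {cfg.batch_size:>8}    learning rate {cfg.learning_rate:>8}",
            f"train samples    {len(self.model.train_samples):>8}    val samples   {len(self.model.val_samples):>8}",
            f"epochs run       {self.n_epochs:>8}    best epoch    {self.best_epoch:>8}",
            "-" * 58,
            "validation-set performance (denormalized):",
            f"  MSE  {val.mse:10.4f}   MAE  {val.mae:10.4f}",
            f"  RMSE {val.rmse:10.4f}   R2   {('%10.4f' % val.r2) if val.r2 is not None else '       n/a'}",
            f"  accuracy within ±{int(round(100 * val.tol))}%: {val.accuracy * 100:5.1f}%",
            "=" * 58,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Single-record prediction entry points
# ---------------------------------------------------------------------------


def _predict_at_visit(artifact: ModelArtifact, record: PatientRecord, at_visit: int) -> float:
    if at_visit < 2 or at_visit > record.n_visits:
        raise IndexError(
            f"at_visit must lie in [2, {record.n_visits}] for patient "
            f"{record.patient_id!r}, got {at_visit}"
        )
    samples = [s for s in build_samples(record, artifact.target) if s.decision_visit == at_visit]
    if not samples:
        raise ValueError(f"no usable sample at visit {at_visit} (dropped label?)")
    return float(artifact.predict_samples(samples)[0])


def predict_dose(artifact: ModelArtifact, record: PatientRecord, at_visit: int) -> float:
    """Predicted adjusted dose (mg/day) at a decision visit (1-based, >= 2)."""
    if artifact.target != "dose":
        raise ValueError("artifact was trained for INR, not dose, prediction")
    return _predict_at_visit(artifact, record, at_visit)


def predict_inr(artifact: ModelArtifact, record: PatientRecord, at_visit: int) -> float:
    """Predicted INR at a decision visit (same wiring, INR label/mask)."""
    if artifact.target != "inr":
        raise ValueError("artifact was trained for dose, not INR, prediction")
    return _predict_at_visit(artifact, record, at_visit)
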