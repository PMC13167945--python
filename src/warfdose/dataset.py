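"""Supervised sample construction, patient-level splits, and batch collation.

Each patient with V visits yields V−1 supervised samples, one per
"decision visit" i ∈ {2..V}.  The sample's sequence covers visits 1..i;
each time step carries (Dose_{i−1}, INR_i, Interval_{i+1}, Dose_i), and
the decision step's own target field (dose for the dose model, INR for
the INR model) is masked — it is the label, so showing it would leak.
The mask is a dedicated indicator channel plus a zeroed value in
normalized space, which is distinguishable from any genuine value that
happens to normalize near zero because the indicator is 1 only at the
masked position.

Splits are patient-grouped: 10% of patients form a held-out test set and
the remaining 90% are partitioned into k cross-validation folds (each
fold once the validation set, ≈9% of patients, the rest ≈81% training).
Normalization statistics are always computed from training-fold samples
only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .core import (
    FIXED_FEATURES,
    NormalizationStats,
    PatientRecord,
    encode_fixed,
    genotype_features,
)

__all__ = [
    "STEP_FEATURES",
    "VisitStep",
    "StructuredSample",
    "SplitPlan",
    "build_samples",
    "build_cohort_samples",
    "make_split",
    "compute_stats",
    "collate",
    "Batch",
]

#: Time-step feature order used throughout the sequence branch.  The
#: trailing "masked" channel is 1 at the decision step's hidden target.
STEP_FEATURES = ("dose_prev", "inr", "interval_next", "dose", "masked")


@dataclass(frozen=True)
class VisitStep:
    dose_prev: float  # mg/day, adjusted dose at the previous visit
    inr: float  # INR at the current visit
    interval_next: float  # days until the next visit
    dose: float  # mg/day, adjusted dose at the current visit
    masked: bool = False  # True at the decision step (target hidden)

    def __post_init__(self) -> None:
        if self.interval_next < 1:
            raise ValueError(f"interval_next must be >= 1 day, got {self.interval_next}")


@dataclass(frozen=True)
class StructuredSample:
    fixed: dict[str, float]  # encoded fixed covariates (NaN = unknown genotype)
    steps: tuple[VisitStep, ...]
    label: float  # mg/day (dose model) or INR (INR model)
    patient_id: str
    decision_visit: int  # 1-based index of the decision visit
    target_low: float
    target_high: float
    target: str = "dose"  # which field is hidden at the decision step
    subgroup: str | None = None

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("steps must be non-empty")
        if not self.label > 0:
            raise ValueError(f"label must be > 0, got {self.label}")


def build_samples(
    record: PatientRecord, target: Literal["dose", "inr"] = "dose"
) -> list[StructuredSample]:
    """One supervised sample per decision visit of a patient record.

    Conventions: the first visit's ``dose_prev`` duplicates its own dose
    (it is the dose the patient arrived on — zero would falsely signal no
    prior anticoagulation); the last step's ``interval_next`` duplicates
    the preceding interval when no later visit exists.  Records with
    fewer than two visits yield no samples; samples with a non-positive
    label are dropped with a warning.
    """
    visits = record.visits
    if len(visits) < 2:
        return []
    fixed = encode_fixed(record.fixed)

    def interval_after(j: int) -> float:
        if j + 1 < len(visits):
            return float(visits[j + 1].day - visits[j].day)
        return float(visits[j].day - visits[j - 1].day) if j > 0 else 1.0

    samples: list[StructuredSample] = []
    for i in range(1, len(visits)):  # decision visit index (0-based i, 1-based i+1)
        steps = []
        for j in range(i + 1):
            decision = j == i
            dose_prev = visits[j - 1].dose if j > 0 else visits[0].dose
            steps.append(
                VisitStep(
                    dose_prev=float(dose_prev),
                    inr=float(visits[j].inr) if not (decision and target == "inr") else 0.0,
                    interval_next=interval_after(j),
                    dose=float(visits[j].dose) if not (decision and target == "dose") else 0.0,
                    masked=decision,
                )
            )
        label = visits[i].dose if target == "dose" else visits[i].inr
        if not label > 0:
            warnings.warn(
                f"patient {record.patient_id}: non-positive {target} label at visit "
                f"{i + 1}; sample dropped"
            )
            continue
        samples.append(
            StructuredSample(
                fixed=fixed,
                steps=tuple(steps),
                label=float(label),
                patient_id=record.patient_id,
                decision_visit=i + 1,
                target_low=record.target.low,
                target_high=record.target.high,
                target=target,
            )
        )
    return samples


def build_cohort_samples(
    records: Iterable[PatientRecord], target: Literal["dose", "inr"] = "dose"
) -> list[StructuredSample]:
    out: list[StructuredSample] = []
    for rec in records:
        out.extend(build_samples(rec, target))
    return out


@dataclass(frozen=True)
class SplitPlan:
    """Patient-level test/CV split: ids only, resolved against a cohort."""

    test_ids: tuple[str, ...]
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, val) per fold
    seed: int

    def fold(self, k: int = 0) -> tuple[tuple[str, ...], tuple[str, ...]]:
        return self.folds[k]

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "test_ids": list(self.test_ids),
            "folds": [{"train": list(tr), "val": list(va)} for tr, va in self.folds],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SplitPlan":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            test_ids=tuple(payload["test_ids"]),
            folds=tuple((tuple(f["train"]), tuple(f["val"])) for f in payload["folds"]),
            seed=int(payload["seed"]),
        )


def make_split(
    records: Sequence[PatientRecord],
    seed: int,
    test_frac: float = 0.10,
    k: int = 10,
) -> SplitPlan:
    """Patient-grouped 10% test split plus k-fold CV of the remainder."""
    ids = [r.patient_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids in cohort")
    if len(ids) < k + 2:
        raise ValueError(f"need at least k+2={k + 2} patients for {k}-fold CV, got {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(len(ids))]
    n_test = max(1, round(test_frac * len(ids)))
    test_ids = tuple(sorted(perm[:n_test]))
    rest = perm[n_test:]
    fold_chunks = [list(c) for c in np.array_split(np.array(rest, dtype=object), k)]
    folds = []
    for i in range(k):
        val = tuple(sorted(str(x) for x in fold_chunks[i]))
        train = tuple(
            sorted(str(x) for j, c in enumerate(fold_chunks) if j != i for x in c)
        )
        if not val or not train:
            raise ValueError("empty fold; too few patients for the requested k")
        folds.append((train, val))
    return SplitPlan(test_ids=test_ids, folds=tuple(folds), seed=seed)


# ---------------------------------------------------------------------------
# Normalization statistics and batch collation
# ---------------------------------------------------------------------------

#: Sequence features that are z-scored ("masked" is a raw 0/1 channel).
_NORMALIZED_STEP_FEATURES = ("dose_prev", "inr", "interval_next", "dose")
LABEL_FEATURE = "label"


def compute_stats(samples: Sequence[StructuredSample]) -> NormalizationStats:
    """Normalization statistics from (training) samples only.

    Fixed genotype entries may be NaN (unknown genotype); they are
    excluded from the moments, matching the neutral-imputation policy.
    """
    if not samples:
        raise ValueError("cannot compute stats from zero samples")
    arrays: dict[str, np.ndarray] = {}
    for feat in FIXED_FEATURES:
        vals = np.array([s.fixed[feat] for s in samples], dtype=float)
        vals = vals[np.isfinite(vals)]
        arrays[feat] = vals if vals.size else np.zeros(1)
    step_vals: dict[str, list[float]] = {f: [] for f in _NORMALIZED_STEP_FEATURES}
    for s in samples:
        for st in s.steps:
            if not st.masked:
                step_vals["dose_prev"].append(st.dose_prev)
                step_vals["inr"].append(st.inr)
                step_vals["interval_next"].append(st.interval_next)
                step_vals["dose"].append(st.dose)
            else:
                # the unmasked channels of the decision step still inform stats
                step_vals["dose_prev"].append(st.dose_prev)
                step_vals["interval_next"].append(st.interval_next)
    for f, v in step_vals.items():
        arrays[f] = np.asarray(v, dtype=float)
    arrays[LABEL_FEATURE] = np.array([s.label for s in samples], dtype=float)
    return NormalizationStats.from_arrays(arrays)


@dataclass
class Batch:
    fixed: np.ndarray  # (B, F) normalized fixed covariates
    steps: np.ndarray  # (B, T, S) normalized sequence features + mask channel
    mask: np.ndarray  # (B, T) bool, True at valid (non-pad) steps
    labels: np.ndarray  # (B,) normalized labels
    lengths: np.ndarray  # (B,) int valid lengths
    samples: tuple[StructuredSample, ...] = ()

    @property
    def size(self) -> int:
        return self.fixed.shape[0]


def collate(
    samples: Sequence[StructuredSample],
    stats: NormalizationStats,
    max_len: int | None = None,
) -> Batch:
    """Normalize and right-pad samples into dense arrays with a pad mask.

    Sequences longer than ``max_len`` are truncated to their most recent
    ``max_len`` steps with a warning.  Labels are z-scored with the label
    feature's training statistics; genotype NaNs become 0 (the training
    mean) after normalization.
    """
    if not samples:
        raise ValueError("cannot collate an empty sample list")
    lengths = []
    seqs = []
    for s in samples:
        steps = s.steps
        if max_len is not None and len(steps) > max_len:
            warnings.warn(
                f"sequence of length {len(steps)} truncated to most recent {max_len} steps"
            )
            steps = steps[-max_len:]
        seqs.append(steps)
        lengths.append(len(steps))
    T = max(lengths)
    B = len(samples)

    fixed = np.zeros((B, len(FIXED_FEATURES)))
    for j, feat in enumerate(FIXED_FEATURES):
        raw = np.array([s.fixed[feat] for s in samples], dtype=float)
        unknown = ~np.isfinite(raw)
        raw[unknown] = stats.mean[feat]
        fixed[:, j] = (raw - stats.mean[feat]) / stats.std[feat]

    steps = np.zeros((B, T, len(STEP_FEATURES)))
    mask = np.zeros((B, T), dtype=bool)
    for b, seq in enumerate(seqs):
        hidden = samples[b].target  # "dose" or "inr": the channel hidden at masked steps
        for t, st in enumerate(seq):
            row = []
            for feat in _NORMALIZED_STEP_FEATURES:
                val = getattr(st, feat)
                if st.masked and feat == hidden:
                    row.append(0.0)  # sentinel: training mean in normalized space
                else:
                    row.append((val - stats.mean[feat]) / stats.std[feat])
            row.append(1.0 if st.masked else 0.0)
            steps[b, t, :] = row
        mask[b, : len(seq)] = True

    labels = (np.array([s.label for s in samples], dtype=float) - stats.mean[LABEL_FEATURE]) / stats.std[LABEL_FEATURE]
    return Batch(
        fixed=fixed,
        steps=steps,
        mask=mask,
        labels=labels,
        lengths=np.array(lengths, dtype=int),
        samples=tuple(samples),
    )


def denormalize_label(values: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return np.asarray(values) * stats.std[LABEL_FEATURE] + stats.mean[LABEL_FEATURE]


# ---------------------------------------------------------------------------
# Sample cache (one JSON object per line)
# ---------------------------------------------------------------------------


def samples_to_jsonl(samples: Sequence[StructuredSample], path) -> None:
    """Cache samples as line-delimited JSON for reproducible training."""
    with open(path, "w", encoding="utf-8") as fh:
        for s in samples:
            fh.write(json.dumps({
                "fixed": {k: (None if not np.isfinite(v) else v) for k, v in s.fixed.items()},
                "steps": [[st.dose_prev, st.inr, st.interval_next, st.dose, int(st.masked)]
                          for st in s.steps],
                "label": s.label,
                "patient_id": s.patient_id,
                "decision_visit": s.decision_visit,
                "target_low": s.target_low,
                "target_high": s.target_high,
                "target": s.target,
            }) + "\n")


def samples_from_jsonl(path) -> list[StructuredSample]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            d = json.loads(line)
            out.append(StructuredSample(
                fixed={k: (np.nan if v is None else float(v)) for k, v in d["fixed"].items()},
                steps=tuple(
                    VisitStep(dose_prev=a, inr=b, interval_next=c, dose=e, masked=bool(m))
                    for a, b, c, e, m in d["steps"]
                ),
                label=float(d["label"]),
                patient_id=d["patient_id"],
                decision_visit=int(d["decision_visit"]),
                target_low=float(d["target_low"]),
                target_high=float(d["target_high"]),
                target=d["target"],
            ))
    return out
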