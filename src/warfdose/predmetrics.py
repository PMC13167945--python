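"""Prediction-evaluation suite for dose/INR models.

Covers tolerance-band classification (within / over / under), accuracy
summaries, stable-dose detection and stable-dose accuracy, per-visit
accuracy, genotype-sensitivity subgroups, the missing-genotype
ablation, and error-distribution summaries.

Conventions: a prediction is "within" when |predicted − reference| ≤
tol·reference (inclusive boundary; tol 0.20 for doses, 0.30 for INR);
reported percentages are rounded half-up to one decimal; prediction
error is predicted − reference, so over-prediction gives positive error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Genotype, PatientRecord
from .dataset import StructuredSample, build_samples
from .models import ModelArtifact

__all__ = [
    "DOSE_TOL",
    "INR_TOL",
    "PredictionOutcome",
    "StableDose",
    "classify",
    "accuracy_summary",
    "detect_stable_dose",
    "stable_dose_accuracy",
    "evaluate_cohort",
    "per_visit_accuracy",
    "sensitivity_subgroup",
    "ablate_genotype",
    "error_summary",
    "persistence_outcomes",
]

DOSE_TOL = 0.20
INR_TOL = 0.30


def round1(x: float) -> float:
    """Round half-up to one decimal, matching printed-report style."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PredictionOutcome:
    predicted: float
    reference: float
    klass: Literal["within", "over", "under"]
    patient_id: str = ""
    visit: int = 0  # decision-visit index (1-based)
    subgroup: str | None = None


def classify(predicted: float, reference: float, tol: float = DOSE_TOL) -> str:
    """Tolerance-band classification with inclusive boundaries."""
    if not reference > 0:
        raise ValueError(f"reference must be positive, got {reference}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    if abs(predicted - reference) <= tol * reference:
        return "within"
    return "over" if predicted > reference else "under"


def make_outcome(
    predicted: float,
    reference: float,
    tol: float = DOSE_TOL,
    patient_id: str = "",
    visit: int = 0,
    subgroup: str | None = None,
) -> PredictionOutcome:
    return PredictionOutcome(
        predicted=float(predicted),
        reference=float(reference),
        klass=classify(predicted, reference, tol),
        patient_id=patient_id,
        visit=visit,
        subgroup=subgroup,
    )


@dataclass(frozen=True)
class AccuracySummary:
    n: int
    counts: dict[str, int]
    within_pct: float
    over_pct: float
    under_pct: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "counts": dict(self.counts),
            "within_pct": self.within_pct,
            "over_pct": self.over_pct,
            "under_pct": self.under_pct,
        }


def accuracy_summary(outcomes: Sequence[PredictionOutcome]) -> AccuracySummary:
    """Class proportions ×100, one-decimal reporting."""
    if not outcomes:
        raise ValueError("cannot summarize zero outcomes")
    counts = {"within": 0, "over": 0, "under": 0}
    for o in outcomes:
        counts[o.klass] += 1
    n = len(outcomes)
    return AccuracySummary(
        n=n,
        counts=counts,
        within_pct=round1(100.0 * counts["within"] / n),
        over_pct=round1(100.0 * counts["over"] / n),
        under_pct=round1(100.0 * counts["under"] / n),
    )


# ---------------------------------------------------------------------------
# Stable dose
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StableDose:
    patient_id: str
    dose: float
    window: tuple[int, int]  # (start day, end day), inclusive


def detect_stable_dose(
    record: PatientRecord,
    min_span_days: int = 14,
    earliest_start_day: int = 7,
    start_within_first_7: bool = False,
) -> StableDose | None:
    """Earliest constant-dose run qualifying as a stable-dose window.

    A run of consecutive visits sharing the same dose qualifies when its
    day span is at least ``min_span_days`` and every in-window INR lies
    inside the patient's target range.  By default the window must begin
    at or after day ``earliest_start_day`` (the initiation transient is
    excluded); with ``start_within_first_7`` the alternative reading is
    used — the window must begin within the first 7 days.
    """
    visits = record.visits
    n = len(visits)
    best: StableDose | None = None
    for s in range(n):
        if start_within_first_7:
            if visits[s].day > 7:
                break
        elif visits[s].day < earliest_start_day:
            continue
        if not record.target.contains(visits[s].inr):
            continue
        e = s
        while (
            e + 1 < n
            and visits[e + 1].dose == visits[s].dose
            and record.target.contains(visits[e + 1].inr)
        ):
            e += 1
        if visits[e].day - visits[s].day >= min_span_days:
            cand = StableDose(record.patient_id, visits[s].dose, (visits[s].day, visits[e].day))
            if best is None or cand.window[0] < best.window[0]:
                best = cand
    return best


def stable_dose_accuracy(
    artifact: ModelArtifact,
    records: Sequence[PatientRecord],
    per_visit_prediction: bool = True,
) -> tuple[AccuracySummary | None, list[PredictionOutcome]]:
    """Classify model predictions against each patient's stable dose.

    For every patient with a detected stable dose, predictions at
    decision visits falling inside the stable window are compared with
    the stable dose at ±20%.  With ``per_visit_prediction`` False only
    the first in-window decision visit is used.  Returns (summary,
    outcomes); summary is None when no patient has a stable dose.
    """
    outcomes: list[PredictionOutcome] = []
    for rec in records:
        stable = detect_stable_dose(rec)
        if stable is None:
            continue
        day_of = {i + 1: v.day for i, v in enumerate(rec.visits)}
        samples = [
            s
            for s in build_samples(rec, artifact.target)
            if stable.window[0] <= day_of[s.decision_visit] <= stable.window[1]
        ]
        if not per_visit_prediction:
            samples = samples[:1]
        if not samples:
            continue
        preds = artifact.predict_samples(samples)
        for s, p in zip(samples, preds):
            outcomes.append(
                make_outcome(p, stable.dose, DOSE_TOL, rec.patient_id, s.decision_visit)
            )
    if not outcomes:
        return None, []
    return accuracy_summary(outcomes), outcomes


def evaluate_cohort(
    artifact: ModelArtifact, records: Sequence[PatientRecord]
) -> tuple[AccuracySummary, list[PredictionOutcome]]:
    """Classify predictions against the actually prescribed values."""
    tol = DOSE_TOL if artifact.target == "dose" else INR_TOL
    outcomes: list[PredictionOutcome] = []
    for rec in records:
        samples = build_samples(rec, artifact.target)
        if not samples:
            continue
        subgroup = sensitivity_subgroup(rec.fixed.genotype)
        preds = artifact.predict_samples(samples)
        for s, p in zip(samples, preds):
            outcomes.append(
                make_outcome(p, s.label, tol, rec.patient_id, s.decision_visit, subgroup)
            )
    if not outcomes:
        raise ValueError("cohort produced no supervised samples")
    return accuracy_summary(outcomes), outcomes


def persistence_outcomes(records: Sequence[PatientRecord]) -> list[PredictionOutcome]:
    """Baseline outcomes for the persistence predictor (previous dose)."""
    outcomes = []
    for rec in records:
        for s in build_samples(rec, "dose"):
            prev = s.steps[-1].dose_prev
            outcomes.append(make_outcome(prev, s.label, DOSE_TOL, rec.patient_id, s.decision_visit))
    return outcomes


def per_visit_accuracy(
    outcomes: Sequence[PredictionOutcome], max_index: int = 10
) -> pd.DataFrame:
    """Within-% by decision-visit index; indices > max_index pooled.

    Decision visits are numbered from 1 (the first visit with a history,
    i.e. the patient's second attendance).  Empty bins are omitted.
    """
    rows = []
    by_bin: dict[object, list[PredictionOutcome]] = {}
    for o in outcomes:
        # decision visit v corresponds to prediction index v-1
        idx = o.visit - 1
        key = idx if idx <= max_index else f">{max_index}"
        by_bin.setdefault(key, []).append(o)

    def sort_key(k):
        return (0, k) if isinstance(k, int) else (1, 0)

    for key in sorted(by_bin, key=sort_key):
        group = by_bin[key]
        s = accuracy_summary(group)
        rows.append({"visit": key, "n": s.n, "within_pct": s.within_pct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genotype subgroups and ablation
# ---------------------------------------------------------------------------

#: Decision table mapping genotype to warfarin-response subgroup
#: (CPIC-style convention; replaceable via the `table` argument).
DEFAULT_SUBGROUP_TABLE = {
    "highly_sensitive": "vkorc1 AA and >=1 CYP2C9 variant allele",
    "sensitive": "vkorc1 AA with *1/*1, or GA/GG with >=1 variant allele",
    "normal": "vkorc1 GA/GG with *1/*1",
}


def sensitivity_subgroup(genotype: Genotype, table: str = "default") -> str:
    """Stratify a genotype into normal / sensitive / highly_sensitive.

    Unknown genotypes fall into a dedicated "unclassified" stratum.
    """
    if not genotype.known:
        return "unclassified"
    aa = genotype.vkorc1 == "AA"
    variants = genotype.cyp2c9_variant_alleles
    if aa and variants >= 1:
        return "highly_sensitive"
    if aa or variants >= 1:
        return "sensitive"
    return "normal"


def ablate_genotype(records: Iterable[PatientRecord]) -> list[PatientRecord]:
    """Copy of the cohort with genotype marked unknown everywhere.

    Downstream encoding then falls back to training-mean imputation;
    nothing else about the records changes.  Idempotent.
    """
    return [rec.with_genotype_unknown() for rec in records]


def subgroup_accuracy(outcomes: Sequence[PredictionOutcome]) -> pd.DataFrame:
    """Accuracy summaries stratified by sensitivity subgroup."""
    rows = []
    by_grp: dict[str, list[PredictionOutcome]] = {}
    for o in outcomes:
        by_grp.setdefault(o.subgroup or "unclassified", []).append(o)
    for grp in sorted(by_grp):
        s = accuracy_summary(by_grp[grp])
        rows.append({"subgroup": grp, **{k: v for k, v in s.as_dict().items() if k != "counts"}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Error distribution
# ---------------------------------------------------------------------------


def error_summary(outcomes: Sequence[PredictionOutcome], bins: int = 30) -> dict:
    """Moment/quantile summary of predicted − reference, plus a histogram.

    Positive error means over-prediction.  Standard deviation and
    skewness use the sample (ddof=1, bias-corrected) conventions.
    """
    if len(outcomes) < 2:
        raise ValueError("need at least two outcomes")
    err = np.array([o.predicted - o.reference for o in outcomes])
    sd = float(np.std(err, ddof=1))
    skew = float(sps.skew(err, bias=False)) if sd > 0 else 0.0
    hist, edges = np.histogram(err, bins=bins)
    return {
        "convention": "error = predicted - reference (over-prediction positive)",
        "n": int(err.size),
        "mean": float(np.mean(err)),
        "sd": sd,
        "skewness": skew,
        "quantiles": {
            q: float(np.quantile(err, q)) for q in (0.05, 0.25, 0.5, 0.75, 0.95)
        },
        "histogram": pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": hist}
        ),
    }
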