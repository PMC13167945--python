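"""Domain types, normalization, target-range policy, and cohort file I/O.

The universal exchange object is :class:`PatientRecord`: fixed covariates
(age, anthropometrics, CYP2C9/VKORC1 genotype, interacting co-medication)
plus an ordered series of follow-up visits, each carrying the day since
warfarin initiation, the measured INR and the adjusted daily dose in mg.

Cohorts are stored as plain UTF-8 CSV with one row per visit; fixed
covariates are repeated on every row of a patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "FixedCovariates",
    "Visit",
    "TargetRange",
    "PatientRecord",
    "NormalizationStats",
    "assign_target_range",
    "normalize",
    "denormalize",
    "encode_fixed",
    "FIXED_FEATURES",
    "read_cohort",
    "write_cohort",
    "INDICATIONS",
    "CYP2C9_DIPLOTYPES",
    "VKORC1_GENOTYPES",
]

#: The six unordered diplotypes over the star alleles observed in practice.
CYP2C9_DIPLOTYPES = ("*1/*1", "*1/*2", "*1/*3", "*2/*2", "*2/*3", "*3/*3")
VKORC1_GENOTYPES = ("GG", "GA", "AA")
INDICATIONS = ("mechanical_valve", "bioprosthetic_valve", "valve_repair", "other")

# Indication-specific therapeutic INR intervals.  The "other" entry is the
# package default for indications whose range the treating clinician would
# set case by case.
_TARGET_BY_INDICATION = {
    "mechanical_valve": (2.0, 2.5),
    "bioprosthetic_valve": (1.8, 2.3),
    "valve_repair": (1.5, 2.5),
    "other": (2.0, 3.0),
}


@dataclass(frozen=True)
class Genotype:
    """CYP2C9 diplotype and VKORC1 −1639G>A genotype.

    When ``known`` is False (genotype never assayed) the diplotype fields
    are ignored by every consumer and the model-facing encoding falls back
    to neutral (training-mean) imputation.
    """

    cyp2c9: str = "*1/*1"
    vkorc1: str = "AA"
    known: bool = True

    def __post_init__(self) -> None:
        if self.known:
            if self.cyp2c9 not in CYP2C9_DIPLOTYPES:
                raise ValueError(f"unrecognized CYP2C9 diplotype: {self.cyp2c9!r}")
            if self.vkorc1 not in VKORC1_GENOTYPES:
                raise ValueError(f"unrecognized VKORC1 genotype: {self.vkorc1!r}")

    @property
    def cyp2c9_variant_alleles(self) -> int:
        """Count of reduced-function alleles (*2 or *3) in the diplotype."""
        return sum(a in ("*2", "*3") for a in self.cyp2c9.split("/"))

    @property
    def cyp2c9_star3(self) -> int:
        """1 if the diplotype carries at least one *3 allele."""
        return int("*3" in self.cyp2c9.split("/"))

    @property
    def vkorc1_a_alleles(self) -> int:
        """Count of −1639 A alleles: GG → 0, GA → 1, AA → 2."""
        return {"GG": 0, "GA": 1, "AA": 2}[self.vkorc1]


@dataclass(frozen=True)
class FixedCovariates:
    age: float  # years
    height: float  # cm
    weight: float  # kg
    genotype: Genotype = field(default_factory=Genotype)
    amiodarone: bool = False
    digoxin: bool = False

    def __post_init__(self) -> None:
        if not self.age > 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if not 100 < self.height < 220:
            raise ValueError(f"height {self.height} cm outside (100, 220)")
        if not 25 < self.weight < 200:
            raise ValueError(f"weight {self.weight} kg outside (25, 200)")


@dataclass(frozen=True)
class Visit:
    """One follow-up visit: day since initiation, measured INR, adjusted dose."""

    day: int
    inr: float
    dose: float  # mg/day, the dose prescribed at this visit going forward

    def __post_init__(self) -> None:
        if not (np.isfinite(self.inr) and self.inr > 0):
            raise ValueError(f"INR must be finite and positive, got {self.inr}")
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")


@dataclass(frozen=True)
class TargetRange:
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high, got ({self.low}, {self.high})")

    def contains(self, inr: float) -> bool:
        """Closed-interval membership: boundary values count as in range."""
        return self.low <= inr <= self.high

    @property
    def mid(self) -> float:
        return 0.5 * (self.low + self.high)


def assign_target_range(indication: str, override: TargetRange | None = None) -> TargetRange:
    """Return the therapeutic INR interval for an indication.

    An explicit ``override`` always wins; otherwise the indication's
    standard range is returned (mechanical valve 2.0–2.5, bioprosthetic
    1.8–2.3, valve repair 1.5–2.5, other 2.0–3.0 by package default).
    """
    if override is not None:
        return override
    try:
        low, high = _TARGET_BY_INDICATION[indication]
    except KeyError:
        raise ValueError(f"unrecognized indication label: {indication!r}") from None
    return TargetRange(low, high)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    fixed: FixedCovariates
    visits: tuple[Visit, ...]
    indication: str = "other"
    target: TargetRange | None = None

    def __post_init__(self) -> None:
        if self.indication not in INDICATIONS:
            raise ValueError(f"unrecognized indication label: {self.indication!r}")
        if len(self.visits) < 1:
            raise ValueError(f"patient {self.patient_id}: at least one visit required")
        days = [v.day for v in self.visits]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"patient {self.patient_id}: visit days must strictly increase")
        if self.target is None:
            object.__setattr__(self, "target", assign_target_range(self.indication))

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def with_genotype_unknown(self) -> "PatientRecord":
        g = self.fixed.genotype
        if not g.known:
            return self
        return replace(self, fixed=replace(self.fixed, genotype=replace(g, known=False)))


# ---------------------------------------------------------------------------
# Normalization (z-scores computed on the training split only)
# ---------------------------------------------------------------------------


class NormalizationStats:
    """Per-feature mean and standard deviation, keyed by feature name.

    Constant features are kept with std set to 1 and flagged in
    ``constant_features`` so that normalization is always well defined.
    """

    def __init__(self, mean: Mapping[str, float], std: Mapping[str, float]):
        if set(mean) != set(std):
            raise ValueError("mean and std must share the same feature keys")
        self.mean = dict(mean)
        self.std = dict(std)
        self.constant_features: set[str] = set()
        for k, s in list(self.std.items()):
            if not np.isfinite(s) or s <= 0:
                self.std[k] = 1.0
                self.constant_features.add(k)

    @classmethod
    def from_arrays(cls, features: Mapping[str, np.ndarray]) -> "NormalizationStats":
        mean = {k: float(np.mean(v)) for k, v in features.items()}
        std = {k: float(np.std(v, ddof=0)) for k, v in features.items()}
        return cls(mean, std)

    def features(self) -> list[str]:
        return list(self.mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": list(self.mean),
                "mean": [self.mean[k] for k in self.mean],
                "std": [self.std[k] for k in self.mean],
                "constant": [k in self.constant_features for k in self.mean],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NormalizationStats":
        stats = cls(
            dict(zip(df["feature"], df["mean"].astype(float))),
            dict(zip(df["feature"], df["std"].astype(float))),
        )
        if "constant" in df:
            stats.constant_features = set(df.loc[df["constant"].astype(bool), "feature"])
        return stats


def normalize(value, stats: NormalizationStats, feature: str):
    """z-score a raw feature value: (x − x̄) / x_std."""
    if feature not in stats.mean:
        raise KeyError(f"unknown feature {feature!r}; have {stats.features()}")
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite input for feature {feature!r}")
    out = (arr - stats.mean[feature]) / stats.std[feature]
    return out if out.ndim else float(out)


def denormalize(value, stats: NormalizationStats, feature: str):
    """Inverse of :func:`normalize`: x = x_norm · x_std + x̄."""
    if feature not in stats.mean:
        raise KeyError(f"unknown feature {feature!r}; have {stats.features()}")
    arr = np.asarray(value, dtype=float)
    out = arr * stats.std[feature] + stats.mean[feature]
    return out if out.ndim else float(out)


#: Order of the model-facing fixed-covariate encoding.
FIXED_FEATURES = (
    "age",
    "height",
    "weight",
    "cyp2c9_variant_alleles",
    "cyp2c9_star3",
    "vkorc1_a_alleles",
    "amiodarone",
    "digoxin",
)

_GENOTYPE_FEATURES = ("cyp2c9_variant_alleles", "cyp2c9_star3", "vkorc1_a_alleles")


def encode_fixed(fixed: FixedCovariates) -> dict[str, float]:
    """Encode fixed covariates as a named numeric vector.

    Genotypes use ordinal gene-dose coding (variant-allele counts), the
    standard choice in warfarin dosing algorithms.  When the genotype is
    unknown the genotype entries are reported as NaN; after normalization
    the caller replaces them with 0 (the training-split mean), i.e. neutral
    imputation.
    """
    g = fixed.genotype
    vec = {
        "age": float(fixed.age),
        "height": float(fixed.height),
        "weight": float(fixed.weight),
        "cyp2c9_variant_alleles": float(g.cyp2c9_variant_alleles) if g.known else np.nan,
        "cyp2c9_star3": float(g.cyp2c9_star3) if g.known else np.nan,
        "vkorc1_a_alleles": float(g.vkorc1_a_alleles) if g.known else np.nan,
        "amiodarone": float(fixed.amiodarone),
        "digoxin": float(fixed.digoxin),
    }
    return vec


def genotype_features() -> tuple[str, ...]:
    return _GENOTYPE_FEATURES


# ---------------------------------------------------------------------------
# Cohort file I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = [
    "patient_id",
    "age",
    "height_cm",
    "weight_kg",
    "cyp2c9",
    "vkorc1",
    "genotype_known",
    "amiodarone",
    "digoxin",
    "indication",
    "day",
    "inr",
    "dose_mg",
]


def write_cohort(records: Iterable[PatientRecord], path) -> None:
    """Serialize a cohort to CSV, one row per visit."""
    rows = []
    for rec in records:
        g = rec.fixed.genotype
        default = assign_target_range(rec.indication)
        has_override = (rec.target.low, rec.target.high) != (default.low, default.high)
        for v in rec.visits:
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "age": float(rec.fixed.age),
                    "height_cm": float(rec.fixed.height),
                    "weight_kg": float(rec.fixed.weight),
                    "cyp2c9": g.cyp2c9 if g.known else "",
                    "vkorc1": g.vkorc1 if g.known else "",
                    "genotype_known": int(g.known),
                    "amiodarone": int(rec.fixed.amiodarone),
                    "digoxin": int(rec.fixed.digoxin),
                    "indication": rec.indication,
                    "day": v.day,
                    "inr": v.inr,
                    "dose_mg": v.dose,
                    "target_low": rec.target.low if has_override else "",
                    "target_high": rec.target.high if has_override else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_cohort(path) -> list[PatientRecord]:
    """Read a cohort CSV into PatientRecords.

    Visits arriving out of day order are re-sorted with a warning; a
    duplicated (patient_id, day) pair is an error.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file missing required column(s): {missing}")
    for col in ("inr", "dose_mg"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ValueError(f"non-numeric values in column {col!r}")

    records: list[PatientRecord] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        dup = grp["day"].duplicated()
        if dup.any():
            day = int(grp.loc[dup, "day"].iloc[0])
            raise ValueError(f"duplicate visit day {day} for patient {pid!r}")
        if not grp["day"].is_monotonic_increasing:
            warnings.warn(f"patient {pid!r}: visits out of day order; re-sorting")
            grp = grp.sort_values("day")
        first = grp.iloc[0]
        known = bool(int(first["genotype_known"]))
        genotype = (
            Genotype(str(first["cyp2c9"]), str(first["vkorc1"]), known=True)
            if known
            else Genotype(known=False)
        )
        fixed = FixedCovariates(
            age=float(first["age"]),
            height=float(first["height_cm"]),
            weight=float(first["weight_kg"]),
            genotype=genotype,
            amiodarone=bool(int(first["amiodarone"])),
            digoxin=bool(int(first["digoxin"])),
        )
        override = None
        if "target_low" in grp.columns and "target_high" in grp.columns:
            lo, hi = first.get("target_low"), first.get("target_high")
            if pd.notna(lo) and str(lo) != "" and pd.notna(hi) and str(hi) != "":
                override = TargetRange(float(lo), float(hi))
        visits = tuple(
            Visit(day=int(r.day), inr=float(r.inr), dose=float(r.dose_mg))
            for r in grp.itertuples()
        )
        records.append(
            PatientRecord(
                patient_id=str(pid),
                fixed=fixed,
                visits=visits,
                indication=str(first["indication"]),
                target=assign_target_range(str(first["indication"]), override),
            )
        )
    return records
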