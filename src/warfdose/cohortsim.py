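"""Seeded virtual-patient simulator for longitudinal warfarin cohorts.

Real anticoagulation cohorts with visit-level INR/dose series are rarely
deposited, so this module generates synthetic cohorts carrying the
statistical structure a sequence dosing model must exploit:

* genotype-dependent dose sensitivity — the dose producing a given INR
  elevation scales multiplicatively with VKORC1 −1639 A-allele count and
  CYP2C9 reduced-function allele count;
* delayed pharmacodynamic onset — the latent INR relaxes toward the
  steady state of the current dose with first-order kinetics, so INR is
  visibly unstable during the first 3–5 days of therapy;
* clinician-driven titration — at every visit the dose is nudged
  proportionally toward the dose whose steady-state INR hits the target
  midpoint, rounded to a prescribing grid;
* irregular follow-up — dense early visits, sparser later, with jitter.

The response model is a deliberately simple delayed Emax (Hill) curve:

    INR_ss(d) = baseline + emax · d^h / (ED50^h + d^h)

with patient-specific ED50 = ed50_base · s_vkorc1^(#A) · s_cyp2c9^(#var)
· lognormal interindividual noise (· amiodarone multiplier when on
amiodarone).  It is a stand-in for a real data-generating process, not a
mechanistic PK/PD model; every constant lives in :class:`SimParams`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .core import (
    INDICATIONS,
    FixedCovariates,
    Genotype,
    PatientRecord,
    TargetRange,
    Visit,
    assign_target_range,
    write_cohort,
)

__all__ = [
    "SimParams",
    "DosingPolicy",
    "VirtualPatient",
    "sample_patient",
    "steady_state_inr",
    "dose_for_target",
    "simulate_followup",
    "generate_cohort",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimParams:
    """Generative constants for the virtual cohort.

    Defaults are calibrated once so that a default cohort reproduces the
    coarse anchors of valve-surgery warfarin populations: baseline INR
    ~1.5, mean stable dose ~2.6 mg/day, Han-Chinese-like allele
    frequencies (VKORC1 −1639A ≈ 0.91, CYP2C9*3 ≈ 0.04).
    """

    baseline_inr: float = 1.5
    emax: float = 2.5  # maximal INR elevation above baseline
    ed50_base: float = 7.0  # mg/day giving half-maximal effect, wild type
    hill: float = 2.0
    sens_vkorc1_per_A: float = 0.80  # ED50 multiplier per −1639 A allele
    sens_cyp2c9_per_allele: float = 0.75  # ED50 multiplier per *2/*3 allele
    amiodarone_ed50_mult: float = 0.70  # static interaction multiplier
    iiv_sd: float = 0.25  # lognormal sd of interindividual ED50 noise
    ke: float = 0.35  # 1/day, first-order approach to steady state
    noise_sd: float = 0.10  # lognormal sd of INR measurement noise
    tau_genotype: float = 12.0  # days; decay of the genotype prior's weight in titration
    freq_vkorc1_a: float = 0.91  # −1639 A allele frequency
    freq_cyp2c9_star2: float = 0.001
    freq_cyp2c9_star3: float = 0.04
    # marginals of age/height/weight: truncated normals
    age_mean: float = 56.0
    age_sd: float = 10.0
    age_bounds: tuple[float, float] = (18.0, 90.0)
    height_mean: float = 161.0
    height_sd: float = 8.0
    height_bounds: tuple[float, float] = (140.0, 190.0)
    weight_mean: float = 59.0
    weight_sd: float = 11.0
    weight_bounds: tuple[float, float] = (35.0, 110.0)
    p_amiodarone: float = 0.03
    p_digoxin: float = 0.88
    p_genotype_known: float = 1.0
    # indication mix (mechanical, bioprosthetic, repair, other)
    indication_probs: tuple[float, float, float, float] = (0.30, 0.40, 0.25, 0.05)

    def __post_init__(self) -> None:
        if self.emax <= 0:
            raise ValueError("emax must be > 0")
        for name in ("sens_vkorc1_per_A", "sens_cyp2c9_per_allele", "amiodarone_ed50_mult"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.ke <= 0:
            raise ValueError("ke must be > 0")
        if self.noise_sd < 0 or self.iiv_sd < 0:
            raise ValueError("noise scales must be >= 0")
        for name in ("freq_vkorc1_a", "freq_cyp2c9_star2", "freq_cyp2c9_star3"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.freq_cyp2c9_star2 + self.freq_cyp2c9_star3 > 1:
            raise ValueError("CYP2C9 variant allele frequencies exceed 1")


@dataclass(frozen=True)
class DosingPolicy:
    """Clinician stand-in: proportional titration toward the target dose.

    At each visit the new dose is ``dose + gain·(d* − dose)`` rounded to
    ``grid`` and clamped to [min_dose, max_dose], where d* is the dose
    whose steady-state INR equals the target midpoint.  Follow-up days
    follow ``schedule`` (extended every ``late_interval`` days up to the
    horizon), optionally jittered by ±``jitter`` days.
    """

    initial_dose: float = 2.5  # mg/day
    gain: float = 0.6
    grid: float = 0.25  # prescribing grid, mg
    min_dose: float = 0.5
    max_dose: float = 10.0
    schedule: tuple[int, ...] = (3, 5, 7, 14, 21, 28)
    late_interval: int = 14
    jitter: int = 2
    decision_sd: float = 0.3  # mg; clinician idiosyncrasy around the rule's dose

    def round_dose(self, dose: float) -> float:
        d = round(dose / self.grid) * self.grid
        return float(min(max(d, self.min_dose), self.max_dose))

    def visit_days(self, horizon_days: int, rng: np.random.Generator | None = None) -> list[int]:
        days = [d for d in self.schedule if d <= horizon_days]
        if days:
            d = max(self.schedule)
            while d + self.late_interval <= horizon_days:
                d += self.late_interval
                days.append(d)
        if rng is not None and self.jitter > 0:
            jittered = []
            prev = 0
            for d in days:
                j = int(rng.integers(-self.jitter, self.jitter + 1))
                jittered.append(max(d + j, prev + 1))
                prev = jittered[-1]
            days = jittered
        if not days:
            raise ValueError("empty visit schedule for the given horizon")
        return days


@dataclass(frozen=True)
class VirtualPatient:
    """Fixed covariates plus the latent sensitivity driving the response."""

    fixed: FixedCovariates
    indication: str
    target: TargetRange
    ed50: float  # mg/day, patient-specific half-maximal dose


def _sample_genotype(rng: np.random.Generator, params: SimParams) -> Genotype:
    """Hardy–Weinberg draw of VKORC1 and CYP2C9 genotypes."""
    a = rng.random(2) < params.freq_vkorc1_a
    vkorc1 = ("GG", "GA", "AA")[int(a.sum())]
    p = np.array(
        [1 - params.freq_cyp2c9_star2 - params.freq_cyp2c9_star3,
         params.freq_cyp2c9_star2,
         params.freq_cyp2c9_star3]
    )
    alleles = sorted(rng.choice(["*1", "*2", "*3"], size=2, p=p))
    known = bool(rng.random() < params.p_genotype_known)
    return Genotype(cyp2c9="/".join(alleles), vkorc1=vkorc1, known=known)


def _trunc_normal(rng: np.random.Generator, mean, sd, bounds, size=None):
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_patient(rng: np.random.Generator, params: SimParams = SimParams()) -> VirtualPatient:
    """Draw one virtual patient: covariates plus latent ED50."""
    genotype = _sample_genotype(rng, params)
    fixed = FixedCovariates(
        age=float(_trunc_normal(rng, params.age_mean, params.age_sd, params.age_bounds)),
        height=float(_trunc_normal(rng, params.height_mean, params.height_sd, params.height_bounds)),
        weight=float(_trunc_normal(rng, params.weight_mean, params.weight_sd, params.weight_bounds)),
        genotype=genotype,
        amiodarone=bool(rng.random() < params.p_amiodarone),
        digoxin=bool(rng.random() < params.p_digoxin),
    )
    indication = str(rng.choice(list(INDICATIONS), p=params.indication_probs))
    ed50 = (
        params.ed50_base
        * params.sens_vkorc1_per_A ** genotype.vkorc1_a_alleles
        * params.sens_cyp2c9_per_allele ** genotype.cyp2c9_variant_alleles
    )
    if fixed.amiodarone:
        ed50 *= params.amiodarone_ed50_mult
    ed50 *= float(np.exp(rng.normal(0.0, params.iiv_sd)))
    return VirtualPatient(
        fixed=fixed,
        indication=indication,
        target=assign_target_range(indication),
        ed50=ed50,
    )


def steady_state_inr(dose: float, patient: VirtualPatient, params: SimParams = SimParams()) -> float:
    """Steady-state INR of a constant daily dose (delayed Emax model)."""
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    if dose == 0:
        return params.baseline_inr
    dh = dose ** params.hill
    return params.baseline_inr + params.emax * dh / (patient.ed50 ** params.hill + dh)


def dose_for_target(target_inr: float, patient: VirtualPatient, params: SimParams = SimParams()) -> float:
    """Invert the Emax curve: dose whose steady-state INR is target_inr."""
    delta = target_inr - params.baseline_inr
    if delta <= 0:
        return 0.0
    if delta >= params.emax:
        raise ValueError(f"target INR {target_inr} unreachable (emax={params.emax})")
    return patient.ed50 * (delta / (params.emax - delta)) ** (1.0 / params.hill)


def implied_target_dose(
    dose: float, measured_inr: float, target_inr: float, params: SimParams = SimParams()
) -> float:
    """Clinician-style inversion: the dose that would put the *observed*
    INR response onto the target, assuming the Emax form.

    The current (dose, measured INR) pair implies an apparent ED50; the
    returned dose solves the Emax curve with that apparent ED50 for the
    target INR.  Because early measurements lag the steady state, this
    estimator over-adjusts during the onset phase — the instability seen
    clinically in the first days of therapy.
    """
    delta_t = target_inr - params.baseline_inr
    if delta_t <= 0:
        return 0.0
    delta_t = min(delta_t, 0.95 * params.emax)
    delta_m = np.clip(measured_inr - params.baseline_inr, 0.05, 0.95 * params.emax)
    ratio = (delta_t / (params.emax - delta_t)) / (delta_m / (params.emax - delta_m))
    return float(dose * ratio ** (1.0 / params.hill))


def genotype_prior_ed50(patient: VirtualPatient, params: SimParams = SimParams()) -> float:
    """Population ED50 implied by genotype and co-medication alone.

    This is what a genotype-guided dosing table knows about the patient
    before any INR feedback — the true latent ED50 without its
    interindividual lognormal deviation.
    """
    g = patient.fixed.genotype
    ed50 = (
        params.ed50_base
        * params.sens_vkorc1_per_A ** g.vkorc1_a_alleles
        * params.sens_cyp2c9_per_allele ** g.cyp2c9_variant_alleles
    )
    if patient.fixed.amiodarone:
        ed50 *= params.amiodarone_ed50_mult
    return ed50


def simulate_followup(
    patient: VirtualPatient,
    policy: DosingPolicy = DosingPolicy(),
    params: SimParams = SimParams(),
    horizon_days: int = 90,
    rng: np.random.Generator | None = None,
    patient_id: str = "sim",
) -> PatientRecord:
    """Simulate one patient's titration course.

    Between visits the latent INR follows dINR/dt = ke·(INR_ss − INR)
    with the dose held constant, solved exactly per segment; the
    measured INR is the latent value times lognormal noise.  At each
    visit the dose moves proportionally (by ``policy.gain``) toward a
    target-dose estimate blending a genotype-guided population prior
    with the inversion of the measured INR; the prior's weight decays
    as exp(−day/tau_genotype), mirroring genotype-guided initiation
    giving way to INR-guided maintenance.  The recorded dose is the
    newly adjusted dose going forward.
    """
    rng_local = rng if rng is not None else np.random.default_rng(0)
    days = policy.visit_days(horizon_days, rng_local if rng is not None else None)

    delta_t = min(patient.target.mid - params.baseline_inr, 0.95 * params.emax)
    prior_dose = 0.0
    if delta_t > 0:
        prior_dose = genotype_prior_ed50(patient, params) * (
            delta_t / (params.emax - delta_t)
        ) ** (1.0 / params.hill)

    inr = params.baseline_inr  # latent state at day 0
    dose = policy.round_dose(policy.initial_dose)
    prev_day = 0
    visits = []
    for day in days:
        dt = day - prev_day
        ss = steady_state_inr(dose, patient, params)
        inr = ss + (inr - ss) * math.exp(-params.ke * dt)
        if not np.isfinite(inr):
            raise FloatingPointError("non-finite latent INR state")
        noise = math.exp(rng_local.normal(0.0, params.noise_sd)) if params.noise_sd > 0 else 1.0
        measured = inr * noise
        w = math.exp(-day / params.tau_genotype)
        d_hat = w * prior_dose + (1.0 - w) * implied_target_dose(
            dose, measured, patient.target.mid, params
        )
        wobble = (
            rng_local.normal(0.0, policy.decision_sd) if policy.decision_sd > 0 else 0.0
        )
        new_dose = policy.round_dose(dose + policy.gain * (d_hat - dose) + wobble)
        visits.append(Visit(day=int(day), inr=float(measured), dose=float(new_dose)))
        dose = new_dose
        prev_day = day
    return PatientRecord(
        patient_id=patient_id,
        fixed=patient.fixed,
        visits=tuple(visits),
        indication=patient.indication,
        target=patient.target,
    )


def simulate_cohort(
    n: int,
    seed: int,
    params: SimParams = SimParams(),
    policy: DosingPolicy = DosingPolicy(),
    horizon_days: int = 90,
    id_prefix: str = "P",
) -> list[PatientRecord]:
    """Generate n virtual PatientRecords, deterministic in the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n)))
    records = []
    for i in range(n):
        patient = sample_patient(rng, params)
        rec = simulate_followup(
            patient, policy, params, horizon_days, rng,
            patient_id=f"{id_prefix}{i:0{width}d}",
        )
        records.append(rec)
    return records


def generate_cohort(
    n: int,
    seed: int,
    path,
    params: SimParams = SimParams(),
    policy: DosingPolicy = DosingPolicy(),
    horizon_days: int = 90,
) -> list[PatientRecord]:
    """Generate a cohort and serialize it to a cohort CSV; returns the records."""
    records = simulate_cohort(n, seed, params, policy, horizon_days)
    write_cohort(records, path)
    return records
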