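# Methods

## Problem

Warfarin dosing after heart valve surgery is feedback control under
uncertainty: the clinician observes the INR at irregular follow-up
visits and adjusts the daily dose toward an indication-specific
therapeutic interval (mechanical valve 2.0–2.5, bioprosthetic valve
1.8–2.3, valve repair 1.5–2.5; 2.0–3.0 is the package default for other
indications).  Dose requirements vary several-fold between patients,
driven largely by CYP2C9 (*2/*3 reduced-function alleles) and VKORC1
−1639G>A genotype, and the pharmacodynamic response is delayed, so INR
is unstable during the first days of therapy.  `warfdose` provides

1. a virtual-patient simulator producing longitudinal cohorts with this
   structure (real visit-level anticoagulation cohorts are rarely
   deposited),
2. a sequence dose-prediction model — a feedforward branch for fixed
   covariates fused with a (bi)directional LSTM branch over the visit
   series — with the full training and model-selection protocol, and
3. the standard evaluation suite: tolerance-band dose/INR accuracy,
   stable-dose detection and accuracy, per-visit accuracy, genotype
   subgroups, the missing-genotype ablation, and Rosendaal
   time-in-therapeutic-range (TTR).

## Virtual-patient model (`cohortsim`)

The simulator is deliberately the simplest generative process that
reproduces the qualitative facts a sequence model must exploit; it is
not a mechanistic PK/PD model (no S/R enantiomers, no clotting-factor
cascade), and all constants live in `SimParams`.

**Steady-state response.**  A Hill (Emax) curve

    INR_ss(d) = baseline + emax · d^h / (ED50^h + d^h)

with `baseline = 1.5` (typical of valve-surgery cohorts after surgery),
`emax = 2.5`, `h = 2`, and a patient-specific half-maximal dose

    ED50 = ed50_base · s_V^(#A alleles) · s_C^(#variant alleles)
           · (amiodarone multiplier) · exp(ε),   ε ~ N(0, 0.25²)

with `ed50_base = 7.0` mg/day, `s_V = 0.80` per VKORC1 −1639 A allele,
`s_C = 0.75` per CYP2C9 *2/*3 allele, amiodarone multiplier 0.70.
Genotypes are drawn under Hardy–Weinberg with Han-Chinese-like allele
frequencies (A allele 0.91, *3 0.04, *2 0.001); anthropometrics come
from truncated normals (age 56 ± 10 y, height 161 ± 8 cm, weight
59 ± 11 kg) matching the marginals of the motivating population.

**Dynamics.**  Between visits the latent INR relaxes toward the current
dose's steady state with first-order kinetics, dINR/dt = ke·(INR_ss −
INR), `ke = 0.35`/day (≈3-day time constant), solved exactly per
constant-dose segment.  Measured INR is the latent value times
lognormal noise (`noise_sd = 0.10`, i.e. ≈10% CV — combined analytic
and biologic variability).  The onset delay makes INR visibly unstable
during days 3–5 of therapy.

**Titration policy.**  At each visit the clinician stand-in moves the
dose proportionally (gain 0.6) toward a target-dose estimate, rounds to
a 0.25 mg prescribing grid and clamps to [0.5, 10] mg/day.  The
estimate blends two sources:

* a *genotype-guided prior* — the dose solving the population Emax
  curve (genotype and co-medication, without the individual lognormal
  deviation) for the target midpoint — weighted `exp(−day/12)`;
* an *INR-guided inversion* — the dose solving the Emax curve whose
  apparent ED50 is implied by the current (dose, measured INR) pair —
  taking over as follow-up accumulates.

This mirrors genotype-guided initiation giving way to INR-guided
maintenance.  Because early measurements lag the steady state, the
inversion over-adjusts in the first week, another realistic source of
early instability.  A clinician-idiosyncrasy term (N(0, 0.3 mg) before
rounding, `decision_sd`) keeps the prescribed dose from being an exact
function of the observables; it bounds every predictor's achievable
accuracy below 100%, without which architecture comparisons would be
sign-flips of numerical noise.
Visits follow days 3, 5, 7, 14, 21, 28, then every 14 days, jittered by
±2 days to emulate irregular real-world monitoring.

Defaults were calibrated once against coarse published anchors — a
default cohort has mean stable dose ≈2.5 mg/day (anchor ≈2.6), median
TTR in the low 80s, and ≈68% of INR measurements in range — and then
frozen.  **What the simulator does not contain:** adherence lapses,
acute illness, diet/drug-interaction dynamics, informative visit
scheduling, measurement outliers, or model misspecification relative to
the Emax form.  Passing the learning-recovery checks therefore shows
the pipeline can recover a realistic titration process from data with
the right qualitative structure; it is not evidence about performance
on real patients.

## Supervised samples (`dataset`)

Each patient with V visits yields V−1 samples, one per decision visit
i ∈ {2..V}.  The sequence covers visits 1..i; a step carries
(Dose_{i−1}, INR_i, Interval_{i+1}, Dose_i) plus a mask-indicator
channel.  At the decision step the target field (dose, or INR for the
INR variant) is hidden: its value is set to the training mean in
normalized space (0) and the indicator set to 1, which cannot collide
with a genuine value because the indicator is 0 everywhere else.  The
model may see the decision visit's INR and the planned next interval —
the interval is planner-chosen, hence known at decision time — but
never its own label.  Two boundary conventions: the first step's
previous dose duplicates its own dose (zero would falsely signal no
prior anticoagulation), and the final step's next interval duplicates
the preceding one when no later visit exists.

Genotype enters the fixed-covariate vector as gene-dose counts (CYP2C9
variant alleles 0–2, a *3-carriage indicator, VKORC1 A alleles 0–2) —
the standard ordinal coding of warfarin dosing algorithms.  Unknown
genotype is encoded as the training-set mean of each genotype feature
(0 after z-normalization): neutral imputation, so a genotype-blind
consumer is exactly the mean-imputed one.

Splits are patient-grouped (records within a patient are correlated):
10% of patients form the held-out test set; the rest are partitioned
into k = 10 cross-validation folds, each fold once the validation set
(≈9% of patients) with the remainder (≈81%) for training.
Normalization statistics (z-scores) are computed from training-fold
samples only and stored inside the trained artifact.

## Network and training (`models`, `nnet`, `train`)

Fixed covariates pass through a one-hidden-layer ReLU feedforward
branch (width 64 by default); the visit sequence through stacked
LSTM layers (2 layers, hidden size 128 by default), optionally
bidirectional — the backward stack runs over the reversed valid prefix
of each right-padded sequence.  Per-step hidden states are max-pooled
over valid (non-pad) time positions, concatenated with the feedforward
representation, and mapped linearly to one scalar: the normalized label.
Pooling over all time positions (rather than taking the final state)
makes predictions invariant to padding by construction.

The engine is NumPy with hand-written backpropagation (gate order
input/forget/cell/output; uniform ±1/√H initialization), verified
against central finite differences in the test suite.  Training is
mini-batch Adam (default learning rate 0.025, batch size 32) on MSE
over normalized doses; accuracy metrics are always computed on
denormalized mg/day.  Early stopping: at most 100 epochs, stop after 10
consecutive epochs whose validation loss fails to undercut the best so
far by ≥1e-4 (normalized-loss units — "no significant reduction"
quantified), restore the best-validation-epoch parameters.  Weight
initialization and batch shuffling derive from the configuration seed;
repeated trainings differ only by seed.

Hyperparameters are tuned coordinate-wise (hidden size, batch size,
layers, learning rate; default grids {32,64,128,256}, {16,32,64},
{1,2,3}, {0.001,0.005,0.01,0.025,0.05}), each candidate scored by the
mean test-set dose accuracy of three seeded replicates; a
single-candidate axis is adopted without training.  Scoring the sweep
on the test set leaks test information into model choice; a
`score_on="val"` switch scores on the validation fold instead.  The
final configuration is trained ten times; the candidate with the best
test accuracy wins, ties broken by lower RMSE (the selection statistic
had to be fixed: accuracy primary, RMSE tiebreak).

## Evaluation (`predmetrics`, `anticoag`)

* **Tolerance bands.**  within iff |pred − ref| ≤ tol·ref with
  inclusive boundary; tol 0.20 for doses, 0.30 for INR; over/under by
  sign otherwise.  Reported percentages are rounded half-up to one
  decimal.  Errors are predicted − reference (over-prediction
  positive); the convention is printed on every error summary.
* **Stable dose.**  The earliest window of consecutive visits with an
  unchanged dose spanning ≥14 days whose in-window INRs all lie inside
  the target range.  The phrase "within 7 days after initial dosing" is
  ambiguous; by default the window must *begin no earlier than day 7*
  (initiation transient excluded), with a flag for the alternative
  reading (begin within the first 7 days).  Stable-dose accuracy
  classifies the model's prediction at every in-window decision visit
  against the stable dose (a flag restricts to the first).
* **Genotype subgroups.**  highly sensitive = VKORC1 AA with ≥1 CYP2C9
  variant allele; sensitive = AA with *1/*1, or GA/GG with ≥1 variant
  allele; normal = GA/GG with *1/*1.  This is a CPIC-style convention
  (the authoritative mapping is not public) and unknown genotypes form
  an explicit "unclassified" stratum.
* **Rosendaal TTR.**  Linear interpolation between consecutive INRs
  with exact boundary-crossing arithmetic; the therapeutic interval is
  closed (boundary values count as in range); consecutive measurements
  more than 56 days apart (a common convention; configurable) are
  excluded from numerator and denominator; a single usable measurement
  reports TTR as missing.  Cohort summaries aggregate per patient
  (median/IQR).  Windowed summaries clip interpolation segments
  geometrically at the window bound.

## Numerical and design notes

* Early-stopping counters are exact: a flat validation loss from epoch
  1 stops after epoch 11 (1 + patience).
* Division-by-zero guards: constant features get std 1 and a flag;
  zero-variance references report R² as missing; degenerate Δ in the
  Emax inversions is clamped.
* Dose predictions are clamped to [0, 10] mg/day, INR predictions to
  ≥0.1.
* The scaled-down experiment driver (`experiments`) uses hidden size
  32, learning rate 0.01 and ≤25 epochs over 3 seeds with cohorts of
  800 training / 200 external patients — sizes chosen so the full study
  runs in minutes on a single CPU while matching the modeling /
  external-validation cohort sizes of the underlying design.

## Known limitations

* The Emax/first-order simulator is a stand-in; none of its constants
  are estimates from data.
* In the simulator, genotype acts on future doses only through channels
  that the visit history itself reveals (the first adjusted doses embed
  the genotype prior, and the INR trajectory pins the patient's
  sensitivity more precisely than the prior does).  A well-fitted model
  therefore learns to lean on the sequence branch, and evaluation-time
  genotype masking moves its predictions only marginally — the
  experiment driver computes and reports this masking effect rather
  than assuming it.  Real cohorts, where genotype carries information
  the recorded history does not, can behave differently.
* The NumPy engine targets clarity and testability, not throughput; it
  is single-threaded and has no GPU path.
* Attention/transformer variants, INR-variability indices, and
  between-model hypothesis tests are out of scope.
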