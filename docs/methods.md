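# Methods

`hypoclamp` implements the computational chain of a standardised
insulin-induced postprandial hypoglycaemic clamp with a dual
glucose-tracer protocol: a virtual-subject simulator with closed-loop
glucose-infusion control, non-steady-state isotope-dilution (Steele)
estimation of glucose fluxes, insulin-secretion reconstruction by
regularised C-peptide deconvolution, insulin sensitivity and clearance
metrics, and the group-comparison statistics used for such cohorts.
This note records the models, the defaults and why, the numerical
choices, and what the synthetic test bed does and does not establish.

## The protocol

All times are minutes relative to the oral glucose load (t0). A primed
(3 mg/kg) continuous (0.03 mg/kg/min) iv glucose-tracer infusion starts
at −100 min. At t0 the subject drinks 15 g of glucose carrying a 1.5%
mass fraction of a second (oral) tracer, over 5 min. A fixed insulin
infusion (0.0623 U/kg/h ≡ 6.23 pmol/kg/min) runs from t90 to t170. A
PID controller modulates the exogenous glucose infusion rate (GIR) so
that blood glucose follows a linear descent from its level at t90 to
the 2.5 mmol/l target at t150, holds the target to t170, then restores
euglycaemia. Outcomes are computed over the postprandial window
[0, 85] and the hypoglycaemic window [150, 170].

## Virtual subject

The simulator is an oral-minimal-model style ODE system (16 states):
single well-mixed glucose pool, two-compartment gut, remote insulin
action `X`, threshold-linear insulin secretion, two-compartment
C-peptide kinetics, one-compartment endogenous-insulin and
insulin-analogue pharmacokinetics, both tracers, and six first-order
counter-regulatory hormone responses activated below per-hormone
glucose thresholds. Counter-regulation feeds back on endogenous
glucose production (EGP) as a threshold-linear term
`gamma_CR * max(0, G_CR − G)` rather than through the hormone
concentrations, so the ground-truth EGP remains a simple, inspectable
function of state; the hormone trajectories are generated in parallel
for the outcome statistics. The tracer prime enters the tracer balance
only — 3 mg/kg is ~0.1% of the glucose pool mass and is neglected in
the cold-glucose balance, which keeps the unperturbed fasting state an
exact fixed point.

Key defaults (all per-kg where applicable):

| parameter | value | units | why |
|---|---|---|---|
| `g_b` | 4.9 | mmol/l | typical fasting glucose of the cohorts analysed |
| `v_g` | 160 | ml/kg | conventional glucose distribution volume |
| `egp_b` | 1.82 | mg/kg/min | basal EGP scale of a fasting tracer study |
| `s_g` | derived | 1/min | chosen so fasting disposal balances `egp_b + F` exactly |
| `s_i` | 3.5e-5 | 1/min per pmol/l | open-loop glucose ≈2.4 mmol/l at t150, so a GIR-only controller (it can add but never remove glucose) can land on the target |
| `p2` | 0.05 | 1/min | ~20-min insulin-action lag |
| `k_empt`, `k_abs` | 0.045, 0.06 | 1/min | early glucose peak (~50 min) with ~90% of the drink absorbed by t85 |
| `f_bio` | 0.68 | – | systemic oral bioavailability net of first-pass splanchnic uptake; yields ~63% oral recovery over [0, 85] |
| `basal_isr`, `beta_sec` | 1.5, 2.4 | pmol/kg/min (, per mmol/l) | fasting insulin ~32 pmol/l and a postprandial ISR peak of ~7 pmol/kg/min |
| `hepatic_extraction` | 0.5 | – | standard first-pass fraction |
| `cl_ins` | 23.4 | ml/kg/min | post-hepatic endogenous clearance; AUC-ratio clearance ≈47 ml/kg/min |
| `cl_aspart` | 7.08 | ml/kg/min | clamped analogue plateau ≈880 pmol/l under the 6.23 pmol/kg/min infusion |

These are calibration choices reproducing the protocol's published
operating points (target reached at t150, low-60% oral recovery,
~900 pmol/l analogue levels, sub-unity HOMA-IR); they are not fitted to
any individual's data. Group templates multiply them to produce the
qualitative contrasts of interest — faster gastric emptying and
steeper secretion after gastric bypass (`k_empt`, `beta_sec` × 1.6–1.8),
blunted glucagon gain (× 0.4) in all surgical groups, a near-absent
pancreatic-polypeptide gain (× 0.1) in the hypoglycaemia-prone group,
and analogue-clearance multipliers spreading the clamped analogue
levels. Only orderings and coarse bands of these contrasts are
asserted anywhere; the multipliers are knobs, not estimates.

Inter-subject variability: kinetic and secretory parameters get
independent lognormal factors with CV 15% (mean 1); the distribution
volume varies at CV 5% (volumes per kg vary much less than rate
constants), body weight at CV 12%, basal glucose as N(4.9, 0.15²)
clipped to [4.2, 5.6]. Measurement noise is multiplicative Gaussian
truncated at zero, per-channel CV: glucose 2%, enrichments 1.5%,
hormones and peptides 5%, GIR exact (it is the actuation record).

Integration is fixed-step RK4 at 0.25 min with truth recorded on a
1-min grid. A fixed-step explicit scheme was chosen over an adaptive
library integrator because the closed loop advances in 5-min chunks
with a discontinuous input at each controller update, the states are
non-stiff at this resolution, and bitwise determinism across platforms
is a requirement (identical master seed ⇒ identical written cohort
files). Doses and phase switches (t0, t5, t90, t170) fall on step
boundaries, so the discontinuities never cross a step. A glucose
excursion below 0.5 mmol/l aborts with an error naming the offending
parameters. Recorded GIR is right-continuous: the value stamped at a
switch time is the rate applying from it, so a zero-order-hold
reconstruction of the sampled GIR channel is exact.

The simulated protocol always executes its nominal phases, so the
sampled record carries the nominal [150, 170] window; the time at
which measured glucose first came within 0.1 mmol/l of the target is
kept in the truth record as a diagnostic. Right-shifted windows — real
experiments in which the plateau came late and the whole sampling
schedule shifted with it — are handled on the analysis side
(`align_hypo_window`): samples at or after the insulin start are
rigidly shifted so the achieved window maps onto [150, 170], samples
before it are untouched (the postprandial window is never distorted),
and a shift that would break time ordering within a channel is an
error rather than a silent repair.

## Controller

A textbook discrete positional PID (default update interval 5 min)
with output clipped to [0, 15] mg/kg/min and conditional-integration
anti-windup (the integral freezes while the output saturates in the
direction the error pushes). The descent reference is linear by
default; an exponential-shape option is provided. Gains (Kp 6, Ki 1,
Kd 12 in mg/kg/min per mmol/l, per mmol/l·min, per mmol/l/min) were
tuned once on the default subject and stored as the config defaults:
the noise-free closed loop reaches 2.50 ± 0.1 mmol/l at t150, holds a
window mean near 2.5, and infuses under 3 g of rescue glucose in the
window. Because the controller can only add glucose, subjects whose
drawn insulin sensitivity is well below nominal plateau late — the
simulator reproduces the delayed-plateau phenomenon seen in a minority
of real experiments.

## Glucose fluxes (dual-tracer, non-steady-state Steele)

With C total plasma glucose in mg/ml, z1 and z2 the iv- and
oral-tracer-to-tracee ratios, F the iv-tracer infusion and p·V the
effective transient volume:

    Ra_tracee = [F − p·V·(C/(1+z1))·dz1/dt] / z1
    Ra_tot    = Ra_tracee + F
    Rd        = Ra_tot − p·V·dC/dt
    C2        = C·z2/(1+z1+z2)
    RaO       = [p·V·dC2/dt + Rd·C2/C] / e_oral
    EGP       = Ra_tot − F − RaO − GIR

Conventions. Ra_tot is reported inclusive of the tracer infusion, so
at fasting steady state Ra_tot − EGP = F exactly (the 0.03 mg/kg/min
gap between a fasting turnover of 1.85 and production of 1.82). The
1.5% oral label is treated as a mass fraction: dividing the oral-tracer
flux by 0.015 gives total oral appearance including the label; a
`ttr` option divides by 0.015/0.985 instead and yields unlabelled oral
appearance. Defaults p = 0.65, V = 160 ml/kg are the conventional
human values, where incomplete mixing makes the effective transient
pool smaller than the anatomical one. Against the simulator — a
perfectly mixed single pool — the matched value is p = 1, and all
recovery tests use it; using 0.65 there would deterministically bias
the oral-appearance AUC by about −20% and would test the convention,
not the estimator.

Smoothing and differentiation. Default: cubic smoothing spline with
the penalty chosen by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`); alternatives: fixed-
penalty spline (exactly linear in the data) and local quadratic
regression with tricube weights. The iv-tracer ratio is smoothed in
log space by default: its washout is exponential, which a cubic spline
tracks poorly in linear space (systematic ~2% underestimation of the
fasting derivative term) and almost exactly in log space. Leading
background draws separated from the kinetic sampling block by more
than 30 min are excluded from the fits — they are calibration samples,
and bridging the gap bends the spline. The GIR record is averaged to
the smoother's bandwidth (11-min moving average) before the EGP
partition, because smoothed derivatives cannot track the controller's
5-min square wave and subtracting it raw injects anti-phase ripple
into EGP; the raw reconstruction stays in the diagnostics. Reported
fluxes are clipped at zero with pre-clip arrays and the clipped-point
fraction kept in the diagnostics.

Fasting fluxes are time-averages over [−30, −15] min. The window ends
a sampling interval before ingestion because the spline cannot
represent the derivative kink at t0 and oscillates for roughly one
sampling interval on either side of it; evaluated there, the fasting
EGP across 100 noisy virtual subjects is median-unbiased to well
within 2%.

Postprandial metrics: trapezoidal AUC(0–15) of RaO/Ra_tot/Rd; EGP
suppression at t15 as (EGP(15) − EGP(0))/EGP(0); oral recovery as
AUC(0–85) of RaO × body weight / oral dose × 100.

## Insulin secretion and clearance

ISR is reconstructed from plasma C-peptide by discretising secretion
as piecewise-constant on 5-min intervals, building the convolution
matrix from the closed-form cumulative two-compartment impulse
response (steady pre-history folded into the first unknown), and
solving `min ‖C − H·s‖² + λ‖D₂·s‖²` subject to `s ≥ 0` (bounded-
variable least squares). λ follows a discrepancy rule — residual RMS
matched to the assay CV (default 4%) over a geometric grid — with a
fixed-λ override. Population C-peptide kinetics derive from the
bi-exponential half-lives 4.95/29.2 min with fast-fraction 0.76
(4.55/26.5/0.78 for obese subjects) inverted to rate constants, and a
distribution volume of 2.66 l per m² DuBois body surface area (≈5 l
for a typical adult); all exposed in `CPeptideKinetics` since the
classical software's exact adjustment rules are not public.

Sensitivity index: Rd/(glucose in mg/ml)/(insulin in nmol/l), i.e. a
glucose clearance normalised by insulin, in ml/min/kg per nmol/l.
Window versions use time-averaged (trapezoidal mean) inputs; the
postprandial version uses endogenous insulin alone, the hypoglycaemic
version endogenous plus analogue, with the analogue assumed equipotent
to human insulin. Total insulin clearance is AUC(ISR)/AUC(endogenous
insulin) ×1000 (ml/kg/min). Post-hepatic clearance fits
`V·dI/dt = 1000·R(t) − CL·I` over the observation intervals of the
analogue record by least squares (V fixed at 140 ml/kg by default, a
fit-V option provided), reducing to CL = 1000·R/I at steady state; a
flat-zero analogue record raises an identifiability error. The classic
HOMA1-IR formula `G·(I/6)/22.5` is provided for fasting resistance
with the explicit caveat that it is the first-generation approximation,
not the structural HOMA2 computer model.

## Outcome statistics

Trapezoidal AUC (window endpoints interpolated when between samples);
incremental AUC relative to a named baseline sample (negative parts
retained — the responses of interest are increases, and truncation is
not part of the definition); window mean/SD/CV as plain sample
statistics of the observations; peaks with ties broken by earliest
time; symptom sum scores over the 11-item scale (total 11–77,
autonomic 4–28, neuroglycopenic 5–35, malaise 2–14).

Group comparison cascade: one-way ANOVA on raw values if Shapiro–Wilk
on residuals and Levene's test both pass at 0.05; otherwise ANOVA on
log-transformed values (only when all values are positive); otherwise
Kruskal–Wallis. Post hoc: Tukey HSD on the ANOVA paths, pairwise
two-sided Mann–Whitney (unadjusted, mirroring the single-variable
α = 0.05 convention) on the Kruskal–Wallis path. The executed checks
are recorded in an assumption trail. Under a 4 × 8 normal null the
full cascade rejects at 4.6–5.4% across seeds (1000 replicates). For
two-time-point variables, paired t vs Wilcoxon signed-rank selected by
Shapiro–Wilk on the differences.

## What the synthetic test bed shows — and what it does not

The generator's purpose is to provide inputs with known ground truth
under the study's protocol conditions. Passing the recovery suites
shows the estimators are correctly derived and numerically stable
against data of the stated sampling density and noise: fluxes whose
oral-appearance AUC is recovered to a few percent (criterion ≤10%
median), median-unbiased fasting EGP (≤2%), deconvolution that inverts
its forward model to <1% noise-free and ~5% under 3% noise, clearances
within 15%. It does not show fidelity to human physiology beyond the
engineered operating points: the glucose pool is perfectly mixed (no
pool-fraction ambiguity), enrichment noise is independent and
multiplicative (real MS runs drift), hormone responses are first-order
with clean thresholds, C-peptide kinetics in the simulator and the
estimator share the same population map (no kinetic-model
misspecification is probed), and group contrasts are encoded, not
emergent. Hormone concentration scales are plausible but deliberately
not fitted to any cohort.

## Problem sizes and runtimes

Default test-bed sizes: one subject ≈ 0.1 s; the four-group cohort
(32 subjects) ≈ 2.5 s; the 100-subject recovery bed ≈ 12 s (simulated
once per session); the 1000-replicate null calibration ≈ 2 s. The
full test suite runs in about half a minute; the acceptance script in
a few seconds.
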