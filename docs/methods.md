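# Methods

This note documents the models, estimators and numerical choices behind
`csfdyn`: what the simulator emulates, how the analysis statistics are
defined, which conventions were open and how they were fixed.

## 1. CSF-dynamics simulator (`csfdyn.simulate`)

### Trend model

The slow component of ICP follows the single-compartment nonlinear storage
equation of CSF dynamics:

    dP/dt = E · (P − P0) · [ I_ext(t) + I_f − (P − P0) / R_out ]

with elastance coefficient `E` (1/ml), reference pressure `P0` (mmHg), CSF
formation rate `I_f` (ml/min), outflow resistance `R_out` (mmHg·min/ml) and
external flow `I_ext` (ml/min; positive = infusion, negative = drainage).
Its steady state under constant net inflow is closed-form,
`P* = P0 + R_out·(I_f + I_ext)`, which anchors the analysis tests: a
noise-free phase-end mean equals `P*` to 1e-3 mmHg.

Defaults: `P0 = 5 mmHg`, `I_f = 0.35 ml/min`, `E = 0.11 /ml`,
`R_out = 13 mmHg·min/ml`, heart rate 1.2 Hz, respiration 0.25 Hz,
`fs = 100 Hz` (20 Hz in the desk-scale studies below). These are
literature-typical values; the resting baseline is
`P0 + R_out·I_f = 9.55 mmHg`, below the 15-mmHg ceiling required of infusion
candidates. The trend relaxation time is `1/(E·I)` minutes (≈ 26 min at
rest, ≈ 5 min under 1.5 ml/min infusion).

### Oscillatory components (additive)

The recorded pressure adds, on top of the trend `P(t)`:

* a cardiac pulse `a(P)·sin(2π f_c t)` with the piecewise-linear AMP law
  `a(P) = a0 + k_amp·max(P − P_bp, 0)` — flat (floor `a0`, default 1 mmHg)
  below the breakpoint pressure `P_bp` where the pressure–volume curve is
  linear, rising (slope `k_amp`, default 0.5) above it;
* a respiratory sinusoid (default 0.3 mmHg);
* slow "B-wave" activity: a bounded (reflected) random walk on the formation
  rate, scaled so the induced pressure modulation spans ±`slow_wave_amp`
  and traverses that band in ≈ `slow_wave_tau_s`. Without this slow
  mean-ICP variance a moving AMP-vs-ICP correlation is degenerate;
* white Gaussian measurement noise (`noise_sd`).

Keeping these additive on the trend solution (rather than coupled into the
ODE) keeps every ground-truth steady state closed-form. The trend is
integrated with fixed-step classical RK4 at step `min(0.1 s, 1/fs)`;
protocol flows are held constant within a step so phase boundaries are
exact, and a step-halving test bounds the integration error below 1e-6
mmHg. Drainage that would push the trend to `P0` is clamped 0.05 mmHg above
it and flagged. Identical `(config, seed)` give bit-identical recordings.

### Infusion-test protocol

`simulate_infusion_test` records ≥ 10 min of baseline, then infuses at
1.5 ml/min, applying the clinical termination rules online: the infusion
ends 10 min after a plateau is confirmed, or immediately when the running
two-point Rout estimate exceeds 18 mmHg·min/ml before any plateau (never
before a 5-min protocol minimum), or at a 45-min cap. The applied reason is
recorded. Two conventions matter:

* the protocol's own plateau confirmation uses a 1-min rolling-mean slope
  < 0.05 mmHg/min sustained 5 min — stricter than the analysis-side
  detector — so the recorded plateau segment is essentially converged;
* the rule decision runs on the deterministic trend (no B-waves/noise), so
  the protocol durations are a reproducible function of the physiology.

`terminate_on_rout=False` runs every test to plateau; this ground-truth
mode is what the recovery studies use, since a true `R_out > 18` would
otherwise be censored at the threshold by design.

### Drainage protocol and the reserve-recovery fraction ρ

`simulate_drainage` produces an 8-h pre-drainage baseline followed by two
24-h drainage days. The latent reserve-recovery fraction `ρ ∈ [0,1]` scales
how far the operating point is drawn below the AMP breakpoint: the target
trend descends from the resting point toward
`P_base − ρ·(P_base − p_low)` (default `p_low = P_bp − 1.7 mmHg`), ~70% of
the descent settling early in day 1 and the rest early in day 2, mirroring
the clinically prompt RAP response to drain opening. The drainage-suited
config lowers `P_bp` to 7.5 mmHg and widens the B-wave band to ±1.5 mmHg so
that partial descents produce a *graded* RAP decline (the fraction of slow
excursions below the breakpoint grows smoothly with ρ).

**Compressed time.** Real 56-h recordings are impractical for tests, so a
`compression` factor (default 60) divides all protocol durations and scales
the day-boundary events. The elastance is multiplied by the same factor so
the trend time constants compress with the protocol (steady states are
E-independent and unchanged). Drained-volume bookkeeping
(`drain_rate_ml_h × 48 h`) stays on the clinical time base via the recorded
compression factor. `compression=1` gives real time.

### Cohort generator (`csfdyn.cohort`)

Fast mode samples per-patient summary statistics directly:

* `Rout ~ N(13.7, 4.1²)` truncated to [6, 25] mmHg·min/ml;
* `RAP1max ~ N(0.70, 0.14²)` (clipped to [0.20, 0.99]), sharing a Gaussian
  copula with Rout (r = 0.40 — higher outflow resistance accompanies poorer
  baseline reserve);
* `ρ ~ Beta(2.5, 1.5)`; day-1/day-2 drop fractions `ρ·δ1 + ε` and
  `ρ·δ2 + ε` with `δ1 = 0.30`, `δ2 = 0.82` and Gaussian noise, giving
  RAP2max and RAP3max marginal means ≈ 0.57 and ≈ 0.34;
* outcome `P(dRL) = logistic(−7.7 + 0.08·ΔRAP1max% + 0.08·ΔRAP2max% +
  0.16·Rout)`, calibrated once to a ≈ 54% dRL prevalence and an AUC
  ordering (total index ≈ 0.89 > ΔRAP2 ≈ 0.86 > ΔRAP1 ≈ 0.81 ≫ Rout ≈ 0.59)
  that mirrors clinically reported behaviour; mRS is then drawn within the
  dRL / non-dRL band. Ground truth (ρ, linear predictor, generative
  probability) is returned in a separate table.

The published per-patient joint distribution of the ΔRAPmax% statistics is
not recoverable from summary tables — the reported ΔRAP1max% mean (40.2%)
is not consistent with the RAPmax means (0.70 → 0.57 implies 18.6% on the
means) — so the generator targets the RAPmax marginals and exposes
`delta1`/`delta2` and the ρ distribution as parameters rather than guessing
a joint law. Under the defaults the ΔRAP% marginals therefore do *not*
match the published 40.2/40.4% means.

Waveform mode simulates a full drainage recording and infusion test per
patient and runs the analysis pipeline on them (~0.7 s/patient); it is the
end-to-end validation path, used at small n.

## 2. Signal reduction (`csfdyn.signal`)

Recordings are cut into consecutive non-overlapping windows (default 10 s).
Per window: `mean_icp` is the arithmetic sample mean; AMP is estimated
spectrally — linear detrend, Hann taper, FFT, peak search within the
cardiac band (0.67–3 Hz = 40–180 bpm), amplitude from the main-lobe energy
(±3 bins, insensitive to the peak falling between bins; ≤ 0.01% error for
in-band sinusoids), frequency refined by parabolic interpolation. A window
is invalid when the in-band peak is < 3× the median in-band level or the
samples are degenerate. A half-peak-to-peak time-domain estimator is
available as a sensitivity alternative.

RAP is the Pearson correlation over the trailing `span_n` windows (default
40 ≈ 6.7 min), stepped one window at a time and timestamped at the centre
of the trailing window (causal convention). A point is valid only when
≥ 75% of its windows are valid and both coordinates are non-degenerate;
degenerate points carry `rap = 0, valid = False` so the series stays
time-aligned. The AMP degeneracy floor is 0.01 mmHg of standard deviation
across the span: below the breakpoint the true AMP is exactly flat, and
without this floor numerically-tiny AMP jitter would produce spurious
null-correlation draws instead of a flagged degenerate span. The clinical
source never states its windowing; 10 s / 40 windows follows the
established bedside-monitoring convention and both are configuration keys.

## 3. Infusion analysis (`csfdyn.infusion`)

* **Baseline**: longest pre-infusion span whose trailing 1-min rolling
  means stay within a 1-mmHg band; must be ≥ 10 min. `Pb` is its mean.
* **Plateau**: final span with |1-min rolling-mean slope| < 0.2 mmHg/min
  sustained ≥ 5 min. `Pp` is the mean over the trailing 3 min of that span —
  the early part still carries the exponential approach and would bias the
  plateau low (≈ 0.2 mmHg at default elastance). With no plateau, a running
  two-point Rout > 18 yields `rout_exceeds_18` with `Pp` the last stable
  rolling mean (flagged); otherwise `max_duration`.
* **Rout**: the two-point form `(Pp − Pb)/I_inf` is the primary estimator;
  `rout·I_inf + Pb = Pp` holds exactly by construction.
* **Full model fit**: (R, E, P0) by multi-start Levenberg–Marquardt on the
  numerically integrated storage equation against the 1-min-averaged curve,
  with the baseline tying `I_f = (Pb − P0)/R`. Noise-free recovery is within
  2% on all three parameters; it serves as a cross-check of the two-point
  estimate, not as the primary value (published variants of the full
  equation differ in secondary terms, so the transparent two-point form is
  primary).
* The protocol's "plateau but ≤ 15 mmHg" safety condition is recorded as a
  compliance flag, not enforced, since simulated tests legitimately exceed
  it.

All thresholds (1 mmHg; 0.2 mmHg/min; 5 min; 18 mmHg·min/ml) are
configuration keys with these defaults.

## 4. Drainage summary (`csfdyn.drainage`)

Segments on the event timeline: baseline `[start, drainage_start)`, day 1
`[drainage_start, day1_end)`, day 2 `[day1_end, day2_end]`, on valid RAP
points only. RAPKmax is the maximum after a 5-point truncated-centred
moving median (suppressible), which absorbs single-window spikes;
ΔRAPKmax% follows the definition above and is exactly recomputable from the
stored maxima. "Interim" maxima are read as RAP2max for ΔRAP1max% and
RAP3max for ΔRAP2max% (change after day K), and the RAP1max baseline is the
pre-drainage monitoring span.

**Wash-in.** A moving correlation emitted shortly after a boundary is still
computed largely from pre-boundary windows, and the drainage-onset descent
itself drives AMP and mean ICP down *together*, transiently inflating the
correlation toward 1. The day segments therefore support a wash-in
exclusion after each boundary (`washin_s`; the pipeline default is one
correlation span plus the descent settling time, 600 s at the default
compression — ≈ 10 h of clinical time at compression 60). Without it the
day-1 maximum is dominated by boundary-straddling spans and the day-on-day
decline is not measurable. The raw event segmentation remains the
function-level default.

A consequence of taking *maxima* of a noisy moving correlation: once AMP
has flattened below the breakpoint, valid RAP points are near-null
correlation draws (SD ≈ 1/√(span_n−1) ≈ 0.16 at span 40), and the segment
maximum over a compressed day reaches ≈ 0.2–0.4 even though the typical
value is ≈ 0. Fully-recovered patients therefore show day-2 RAPmax below
≈ 0.45 (not ≈ 0) under measurement noise; with noise off the flat-AMP spans
are flagged degenerate instead. Tests assert exactly these constructions.

## 5. Prediction layer (`csfdyn.predict`)

* **Outcome**: dRL ⇔ mRS ≤ 2.
* **Screen**: per-predictor single-covariate logistic fit, Wald p, retain
  p < 0.10; zero-variance predictors excluded with a flag.
* **Logistic regression**: Newton/IRLS with deviance step-halving
  (deviance is non-increasing by construction), convergence at max
  coefficient step < 1e-8 or 100 iterations; Wald SEs from the inverse
  observed information; (quasi-)separation raises a warning and is flagged
  while the final-iteration coefficients remain available. Listwise
  deletion with a logged count handles missingness.
* **ROC**: Mann–Whitney AUC with ties counted ½ (verified against
  brute-force pairwise concordance); DeLong variance for the 95% CI
  (truncated to [0, 1]) and the two-sided test against AUC = 0.5 — the
  default of the ROC software conventionally used in this clinical
  literature; a stratified bootstrap CI is available as an option.
* **Cut-offs**: Youden's J over observed thresholds, ties broken toward
  higher sensitivity then lower threshold. Single-predictor models are
  scored by the raw predictor — monotone-equivalent to the univariate
  logistic probability (identical AUC) and yielding cut-offs in predictor
  units; ΔRAP% and Rout cut-offs predict dRL in the "≥ cut-off" direction,
  segment-RAPmax cut-offs predict non-dRL in the "≥ cut-off" direction.
* **Calibration**: Hosmer–Lemeshow over deciles of predicted risk, ties to
  the lower group; empty groups are merged with the degrees of freedom
  reduced and flagged; p from χ²(g−2).
* **Correlation**: Pearson when both variables pass Shapiro–Wilk at 0.05,
  Spearman otherwise; the method used is reported.
* **Reporting**: percentages are rounded half-up to one decimal at the
  reporting layer only.

`evaluate_models` emits the five specifications in fixed order
(Rout; ΔRAP1max%; ΔRAP2max%; ΔRAP1max% + ΔRAP2max%; total index), each with
AUC/CI/p, Youden operating point, sensitivity/specificity/PPV/NPV at the
cut-off, and the Hosmer–Lemeshow pair; failed rows carry their reason.

## 6. Validation scope and problem sizes

The suite validates, at desk scale: exact steady-state and printed-table
arithmetic (no tolerance); Rout recovery within 5% noise-free over
R ∈ {6…24} and mean bias within ±0.3 mmHg·min/ml over 200 noisy replicates
(fs 20 Hz); RAP > 0.95 above the breakpoint and degenerate/near-0 below;
oracle equality of the ROC machinery (1e-12); 95% Wald coverage within
[90%, 98%] over 200 replicates at n = 500 and Hosmer–Lemeshow size within
[3%, 8%] over 500 replicates at n = 1000; and, on a 2000-patient generated
cohort, per-predictor AUCs within ±0.05 of a 100 000-draw Monte-Carlo
evaluation of the generative model with the combined model dominating every
single predictor. These sizes keep the full suite around a minute on one
core while leaving Monte-Carlo error well inside each tolerance band.

What passing does **not** show: the simulator has no autoregulation,
plateau waves, posture/artifact events, beat-to-beat variability or
non-stationary noise, and the cohort generator's outcome link is exactly
logistic in the three indices — so these results validate the *estimators
and pipeline plumbing*, not clinical performance on real patients. The
published patient-level AUCs are not reproduction targets (no deposited
data); the generator's discrimination structure merely mirrors their
ordering.

## 7. Known limitations

* The two-point Rout ignores the sagittal-sinus pressure term of the fuller
  clinical formulation; with simulated data the two coincide.
* Segment maxima of a moving correlation are upward-biased order statistics
  (§4); comparisons between patients are consistent, absolute levels depend
  on segment length and span.
* Published non-dRL RAPmax operating points are not Bayes-consistent with
  the accompanying prevalence and are therefore not used as validation
  arithmetic.
* Compressed-time drainage scales the trend dynamics exactly but leaves the
  cardiac/respiratory frequencies untouched; analyses mixing both time
  scales must use the recorded compression factor, as `summarize_drainage`
  does for volume bookkeeping.
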