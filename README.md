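# csfdyn

CSF-dynamics simulation and intracranial-pressure (ICP) analysis for
predicting the outcome of shunt surgery in (post-traumatic) hydrocephalus.

## The problem

Shunting helps many — but not all — patients with post-traumatic
hydrocephalus (PTH). Two bedside measurements are used to pick responders
before surgery:

* **Rout**, the resistance to CSF outflow (mmHg·min/ml), estimated from a
  constant-rate lumbar **infusion test**: saline is infused at
  `I_inf = 1.5 ml/min` until ICP reaches a plateau, and

  `Rout = (Pp − Pb) / I_inf`

  with `Pb` the steady baseline and `Pp` the plateau mean ICP.

* **RAP**, the compensatory-reserve index: the moving Pearson correlation
  between the fundamental (cardiac-frequency) amplitude of the ICP pulse
  (**AMP**) and mean ICP over consecutive short windows. RAP ≈ 0 on the
  linear part of the cerebrospinal pressure–volume curve (reserve intact)
  and ≈ 1 on the exponential part (reserve exhausted). During ~48 h of
  external lumbar drainage (ELD, 10–15 ml/h), segment maxima
  `RAP1max / RAP2max / RAP3max` (pre-drainage baseline, day 1, day 2) and
  their relative declines

  `ΔRAPKmax% = 100 · (RAP1max − RAP(K+1)max) / RAP1max`

  quantify how much reserve the drainage (a shunt surrogate) recovers.

The outcome is dichotomized on the modified Rankin Scale: **dRL**
(desirable recovery level, mRS 0–2) versus non-dRL (mRS 3–6). Five logistic
/ ROC model specifications are compared: Rout alone, ΔRAP1max%, ΔRAP2max%,
both ΔRAP% terms, and the **total index** combining all three.

Because no patient recordings are publicly deposited, the package bundles a
Marmarou-type CSF-dynamics simulator (nonlinear storage equation
`dP/dt = E·(P−P0)·[I_ext + I_f − (P−P0)/Rout]` with cardiac, respiratory and
slow-wave components) and a cohort generator with known ground truth, so
every stage of the pipeline can be exercised and validated end to end. See
`docs/methods.md` for the model details and design choices.

## Worked example

Simulate an infusion test with true Rout = 13, analyze it, then generate a
70-patient cohort and evaluate the five predictive models:

```bash
csfdyn simulate-recording --protocol infusion --rout 13 --seed 7 --out rec
csfdyn infusion-analyze --waveform rec/waveform.csv --events rec/events.csv \
    --rate 1.5 --out infusion.json
# INFO csfdyn: Rout = 12.99 mmHg*min/ml (plateau_reached)

csfdyn simulate-cohort --n 70 --seed 7 --out cohort
csfdyn report --cohort cohort/cohort.csv
```

```
Cohort: cohort/cohort.csv  (n = 70, dRL = 39/70)

model                 AUC          95% CI   sens%   spec%   PPV%   NPV%    HL p
rout_only           0.592   (0.457-0.728)    64.1    61.3   67.6   57.6   0.552
drap1               0.833   (0.736-0.930)    71.8    87.1   87.5   71.1   0.396
drap2               0.830   (0.732-0.927)    92.3    61.3   75.0   86.4   0.498
drap1_plus_drap2    0.859   (0.770-0.947)    61.5    96.8   96.0   66.7   0.643
total_index         0.888   (0.813-0.963)    82.1    87.1   88.9   79.4   0.152
```

The analyzer recovers the simulated Rout to 0.1%. On the synthetic cohort —
whose generative outcome model links dRL to ΔRAP1max%, ΔRAP2max% and Rout —
Rout alone discriminates weakly (AUC ≈ 0.59), each drainage-response index
does well on its own (≈ 0.83), and the combined total index is best
(AUC ≈ 0.89) with an acceptable Hosmer–Lemeshow calibration p-value. AUC
confidence intervals are DeLong; cut-offs maximize the Youden index.

The same machinery is available as a library: `simulate_infusion_test`,
`analyze_infusion` / `InfusionAnalyzer`, `RapExtractor` (an sklearn-style
transformer recording → RAP series), `summarize_drainage`,
`LogisticOutcomeModel` (an sklearn-compatible IRLS logistic classifier) and
`evaluate_models`.

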