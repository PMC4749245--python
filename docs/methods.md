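# Methods

`vfshock` implements a defibrillation-outcome prediction pipeline for
out-of-hospital cardiac arrest: quantify the pre-shock ventricular
fibrillation (VF) waveform, add features describing the patient's previous
shock, combine them with a small learner, and report validation performance
at a fixed-specificity operating point. Because the underlying defibrillator
recordings are not publicly available, the package ships a calibrated
synthetic cohort generator so every stage is testable end to end.

## Waveform quantification (AMSA)

An analysis episode is 2.05 s of ECG ending 0.5 s before the shock
(half-open window `[t − 2.55, t − 0.5)` s; sample count
`round(2.05 × fs)`, 512 samples at the 250 Hz default). Preprocessing is a
2–48 Hz band-pass to remove baseline drift and high-frequency interference;
the episode is then transformed with an FFT (rectangular window, no zero
padding) and

&nbsp;&nbsp;&nbsp;&nbsp;AMSA = Σᵢ Aᵢ · Fᵢ  over 2 Hz ≤ Fᵢ ≤ 48 Hz,

with Aᵢ the single-sided amplitude (mV) at frequency Fᵢ (Hz).

Numerical conventions, chosen where the procedure is conventionally
underdetermined:

* **Amplitude normalisation.** `A_k = 2|X_k|/N` at interior bins
  (`|X_k|/N` at DC/Nyquist), so a bin-aligned sinusoid of amplitude
  a mV contributes exactly a mV at its bin. Absolute AMSA values are
  device- and convention-dependent; only the internal mV·Hz scale is
  guaranteed, and the convention is recorded with every report.
* **Window.** Rectangular by default, since the AMSA sum is defined
  directly on FFT amplitudes; a Hann alternative (coherent-gain
  compensated) is available for leakage-sensitive work. With the
  rectangular window, content that is not aligned to a DFT bin leaks into
  neighbouring bins; this is an inherent property of the convention, not an
  implementation artefact.
* **Filter.** 4th-order Butterworth band-pass, zero phase. The squared
  magnitude response (identical to a forward–backward pass) is applied in
  the frequency domain rather than by time-domain `filtfilt`: a 2.05 s
  episode is shorter than the settling time of the 2 Hz edge, and
  reflection-padded `filtfilt` injects broadband edge transients that
  inflate the AMSA of a clean mid-band tone by tens of percent. The
  circular application has no edge transients and meets the design
  targets exactly (≥ 20 dB at 1 Hz and 96 Hz, ≤ 1 dB mid-band ripple,
  zero phase, same length).
* Any sampling rate above 96 Hz (Nyquist above the 48 Hz band edge) is
  accepted; 250 Hz is the default, typical for defibrillator ECG channels.

## Previous-shock features and combinations

For the k-th shock of a patient (success = 1):

* PSI (previous shock index): 0 for k = 1, +1 if shock k−1 succeeded,
  −1 if it failed.
* ΔAMSA: 0 for k = 1, AMSA_k − AMSA_{k−1} otherwise.

Feature combinations: AMSA alone; C1 = AMSA+PSI; C2 = AMSA+ΔAMSA;
C3 = AMSA+PSI+ΔAMSA. Shocks whose AMSA cannot be measured are dropped
without re-indexing, because the formulas are defined on actual consecutive
shocks; a strict mode raises instead. How a shock whose predecessor had an
indeterminate rhythm should be treated is genuinely open; the
drop-without-reindex rule is this package's choice.

## Learners

**BP network.** Inputs → 3 logistic-sigmoid units → 2 linear units → 1
logistic-sigmoid output, producing a probability. Training minimises
summed cross-entropy plus an L2 penalty λ·Σw² with L-BFGS (deterministic
given the seed). λ follows the evidence approximation used in Bayesian
regularisation: after each optimisation stage, γ = Σ hᵢ/(hᵢ+2λ) over the
data-term Hessian eigenvalues and λ ← γ/(2Σw²), for three updates
(`lam_policy="fixed"` keeps λ at its initial value, 0.01 by default).
Cross-entropy is used rather than squared error because the output is a
probability feeding ROC analysis. Inputs are standardised by
training-column z-scores; zero-variance columns get unit scale so
degenerate strata (e.g. first shocks, where PSI ≡ 0) remain well-posed.

**Logistic regression.** Pooled (statsmodels `Logit`) or with a
patient-level random intercept b ~ N(0, σ_b²) capturing the dependence of
repeated shocks within a patient. The random-intercept likelihood is
integrated by adaptive Gauss–Hermite quadrature (15 nodes by default;
per-patient re-centring at the posterior mode with curvature rescaling)
and maximised by L-BFGS; Wald standard errors come from the
finite-difference observed information. Odds ratios are exp(β) with
symmetric 95% CIs on the log scale. Validation patients are unseen, so
prediction is marginal (b = 0). Training is stratified: first-shock models
are fitted on first shocks (pooled — one shock per patient leaves σ_b
unidentified), subsequent-shock models on subsequent shocks.

## Evaluation

ROC curves are built over all distinct score thresholds; AUC is the
trapezoidal area (ties contribute half a concordance). The operating point
is the threshold whose *training* specificity first reaches 90% — exact
equality is rarely attainable on finite data, so the rule is "smallest
threshold with specificity ≥ 0.90" (equivalently, the most sensitive such
threshold). `score ≥ threshold` predicts success everywhere. Reported
metrics: sensitivity, specificity, PPV, NPV and prediction accuracy, all
derivable from the stored confusion counts.

Statistical battery: paired AUCs are compared with the DeLong
placement-value Z-test (the generic "Z-test" is underdetermined; the
correlated-curves method is correct for two scores on the same validation
shocks, and an unpaired normal fallback is provided); proportions with the
2×2 chi-square *without* continuity correction (borderline p-values near
0.03 on n ≈ 173 are only consistent with the uncorrected test; a corrected
variant is available); group means with the pooled-variance t-test (Welch
optional); rank association with Kendall's tau-b; and model specification
with Hausman's test, H = (β_FE − β_RE)²/(var_FE − var_RE) on 1 df, where
β_FE comes from conditional logistic regression and β_RE from the
random-intercept fit. A non-positive variance difference (a finite-sample
artefact) is flagged inconclusive rather than forced.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis relies on,
not VF electrophysiology:

* **First shocks.** Outcome ~ Bernoulli(0.377); AMSA drawn from
  outcome-conditional normals (success 15.9 ± 9.0, failure 9.3 ± 5.8
  mV·Hz), floored at 0.5 mV·Hz (non-negative waveform energy).
* **AMSA dynamics.** AMSA_k = 0.7·AMSA_{k−1} + drift(outcome_{k−1}) +
  N(0, 5²), drift 6.5 mV·Hz after a success and 2.2 after a failure, so
  consecutive shocks are correlated and ΔAMSA carries signal.
* **Subsequent outcomes.** P(success) = logistic(−2.9 + 0.20·AMSA +
  1.2·PSI + b), b ~ N(0, 1). The direct PSI term is deliberate: a shared
  intercept alone caps the achievable AUC gain of AMSA+PSI over AMSA near
  +0.01–0.03, far below the reported clinical benefit, whereas the
  previous shock's outcome is clinically an independent predictor
  (recurrent VF after a transiently successful shock defibrillates more
  easily than shock-resistant VF).
* **Sequence termination.** After a success the patient refibrillates and
  receives another shock with probability 0.45; after a failure
  resuscitation continues with probability 0.78; hard stop at 8 shocks.
  Sequences *must* be able to continue past a success — otherwise PSI
  would be constant (−1) on all subsequent shocks and uninformative,
  contradicting the observed PSI distribution. The per-patient shock-count
  distribution is not reported in the clinical material, so the
  max-shocks default (8) is a guess, chosen to put the mean near 2.6
  shocks per patient.
* **Waveforms.** Each shock's episode is a sum of 12 bin-aligned
  sinusoids in 2–48 Hz with random phases and a low-frequency-weighted
  envelope, rescaled so the full AMSA pipeline returns the record's AMSA
  exactly; the generator is reproducible from a single seed.

At these defaults a 400-patient cohort reproduces the calibration targets:
first-shock success ≈ 0.38, subsequent-shock success ≈ 0.27–0.29, ≈ 65% of
patients needing repeat shocks, subsequent AMSA ≈ 16.6 ± 7.5 (success) vs
8.6 ± 5.9 (failure) mV·Hz, Kendall tau(AMSA, PSI) ≈ 0.36–0.39, AMSA-only
validation AUC ≈ 0.80–0.84 on subsequent shocks and ≈ 0.72 on first
shocks, and an AMSA+PSI(+ΔAMSA) gain of ≈ +0.03–0.04 AUC.

What the generator does **not** emulate: VF morphology beyond the
amplitude spectrum, chest-compression artefacts, drug effects, device
differences, aetiology, or survival beyond the per-shock outcome. Passing
tests therefore demonstrate correctness of the analysis machinery and
internal consistency with the modelled structure, not clinical validity on
real recordings.

### Parameter-recovery design

`parameter_recovery_config()` defines a separate, correctly-specified
study for checking the mixed-model estimator: no direct PSI effect, no
outcome-dependent drift or termination, 14 shocks per patient, AMSA
carryover 0.5 with innovation SD 8.7 (stationary mean 12, SD ≈ 10 mV·Hz,
matching the clinical spread). The design was sized so the ML estimate of
a true AMSA slope of 0.03 per mV·Hz has a replicate SD near 0.004,
putting ±0.01 recovery beyond the 90% level with margin.

## Orchestration and reproducibility

Patients — never shocks — are randomised to training and validation
(default 50/50): the clinical split counts (99 vs 100 patients, 255 vs 273
shocks) show the patient was the split unit, and shock-level splitting
would leak within-patient correlation. A single top-level seed fans out
via `numpy.random.SeedSequence` to the generator, the split and the
per-feature-set network initialisations, so identical configurations give
identical results and components are reproducible in isolation. Cohorts
round-trip through a manifest CSV plus one plain-text episode file per
shock; results round-trip through JSON plus CSV tables.

Problem sizes used by the test-suite simulations (chosen as desk-scale
study designs): 200-patient cohorts for replicated experiments (50
replicates), 300 patients × 14 shocks for parameter recovery (100
replicates), 200 patients × 5 shocks for the Hausman null (500
replicates), and n = 150 score vectors for the AUC-test null (1000
replicates).

## Known limitations

* Absolute AMSA values depend on the FFT normalisation and device gain;
  cross-study comparability of thresholds in mV·Hz is not guaranteed.
* The evidence-style λ re-estimation is a practical stand-in for full
  Levenberg–Marquardt Bayesian regularisation; the contract is the
  regularised objective, determinism, and a logged λ policy.
* Whether validation predictions for the mixed model should use marginal
  (b = 0) or sequentially updated patient effects is an open design
  question; this package predicts marginally, which is conservative for
  unseen patients.
* The Hausman statistic can be inconclusive (negative variance
  difference) on small samples; it is flagged, not silently dropped.
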