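# Methods

This note documents the models, parameters, and numerical choices behind
`attentrf`, and what the synthetic data do and do not establish.

## Signal processing

**Envelope extraction** (`attentrf.dsp`). The speech envelope is computed with
a gammatone filterbank of 28 bands with center frequencies from 50 to 5000 Hz,
equally spaced on the ERB_N number scale E(f) = 21.4·log10(0.00437·f + 1).
Each band is a 4th-order all-pole gammatone implemented as four cascaded IIR
biquads (the classic digital approximation with analytic unity-gain
normalization at the center frequency). Per band the signal is full-wave
rectified and raised to the power 0.6 (compressive loudness-like
nonlinearity); the 28 band envelopes are averaged, resampled to 64 Hz with an
anti-aliased polyphase stage, and low-pass filtered below 8 Hz with a
zero-phase (forward–backward) 4th-order Butterworth filter. Two consequences
worth knowing:

- the final low-pass can push envelope samples slightly below zero; they are
  not clipped, since Pearson correlation is shift/scale invariant;
- the anti-aliased resampler already low-passes below 32 Hz, so applying the
  8 Hz low-pass after downsampling (rather than before) does not alias.

**EEG preprocessing.** Band-pass 2–8 Hz, zero-phase Butterworth order 4
(effective order 8 after the forward–backward pass), then polyphase
downsampling to 64 Hz. Zero-phase filtering is used throughout so that no
filter group delay biases the TRF lag axis. All trial-level signals share a
64 Hz grid starting at trial onset; sample 0 covers [0, 1/64) s.

## Inferred attended stimulus

The inferred stimulus is realised as a partition-of-unity mixer: per-sample
weights w_T, w_M, w_F ≥ 0 with w_T + w_M + w_F = 1 and
x̂ = w_T·x_T + w_M·x_M + w_F·filler. Inside response window i the source
dictated by the answer has weight 1; outside, the scope rule applies
(`segments`: each window's source extends to cut points halfway between
consecutive windows and to the trial edges; `target_windows`: the target is
assumed attended). Design choices where the construction was genuinely open:

- **Crossfades** are complementary raised cosines *centered* on each
  source-change boundary, with weight exactly 0.5 at the boundary instant.
  Ramps are applied at every source change, including segment cut points.
- **Truncation.** If a boundary is closer than half the switch duration to a
  neighboring boundary or trial edge, its ramp is truncated at the midpoint
  (logged as a warning, not an error). Because only one crossfade can be
  active at a time after truncation, the weights remain an exact partition of
  unity without explicit renormalization.
- **Trial edges** hold their plateau; no ramp at t = 0 or trial end.
- **Extraneous answers** replace the whole union window with the filler; the
  window is not subdivided.
- **Fillers.** Mixture x_T + x_M, target, masker, white Gaussian noise, or an
  unrelated speech signal (looped/truncated to trial length); noise and
  other-speech fillers are scaled to the target's RMS level. The noise filler
  is white by default; envelope-domain callers may pass any signal.
- **Domains.** The reference path mixes waveforms and then extracts the
  envelope; an envelope-domain fast path mixes precomputed envelopes with the
  same weights. The two agree at r ≥ 0.95 on modulated-noise sources (tested);
  the envelope of a sum is not exactly the sum of envelopes, so the fast path
  is an approximation used for simulation studies.

The "behavioral" configuration is scope `target_windows`, filler mixture,
switch duration 2 s.

## Decoder estimation

The backward TRF uses lags −900…0 ms at 64 Hz. Since −900 ms is 57.6 samples,
the integer lag grid is −57…0 (58 lags, step 15.625 ms). The lag matrix pads
the time axis by the lag span (T = trial samples + 57) and zero-pads the
envelope to match, so every EEG sample participates.

The weights are the exact ridge solution d = (RRᵀ + λI)⁻¹(RSᵀ) with
λ = 10^(1/2) by default. Numerical choices:

- **Standardization.** EEG channels are z-scored and envelopes mean-centered
  per trial before fitting (switchable), so a fixed λ is meaningful across
  scales. An optional λ grid (10⁻³…10⁵, log-spaced) is exposed but off by
  default.
- **Dual solve.** When rows (channels·lags) exceed time points, the
  algebraically identical dual form d = R(RᵀR + λI)⁻¹Sᵀ is used. For
  per-trial fitting, RᵀR is assembled from the shift structure of the lag
  matrix (each diagonal is a 58-wide running sum along the corresponding
  diagonal of XᵀX), and the Cholesky factor of RᵀR + λI is computed once per
  trial and shared across all training envelopes. Equality with the explicit
  primal solve is unit-tested to 1e-8.
- **λ = 0** falls back to a pseudo-inverse with a warning if the system is
  singular.
- **Leave-one-out.** One decoder per trial; each held-out trial is
  reconstructed with the unweighted mean of the other trials' decoders.
  Held-out accuracy is always scored against the trial's *original target*
  envelope, whatever envelope was used for training — this makes the
  target-trained and behaviorally-trained decoders directly comparable, and
  is recorded in the results metadata. Correlations are computed over the
  full padded length, which affects both decoders identically.

## Synthetic data

The generator (`attentrf.simulate`) emulates the statistical structure the
analysis needs, not speech itself:

- **Streams**: rectified sums of 8 sinusoidal components with frequencies
  drawn from 2–8 Hz — nonnegative envelopes whose modulation spectra peak in
  the syllabic range. Waveform mode modulates a noise carrier.
- **Trials**: durations uniform in 11–18 s; three keyword windows (keyword
  lengths 0.3–0.8 s, paired-onset offsets 0–1 s) placed in the early, middle
  and late thirds, so windows are ordered and disjoint by construction.
- **Attention**: a latent binary trajectory starting on the target, switching
  at Poisson times with a per-condition hazard and a 1 s minimum dwell.
  The difficulty ladder defaults to hazards 0.00 / 0.02 / 0.08 s⁻¹ with lapse
  probabilities 0.05 / 0.10 / 0.15 — chosen so simulated response error rates
  bracket a ~2–3× ratio between the hardest and easiest conditions.
- **Responses**: the majority-attended source within each window, replaced by
  "extraneous" with the lapse probability. Lapses are response-level, not
  signal-level: the paradigm cannot distinguish divided attention from
  inattention, so the simulator does not commit to either (the attended
  signal remains the trajectory-weighted mixture).
- **EEG**: channel n = kernel_n ⊗ attended envelope + Gaussian noise, with
  the attended envelope following the true trajectory through 250 ms
  raised-cosine crossfades. Kernels are a gamma-windowed 3 Hz sinusoid
  peaking at 150 ms with 400 ms support — typical speech-TRF morphology —
  scaled by per-channel gains ~ N(1, 0.3) (sign flips allowed, as in real
  topographies). The default SNR (signal power / noise power) is 0.05.
- **Seeding** is hierarchical (master → subject → condition → trial → named
  stream), so every artifact is a pure function of (config, master seed).

**What the simulation does not capture**: real speech acoustics and
linguistics, EEG artifacts (blinks, drift), inter-subject kernel variability
beyond channel gains, graded or divided attention states, and any dependence
of behavior on acoustics. Passing tests therefore establish that the
*pipeline* behaves correctly and that the behavioral-training advantage
follows from the assumed generative structure — not that it will attain any
particular effect size on real recordings. Absolute reconstruction accuracies
in simulation are far higher than the ~0.1 typical of real EEG because the
forward model is clean and stationary.

## Evaluation

The grid runs every (condition × scope × filler × switch duration) cell by
rebuilding inferred envelopes and re-running leave-one-out training; per-trial
Cholesky factors are shared across cells since the EEG is unchanged. Cell
summaries report the mean r and the mean Fisher z (mean of atanh(r), never
atanh of the mean).

The headline contrast compares behavioral vs target training per condition as
a paired t-test on subject-level Fisher-z means with Benjamini–Hochberg
correction across conditions (via statsmodels). Mixed-effects models are
deliberately out of scope: the object under test is the inferred-stimulus
construction, and paired tests preserve the comparison structure at package
scale. When every paired difference is exactly zero (error-free responses
make the inferred envelope bit-identical to the target, hence identical
decoders), p = 1 by convention.

Problem sizes used in the shipped end-to-end checks — chosen as the smallest
designs at which each property is stable: estimator oracle at 6 unknowns × 40
samples × 50 instances; forward-model recovery at 31 channels × 20 noiseless
12 s trials; directional replication at 10 master seeds × 20 subjects × 3
conditions × 16 trials (hazards 0/0.02/0.08, the zero-switch condition with
lapse 0 so the null is exact, SNR 0.05).

## Known limitations

- The envelope fast path slightly mismatches the waveform path by design
  (documented r ≥ 0.95 agreement).
- The per-trial standardization choice is a convention; raw-scale fitting is
  available but then a fixed λ is not comparable across datasets.
- `load_dataset` reconstructs trials from CSV without the latent attention
  trajectory (ground truth is not part of the interchange format).
- The simulator's response model is intentionally minimal; it cannot emulate
  phonemic restoration or partial recall.
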