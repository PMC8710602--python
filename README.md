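# attentrf

**Behaviorally informed EEG stimulus reconstruction for competing-speech
listening.**

When a listener attends one of two simultaneous talkers (a *target* and a
*masker*), the cortical response tracks the attended speech envelope, and a
backward temporal response function (TRF) — a *decoder* — can reconstruct that
envelope from multichannel EEG. Standard analyses assume the listener's
attention never leaves the target. It does, though: especially when the two
voices are similar, attention occasionally switches to the masker or drifts
away entirely, which corrupts both decoder training and evaluation.

`attentrf` implements an analysis in which post-trial keyword-recall responses
are used to infer, retrospectively, *which* stream was attended at three probed
moments of each trial, and to assemble a behaviorally **inferred stimulus**
x̂(t) — a piecewise combination of target, masker, and filler signals with
raised-cosine attention-switch ramps. Decoders trained on x̂ are then compared
with decoders trained on the assumed-target envelope. A synthetic cocktail-party
generator with a latent attention process provides fully controlled data, so
every stage of the pipeline is testable without any recordings.

## The model

Envelopes S are extracted with a 28-band gammatone filterbank (50–5000 Hz,
ERB_N-spaced), full-wave rectification, a compressive power law (|·|^0.6),
band-averaging, resampling to 64 Hz, and an 8 Hz low-pass. EEG is band-passed
2–8 Hz (zero phase) and resampled to the same 64 Hz grid.

The decoder maps lagged EEG R (31 channels × 58 lags covering −900…0 ms) to
the envelope:

    Ŝ(t) = Σ_n Σ_τ d(τ, n) R(t − τ, n),      d = (R Rᵀ + λ I)⁻¹ (R Sᵀ)

with ridge parameter λ = 10^(1/2). Each held-out trial is reconstructed with
the unweighted mean of the decoders fitted on all other trials, and scored by
the Pearson correlation r (Fisher-z transformed for statistics) against that
trial's original target envelope.

The inferred stimulus is

    x̂(t) = f(x_T, x_M, R_i)(t)  if t ∈ keyword window i,   g(x_T, x_M)(t) otherwise

where f selects the target for a target answer, the masker for a masker
answer, and a filler h(x_T, x_M) (mixture, target, masker, noise, or unrelated
speech) for an extraneous answer; the scope g either extends each window's
source over a whole segment (`segments`) or assumes the target elsewhere
(`target_windows`); and every source change is a raised-cosine crossfade of
1–3 s. The "behavioral decoder" uses (`target_windows`, mixture, 2 s).

## Worked example

Simulate six subjects in an easy (no attention switches) and a difficult
(0.08 switches/s, 15% response lapses) condition, fit the leave-one-out
reconstruction model, and contrast the two training strategies:

```python
from attentrf import (SimConfig, ConditionSpec, EEGSimSpec, gen_dataset,
                      StimulusReconstruction)
from attentrf.evaluate import contrast_decoders, contrast_to_frame

cfg = SimConfig(n_subjects=6, n_trials_per_condition=12,
                conditions=(ConditionSpec("easy", 0.0, 0.05),
                            ConditionSpec("difficult", 0.08, 0.15)),
                eeg=EEGSimSpec(n_channels=31, snr=0.05), master_seed=1)
dataset = gen_dataset(cfg)

res = StimulusReconstruction(dataset[0].trials_in("difficult"),
                             train_on="target").fit()
print(res.summary())
print(contrast_to_frame(contrast_decoders(dataset, alternative="greater"))
      .round(4).to_string(index=False))
```

```
Stimulus reconstruction (leave-one-trial-out backward TRF)
============================================================
trials:            12
training envelope: target
ridge lambda:      3.1623
lags:              -900...0 ms (58 lags)
mean r:            0.4084
mean Fisher z:     0.4583 (SEM 0.0765)
============================================================

condition  mean_r_target_decoder  mean_r_behavioral_decoder  mean_z_target_decoder  mean_z_behavioral_decoder  statistic  p_value  adjusted_p  n_subjects
     easy                 0.6410                     0.6406                 0.7709                     0.7703    -1.3074    0.876      0.8760           6
difficult                 0.4047                     0.4188                 0.4499                     0.4699    11.5395    0.000      0.0001           6
```

Read this as: reconstruction is harder in the difficult condition (mean r
0.40 vs 0.64), and training on the behaviorally inferred stimulus improves
held-out reconstruction *only there* (paired one-sided t = 11.5 on
subject-level Fisher-z means, Benjamini–Hochberg adjusted p ≈ 1e-4), while in
the easy condition the two trainings are essentially identical — the same
interaction the method is designed to expose. Absolute r values are higher
than in real EEG because the simulated forward model is clean.

## Command line

```sh
attentrf simulate --config sim.json --out data/        # synthetic dataset + manifest
attentrf envelope --in stimulus.wav --out env.csv      # gammatone envelope
attentrf infer --target t.wav --masker m.wav --events events.csv \
        --scope target_windows --filler mixture --switch 2.0 --out inferred.wav
attentrf train-eval --trials data/manifest.csv --train-on inferred --out scores.csv
attentrf compare --data data/manifest.csv --out results/
attentrf run-all --config run.json --seed 7            # end-to-end pipeline
```

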