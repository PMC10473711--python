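# avmsi

EEG speech-envelope decoding and audiovisual multisensory-integration
analysis for cocktail-party experiments — with a synthetic cohort
generator for end-to-end validation.

## The problem

When two people speak at once, seeing a speaker's face helps a listener
track that speaker's voice. One way to measure this with EEG is *stimulus
reconstruction*: a linear backward decoder g(τ, n) maps multichannel EEG
across stimulus–response lags τ to an estimate of the attended speech
envelope,

    ŝ(t) = Σ_n Σ_τ r_n(t + τ) g(τ, n),
    g = (RᵀR + λI)⁻¹ Rᵀs,

with the ridge parameter λ chosen by leave-one-trial-out cross-validation.
Multisensory integration is quantified with the additive-model criterion:
compare a decoder trained on audiovisual (AV) trials against an "(A+V)"
decoder built from the *summed covariance statistics* of audio-only and
visual-only trials, both reconstructing the same congruent AV speech:

    MSI = mean_trials r_AV − mean_trials r_(A+V).

If audiovisual speech were processed as two independent unisensory
streams, the two decoders would perform alike (MSI ≈ 0); a positive MSI
indicates nonlinear audiovisual interaction. Doing this per attention
state (attended vs unattended speaker) and per gaze condition (direct
looking, central crosshair, eavesdropping) asks how attention and gaze
gate integration. Single-lag decoders (65 one-sample lags, −500…500 ms)
resolve the effects over time; permutation nulls, Wilcoxon tests and
Benjamini–Hochberg FDR provide inference; behavioral engagement is scored
as d′ on visual-target detection and four-choice comprehension accuracy;
and random-intercept mixed models with likelihood-ratio tests relate every
measure to gaze across experiments.

The package is aimed at auditory/EEG researchers who want a tested,
reusable implementation of this analysis stack, plus a generative model of
the paradigm (`avmsi.synthetic`) that makes every quantity recoverable
ground truth — so the machinery can be validated without access to human
recordings.

## Worked example

```python
import numpy as np
from avmsi import (EnvelopeDecoder, fit_sum_decoder, make_forward_model,
                   simulate_subject, signed_rank)

fm = make_forward_model(n_channels=16, seed=0, noise_sd=30.0)
schedule, trials = simulate_subject(2, fm, seed=0, trials_per_cell=6,
                                    duration_s=30.0)

av = [t for t in trials if t.modality == "AV" and t.gaze == "d"]
dec = EnvelopeDecoder().fit([t.eeg for t in av], [t.env_att for t in av])
i = int(np.flatnonzero(dec._lambdas() == dec.lambda_)[0])
r_av = float(np.nanmean(dec.cv_fold_scores_[i]))

sdec = fit_sum_decoder(trials, "attended", gaze="d")
r_sum = sdec.score([t.eeg for t in av], [t.env_att for t in av])

print(f"lambda* = {dec.lambda_:g}")
print(f"r_AV  = {r_av:.3f}")
print(f"r_A+V = {r_sum:.3f}")
print(f"MSI   = {r_av - r_sum:+.4f}")
```

Output:

```
lambda* = 1e+30
r_AV  = 0.247
r_A+V = 0.241
MSI   = +0.0057
```

`r_AV` is the held-out accuracy of the AV decoder on congruent AV trials
(leave-one-trial-out at the selected ridge parameter); `r_A+V` is the
summed-covariance decoder's accuracy on the same trials; their difference
is this subject's multisensory-integration index in the direct-looking,
attended condition. Across a cohort these per-subject indices feed the
signed-rank test (`signed_rank(msi_values)`) and the gaze mixed models.

A full synthetic two-experiment run (60 + 84 trials per subject, the
complete 24-decoder inventory, MSI/behavior/statistics/LME tables as CSV):

```bash
avmsi run-all --seed 1 --out-dir results/
```

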