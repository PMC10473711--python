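# Methods

This note documents the models and procedures implemented in `avmsi`, the
choices made where a convention had to be fixed, and what the synthetic
validation studies do and do not establish.

## Stimulus representation

The analysis relates EEG to the broadband acoustic envelope of speech.
Audio is decomposed by a fourth-order IIR gammatone filter bank (default
128 bands, logarithmically spaced center frequencies from 100 to 6500 Hz,
endpoints inclusive; filters applied as second-order sections for
numerical stability at low center frequencies). Each band's envelope is
the magnitude of its analytic (Hilbert) signal; the broadband envelope is
the across-band mean, low-pass filtered at 32 Hz, resampled to the EEG
analysis rate of 64 Hz, and z-scored per trial. Per-trial z-scoring (rather
than per-session) matches the trial's role as the cross-validation unit; a
`zscore` flag switches it off for callers who standardize elsewhere.
Because every stage is linear up to the final standardization, the
pipeline is invariant to the absolute scale of the input audio.

## EEG conditioning

Preprocessing order is fixed: zero-phase band-pass (0.3–30 Hz) →
resampling to 64 Hz → mastoid-average re-referencing → bad-channel
detection → spherical-spline interpolation → per-channel z-scoring.

- The band-pass is a third-order Butterworth applied forward–backward.
  Design edges are widened (0.2–38 Hz for the default band) so the
  *two-pass* response stays within 3 dB across the nominal band while
  attenuating 0.05 Hz and 55–60 Hz by more than 20 dB (verified
  numerically in the test suite).
- Bad channels are flagged by any of three rules: variance above 3× the
  mean channel variance; robust z-score (median/MAD across channels) of
  excess kurtosis above 5; robust z-score of the mean negative
  log-probability of the channel's samples under the pooled
  robust-Gaussian amplitude distribution above 5. The latter two re-specify
  toolbox-style "kurtosis/probability" criteria as explicit, reproducible
  statistics.
- Interpolation uses spherical splines of order m = 4 with regularization
  1e-5 and a Legendre series truncated at degree 7 (configurable; the test
  suite cross-checks a longer series against an independent
  implementation). Good channels are never modified.

## Backward decoding

A decoder maps lagged multichannel EEG to the envelope:
ŝ(t) = Σ_n Σ_τ r_n(t+τ) g(τ, n), with τ spanning 0–500 ms (33 lags at
64 Hz) for the integrated decoder and single one-sample lags over
−500…500 ms (65 lags, 15.625 ms apart) for the time-resolved analysis.
Weights solve the ridge system g = (RᵀR + λI)⁻¹Rᵀs.

Implementation choices:

- Trials enter only through accumulated sufficient statistics
  (RᵀR, Rᵀs, column sums). Accumulators add exactly, so leave-one-trial-out
  training is a subtraction and the (A+V) decoder is literally the solve of
  summed unisensory statistics.
- The intercept is unpenalized, implemented by mean-centering the
  accumulated moments (algebraically identical to an unpenalized constant
  column; the test suite verifies the equivalence against the explicit
  augmented system to 1e-10).
- Trial edges are zero-padded, keeping all trials the same length so
  covariance sums stay balanced.
- λ is selected by leave-one-trial-out cross-validation over the grid
  10⁻⁶, 10⁻⁴, …, 10³⁰ (19 candidates), maximizing the mean per-trial
  Pearson r on held-out trials; ties break toward the larger (more
  regularized) λ. Per-fold eigendecompositions of the centered gram matrix
  make the whole λ grid, both attention targets, and all permutation
  refits reusable from one O(p³) factorization per fold.
- Reported accuracies are trial-averaged per-trial correlations (not
  pooled-sample correlations). A constant reconstruction or target raises
  an explicit degenerate-signal error rather than returning r = 0.
- The (A+V) decoder accumulates audio-only trials against the heard
  envelope and visual-only trials against the *unheard* envelope matched
  to the visible face, sums the accumulators, and selects its λ to
  maximize reconstruction of the congruent audiovisual trials — which are
  never part of its training statistics.

Multisensory integration is the additive-model index
MSI = mean r(AV decoder) − mean r(A+V decoder), computed per subject,
gaze condition, and attention state on the same congruent AV trials
(attended decoders target the attended stream, unattended decoders the
competing stream).

## Inference

- Chance levels: the stimulus–EEG pairing is shuffled between trials
  (within condition), the decoder is refit with the full λ
  cross-validation per shuffle (default 1000 shuffles), and the
  per-subject null summary is the mean of the shuffled accuracies; groups
  are compared by two-sided Wilcoxon signed-rank between actual and null
  summaries. Because shuffling changes only the stimulus side of the
  cross-products, gram factorizations are shared across shuffles, which is
  what makes 1000 refits cheap.
- Wilcoxon signed-rank drops zero differences and returns p = 1 when all
  differences are zero; the exact null is used for n ≤ 25 nonzero pairs,
  a continuity-corrected normal approximation above. Rank-sum comparisons
  use the Mann–Whitney form with mid-rank ties. Single-lag families are
  corrected by Benjamini–Hochberg FDR.
- Behavioral sensitivity: a response within 2 s of a glitch onset or 4 s
  of a slow-motion onset is a hit (one response credited per target);
  remaining responses are false alarms. The false-alarm denominator is the
  number of window-length non-target bins tiling each trial — the paradigm
  leaves no canonical "non-target trial count", and window tiling yields a
  proper rate in (0, 1). Perfect rates are corrected by 1/(2N) before the
  inverse-normal transform.

## Mixed models

Gaze effects on comprehension, d′, speech tracking, MSI, and attention
benefit are modeled as Gaussian random-intercept models
`y ~ gz + exp + (1|ptc)` against the reduced `y ~ exp + (1|ptc)`, fit by
maximum likelihood (not REML) so the likelihood-ratio statistic
2·(ll_full − ll_reduced) is χ²(1)-distributed under the null. Gaze is
coded numerically by distance from the attention target (direct = 0,
crosshair = 1, eavesdrop = 2): one degree of freedom, and a negative β
means performance falls as gaze leaves the attended speaker. Participants
appearing in both experiments share one random intercept. When the
random-intercept variance is driven to its zero boundary (where some
optimizers return a singular Hessian), the fit falls back to ordinary
least squares, which is the exact boundary ML solution. Per-lag model
families are FDR-corrected across the 65 lags.

## Synthetic cohort generator

The generator produces the statistical structure the analysis assumes,
with ground truth:

- **Envelopes** are low-pass-filtered rectified noise with modulation
  energy below ~8 Hz, z-scored per trial (the nonnegative pre-z-score
  envelope is kept for the interaction drive).
- **Visual drives** are the envelope advanced by 120 ms, smoothed
  (60 ms FWHM) and jittered (0.3 SD), mimicking mouth kinematics that
  precede the acoustics.
- **Forward model**: rank-one kernels (smooth random channel topography ×
  unit-norm temporal profile). The auditory kernel is a gamma bump with
  undershoot on 0–400 ms peaking at 100 ms. The visual kernel lives on
  −200…300 ms relative to its drive and peaks at −50 ms by default, so the
  visual response sits ~170 ms *before* the acoustic envelope — a
  pre-stimulus visual-speech response. The interaction kernel is a delayed
  (200–400 ms) bump sharing the auditory topography.
- **Attention** scales each pathway by the attended modality: attended
  streams at gain 1.0 in their attended modality, everything else at 0.4
  (in visual-only trials the heard audio is ignored; in audio-only trials
  the visible face is ignored; the competing stream is always ignored).
  **Gaze** scales visual fidelity: direct 1.0, crosshair 0.5, eavesdrop
  0.2, with the unattended face receiving the complementary condition's
  gain (eavesdropping fixates the ignored face).
- **Interaction**: congruent attended streams add
  κ · g_vis · h_I ∗ z(s⁺ ⊙ v⁺), the product taken on the nonnegative
  envelope/drive versions (the product of correlated nonnegative signals
  retains envelope correlation; for zero-mean versions it would not).
  κ = 0 is the additive null; an unattended-stream κ exists and defaults
  to 0. Because the interaction is scaled by the gaze-dependent visual
  gain, gaze gates integration strength.
- **Noise** is Gaussian with exponential spatial correlation across
  channel index (adjacent-channel ρ = 0.3) and AR(1) temporal shaping
  (coefficient 0.6). The study default `noise_sd = 100` (relative to
  unit-norm kernel responses) puts single-subject integrated-decoder
  accuracies near r ≈ 0.05, the regime typical of competing-speaker
  envelope reconstruction; d-prime and comprehension streams are generated
  from the equal-variance signal-detection model and a per-question
  Bernoulli.

What the generator does **not** emulate: real EEG spectra beyond AR(1)
shaping, eye- or muscle-artifact structure, electrode drift, higher-rank
response topographies, linguistic structure in the envelope, or any
dependence between behavioral performance and neural SNR. Passing the
validation studies therefore establishes the *analysis machinery* —
estimator correctness, calibration of the inference, recoverability of
injected effects — not claims about real cortical integration.

## Validation studies and problem sizes

The operating-characteristic studies run on scaled-down cohorts chosen so
the full battery completes in minutes on one core:

- Additive null: 10 cohorts × 16 subjects, 6 trials × 30 s per modality
  cell, 16 channels, κ = 0.
- Interaction recovery: 10 cohorts × 16 subjects, 12 trials × 60 s per
  cell, 8 channels, κ = 0.5 (calibrated once so attended-direct MSI sits
  in the 0.01–0.02 band); detection power depends on per-subject data
  volume, so this study uses trial counts close to the real paradigm.
- Permutation-null calibration: 200 cohorts × 6 subjects, 4 trials × 12 s,
  3 channels, 100 shuffles, analyzed against freshly drawn envelopes the
  EEG never saw.
- Single-lag localization: 10 simulations, 8 channels, 6 trials × 30 s.
- Mixed models: 300 coverage fits and 500 null-LLR fits at 31
  participants × 3 gaze levels (slope −0.5, intercept SD 0.3, residual SD
  0.5).
- d′ round trip: ~500 targets at d′ = 2, false-alarm rate 0.1.

## Known limitations

- **The additive-model MSI index has a small positive finite-sample bias
  under the additive null in this generator.** The summed-covariance
  decoder inherits cross-covariance noise from each unisensory trial's
  *other*-pathway response (present but ignored), noise the congruent-AV
  training statistics do not carry; the AV-trained decoder is also
  distribution-matched to its evaluation trials. Empirically the shift is
  roughly a quarter of the between-subject SD at the additive-null study
  sizes (≈ +0.008 in r units), shrinking with per-subject data volume and
  with the strength of ignored-pathway responses. It is a property of the
  AV-vs-(A+V) construction itself, not of the solver: it persists with a
  fixed ridge parameter and on freshly simulated evaluation trials.
  Group-level additive-null tests are therefore mildly anticonservative
  at small trial counts; interaction effects should be interpreted
  relative to a simulated null, which the study functions report.
- Single-lag profiles inherit the envelope's autocorrelation: responses
  separated by less than ~100 ms blend into one peak, and effects smear
  across neighboring lags. No decorrelation correction is applied; the
  profiles are reported as measured.
- The permutation group test is run at reduced cohort sizes in the
  calibration study; with 6 subjects the smallest attainable two-sided
  signed-rank p is 0.031, so rejections are coarse-grained.
- Wald p-values for mixed-model coefficients use the asymptotic normal
  approximation; with ML (not REML) estimation, standard errors are
  slightly anticonservative at small participant counts.
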