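# Methods

This note documents the models, estimators and numerical choices behind
`pdvoice`, and what the synthetic cohort does and does not establish.

## The synthetic vowel model

A sustained /a/ is synthesized source–filter style:

- **Glottal source.** A pulse train with per-cycle control.  The cycle rate
  follows F0(t) = f0_mean + d(t), where d(t) is an AR(1) drift (pole 0.97,
  stationary SD `f0_sd`) updated once per cycle — slow pitch wander, as
  distinct from jitter.  Each period is then multiplied by
  (1 + ε_i), ε_i ~ N(0, jitter_pct/100) i.i.d., and each pulse amplitude by
  (1 + η_i), η_i ~ N(0, shimmer_pct/100).  Pulses are laid down as
  Hann-tapered sinc kernels (half-width 16 samples) at their *continuous*
  onset times.  This band-limited placement matters: splitting an impulse
  across two samples linearly applies a different fractional-delay low-pass
  every cycle, which leaks spurious cycle-to-cycle variability into every
  perturbation measure and caps measurable HNR near 14 dB.
- **Vocal tract.** A cascade of four second-order resonators (poles at the
  formant frequencies with bandwidth-controlled radii, b = [1−r]).
  Defaults approximate /a/: male (710, 1150, 2500, 3300) Hz, female (820,
  1300, 2750, 3500) Hz, bandwidths 80–200 Hz.
- **Aspiration noise.** White noise passed through the same resonators and
  scaled *after* filtering so the harmonic-to-noise power ratio at the
  filter output equals `hnr_target` dB exactly.
- **Telephone channel.** 4th-order Butterworth band-pass 300–3400 Hz, then
  peak normalization and 16-bit quantization at 8 kHz.  The band-pass
  removes the fundamental itself for typical male F0 — periodicity then
  rests entirely on the harmonics, which is exactly the regime a telephone
  pitch tracker must survive.

### Cohort defaults

All generator distributions sit in one config block
(`pdvoice.synth.CohortDefaults`).  Group medians (log-normal, σ = 0.35):
jitter 0.5 % (HC) vs 1.5 % (PD); shimmer 3 % vs 6.5 %; F0 drift SD 1.5 Hz
vs 4 Hz; HNR Gaussian 22 ± 2.5 dB vs 14 ± 2.5 dB; vowel duration 2.8 s vs
2.2 s.  Sex-conditional F0: male 115 ± 10 Hz, female 180 ± 15 Hz (ratio
≈ 1.57, inside the physiological 1.45–1.7 band).  Demographics follow the
study population: HC 16M/24F, age 47.9 ± 14.5 y; PD 21M/19F, 66.6 ± 9.0 y
(truncated to 18–95).  The effect *directions* (PD ↑ jitter/shimmer/F0
drift, ↓ HNR, shorter phonation) are the documented dysphonia pattern; the
*magnitudes* are configuration, not estimates of any human cohort — they
are chosen once so that a 40 + 40 cohort is clearly separable by the
random-forest track (mean AUC ≥ 0.9), giving the protocol tests a strong
signal to detect.  No human dataset is emulated beyond these summary
statistics; in particular the generator produces stationary vowels with
i.i.d. perturbations and no recording-channel artifacts beyond band-pass
and quantization, so passing tests certify the *estimators and protocol*,
not clinical performance.

## Phonation features (23)

- **Pitch.** 40 ms frames every 10 ms; per frame the normalized
  autocorrelation (each lag normalized as a true correlation coefficient of
  the overlapping segments) is scanned over the sex-specific lag band
  (75–300 Hz male, 100–600 Hz female).  All local maxima are parabolically
  refined into candidates; the smallest lag within 0.04 of the frame's best
  peak wins (for a periodic frame every period multiple peaks equally, so
  the smallest credible lag is the period).  A second pass snaps every
  frame to the candidate nearest the contour median — a sustained vowel has
  one pitch, and this repairs residual octave slips that a missing
  fundamental provokes at high jitter.  Voicing threshold: 0.45.
- **Cycles.** The waveform is sinc-upsampled ×8 and cycle peaks are picked
  in F0-guided windows (0.7–1.3 local periods ahead of the previous peak),
  each refined by a three-point parabola.  Sub-sample precision is not a
  luxury: at 8 kHz one sample is ≈ 1.5 % of a 120 Hz period — the same
  order as pathological jitter.
- **Jitter / shimmer.** Standard definitions on the cycle sequence:
  local = mean |ΔT| / mean T; RAP/PPQ5 (APQ3/5/11) = mean absolute
  deviation from the 3/5(/11)-point moving mean, relative to the overall
  mean; DDP = 3·RAP and DDA = 3·APQ3 exactly; shimmer local-dB =
  mean |20 log₁₀(A_{i+1}/A_i)|.
- **HNR.** Per voiced frame, r at the pitch lag (on the ×8-upsampled frame,
  lag chosen nearest the recording's median period) gives
  10·log₁₀(r/(1−r)), capped at 40 dB; the reported HNR is the mean over
  voiced frames.  Jitter and shimmer genuinely lower this quantity — an
  aperiodic voice *is* noisier at the pitch lag — so the estimator matches
  the generator's `hnr_target` only when other perturbations are small
  (validated at ±3 dB for a 20 dB source with zero jitter).
- **Formants.** Pre-emphasis 0.97, 30 ms Hamming frames every 10 ms, LPC
  order 10 (the 2 + fs/1000 rule at 8 kHz) via Levinson–Durbin on the
  biased autocorrelation; roots of the prediction polynomial with positive
  imaginary part, bandwidth < 400 Hz and frequency > 150 Hz become formant
  candidates; the lowest four, averaged over frames.  Validated to within
  7 % of the generator's resonator frequencies on the unfiltered synthesis
  path: the telephone band edge at 3400 Hz sits on top of f4, and the
  channel roll-off biases any estimator there — with the channel on, the
  f4 error reflects the channel, not the tracker.

## Spectral features

256-sample (32 ms) windows, 50 % overlap, trailing partial window
discarded — a 1.5 s recording yields exactly 92 windows.  Per window the
order-10 Yule–Walker system on the biased autocorrelation (divide by N,
guaranteeing positive semidefiniteness and |c_k| < 1) is solved by the
Levinson–Durbin recursion; no taper is applied before the AR fit
(textbook Yule–Walker), while the spectrogram stage tapers independently.
Convention: A(z) = 1 − Σ a_k z^(−k), i.e. a_k are predictor coefficients;
under this convention the first model-spectrum cepstral coefficient equals
+a₁ (it equals −a₁ under the 1 + Σ convention; one convention is used
consistently by the formant, cepstrum and LAR code).  LAR:
g_k = log((1−c_k)/(1+c_k)).  Cepstrum: the standard recursion
cep_n = a_n + Σ_{m<n} (m/n)·cep_m·a_{n−m}, 12 coefficients, gain term
excluded.  MFCC: Hamming-windowed magnitude spectrum → 26 triangular mel
filters over 0–4 kHz (HTK mel map) → log energies floored at 1e−12 →
orthonormal DCT-II → 13 coefficients including the 0th (energy).
Pooling: elementwise mean and sample variance (ddof = 1) across windows.

## Spectrograms and the image classifier

STFT with the same 256/50 % framing, Hann taper, zero-padded 1024-point
FFT (513 × 92 for 1.5 s at 8 kHz); normalization 10·log₁₀(|S|/max|S|)
(max exactly 0, invariant to recording level; zero bins floored at
1e−12·max before the log).  Rendering clips at −80 dB, maps through
viridis (color) or a linear ramp (grayscale), frequency upward, no axes or
margins, bilinear-resampled to 600 × 600, written losslessly as PNG (a
JPEG option exists for fidelity experiments).

The image classifier follows the transfer-learning recipe at desk scale: a
*frozen* convolutional feature extractor and a trained four-layer head
(batch normalization → dense(256, ReLU) → dropout 0.5 → dense(1, sigmoid)),
optimized with Adam (lr 0.001, 10 epochs, batches of 4, binary
cross-entropy, no augmentation).  The backbone is a compact stack of seeded
random He-initialized 5×5 convolutions (stride 2, ReLU) pooled to a 4×4
grid of per-cell activation means *and* standard deviations.  Random
convolutional features are a standard strong baseline for small-image
problems; the std-pooling channel is essential here because the 256-sample
window barely resolves individual harmonics (its main lobe is as wide as
the harmonic spacing for male F0), so the group signal lives in the
*temporal texture* of the time–frequency field, not in its smooth layout.
Freezing the backbone keeps the recipe honest about its tiny sample size
and lets activations be cached across the 100 evaluation splits.
Grayscale images are channel-replicated before the backbone, so color and
grayscale runs share one architecture.  Head widths, dropout rate and the
freeze policy are package choices.

## Classifiers and the evaluation protocol

- **Stepwise-AIC logistic regression.** Bidirectional search from the
  intercept-only model; at each step the single add/remove move that most
  lowers the AIC is applied until none improves it (BFGS-fitted
  statsmodels logits).  Complete separation — likely given the deliberate
  jitter/shimmer collinearity — is detected by exploding coefficients and
  answered with a ridge-penalized fit over the selected terms, with a
  warning.
- **Random forest.** Breiman CART bagging via scikit-learn: 1000 trees,
  6 candidate variables per split, terminal nodes ≥ 5, Gini criterion;
  importances are mean decrease in Gini impurity.
- **AUC.** Mann–Whitney rank formulation with half-credit ties; verified
  exactly against exhaustive concordant-pair counting.
- **Protocol.** Per iteration: stratified 70/30 split (stratification
  prevents empty-class test sets at n ≈ 80), 3-fold CV inside the training
  part as a model-assessment loop (the forest's hyperparameters are fixed,
  so CV tunes nothing; its fold AUCs are reported as a stability
  diagnostic, and the loop can be switched off where only test AUCs are
  needed), final fit on the full training part, AUC on the untouched test
  part; 100 iterations with per-iteration seeds derived from one master
  seed.  No multiple-testing correction is applied anywhere.
- **Ancillary checks.** Pearson chi-square (no continuity correction) for
  sex-by-group independence; an age-adjusted group test as the linear model
  feature ~ group + age with the Wald p-value on the group term; Pearson
  correlation matrices for the collinearity report, with zero-variance
  columns flagged by warning rather than silently NaN.

## Problem sizes used by the test suite

The suite exercises the full protocol at sizes chosen for a single CPU:
one session-wide 40 + 40 cohort at the generator defaults; 100–200 voices
for parameter-recovery and collinearity checks; 25 protocol iterations for
the separability check and 4 permutations × 6 iterations per track for
null calibration (averaging over permutations separates protocol bias from
the chance association any single permutation carries at n = 80); image
runs at 128 px.  The acceptance script synthesizes its 200-voice cohort in
full.

## Known limitations

- The generator's perturbations are i.i.d. Gaussian per cycle
  (an AR-correlated jitter option is a natural extension); real tremor and
  breath effects are not modeled, nor are room acoustics, codec artifacts
  or background noise (an optional spectral-subtraction denoiser is out of
  scope because the synthetic channel adds no additive stationary noise).
- Measured jitter/shimmer include a physical cross-coupling: resonator
  tails overlap successive cycles, so period perturbation modulates peak
  amplitudes (and vice versa).  Recovery is therefore validated by
  correlation under single-factor designs, not by absolute agreement.
- HNR compresses above ≈ 30 dB (cap 40 dB) and is depressed by jitter, as
  discussed above.
- The image classifier is a desk-scale stand-in faithful to the head
  recipe and protocol; it makes no claim of matching a large pretrained
  network's representation quality.
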