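# Methods

## The synthetic EEG model

Real two-state driving-fatigue recordings are rarely shareable, so every
stage of the pipeline is exercised on synthetic data whose statistical
structure matches what the analysis assumes.

Each channel is a sum of five band-limited processes — delta 0.5–4, theta
4–8, alpha 8–13, beta 13–30, gamma 30–50 Hz (configurable) — realised as
4th-order-Butterworth-filtered white noise normalised to unit RMS and scaled
by a per-state band amplitude in microvolts. Filtered noise, not pure
tones, is deliberate: tones would make EMD and the band-power features
trivially easy. Default amplitudes (µV RMS):

| state   | delta | theta | alpha | beta | gamma |
|---------|-------|-------|-------|------|-------|
| normal  | 3.0   | 2.5   | 9.0   | 5.0  | 1.5   |
| fatigue | 8.0   | 8.5   | 4.0   | 2.5  | 1.5   |

The contrast direction (fatigue raises delta/theta, wakefulness shows the
alpha/beta peaks) is the physiological signature the classifiers must
exploit; the magnitudes are free parameters of the simulator chosen to give
a clear but not degenerate separation while keeping the 99th percentile of
absolute amplitude below the ~100 µV ceiling of scalp EEG. They are not
estimates of any particular dataset. On top of the oscillations the
generator adds Gaussian sensor noise (default SD 2 µV), a 50 Hz mains
sinusoid with random phase per channel (1 µV), and Poisson-arriving
(4/minute) ocular-like transients: 1–3 Hz oscillations with a 0.3 s
exponential decay at five times the background RMS.

Subject identity enters as a log-normal gain (σ = 0.2) on every band
amplitude, drawn from a seed derived from the subject label. This is what
makes leave-one-subject-out evaluation genuinely harder than a random
split: a held-out subject's overall spectral balance differs from every
training subject's.

What the generator does *not* model: volume conduction and inter-channel
correlation structure (channels are independent realisations), non-
stationarity within a session, true eye-blink topographies, electrode
drift. Passing tests therefore demonstrate the pipeline's correctness and
the direction of its comparisons, not field performance on real EEG.

## Preprocessing

Downsampling low-passes at 0.8× the target Nyquist frequency (8th-order
Butterworth, forward–backward) before decimating — the 0.8 factor guards
the 50 Hz analysis edge when reducing to 200 Hz. The band-pass is applied
after downsampling (the order is configurable) and is implemented as two
zero-phase stages: an SOS Butterworth low-pass, then a transfer-function
Butterworth high-pass solved with Gustafsson initial conditions. A single
combined band-pass with a 0.1 Hz lower edge mixes second-scale poles into
every section and lets padding transients ring across the whole record;
separating the stages and using Gustafsson's method removes that failure
mode. The high-pass stage is capped at order 4 — polynomial filter
coefficients at a sub-Hz edge are ill-conditioned beyond that, and a
steeper skirt at 0.1 Hz has no analysis value.

Epochs are consecutive, non-overlapping, and drop the trailing partial
window; 20 minutes at 10 s/epoch gives exactly 120 epochs per recording,
so the 6-subject × 2-state design yields 720 + 720 = 1440 samples.

## Wavelet denoising

Default wavelet db4 with 3 decomposition levels, both configurable;
thresholding touches detail levels only. The noise scale is estimated from
the finest-level details as `σ̂ = Σ|d₁ₖ|/(0.6745 N)`; the magnitudes are
essential (a signed sum has expectation zero for zero-mean noise), and the
classical `median(|d₁|)/0.6745` is available as `sigma_mode="median"`.
Note the mean-absolute form is biased high for pure Gaussian noise
(expectation `σ·√(2/π)/0.6745 ≈ 1.18σ`), which makes the global `3σ̂` rule
conservative — intentionally retained as specified behaviour.

The level-dependent rule is `λ_j = σ̂·√(2 log N_j)/log(j+1)` with natural
logarithms (configurable base). An optional overall multiplier on λ
(`lambda_scale`) defaults to 1; the benchmark uses 0.5.

SNR is `10·log₁₀(Σx²/Σ(x−x̂)²)` — the denominator is the residual power,
which is the only reading consistent with RMSE and with double-digit dB for
a working denoiser — and returns +∞ for an exact reconstruction.

The three-method benchmark runs each rule under its native threshold
selection: hard and soft with the global 3σ̂ rule, improved-soft with
level-dependent thresholds, shape coefficient a = 0.01 and scale 0.5. Under
these settings the improved rule attains the best mean SNR and lowest mean
RMSE of the three on 100 noisy epochs (clean band-mixture signals plus
Gaussian noise of SD 5 µV), with hard slightly ahead of soft — the
qualitative ordering the comparison is designed to show. At a *common*
threshold the improved rule with a small shape coefficient is numerically
close to soft and would not dominate hard; the per-method threshold rules
are part of the method definitions here.

## Empirical mode decomposition

Strict local extrema by neighbour comparison; an extremal plateau
contributes its midpoint (earlier index on even-length runs). Envelopes are
cubic splines through the extrema, with the two end extrema mirrored beyond
each boundary before fitting (a clamped mode is available); boundary
handling dominates EMD quality in practice and mirroring suppresses the end
swings that corrupt IMF energies. One sift subtracts the envelope mean
`(e_up + e_low)/2`.

Sifting accepts an IMF when the Cauchy criterion
`Σ(h_prev−h)²/Σh_prev² < 0.2` *and* the candidate satisfies the IMF
condition that extrema and zero-crossing counts differ by at most one; the
Cauchy test alone stops too early on broadband signals, leaving riding
waves. A fixed-sift-count mode is available instead. Extraction stops when
the residual has fewer than two maxima or minima, when `max_imfs` is
reached, or when the residual energy falls below 1% of the input energy.
IMFs plus residual reconstruct the input to machine precision by the
telescoping construction.

## Features

The STFT uses the symmetric Hann window `0.5(1−cos(2πn/(N−1)))`
(equivalently `sin²(πn/(N−1))`), window length 1 s at the epoch's rate and
50% overlap by default, with full-DFT bins `w_k = 2πk/N`. The per-epoch
power spectrum is the squared magnitude averaged over frames, divided by N;
band energies sum bins over half-open intervals `[f_lo, f_hi)` so bands
partition the axis without double counting. Energy spectral density is
`|DFT(x)|²/2π`, and one EMD feature is the total ESD of one IMF. Channels
yielding fewer than `n_imfs` IMFs contribute zero-energy placeholders so
the matrix stays rectangular. Energy features scale quadratically with
amplitude.

The higher-order-spectrum estimators (segmented third-order cumulant with
the `s₁/s₂` edge truncation, and the AR-model bispectrum
`B(w₁,w₂) = β̂·Î(w₁)Î(w₂)Î*(w₁+w₂)`) are implemented and tested but sit
off the default classification path. The AR transfer function uses the
exponent `exp(−jw(n−1))` by default with a `convention="standard"` switch
for the textbook `exp(−jwn)`.

## Classifiers

ELM: inputs are z-scored with training-fold statistics stored in the model
(energy features span orders of magnitude and would otherwise saturate a
sigmoid); hidden weights and biases are uniform on [−1, 1] from the seed;
output weights solve the ridge system `(HᵀH + C·I)β = HᵀT`, so larger C
means stronger shrinkage. H-ELM stacks sparse ELM autoencoders: each layer
expands through a random hidden map, learns reconstruction weights by 50
FISTA iterations of ℓ1-regularised least squares, and projects forward with
their transpose; defaults are two 100-unit layers and a 500-hidden final
ELM. PSO uses the canonical inertia/cognitive/social update (ω = 0.7,
c₁ = c₂ = 1.5, velocity clamped to half the box per dimension).

PSO-H-ELM searches layer sizes in [20, 300], final hidden width in
[100, 1000] and log₁₀C in [−4, 4] (swarm 15, 30 iterations by default),
scoring each particle by stratified k-fold CV accuracy on the training rows
only and rounding integer dimensions at evaluation time. The swarm is
warm-started at the default H-ELM configuration, so the search abandons the
incumbent only on cross-validation evidence; the returned model is
retrained on all training rows at the best position. What exactly the
optimiser should tune is an open design choice; hyperparameter search is
the implemented reading (optimising the random input weights themselves is
deliberately not done — it forfeits the ELM's main computational
advantage).

## Evaluation

LOSO folds are one per subject and partition the epochs exactly. Report
averages are the arithmetic means of the report's own cells; cells where a
classifier fails are excluded from that classifier's average with a logged
count rather than propagating NaN. Paired t-tests use the n−1 variance,
Student-t confidence intervals and two-sided p-values; zero-variance
difference vectors are flagged degenerate instead of dividing by zero. No
multiple-testing correction is applied by default, matching the usual
presentation of such comparison tables; Holm-adjusted p-values can be
requested (`holm=True`), which controls the family-wise error rate over
the reference-vs-rest comparisons.

## Problem sizes and determinism

The default test suite and the acceptance script use these sizes, chosen as
the package's own desk-scale study conditions: the epoch/split contracts
run the full 6 × 20-min design at 200 Hz and 32 channels; the denoising
benchmark uses 100 ten-second epochs; classifier comparisons use 4 subjects
× 1 minute per state × 8 channels with a swarm of 4 and 4 PSO iterations
(warm-started), which preserves the comparisons' direction at a fraction of
the full-design cost. All randomness flows from explicit integer seeds;
equal seeds give bit-identical datasets, features and reports.

## Known limitations

- EMD has no uniqueness theory; results depend on the stopping rules and
  boundary handling documented above.
- The improved-soft benchmark ordering is a property of the per-method
  threshold rules and the synthetic noise model, not a universal dominance
  claim.
- The EDF writer covers the subset of the format the pipeline needs
  (one data record per second, uniform rate, 16-bit amplitudes, per-channel
  symmetric physical range); it is not a general-purpose EDF+ library.
- Synthetic channels are spatially independent; any result that would rely
  on cross-channel structure (e.g. spatial filtering) is out of scope.
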