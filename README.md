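# fatigueeg

Detecting driving fatigue from scalp EEG. The package implements a complete,
tested signal-processing and classification pipeline for two-state
(normal vs. fatigue) EEG experiments:

1. **Synthetic EEG** — a generator for multichannel 10–20-montage recordings
   whose band structure carries the physiological fatigue signature
   (elevated delta/theta power when fatigued, prominent alpha/beta peaks when
   awake), contaminated with broadband noise, 50 Hz mains interference and
   ocular-artifact transients.
2. **Preprocessing** — EDF/CSV I/O, anti-aliased downsampling (1000 → 200 Hz),
   zero-phase Butterworth band-pass ([0.1, 50] Hz) and 10-s epoching.
3. **Wavelet denoising** — hard, soft and improved-soft threshold rules with
   global 3σ or level-dependent thresholds, a finest-level noise-scale
   estimator, and SNR/RMSE quality metrics.
4. **Feature extraction** — Hann-windowed STFT band powers per channel, and
   EMD + energy-spectral-density features (first 3 intrinsic mode functions
   per channel: 32 × 3 = 96 features), plus optional higher-order-spectrum
   estimators (segmented third-order cumulants, AR-model bispectrum).
5. **Classification** — extreme learning machine (ELM), hierarchical ELM
   (stacked sparse ELM autoencoders), PSO-tuned H-ELM, and KNN/SVM baselines.
6. **Evaluation** — a leave-one-subject-out (LOSO) harness with per-subject
   accuracies, averages and paired t-tests.

## The core methods

**Improved-soft wavelet thresholding.** For detail coefficient `d`,
threshold `λ` and shape coefficient `a < 1/λ`:

```
d̃ = aλ² − λ + d   (d ≥ λ)          d̃ = a·d²     (0 < d < λ)
d̃ = −aλ² + λ + d  (d ≤ −λ)         d̃ = −a·d²    (−λ < d < 0)
```

At `a = 0` this is exactly the soft rule `sign(d)(|d| − λ)`; as `a → 1/λ`
it approaches the hard keep/kill rule while staying continuous. Thresholds
come from `λ = 3σ̂` or the level rule `λ_j = σ̂√(2 ln N_j)/ln(j+1)`, with
`σ̂ = Σ|d_{1k}|/(0.6745 N)` from the finest detail level.

**EMD + energy spectrum features.** Each channel is decomposed by
envelope-mean sifting into intrinsic mode functions; each of the first
three IMFs is summarised by its total energy spectral density
`Σ_k |F(w_k)|²/2π`.

**ELM family.** `H = g(XW + b)` with random fixed `W, b`;
`β = (HᵀH + C·I)⁻¹HᵀT` against one-hot labels. H-ELM stacks sparse ELM
autoencoders (ℓ1-regularised reconstruction, solved by FISTA) before the
final ELM; PSO-H-ELM tunes layer sizes and `log₁₀C` by particle swarm with
stratified-CV fitness computed on training folds only.

## Worked example

```python
from fatigueeg import SimConfig, generate_dataset, run_experiment

cfg = SimConfig(n_subjects=4, minutes_per_state=1.0, rate=200.0,
                n_channels=8, seed=3)
report = run_experiment(generate_dataset(cfg), feature_method="emd",
                        classifiers=["knn", "svm", "elm", "helm"], seed=3,
                        target_rate=None)
print(report.summary())
```

prints

```
Per-subject accuracy (%)
        S01    S02    S03    S04
knn   100.0  58.33  100.0  100.0
svm   100.0  50.00  100.0   50.0
elm   100.0  50.00  100.0  100.0
helm  100.0  58.33  100.0  100.0

Average accuracy (%)
knn     89.58
svm     75.00
elm     87.50
helm    89.58
```

Each column is one LOSO fold: the classifier never saw that subject during
training, so a 58% column (subject S02) means that subject's per-subject
gain pattern transfers poorly — exactly the inter-subject variability LOSO
is designed to expose. The averages are the arithmetic means of the rows.

A command-line interface mirrors the stages:

```bash
fatigueeg simulate --subjects 6 --minutes 20 --out-dir data/
fatigueeg preprocess --in data/S01_normal.edf --out S01_pp.edf --rate 200
fatigueeg denoise --in S01_pp.edf --out S01_dn.edf --method improved --a 0.01
fatigueeg features --in S01_dn.edf --out S01_feats.csv --method emd
fatigueeg evaluate --subjects 4 --minutes 2 --feature-method psd
```

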