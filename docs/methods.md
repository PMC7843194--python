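# Methods

`sdaeconn` implements an adaptive EEG feature-extraction and
brain-connectivity pipeline: multichannel recordings are spatially
sharpened with a 4-neighbor surface Laplacian, compressed per brain area by
a two-stage stacked denoising autoencoder (SDAE) whose hidden widths can be
chosen by a spectral model-selection score, scored for rhythm SNR by the
RPFA statistic, and finally analyzed for directed interactions between
areas with conditional Granger causality (GC) and a permutation
significance test. This note records the model, the defaults and the design
decisions, in enough detail to reproduce or criticize them.

## Preprocessing

* **Band-pass + notch.** 4th-order Butterworth band-pass (default
  0.5–100 Hz) and 2nd-order Butterworth band-stop (default 48–52 Hz), both
  applied forward–backward (`sosfiltfilt`) so the output is zero-phase.
  Reflective padding of 3 s bounds the start-up transient of the 0.5 Hz
  high-pass edge. Zero-phase filtering is *non-causal*: it spreads
  information backwards in time, and we measured that it injects spurious
  reversed Granger causality (reverse-direction F up to ≈0.013 against a
  null scale of ≈0.003 on otherwise clean synthetic data). The pipeline
  therefore exposes `apply_bandpass` and the synthetic connectivity studies
  run without temporal filtering; for real EDF recordings (which need mains
  and drift suppression for the spectral analyses) the filter stays on, and
  the pre-whitening step below limits the damage to GC.
* **Surface Laplacian.** Every channel with a complete set of 4 symmetric
  montage neighbors is replaced by
  `V_C = V_CO − (V1+V2+V3+V4)/4` per sample; border electrodes without a
  full neighbor set pass through unchanged and are listed in the output
  metadata. The montage is user-supplied configuration (YAML label → 4
  neighbor labels); a rectangular-grid montage builder ships for synthetic
  data. The operation is exact arithmetic — tests compare against a
  per-sample brute-force loop at 1e−12.
* **Decimation.** Anti-aliased IIR decimation by an integer factor, refused
  whenever the new Nyquist frequency would fall below 20 Hz (all analyzed
  content is below 30 Hz). The intended workflow decimates 1200 Hz
  acquisitions to 120 Hz before model fitting.

## Stacked denoising autoencoder

Two sigmoid autoencoders trained greedily. Stage 1 maps the c channels of
one area to n hidden units, stage 2 maps those to m ≤ n units; the m deep
hidden series averaged across units form the extracted per-area feature.

* **Corruption** is masking noise: each input entry is independently zeroed
  with probability 0.5 before encoding while the reconstruction target
  stays clean.
* **Scaling.** Channels are min–max scaled to [0, 1] per channel before the
  sigmoid network (sigmoid outputs cannot reproduce signed microvolt
  values); the scaler is stored in the fitted results.
* **Training** is plain minibatch SGD on squared reconstruction error
  (learning rate 1, minibatch 200), untied decoder weights, uniform
  initialization in ±4·√(6/(fan_in+fan_out)), no momentum or weight decay.
  The inner loop is numba-compiled; training is bit-reproducible under the
  configuration seed. Stage 2 trains on stage 1's clean hidden output with
  corruption re-applied.
* **Epochs.** The reference configuration (corruption 0.5, lr 1, minibatch
  200, 8 epochs, widths n=8/m=3) is tuned for 1-minute recordings at
  1200 Hz, i.e. ≈2880 SGD steps. At the 120 Hz working rate the pipeline
  default is 80 epochs, which restores the same gradient-step budget; with
  only 8 epochs at 120 Hz the autoencoder is visibly undertrained (its
  reconstruction error stays at the variance of the input).

## Width selection (the c_f score)

For each admissible pair (n, m) — m·n ≤ U_def, m ≤ n < C_def,
1 ≤ m < C_com, defaults U_def=30, C_def=15 (must stay below the channel
count), C_com=5 — an SDAE is trained with a shared seed and scored by

    c_f = λ·exp(−(e1+e2)/(2c)) + (1−λ)·Σ_j c̄_j³ ,   λ = 0.2

where e1, e2 are the two stages' reconstruction errors (squared error
time-averaged per channel/unit, summed over channels/units, so the score is
length-invariant) and c̄_j are the min–max-normalized time-summed STFT
magnitudes of the extracted feature over the bins at or below 20 Hz (Hann
window of 1 s, 50% hop). Ties break toward smaller m, then smaller n. The
grid search shares stage-1 models across pairs with equal n (bit-identical
to independent training, verified by test).

**Caveat, by measurement:** after min–max normalization over the sub-20 Hz
bins, a spectrally *flat* feature scatters c̄ over [0, 1] and obtains a
*larger* cubed sum (≈d/4) than a single-peak feature (≈1). The automatic
search therefore often prefers degenerate widths such as (1, 1) whose
features carry little of the broadband structure needed downstream; in the
planted-chain study the recovery rate drops from 19/20 with the reference
widths (8, 3) to roughly half with automatic selection. The pipeline
consequently defaults to the reference widths (`select_widths=False`), with
the full grid search available as an option and as a diagnostic artifact.

## Spectral features

* **Power spectra** are Welch periodograms (2 s Hann segments, 50%
  overlap).
* **RPFA** — the ratio of the power at the dominant in-band frequency to
  the mean in-band power — is the SNR proxy for a band-limited rhythm;
  always ≥ 1, invariant to gain. The scored band depends on the mental
  condition: alpha∪beta (8–30 Hz) when awake, delta∪theta (0.5–7 Hz) for
  fatigue and sleep deprivation.
* **PCA baseline**: projections on the top-k principal axes of the channel
  covariance; the comparison feature is the mean of the k projection
  series, mirroring the SDAE's feature averaging.
* **Paired t-test** on matched RPFA (or normalized STFT) observations,
  two-sided.

## Conditional Granger causality

Per-equation OLS VAR with intercept;
`F_{source→target|rest} = ln(var_restricted/var_full)` where the restricted
model omits all lags of the source. The VAR order is the BIC minimizer over
1..p_max (default 20) on a common sample, with the AIC/BIC curve exposed as
a diagnostic. Edge significance uses a circular-shift permutation null
(source series rotated by a random offset, statistic recomputed; add-one
p-value, n_perm = 199 so p < 0.01 requires beating every permutation),
α = 0.01.

Two robustness measures are applied by the model class (and hence the
pipeline) before/within estimation; both leave genuine lagged causal
structure intact and both can be disabled:

1. **Univariate pre-whitening** (AR(40) OLS residuals per series, ≈ a third
   of a second of memory at 120 Hz). GC is invariant to invertible causal
   per-series filtering, but a linear VAR fitted to sigmoid-compressed
   observations of a smooth process extracts spurious cross-predictions
   from the distorted smooth component; removing each series'
   self-predictable part eliminates most of that artifact and lets BIC find
   the true short lag order.
2. **Net time-reversed statistic**: F(data) − F(time-reversed data).
   Genuine lagged flow flips direction under time reversal whereas
   artifacts of measurement noise, instantaneous mixing and static
   nonlinear distortion are time-symmetric and cancel. On the planted-chain
   study this removes essentially all remaining spurious reversed edges
   (recovery 19/20 versus ≈16/20 without it). The low-level
   `conditional_gc` operation and the default of `significance` keep the
   plain statistic.

## Synthetic data generator

Each area has one latent source: a band-limited rhythm (narrowband-filtered
noise — spectra resemble EEG rhythms, not spectral lines) plus broadband
Gaussian innovation, propagated through the directed lagged couplings
(a low-order VAR whose companion spectral radius must stay below 1).
Channels observe their area's source through per-channel lead-field gains
plus independent sensor noise and a slow 0.2–0.5 Hz drift.

Defaults (the desk-scale study conditions): 4 areas × 25 channels on a 5×5
grid (a 126-electrode cap split into four regions has ~31 electrodes each;
25 also satisfies the selection constraint C_def=15 < channels), 120 Hz,
60 s, 10 Hz alpha rhythm of amplitude 0.5 on a 0.7-sd broadband background
(rhythms ride on a comparable 1/f background in real EEG), gains
U(0.5, 1.5), sensor noise sd 0.2, drift amplitude 0.5 (most sub-0.5 Hz
drift is removed by acquisition filtering; a residual remains, as the
spectra of real recordings show).

Two named conditions:

* `chain_spec`: the connectivity study — couplings 1→2→3→4, gain 0.6, lag
  2 samples. Single-polarity topography: mixing electrode polarities
  interacts with the sigmoid's distortion and measurably degrades directed
  recovery, which is a known limitation of the feature extractor, not of
  the generator.
* `buried_rhythm_spec`: the SNR study — rhythm amplitude 1.0 buried per
  channel under drift 1.5 and sensor noise 2.0, with a strongly dipolar
  topography (40% of electrodes inverted). Under these conditions the
  naive channel average cancels much of the rhythm while the SDAE learns
  signed weights, so mean RPFA orders SDAE > raw average (and > PCA's mean
  projection); with a single-polarity topography the naive average is
  already within a few percent of the oracle-weighted combination and no
  extractor can beat it materially.

What the generator does **not** emulate: volume-conduction mixing *between*
areas, non-Gaussian artifacts (blinks, muscle), nonstationary rhythm power,
and realistic 10-5 electrode geometry. Passing tests on this generator
therefore demonstrate correctness of the algorithms and recoverability
under controlled conditions, not performance on clinical recordings.

## Numerical conventions and degenerate inputs

* Min–max normalization of STFT sums defines the all-equal case as all
  zeros; constant channels get unit scale in the SDAE scaler.
* Residual covariances use the maximum-likelihood divisor (N_eff); GC is a
  ratio, so the divisor cancels.
* The permutation p-value is (1+#exceed)/(1+n_perm), never 0.
* `fit_var` raises on rank-deficient regressors (duplicated series);
  `conditional_gc` raises on non-positive residual variances.
* Sigmoid evaluation is branch-split to avoid overflow; outputs saturate to
  exactly 0/1 only beyond |a| ≈ 37 (float64).

## Problem sizes

The test-suite and acceptance-script studies use the defaults above: 60 s
at 120 Hz (7200 samples), 20 seeds for the chain-recovery study, 10 seeds ×
2 areas for the RPFA study, 500 simulations for the permutation-test
calibration. These sizes give stable Monte Carlo estimates (binomial 99%
intervals are asserted where a rate is checked) while keeping a full run in
minutes on one CPU.

## Known limitations

* The c_f spectral term prefers flat sub-20 Hz spectra (see above); width
  selection should be treated as a diagnostic, not an oracle.
* Sigmoid feature distortion both limits RPFA gains in benign conditions
  and is the source of the GC artifacts that pre-whitening and the
  time-reversed statistic suppress; a strongly dipolar topography degrades
  directed recovery.
* EDF support covers plain 16-bit EDF (the writer exists so fixtures can be
  round-tripped; it does not write EDF+ annotations).
* Conditional GC is time-domain only; no spectral/state-space variants.
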