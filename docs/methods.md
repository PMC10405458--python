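# Methods

This note documents the models, parameter choices and numerical conventions
behind `oxygait`, and what the synthetic cohort generator does and does not
emulate.

## The signal model behind the synthetic cohorts

The generator (`oxygait.synthetic`) produces coupled fNIRS/gait trials for a
protocol in which a subject either ramps walking speed at constant stride
length (`mode="speed"`) or ramps stride length at constant speed
(`mode="stride"`). A slow latent intensity profile in (0, 1] — a linear ramp
from 0.3 to 1.0 over the trial with small smooth sinusoidal jitter
(`latent_jitter`, default 0.02) — is the single hidden variable both
modalities share.

**Hemodynamics.** Each of the 6 channels (10 Hz default sampling, typical
for continuous-wave instruments and sufficient for the 0.6–2.0 Hz cardiac
band) is a sum over the five physiological bands of amplitude-modulated
sinusoids at the band's geometric-center frequency with slow random phase
drift. AM oscillators were chosen over filtered noise because their envelope
and spectral placement are analytically checkable. In the informative
channels (default the first three, standing in for motor-cortex optodes) the
oscillator envelope is `base_amplitude × (0.2 + coupling_gain × intensity)`;
elsewhere the envelope is constant at the same mean power, so informative and
uninformative channels differ only in modulation, not scale. Base amplitudes
decrease with frequency (endothelial 1.0 → cardiac 0.4 µM), mimicking the
1/f-like shape of resting hemodynamics. HbR is −0.4 × HbO (opposite sign,
reduced magnitude, as oxy/deoxy changes typically anticorrelate), which also
exercises the sign-insensitive |c| in the selection score; HbT = HbO + HbR
holds exactly by construction. Linear drift (0.001 µM/s) and white noise
(0.05 µM) are added per channel; each subject carries a multiplicative gain
(sd 0.1) and additive offset (sd 0.05 µM) so that Z-score normalization and
individual adaptation have real work to do. Defaults were chosen once as a
clean-but-plausible operating point in which the informative-band envelope
correlates with the latent intensity at r ≈ 0.85 — comfortably above the
r > 0.5 floor below which no downstream recovery could be expected.

**Gait.** The knee angular-velocity trace is a train of half-sine bursts,
one per cycle, cycle durations drawn uniformly from 0.9–1.3 s; the per-cycle
peak is an affine map of the speed intensity at the cycle midpoint
(100 + 200·s deg/s). The angle series is the analogous burst train driven by
stride intensity (30 + 40·l deg). White sensor noise of 1 deg/s (deg) is
added. The trace ends at the last complete cycle boundary, so every
generated cycle is whole; ground-truth boundaries and noiseless per-cycle
maxima are stored for oracle tests. Bursts are nonnegative with zeros at
boundaries, so rectification is near-identity and envelope minima coincide
with the true cycle boundaries.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: photon-transport/optode geometry, motion
artifacts, task-evoked hemodynamic response shapes, respiration/cardiac
coupling into gait, non-stationary noise, electrode drop-out, or any
relationship between the two trial types of a real subject. Recovery results
on this cohort demonstrate that the pipeline's machinery is correct and
well-coupled, not that real cortical signals carry this much information.

## Preprocessing conventions

* Baseline removal subtracts the first sample per channel (idempotent).
* Band-pass: Chebyshev type I, order 2, 0.5 dB passband ripple — "second
  order Chebyshev" admits several readings; type I with modest ripple is the
  conventional one. Filters are applied forward-backward (zero phase) so
  features and targets stay time-aligned; this doubles the effective order,
  and amplitude criteria therefore apply to |H(f)|². Second-order sections
  are used throughout for numerical stability of the very narrow
  low-frequency bands.
* Adjacent bands share an edge frequency, so a second-order filter is still
  at 7–14% gain at its neighbour's center; attenuation below 5% holds from
  one band to any non-adjacent band.
* Gait: Butterworth order 2 low-pass at 6 Hz, rectification, centered
  moving average of 0.25 s (shorter than any plausible gait cycle, so cycle
  minima survive; edges average over the available samples only). Cycle
  boundaries are local minima of the smoothed envelope at least 0.4 s apart
  (prevents noise-split cycles); the trace start/end close the first and
  last cycle, which are flagged partial and excluded from training targets.
* Staircase values are assigned over the closed-open interval [b_k, b_{k+1}).

## Feature battery

Windows are 5 s long with 0.5 s stride, end-aligned to the target sample —
long enough to contain low-band content at 10 Hz while giving ~100 windows
per 60 s trial. Moments use population (1/n) normalization; kurtosis is the
plain fourth standardized moment; on a constant window std, skewness,
kurtosis and entropy are all defined as 0. Zero crossings count strict sign
changes with zeros inheriting the previous sign. Entropy is Shannon entropy
(bits) of a 16-equal-width-bin histogram over the window's own min–max
range. Pearson pairs are enumerated in lexicographic channel order; a
zero-variance channel yields coefficient 0 with a warning. The five-band
decomposition itself is the frequency dimension of the battery; no separate
spectral features are extracted, which is what makes the 6-channel count
come out at exactly 5 × 3 × (6·9 + 15) = 1,035.

## Selection and reduction

The Pearson screen uses the absolute correlation (a strong negative
correlation is as informative as a positive one) with a strict threshold of
0.3. The embedded stage is scikit-learn's `GradientBoostingRegressor` with
100 trees, depth 3, learning rate 0.1 and a fixed seed; its importances are
the coefficients c. Scores combine as f_score = 2p|c|/(p+|c|) with a guarded
denominator (0 when both vanish); the top k = 100 features (ties broken by
earlier column position) feed the autoencoder. The autoencoder
(`oxygait.nn.Autoencoder`) is a single-hidden-layer encoder/decoder with
linear activations by default (an undercomplete linear AE converges to the
principal subspace, which makes its behaviour verifiable against constructed
low-rank fixtures; `tanh` is available), trained with Adam on standardized
inputs, up to 200 epochs with patience-8 early stopping on reconstruction
loss, latent dimension 20. The whole selector is fitted on training subjects
only and applied frozen to validation, test and adaptation rows.

## Regression and adaptation

The LSTM (`oxygait.nn.LSTMRegressor`) is a single recurrent layer (64 hidden
units, forget-gate bias initialized to 1) with a linear scalar readout from
the last hidden state. Each sample is the sequence of the last 10 window
vectors of the same subject; a subject's first windows are front-padded by
repeating its earliest row so every target row gets a prediction. Training:
Adam, learning rate 1e-3, minibatch 64, L2 1e-4 on all weight matrices,
dropout 0.2 on the last hidden state ("forgetting rate" is read as a dropout
probability; recurrent-state decay and replay-ratio readings were considered
and rejected as less standard), up to 200 iterations with early stopping
after 8 non-improving validation-RMSE iterations and restoration of the best
checkpoint. Cross-validation is subject-level 4-fold (no subject straddles
folds); the deployable model is a refit on all cross-validation subjects
with a deterministic 1-in-10 row slice held out purely for early stopping.
Z-score statistics are global (computed over all training subjects); a
per-subject variant was considered but the global default keeps new-subject
prediction possible without calibration data.

Adaptation fine-tunes a copy of the network on a new subject's adaptation
rows (20 iterations, learning rate 3e-4) and keeps the update only if R² on
the subject's gating rows strictly improves. The gating rows are an
interleaved 30% of the subject's windows (every third window) rather than a
trailing slice, so both sets span the full intensity ramp; gating rows are
never trained on, which prevents trivially self-confirming updates. The
reported post-adaptation metric is that of the retained model, so the
per-subject ΔR² on gating rows is ≥ 0 by construction.

## Evaluation

Relative RMSE is reported in percent (the ×100 convention matches the
magnitudes the metric is usually quoted at); an epsilon guard (1e-9) on the
true series turns an accidental non-positive target into a loud error.
Metrics are computed on staircase-sampled window rows, excluding flagged
partial edge cycles. R² is 1 − SS_res/SS_tot and can be negative for a model
worse than the mean.

## Problem sizes

Unit tests run on 1–8-subject cohorts with 30 s trials; the end-to-end
recovery and adaptation checks and the acceptance script use 12-subject
cohorts (60 s trials, ~107 windows each) with 8–10 unseen adaptation
subjects — small enough to run on a single CPU in minutes while leaving
enough held-out rows (~200 per target) for stable metrics.

## Interfaces

The library surface (`PipelineConfig`, `generate_cohort`, `run_fit`,
`adapt_cohort`, `adaptive_update`) is the primary interface; the CLI wraps
it with `simulate`, `fit`, `adapt` and `report` subcommands. The
intermediate stages (preprocess, features, select, train) are deliberately
not separate subcommands: none of their artifacts is meaningful in
isolation, and a single `fit` stage guarantees train-only fitting of every
learned transform. Configuration is one YAML document with sections per
stage and a single master seed; every run writes a config echo and (for
`simulate`) a SHA-256 manifest next to its outputs.

## Known limitations

* The NumPy LSTM is single-layer and CPU-bound; it is sized for the
  synthetic cohorts, not for large real datasets.
* The generator's coupling is stationary and linear in the latent intensity;
  real fNIRS/gait coupling is neither.
* Only the stated R²-gated adaptation is implemented — no replay buffers,
  no meta-learning, no online streaming inference.
* No motion-artifact correction or short-separation regression is applied;
  the generator produces no such artifacts.
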