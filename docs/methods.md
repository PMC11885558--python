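# Methods

`stecg` classifies single-lead ECG into AAMI beat classes without any R-peak
or QRS detection: fixed 10-second segments are mapped to band-limited
Stockwell-transform (S-transform) time–frequency images and classified by a
hybrid convolutional/Transformer network. This note records the models,
parameter choices and numerical conventions, what the synthetic data does and
does not emulate, and the scaling decisions behind the desk-scale study.

## Preprocessing

Raw ECG (any rate ≥ 100 Hz; MIT-BIH-style records are 360 Hz) passes through
eight stages, in order:

1. **50-s windowing.** Non-overlapping; a trailing remainder is dropped.
2. **Low-pass filtering.** Order-4 Butterworth at 30 Hz, applied
   forward–backward (`sosfiltfilt`), so the effective magnitude response is
   |H|² and the phase is exactly zero — beat morphology is not skewed. At
   360 Hz this leaves a 1 Hz tone essentially untouched (RMS ratio
   ≥ 0.999) and attenuates 45 Hz to ≤ 5 % RMS.
3. **Resampling to 100 Hz.** Polyphase rational-ratio resampling
   (`resample_poly`, 5/18 for 360 Hz sources) with built-in anti-aliasing;
   upsampling is out of scope.
4. **Smoothness-priors detrending.** The trend is the ridge solution
   `(I + λ²D₂ᵀD₂)⁻¹x` with D₂ the second-difference operator; the output is
   `x − trend`. λ defaults to 500, giving a sub-hertz effective cutoff at
   100 Hz — below the retained ECG band but above baseline wander. Affine
   signals lie in the null space of D₂ and are removed exactly, for any λ.
   The system is pentadiagonal and symmetric positive definite and is solved
   with a banded Cholesky solver (O(N); N = 5000 in ≪ 1 s).
5. **10-s windowing** into 1000-sample segments.
6. **Outlier rejection.** Tukey fences on a per-segment statistic (default
   peak-to-peak amplitude), Q1 − 1.5·IQR to Q3 + 1.5·IQR, percentiles by
   linear interpolation, computed **per record**. With fewer than 4 segments
   everything is kept. Note a degenerate regime: on strictly noise-free
   synthetic records all amplitudes nearly coincide, the fences collapse,
   and a few segments are rejected on micro-variation; at physiological
   noise levels the spread is real and rejection is rare.
7. **Min-Max normalisation** to exactly [0, 1]; a constant segment becomes
   all zeros with a `degenerate` flag and is excluded from training.
8. **Labelling.** Beat annotations are mapped to AAMI classes
   ({N,L,R,e,j}→N, {A,a,S,J}→S, {V,E}→V, {F}→F, {/,f,Q,U and unknown}→Q;
   rhythm/quality marks are dropped), indices rescaled to the 100 Hz base
   with round-half-even, and each segment takes the majority **non-normal**
   class of its half-open window (all-N → N; no beats → excluded), with
   ties broken by severity V > S > F > Q. The policy is configurable: the
   upstream literature reports segment counts without stating its rule, so
   majority-non-N was chosen as the least surprising default.

## S-transform

For a segment x of length N the discrete S-transform is computed per
frequency voice in the spectral domain:
`S[n,·] = IDFT_m { X[(m+n) mod N] · exp(−2π²m̃²/n²) }` with m̃ the symmetric
alias of m. This is the standard 1/f Gaussian-window convention: wide windows
(fine frequency resolution) at low f, narrow windows (fine time resolution)
at high f, with absolutely referenced phase. Two identities are enforced by
tests and make the transform essentially self-verifying:

* **time marginal** — Σ_k S[n,k] = X[n] exactly (the Gaussian factor is 1 at
  m = 0), giving inversion-grade verification without an inverse API;
* **tone localisation** — a unit cosine at an in-band bin yields |S| = 1/2
  along its voice (half the mass sits at the mirrored negative frequency).

The matrix is band-limited to 0–15 Hz (inclusive; 151 voices at Δf = 0.1 Hz
for N = 1000), where diagnostic beat morphology lives and above which muscle
and mains artifacts dominate. The 0 Hz voice has no finite-width window; by
convention it carries the signal mean. The complex matrix is split losslessly
into a real and an imaginary channel — the network's 2-channel input — so no
phase information is discarded. A brute-force O(N²)-per-voice implementation
(explicit DFT matrices, no FFT) ships as an independent oracle and the two
agree to 1e-10 on every tested signal.

## Classifier

The network follows a fixed table of stages (defaults in `ModelConfig`):

* stem: 7×7 conv, stride 2, 64 ch → 3×3 max-pool, stride 2;
* four stages of two ResNeXt bottleneck blocks (64, 128, 256, 512 ch;
  stages 2–4 downsample by 2). Each block: 1×1 reduce to group width
  (out/2), grouped 3×3 (cardinality 32), 1×1 restore, BN+ReLU between,
  squeeze-and-excitation gate (reduction 16), per-sample stochastic depth
  (p = 0.2, survival-scaled at train time, exact identity at eval), and a
  residual add (1×1-projected when shape changes);
* 1×1 conv to the 512-d embedding; flatten frequency-row-major to
  [B, T, 512]; add a learnable 2-D positional encoding (one vector per row
  index plus one per column index — O(H′+W′) parameters instead of O(H′·W′));
* four post-norm Transformer encoder blocks (8 heads, FFN 2048,
  dropout 0.2), a **global** residual connection from encoder input to
  encoder output (the blocks already carry internal residuals), mean pooling
  over T;
* head: Linear 512→256 → LayerNorm → Linear 256→n_classes.

Convolutions use "same"-style padding so spatial sizes follow ceil(H/stride);
a 151×1000 input therefore reaches exactly 5×32 = 160 tokens. All stochastic
regularisers draw from one seeded generator and are disabled at eval, making
inference bit-deterministic.

The layers run on a small reverse-mode autodiff kernel written on numpy
(`stecg.nn`): broadcast arithmetic, matmul, reductions, im2col convolution
with a pointwise fast path, tap-loop max-pooling and a fused batch-norm
primitive. Every primitive is validated against central finite differences in
the test suite. This keeps the package importable and trainable on a bare
scientific-Python stack; it is not a general deep-learning framework.

## Training

* **Loss** — focal loss, mean of −α_y(1−p_y)^γ log p_y, γ = 2 and uniform α
  by default (γ = 0 reduces exactly to cross-entropy; probabilities are
  clamped at 1e-12). Down-weighting easy examples matters because normal
  beats dominate real arrhythmia data by orders of magnitude.
* **Balancing** — SMOTE on the training split only: every class is raised to
  the majority count by sampling x_i + u(x_nn − x_i), u ~ U(0,1), from the
  k = 5 same-class nearest neighbours. Feature space is the flattened input
  tensor. A singleton class raises an error suggesting duplication instead.
* **Optimizer** — RAdam at lr 3e-4 (default), cosine annealing with warm
  restarts (T₀ = 10, T_mult = 2) or exponential decay (γ = 0.98), batch 64.
* **Early stopping** — patience 15 on validation loss; the best-validation
  weights are restored, so the returned model never post-dates the best
  epoch.
* **Determinism** — a single integer seeds record synthesis, splits, SMOTE,
  initialisation, batch order and every dropout/stochastic-depth mask; two
  identically seeded runs reproduce losses and predictions exactly.

## Synthetic data

Beats are sums of Gaussian bumps (P, Q, R, S, T) with class-specific
morphology: S drops the P wave and arrives prematurely (preceding RR × 0.65
with a compensatory pause that preserves the mean rate); V has a ≥ 2×-wide,
high-amplitude QRS with discordant T and no P; F is the pointwise N/V
average; Q is a narrow pacer-like spike. Widths give a ~90 ms normal QRS,
which keeps ≥ 95 % of the beat's spectral energy below 15 Hz, as in adult
surface ECG. Records add baseline wander (0.1 mV at 0.33 Hz), powerline
interference (0.05 mV at 60 Hz) and white noise (0.02 mV s.d.) — enough that
the preprocessing visibly matters, while class identity survives.

The generator emulates beat-class morphology, premature timing and
stationary noise. It does **not** emulate rhythm disorders (AF), ectopy
coupling (bigeminy runs), electrode motion artifacts, inter-patient
morphology variation, or class co-occurrence within a record (study records
are single-class). Passing the desk study therefore demonstrates that the
pipeline, transform, network and harness function and can learn
class-distinguishing time-frequency structure — not clinical-grade accuracy
on real Holter data.

## The desk-scale study

The end-to-end study (`stecg.workflow.run_desk_study`) simulates 50
single-class 50-s records per class of the four-class scheme (N, S, V, Q),
runs the full pipeline (1000 candidate segments, of which ~10-15 % fall to
IQR rejection),
splits 20 % held-out test and 20 % validation (stratified), balances with
SMOTE, trains and evaluates. Two scaling choices keep a run on one CPU core
at a few minutes while leaving every architectural element in place:

* the time-frequency tensors are **decimated** (strided subsampling) to a
  coarser grid before training. Decimation rather than averaging is
  deliberate: the real/imaginary channels oscillate at each voice's own
  frequency, so block-averaging along time acts as a low-pass on the phase
  carriers and erases exactly the high-band structure that separates subtle
  classes, while strided columns of the (heavily oversampled) S-transform
  keep it;
* the model is a reduced-width instance of the same architecture
  (`desk_config`: widths 8/16/32/64, cardinality 4, embedding 64, 4 heads,
  FFN 128; identical block structure, depth, SE, stochastic depth,
  positional encoding, global skip).

Batch size (64) and early-stopping patience (15) match the full-scale
protocol. The learning rate is raised above the full-scale default of 3e-4
to 1e-3, with at most 30 epochs: with ~10³ training segments instead of ~10⁶
the step budget shrinks by three orders of magnitude and the optimizer is
rescaled accordingly. The full-size configuration remains the package
default everywhere else. A run takes roughly three minutes on one CPU core
and reaches ≥ 0.95 validation accuracy by about epoch 13.

## Numerical conventions and edge rules

* Percentiles: numpy linear interpolation (documented so oracles match).
* Annotation index rescaling: round-half-even (numpy's `round`).
* Metric 0/0 cells (empty class rows/columns, degenerate MCC or kappa
  denominators) evaluate to 0, never NaN; affected classes are flagged in
  the report.
* `predict` breaks logit ties toward the lower class index.
* Min-Max of a constant segment: zeros plus a flag.
* WFDB I/O supports text headers, format-16 signals and MIT annotations;
  round-trips are exact up to the 16-bit gain quantisation (0.5/gain mV).

## Known limitations

* The numpy training kernel is single-core and ~10-100× slower than a GPU
  framework; full-size training on real PhysioNet corpora is supported by the
  code paths but not by this compute envelope.
* The S/N distinction in the synthetic study rests on a missing P wave and
  premature timing only — the hardest pair by construction, and the source
  of whatever residual confusion desk-scale runs show.
* Inter-patient splitting is available but the desk study splits by segment
  (synthetic records carry no patient identity).
* The 2-D form of the transform (for images) is not implemented; ECG is 1-D
  and the network consumes the single time-frequency plane.
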