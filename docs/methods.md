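# Methods

## Signal model and preprocessing

Uterine electrical activity recorded from abdominal surface electrodes
(electrohysterogram, EHG) carries its physiological content between roughly
0.1 and 3 Hz; everything outside that band is dominated by baseline drift,
maternal ECG and motion artifact.  Records are therefore band-passed with a
Butterworth filter (defaults: 0.1–3 Hz, order 4).  The filter is applied
forward–backward (`sosfiltfilt`), i.e. zero-phase: the entropy features
downstream are sensitive to waveform shape, and a causal pass would add
phase distortion that differs across the band.  Order and single-pass mode
are configurable; order 4 gives ≥ 40 dB attenuation one octave outside the
band while keeping the passband flat to within 5 %.

Analysis operates on fixed windows of 4096 samples (20.48 s at 200 Hz),
cut at explicit start indices.  Clinical practice locates contraction
bursts on a simultaneous tocogram; since that annotation cannot be
automated faithfully, segmentation is driven by caller-supplied indices,
with an optional heuristic (`suggest_burst_starts`) that proposes
non-overlapping windows whose channel-pooled RMS exceeds a multiple of the
median window RMS, taking windows greedily in order of decreasing RMS.  At
`threshold_factor = 0` the heuristic degenerates to the aligned maximal
tiling of the record.

## Wavelet subband decomposition

Each channel is decomposed with the orthonormal Haar (db1) analysis pair
`cA_k = (x_{2k} + x_{2k+1})/√2`, `cD_k = (x_{2k} − x_{2k+1})/√2`,
applied recursively to the approximation branch for J = 3 levels.  Each
level halves the effective sampling rate, so at 200 Hz the nominal bands
are D1 = 50–100 Hz, D2 = 25–50 Hz, D3 = 12.5–25 Hz, A3 = 0–12.5 Hz.  The
orthonormal normalisation conserves energy exactly and admits perfect
reconstruction; both properties are enforced by tests at 1e-8 / 1e-10.
Periodization is the default boundary mode (4096 = 2¹² makes every level
exact); zero-padding is available for non-dyadic lengths.  The transform is
implemented directly (it is two lines per level and the feature definition
depends on its exact normalisation); the test suite cross-checks it
coefficient-wise against PyWavelets.

Features use the raw coefficient vectors cD1, cD2, cD3, cA3, not the
reconstructed time-domain band signals; a `use_reconstructed_bands` switch
provides the alternative reading.  The two differ only in redundant
upsampling, and in relative-tolerance entropy mode the choice moves values
slightly but consistently for both classes.

## Sample entropy

`SampEn(m, r, N) = −ln(B^{m+1}/B^m)` with both template counts taken over
the first N − m vectors (the Richman–Moorman convention, making the ratio a
proper conditional probability), Chebyshev distance, self-matches excluded.
Defaults m = 2, r = 0.15 × SD of the series (relative mode), the prevailing
convention in the EHG-entropy literature; both are configurable and a
constant series returns exactly 0.  When no template pair matches at length
m or m + 1 the value is undefined; the function returns `+inf` with a
warning rather than raising, and the feature extractor replaces the
sentinel with a cap (default: the largest finite entropy in the vector —
an undefined entropy arises from extreme irregularity, so the cap keeps
the ordering sensible) so batch extraction never aborts.  A deliberately
unoptimised O(N²m) double-loop oracle ships alongside the production
implementation (numba-compiled counting loop, with an identical-count numpy
fallback); tests require exact agreement between the two.

## Feature vectors and normalisation

One segment yields 4 entropies per channel in fixed channel-major order
(`ch1_cD1, ch1_cD2, ch1_cD3, ch1_cA3, ch2_cD1, …`) — 64 features for 16
channels.  Feature tables are min–max scaled to [0, 1].  The scaling state
is learned on the training split only and applied with clipping to held-out
data; fitting on the pooled table before splitting ("global" mode) is
available but leaks test-set ranges into training and is not the default.
Constant features map to 0 instead of dividing by zero.

## Stacked sparse autoencoder

One sparse autoencoder: logistic encoder `Z = σ(W₁X + b₁)`, logistic
decoder `h = σ(W₂Z + b₂)` (sigmoid output matches the [0, 1] feature
range; squared-error reconstruction loss), objective

    J = (1/N) Σᵢ ½‖h(xᵢ) − xᵢ‖² + (λ/2)(‖W₁‖² + ‖W₂‖²) + β Σⱼ KL(ρ‖ρ̂ⱼ)

with ρ̂ⱼ the mean activation of hidden unit j and Bernoulli KL divergence
clamped to [1e-12, 1−1e-12].  Weights are untied.  Analytic gradients
(including the KL contribution to the hidden delta) are verified against
central differences to 1e-6 relative.

Architecture and regularisation defaults: 64→30→10 encoder, 2-way softmax,
ρ = 0.05, β = 8, λ = 0.001 for both layers.  Training is deterministic
given a seed: uniform Glorot-style initialisation, full-batch gradient
descent (the training sets here are a few hundred samples, where full-batch
is the stable special case of SGD), learning rate 0.1 for 400 pretraining
epochs per layer.  Layer 2 trains on layer 1's hidden activations (greedy
layer-wise pretraining); a softmax head is then fitted on the frozen top
representation and the entire network fine-tuned by cross-entropy gradient
descent (200 epochs).  A frozen-stack mode (no fine-tuning) is available.

The fine-tuning learning rate defaults to 0.5 rather than matching the
pretraining rate: with β = 8 the pretrained hidden units sit near ρ = 0.05,
deep in the flat region of the sigmoid, and supervised gradients through
them are small; 0.5 converges reliably across seeds on both toy and
full-size problems while remaining stable (training is full-batch and the
loss is monitored — divergence to NaN aborts with a diagnostic).  The cost
is not forced to be monotone; tests check trailing-window decrease.

Divergence of the pretraining objective raises immediately rather than
returning a silently broken model.

## Baselines

*ELM*: 20 sigmoid hidden units, input weights and biases uniform on [−1, 1]
(seeded), output weights the ridge-regularised (1e-8) least-squares
solution against one-hot targets — closed form, bitwise reproducible.
*SVM*: RBF kernel via scikit-learn, (C, γ) selected by stratified 5-fold
cross-validation on the training split over C ∈ {0.1, 1, 10, 100},
γ ∈ {0.01, 0.1, 1, 10}.  Both consume exactly the same normalised feature
tables as the SSAE.  The SVM optimiser is delegated to scikit-learn; it is
a baseline, not the package's contribution.

## Evaluation

Labor is the positive class: TP counts labor windows predicted labor.
Sensitivity, specificity and accuracy are computed with exact rational
arithmetic before conversion to float; a zero denominator yields NaN for
that metric.  The ROC curve sweeps the unique decision scores in descending
order with ties grouped, and AUC is the trapezoidal area — equal, by
construction, to P(score⁺ > score⁻) + ½P(tie), which the tests verify
against an explicit pairwise oracle.  The default experimental protocol is
a seeded per-class split of 100 training and 50 test windows per class.

## Synthetic data generator

Each channel of a generated segment is

    env(t) · [ Σ_b a_b sin(2πf_b t + φ) + c · AR(1) noise ] + sensor noise

where `env` is a raised-cosine burst (70 % of the window over a 0.2
baseline, shared across channels), the four tones sit at the centres of the
nominal subbands (70, 35, 17 Hz and 0.8 Hz — the last inside the 0.1–3 Hz
physiological band), the AR(1) coefficient controls noise smoothness, and
phases/noise are independent per channel.  Class profiles differ in
tone-to-noise ratio and AR smoothness; because the downstream features are
exactly subband entropies, this injects the class signal directly into the
measured quantity: the "pregnancy" profile (AR 0.95, strong tones, low
sensor noise) is regular — low entropy in every band — while "labor"
(AR 0.5, weak tones, more noise) is rough.  Three stock configurations:

* `separable` — the default study conditions (all 64 features separate the
  classes by many standard errors; the pipeline should be near-perfect);
* `hard` — overlapping profiles (AR 0.78 vs 0.75, tone amplitudes 10 %
  apart) giving non-trivial error rates and ROC shapes;
* `identical` — both classes share one profile; any classifier must sit at
  chance, which the tests use as a leakage control.

What the generator does **not** emulate: physiological burst-shape
variability, electrode crosstalk and spatial correlation across the 4×4
grid, maternal ECG and motion artifact, non-stationarity within a window,
and class overlap structure of real pregnancy/labor recordings.  Passing
the synthetic benchmark therefore demonstrates that the pipeline recovers
subband-complexity class differences when they exist — not any particular
clinical accuracy.  Sample sizes mirror the study conditions: 150 segments
per class, 100/50 per-class train/test split.

## Numerical choices and degenerate inputs

* Zero-variance series: relative-mode SampEn returns 0 directly.
* KL arguments and softmax logits are clamped/shifted against overflow; the
  sigmoid uses the piecewise-stable form.
* Constant feature columns normalise to 0; out-of-range test values clip.
* Model bundles serialise to JSON with full float64 round-trip, so a reload
  reproduces predictions bitwise; CSV I/O uses 17-significant-digit output
  and round-trip parsing for the same reason.
* Provenance files record config hash, seed and package version — no
  timestamps — so identical runs are byte-identical.

## Known limitations

* Only the Haar wavelet is implemented; the feature definition is tied to
  its orthonormal form.
* The SSAE trainer is plain full-batch gradient descent — adequate at a few
  hundred samples, slow beyond that; no minibatching or momentum.
* The stack is configurable beyond two layers but untested there.
* The WFDB reader requires the optional `wfdb` package and real recordings;
  all bundled workflows use CSV.
* Undefined-entropy capping is a heuristic; on very short subbands (e.g.
  64 coefficients) it fires noticeably more often than at full window
  length.
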