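# Methods

## Problem and pipeline

The package classifies 30 s epochs of single-channel ballistocardiogram
(BCG) signal, sampled at 100 Hz, into healthy-control (HC) and
hypertensive (HPT) classes. The pipeline is: per-recording z-score
normalization → 30 s segmentation → generalized Morse wavelet CWT
scalogram (224×224 → 32×32 grayscale) → 24-layer 2D CNN → hold-out and
k-fold evaluation with the standard binary diagnostic metrics (HPT
positive).

## Synthetic BCG generator

The generator exists because clinical smart-mattress recordings cannot be
shipped. It emulates the statistical and morphological structure the
classifier relies on, not the hemodynamics that produce it.

**Beat model.** One beat is a sum of Gaussian bumps, one per lettered
deflection, `a·exp(−(t−latency)²/(2·width²))`. Defaults (latency s,
amplitude a.u., width s): G(0.10, −0.20, 0.015), H(0.17, +0.50, 0.018),
I(0.22, −0.60, 0.018), J(0.28, +1.00, 0.020), K(0.35, −0.50, 0.025),
L(0.45, +0.25, 0.030), M(0.52, −0.15, 0.030), N(0.60, +0.12, 0.030).
These reproduce the canonical shape — small pre-systolic G dip, H–I–J
systolic complex with dominant headward J, K trough, decaying diastolic
L/M/N ripple — and are fully overridable. Construction enforces the
invariants: latencies strictly increasing in G<H<I<J<K<L<M<N order,
headward waves (H, J, L, N) positive, footward (G, I, K, M) negative, |J|
maximal.

**Recording model.** Beats are placed at onsets separated by
`Normal(60/hr_mean, 60·hr_sd/hr_mean²)` seconds (the delta-method
conversion of a beats/min spread to seconds; draws are floored at 30% of
the mean interval to keep the train physical). The beat train is
multiplied by `1 + resp_depth·sin(2π·resp_freq·t)` and white Gaussian
noise is added. Defaults: hr_mean 70 bpm and hr_sd 3 bpm (resting adult
heart rate and a normal short-term variability), resp_freq 0.25 Hz with
depth 0.2 (15 breaths/min, moderate baseline modulation as seen in
mattress BCG), noise_sd 0.1 (a tenth of the J amplitude — visibly noisy
but far from masking the beat).

**HPT class.** Hypertension alters BCG morphology in ways no public
quantitative model captures; the generator expresses the class through
exactly two documented knobs, chosen to mirror the qualitative
description of hypertensive traces (abrupt amplitude rises/falls, fast
timing variations): each beat's amplitude is doubled
(`hpt_amp_jump_scale` 2.0) with per-beat probability 0.3, and the
inter-beat-interval spread is doubled (`hpt_hr_sd_scale` 2.0). With ~35
beats per 30 s epoch, essentially every HPT epoch contains several jumps,
so the classes are separable by construction — the end-to-end tests
verify that the pipeline *recovers* this built-in structure, which is a
correctness check on the software, not evidence about clinical data.
Real BCG additionally contains motion artifacts, posture-dependent
morphology changes, sensor transfer functions and between-subject
variability that the generator does not model; accuracy numbers on
synthetic data therefore do not transfer to the clinic.

A consequence of whole-recording normalization worth knowing: amplitude
jumps inflate a recording's global σ, so after z-scoring the *bulk* of an
HPT epoch is compressed and its inter-quartile range is systematically
*smaller* than an HC epoch's. The label signal is strong (an
orientation-free IQR threshold alone separates the default classes) but
its sign is the opposite of naive intuition.

## Normalization and segmentation

z-scoring uses the sample (n−1) standard deviation by default (`ddof`
configurable) and is applied to the full recording before segmentation.
Constant or near-empty signals raise a degenerate-signal error rather
than returning NaNs. Segmentation takes `floor(n/(30·fs))` epochs with
stride equal to the epoch length; the trailing partial epoch is dropped.

## Scalograms

The analytic generalized Morse wavelet is defined in the frequency
domain, `Ψ(ω) = 2·H(ω)·(ω/ω_p)^β·exp((β/γ)(1 − (ω/ω_p)^γ))` with
`β = P²/γ` and peak angular frequency `ω_p = (β/γ)^{1/γ}`; defaults
(γ, P²) = (3, 60), peak-normalized to 2. Scales form a geometric grid
from fmax = 50 Hz down to fmin = 0.5 Hz at ratio `2^{−1/12}` (12 voices
per octave, 80 scales) — the cardiac/BCG band inside Nyquist at 100 Hz.
The transform is FFT circular convolution per scale; the Morse filter is
identically zero at ω ≤ 0, so the epoch mean is annihilated and the cone
of influence is left unmasked. An O(N²) brute-force oracle (explicit DFT
sums plus explicit circular convolution) pins the FFT path to < 1e−6
relative error away from the 10% boundary margins.

Rendering: `log1p` compression (preserves low-magnitude structure),
bilinear resampling to 224×224, then min–max scaling to [0, 255]. Because
bilinear resampling commutes with affine rescaling, normalizing after the
resample yields the same image while guaranteeing the full 8-bit range is
used; a constant magnitude maps to an all-zero image by convention.
Row 0 is the highest frequency. The 224×224 image is bilinearly resized
to the 32×32 network input. Magnitude is rendered directly to grayscale —
deterministic and colormap-free; a jet-colormap + luminance conversion
path was considered and rejected as the default because it adds an
arbitrary colormap dependency without changing the information content.

## The classifier

24 layers, in order: conv(64,k3,s2) · pool · BN · drop(.25) ·
conv(64,k5,s2) · pool · BN · drop(.25) · conv(128,k7,s2) · BN · drop(.25)
· conv(128,k7,s2) · pool · drop(.25) · conv(256,k3,s2) · conv(256,k3,s2)
· pool · conv(64,k3,s2) · conv(64,k5,s2) · pool · flatten ·
dense(128,ReLU) · drop(.5) · dense(2,sigmoid). All convolutions use
"same" padding and ReLU; max-pool layers are size 1 / stride 1 (spatial
identities — kept because the architecture specifies them; pool size is
overridable). All conv/dense kernels carry L1(0.001). With a 32×32 input
the spatial side after each conv is 16, 8, 4, 2, 1, 1, 1, 1.

The final layer is a 2-unit *sigmoid* (not softmax) trained with binary
cross-entropy against one-hot targets; prediction is argmax with exact
ties resolving to HC. Optimizer is Adam (lr 0.001); "decay 0.01" is
implemented as the classical schedule `lr/(1 + 0.01·epochs_completed)`.
Inputs are scaled to [0, 1] by dividing by 255.

The network is implemented directly in numpy: im2col convolution with
hand-derived backward passes, verified against central finite differences
to ~1e−9 relative error. Two numerical choices matter at small scale:

- **Batch-norm inference statistics** are bias-corrected exponential
  moving averages (the stored EMA is divided by `1 − 0.99^t`). A plain
  0.99-momentum EMA needs thousands of updates to forget its (0, 1)
  initialization, which silently breaks inference for short training
  runs; the debiased form is asymptotically identical and exact from the
  first step.
- **Regularization scale.** L1 = 0.001 with Adam lr 0.001 is calibrated
  for training sets of ~10⁵ images (~10³ updates per epoch). On a few
  hundred images the constant `l1·sign(w)` pull drives the kernels of the
  un-batchnormed convolutions to zero within ~40 Adam steps, after which
  the ReLU stack is permanently silent. `small_sample_hyperparams()`
  (batch 32, L1 off, 10 epochs) is the supported protocol for datasets of
  a few hundred epochs and is what the end-to-end tests and examples use;
  `Hyperparams()` keeps the full-scale defaults (batch 100, L1 0.001,
  50 epochs).

## Evaluation protocol

Hold-out: seeded shuffle, 80/10/10 by rounded fractions. The split unit
defaults to the epoch level, which matches segment-count bookkeeping but
leaks subject identity between partitions; `unit="subject"` groups all of
a subject's epochs into one partition and is the recommendation for any
real-data use. k-fold CV uses seeded near-equal folds (sizes differ by at
most one), a freshly initialized model per fold (fold-derived seed), 1/9
of the training portion carved out as validation, and reports per-fold
metrics, their unweighted mean ± sd, and the pooled confusion matrix
(each instance tested exactly once).

Metrics: accuracy (tp+tn)/n, sensitivity tp/(tp+fn), specificity
tn/(tn+fp), precision tp/(tp+fp), F1 = 2PR/(P+R). Zero-denominator
ratios are reported as NaN with a warning, never silently as 0. Values
are kept at four decimals internally; summaries print percentages to two
decimals.

## Problem sizes used by the test suite

The end-to-end checks run on 100 subjects × 2 min (400 epochs, 320
training images, 10 training epochs of the small-sample protocol), a size
at which the pipeline's statistical properties are already
unambiguous: hold-out recovery of the separable classes, a permuted-label
chance floor inside [0.40, 0.60], and bitwise seed determinism at every
stage. The oracle-equivalence check uses 256-sample signals where the
O(N²) reference is exact and cheap.

## Known limitations

- The generator is phenomenological; it makes no claim about recoil-force
  physics, sensor coupling, or how hypertension actually reshapes BCG
  morphology beyond the two documented knobs.
- Pixel-exact reproduction of any particular scalogram rendering
  (colormap, interpolation kernel, display scaling) is not attempted;
  only the information-preserving steps are specified.
- The epoch-level default split overstates performance whenever multiple
  epochs share a subject; use subject-level splits for honest estimates
  on real recordings.
- The numpy trainer is single-threaded BLAS-bound; it is sized for
  hundreds-to-thousands of 32×32 images, not for 10⁵-image clinical
  corpora.
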