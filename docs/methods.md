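# Methods

This note documents the models, procedures and numerical choices behind
`ppgdenoise`: the synthetic PPG generator, the noise-corruption framework,
the classical baselines, the reference-based neural denoiser, and the
evaluation protocol.

## Signal model and preprocessing

All processing operates on fixed-length segments of a single-channel PPG
signal. The preprocessing chain is: band-limited resampling to a common rate
(default 50 Hz), segmentation into non-overlapping 6 s windows (300 samples
at 50 Hz; a trailing remainder shorter than one window is dropped), and
per-segment affine min–max normalization to `[-1, 1]`. Resampling uses
polyphase filtering when the rate ratio is rational with a small denominator
and FFT resampling otherwise; linear interpolation is deliberately not used
here because it attenuates in-band content. Normalization is per segment, so
every segment attains both endpoints exactly; constant segments are rejected
rather than mapped arbitrarily.

### Synthetic PPG generator

The generator emulates the morphology that matters for denoising: a
quasi-periodic pulse wave with a systolic peak and a dicrotic bump, beat-to-
beat period variability, and slow baseline wander. Per beat, two Gaussian
bumps are placed at 15% and 45% of the beat period with widths proportional
to the period; beat periods are i.i.d. around `60/HR` seconds with relative
standard deviation `hr_jitter` (truncated at ±50% so periods stay positive);
a sinusoid models respiratory drift. Defaults: heart rate 70 bpm, jitter
0.03, systolic/dicrotic amplitudes 1.0/0.35, widths 0.10/0.14 of the period,
wander amplitude 0.15 at 0.25 Hz. The evaluation helper
`evaluate.make_clean_segments` varies the heart rate ±10% across batches so
a segment pool is not a single morphology.

What the generator does **not** emulate: sensor-specific pulse shapes,
perfusion and SpO2 effects, arrhythmias, and the slow amplitude modulation of
real recordings. Tests passing on this generator therefore demonstrate the
correctness and the directional behaviour of the pipeline, not clinical
performance on recorded data.

The generator is a pure function of `(params, n_seconds, fs)`: beats are laid
down from two periods before the window to two periods after it, so a
jitter-free configuration is exactly periodic in the interior (verified to
1e-9 in the tests).

## Noise-corruption framework

Corruption happens in unit space: the clean `[-1, 1]` segment is mapped by
the fixed affine `x -> (x+1)/2`, the noise stages are applied in order, the
result is clipped to `[0, 1]` and mapped back by `x -> 2x-1`. Fixed maps
(not per-segment min–max) keep the clean and noisy segments comparable
sample by sample, which every metric depends on.

Five single-noise generators, with defaults chosen as the study conditions:

| kind        | model                                   | default |
|-------------|------------------------------------------|---------|
| gaussian    | `y = x + N(0, σ²)`                      | σ = 0.01 |
| poisson     | `y = Poisson(x·scale)/scale`            | scale = 255 |
| salt_pepper | `round(rate·L)` samples forced to 0 or 1 | rate = 0.05 |
| speckle     | `y = x·(1 + N(0, σ²))`                  | σ = 0.01 |
| uniform     | `y = x + U[lo, hi]`                     | lo = 0, hi = 0.1 |

Choices where a convention had to be fixed: speckle is multiplicative (the
standard definition); Poisson uses the image-processing intensity scale of
255; salt-and-pepper replaces an *exact* count of positions (sampled without
replacement, salt and pepper equiprobable) so a 5% rate is exact per segment
rather than a Bernoulli expectation. All generators clip to `[0, 1]` and are
the identity at their null parameter (σ = 0, rate = 0, lo = hi = 0).

Mixed noise draws `k ∈ [2, 5]` distinct kinds uniformly without replacement,
applies them in the drawn order with default parameters, and derives each
stage's seed from the chain's master seed by a splitmix64 step (golden-ratio
increment followed by the splitmix64 finalizer, reduced below 2³¹). Chains
serialize to JSON and reproduce their noisy output bit for bit.

Motion artifacts are synthesized, not recorded: a Gaussian random walk
(integrated white noise, matching the low-frequency emphasis of limb
movement) is band-pass filtered to 0.5–5 Hz with a zero-phase 4th-order
Butterworth filter and min–max normalized to `[-1, 1]`. Injection blends the
artifact into a window of `round(ratio·L)` samples additively in unit space
(the artifact is halved so its swing matches the unit-space half-range),
clipping as usual; samples outside the window pass through unchanged. The
additive reading was chosen over replacement because a blended segment
retains the underlying pulse, which is what distinguishes an artifact from a
dropout.

## Classical baselines

Wavelet shrinkage: multi-level DWT with symmetric boundary extension,
soft thresholding of all detail bands at the universal threshold
`σ̂·sqrt(2·ln N)` with `σ̂ = MAD(finest details)/0.6745`, reconstruction,
and truncation to the input length. Decomposition levels beyond the nominal
maximum for a 300-sample segment (the Symlet-15 configuration uses level 9)
are honoured through boundary extension rather than rejected. The per-noise
wavelet table benchmarked is: discrete Meyer level 3 (gaussian), Daubechies
19 level 3 (poisson), Daubechies 18 level 6 (salt-and-pepper), Daubechies 20
level 3 (speckle), Symlet 15 level 9 (uniform).

One numerical caveat, verified empirically: the discrete Meyer wavelet is a
62-tap FIR truncation of the (infinitely supported) Meyer filter and is only
approximately orthogonal, so analysis/synthesis has an inherent error floor
of order 1e-2 regardless of boundary mode. The Daubechies and Symlet filters
reconstruct to ~1e-12.

Sliding filters, each with edge replication: median (odd window), a
local-statistics Wiener filter (`y = m + max(v-ν, 0)/max(v, ν)·(x-m)` with
local mean `m`, local variance `v`, and noise power `ν` estimated as the
segment mean of `v`), and Gaussian smoothing with a normalized kernel
truncated at 4σ. The best-filter-per-noise table is: Wiener window 5
(gaussian), median window 3 (poisson), median window 5 (salt-and-pepper),
Wiener window 3 (speckle), Gaussian σ = 1 (uniform).

## The neural denoiser

The denoiser treats noise removal as reference-based signal restoration, in
the style of texture-transformer super-resolution, mapped to 1D. Four
aligned inputs are prepared from the noisy segment and a clean reference
segment: the noisy segment itself, the reference, the reference after a
down/up-sampling round trip at `scale_factor` (default 4, stride
decimation + linear interpolation), and the noisy segment after the same
round trip. The round trip puts the query and key textures in the same
degraded domain, which is what makes their patch similarities meaningful.

A single convolutional texture encoder (shared weights) produces features
`Q` (degraded noisy), `K` (degraded reference) and `V` (original reference).
Overlapping feature patches (length 3, stride 1, spanning all channels) of
`Q` and `K` are compared by normalized inner products — the relevance
matrix, entries in `[-1, 1]`. Per query patch, the hard attention map `H` is
the row argmax (ties break to the lowest index) and the soft attention map
`S` the score at that index. `V`-patches gathered by `H` are folded back to
signal geometry by overlap averaging (`T`), and the patch scores are folded
the same way into a per-sample gate. Fusion is residual and gated:
`F' = F + conv(concat(F, T)) ⊙ S`, with `F` the backbone features of the
noisy input; a two-layer decoder maps `F'` to the restored signal, clamped
to `[-1, 1]`. A zero gate provably reduces the network to its backbone-only
reconstruction (tested).

The network is built on a compact in-package reverse-mode autodiff engine
over float64 numpy arrays (convolution via im2col, unfold/fold with
scatter-add adjoints, index gathers with argmax treated as a constant).
Analytic gradients are verified against central differences through the full
forward pass — including the normalized-inner-product attention path — to
1e-3 relative error. Everything is single-threaded float64, so training and
inference are bitwise reproducible given the seeds.

Default architecture: 16 channels, 3 convolution layers (kernel 3) in both
encoder and backbone, one fusion convolution, two decoder layers — about
5,600 parameters, deliberately small enough that the test suite trains
models in seconds to minutes on one CPU core. Training minimizes the mean
absolute reconstruction error (L1) with Adam (default learning rate 2e-3,
bias-corrected moments); the adversarial/perceptual losses of the 2D
super-resolution ancestor are omitted as extension hooks. References are
always clean segments drawn from a pool disjoint from the training targets —
never the example's own ground truth — mirroring a split into input,
reference and test pools.

Problem sizes used by the shipped experiments: 256 training pairs, batch 16,
10–12 epochs for the generalization runs; 300 full-batch iterations for the
single-pair capacity check. At these sizes a training run completes in about
a minute on one core while still clearing the behavioural bars (held-out
PSNR far above the noisy input; single-pair overfit beyond 30 dB).

## Evaluation protocol

MSE is the plain mean of squared differences; PSNR is `-10·log10(MSE)` dB,
taking the signal peak as 1 for `[-1, 1]`-normalized segments (base 10 is
the dB convention and the only reading consistent with PSNR/MSE tables of
this magnitude). Identical segments give MSE 0; PSNR then reports `+inf`,
which aggregation excludes from means with a logged warning.

Aggregate PSNR is the arithmetic mean of per-segment PSNRs, not the PSNR of
the mean MSE; published tables of this kind are consistent only with
per-segment averaging (the two differ by a Jensen gap). Method comparisons
use the two-sided paired t-test on per-segment PSNRs; all-zero differences
report t = 0, p = 1, and no multiple-comparison correction is applied (the
comparisons are reported raw, as is conventional for this protocol — flagged
here deliberately).

The experiment runner (`evaluate.run_experiment`) generates a seeded clean
pool, corrupts it per condition (`none`, `single:<kind>`, `mix:<k>`,
`motion:<ratio>`), applies each method, and emits per-segment records plus a
(condition, method) summary table; both are reproducible at the CSV byte
level under a fixed seed.

## Known limitations

- The synthetic generator and artifact process are stand-ins; absolute PSNR
  levels on them differ from any recorded corpus (directional orderings are
  what the tests assert).
- The discrete Meyer configuration carries the FIR-approximation floor noted
  above.
- The neural denoiser is sized for CPU training; scaling behaviour at larger
  widths/depths is untested here.
- The default noise magnitudes (σ = 0.01 etc.) are configuration knobs;
  unit-space σ = 0.01 is small relative to a unit-range pulse, so the
  Gaussian condition is a mild corruption at these defaults.
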