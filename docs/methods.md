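# Methods

`tfrinfo` scores how much *class information* a time-frequency
representation (TFR) of single-trial neural signals carries, and localizes
which time-frequency components carry it.  The pipeline is: synthesize (or
read) trial-segmented signals → compute a TFR per trial with one of four
estimators → resample, tile, and linearize the grids into fixed-length
feature vectors → measure class information with a repeated-split MLP
classification protocol → attribute it to tiles with correlated-feature
permutation importance.

## Time-frequency estimators

All estimators return a real frequency × time matrix with explicit,
uniformly spaced axes.

**Spectrogram (STFT).**  Squared magnitude of windowed Fourier transforms.
Defaults: 250 ms Blackman window, zero-padded to a 2 s DFT (0.5 Hz bins),
1 ms hop.  The window length fixes one time/frequency trade-off for all
frequencies.

**Morlet CWT.**  `CWT(t, f) = 2 |(ψ_{f,c} ∗ x)(t)|²` with
`ψ_{f,c}(t) = (B_c √(2π))⁻¹ exp(−t²/2B_c²) exp(j2πft)` and
`B_c = c/(5f)`; default `c = 3`.  The kernel is truncated where its
envelope falls below 10⁻⁶ of peak and convolved by FFT with zero padding;
discrete convolutions carry a `1/fs` weight so values approximate the
continuous integral.  The printed wavelet has no zero-mean correction
term; for `c ≥ 2` the DC leakage is negligible and it is implemented as
written.

**Superlet (SLT).**  Geometric mean of `o` Morlet CWTs per frequency,
`SLT = (∏ᵢ CWT(cᵢ))^(1/o)`, computed in log space so exact zeros are
preserved.  The cycle progression is multiplicative, `cᵢ = i·c₁`
(additive `cᵢ = c₁ + (i−1)` available); the two canonical settings are
`c₁ = 2, o = 5` (short temporal footprint) and `c₁ = 3, o = 10` (sharp
frequency concentration, the default).  Short wavelets suppress responses
outside a burst's time span, long ones outside its frequency band; their
geometric mean localizes jointly better than any single cycle setting.

**Wigner-Ville (WVD) and Choi-Williams.**  Discrete pseudo-WVD of the
analytic signal (one-sided-spectrum Hilbert method): the instantaneous
autocorrelation `K[m, n] = z[n+m] z*[n−m]` is built over an odd rectangular
lag window (signal length, capped at 1023 lags) and Fourier-transformed
over the lag, giving frequency bins `fs/(2L)` apart.  The time marginal
`Σ_f W(t,f) Δf = |z(t)|²` holds exactly in this discretization.  The
Choi-Williams variant transports `K` to the ambiguity plane (doppler θ in
Hz, lag τ in s), weights it by `Φ(θ, τ) = exp(−(θτ)²/σ)` (default
`σ = 3`), and transforms back.  The kernel is 1 along both axes, so
auto-terms near the axes survive while cross-terms — which sit at large
`|θτ|` offsets between components — are attenuated; as `σ → ∞` the WVD is
recovered.  Grids are kept signed (a magnitude option exists at the CLI):
the signed values are what the distribution defines, and downstream
normalization does not require positivity.

Boundary handling everywhere is zero padding; each grid records a validity
mask marking bins at least half a kernel support away from the edges, used
by tests to exclude edge effects.  Frequency-range restriction for
WVD/Choi-Williams is applied after computation, because their frequency
binning is fixed by the sampling rate rather than requested.

## Feature extraction

Native grids are resampled by bicubic spline interpolation
(`RectBivariateSpline`, `kx = ky = 3`) onto a standard cell-centered grid —
1 ms × 0.5 Hz by default — over a per-protocol analysis window:

| protocol | time window | frequency window | tiles (time × freq) | D |
|---|---|---|---|---|
| RF | 0–3 s | 50–70 Hz | 30 × 20 | 600 |
| SRCS-1 | 0–4 s | 35–55 Hz | 40 × 20 | 800 |
| SRCS-2 | 0–4 s | 30–50 Hz | 40 × 20 | 800 |
| EEG | 0.3–1.0 s | 5–55 Hz | 14 × 25 | 350 |

The EEG window starts 300 ms post-stimulus to skip onset transients.  The
standard grid is averaged over the tile grid and linearized
frequency-major (low→high frequency; within a band, time low→high) — the
order the importance maps invert.  If a standard-grid axis is not
divisible by its tile count, a remainder smaller than one tile is trimmed
from the trailing edge; larger mismatches are errors (silent resampling
would distort tile geometry).

Dataset normalization: LFP-style features get one global affine min-max
map to `[−3.3823, +1.323]` (an arbitrary but fixed configuration constant,
kept configurable); EEG-style features are z-scored per sample.

## Classifier and training

A fixed two-hidden-layer MLP: hidden sizes are 20% and 10% of the input
size (round half up, minimum 1), softmax output.  Hidden units use the
Soft++ activation `f(x) = ln(1 + e^{kx}) + x/c − ln 2` (`k = 1`,
`c = 30`), computed in log-sum-exp form; its derivative
`k·σ(kx) + 1/c ≥ 1/c` never vanishes, so gradient signs stay informative.
Weights are LeCun-normal (`std = 1/√fan_in`) resampled until inside the
configured range (`±0.1` LFP-style, `±0.01` EEG-style); biases start at 0.

Training is full-batch iRPROP+ for 1000 epochs on the mean squared error
between softmax outputs and one-hot targets (MSE rather than
cross-entropy because the importance analysis quantifies degradation as a
ΔMSE; cross-entropy is a configuration option away in principle but not
required by any analysis here).  Per-parameter step sizes start at
`0.001/fan_in`, grow ×1.05 on gradient-sign agreement (cap `Δmax`: 0.01
LFP, 0.001 EEG), shrink ×0.95 on a sign flip (floor `10⁻¹⁵`), and a
flipped parameter's previous update is reverted when the epoch error
increased.  Dropout (p = 0.1) is applied to hidden layers only, one fresh
mask per epoch (full-batch training has one step per epoch), with inverted
scaling at train time.

**Best-state selection.**  The saved "best network state" is the epoch
with the lowest validation MSE (ties: higher validation accuracy, then
earlier epoch).  Selecting on validation *accuracy* would take a maximum
over ~1000 noisy draws of a small-sample statistic; on a 32-sample
validation set this inflates the shuffled-label chance estimate from
~12.5% to ~20–28%, which is why the error function is the selection
criterion.  Both accuracy and MSE curves are recorded per epoch so either
choice can be audited.

## Evaluation protocol

Information content = mean best validation accuracy over `n_runs = 100`
repetitions (tests and the acceptance script run 25–50 and say so) of:
random 60/40 train/validation split (plain, not stratified — repetition,
not stratification, averages out biased sampling), fresh initialization,
full training.  Each run derives four independent RNG substreams (split,
label shuffle, init, dropout) from `(base_seed, run index)` via
`SeedSequence` spawning, so any single run is reproducible in isolation.
Chance level is the same protocol with labels permuted across the whole
dataset before splitting (preserving class priors); it converges to the
majority-class fraction — 12.5% for the balanced 8-class designs, 60% for
the 90/60 two-class design.  A `fixed_split` flag pins the run-0 split for
all runs, isolating initialization variability, and is used before
importance analysis.

## Permutation importance

Given a trained model and the validation split: the reference accuracy and
MSE are computed once on the intact set.  For each feature, its correlated
set `{j : |r(feature, j)| > 0.5}` (direct Pearson neighborhood on the
validation features, no transitive closure; constant features are assigned
correlation 0) is permuted jointly — one shared row permutation per
repetition, 10 repetitions — and the mean performance change recorded:
`ΔMSE = perturbed − reference` and `ΔPAcc = perturbed − reference`
accuracy.  Figures display `−ΔPAcc`, so informative tiles are positive and
*distractors* — features whose removal helps — are negative.  The
threshold applies to `|r|`: negatively correlated features are equally
redundant.  A threshold > 1 disables grouping (useful as a control).  The
model passed to this analysis is the best of 5 networks trained on one
fixed split, which is also how the pipeline stage selects the model it
explains.

## Synthetic data

Recorded LFP/EEG from the motivating experiments is not publicly
deposited, so a seeded generator emulates the three designs.  All
randomness flows through one `numpy` Generator; identical (spec, seed)
gives bit-identical data.

A *burst* is a cosine under a Gaussian envelope whose FWHM is
`n_cycles/center_freq` — "cycles" therefore means the same thing for
planted packets and analysis wavelets.  The *background* is 1/f^α colored
noise (α = 1, variance 0.1 by default) plus optional 5 ms white-noise
clicks (Poisson-scheduled, amplitude 5× the background SD) standing in for
broadband movement/electrical artifacts.

* `rf_like` (8 × 10 trials, 3 s, 1000 Hz): one 60 Hz burst per trial at
  latency `(k + 0.5)/8 · 3 s` for class `k` — classes separate purely in
  time, which is why every estimator classifies it near 100%.
* `srcs_like` (8 × 10 trials, 4 s): a burst train at the 1.75 cycles/s
  grating rate whose onset phase is `k/8` of the period.
* `eeg_like` (90 "seen" / 60 "nothing", 0.7 s from 0.3 s post-stimulus,
  1024 Hz): every trial carries a Poisson-mean-6 set of class-independent
  broadband distractor bursts (5–55 Hz) plus one burst in the effect band
  (default 8–15 Hz) whose power is `(1 + effect_size)` larger for "seen".
  The distractor bursts matter: per-sample z-scoring couples all features
  through the trial mean/SD, and without broadband variance the class
  contrast would relocate into the quiet high-frequency rows as a
  normalization echo rather than staying in the alpha band.

Default effect sizes are chosen so the qualitative phenomena are
reproducible, not to match any recorded accuracy: `effect_size = 1`
everywhere; the importance-localization analysis plants a strong narrow
effect (`effect_size = 5`, band 9.5–10.5 Hz), and the method-ordering
analysis uses weak bursts with heavy contamination (`effect_size = 0.2`,
8 clicks/s), where the spectrogram's 250 ms windows average the clicks
away while the short high-frequency wavelets of the CWT emphasize them.

What a green test does *not* establish: the generator has a single
channel, stationary 1/f noise, Gaussian-envelope bursts with independent
phases, and no eye/muscle artifacts, volume conduction, or
cross-frequency structure.  Absolute accuracies on it say nothing about
recorded data; only the dimensional contracts, the chance levels, and the
qualitative orderings/localizations are meaningful.

## Numerical notes and limitations

* Geometric means use log-space accumulation; any zero constituent makes
  the superlet value exactly 0.
* The iRPROP+ error comparison uses the dropout-noised epoch loss; with
  full-batch training this is the standard choice and converges in
  practice (XOR is solved in ≤1000 epochs for ≈100% of seeds).
* `ΔPAcc` on an `n`-sample validation set is quantized to `1/n`; with 10
  permutations its resolution is `1/(10n)`.  `ΔMSE` is the smoother
  measure.
* The discrete WVD/Choi-Williams cost is O(N·L) memory; trials much
  longer than ~4 s at 1 kHz get the lag cap (1023) rather than full lags.
* No reassignment/synchrosqueezing, no other RID kernels, no
  convolutional classifiers, no multi-channel fusion.
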