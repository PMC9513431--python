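# Methods

This note documents the models, algorithms and design choices behind
`fexbci`, module by module, including the places where the underlying
protocol leaves details open and what this package chose.

## Synthetic epoch generation

**Model.** An epoch is 4 s of 8-channel scalp potential in microvolts.
Each channel is synthesised in the frequency domain as band-limited pink
noise: complex Gaussian rFFT coefficients weighted 1/√f inside the
background band (default 1–45 Hz), scaled so a plain channel has 10 μV
RMS — the typical scalp EEG amplitude scale. Class structure is imposed
spectrally, through one of three signature families:

* **Boost** (`default_signatures`, gain 4 by default): each expression
  multiplies the power of designated (channel, band) pairs — mu-band on the
  contralateral prefrontal pair for the smirks, theta/beta on frontal
  midline channels for the brow movements. The cue is *where the power
  is*; any per-channel band-power feature can read it.
* **Shift** (`shift_signatures`): the same band boosts, but each affected
  channel is damped by 1/(1 + (g−1)·f_B) (f_B = fraction of background
  power in the boosted band, computed from the generator's own spectral
  weights), so total channel power is class-invariant. The cue is purely
  spectral *shape*.
* **Coupling** (`coupling_signatures`, strength 8 by default): two shared
  band-limited sources drive the channel pairs (FC5, F7) and (FC6, F8)
  with a class-specific polarity pattern (+,+)/(+,−)/(−,+)/(−,−). Marginal
  channel spectra are identical across classes by construction; the only
  class information is the *sign of the inter-channel correlation* — a
  synchrony cue, of the kind spatial convolution can read but per-channel
  summary features cannot.

Artifacts are additive and seeded: EOG as a common 0.3–2 Hz drift on the
prefrontal channels (peak amplitude, default tests use 100 μV), EMG as
independent 30–100 Hz noise on designated channels, and power-line hum as
a 50 Hz sinusoid with shared random phase. Because injection returns a new
epoch set, the caller retains clean ground truth for recovery scoring.

**What the generator does not emulate:** volume conduction and realistic
source mixing, inter-subject variability, nonstationarity within an epoch,
electrode artifacts, line-noise harmonics. Passing tests on this generator
therefore demonstrate that the pipeline's machinery behaves as specified
(filters filter, the GA optimises, cleaning removes what it is pointed at),
not that the same accuracies would be obtained on real recordings.

## Artifact removal

Stage one is a 5th-order Butterworth band-pass, 0.5–45 Hz, applied
zero-phase (forward–backward). The offline setting permits non-causal
filtering, and phase preservation matters for the later correlation-based
efficacy scoring; the effective magnitude response is the square of the
designed one.

Stage two is NA-MEMD + sample-entropy rejection, per epoch (classification
consumes 4 s epochs, so there is no benefit to continuous-time cleaning):

* **NA-MEMD.** Multivariate EMD sifts all channels jointly: the signal is
  projected onto direction vectors on the unit hypersphere (64 directions
  from a scrambled Halton sequence mapped through the inverse normal CDF),
  the extrema of each scalar projection define knots at which every channel
  is interpolated with natural cubic splines (series endpoints included as
  knots to tame boundary extrapolation), and the direction-averaged mean
  envelope is subtracted until the mode criterion is met. Sifting stops
  when the mean envelope magnitude falls below 0.075 of the current mode
  amplitude, or after 10 passes (reported via warning, never silent). Two
  independent white-noise channels at 10% of the mean channel SD are
  appended before sifting and discarded afterwards; their broadband
  structure stabilises the dyadic mode alignment. The residual is defined
  as input minus the sum of extracted IMFs, so completeness holds to
  floating-point accuracy by construction; the tests verify < 1e-8
  relative error explicitly. One known EMD artifact is visible in tests:
  a slow pure tone can split across two adjacent modes ("mode splitting"),
  so tone-recovery checks score the sum of the slow modes.
* **Sample entropy.** SampEn(m, r·sd) = −ln(A/B), with B the number of
  length-m template pairs within Chebyshev tolerance and A the pairs still
  matching at length m+1; self-matches excluded; only extendable templates
  counted; A = 0 or B = 0 returns +inf (maximally irregular sentinel);
  constant series fall back to an absolute tolerance r and give 0.
  Defaults m = 2, r = 0.2 — the field standard.
* **Rejection rule.** Each IMF is scored by channel-averaged sample
  entropy, computed on series decimated by 4 (at 1 kHz this is an
  effective 250 Hz scoring rate; band-passed content is far below the
  decimated Nyquist, and the O(T²) count becomes cheap), plus a dominant
  frequency from the mean zero-crossing rate. Flags: entropy > 0.75 →
  myogenic/noise-like; entropy < 0.2 *and* dominant frequency < 3 Hz →
  ocular/trend-like; the residual is treated as one more slow mode. The
  thresholds sit in the gaps of the entropy landscape of band-passed
  epochs at the 250 Hz scoring rate: modes carrying > 30 Hz content score
  above ≈ 0.8, rhythmic (theta–beta) modes at or below ≈ 0.7, slow ocular
  modes below ≈ 0.2. The slow-mode frequency gate is 3 Hz rather than a
  sub-1 Hz cutoff because ocular drift in the 0.3–2 Hz band produces modes
  with dominant frequencies up to ≈ 2.5 Hz. On contaminated synthetic
  epochs this rule raises the frontal-channel correlation to the clean
  ground truth from ≈ 0.3 to ≈ 0.7 (EOG) and cuts > 30 Hz power by more
  than an order of magnitude (EMG); both are recomputed by the tests and
  the acceptance script, never assumed.

## CNN classifier

The architecture is fixed up to the genome g = (k1, k2, k3, n1, n2):
three 3×3 same-padding stride-1 convolutions (so the 8-row channel axis
survives and adjacent-channel correlation stays visible), batch norm after
conv1 and conv2, ReLU throughout, one 2×2 max pool after conv3, then
FC(n1) → dropout(0.5) → FC(n2) → FC(4) → softmax. Training: batch 16,
learning rate 1e-3, categorical cross-entropy; the optimiser is Adam
(unstated in the protocol; standard for this family; SGD available). The
trainable-parameter count has the closed form documented in
`count_parameters`.

The implementation is plain numpy (float32) with hand-written
backpropagation and seeded He initialisation — deliberately
framework-free, so training is bit-reproducible under a seed on any
machine. Inference disables dropout and uses batch-norm running statistics;
probability rows are renormalised in float64.

**Normalisation.** Epochs are z-scored per epoch over all channels
jointly. Per-channel z-scoring was considered and rejected: it erases the
relative power between channels, which is exactly the topographic cue that
distinguishes the classes, and empirically leaves the network memorising
the training folds at chance-level generalisation. Global per-epoch
scaling removes inter-epoch gain drift while preserving the topography.

## Genetic algorithm

Genes are binary-coded with per-gene length l chosen as the smallest
integer with (u_max − u_min)/(2^l − 1) ≤ 1, giving 5 bits for each kernel
count and 9 bits for each layer width (33 bits total). Decoding is
u_min + round(raw·δ) with clamping, so any bit pattern yields a valid
genome and encode/decode round-trips exactly on every in-range integer
(verified exhaustively).

The loop is: evaluate (with caching by bit pattern — repeated genomes cost
nothing), roulette selection, multipoint crossover (2 cut points,
probability 0.8), per-bit mutation (0.03 ≈ 1/L), and single-individual
elitism, for 20 individuals × 20 generations at full scale.

**Selection scaling.** The roulette wheel itself is fitness-proportional,
P(i) = f_i / Σf. Applied to raw accuracies, which span a narrow band well
above zero, this gives nearly uniform selection and the search cannot
converge within a 400-evaluation budget (measured: 0/10 recovery of a
hidden 33-bit optimum on a surrogate landscape). `run_ga` therefore feeds
the wheel Boltzmann-scaled weights exp(β·(f − f_max)) with β = 80 — a
classical selection-scaling technique that preserves the wheel mechanism
while giving meaningful selection pressure (measured: 10/10 recovery
across three disjoint 10-seed sets). `selection_scaling="none"` restores
literal proportional selection.

Fitness is evaluated on a stratified 80/20 inner split of the training
data, never on the outer test folds (preventing selection-induced
leakage). A `fast` mode (subsampled training set, few epochs) exists for
smoke-scale runs and is labelled as the shortcut it is.

## Evaluation

Stratified k-fold cross-validation (k = 5, optionally repeated with fresh
shuffles; stratification guarantees every class in every training fold).
The protocol description is ambiguous between two and four repetitions;
`repeats` is a parameter with default 2. Metrics come from the pooled
confusion matrix: p0 = trace/N, pe = Σ_c row_c·col_c / N² — the multiclass
marginal-product form, which reduces exactly to the familiar TP/TN/FP/FN
expression for two classes — and κ = (p0 − pe)/(1 − pe), with the pe = 1
degenerate case reported as undefined-with-reason rather than NaN.
Per-fold accuracies, per-fold confusion matrices, and mean ± sd are
exposed alongside the pooled values. Method comparison uses paired
t-tests per pair and one-way ANOVA across methods, with zero-variance
degeneracies flagged, and no significance verdicts hard-coded.

## Baseline

Per channel, a level-5 db3 discrete wavelet decomposition with periodised
boundaries (orthogonal, so coefficient energy equals time-domain energy
exactly); energy and variance pooled over all subband coefficients give
2 × 8 = 16 features per epoch — pooling over subbands is forced by the
16-node input layer of the reference network. The classifier is a
one-hidden-layer (20 logistic units) back-propagation network trained by
SGD (learning rate 0.01, 500 epochs, standardised inputs), with 4 output
nodes. The reference description prints a two-node output layer, which
cannot express a 4-class decision; the width is configurable and defaults
to 4.

## Scales, runtimes, degenerate inputs

Two presets bracket the scale. `full` is the faithful protocol:
240 epochs of 8 × 4000 at 1 kHz, 100 training epochs, GA 20 × 20 with full
fitness — hours of CPU, intended for real runs. `smoke` is the
development/CI scale used by the test suite and the acceptance script:
240 epochs at 40 Hz (8 × 160), 20 training epochs, GA 6 × 3 with fast
fitness — minutes. Decomposition-related checks always run at the native
8 × 4000 size. All stages are seeded; every stage of a pipeline run is
recorded in a manifest (config hash, versions, timings, outputs) and
completed stages are skipped on resume.

The method-comparison conditions use the coupling signature family at
40 Hz deliberately: at smoke scale the CNN cannot win on amplitude-coded
classes (pooled band-energy features are a sufficient statistic there, and
the wavelet + BPNN baseline is near-ceiling), whereas synchrony-coded
classes are readable by 3×3 spatial kernels and invisible to per-channel
features. The regimes bracket the two failure modes and make the expected
ordering CNN-GA ≥ fixed CNN ≥ WT-BPNN testable at desk scale; magnitudes
on real recordings are outside what this synthetic study can show.

Degenerate inputs are handled explicitly throughout: zero-variance series
in sample entropy (absolute tolerance fallback), all-zero fitness vectors
(uniform selection, logged), pe = 1 kappa (undefined with reason),
monotone residuals in sifting (decomposition ends), failed fitness
evaluations (scored 0, recorded), degenerate epochs in cleaning (passed
through, flagged in diagnostics).

## Known limitations

* The synthetic generator's class signatures are stipulated, not estimated
  from real FE-BCI recordings; no claim about real-data accuracy follows
  from any number in this repository.
* NA-MEMD uses a scalar sifting criterion and fixed direction count;
  extremely short or near-monotone epochs yield few modes.
* The numpy CNN is CPU-bound; full GA runs (400 CNN trainings on
  8 × 4000 inputs) are feasible but slow by design, not optimised for
  throughput.
* Sample-entropy scoring decimates by 4 for tractability; for sampling
  rates below ≈ 100 Hz the decimation should be reduced accordingly.
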