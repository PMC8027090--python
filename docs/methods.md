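# Methods

This note documents the models, conventions and design choices behind
`mieeg`, in the order the pipeline runs.

## Synthetic ERD/ERS trials

**What is emulated.** A two-class (left vs right hand) motor-imagery
protocol recorded from the C3/C4 electrode pair: 7 s trials sampled at
100 Hz, an imagery window starting at 1.5 s and lasting 3.5 s, balanced
class counts.  Each channel is the sum of

* 1/f-shaped Gaussian background noise (spectrum flat below 1 Hz so the DC
  region stays bounded), parameterized by its RMS (`noise_amplitude`,
  default 1.0);
* a mu-band (8–12 Hz) and a beta-band (12–25 Hz) oscillation, each a
  band-limited process with unit RMS scaled by its base amplitude
  (defaults: mu 1.0, beta 0.7).

Inside the imagery window the mu amplitude of the channel contralateral to
the imagined hand is multiplied by `1 − erd_depth` (default 0.5) and the
beta amplitude of the ipsilateral channel by `1 + ers_gain` (default 0.5).
The contralateral mapping — C3 for right-hand, C4 for left-hand imagery —
follows standard 10–20 physiology.  Defaults correspond to roughly 0 dB
broadband SNR with a ~75% contralateral mu-power drop, deliberately on the
clean side of real recordings so that pipeline failures indicate code
defects rather than statistical noise.

**Oscillation synthesis.** Narrowband processes are 4th-order Butterworth
band-pass filtered white noise (zero-phase), normalized to unit RMS per
trial — filtered noise rather than pure sinusoids so CSP sees a realistic
variance structure.  A `sinusoid` mode (random-phase sinusoid at the band
centre, RMS-calibrated) is kept because its band power is known in closed
form and anchors the oracle tests.

**Envelope edges.** Amplitude modulation uses 0.1 s raised-cosine ramps
placed just *outside* the imagery window, so that inside the window the
modulation factor is exact (e.g. `erd_depth = 1` really zeroes in-window mu
power) while the signal remains continuous.

**What is not modelled.** Only two channels; no eye-blink/EMG artifacts,
no inter-trial nonstationarity, no inter-subject variability, no volume
conduction between channels.  Passing tests therefore demonstrate pipeline
correctness and sensitivity, not expected accuracy on real recordings —
real MI-BCI data are substantially harder.

## Time–frequency front ends

**STFT.** Frame k is centred at sample `k · hop` (hop 10), windowed with a
symmetric Hamming window of 0.5 s (50 samples), zero-padded at the signal
edges and to a DFT length of 64, giving 33 one-sided bins; a 3.5 s segment
at 100 Hz yields 35 frames, i.e. the canonical 33 × 35 × 2 tensor
(axes frequency × time × channel).  Magnitude (not power or complex)
spectrograms are returned.  Centred frames with edge zero-padding are the
one convention that reproduces that printed shape, and they are frozen here
as the package's canonical layout.

**Morlet CWT.** The mother wavelet is the real, even function
ψ(x) = e^(−x²) cos(ω₀x) with ω₀ = π√(2/ln 2) ≈ 5.336 rad/s.  The transform
is computed on the sample grid, W(a, b) = Σₙ x[n] ψ((n−b)/a)/√a, with one
shift per sample, via FFT convolution with the full-support kernel so it
equals the literal double sum to round-off.  The scalogram time axis equals
the input length (700 samples for a 7 s trial); 35 log-spaced scales cover
pseudo-frequencies 4–40 Hz through a = ω₀ fs / (2π f).

**Wavelet moments.** Centre time and time span are first and second moments
of |ψ(t)|² by trapezoidal quadrature (the span is the RMS spread, so a pure
Gaussian e^(−x²) has span 0.5); centre frequency and bandwidth are the
analogous moments of |Ψ(ω)|² restricted to ω ∈ [0, ∞).  For a real wavelet
the spectrum is even, so the two-sided first moment is identically zero and
the one-sided domain is the only definition that yields a meaningful centre
frequency (~ω₀ for this wavelet, since its spectrum is a Gaussian centred
on the cosine frequency).

## CSP

Per band (mu and beta by default): each trial is zero-phase band-pass
filtered, its spatial covariance XXᵀ is trace-normalized and averaged per
class, and the generalized eigenproblem C₁w = λ(C₁+C₂)w is solved with a
1e-8 ridge on the composite matrix.  Eigenvectors come scaled so that
W(C₁+C₂)Wᵀ = I; the m largest-λ and m smallest-λ filters are kept
(with two channels m = 1 is forced, so N = 4 over the two bands).  Features
are log of each projection's variance normalized by the within-band total
(standard log-variance CSP practice), with a 1e-12 floor inside the log
guarding zero-variance projections.  In the pipeline, CSP is fitted on the
training partition only and applied to both partitions, avoiding
information leakage into validation metrics; trials are cropped to the
imagery window before covariance estimation, since that is where the class
signal lives.

## The 1-D CNN

**Architecture.** I1(1×N) − C2 − C3 − F4 − O5.  Convolutions are valid
(no padding) 1-D cross-correlations summed over input depth with ReLU;
F4 is a tanh dense layer; O5 is a 2-class softmax.  The loss is the sum of
squared errors between softmax outputs and one-hot targets (a
cross-entropy-free choice kept deliberately; the softmax Jacobian is
handled explicitly in the output delta).  Defaults for the CSP path
(N = 4): 8 kernels of length 2, then 16 kernels of length 2, dense width
32.  Kernel length 2 is the longest that leaves valid outputs at N = 4
through two conv layers.  Pooling (max and average, with the argmax-routing
and even-split backward rules respectively, ties to the lowest index) is
implemented and tested but disabled by default — with inputs this short
there is nothing to downsample.

**Initialization.** Conv kernels ~ Uniform(−0.3, 0.3); dense weights
~ Normal(0, 0.1) truncated (by resampling) to the same interval — both
stated initializer families are honoured, each in its own layer class; all
biases are the constant 0.1.

**Training.** Plain mini-batch gradient descent (no momentum or adaptive
optimizers), batch 64, gradients averaged over the batch.  The learning
rate at global iteration i is `lr_end + (lr_start − lr_end)·e^(−i/1000)`
with endpoints 0.02 and 0.0002 — the interpolated-exponential form that
matches both endpoints.  Inverted dropout (rate 0.5) is applied at F4
during training only, so inference needs no rescaling.  All randomness
(init, shuffling, dropout) flows from a single seed; runs are bit-
reproducible.

**Gradient correctness.** The contract for the whole backward pass is the
finite-difference check: on random small architectures every analytic
gradient matches central differences with relative error below 1e-5
(entries whose absolute discrepancy is below ~1e-9 are accepted outright,
since at step h = 1e-6 the central difference itself carries that much
round-off).

## Evaluation

Stratified 8:2 splits use largest-remainder rounding so totals are exact
(8,600 → 6,880/1,720).  The positive class is left-hand imagery (code 0).
Precision is also reported under the name "discrimination", as some BCI
evaluation tables label that column.  AUC is the Mann–Whitney concordance
probability of the predicted positive-class probability, ties counted ½;
the test suite cross-checks the whole metric suite against scikit-learn to
1e-10.  The kernel-size sweep retrains the same seed per first-layer kernel
length and reports validation accuracy (invalid lengths are recorded as
missing).  The time-segment analysis slices trials into [0, 2), [2, 4) and
[4, 6) s **from trial start** and runs the full pipeline per slice; with a
1.5 s imagery onset a window anchored at the onset would overrun a 7 s
trial, and the 0–6 s framing matches the protocol timeline.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale versions of each experiment:
200 trials/class for the main training run (8,000 iterations at batch 64),
1,000 trials/class for the chance-level control (400 validation trials,
so the [0.4, 0.6] band sits ~4 binomial SDs wide), shorter runs (a few
hundred iterations) for sweeps and segment analyses.  These sizes make the
statistical assertions sharp while keeping any single test in seconds.
Argmax ties (prediction and max pooling) resolve to the lowest index.
Degenerate inputs are rejected early with named errors: bands outside the
Nyquist range, imagery windows outside the trial, kernels longer than their
input, single-class evaluation sets (AUC undefined).

## Known limitations

* The simulator's class signal is stationary within the imagery window and
  identical in distribution across trials; accuracies near 1.0 on defaults
  reflect that idealization.
* The CWT path produces large flattened inputs (35 × 700 × 2); the default
  CNN is sized for the CSP path, and tensor-path training is exercised only
  at smoke scale.
* Only binary classification is supported (the O5 head is 2-class by
  construction).
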