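# Methods

This note documents the signal model, the numerical conventions and the
design choices behind `emggate`, and states precisely what the synthetic
corpus does and does not establish.

## Signal chain

Raw signals are integer ADC counts at 10 kHz. The analog sensor front end
is emulated as a first-order bandpass (11–1064 Hz, bilinear-designed
Butterworth sections); decimation to 2 kHz is a plain 5-sample integer
average (the EMG band ends well below the post-decimation Nyquist rate).
Power-line interference is removed by an FIR comb `y_i = x_i − x_{i−fs/50}`
with zeros at 0, 50, 100, … Hz; the comb runs at 2 kHz (post-decimation).
A first-order lowpass at 531 Hz limits the band; the feature path adds a
second-order highpass at 60 Hz. The recursive filters are bilinear designs
with pre-warping at the cutoff and run in floating point; the feature input
is rounded to integer counts afterwards, because the features themselves
are integer state machines. A fixed-point realization of the first-order
lowpass (coefficients on a 2⁻¹⁶ grid, 64-bit intermediates) is exposed for
embedded parity checks but is not part of the default chain.

Filters start from zero state. Start-up transients are not handled
specially: the transition-tolerant evaluation absorbs them.

## Fixed-point contract

Every multiplicative constant is a dyadic rational `m/2^k` (k ≤ 8 for all
shipped coefficients) applied as a widening integer multiply followed by an
arithmetic right shift. Shifts floor toward −∞, matching two's-complement
hardware. `quantize_coeff` does an exhaustive search over `k ≤ k_max` and
breaks ties toward smaller shifts, so exact dyadic targets return in lowest
terms (0.9922 → 127/128, numerically identical to 254/256 — and
`(v·127)>>7 == (v·254)>>8` exactly).

Floor truncation has one important consequence: relative to an ideal
(untruncated) real-valued EMA, the integer EMA carries a deterministic
negative bias of roughly `0.5·b/(1−b)` counts — about 127 counts at
`b = 255/256` — because each step discards a fractional remainder that is
0.5 on average and the recursion amplifies it by the DC gain. For features
whose working values are tens of thousands (MAV1, VAR) the bias is
negligible (< 0.1 %); for features whose values are a few hundred (WFL) it
is tens of percent of the value. This is intrinsic to truncating
arithmetic, not an implementation artifact; the design reference of such a
system must model the truncation (as the fixed-point fidelity tests here
do for the quantization layers, and the bit-exact streamed-vs-batch tests
do for the feature recursions). The bias largely cancels downstream,
because min-max normalization is fitted on the same truncated values the
classifier later consumes.

Feature values are clamped into `[lb, ub]` after every update. The
parameter registry gives every variant an upper bound — `2^16−1` where no
tighter bound is printed — and the clamp doubles as overflow protection:
with the registry bounds no 32-bit quantity can overflow for inputs within
the 16-bit ADC range. The tight "S"-variant bounds serve a second purpose:
a feature pinned at its bound has no headroom to drift, so it crosses a
decision threshold quickly when the class changes.

## Feature bank

All 26 variants share the saturating accumulate-and-scale smoother
`feat_i = clamp((feat_{i−1} + f(x_i))·b, lb, ub)`. Event features (ZCR,
MCR, SSC, WAM) contribute 100 per event (10 for WAM2, whose integrand is
already scaled up by the gain d = 16); magnitude features contribute
`|Δx|·d` (WFL), `|x|` (MAV1), `|MAV1_i − MAV1_{i−delay}|` (MAV2, whose
inner recursion uses the row's `b` and bound `ub1`, the outer EMA the
row's `c` and `ub2`) or `x²` (VAR). The slope-sign-change cascade is
implemented exactly in its printed branch order; `w` counts consecutive
candidate-direction samples (a change is accepted only once `w ≥ dmin`) and
`p` counts continuation samples of the accepted direction (a change is
*counted* only if `p < dmax`). One consequence of the verbatim cascade is a
single start-up event on monotone input — the initial "up" transition from
the zero state is itself a slope-sign change; the tests pin this behavior.

Initial state is `feat = lb`, everything else zero. Crossing hysteresis is
one-sided by construction: from state `s = 0` only an excursion above
`+hyst` fires, from `s = 1` only one below `−hyst`.

Batch execution runs through a single numba kernel (the recursions are
inherently sequential); a pure-Python per-sample `FeatureStream` mirrors
the kernel and the suite asserts bit-exact equivalence between the two on
every variant, which is also the embedded-parity argument: any
implementation of the same integer recursion must reproduce these values
exactly. A floating-point reference (same recursions, no truncation) is
exposed for closed-form checks.

The effective smoothing time constant is `T = b/((1−b)·fs)`: 127.5 ms for
`b = 255/256` and 63.5 ms for `b = 254/256` at 2 kHz. The envelope smoother
uses the dyadic coefficient whose *time constant* is closest to 51 ms
(253/256, T ≈ 42 ms on the /256 grid — the grid brackets 51 ms with 42 and
63.5 ms and the lower neighbour is closer), selected by time-constant
error rather than coefficient error because the time constant is the
specified quantity.

## Synthetic corpus

The original single-subject recordings are not deposited, so the generator
defines the study conditions. Scale calibration: strong-contraction RMS is
300 ADC counts, which is what makes the shipped thresholds meaningful
(ZCR hysteresis 242 ≈ 0.8 σ of a strong contraction; Willison threshold 44
well below weak-contraction amplitudes; variance bound 4000 reachable from
the noise floor). The always-on white noise floor is 0.5 % of strong RMS
(~1.5 counts): the MAV1S bound of 600 implies the baseline rectified mean
times the EMA gain must stay below 600, i.e. baseline mean |x| < 2.4
counts — a 1 % floor would already pin MAV1S everywhere.

Contractions are 60–500 Hz Gaussian noise under a trapezoidal envelope
(rise/fall 50–150 ms); `weak` scales amplitude by 0.3; `short` is a train
of bursts (0.15–0.4 s each, 50–100 ms gaps — the co-contraction command
pattern) with a 2–10 Hz bump at each burst edge emulating the tissue
movement that overlays short contractions. Artifacts are lift-off (large
0.5–5 Hz excursion with millisecond-scale broadband "snaps" at the detach
instants), shock (sharp-onset damped 5–25 Hz oscillations) and vibration
(5–12 Hz tone, weak second harmonic); half of them carry an additional
small stationary in-band component (3–10 % of strong RMS). The key
modeling decision is that artifact energy inside the EMG band is
*impulsive* — the spectral tail of a mechanical event — rather than a
stationary EMG-like hiss: a stationary in-band artifact component at
contraction amplitude would be indistinguishable from EMG by construction
and contradicts the high accuracies such pipelines achieve on real data.

What passing tests on this corpus show: that the feature bank, training
machinery, quantization, debouncing and tolerant scoring interoperate and
can recover a class structure of realistic geometry at realistic sample
sizes. What they do not show: performance on real EMG, whose artifact
taxonomy, nonstationarity and inter-session variability the generator does
not model; the accuracies printed by the end-to-end tests characterize the
synthetic conditions, not the original recordings.

## Dataset pipeline

Windows (1 s, or 0.5–1.5 s varied for the recurrent models so that window
periodicity cannot be learned) are chopped per segment, small-signal
windows removed (envelope never exceeding 3× the noise-floor envelope:
such windows would not activate the drive), and the classes strictly
alternated so every boundary is a transition. Features run over the
concatenated stream — state flows across window boundaries exactly as it
would online — and are decimated to 40 Hz (250 Hz for the recurrent
models) by plain subsampling, the EMA having already band-limited them.

Correlation pruning removes one member of every pair with |r| > 0.9 on the
training partition. The scan keeps the *later* member in registry order:
within each family the specialized (bounded, hysteresis-tuned) variants
follow their plain parents, and on saturating data the pair correlates
highly while only the bounded variant retains the fast-transition property
it was built for; discarding it would systematically remove the better
feature (`keep="earlier"` is available). Min-max normalization to [−1, 1]
is fitted on training data only; out-of-range values extrapolate (no
clip), and the quantized path rounds to the 1024 = 1.0 grid. The 70/15/15
split assigns contiguous chunks of windows (sized for at least ~15
assignable chunks) greedily to the partition furthest below its target
share, so adjacent-sample correlation never leaks across partitions and
subtype shares track the corpus.

Samples within 100 ms after a target transition are excluded from every
*fit* (dropped rows for the static models, zero loss weights for the
recurrent one), mirroring their exclusion from the error calculation: they
carry settling-time ambiguity, not class information.

## Models and training

Feature subsets: the logistic regression uses the L1 path (30 log-spaced
penalties, densest-to-empty; the support nearest the budget, trimmed by
coefficient magnitude). The tree selects embedded-style: a split-capped
CART probe on all retained features picks its own splits greedily and its
Gini importances rank the subset — CART's split choice is itself a feature
selector, and a wrapper around the 26-feature bank confirmed it dominates
both the L1 path and greedy backward selection here. The networks reuse
the L1 path as a fast stand-in for sequential backward selection, which is
quadratic in the feature count when every step retrains a network;
`sbs_select` itself is implemented and tested.

The networks are one-hidden-layer satlins/purelin machines (the recurrent
variant adds a delay-1 hidden-to-hidden path, zero initial state, full
BPTT over padded sequences). They minimize a cross-entropy surrogate —
logistic loss on `4·(out − 0.5)` — which keeps the decision boundary
exactly at the 0.5 output threshold (512 quantized) while giving a smooth
gradient; the optimizer is full-batch Adam with gradient-norm clipping.
Three numerical choices matter for the hard-clipping activation: (i) the
training derivative of satlins keeps a 0.05 leak outside [−1, 1], because
a hard zero permanently silences any unit whose pre-activation escapes the
linear region; (ii) initial weights are scaled (2/√F input, 1/√H output)
so pre-activations reach the knees at initialization — a satlins network
initialized deep inside its linear region is a linear model and cannot
start learning XOR-type structure; (iii) each "epoch" of the stated
stopping rule (at most 1000/100 epochs, stop after 6 consecutive
validation failures, restore best-validation weights) wraps five optimizer
steps, since one first-order full-batch step is far smaller than one epoch
of a second-order optimizer.

Quantization multiplies every parameter by 1024 and rounds; forward passes
are pure integer arithmetic (products rescaled by `>> 10`, satlins clamp
at ±1024, threshold 512). Tree thresholds are floored on the raw integer
feature scale, so tree quantization changes no decision. Measured
disagreement between quantized and float network/regression decisions on
synthetic corpora is 0 %.

## Runtime post-processing

The debounce requires strictly more than `n_slope` consecutive equal
decisions before the output may switch (initial state: artifact — fail-safe
at power-up); a non-strict variant is available. Offline `n_slope` is 2
for the 40 Hz models and 3 for the 250 Hz recurrent model; online the
2 kHz models use 20 so the wall-clock delay stays comparable. The gated
output is either zero during artifacts ("off") or holds the last
contraction-phase envelope value ("hold"); the envelope is delayed 100 ms
(plus the 51 ms smoothing lag it already carries) to line up with the
decision that gates it.

## Evaluation

Contraction is the positive class. Tolerant accuracy excludes
`round(tol·rate)` samples after each target transition (post-transition
only), tallies the rest into a confusion matrix, and reports
`100·(TP+TN)/N` rounded half-up to two decimals. Reported grid accuracies
score the *quantized, debounced* decisions, with the recurrent hidden
state and the debounce state reset at each contiguous test-run boundary.

## Problem sizes

The end-to-end tests use 120 s per class (about 240 windows), scaled down
from the 870 s study corpus; the fidelity and oracle fixtures use 10–20 s
per class. These sizes were chosen as the smallest at which the split
granularity, the validation set for early stopping and the per-subtype
test counts are all comfortably populated; accuracies were stable
(tree 97.3–99.2 %, recurrent network 98.5–99.6 %) across five generator
seeds at this size.

## Known limitations

* The generator is a statistical caricature: no motor-unit physiology, no
  electrode-skin impedance dynamics, no inter-subject variability.
* The Levenberg–Marquardt optimizer of the original toolchain is replaced
  by Adam with the same architecture and stopping rules; the model class,
  not the optimizer, is treated as the specification.
* Online (2 kHz, no feature decimation) inference is modeled by the
  `stream` verb but not cycle-accurately benchmarked; instruction-level
  emulation of the target microcontroller is out of scope.
* The fixed-point feature recursions are validated by bit-exact
  cross-implementation equivalence, not against an idealized real-valued
  EMA — the floor-truncation bias analysed above makes the latter
  comparison meaningful only for large-valued features.
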