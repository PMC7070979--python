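# emggate

Motion-artifact suppression for insulated (capacitively coupled) surface
EMG, built the way it runs on a prosthesis microcontroller: a bank of
fixed-point streaming time-domain features feeds a shallow classifier whose
debounced binary decision gates a delayed EMG envelope, so the prosthesis
drive is activated only during true muscle contractions.

Motion artifacts — sensor lift-off, mechanical shocks, vibration — are the
main failure mode of myoelectric control in the real world. They overlap
the 60–500 Hz EMG band, so no filter can remove them; the signal must be
*classified*, sample by sample, into contraction vs. artifact. This package
is for biosignal/rehabilitation engineers who want a faithful,
testable software model of such an embedded pipeline: every coefficient is
a dyadic rational applied as a multiply-and-shift, every feature is an
integer state machine, and the quantized models are bit-exact
re-implementations of their floating-point counterparts.

## The model

Every feature is an event or magnitude stream pushed through the same
exponentially decaying moving average (EMA) with saturation:

```
feat_i = clamp( (feat_{i-1} + f(x_i)) · b ,  lb, ub ),    b = m / 2^k
```

where `x_i` is the comb-, lowpass- (531 Hz) and highpass-filtered (60 Hz)
signal at 2 kHz, and `f` defines the family: zero/mean-crossing events
beyond a hysteresis (ZCR, MCR), slope-sign changes with run-length gates
(SSC), scaled first differences (WFL), rectified magnitude and its delayed
difference (MAV1/MAV2), threshold exceedances (WAM), or the squared signal
(VAR). 26 parameter variants are shipped, registry-exact. The effective
smoothing time constant is `T = b/((1−b)·fs)` — 63.5 ms for `b = 254/256`
and 127.5 ms for `b = 255/256` at 2 kHz.

Four classifier families consume the (min-max normalized, ±1024
fixed-point) features: L1-selected/L2-trained logistic regression, a
split-capped Gini decision tree on raw features, a one-hidden-layer
satlins/purelin network, and the same network with a delay-1 recurrent
hidden path trained by BPTT at 250 Hz. Decisions pass an `n_slope` debounce
(a class switch requires more than `n_slope` consecutive equal decisions)
and gate the 51 ms-smoothed, 100 ms-delayed envelope. Accuracy is scored
with transition tolerance: samples within 100 ms (training) / 150 ms (test)
after a ground-truth class change are excluded, so models pay for
sluggishness only beyond the tolerated settling window.

The single-subject study recordings behind the original parameterization
are not public, so `emggate.synthetic` generates labeled
contraction/artifact corpora with the same statistical structure (strong /
weak / short-burst-train contractions; lift-off, shock, vibration
artifacts with impulsive in-band bleed) on the integer scale that makes the
shipped thresholds meaningful.

## Worked example

Train the minimal-footprint model — a 3-feature decision tree — on a
seeded synthetic corpus (60 s per class) and stream a signal through it:

```
$ emggate train --family tree --n-features 3 --seed 7 \
      --budget-contraction 60 --budget-artifact 60 --out tree.json
test accuracy (quantized, debounced, 150 ms tolerance): 98.38 %
tree.json
```

The trained model selected the features `ZCR2S`, `SSC1S`, `WAM1` — a
bounded zero-crossing rate, a bounded slope-sign-change rate and the
Willison amplitude. The printed number is the transition-tolerant test
accuracy of the *quantized* tree after `n_slope = 2` debouncing: 98.38 %
of scored test samples (150 ms after each class change excluded) were
classified correctly. `emggate stream --model tree.json --input seg.txt
--policy off` then emits a four-column trace (raw decision, debounced
decision, delayed envelope, gated output); the gated column is zero during
detected artifacts and equals the envelope during contractions.

The same workflow is available from Python:

```python
from emggate.synthetic import GeneratorConfig, gen_corpus
from emggate.pipeline import (assemble_alternating, featurize_windows,
                              stratified_contiguous_split,
                              default_activation_threshold)
from emggate.evaluation import fit_model, evaluate_model

corpus = gen_corpus(GeneratorConfig(budget_contraction_s=60,
                                    budget_artifact_s=60, seed=7))
windows = assemble_alternating(corpus, window_s=1.0, seed=7,
                               activation_threshold=default_activation_threshold())
fd = featurize_windows(windows, rate_hz=40)
split = stratified_contiguous_split(windows, seed=7)
fm = fit_model("tree", fd, split, n_features=3, max_splits=4)
print(evaluate_model(fm, fd, split.test).accuracy)
```

Other CLI verbs: `simulate` (write a labeled corpus as text or WAV),
`features` (feature matrix of a signal file), `evaluate`, `sweep` (the full
family × feature-count accuracy grid).

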