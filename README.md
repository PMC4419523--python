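# memhnn

Behavioural simulator of a memristive hardware neural network that
recognises imagined vowels (/a/, /i/, /u/) from EEG.

The simulated system is a single-layer neuromorphic classifier: 32
pre-neurons drive a 32x6 cross-point array of analogue memristive (PCMO)
synapses, whose column currents integrate on six leaky integrate-and-fire
post-neurons; decision logic pairs the post-neurons into three groups
(/a/ vs /i/, /a/ vs /u/, /i/ vs /u/) and recognises the class that wins
two groups first.  The package models every stage:

* **device** — a synapse conductance `g in [1.5, 5.5] nA/V` with ohmic
  reads, a 1 V switching threshold, and saturating state-dependent
  updates `dg = alpha (g_max - g)` (potentiation) / `-alpha (g - g_min)`
  (depression), reproducing the measured 0.2-0.5 nA/V per-pulse change in
  the low state and 0.02-0.05 nA/V near saturation;
* **crossbar** — the modified half-bias write scheme (V_H/V_CM/V_L =
  5/4/3 V): targeted cells see exactly +-2 V, every half-selected cell
  stays within the 1 V threshold, and supervised potentiation/depression
  phases train the array on labelled 32-bit feature codes;
* **neuron / decision** — inverting leaky integrators
  `v(t) = v_sat + (v_reset - v_sat) e^(-t/tau)` with a 3 V comparator,
  refractory reset to 4 V, and first-to-fire pairwise majority voting
  with a decision latch;
* **eeg** — the feature front-end: 8-30 Hz Butterworth band-pass,
  baseline correction, (noise-assisted) multivariate empirical mode
  decomposition, dominant alpha-band (8-12 Hz) IMF selection, pairwise
  common spatial patterns, and binarization to 32-bit codes;
* **synth** — seeded generators for class-structured synthetic EEG and
  for prototype-plus-flips feature codes (65 training / 15 testing), so
  the whole chain runs and is testable without any recording.

It is written for researchers in neuromorphic computing and BCI signal
processing who want a reproducible software twin of such a system to
study learning schemes, device non-idealities and front-end choices.

## Worked example

```python
from memhnn import CodeGenConfig, MemristiveHNN, gen_codes

train, test, prototypes = gen_codes(CodeGenConfig(seed=0))
model = MemristiveHNN(train)          # 32x6 array, default device constants
results = model.fit()                 # half-bias training + comparator calibration
print(results.summary(test))
```

prints

```
Memristive HNN fit
==================
array                 : 6 x 32 = 192 cells
epochs run            : 1
training accuracy     : 1.000
conductance range     : [1.543, 5.180] nA/V
firing threshold      : 39.88 nA (margin 49.85 / 54.83)
calibrated gain       : 0.02525 V/nA
train currents separable: False
test accuracy         : 1.000 (15/15)
```

Reading this: the 192 synapses started at the mid conductance 3.5 nA/V
and one epoch of potentiation/depression already separates the classes;
conductances span almost the full device range.  Calibration placed the
comparator's firing-threshold current at 39.9 nA — 0.8 x the weakest
class-row response seen on the training set (49.9 nA) — so the two
neurons representing a code's class always fire, and fire first; the
winner/other current *populations* overlap in absolute terms
("separable: False", a consequence of varying code weight), which is why
recognition is by firing order with a decision latch rather than by an
absolute current cut.  All 15 held-out codes are recognised, and on every
correctly recognised trial exactly two of the six neurons fire before the
decision latches.

Per-trial details (fire times, per-group winners, fire counts) come from
`results.report(test)`; integrator traces for a single code from
`results.trial(code)` (plot with `memhnn.plotting.plot_traces`).

The same interface runs from synthetic EEG instead of synthetic codes:

```python
from memhnn import EEGGenConfig, MemristiveHNN, gen_eeg

dataset = gen_eeg(EEGGenConfig(seed=0))            # 81 trials, 16 ch, 250 S/s
model = MemristiveHNN.from_eeg(dataset)            # band-pass -> MEMD -> CSP -> bits
results = model.fit()
print(results.score(model.test_codes))             # 1.0 at this seed
```

## Command line

The `memhnn` console script exposes the stages as subcommands, each
writing delimited-text outputs plus a manifest (config hash, seed,
version) for bit-exact reproduction:

```bash
memhnn simulate-device --pulses 200 --out dev/     # pulse-train response
memhnn gen-data --kind codes --seed 0 --out data/
memhnn run-all --path eeg --seed 0 --out run/      # full chain end to end
```

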