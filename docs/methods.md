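# Methods

`memhnn` is a behavioural simulator of a small neuromorphic recogniser for
imagined-speech EEG: 32 pre-neurons drive a 32x6 cross-point array of
analogue memristive synapses whose summed currents feed six leaky
integrate-and-fire (LIF) post-neurons, paired into three groups that
compare the vowels /a/ vs /i/, /a/ vs /u/ and /i/ vs /u/.  This note
records the models, the defaults and the design choices, and what the
synthetic-data experiments do and do not demonstrate.

## Synapse model

A device is one conductance `g` in nA/V, bounded by `g_min = 1.5` and
`g_max = 5.5`.  Reads are ohmic (`I = g v`, valid for |v| <= 1 V).  Writes
are threshold-gated: pulses with |v| <= V_R = 1 V leave the state
unchanged, which is what makes the half-bias write scheme safe.  A
supra-threshold pulse moves the state by a fixed fraction of the remaining
headroom,

    potentiation:  g <- g + alpha (g_max - g)
    depression:    g <- g - alpha (g - g_min)

with symmetric `alpha = 0.35 / (g_max - g_min) = 0.0875` at defaults.
Only the endpoint behaviour of the device is documented (per-pulse change
0.2-0.5 nA/V in the low state, falling to 0.02-0.05 nA/V near saturation,
with saturating, symmetric pulse-train responses); the exponential-
saturation rule is the simplest form matching both windows: 0.35 nA/V at
`g_min` and 0.035 nA/V at 90 % of the range.  Note the rule implies the
per-pulse change drops *below* 0.02 nA/V once the remaining headroom falls
under ~5.7 % of the range — an unavoidable consequence of any
saturating-update model, so the near-saturation window is asserted at
exactly 10 % headroom.  Two optional non-idealities are modelled and off
by default: per-pulse rate jitter (uniform in the documented window,
seeded) and sub-threshold disturb (a configurable fraction of the full
update, for studying unintended half-select switching).

## Crossbar and the modified half-bias learning scheme

Rows are post-neuron (top-electrode) lines, columns pre-neuron
(bottom-electrode) lines; the default 6x32 array holds 192 cells, all
initialised to the mid conductance 3.5 nA/V.  Training a labelled 32-bit
code takes a potentiation phase and a depression phase per presentation:

* potentiation — desired rows at V_L = 3 V, active ('1') columns at
  V_H = 5 V, everything else at V_CM = 4 V.  Targeted cells see
  BE - TE = +2 V; every half-selected cell sees at most 1 V = V_R.
* depression — depressed rows at V_H, active columns at V_L; targeted
  cells see -2 V.

V_CM is not documented; the midpoint of V_H and V_L is the unique choice
bounding all half-selected magnitudes by V_R.  Which rows the depression
phase targets is also not documented.  The default here is the label
complement: every row whose desired output is 0 is depressed at the active
columns.  The narrower alternative (only the in-group rivals of the code's
class) is available as `depression_mode="rival_active"`, along with
`"winner_inactive"` and `"both"`; the label-complement default is the one
that reliably reproduces the two-of-six firing signature (see *Comparator
calibration* below), because it also un-learns the class rows of the third
vowel's groups, which otherwise keep elevated currents through prototype
bits shared between classes.  Training iterates the dataset for up to 20
epochs with one pulse per phase, stopping early once every training code
is recognised.

## LIF post-neuron

The integrator output starts at the reset level 4 V and relaxes toward a
saturation level set by the input current,

    v(t)   = v_sat + (v_reset - v_sat) exp(-t / tau)
    v_sat  = v_reset - gain * I

so the early drop is almost linear and the neuron fires iff the output
crosses the comparator threshold V_TH = 3 V (strict crossing; the
closed-form crossing time must also fall inside the integration window).
Defaults: tau = 10 ms, t_integrate = 50 ms, t_refractory = 10 ms,
dt = 0.1 ms.  The stepped simulation uses the exact exponential update per
step, so it matches the closed form to round-off; fire times are taken
from the closed form.  After the integration phase every trace is
discharged back to the reset level (refractory), clearing the array for
the next code.

## Decision logic and comparator calibration

Within each group the member that fires first wins (a firing member beats
a silent one; an exact tie abstains); the recognised class is the one
winning at least two groups, and a cyclic outcome abstains.  Recognition
is *latched*: fire events are consumed in time order and integration ends
the moment some class has won two groups — that is when the refractory
phase begins in the hardware — so the system's fire count on a recognised
input is the number of crossings up to the decision.  The full-window
crossing record is retained separately for diagnostics.

The transimpedance gain is a bring-up parameter, not a published constant.
`fit()` calibrates it from the trained array: the firing-threshold current
is placed at 0.8 x the smallest training-set current of any class-labelled
(winner) row, so every class neuron reliably fires on its own class while
strongly depressed rows saturate above V_TH and stay silent.  An absolute
mid-gap threshold is *not* used because binary input codes vary in weight
(number of active bits), which moves all six currents of a trial up or
down together; with the synthetic generator's i.i.d. bit flips the winner
and non-winner current populations overlap through this common mode, while
their firing *order* within a trial is weight-invariant and cleanly
separated.  On a correctly recognised input the two class neurons fire
first and the latch closes after the second fire signal — the measured
"two of six neurons fire" signature.  This is a real prediction, not a
tautology: a non-class neuron firing before the second class neuron still
inflates the count (and does, under the rival-only depression variant).

## EEG front-end

The chain is: 8-30 Hz Butterworth band-pass (order 5, zero-phase
forward-backward), baseline correction against the pre-stimulus window,
multivariate empirical mode decomposition, selection of the dominant
alpha-band (8-12 Hz) IMF, pairwise CSP, binarization to 32 bits.  An
artifact-removal hook exists as an optional pass-through (criteria for the
recording study's ICA step are unpublished).

**MEMD.**  Implemented in-package: projections onto 64 low-discrepancy
(Hammersley) directions on the channel-space sphere, cubic-spline envelopes
through the multichannel values at each projection's extrema (mirrored end
extrema, natural end conditions, numba-accelerated), Rilling stopping
(thresholds 0.05/0.5, tolerance 0.05, at most 15 siftings), at most 8
IMFs with an early stop once the residual RMS falls below 1 % of the
input.  IMFs plus residual reconstruct the input to machine precision by
construction.  The pipeline runs MEMD *noise-assisted*: two independent
white Gaussian channels at 0.25 x the signal RMS (seeded) are appended
before sifting and stripped afterwards.  Without assistance a 10 Hz
narrow-band component sits on a boundary of MEMD's dyadic filter bank and
splits between two modes on a per-trial coin flip, which caps downstream
recovery regardless of effect size; the noise channels anchor the filter
bank so the alpha component lands in a single mode.

**Alpha-IMF selection.**  The dominant alpha IMF is the one with the
largest mean in-band spectral power (periodogram, averaged over channels);
a pure in-band power *fraction* would favour negligible slow modes that
happen to lie inside the band.  Ties go to the fastest mode.

**CSP.**  Per class pair, trial covariances are trace-normalised and
averaged; filters solve `C1 w = lambda (C1 + C2) w`.  Covariances are
shrunk 10 % toward a trace-scaled identity (small-sample stabilisation;
~22 trials per class at 16 channels), and a 1e-6 trace-scaled ridge guards
near-singular composites.  Six filters per pair are kept (3 largest + 3
smallest eigenvalues): with this little training data the interior
eigenvector features are noise that dilutes the binary code.  Features are
log variance ratios of the filtered task-window signal.

**Binarization.**  The three 6-feature pair blocks are concatenated
(18 features) and zero-padded to 32 bits.  Each feature is cut at a
threshold fitted on training features only.  The default cut is the
midpoint of a one-dimensional 2-means (Otsu-style) cluster split rather
than the median: with three classes a pairwise-CSP feature is bimodal with
a 1:2 class split, and the median lands inside the thicker mode,
randomising the bit for two of the three classes (this measurably caps
nearest-prototype recovery at ~87 %).  A `median` method is retained for
comparison.  Bits are 1 on strict exceedance; a feature exactly at the
cutoff maps to 0.  Train/test splitting is stratified and seeded; CSP
filters and cutoffs never see test trials.  Identical codes are collapsed
with a logged count, so the 65/15 split can yield slightly fewer distinct
training codes — the recording study likewise reports 65/15 *distinct*
patterns distilled from ~300 trials.

## Synthetic data

**EEG generator** (seeded): 16 channels (64 supported) at 250 samples/s,
3.5 s trials partitioned into cue (0-1 s), baseline (1-2 s), preparation
(2-2.25 s) and imagery (2.25-3.5 s) windows; pink-noise (1/f) background
at 10 uV RMS on every channel; during the imagery window a Hann-enveloped
10 Hz oscillation, with random phase and log-normal (sigma = 0.2)
amplitude jitter, mixed through one of three orthogonal unit-norm spatial
patterns supported on disjoint 4-channel groups.  `effect_size` (planted
amplitude over noise RMS) defaults to 2.0, the smallest round value at
which the full front-end recovers the planted structure with >90 %
held-out nearest-prototype accuracy across seeds — the property the
generator exists to certify; at this setting imagery-window alpha power on
pattern channels exceeds baseline by well over the documented 2x.
27 trials per class (81 total) cover the 65/15 split at desk scale.

**Code generator** (seeded): three balanced (16-of-32) prototypes with
pairwise Hamming distance >= 12, one per vowel — balance mirrors the
threshold binarizer's output statistics; samples are prototypes with
i.i.d. bit flips at p = 0.05, emitted interleaved and pairwise distinct,
65 training and 15 testing codes.

What passing these synthetic experiments shows: the learning scheme,
decision logic, calibration and front-end interact correctly on data with
the statistical structure the system assumes (class-dependent alpha-band
spatial patterns; near-prototype binary codes).  What it does not show:
performance on recorded EEG, where artifacts, non-stationary rhythms,
volume conduction and inter-subject variability are all absent from the
generator, and where absolute fire times depend on unpublished RC
constants (only their order is meaningful here).

## Numerical choices and degenerate inputs

Exact threshold equality never fires (closed-form boundary); within-group
simultaneous fires abstain the group; a no-majority (cyclic) outcome
abstains the trial and both are visible in reports.  Sub-threshold pulse
sequences leave conductances bit-identical (no drift by construction).
Constant or monotone signals return zero IMFs with the input as residual;
band edges, window bounds, conductance bounds and label sets are
validated.  All randomness (generators, NA-MEMD, optional device jitter)
flows from explicit seeds; identical seeds give bit-identical datasets,
trained arrays and reports.

## Known limitations

* No wire resistance, sneak paths, retention/endurance or electro-thermal
  physics; the read is an ideal virtual-ground row sum.
* No comparator hysteresis, op-amp offsets or analog noise in the neuron.
* The depression targeting, V_CM, neuron RC constants, CSP filter count
  and bit layout are reconstructions of undocumented hardware choices;
  each is configurable, and the defaults are the combination validated by
  the end-to-end experiments above.
* MEMD uses natural-spline envelopes with mirrored end extrema; other EMD
  variants (not-a-knot boundaries, different stopping rules) yield
  slightly different mode splits.
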